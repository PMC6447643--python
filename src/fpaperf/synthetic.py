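"""Synthetic acquisition specs, aortic enhancement curves, and 4-D phantoms.

Everything downstream of this module (fitting, protocol simulation,
perfusion mapping, statistics) is exercised on data produced here, with
known ground truth and seeded determinism.

The generator enforces the timing rule by construction: given a shape
parameter ``b`` and a target base-to-peak interval ``T_i/2 + d``, it solves
for ``tau`` using the linear scaling of the second-derivative landmark in
``tau`` at fixed ``b``.

Myocardial voxels follow a one-compartment forward model with no venous
outflow over the measurement window:

    HU_v(t) = baseline + (P_v * rho / 60) * int_{t0}^{t} c_a(s) ds

with ``c_a`` the baseline-subtracted aortic curve, ``rho`` the tissue
density (g/mL) and ``P_v`` the voxel's true perfusion (mL/min/g).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DimensionError, InvalidParameterError
from .gamma_model import GammaParams, gamma_curve, gamma_cumulative, landmark_fraction

__all__ = [
    "CONDITION_DEFAULTS",
    "AcquisitionSpec",
    "CurveModel",
    "AorticCurve",
    "PhantomSpec",
    "DynamicSeries",
    "make_acquisition_spec",
    "generate_aortic_curve",
    "sample_curve",
    "generate_dynamic_phantom",
    "make_phantom",
]

# Cohort means under rest/stress conditions (heart rate in beats/min,
# absolute peak aortic enhancement in HU).
CONDITION_DEFAULTS: Mapping[str, Mapping[str, float]] = {
    "rest": {"heart_rate": 84.86, "peak_hu": 640.07},
    "stress": {"heart_rate": 93.04, "peak_hu": 540.07},
}


@dataclass(frozen=True)
class AcquisitionSpec:
    """Injection/gating protocol for one contrast-enhanced acquisition."""

    weight: float  # kg
    condition: str  # "rest" | "stress"
    heart_rate: float  # beats/min
    contrast_dose: float = 1.0  # mL/kg
    injection_rate: float = 5.0  # mL/s
    saline_dose: float = 0.5  # mL/kg
    gating_phase: float = 0.75  # fraction of the R-R interval
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.weight > 0):
            raise InvalidParameterError(f"weight must be > 0, got {self.weight}")
        if self.condition not in CONDITION_DEFAULTS:
            raise InvalidParameterError(
                f"condition must be one of {sorted(CONDITION_DEFAULTS)}"
            )
        if not (self.heart_rate > 0):
            raise InvalidParameterError("heart_rate must be > 0")
        if not (self.contrast_dose > 0 and self.injection_rate > 0):
            raise InvalidParameterError("contrast dose and rate must be > 0")
        if not (0 <= self.gating_phase < 1):
            raise InvalidParameterError("gating_phase must be in [0, 1)")

    @property
    def injection_time(self) -> float:
        """Contrast injection duration T_i = dose * weight / rate (s)."""
        return self.contrast_dose * self.weight / self.injection_rate

    @property
    def rr_interval(self) -> float:
        """Cardiac cycle length (s)."""
        return 60.0 / self.heart_rate

    def gate_times(self, duration: float) -> np.ndarray:
        """ECG-gate timestamps at ``gating_phase`` of each R-R interval."""
        rr = self.rr_interval
        n = int(np.ceil(duration / rr))
        return (np.arange(n) + self.gating_phase) * rr


def make_acquisition_spec(
    weight: float,
    condition: str = "rest",
    heart_rate: float | None = None,
    seed: int = 0,
    **kwargs,
) -> AcquisitionSpec:
    """Build an :class:`AcquisitionSpec` with condition-based defaults.

    When ``heart_rate`` is omitted, the cohort mean for the requested
    condition is used.
    """
    if condition not in CONDITION_DEFAULTS:
        raise InvalidParameterError(
            f"condition must be one of {sorted(CONDITION_DEFAULTS)}"
        )
    if heart_rate is None:
        heart_rate = CONDITION_DEFAULTS[condition]["heart_rate"]
    return AcquisitionSpec(
        weight=weight, condition=condition, heart_rate=heart_rate, seed=seed,
        **kwargs,
    )


@dataclass(frozen=True)
class CurveModel:
    """Ground-truth aortic curve parameters used by the generator."""

    A: float  # HU above baseline
    tau: float  # s
    b: float  # dimensionless, > 2
    C: float  # baseline HU
    t0: float  # arrival delay, s
    dispersion_delay: float  # generator's true dispersion delay, s
    noise_sd: float  # HU

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.tau > 0):
            raise InvalidParameterError("A and tau must be > 0")
        if self.b <= 2:
            raise InvalidParameterError(
                f"shape b must exceed 2 (base landmark ill-posed), got {self.b}"
            )
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.t0 < 0:
            raise InvalidParameterError("t0 must be >= 0")

    @property
    def params(self) -> GammaParams:
        """Equivalent fitted-parameter view (for analytic evaluation)."""
        return GammaParams(A=self.A, tau=self.tau, b=self.b, C=self.C, t0=self.t0)

    @property
    def t_peak(self) -> float:
        return self.t0 + self.tau

    def __call__(self, t):
        """Noiseless enhancement at times ``t`` (absolute HU)."""
        return gamma_curve(t, self.A, self.tau, self.b, self.C, self.t0)


@dataclass(frozen=True)
class AorticCurve:
    """Sampled aortic time-density curve."""

    times: np.ndarray  # s, strictly increasing
    enhancement: np.ndarray  # HU
    baseline: float | None = None  # pre-contrast HU, if known

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.enhancement, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise DimensionError("times and enhancement must be equal-length 1-D")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise InvalidParameterError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "enhancement", y)

    @property
    def n_samples(self) -> int:
        return int(self.times.size)


def _solve_tau(target_tg: float, b: float) -> float:
    # T_g = (1 - x*(b)) * tau  =>  tau = target / (1 - x*)
    frac = 1.0 - landmark_fraction(b)
    return target_tg / frac


def _default_duration(model_t_peak: float) -> float:
    return max(25.0, model_t_peak + 8.0)


def build_curve_model(
    spec: AcquisitionSpec,
    peak_hu: float | None = None,
    b: float = 3.0,
    baseline_hu: float = 40.0,
    t0: float = 8.0,
    dispersion_delay: float = 2.3,
    noise_sd: float = 10.0,
) -> CurveModel:
    """Solve the curve model whose base-to-peak interval is T_i/2 + delay."""
    if b <= 2:
        raise InvalidParameterError(f"shape b must exceed 2, got {b}")
    if peak_hu is None:
        peak_hu = CONDITION_DEFAULTS[spec.condition]["peak_hu"]
    amplitude = peak_hu - baseline_hu
    if amplitude <= 0:
        raise InvalidParameterError("peak_hu must exceed baseline_hu")
    target = spec.injection_time / 2.0 + dispersion_delay
    tau = _solve_tau(target, b)
    return CurveModel(
        A=amplitude, tau=tau, b=b, C=baseline_hu, t0=t0,
        dispersion_delay=dispersion_delay, noise_sd=noise_sd,
    )


def sample_curve(
    model: CurveModel,
    times: np.ndarray,
    rng: np.random.Generator | None = None,
) -> AorticCurve:
    """Sample the model at ``times``, adding Gaussian HU noise."""
    times = np.asarray(times, dtype=float)
    y = model(times)
    if model.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        y = y + rng.normal(0.0, model.noise_sd, size=times.shape)
    return AorticCurve(times=times, enhancement=y, baseline=model.C)


def generate_aortic_curve(
    spec: AcquisitionSpec,
    rng: np.random.Generator | None = None,
    duration: float | None = None,
    sampling_interval: float | None = None,
    **model_config,
) -> tuple[AorticCurve, CurveModel]:
    """Generate an aortic enhancement curve for an acquisition spec.

    The noiseless curve's base-to-peak interval equals
    ``T_i/2 + dispersion_delay`` by construction.  Sampling defaults to
    one sample per cardiac gate; pass ``sampling_interval`` for a finer
    monitoring cadence.

    Accepted ``model_config`` keys: ``peak_hu``, ``b``, ``baseline_hu``,
    ``t0``, ``dispersion_delay``, ``noise_sd``.
    """
    model = build_curve_model(spec, **model_config)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if duration is None:
        duration = _default_duration(model.t_peak)
    if sampling_interval is None:
        times = spec.gate_times(duration)
    else:
        times = np.arange(0.0, duration, sampling_interval)
    return sample_curve(model, times, rng), model


@dataclass(frozen=True)
class PhantomSpec:
    """Static anatomy of the digital phantom.

    ``true_perfusion`` is a full-grid array in mL/min/g; values outside the
    myocardium mask are ignored.
    """

    grid_shape: tuple[int, int, int]
    voxel_size: float  # mm, isotropic
    aorta_mask: np.ndarray
    myocardium_mask: np.ndarray
    true_perfusion: np.ndarray
    tissue_density: float = 1.05  # g/mL
    baseline_hu_myo: float = 45.0

    def __post_init__(self) -> None:
        shape = tuple(self.grid_shape)
        for name in ("aorta_mask", "myocardium_mask", "true_perfusion"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise DimensionError(f"{name} shape {arr.shape} != grid {shape}")
        if np.any(np.asarray(self.aorta_mask) & np.asarray(self.myocardium_mask)):
            raise InvalidParameterError("aorta and myocardium masks overlap")
        if np.any(np.asarray(self.true_perfusion) < 0):
            raise InvalidParameterError("true_perfusion must be >= 0")
        if not (self.tissue_density > 0):
            raise InvalidParameterError("tissue_density must be > 0")
        if not (self.voxel_size > 0):
            raise InvalidParameterError("voxel_size must be > 0")

    @property
    def voxel_volume_ml(self) -> float:
        return (self.voxel_size**3) * 1e-3


def make_phantom(
    grid_shape: tuple[int, int, int] = (32, 32, 16),
    voxel_size: float = 1.0,
    perfusion: float = 1.5,
    insert_perfusion: float | None = None,
    tissue_density: float = 1.05,
    baseline_hu_myo: float = 45.0,
) -> PhantomSpec:
    """Build a simple cylindrical phantom: central aorta, annular myocardium.

    ``insert_perfusion`` carves a low-perfusion wedge (x above centre) out
    of the myocardium, emulating a stenosed territory.
    """
    nx, ny, nz = grid_shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    r = np.hypot(xx - cx, yy - cy)
    r_aorta = max(min(nx, ny) / 10.0, 1.5)
    r_in, r_out = min(nx, ny) / 5.0, min(nx, ny) / 2.5
    aorta2d = r <= r_aorta
    myo2d = (r >= r_in) & (r <= r_out)
    aorta = np.repeat(aorta2d[:, :, None], nz, axis=2)
    myo = np.repeat(myo2d[:, :, None], nz, axis=2)

    perf = np.zeros(grid_shape)
    perf[myo] = perfusion
    if insert_perfusion is not None:
        wedge = myo & np.repeat((xx > cx + r_in)[:, :, None], nz, axis=2)
        perf[wedge] = insert_perfusion
    return PhantomSpec(
        grid_shape=tuple(grid_shape), voxel_size=voxel_size,
        aorta_mask=aorta, myocardium_mask=myo, true_perfusion=perf,
        tissue_density=tissue_density, baseline_hu_myo=baseline_hu_myo,
    )


@dataclass(frozen=True)
class DynamicSeries:
    """ECG-gated 4-D phantom series: one HU volume per cardiac gate."""

    gate_times: np.ndarray
    volumes: np.ndarray  # (n_gates, *grid_shape)
    spec: AcquisitionSpec
    phantom: PhantomSpec
    curve_model: CurveModel

    def __post_init__(self) -> None:
        gt = np.asarray(self.gate_times, dtype=float)
        vols = np.asarray(self.volumes, dtype=float)
        if vols.shape != (gt.size, *self.phantom.grid_shape):
            raise DimensionError(
                f"volumes shape {vols.shape} incompatible with "
                f"{gt.size} gates on grid {self.phantom.grid_shape}"
            )
        object.__setattr__(self, "gate_times", gt)
        object.__setattr__(self, "volumes", vols)

    @property
    def n_gates(self) -> int:
        return int(self.gate_times.size)

    def roi_curve(self, mask: np.ndarray) -> np.ndarray:
        """Mean HU over ``mask`` at every gate."""
        m = np.asarray(mask, dtype=bool)
        return self.volumes[:, m].mean(axis=1)

    def aortic_curve(self) -> AorticCurve:
        """Aortic-ROI time-density curve of the series."""
        return AorticCurve(
            times=self.gate_times,
            enhancement=self.roi_curve(self.phantom.aorta_mask),
            baseline=self.curve_model.C,
        )


def generate_dynamic_phantom(
    spec: AcquisitionSpec,
    phantom: PhantomSpec,
    model: CurveModel,
    duration: float | None = None,
    rng: np.random.Generator | None = None,
) -> DynamicSeries:
    """Forward-simulate the gated volume series for a phantom.

    Aorta voxels follow the aortic curve; myocardial voxels accumulate the
    baseline-subtracted aortic input according to their true perfusion;
    background stays at 0 HU.  Per-voxel Gaussian noise with the model's
    ``noise_sd`` is added to every gate.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if duration is None:
        duration = _default_duration(model.t_peak)
    gate_times = spec.gate_times(duration)

    aorta = np.asarray(phantom.aorta_mask, dtype=bool)
    myo = np.asarray(phantom.myocardium_mask, dtype=bool)
    perf_myo = np.asarray(phantom.true_perfusion)[myo]
    rho = phantom.tissue_density

    aorta_vals = model(gate_times)
    cumulative = gamma_cumulative(model.params, gate_times)  # HU*s

    n = gate_times.size
    vols = np.zeros((n, *phantom.grid_shape))
    for k in range(n):
        vol = vols[k]
        vol[aorta] = aorta_vals[k]
        vol[myo] = phantom.baseline_hu_myo + perf_myo * rho / 60.0 * cumulative[k]
        if model.noise_sd > 0:
            vol += rng.normal(0.0, model.noise_sd, size=vol.shape)
    return DynamicSeries(
        gate_times=gate_times, volumes=vols, spec=spec,
        phantom=phantom, curve_model=model,
    )
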