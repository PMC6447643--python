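"""Voxel-wise first-pass perfusion mapping from two gated volume scans.

Perfusion follows the lumped one-compartment relation: the global mean is

    P_AVE = 60 * dHU_AVE / (rho * C_in * (t2 - t1))    [mL/min/g]

and each voxel scales the global mean by its enhancement change relative to
the mask average, which makes the mask mean of the voxel map equal the
global mean identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DimensionError,
    InvalidEnhancementError,
    InvalidParameterError,
    NonPhysiologicalInputError,
)
from .gamma_model import GammaParams, gamma_cumulative, timing_landmarks
from .protocol import ProtocolConfig, ProtocolResult, run_protocol, ProtocolAcquisition
from .synthetic import DynamicSeries

__all__ = [
    "VolumePair",
    "PerfusionMap",
    "compute_cin",
    "fpa_map",
    "reference_retrospective",
    "low_dose_map",
    "pair_from_series",
]

DEFAULT_DENSITY = 1.05  # myocardial tissue density, g/mL


@dataclass(frozen=True)
class VolumePair:
    """The two volume scans plus geometry needed for perfusion mapping."""

    v1: np.ndarray  # HU
    v2: np.ndarray  # HU
    t1: float  # s
    t2: float  # s
    myocardium_mask: np.ndarray
    aorta_mask: np.ndarray
    voxel_volume: float  # mL

    def __post_init__(self) -> None:
        if not (self.t2 > self.t1):
            raise InvalidParameterError("t2 must be later than t1")
        shape = np.asarray(self.v1).shape
        for name in ("v2", "myocardium_mask", "aorta_mask"):
            if np.asarray(getattr(self, name)).shape != shape:
                raise DimensionError(f"{name} shape mismatch with v1 {shape}")
        if not (self.voxel_volume > 0):
            raise InvalidParameterError("voxel_volume must be > 0")


@dataclass(frozen=True)
class PerfusionMap:
    """Voxel-wise perfusion plus the intermediates that produced it."""

    voxel_perfusion: np.ndarray  # mL/min/g, full grid, 0 outside mask
    global_mean: float  # mL/min/g
    m_t: float  # compartment tissue mass, g
    c_in: float  # average arterial input, HU
    delta_hu_ave: float  # HU
    dmc_dt: float  # HU*mL/s
    t1: float = float("nan")
    t2: float = float("nan")

    def masked(self, mask: np.ndarray) -> np.ndarray:
        return self.voxel_perfusion[np.asarray(mask, dtype=bool)]


def compute_cin(
    pair: VolumePair,
    mode: str = "two_point",
    fitted: GammaParams | None = None,
    baseline: float | None = None,
) -> float:
    """Average aortic blood-pool enhancement between the two scans.

    ``two_point`` averages the baseline-subtracted aortic-ROI means of the
    two volumes; ``integral`` averages the fitted baseline-subtracted curve
    over [t1, t2] (requires ``fitted``).
    """
    aorta = np.asarray(pair.aorta_mask, dtype=bool)
    if not aorta.any():
        raise InvalidParameterError("aorta mask is empty")

    if mode == "two_point":
        if baseline is None:
            if fitted is None:
                raise InvalidParameterError(
                    "two_point mode needs a baseline (or fitted params)"
                )
            baseline = fitted.C
        roi1 = float(np.asarray(pair.v1)[aorta].mean()) - baseline
        roi2 = float(np.asarray(pair.v2)[aorta].mean()) - baseline
        c_in = 0.5 * (roi1 + roi2)
    elif mode == "integral":
        if fitted is None:
            raise InvalidParameterError("integral mode requires fitted params")
        area = gamma_cumulative(fitted, pair.t2) - gamma_cumulative(fitted, pair.t1)
        c_in = float(area) / (pair.t2 - pair.t1)
    else:
        raise InvalidParameterError(f"unknown C_in mode {mode!r}")

    if c_in <= 0:
        raise NonPhysiologicalInputError(
            f"non-positive arterial input C_in = {c_in:.3g} HU"
        )
    return float(c_in)


def fpa_map(
    pair: VolumePair,
    c_in: float,
    density: float = DEFAULT_DENSITY,
    allow_nonpositive: bool = False,
) -> PerfusionMap:
    """Voxel-wise perfusion from an enhancement change and arterial input.

    Raises :class:`InvalidEnhancementError` when the mean myocardial
    enhancement change is not positive (V2 not later on the upslope than
    V1), unless ``allow_nonpositive`` is set, in which case an all-zero map
    is returned.
    """
    if not (c_in > 0):
        raise NonPhysiologicalInputError("C_in must be > 0")
    myo = np.asarray(pair.myocardium_mask, dtype=bool)
    if not myo.any():
        raise InvalidParameterError("myocardium mask is empty")
    dt = pair.t2 - pair.t1

    delta_hu = np.asarray(pair.v2, dtype=float) - np.asarray(pair.v1, dtype=float)
    delta_myo = delta_hu[myo]
    delta_ave = float(delta_myo.mean())
    n_vox = int(myo.sum())
    m_t = density * pair.voxel_volume * n_vox
    dmc_dt = float(delta_myo.sum()) * pair.voxel_volume / dt

    if delta_ave <= 0:
        if not allow_nonpositive:
            raise InvalidEnhancementError(
                f"mean myocardial enhancement change {delta_ave:.3g} HU <= 0"
            )
        vox = np.zeros(delta_hu.shape)
        return PerfusionMap(
            voxel_perfusion=vox, global_mean=0.0, m_t=m_t, c_in=c_in,
            delta_hu_ave=delta_ave, dmc_dt=dmc_dt, t1=pair.t1, t2=pair.t2,
        )

    global_mean = 60.0 * delta_ave / (density * c_in * dt)
    vox = np.zeros(delta_hu.shape)
    vox[myo] = global_mean * delta_myo / delta_ave
    return PerfusionMap(
        voxel_perfusion=vox, global_mean=float(global_mean), m_t=m_t,
        c_in=c_in, delta_hu_ave=delta_ave, dmc_dt=dmc_dt,
        t1=pair.t1, t2=pair.t2,
    )


def pair_from_series(series: DynamicSeries, t1: float, t2: float) -> VolumePair:
    """Extract the volume pair at the gates nearest ``t1`` and ``t2``."""
    gt = series.gate_times
    i1 = int(np.argmin(np.abs(gt - t1)))
    i2 = int(np.argmin(np.abs(gt - t2)))
    if i2 <= i1:
        raise InvalidParameterError(
            f"selected gates not ordered: t1 -> gate {i1}, t2 -> gate {i2}"
        )
    return VolumePair(
        v1=series.volumes[i1], v2=series.volumes[i2],
        t1=float(gt[i1]), t2=float(gt[i2]),
        myocardium_mask=series.phantom.myocardium_mask,
        aorta_mask=series.phantom.aorta_mask,
        voxel_volume=series.phantom.voxel_volume_ml,
    )


def reference_retrospective(
    series: DynamicSeries,
    fitted: GammaParams | None = None,
) -> PerfusionMap:
    """Reference-standard map from the full retrospective series.

    Fits the aortic curve (unless ``fitted`` is given), selects the gates
    nearest the base and peak landmarks, and maps perfusion with the
    integral-mode arterial input.
    """
    from .gamma_model import fit_gamma

    if fitted is None:
        fitted = fit_gamma(series.aortic_curve())
    marks = timing_landmarks(fitted)
    pair = pair_from_series(series, marks.t_base, marks.t_peak)
    c_in = compute_cin(pair, mode="integral", fitted=fitted)
    return fpa_map(pair, c_in, density=series.phantom.tissue_density)


def low_dose_map(
    series: DynamicSeries,
    config: ProtocolConfig,
    d: float | None = None,
    cin_mode: str = "integral",
    monitoring_curve=None,
    fitted: GammaParams | None = None,
) -> tuple[PerfusionMap, ProtocolResult]:
    """Protocol-selected (prospective) perfusion map.

    Runs trigger detection and V1/V2 selection on ``monitoring_curve``
    (defaults to the gate-sampled aortic curve of the series), then maps
    perfusion from the selected pair.  ``cin_mode`` defaults to the fitted
    integral, mirroring the retrospective simulation of the prospective
    protocol; ``two_point`` uses only the two selected volumes.
    """
    from .gamma_model import fit_gamma

    if fitted is None:
        fitted = fit_gamma(series.aortic_curve())
    if monitoring_curve is None:
        monitoring_curve = series.aortic_curve()
    marks = timing_landmarks(fitted)
    acq = ProtocolAcquisition(
        spec=series.spec, gate_times=series.gate_times,
        curve=monitoring_curve, ideal_peak_time=marks.t_peak,
    )
    result = run_protocol(acq, config, d=d)
    pair = pair_from_series(series, result.v1_time, result.v2_time)
    c_in = compute_cin(pair, mode=cin_mode, fitted=fitted)
    return fpa_map(pair, c_in, density=series.phantom.tissue_density), result
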