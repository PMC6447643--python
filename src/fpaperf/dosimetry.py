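"""Dose bookkeeping: SSDE, DLP, and effective dose.

The size-specific dose estimate converts the 32-cm-phantom CTDIvol with the
standard exponential fit of the conversion factor against effective
diameter (valid for 6-55 cm):

    f32(d) = 3.704369 * exp(-0.03671937 * d)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DiameterRangeError, InvalidParameterError

__all__ = ["DoseParams", "ssde", "dlp", "effective_dose", "dose_report"]

_SSDE_A = 3.704369
_SSDE_B = 0.03671937
_DIAMETER_RANGE = (6.0, 55.0)  # cm, table validity


@dataclass(frozen=True)
class DoseParams:
    """Inputs of the dose chain."""

    ctdi_vol_32: float  # mGy
    effective_diameter: float  # cm
    scan_length: float  # cm
    k_factor: float = 0.014  # mSv / (mGy*cm), adult chest

    def __post_init__(self) -> None:
        for name in ("ctdi_vol_32", "effective_diameter", "scan_length", "k_factor"):
            if not (getattr(self, name) > 0):
                raise InvalidParameterError(f"{name} must be > 0")


def conversion_factor(effective_diameter: float) -> float:
    """32-cm-phantom size conversion factor f32(d)."""
    lo, hi = _DIAMETER_RANGE
    if not (lo <= effective_diameter <= hi):
        raise DiameterRangeError(
            f"effective diameter {effective_diameter} cm outside [{lo}, {hi}]"
        )
    return _SSDE_A * float(np.exp(-_SSDE_B * effective_diameter))


def ssde(ctdi_vol_32: float, effective_diameter: float) -> float:
    """Size-specific dose estimate in mGy."""
    if ctdi_vol_32 < 0:
        raise InvalidParameterError("CTDIvol must be >= 0")
    return conversion_factor(effective_diameter) * ctdi_vol_32


def dlp(ctdi_vol: float, scan_length: float) -> float:
    """Dose-length product in mGy*cm."""
    return ctdi_vol * scan_length


def effective_dose(ctdi_vol: float, scan_length: float, k_factor: float = 0.014) -> float:
    """Effective dose E = k * CTDIvol * L in mSv."""
    return k_factor * dlp(ctdi_vol, scan_length)


def dose_report(params: DoseParams) -> dict:
    """Full dose chain, with raw values and 1-decimal report rounding."""
    s = ssde(params.ctdi_vol_32, params.effective_diameter)
    e = effective_dose(params.ctdi_vol_32, params.scan_length, params.k_factor)
    e_size = effective_dose(s, params.scan_length, params.k_factor)
    return {
        "ctdi_vol_32_mgy": params.ctdi_vol_32,
        "ssde_mgy": s,
        "dlp_mgy_cm": dlp(params.ctdi_vol_32, params.scan_length),
        "effective_dose_msv": e,
        "size_specific_effective_dose_msv": e_size,
        "rounded": {
            "ssde_mgy": round(s, 1),
            "effective_dose_msv": round(e, 1),
            "size_specific_effective_dose_msv": round(e_size, 1),
        },
    }
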