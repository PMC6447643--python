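"""Method-agreement statistics.

OLS regression with Pearson r, RMS residuals about the identity line (RMSE)
and about the fitted line (RMSD), Bland-Altman bias and limits of
agreement, Lin's concordance correlation coefficient, and paired t tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DegenerateRegressorError,
    DegenerateTestError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = ["AgreementResult", "agreement", "paired_t"]


@dataclass(frozen=True)
class AgreementResult:
    slope: float
    intercept: float
    pearson_r: float
    ccc: float
    rmse: float
    rmsd: float
    bias: float
    loa_low: float
    loa_high: float
    t_stat: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def paired_t(a, b, zero_variance: str = "error") -> tuple[float, float]:
    """Two-sided paired t test on matched measurements.

    ``zero_variance`` controls behaviour when the differences have zero
    variance: ``"error"`` raises :class:`DegenerateTestError` (default);
    ``"convention"`` returns t = 0, p = 1 for identical samples and
    +/- inf, p = 0 for a constant nonzero shift.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError("paired samples must be equal-length 1-D")
    n = a.size
    if n < 2:
        raise InsufficientDataError("paired t requires n >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        if zero_variance == "convention":
            if diff[0] == 0:
                return 0.0, 1.0
            return float(np.sign(diff[0]) * np.inf), 0.0
        raise DegenerateTestError("differences have zero variance")
    t = float(diff.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return t, p


def agreement(x, y, literal_rms: bool = False) -> AgreementResult:
    """Full agreement panel of measurements ``y`` against reference ``x``.

    RMSE is the RMS residual about the identity line y = x; RMSD the RMS
    residual about the OLS fit of y on x (``literal_rms`` switches both to
    the literal square-root-of-the-residual-standard-deviation reading).
    CCC uses population moments: 2*s_xy / (s_x^2 + s_y^2 + (mx - my)^2).
    Bland-Altman: bias = mean(y - x), LoA = bias +/- 1.96 sd(y - x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("x and y must be equal-length 1-D")
    n = x.size
    if n < 3:
        raise InsufficientDataError("agreement requires n >= 3")
    if np.var(x) == 0 and np.var(y) == 0:
        raise DegenerateRegressorError("both samples are constant")
    if np.var(x) == 0:  # includes underflow of near-constant samples
        raise DegenerateRegressorError("reference sample is constant")

    fit = stats.linregress(x, y)
    resid_fit = y - (fit.slope * x + fit.intercept)
    resid_identity = y - x
    if literal_rms:
        rmse = float(np.sqrt(np.std(resid_identity, ddof=1)))
        rmsd = float(np.sqrt(np.std(resid_fit, ddof=1)))
    else:
        rmse = float(np.sqrt(np.mean(resid_identity**2)))
        rmsd = float(np.sqrt(np.mean(resid_fit**2)))

    mx, my = x.mean(), y.mean()
    s_xy = float(np.mean((x - mx) * (y - my)))
    s_x2 = float(np.mean((x - mx) ** 2))
    s_y2 = float(np.mean((y - my) ** 2))
    ccc = 2.0 * s_xy / (s_x2 + s_y2 + (mx - my) ** 2)

    diff = y - x
    bias = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    loa_low = bias - 1.96 * sd_diff
    loa_high = bias + 1.96 * sd_diff

    t_stat, p_value = paired_t(y, x, zero_variance="convention")

    return AgreementResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue), ccc=float(ccc),
        rmse=rmse, rmsd=rmsd, bias=bias,
        loa_low=float(loa_low), loa_high=float(loa_high),
        t_stat=t_stat, p_value=p_value, n=int(n),
    )
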