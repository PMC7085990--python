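"""Test-retest statistics: Bland-Altman, repeatability coefficient, Deming line.

All relative statistics use the symmetric within-pair relative difference
``d = 2 (x2 - x1) / (x1 + x2) * 100%``, which treats the two visits
interchangeably.  The repeatability coefficient (RC) is the bound below
which the absolute difference between two repeated measurements falls for
95% of pairs; several near-equivalent conventions circulate in the
imaging-biomarker literature, so the one used is always named in the
result rather than left implicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import InsufficientDataError, KineticsError

__all__ = [
    "BlandAltman",
    "DemingResult",
    "bland_altman",
    "repeatability_coefficient",
    "RC_CONVENTIONS",
    "deming_fit",
]


def _paired(test, retest):
    x1 = np.asarray(test, dtype=float)
    x2 = np.asarray(retest, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise KineticsError("test and retest must be equal-length 1-D arrays")
    return x1, x2


@dataclass(frozen=True)
class BlandAltman:
    """Relative Bland-Altman summary (percent of the pair mean)."""

    bias_pct: float
    loa_lower: float
    loa_upper: float
    diffs_pct: np.ndarray
    means: np.ndarray
    n_excluded: int


def bland_altman(test, retest) -> BlandAltman:
    """Bland-Altman analysis on relative differences.

    ``d_i = (x2_i - x1_i) / mean_i * 100%``; bias is the mean of d and the
    limits of agreement are ``bias +- 1.96 SD(d)``.  Pairs with a
    non-positive mean are excluded with a warning.
    """
    x1, x2 = _paired(test, retest)
    if x1.size < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 pairs")
    means = 0.5 * (x1 + x2)
    ok = means > 0
    n_exc = int((~ok).sum())
    if n_exc:
        warnings.warn(f"excluded {n_exc} pair(s) with non-positive mean")
    d = (x2[ok] - x1[ok]) / means[ok] * 100.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return BlandAltman(
        bias_pct=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        diffs_pct=d,
        means=means[ok],
        n_excluded=n_exc,
    )


RC_CONVENTIONS = ("relative", "log", "cv277")


def repeatability_coefficient(test, retest, convention: str = "relative") -> float:
    """Relative repeatability coefficient in percent.

    Conventions (numerically close for moderate variability; the report
    should always name the one used):

    * ``"relative"`` (default): ``1.96 * sqrt(mean(d^2))`` with d the
      symmetric within-pair relative difference in percent — the paired
      form of 1.96*sqrt(2)*wCV, with the sqrt(2) absorbed by using the
      difference of two measurements directly;
    * ``"log"``: ``1.96*sqrt(2)*wCV`` with the within-subject CV from the
      variance of log-ratios, ``wCV = sqrt(exp(s2) - 1)``,
      ``s2 = mean(ln(x2/x1)^2)/2``;
    * ``"cv277"``: ``2.77 * wCV`` with ``wCV = sqrt(mean(d^2)/2)``.
    """
    x1, x2 = _paired(test, retest)
    ok = (x1 > 0) & (x2 > 0)
    if int(ok.sum()) < 2:
        raise InsufficientDataError("RC needs at least 2 positive pairs")
    x1, x2 = x1[ok], x2[ok]
    d = 2.0 * (x2 - x1) / (x1 + x2) * 100.0
    if convention == "relative":
        return float(1.96 * np.sqrt(np.mean(d**2)))
    if convention == "log":
        s2 = float(np.mean(np.log(x2 / x1) ** 2)) / 2.0
        wcv = np.sqrt(np.expm1(s2))
        return float(1.96 * np.sqrt(2.0) * 100.0 * wcv)
    if convention == "cv277":
        wcv = np.sqrt(np.mean(d**2) / 2.0)
        return float(2.77 * wcv)
    raise KineticsError(f"unknown RC convention {convention!r}; use one of {RC_CONVENTIONS}")


@dataclass(frozen=True)
class DemingResult:
    slope: float
    intercept: float
    lam: float


def deming_fit(test, retest, lam: float = 1.0) -> DemingResult:
    """Errors-in-variables (Deming) regression of retest on test.

    ``lam`` is the ratio of the y to x error variances; the default 1
    treats both visits as equally noisy (same instrument, same protocol),
    which removes the attenuation bias OLS suffers when the predictor is
    itself noisy.
    """
    x, y = _paired(test, retest)
    if x.size < 3:
        raise InsufficientDataError("Deming regression needs at least 3 pairs")
    xb, yb = x.mean(), y.mean()
    sxx = float(np.mean((x - xb) ** 2))
    syy = float(np.mean((y - yb) ** 2))
    sxy = float(np.mean((x - xb) * (y - yb)))
    if sxy == 0 or sxx == 0:
        raise KineticsError("degenerate spread: Deming slope undefined")
    slope = (syy - lam * sxx + np.sqrt((syy - lam * sxx) ** 2 + 4 * lam * sxy**2)) / (
        2 * sxy
    )
    return DemingResult(slope=float(slope), intercept=float(yb - slope * xb), lam=float(lam))
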