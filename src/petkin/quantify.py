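"""Image-derived input function, SUV, tumour contrast and cutoff calibration.

The SUV definition is the body-weight normalisation
``SUV = C (Bq/mL) * weight (g) / injected activity (Bq)``; with matched
decay-correction conventions on both sides the result is invariant to the
correction reference time.  Cutoff calibration regresses region Ki on
region SUV and translates the previously established SUV positivity
threshold into a Ki threshold with a proper confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
import yaml
from scipy import stats

from .core import (
    ConfigurationError,
    InputFunction,
    InsufficientDataError,
    KineticsError,
)
from .parametric import DynamicImage

__all__ = [
    "StudyMeta",
    "CutoffResult",
    "extract_idif",
    "compute_suv",
    "tn_ratio",
    "calibrate_cutoff",
]


@dataclass(frozen=True)
class StudyMeta:
    """Injection metadata needed for SUV computation."""

    injected_bq: float
    weight_g: float
    injection_time_min: float = 0.0

    def __post_init__(self) -> None:
        if self.injected_bq <= 0:
            raise ConfigurationError("injected activity must be positive")
        if self.weight_g <= 0:
            raise ConfigurationError("body weight must be positive")

    @classmethod
    def from_yaml(cls, path) -> "StudyMeta":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        try:
            return cls(
                injected_bq=float(d["injected_Bq"]),
                weight_g=float(d["weight_g"]),
                injection_time_min=float(d.get("injection_time_min", 0.0)),
            )
        except KeyError as e:  # pragma: no cover - config error path
            raise ConfigurationError(f"study metadata missing key {e}") from e

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "injected_Bq": float(self.injected_bq),
                    "weight_g": float(self.weight_g),
                    "injection_time_min": float(self.injection_time_min),
                },
                fh,
            )


def extract_idif(
    dyn: DynamicImage,
    labels: np.ndarray,
    aorta_label: int,
    threshold: float = 0.5,
    return_mask: bool = False,
):
    """Image-derived input function from an aorta label.

    The first-pass peak frame is the frame with the highest label-mean
    activity (ties resolve to the earlier frame).  The final VOI keeps the
    voxels whose value in that frame reaches ``threshold`` times the
    within-label maximum — counteracting partial-volume dilution at the
    vessel edge — and the IDIF is the mean TAC over that refined VOI,
    sampled at frame mid-times with a zero sample prepended at t = 0.
    """
    labels = np.asarray(labels)
    m = labels == aorta_label
    if not m.any():
        raise InsufficientDataError(f"aorta label {aorta_label} is empty")
    if not (0 <= threshold < 1):
        raise ConfigurationError("threshold must lie in [0, 1)")
    tacs = dyn.data[m]  # (n_voxels, n_frames)
    label_mean = tacs.mean(axis=0)
    peak = int(np.argmax(label_mean))
    if peak == dyn.schedule.n_frames - 1:
        warnings.warn(
            "aorta peak found in the last frame: first-pass timing is suspicious"
        )
    if threshold > 0:
        keep = tacs[:, peak] >= threshold * tacs[:, peak].max()
    else:
        keep = np.ones(tacs.shape[0], dtype=bool)
    values = np.clip(tacs[keep].mean(axis=0), 0.0, None)
    # sample at frame mid-times; hold the last frame's value to the scan end
    # so frame-averaged model evaluation is defined over the whole scan
    mid = dyn.schedule.mid_times
    t_end = dyn.schedule.end_times[-1]
    idif = InputFunction(
        np.concatenate([[0.0], mid, [t_end]]),
        np.concatenate([[0.0], values, [values[-1]]]),
    )
    if return_mask:
        full = np.zeros_like(m)
        full[m] = keep
        return idif, full
    return idif


def compute_suv(concentration, meta: StudyMeta, units: str = "kBq/mL"):
    """SUV = concentration (Bq/mL) x body weight (g) / injected activity (Bq).

    Accepts a scalar, array or map; ``units`` names the concentration unit
    ("kBq/mL" or "Bq/mL").
    """
    factor = {"kBq/mL": 1e3, "Bq/mL": 1.0}.get(units)
    if factor is None:
        raise ConfigurationError(f"unknown concentration units {units!r}")
    return np.asarray(concentration, dtype=float) * factor * meta.weight_g / meta.injected_bq


def tn_ratio(lesion_value: float, normal_mean: float) -> float:
    """Tumour-to-normal contrast for one lesion statistic.

    Pass the lesion max for Tmax/Nmean or the lesion mean for Tmean/Nmean;
    the denominator is always the normal-tissue mean.
    """
    if normal_mean <= 0:
        raise KineticsError("normal-tissue mean must be positive for a T/N ratio")
    return float(lesion_value) / float(normal_mean)


@dataclass(frozen=True)
class CutoffResult:
    """Ki threshold corresponding to a reference SUV cutoff, with 95% CI."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    suv_ref: float
    ki_cutoff: float
    ki_ci: tuple[float, float]
    suv_ci: tuple[float, float]
    n: int
    r_squared: float


def calibrate_cutoff(
    suv,
    ki,
    suv_ref: float = 6.0,
    conf: float = 0.95,
    use_covariance: bool = True,
) -> CutoffResult:
    """Translate an SUV positivity cutoff into a Ki cutoff by linear regression.

    Fits ``Ki = a*SUV + b`` by OLS; the Ki cutoff is the prediction at
    ``suv_ref`` with its CI propagated from the coefficient standard
    errors.  ``use_covariance=True`` (default) includes the slope/intercept
    covariance term, which is the exact mean-prediction variance; the
    independent-SE mode reproduces the simpler propagation and coincides
    when the covariance is negligible.  The SUV interval corresponding to
    the Ki cutoff is obtained by inverting the confidence band (Fieller).
    """
    suv = np.asarray(suv, dtype=float)
    ki = np.asarray(ki, dtype=float)
    if suv.size != ki.size or suv.size < 3:
        raise InsufficientDataError("cutoff calibration needs >=3 paired values")
    if np.ptp(suv) <= 0:
        raise InsufficientDataError("degenerate design: SUV values have no spread")

    X = sm.add_constant(suv)
    fit = sm.OLS(ki, X).fit()
    b, a = fit.params
    cov = np.asarray(fit.cov_params())
    var_b, var_a = cov[0, 0], cov[1, 1]
    cov_ab = cov[0, 1] if use_covariance else 0.0

    pred = a * suv_ref + b
    var_pred = var_b + suv_ref**2 * var_a + 2 * suv_ref * cov_ab
    tq = stats.t.ppf(0.5 + conf / 2.0, df=suv.size - 2)
    half = tq * np.sqrt(max(var_pred, 0.0))
    ki_ci = (pred - half, pred + half)

    # Fieller inversion: SUV values s where the band a*s + b +- t*se(s)
    # crosses the Ki cutoff, i.e. (a*s + b - pred)^2 = t^2 * var(s)
    t2 = tq**2
    qa = a**2 - t2 * var_a
    qb = 2 * (a * (b - pred) - t2 * cov_ab)
    qc = (b - pred) ** 2 - t2 * var_b
    disc = qb**2 - 4 * qa * qc
    if qa > 0 and disc >= 0:
        r = np.sqrt(disc)
        suv_ci = tuple(sorted(((-qb - r) / (2 * qa), (-qb + r) / (2 * qa))))
    else:
        suv_ci = (np.nan, np.nan)
        if not (qa > 0):
            warnings.warn("slope not significantly non-zero: SUV interval unbounded")

    return CutoffResult(
        slope=float(a),
        intercept=float(b),
        slope_se=float(np.sqrt(var_a)),
        intercept_se=float(np.sqrt(var_b)),
        suv_ref=float(suv_ref),
        ki_cutoff=float(pred),
        ki_ci=(float(ki_ci[0]), float(ki_ci[1])),
        suv_ci=(float(suv_ci[0]), float(suv_ci[1])),
        n=int(suv.size),
        r_squared=float(fit.rsquared),
    )
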