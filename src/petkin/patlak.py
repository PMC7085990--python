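"""Patlak graphical analysis of the net influx rate.

For an irreversibly trapping tracer the normalised tissue curve
``C(t)/Cp(t)`` becomes linear in the "stretched time"
``x(t) = int_0^t Cp ds / Cp(t)`` once the reversible compartments have
equilibrated (t >= t*).  The slope of that line estimates Ki and the
intercept Ve, a distribution volume that includes the blood volume.  When
the kinetics are in fact mildly reversible (k4 > 0), the Patlak slope
underestimates the compartmental Ki and the intercept overestimates the
distribution volume — a bias this module deliberately preserves, since it
is what makes Patlak images low-background in tissue with reversible
uptake.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InputFunction, InsufficientDataError, TimeActivityCurve

__all__ = ["PatlakResult", "patlak_fit", "DEFAULT_T_STAR"]

#: default start of the linear segment (minutes); on the 45-min schedule
#: this keeps the last five 5-min frames minus the first
DEFAULT_T_STAR = 15.0


@dataclass(frozen=True)
class PatlakResult:
    """Patlak line for one region: Ki (slope) and Ve (intercept)."""

    ki: float
    ve: float
    t_star: float
    r_squared: float
    frames_used: np.ndarray
    ki_se: float
    ve_se: float

    @property
    def n_used(self) -> int:
        return int(np.size(self.frames_used))


def patlak_fit(
    tac: TimeActivityCurve,
    input_function: InputFunction,
    t_star: float = DEFAULT_T_STAR,
    weighted: bool = False,
) -> PatlakResult:
    """Fit the Patlak line to frames with mid-time >= ``t_star``.

    Patlak coordinates are evaluated at frame mid-times using the
    frame-averaged TAC values.  The line is fitted by ordinary least
    squares by default; ``weighted=True`` applies the TAC's frame weights.
    """
    mid = tac.schedule.mid_times
    cp = input_function(mid)
    use = (mid >= t_star) & (cp > 0)
    if int(use.sum()) < 3:
        raise InsufficientDataError(
            f"Patlak needs >=3 frames with mid-time >= t*={t_star:g} min and Cp > 0"
        )
    x = input_function.integral(mid[use]) / cp[use]
    y = tac.values[use] / cp[use]
    w = tac.weights[use] if weighted else np.ones(x.size)

    sw = w / w.sum()
    xb = float(np.sum(sw * x))
    yb = float(np.sum(sw * y))
    sxx = float(np.sum(sw * (x - xb) ** 2))
    if sxx <= 0:
        raise InsufficientDataError("degenerate Patlak abscissa (no spread in x)")
    sxy = float(np.sum(sw * (x - xb) * (y - yb)))
    slope = sxy / sxx
    intercept = yb - slope * xb

    resid = y - (slope * x + intercept)
    syy = float(np.sum(sw * (y - yb) ** 2))
    r2 = 1.0 - float(np.sum(sw * resid**2)) / syy if syy > 0 else 1.0
    dof = x.size - 2
    if dof > 0:
        s2 = float(np.sum(w * resid**2)) / dof
        wsum = float(w.sum())
        ki_se = np.sqrt(s2 / (wsum * sxx))
        ve_se = np.sqrt(s2 * (1.0 / wsum + xb**2 / (wsum * sxx)))
    else:
        ki_se = ve_se = np.nan

    return PatlakResult(
        ki=slope,
        ve=intercept,
        t_star=float(t_star),
        r_squared=r2,
        frames_used=np.flatnonzero(use),
        ki_se=float(ki_se),
        ve_se=float(ve_se),
    )
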