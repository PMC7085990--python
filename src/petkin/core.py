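"""Core domain types and forward compartment models for dynamic PET.

Units and conventions used throughout the package:

* time is in **minutes**, with t = 0 at tracer injection;
* activity concentration is in **kBq/mL** and assumed decay-corrected to
  injection time (as reconstructed PET images are), so no isotope
  half-life enters the forward models;
* ``K1`` and the net influx rate ``Ki`` are in mL/cm^3/min, ``k2``,
  ``k3``, ``k4`` in 1/min, the fractional blood volume ``Vb`` is
  dimensionless;
* the blood input curve is treated as both the plasma input and the
  whole-blood curve occupying the vascular fraction of a voxel (no
  metabolite or plasma-fraction correction), matching the use of an
  aorta-derived input function for a tracer with negligible metabolism
  over the scan.

The convolution of the input curve with exponential kernels — the
workhorse of every compartment-model operational equation — is computed
analytically for a piecewise-linear input, not by discrete summation, so
model values and frame averages are exact for the interpolation rule the
:class:`InputFunction` contract defines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _fastconv

__all__ = [
    "KineticsError",
    "InsufficientDataError",
    "ConfigurationError",
    "GeometryError",
    "FrameSchedule",
    "InputFunction",
    "TimeActivityCurve",
    "KineticParameters",
    "ModelSpec",
    "ONE_TISSUE",
    "IRREVERSIBLE_2TC",
    "REVERSIBLE_2TC",
    "convolve_exp",
    "FrameConvolver",
    "model_tac",
    "model_conc",
    "net_influx",
]


class KineticsError(ValueError):
    """Invalid parameter or data for a kinetic computation."""


class InsufficientDataError(KineticsError):
    """Not enough usable samples for the requested estimate."""


class ConfigurationError(ValueError):
    """Invalid run or module configuration."""


class GeometryError(ValueError):
    """Inconsistent or overlapping spatial definitions."""


def _farr(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    return np.atleast_1d(a)


# ---------------------------------------------------------------------------
# frame schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameSchedule:
    """Start times and durations (minutes) of the dynamic frames."""

    start_times: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        st = _farr(self.start_times)
        du = _farr(self.durations)
        if st.shape != du.shape or st.ndim != 1 or st.size == 0:
            raise KineticsError("start_times and durations must be equal-length 1-D arrays")
        if np.any(du <= 0):
            raise KineticsError("all frame durations must be positive")
        if np.any(np.diff(st) <= 0):
            raise KineticsError("frame start times must be strictly ascending")
        ends = st + du
        if np.any(ends[:-1] > st[1:] * (1 + 1e-12) + 1e-12):
            raise KineticsError("frames overlap: end_time[i] must not exceed start_time[i+1]")
        st.setflags(write=False)
        du.setflags(write=False)
        object.__setattr__(self, "start_times", st)
        object.__setattr__(self, "durations", du)

    @property
    def n_frames(self) -> int:
        return self.start_times.size

    @property
    def end_times(self) -> np.ndarray:
        return self.start_times + self.durations

    @property
    def mid_times(self) -> np.ndarray:
        return self.start_times + 0.5 * self.durations

    @property
    def total_span(self) -> float:
        """Scan length in minutes (last end minus first start)."""
        return float(self.end_times[-1] - self.start_times[0])

    def boundaries(self) -> np.ndarray:
        """Sorted unique frame boundary times."""
        return np.unique(np.concatenate([self.start_times, self.end_times]))

    @classmethod
    def from_durations_s(cls, durations_s, t0: float = 0.0) -> "FrameSchedule":
        """Build a contiguous schedule from frame durations in seconds."""
        du = _farr(durations_s) / 60.0
        starts = t0 + np.concatenate([[0.0], np.cumsum(du)[:-1]])
        return cls(starts, du)

    @classmethod
    def abdominal_45min(cls) -> "FrameSchedule":
        """The 22-frame, 45-min abdominal acquisition: 6x10, 3x20, 3x60, 5x180, 5x300 s."""
        durations = [10] * 6 + [20] * 3 + [60] * 3 + [180] * 5 + [300] * 5
        return cls.from_durations_s(durations)


# ---------------------------------------------------------------------------
# input function
# ---------------------------------------------------------------------------


def _phi1(x: np.ndarray) -> np.ndarray:
    """(1 - exp(-x))/x for x >= 0, stable near 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < 1e-5
    xs = x[small]
    out[small] = 1.0 - xs / 2.0 + xs * xs / 6.0
    xl = x[~small]
    out[~small] = -np.expm1(-xl) / xl
    return out


def _psi(x: np.ndarray) -> np.ndarray:
    """(1 - exp(-x)*(1+x))/x^2 for x >= 0, stable near 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < 1e-4
    xs = x[small]
    out[small] = 0.5 - xs / 3.0 + xs * xs / 8.0
    xl = x[~small]
    out[~small] = (-np.expm1(-xl) - xl * np.exp(-xl)) / (xl * xl)
    return out


@dataclass(frozen=True)
class InputFunction:
    """Blood activity curve with a piecewise-linear interpolation contract.

    The curve starts at ``C(0) = 0`` (a zero sample is prepended when the
    first sample time is positive) and is non-negative everywhere.  All
    integral and convolution accessors are *exact* for the piecewise-linear
    interpolant, including partial segments.
    """

    sample_times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        t = _farr(self.sample_times)
        c = _farr(self.concentrations)
        if t.shape != c.shape or t.ndim != 1:
            raise KineticsError("sample_times and concentrations must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise KineticsError("sample_times must be strictly ascending")
        if t[0] < 0:
            raise KineticsError("sample times must be non-negative")
        if t[0] > 0:
            t = np.concatenate([[0.0], t])
            c = np.concatenate([[0.0], c])
        if c[0] != 0.0:
            raise KineticsError("concentration at t=0 must be zero")
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise KineticsError("concentrations must be finite and non-negative")
        t.setflags(write=False)
        c.setflags(write=False)
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "concentrations", c)
        # cumulative trapezoid at the nodes (exact for piecewise-linear data)
        dt = np.diff(t)
        inode = np.concatenate([[0.0], np.cumsum(0.5 * dt * (c[:-1] + c[1:]))])
        inode.setflags(write=False)
        object.__setattr__(self, "_inode", inode)

    # -- basic accessors ----------------------------------------------------

    @property
    def t_max(self) -> float:
        return float(self.sample_times[-1])

    def __call__(self, times):
        scalar = np.isscalar(times) or np.ndim(times) == 0
        times = _farr(times)
        self._check_range(times)
        out = np.interp(times, self.sample_times, self.concentrations)
        return float(out[0]) if scalar else out

    def _check_range(self, times: np.ndarray) -> None:
        if np.any(times < -1e-12):
            raise KineticsError("evaluation times must be non-negative")
        if np.any(times > self.t_max * (1 + 1e-12) + 1e-12):
            raise KineticsError(
                f"evaluation time beyond the sampled input range (t_max={self.t_max:g} min)"
            )

    def _segment_of(self, times: np.ndarray) -> np.ndarray:
        j = np.searchsorted(self.sample_times, times, side="right") - 1
        return np.clip(j, 0, self.sample_times.size - 2)

    # -- integral accessors -------------------------------------------------

    def integral(self, times):
        """Running integral of the curve, exact for partial segments."""
        scalar = np.isscalar(times) or np.ndim(times) == 0
        times = _farr(times)
        self._check_range(times)
        t, c = self.sample_times, self.concentrations
        j = self._segment_of(times)
        dp = times - t[j]
        m = (c[j + 1] - c[j]) / (t[j + 1] - t[j])
        out = self._inode[j] + dp * (c[j] + 0.5 * m * dp)
        return float(out[0]) if scalar else out

    def _conv_nodes(self, theta: float) -> np.ndarray:
        """exp(-theta t) (x) C at the sample nodes (analytic per segment)."""
        if _fastconv.HAVE_NUMBA:
            return _fastconv.conv_nodes(self.sample_times, self.concentrations, theta)
        return self._conv_nodes_numpy(theta)

    def _conv_nodes_numpy(self, theta: float) -> np.ndarray:
        """Vectorised log-domain fallback for :meth:`_conv_nodes`."""
        t, c = self.sample_times, self.concentrations
        dt = np.diff(t)
        x = theta * dt
        p1 = _phi1(x)
        seg = dt * (c[:-1] * p1 + (c[1:] - c[:-1]) * (p1 - _psi(x)))
        # y_k = sum_{j<k} seg_j * exp(-theta (t_k - t_{j+1})); accumulate in
        # the log domain so large theta*t never overflows
        with np.errstate(divide="ignore"):
            a = np.log(seg) + theta * t[1:]
        s = np.logaddexp.accumulate(a)
        y = np.zeros_like(t)
        with np.errstate(invalid="ignore"):
            y[1:] = np.exp(s - theta * t[1:])
        return np.nan_to_num(y, nan=0.0)

    def conv_exp(self, theta: float, times) -> np.ndarray:
        """Evaluate ``exp(-theta t) (x) C(t)`` at arbitrary times, exactly.

        For ``theta == 0`` the kernel degenerates to the running integral.
        """
        if theta < 0:
            raise KineticsError("convolution rate theta must be non-negative")
        times = _farr(times)
        self._check_range(times)
        if theta == 0.0:
            return self.integral(times)
        t, c = self.sample_times, self.concentrations
        yn = self._conv_nodes(theta)
        j = self._segment_of(times)
        dp = times - t[j]
        m = (c[j + 1] - c[j]) / (t[j + 1] - t[j])
        cu = c[j]
        cv = cu + m * dp
        x = theta * dp
        p1 = _phi1(x)
        part = dp * (cu * p1 + (cv - cu) * (p1 - _psi(x)))
        return yn[j] * np.exp(-x) + part

    # -- frame-averaged accessors -------------------------------------------

    def frame_averages(self, schedule: FrameSchedule) -> np.ndarray:
        """Frame-averaged curve: mean of C over each [start, end]."""
        a = self.integral(schedule.start_times)
        b = self.integral(schedule.end_times)
        return (b - a) / schedule.durations

    def _double_integral(self, times) -> np.ndarray:
        """H(t) = int_0^t int_0^s C du ds, exact (piecewise cubic)."""
        times = _farr(times)
        self._check_range(times)
        t, c = self.sample_times, self.concentrations
        dt = np.diff(t)
        m = np.diff(c) / dt
        seg = self._inode[:-1] * dt + c[:-1] * dt**2 / 2.0 + m * dt**3 / 6.0
        hnode = np.concatenate([[0.0], np.cumsum(seg)])
        j = self._segment_of(times)
        dp = times - t[j]
        return hnode[j] + self._inode[j] * dp + c[j] * dp**2 / 2.0 + m[j] * dp**3 / 6.0

    def frame_avg_integral(self, schedule: FrameSchedule) -> np.ndarray:
        """Frame-averaged running integral of the curve."""
        a = self._double_integral(schedule.start_times)
        b = self._double_integral(schedule.end_times)
        return (b - a) / schedule.durations

    def frame_avg_conv_exp(self, theta: float, schedule: FrameSchedule) -> np.ndarray:
        """Frame-averaged ``exp(-theta t) (x) C``.

        Uses the ODE identity y' = C - theta*y, i.e.
        ``int_a^b y = (int_a^b C - (y(b) - y(a))) / theta``, which is exact;
        for vanishing theta the limit (frame-averaged running integral) is
        returned instead.
        """
        if theta < 0:
            raise KineticsError("convolution rate theta must be non-negative")
        if theta * self.t_max < 1e-7:
            return self.frame_avg_integral(schedule)
        icp = self.integral(schedule.end_times) - self.integral(schedule.start_times)
        dy = self.conv_exp(theta, schedule.end_times) - self.conv_exp(
            theta, schedule.start_times
        )
        return (icp - dy) / (theta * schedule.durations)

    # -- construction helpers -----------------------------------------------

    def rescaled(self, factor: float) -> "InputFunction":
        return InputFunction(self.sample_times, self.concentrations * factor)


def convolve_exp(theta: float, input_function: InputFunction, times) -> np.ndarray:
    """Analytic convolution ``exp(-theta t) (x) Cp(t)`` at the given times."""
    return input_function.conv_exp(theta, times)


class FrameConvolver:
    """Precomputed frame-averaged convolution for one (input, schedule) pair.

    Caches everything that does not depend on the kernel rate theta so that
    repeated evaluations inside an optimiser or a basis-function sweep only
    pay for the theta-dependent exponentials.  ``favg(theta)`` is exactly
    ``input.frame_avg_conv_exp(theta, schedule)``.
    """

    def __init__(self, input_function: InputFunction, schedule: FrameSchedule) -> None:
        self.input = input_function
        self.schedule = schedule
        inp = input_function
        t, c = inp.sample_times, inp.concentrations
        times = np.concatenate([schedule.start_times, schedule.end_times])
        inp._check_range(times)
        j = inp._segment_of(times)
        self._j = j
        self._dp = times - t[j]
        m = (c[j + 1] - c[j]) / (t[j + 1] - t[j])
        self._cu = c[j]
        self._cv = self._cu + m * self._dp
        n = schedule.n_frames
        ib = inp.integral(times)
        self._icp = ib[n:] - ib[:n]
        self.frame_avg_integral = inp.frame_avg_integral(schedule)
        self.frame_avg_input = self._icp / schedule.durations

    def favg(self, theta: float) -> np.ndarray:
        inp, sched = self.input, self.schedule
        if theta < 0:
            raise KineticsError("convolution rate theta must be non-negative")
        if theta * inp.t_max < 1e-7:
            return self.frame_avg_integral
        if _fastconv.HAVE_NUMBA:
            return _fastconv.frame_avg_conv(
                inp.sample_times,
                inp.concentrations,
                theta,
                self._j,
                self._dp,
                self._cu,
                self._cv,
                self._icp,
                sched.durations,
            )
        yn = inp._conv_nodes(theta)
        x = theta * self._dp
        p1 = _phi1(x)
        part = self._dp * (self._cu * p1 + (self._cv - self._cu) * (p1 - _psi(x)))
        y = yn[self._j] * np.exp(-x) + part
        n = sched.n_frames
        dy = y[n:] - y[:n]
        return (self._icp - dy) / (theta * sched.durations)


# ---------------------------------------------------------------------------
# TAC and kinetic parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged activity concentration with per-frame fit weights.

    Default weights are proportional to frame duration: with roughly
    constant count rate, longer frames have lower relative variance.
    """

    schedule: FrameSchedule
    values: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = _farr(self.values)
        if v.size != self.schedule.n_frames:
            raise KineticsError("values length must equal the number of frames")
        if self.weights is None:
            w = self.schedule.durations / self.schedule.durations.max()
        else:
            w = _farr(self.weights)
        if w.shape != v.shape or np.any(w <= 0):
            raise KineticsError("weights must be positive and match the number of frames")
        v.setflags(write=False)
        w = np.array(w)
        w.setflags(write=False)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "weights", w)

    @property
    def mid_times(self) -> np.ndarray:
        return self.schedule.mid_times

    def rescaled(self, factor: float) -> "TimeActivityCurve":
        return TimeActivityCurve(self.schedule, self.values * factor, self.weights)


@dataclass(frozen=True)
class KineticParameters:
    """Micro-parameters of a (two-)tissue compartment model.

    ``k4 = 0`` encodes irreversible binding.  The derived macro-parameters
    are the net influx rate ``Ki = K1*k3/(k2+k3)`` and the non-displaceable
    distribution volume ``VND = K1/k2``.
    """

    K1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    k4: float = 0.0
    vb: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise KineticsError(f"{name} must be non-negative")
        if not (0 <= self.vb < 1):
            raise KineticsError("vb must lie in [0, 1)")

    @property
    def ki(self) -> float:
        """Net influx rate K1*k3/(k2+k3) (mL/cm^3/min)."""
        if self.k2 + self.k3 <= 0:
            raise KineticsError("Ki undefined: k2 + k3 must be positive")
        return self.K1 * self.k3 / (self.k2 + self.k3)

    @property
    def vnd(self) -> float:
        """Non-displaceable distribution volume K1/k2 (mL/cm^3)."""
        if self.k2 <= 0:
            raise KineticsError("VND undefined: k2 must be positive")
        return self.K1 / self.k2

    def with_(self, **kw) -> "KineticParameters":
        return replace(self, **kw)


def net_influx(params: KineticParameters) -> float:
    """Net influx rate constant Ki = K1*k3/(k2+k3)."""
    return params.ki


# ---------------------------------------------------------------------------
# model specifications and forward equations
# ---------------------------------------------------------------------------


_N_FREE = {"1TC": 3, "2TC-3k": 4, "2TC-4k": 5}
_FREE_NAMES = {
    "1TC": ("K1", "k2", "vb"),
    "2TC-3k": ("K1", "k2", "k3", "vb"),
    "2TC-4k": ("K1", "k2", "k3", "k4", "vb"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Identifier of a compartment model variant (all fit Vb).

    1TC: single-tissue (K1, k2, Vb); 2TC-3k: irreversible two-tissue
    (k4 pinned to 0); 2TC-4k: reversible two-tissue.
    """

    model_id: str

    def __post_init__(self) -> None:
        if self.model_id not in _N_FREE:
            raise ConfigurationError(f"unknown model id {self.model_id!r}")

    @property
    def n_params(self) -> int:
        return _N_FREE[self.model_id]

    @property
    def free_params(self) -> tuple[str, ...]:
        return _FREE_NAMES[self.model_id]

    def validate_params(self, params: KineticParameters) -> None:
        if self.model_id == "1TC" and (params.k3 != 0 or params.k4 != 0):
            raise KineticsError("1TC requires k3 = k4 = 0")
        if self.model_id == "2TC-3k" and params.k4 != 0:
            raise KineticsError("2TC-3k requires k4 = 0")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.model_id


ONE_TISSUE = ModelSpec("1TC")
IRREVERSIBLE_2TC = ModelSpec("2TC-3k")
REVERSIBLE_2TC = ModelSpec("2TC-4k")


def _eigenrates(k2: float, k3: float, k4: float) -> tuple[float, float]:
    """Eigenvalues alpha1 <= alpha2 of the reversible two-tissue system.

    alpha1 is computed as 2*k2*k4/(s+d) (product/sum form) to avoid the
    catastrophic cancellation of (s-d)/2 when k4 is small.
    """
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    d = np.sqrt(max(disc, 0.0))
    a2 = 0.5 * (s + d)
    a1 = (2.0 * k2 * k4 / (s + d)) if (s + d) > 0 else 0.0
    return a1, a2


def _tissue_response(
    params: KineticParameters,
    spec: ModelSpec,
    inp: InputFunction,
    conv,
    integ,
) -> np.ndarray:
    """Tissue concentration via callables conv(theta) and integ() -> arrays."""
    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4
    if spec.model_id == "1TC":
        return K1 * conv(k2)
    if spec.model_id == "2TC-3k" or k4 == 0.0:
        th = k2 + k3
        if th == 0.0:
            # both exchange rates vanish: pure trapping of delivered tracer
            return K1 * integ()
        return (K1 * k3 / th) * integ() + (K1 * k2 / th) * conv(th)
    a1, a2 = _eigenrates(k2, k3, k4)
    if a2 - a1 < 1e-12:
        # repeated eigenvalue (k3 = 0, k2 = k4): perturb infinitesimally
        a2 = a1 + 1e-12
    c1 = (k3 + k4 - a1) / (a2 - a1)
    c2 = (a2 - k3 - k4) / (a2 - a1)
    return K1 * (c1 * conv(a1) + c2 * conv(a2))


def model_tac(
    params: KineticParameters,
    spec: ModelSpec,
    input_function: InputFunction,
    schedule: FrameSchedule,
    blood: InputFunction | None = None,
    weights: np.ndarray | None = None,
) -> TimeActivityCurve:
    """Forward-model a frame-averaged TAC.

    The measured signal is ``(1-Vb)*C_T(t) + Vb*C_b(t)`` averaged
    analytically over each frame interval (midpoint sampling would bias the
    10-s early frames against the 5-min late frames).  ``blood`` defaults to
    the input function itself (aorta curve used for both roles).
    """
    spec.validate_params(params)
    blood = input_function if blood is None else blood

    def conv(theta: float) -> np.ndarray:
        return input_function.frame_avg_conv_exp(theta, schedule)

    def integ() -> np.ndarray:
        return input_function.frame_avg_integral(schedule)

    ct = _tissue_response(params, spec, input_function, conv, integ)
    values = (1.0 - params.vb) * ct + params.vb * blood.frame_averages(schedule)
    return TimeActivityCurve(schedule, values, weights)


def model_conc(
    params: KineticParameters,
    spec: ModelSpec,
    input_function: InputFunction,
    times,
    blood: InputFunction | None = None,
) -> np.ndarray:
    """Instantaneous modelled concentration at arbitrary times (not frame-averaged)."""
    spec.validate_params(params)
    blood = input_function if blood is None else blood
    times = _farr(times)

    def conv(theta: float) -> np.ndarray:
        return input_function.conv_exp(theta, times)

    def integ() -> np.ndarray:
        return input_function.integral(times)

    ct = _tissue_response(params, spec, input_function, conv, integ)
    return (1.0 - params.vb) * ct + params.vb * blood(times)
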