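"""Voxel-wise parametric imaging.

Two parametric methods operate on a 4D dynamic image:

* a basis-function implementation of the irreversible two-tissue model —
  for each candidate rate ``theta = k2 + k3`` the frame-averaged column
  ``B_theta = exp(-theta t) (x) Cp`` is precomputed once, and each voxel is
  solved by *non-negative* linear least squares over
  ``C = Vb*C_b + alpha*int(Cp) + beta*B_theta``, picking the theta with the
  lowest residual.  Micro-parameters follow from ``K1 = alpha + beta``,
  ``k3 = theta*alpha/K1``, ``k2 = theta*beta/K1``; note ``Ki = alpha``
  identically.  Maps of K1, Ki, Vb and VND = K1/k2 are produced.
* voxel-wise Patlak analysis, producing Ki and Ve maps.

With three basis columns the exact non-negative solution is found by
enumerating all coefficient support sets and keeping the feasible one with
the lowest residual — this is deterministic and fully vectorised over
voxels.

The blood-volume convention here is the *unscaled* linear form
``C = Vb*C_b + (tissue terms)``: tissue coefficients are reported without
a (1-Vb) correction unless ``vb_correction=True``, which divides the
tissue coefficients by (1-Vb).  The correction changes K1 and Ki by
roughly the blood-volume fraction (~5-10%), so the choice is surfaced
prominently in the result metadata.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    FrameConvolver,
    FrameSchedule,
    InputFunction,
    InsufficientDataError,
    KineticParameters,
    KineticsError,
)
from .patlak import DEFAULT_T_STAR

__all__ = [
    "DynamicImage",
    "BasisSet",
    "ParametricMaps",
    "default_theta_grid",
    "make_basis",
    "fit_voxel_basis",
    "fit_parametric",
    "patlak_voxelwise",
    "extract_voi_values",
]


# ---------------------------------------------------------------------------
# image containers
# ---------------------------------------------------------------------------


def _default_affine(voxel_size) -> np.ndarray:
    aff = np.diag([*voxel_size, 1.0])
    return aff


@dataclass
class DynamicImage:
    """4D dynamic PET volume (x, y, z, frame) in kBq/mL plus its schedule."""

    data: np.ndarray
    schedule: FrameSchedule
    voxel_size: tuple[float, float, float] = (3.9, 3.9, 3.27)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise KineticsError("dynamic image must be 4-D (x, y, z, frame)")
        if self.data.shape[-1] != self.schedule.n_frames:
            raise KineticsError("frame axis length must equal the schedule length")
        if not np.all(np.isfinite(self.data)):
            raise KineticsError("dynamic image contains non-finite values")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape[:3]

    def voi_tac(self, labels: np.ndarray, label: int):
        """Mean TAC over a labelled VOI."""
        from .core import TimeActivityCurve

        m = np.asarray(labels) == label
        if not m.any():
            raise InsufficientDataError(f"label {label} is empty")
        return TimeActivityCurve(self.schedule, self.data[m].mean(axis=0))

    def to_nifti(self, path) -> None:
        nib.Nifti1Image(self.data.astype(np.float32), self.affine).to_filename(str(path))

    @classmethod
    def from_nifti(cls, path, schedule: FrameSchedule) -> "DynamicImage":
        img = nib.load(str(path))
        vs = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=float), schedule, vs, img.affine)


@dataclass
class ParametricMaps:
    """Named 3D parameter maps sharing one geometry, plus the fitted-voxel mask."""

    maps: dict[str, np.ndarray]
    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.maps.values()} | {self.mask.shape}
        if len(shapes) != 1:
            raise KineticsError("all maps must share one geometry")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    def __contains__(self, name: str) -> bool:
        return name in self.maps

    def to_nifti(self, outdir) -> list[str]:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, arr in self.maps.items():
            p = outdir / f"{name}.nii"
            nib.Nifti1Image(arr.astype(np.float32), self.affine).to_filename(str(p))
            written.append(str(p))
        return written


# ---------------------------------------------------------------------------
# basis functions
# ---------------------------------------------------------------------------


def default_theta_grid(n: int = 64, lo: float = 0.006, hi: float = 3.0) -> np.ndarray:
    """Log-spaced grid of theta = k2 + k3 (1/min) spanning liver/lesion kinetics."""
    return np.geomspace(lo, hi, n)


@dataclass
class BasisSet:
    """Precomputed frame-averaged basis columns for one study."""

    thetas: np.ndarray
    conv: np.ndarray  # (n_frames, n_theta): exp(-theta t) (x) Cp, frame-averaged
    blood_avg: np.ndarray  # (n_frames,)
    int_avg: np.ndarray  # (n_frames,) frame-averaged running integral of Cp
    schedule: FrameSchedule

    @property
    def n_frames(self) -> int:
        return self.blood_avg.size


def make_basis(
    input_function: InputFunction,
    schedule: FrameSchedule,
    thetas: np.ndarray | None = None,
    blood: InputFunction | None = None,
) -> BasisSet:
    """Precompute basis columns for the irreversible two-tissue solve."""
    thetas = default_theta_grid() if thetas is None else np.asarray(thetas, dtype=float)
    if thetas.size == 0:
        raise ConfigurationError("theta grid must not be empty")
    if np.any(thetas <= 0) or np.any(np.diff(thetas) <= 0):
        raise ConfigurationError("theta grid must be positive and strictly ascending")
    blood = input_function if blood is None else blood
    conv = FrameConvolver(input_function, schedule)
    cols = np.column_stack([conv.favg(th) for th in thetas])
    return BasisSet(
        thetas=thetas,
        conv=cols,
        blood_avg=blood.frame_averages(schedule),
        int_avg=conv.frame_avg_integral,
        schedule=schedule,
    )


# all non-empty support sets of the 3 coefficients (Vb, alpha, beta),
# ordered small-to-large so RSS ties resolve toward sparser solutions
_SUPPORTS = [
    s
    for size in (1, 2, 3)
    for s in itertools.combinations(range(3), size)
]


def _nnls_scan(Y: np.ndarray, basis: BasisSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact NNLS over the theta grid for many voxels at once.

    Y is (n_frames, n_voxels).  Returns (coeffs (3, n_voxels) in the order
    [Vb, alpha, beta], theta index per voxel (-1 for the all-zero
    solution), and per-voxel RSS).
    """
    nf, nv = Y.shape
    yy = np.einsum("fv,fv->v", Y, Y)
    best_rss = yy.copy()
    best_coef = np.zeros((3, nv))
    best_theta = np.full(nv, -1, dtype=int)

    for k in range(basis.thetas.size):
        A = np.column_stack([basis.blood_avg, basis.int_avg, basis.conv[:, k]])
        G = A.T @ A
        ATY = A.T @ Y
        for S in _SUPPORTS:
            S = list(S)
            GS = G[np.ix_(S, S)]
            try:
                cS = np.linalg.solve(GS, ATY[S])
            except np.linalg.LinAlgError:
                cS = np.linalg.pinv(GS) @ ATY[S]
            feasible = np.all(cS >= -1e-12, axis=0)
            rss = yy - np.sum(cS * ATY[S], axis=0)
            rss = np.where(feasible, np.clip(rss, 0.0, None), np.inf)
            better = rss < best_rss
            if np.any(better):
                best_rss[better] = rss[better]
                best_theta[better] = k
                best_coef[:, better] = 0.0
                for row, s in enumerate(S):
                    best_coef[s, better] = np.clip(cS[row, better], 0.0, None)
    return best_coef, best_theta, best_rss


def _micro_from_coeffs(coef, thetas, theta_idx, vb_correction: bool):
    """Recover (K1, k2, k3, Ki, VND, Vb) arrays from basis coefficients."""
    vb = coef[0]
    alpha = coef[1].copy()
    beta = coef[2].copy()
    if vb_correction:
        scale = 1.0 / np.clip(1.0 - vb, 1e-6, None)
        alpha *= scale
        beta *= scale
    th = np.where(theta_idx >= 0, thetas[np.clip(theta_idx, 0, None)], 0.0)
    k1 = alpha + beta
    with np.errstate(divide="ignore", invalid="ignore"):
        k3 = np.where(k1 > 0, th * alpha / k1, 0.0)
        k2 = np.where(k1 > 0, th * beta / k1, 0.0)
        vnd = np.where(k2 > 0, k1 / k2, 0.0)
    return k1, k2, k3, alpha, vnd, vb


def fit_voxel_basis(
    values: np.ndarray,
    basis: BasisSet,
    vb_correction: bool = False,
) -> tuple[KineticParameters, float]:
    """Basis-function solve for one voxel TAC; returns (parameters, RSS)."""
    values = np.asarray(values, dtype=float)
    if values.shape != (basis.n_frames,):
        raise KineticsError("voxel TAC length must equal the number of frames")
    if not np.all(np.isfinite(values)):
        raise KineticsError("voxel TAC must be finite")
    coef, tidx, rss = _nnls_scan(values[:, None], basis)
    k1, k2, k3, ki, vnd, vb = _micro_from_coeffs(coef, basis.thetas, tidx, vb_correction)
    params = KineticParameters(
        K1=float(k1[0]), k2=float(k2[0]), k3=float(k3[0]), vb=float(min(vb[0], 1 - 1e-9))
    )
    return params, float(rss[0])


def _default_mask(dyn: DynamicImage, fraction: float = 0.01) -> np.ndarray:
    """Fit only voxels whose time-summed activity exceeds ``fraction`` of the max."""
    s = dyn.data.sum(axis=-1)
    return s > fraction * s.max()


def fit_parametric(
    dyn: DynamicImage,
    input_function: InputFunction,
    thetas: np.ndarray | None = None,
    basis: BasisSet | None = None,
    mask: np.ndarray | None = None,
    vb_correction: bool = False,
    blood: InputFunction | None = None,
) -> ParametricMaps:
    """Basis-function parametric maps: K1, Ki2TC, Vb, VND (+ k2, k3, RSS)."""
    if basis is None:
        basis = make_basis(input_function, dyn.schedule, thetas, blood)
    mask = _default_mask(dyn) if mask is None else np.asarray(mask, bool)
    Y = dyn.data[mask].T  # (n_frames, n_voxels)
    coef, tidx, rss = _nnls_scan(Y, basis)
    k1, k2, k3, ki, vnd, vb = _micro_from_coeffs(coef, basis.thetas, tidx, vb_correction)
    vb = np.clip(vb, 0.0, 1 - 1e-9)

    fitted = mask.copy()
    fitted[mask] = ~((tidx < 0) & (np.einsum("fv,fv->v", Y, Y) == 0))

    def full(v):
        out = np.zeros(dyn.shape)
        out[mask] = v
        return out

    maps = {
        "K1": full(k1),
        "Ki2TC": full(ki),
        "Vb": full(vb),
        "VND": full(vnd),
        "k2": full(k2),
        "k3": full(k3),
        "RSS2TC": full(rss),
    }
    return ParametricMaps(
        maps=maps,
        mask=fitted,
        voxel_size=dyn.voxel_size,
        affine=dyn.affine,
        meta={
            "method": "basis-2TC-3k",
            "vb_correction": vb_correction,
            "theta_min": float(basis.thetas[0]),
            "theta_max": float(basis.thetas[-1]),
            "n_theta": int(basis.thetas.size),
        },
    )


def patlak_voxelwise(
    dyn: DynamicImage,
    input_function: InputFunction,
    t_star: float = DEFAULT_T_STAR,
    mask: np.ndarray | None = None,
) -> ParametricMaps:
    """Voxel-wise Patlak Ki and Ve maps (unweighted OLS per voxel)."""
    mid = dyn.schedule.mid_times
    cp = input_function(mid)
    use = (mid >= t_star) & (cp > 0)
    if int(use.sum()) < 3:
        raise InsufficientDataError(
            f"Patlak needs >=3 frames with mid-time >= t*={t_star:g} min"
        )
    mask = _default_mask(dyn) if mask is None else np.asarray(mask, bool)
    x = input_function.integral(mid[use]) / cp[use]
    Y = dyn.data[mask][:, use] / cp[use]  # (n_voxels, n_used)

    xb = x.mean()
    yb = Y.mean(axis=1)
    dx = x - xb
    sxx = float(np.sum(dx**2))
    slope = (Y - yb[:, None]) @ dx / sxx
    intercept = yb - slope * xb
    resid = Y - (slope[:, None] * x + intercept[:, None])
    syy = np.sum((Y - yb[:, None]) ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(syy > 0, 1.0 - np.sum(resid**2, axis=1) / syy, 1.0)

    def full(v):
        out = np.zeros(dyn.shape)
        out[mask] = v
        return out

    return ParametricMaps(
        maps={"KiPatlak": full(slope), "Ve": full(intercept), "R2Patlak": full(r2)},
        mask=mask.copy(),
        voxel_size=dyn.voxel_size,
        affine=dyn.affine,
        meta={"method": "patlak", "t_star": float(t_star)},
    )


def extract_voi_values(
    maps: ParametricMaps, labels: np.ndarray, label_ids: list[int] | None = None
) -> pd.DataFrame:
    """Per-VOI statistics (mean/median/max/min/n) for every map.

    Returns a tidy table with one row per (label, map).  ``label_ids``
    defaults to every non-zero label present; explicitly requested labels
    that are empty yield a missing-value row and a warning.
    """
    labels = np.asarray(labels)
    if labels.shape != maps.mask.shape:
        raise KineticsError("label geometry does not match the maps")
    rows = []
    if label_ids is None:
        ids = [int(v) for v in np.unique(labels) if v != 0]
    else:
        ids = [int(v) for v in label_ids]
    for lab in ids:
        m = labels == lab
        n = int(m.sum())
        for name, arr in maps.maps.items():
            if n == 0:
                rows.append(
                    {"label": lab, "map": name, "n_voxels": 0, "mean": np.nan,
                     "median": np.nan, "max": np.nan, "min": np.nan}
                )
                continue
            v = arr[m]
            rows.append(
                {"label": lab, "map": name, "n_voxels": n, "mean": float(v.mean()),
                 "median": float(np.median(v)), "max": float(v.max()),
                 "min": float(v.min())}
            )
        if n == 0:
            warnings.warn(f"label {lab} contains no voxels")
    return pd.DataFrame(rows)
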