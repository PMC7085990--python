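"""Synthetic dynamic-PET studies with known ground truth.

The generator emulates a 45-min abdominal acquisition of an irreversibly
binding, fast-clearing receptor tracer: an arterial input with a sharp
first-pass peak and slowly decaying tail, a liver background with high
delivery (K1 ~ 0.37 mL/cm^3/min), low net trapping (Ki ~ 0.015) and a
small reversible component (k4 ~ 0.01 1/min), and spherical liver lesions
with *lower* delivery than liver but net influx spanning roughly
0.003-0.095 mL/cm^3/min — from receptor-negative to strongly positive.
Frame noise is Gaussian with variance proportional to concentration over
frame duration, which reproduces the count-statistics behaviour of
reconstructed frames (short early frames are noisy, long late frames are
not).

What the phantom deliberately does not emulate: scanner resolution (no
point-spread blurring by default, so no partial-volume effect), anatomy
beyond box/cylinder/sphere geometry, motion, scatter or reconstruction
artefacts.  Recovery results on the phantom therefore show algorithmic
correctness, not robustness to those effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .core import (
    FrameSchedule,
    GeometryError,
    InputFunction,
    IRREVERSIBLE_2TC,
    REVERSIBLE_2TC,
    KineticParameters,
    KineticsError,
    TimeActivityCurve,
    model_conc,
    model_tac,
)
from .parametric import DynamicImage
from .quantify import StudyMeta, compute_suv

__all__ = [
    "make_input_function",
    "LesionSpec",
    "PhantomSpec",
    "PhantomStudy",
    "make_phantom",
    "make_test_retest",
    "make_test_retest_pairs",
    "add_tac_noise",
    "default_lesions",
    "LIVER_LABEL",
    "AORTA_LABEL",
    "LESION_LABEL_START",
]

LIVER_LABEL = 1
AORTA_LABEL = 2
LESION_LABEL_START = 3


# ---------------------------------------------------------------------------
# input function
# ---------------------------------------------------------------------------


def make_input_function(
    amplitudes: tuple[float, float, float] = (600.0, 30.0, 25.0),
    rates: tuple[float, float, float] = (4.0, 0.5, 0.008),
    delay_min: float = 0.25,
    dose_scale: float = 1.0,
    t_max: float = 245.0,
) -> InputFunction:
    """Analytic arterial input: linear first-pass rise with tri-exponential decay.

    ``Cp(t) = (A1 (t-d) - A2 - A3) e^{-l1 (t-d)} + A2 e^{-l2 (t-d)}
    + A3 e^{-l3 (t-d)}`` for t > d, 0 before — a sharp peak around
    0.5-1 min post-injection followed by fast clearance and a slow tail
    whose late log-slope is the smallest rate.  ``dose_scale`` multiplies
    all amplitudes (peak height is linear in injected dose).  Sampled on a
    grid dense through the first-pass (0.02 min), moderate over the rest
    of the dynamic scan (0.2 min) and coarse out to ``t_max`` so the curve
    supports late static time points.
    """
    a1, a2, a3 = (a * dose_scale for a in amplitudes)
    l1, l2, l3 = rates
    if min(a1, a2, a3) < 0 or min(l1, l2, l3) <= 0:
        raise KineticsError("input-function amplitudes must be >=0 and rates > 0")
    if not (l1 > l2 > l3):
        raise KineticsError("rates must be ordered fast > intermediate > slow")
    t = np.concatenate(
        [
            np.arange(0.0, 3.0, 0.02),
            np.arange(3.0, min(45.2, t_max), 0.2),
            np.arange(45.5, t_max + 1e-9, 2.5),
        ]
    )
    tr = t - delay_min
    c = np.where(
        tr > 0,
        (a1 * tr - a2 - a3) * np.exp(-l1 * tr)
        + a2 * np.exp(-l2 * tr)
        + a3 * np.exp(-l3 * tr),
        0.0,
    )
    c = np.clip(c, 0.0, None)
    inp = InputFunction(t, c)
    peak_t = t[int(np.argmax(c))]
    if peak_t > 2.0:
        raise KineticsError(f"first-pass peak at {peak_t:.2f} min: must arrive within 2 min")
    return inp


# ---------------------------------------------------------------------------
# phantom specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LesionSpec:
    """A spherical lesion: position/diameter in mm plus its kinetics."""

    center_mm: tuple[float, float, float]
    diameter_mm: float
    params: KineticParameters


def _lesion(center, diameter, K1, k2, ki, vb=0.05) -> LesionSpec:
    if not 0 < ki < K1:
        raise KineticsError("lesion needs 0 < Ki < K1")
    k3 = ki * k2 / (K1 - ki)
    return LesionSpec(center, diameter, KineticParameters(K1=K1, k2=k2, k3=k3, vb=vb))


def default_lesions() -> list[LesionSpec]:
    """Twelve liver lesions spanning receptor-negative to strongly positive.

    Delivery is always below the liver's K1 (lesions show as cold spots in
    K1 maps) while net influx spans ~0.003-0.095 mL/cm^3/min; diameters run
    from 30 mm down to 8 mm (~2 voxels, below the resolution of a typical
    reconstruction).
    """
    kin = [
        # (K1, k2, Ki)
        (0.38, 0.20, 0.095),
        (0.35, 0.20, 0.075),
        (0.30, 0.25, 0.060),
        (0.28, 0.20, 0.050),
        (0.25, 0.30, 0.040),
        (0.22, 0.25, 0.032),
        (0.20, 0.20, 0.025),
        (0.16, 0.30, 0.018),
        (0.12, 0.25, 0.012),
        (0.08, 0.30, 0.009),
        (0.05, 0.25, 0.006),
        (0.02, 0.20, 0.003),
    ]
    xs = (40.0, 75.0, 110.0, 145.0)
    ys = (65.0, 120.0, 175.0)
    diam = [30, 28, 26, 24, 22, 20, 18, 16, 14, 12, 10, 8]
    lesions = []
    for i, (K1, k2, ki) in enumerate(kin):
        cx = xs[i % 4]
        cy = ys[(i // 4) % 3]
        cz = 35.0 if i % 2 == 0 else 70.0
        lesions.append(_lesion((cx, cy, cz), float(diam[i]), K1, k2, ki))
    return lesions


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, kinetics and noise of one synthetic study."""

    shape: tuple[int, int, int] = (64, 64, 32)
    voxel_mm: tuple[float, float, float] = (3.9, 3.9, 3.27)
    liver_box_mm: tuple[tuple[float, float], ...] = ((20, 170), (40, 200), (10, 95))
    liver_params: KineticParameters = field(
        default_factory=lambda: KineticParameters(
            K1=0.37, k2=0.25, k3=0.0105634, k4=0.01, vb=0.12
        )
    )
    aorta_center_mm: tuple[float, float] = (200.0, 125.0)
    aorta_radius_mm: float = 11.0
    lesions: tuple[LesionSpec, ...] = field(default_factory=lambda: tuple(default_lesions()))
    noise_scale: float = 0.6
    seed: int = 0
    schedule: FrameSchedule = field(default_factory=FrameSchedule.abdominal_45min)
    meta: StudyMeta = field(default_factory=lambda: StudyMeta(241e6, 70000.0))
    static_times_min: tuple[float, ...] = (120.0, 240.0)
    psf_fwhm_mm: float = 0.0


@dataclass
class PhantomStudy:
    """A generated study: images, labels, ground truth and metadata."""

    dynamic: DynamicImage
    labels: np.ndarray
    truth: dict[int, KineticParameters]
    truth_maps: dict[str, np.ndarray]
    static_suv: dict[float, np.ndarray]
    input_function: InputFunction
    meta: StudyMeta
    spec: PhantomSpec

    @property
    def lesion_labels(self) -> list[int]:
        return [k for k in sorted(self.truth) if k >= LESION_LABEL_START]

    def write(self, outdir) -> None:
        """Write NIfTI volumes plus a YAML manifest of the ground truth."""
        from pathlib import Path

        import nibabel as nib

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.dynamic.to_nifti(outdir / "dynamic.nii")
        aff = self.dynamic.affine
        nib.Nifti1Image(self.labels.astype(np.int16), aff).to_filename(
            str(outdir / "labels.nii")
        )
        for name, arr in self.truth_maps.items():
            nib.Nifti1Image(arr.astype(np.float32), aff).to_filename(
                str(outdir / f"truth_{name}.nii")
            )
        for t, arr in self.static_suv.items():
            nib.Nifti1Image(arr.astype(np.float32), aff).to_filename(
                str(outdir / f"static_suv_{int(t)}min.nii")
            )
        np.savetxt(
            outdir / "input_function.tsv",
            np.column_stack([self.input_function.sample_times,
                             self.input_function.concentrations]),
            header="time_min\tconc_kBq_per_mL", delimiter="\t",
        )
        manifest = {
            "seed": int(self.spec.seed),
            "noise_scale": float(self.spec.noise_scale),
            "schedule_start_min": self.dynamic.schedule.start_times.tolist(),
            "schedule_duration_min": self.dynamic.schedule.durations.tolist(),
            "injected_Bq": float(self.meta.injected_bq),
            "weight_g": float(self.meta.weight_g),
            "regions": {
                int(lab): {k: float(getattr(p, k)) for k in ("K1", "k2", "k3", "k4", "vb")}
                for lab, p in self.truth.items()
            },
        }
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh)


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------


def _voxel_centers(shape, voxel_mm):
    idx = [np.arange(n) * v + v / 2.0 for n, v in zip(shape, voxel_mm)]
    return np.meshgrid(*idx, indexing="ij")


def _build_labels(spec: PhantomSpec) -> np.ndarray:
    X, Y, Z = _voxel_centers(spec.shape, spec.voxel_mm)
    labels = np.zeros(spec.shape, dtype=np.int16)
    (x0, x1), (y0, y1), (z0, z1) = spec.liver_box_mm
    liver = (X >= x0) & (X < x1) & (Y >= y0) & (Y < y1) & (Z >= z0) & (Z < z1)
    labels[liver] = LIVER_LABEL
    cx, cy = spec.aorta_center_mm
    aorta = (X - cx) ** 2 + (Y - cy) ** 2 <= spec.aorta_radius_mm**2
    if np.any(aorta & liver):
        raise GeometryError("aorta cylinder intersects the liver box")
    labels[aorta] = AORTA_LABEL
    spheres = []
    for i, les in enumerate(spec.lesions):
        c = les.center_mm
        r = les.diameter_mm / 2.0
        s = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= r**2
        if not s.any():
            raise GeometryError(f"lesion {i} ({les.diameter_mm} mm) covers no voxels")
        if np.any(s & aorta):
            raise GeometryError(f"lesion {i} intersects the aorta")
        for j, prev in enumerate(spheres):
            if np.any(s & prev):
                raise GeometryError(f"lesions {j} and {i} overlap")
        spheres.append(s)
        labels[s] = LESION_LABEL_START + i
    return labels


def _region_params(spec: PhantomSpec) -> dict[int, KineticParameters]:
    truth = {LIVER_LABEL: spec.liver_params}
    for i, les in enumerate(spec.lesions):
        truth[LESION_LABEL_START + i] = les.params
    return truth


def make_phantom(spec: PhantomSpec | None = None,
                 input_function: InputFunction | None = None) -> PhantomStudy:
    """Generate one synthetic dynamic study with static SUV volumes.

    Voxels within each region carry that region's noise-free forward-model
    TAC plus seeded Gaussian noise with ``sigma = noise_scale *
    sqrt(C / frame_duration)``; aorta voxels carry the frame-averaged
    input curve (pure blood).  Static volumes are the instantaneous model
    concentration at the requested post-injection times converted to SUV
    (noise-free).  Identical spec and seed give bit-identical output.
    """
    spec = spec or PhantomSpec()
    inp = input_function if input_function is not None else make_input_function()
    sched = spec.schedule
    labels = _build_labels(spec)
    truth = _region_params(spec)

    region_tac: dict[int, np.ndarray] = {}
    region_static: dict[int, np.ndarray] = {}
    stimes = np.asarray(spec.static_times_min, dtype=float)
    for lab, p in truth.items():
        ms = REVERSIBLE_2TC if p.k4 > 0 else IRREVERSIBLE_2TC
        region_tac[lab] = model_tac(p, ms, inp, sched).values
        region_static[lab] = model_conc(p, ms, inp, stimes)
    region_tac[AORTA_LABEL] = inp.frame_averages(sched)
    region_static[AORTA_LABEL] = inp(stimes)

    nf = sched.n_frames
    dyn = np.zeros(spec.shape + (nf,))
    truth_k1 = np.zeros(spec.shape)
    truth_ki = np.zeros(spec.shape)
    static = {float(t): np.zeros(spec.shape) for t in stimes}
    for lab in list(truth) + [AORTA_LABEL]:
        m = labels == lab
        dyn[m] = region_tac[lab]
        for j, t in enumerate(stimes):
            static[float(t)][m] = region_static[lab][j]
        if lab in truth:
            p = truth[lab]
            truth_k1[m] = p.K1
            truth_ki[m] = p.ki if p.k2 + p.k3 > 0 else 0.0

    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = spec.noise_scale * np.sqrt(
            np.clip(dyn, 0.0, None) / sched.durations
        )
        dyn = dyn + rng.normal(0.0, 1.0, dyn.shape) * sigma

    if spec.psf_fwhm_mm > 0:
        from scipy.ndimage import gaussian_filter

        sig_vox = spec.psf_fwhm_mm / 2.3548 / np.asarray(spec.voxel_mm)
        for f in range(nf):
            dyn[..., f] = gaussian_filter(dyn[..., f], sig_vox)

    static_suv = {
        t: np.asarray(compute_suv(arr, spec.meta)) for t, arr in static.items()
    }
    dimg = DynamicImage(dyn, sched, spec.voxel_mm)
    return PhantomStudy(
        dynamic=dimg,
        labels=labels,
        truth=truth,
        truth_maps={"K1": truth_k1, "Ki": truth_ki},
        static_suv=static_suv,
        input_function=inp,
        meta=spec.meta,
        spec=spec,
    )


def add_tac_noise(tac: TimeActivityCurve, noise_scale: float, rng) -> TimeActivityCurve:
    """Frame-duration-dependent Gaussian noise on a TAC, floored at ~0."""
    sigma = noise_scale * np.sqrt(np.clip(tac.values, 0.0, None) / tac.schedule.durations)
    noisy = tac.values + rng.normal(0.0, 1.0, tac.values.shape) * sigma
    return TimeActivityCurve(tac.schedule, np.clip(noisy, 1e-6, None), tac.weights)


# ---------------------------------------------------------------------------
# test-retest generation
# ---------------------------------------------------------------------------


def _jitter_ki(params: KineticParameters, factor: float) -> KineticParameters:
    """Scale a lesion's net influx by ``factor`` via k3, holding K1, k2, Vb."""
    ki_new = min(params.ki * factor, 0.9 * params.K1)
    k3_new = ki_new * params.k2 / (params.K1 - ki_new)
    return replace(params, k3=k3_new)


def make_test_retest(
    spec: PhantomSpec, wcv_pct: float = 10.8, seed: int | None = None
) -> tuple[PhantomStudy, PhantomStudy]:
    """Two studies of the same subject with biologically jittered lesions.

    Each visit draws an independent lognormal factor of the stated
    within-subject CV for every lesion's Ki (delivery and liver background
    are held fixed) and an independent noise realisation.
    """
    if wcv_pct < 0:
        raise KineticsError("wCV must be non-negative")
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    sig = wcv_pct / 100.0
    studies = []
    for visit in range(2):
        lesions = tuple(
            replace(les, params=_jitter_ki(les.params, float(np.exp(rng.normal(0.0, sig)))))
            if sig > 0
            else les
            for les in spec.lesions
        )
        vspec = replace(spec, lesions=lesions, seed=int(seed * 2 + visit))
        studies.append(make_phantom(vspec))
    return studies[0], studies[1]


def make_test_retest_pairs(
    n: int,
    wcv_pct: float = 10.8,
    seed: int = 0,
    ki_median: float = 0.025,
    ki_spread: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired lesion-level Ki measurements with a known within-subject CV.

    Each pair shares a true Ki drawn lognormally around ``ki_median``; the
    two visit values multiply it by independent lognormal factors with
    log-SD ``wcv_pct/100``.  Useful for validating repeatability
    statistics at large n without building thousands of phantoms.
    """
    rng = np.random.default_rng(seed)
    truth = ki_median * np.exp(rng.normal(0.0, ki_spread, n))
    sig = wcv_pct / 100.0
    test = truth * np.exp(rng.normal(0.0, sig, n))
    retest = truth * np.exp(rng.normal(0.0, sig, n))
    return test, retest
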