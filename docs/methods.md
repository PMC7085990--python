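# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `petkin`, in the spirit of the methods sections that
accompany kinetic-modelling toolboxes.

## Setting

The package quantifies dynamic PET of a receptor tracer with essentially
irreversible binding and fast blood clearance (the motivating application
is a radiolabelled HER2-binding scaffold protein imaged over the liver in
metastatic breast cancer).  A 45-min dynamic acquisition (22 frames: 6x10,
3x20, 3x60, 5x180, 5x300 s) is followed by static whole-body imaging at
~2 h and ~4 h.  All concentrations are decay-corrected to injection, so no
isotope half-life appears anywhere: the forward models, SUV and all
statistics operate on decay-corrected kBq/mL.

## Compartment models

Three nested models are supported, all with a fitted fractional blood
volume `Vb`:

* **1TC** — single tissue compartment, `dC_T/dt = K1 Cp - k2 C_T`;
* **2TC-3k** — irreversible two-tissue model,
  `C_T(t) = K1/(k2+k3) [k3 + k2 e^{-(k2+k3)t}] (x) Cp(t)`;
* **2TC-4k** — reversible two-tissue model, the bi-exponential solution
  with eigenrates `alpha_{1,2} = (s -+ sqrt(s^2 - 4 k2 k4))/2`,
  `s = k2+k3+k4`.  `alpha_1` is computed as `2 k2 k4/(s+d)` to avoid
  cancellation at small `k4`; a repeated eigenvalue (`k3=0, k2=k4`) is
  perturbed by 1e-12.

The measured signal is `(1-Vb) C_T + Vb C_b`, with the aorta curve serving
as both plasma input and whole blood (no metabolite or plasma-fraction
correction — appropriate for a tracer with negligible metabolite buildup
over 45 min, and the only option when the input is image-derived).

Macro-parameters: net influx rate `Ki = K1 k3/(k2+k3)` (the
HER2-expression surrogate) and non-displaceable distribution volume
`VND = K1/k2`.

### Exact convolution and frame averaging

The input curve is piecewise linear by contract (`C(0) = 0`,
non-negative).  `e^{-theta t} (x) Cp` is evaluated *analytically* per
segment and chained with the stable recursion
`y_{k+1} = y_k e^{-theta dt} + J_k`; near-zero exponents use series
expansions of `(1-e^-x)/x` and `(1-e^-x(1+x))/x^2`.  Model TACs are
averaged over each frame interval analytically via the ODE identity
`int_a^b y = (int_a^b Cp - (y(b)-y(a)))/theta` (limit form below
`theta*t_max < 1e-7`), because midpoint sampling would bias 10-s early
frames against 5-min late frames.  A numba-compiled inner loop carries the
recursion; a vectorised log-domain numpy implementation of the same math
is the fallback and the cross-check.

## Non-linear fitting and model selection

Weighted least squares with weights proportional to frame duration
(longer frames have lower relative variance under count statistics;
uniform weighting is available).  Optimisation is trust-region reflective
within bounds `K1, k2, k3, k4 in [0,5]`, `Vb in [0,0.5]`.  Multi-start:
a grid of 3 log-spaced values per rate constant and `Vb in {0.03, 0.1}`
is ranked by initial cost; the best 16 starts are run at coarse tolerance
and the 3 best minima re-polished at 1e-12 (the full grid can be forced
with `n_refine=None`).  On noise-free data the sweep stops at the
numerical noise floor, where no start can improve.  Standard errors come
from the Gauss-Newton covariance `(J^T J)^{-1} RSS/(n-p)`.

Model selection uses `AIC = n ln(RSS/n) + 2p` (Gaussian, constant
dropped; no small-sample correction).  Richer models are warm-started
from nested optima, so best-fit RSS is monotone in model complexity, and
an RSS at the noise floor is treated as zero so that exact fits tie and
the tie breaks toward fewer parameters.

## Patlak analysis

`y = C(t)/Cp(t)` against `x = int_0^t Cp/Cp(t)` over frames with mid-time
`>= t* = 15 min` (the last seven frames of the default schedule),
unweighted OLS by default.  Two properties worth remembering when reading
results:

* the slope on the *measured* signal is `(1-Vb) Ki` exactly — Patlak does
  not remove the blood-volume scaling any more than the uncorrected
  basis-function solve does;
* with reversible kinetics (`k4 > 0`) the slope underestimates `Ki` and
  the intercept `Ve` overestimates the distribution volume.  In a liver
  with a small reversible component this is precisely why Patlak images
  show lower normal-liver background and hence *higher* lesion contrast
  than the compartmental Ki images — a useful artefact of a violated
  assumption, and the pipeline reproduces it.

Equilibration bias decays with `t*`: for liver-like kinetics
(`k2+k3 ~ 0.26/min`) it is about -2% at `t* = 15` and under -1% at
`t* = 20`; for lesion-range kinetics it is below 1% at `t* = 15`.
Sensitivity to `t* in {10, 15, 20}` can be probed by passing `t_star`.

## Basis-function parametric imaging

For each `theta = k2+k3` on a 64-point log grid over `[0.006, 3]` 1/min
(chosen to span the kinetics implied by the liver/lesion parameter ranges
with margin), the frame-averaged column `B_theta = e^{-theta t} (x) Cp` is
precomputed.  Each voxel solves the non-negative linear model
`C = Vb C_b + alpha int(Cp) + beta B_theta` and keeps the `theta`
minimising RSS.  With three columns the exact NNLS solution is found by
enumerating all 7 coefficient support sets — deterministic, fully
vectorised across voxels, and testable against an independent NNLS solver.
Micro-parameters: `K1 = alpha+beta`, `k3 = theta alpha/K1`,
`k2 = theta beta/K1`, and identically `Ki = alpha`, `VND = K1/k2`.

Blood-volume convention: the linear solve uses the *unscaled* form, so
tissue coefficients carry the `(1-Vb)` factor (~5-12% on `K1`/`Ki` at
typical blood volumes).  `vb_correction=True` divides them out.  The
default is the uncorrected form; the VOI-level NLLS, by contrast, models
`(1-Vb) C_T + Vb C_b` and reports unscaled micro-parameters.  Because the
two conventions differ by a near-constant factor, VOI-mean parametric Ki
and NLLS Ki still agree with R^2 > 0.99 on phantoms, which is the level at
which the two routes are compared.

Voxels are fitted inside a mask of time-summed activity above 1% of the
image maximum; all-zero voxels are excluded from the fitted mask.
Voxel-wise Patlak uses the same closed-form OLS per voxel.

## SUV, contrast and cutoff calibration

`SUV = C(Bq/mL) * weight(g) / injected activity(Bq)`, invariant to a
common decay-correction convention on image and dose.  T/N contrast is
lesion max (or mean) over normal-liver mean, computed per lesion for SUV,
compartmental Ki and Patlak Ki maps.  Cutoff calibration regresses lesion
Ki on lesion SUV (SUV-mean), predicts Ki at the reference SUV of 6.0, and
propagates the 95% CI from the full coefficient covariance (independent-SE
mode available; it coincides when the covariance is negligible).  The SUV
interval corresponding to the Ki cutoff comes from Fieller inversion of
the confidence band.

## Test-retest statistics

Relative Bland-Altman differences `d = 2(x2-x1)/(x1+x2) x 100%`; the
repeatability coefficient defaults to `RC% = 1.96 sqrt(mean d^2)` — the
paired form of `1.96 sqrt(2) wCV` with the `sqrt(2)` absorbed by using
within-pair differences.  Log-ratio (`1.96 sqrt2 * sqrt(e^{s^2}-1)`) and
`2.77 wCV` conventions are implemented behind a flag and named in every
report; at moderate wCV they differ by well under one percentage point.
Deming regression uses an error-variance ratio of 1 (same scanner and
protocol at both visits).  Note the Deming slope equals the geometric mean
of the two OLS slopes only when the marginal variances are equal (or the
correlation is perfect) — a sharper condition than "centered data".

## Synthetic studies

The generator's defaults define the study conditions:

* **Input function**: linear-rise/tri-exponential decay
  (Feng-type) `Cp(t) = (A1 t' - A2 - A3)e^{-l1 t'} + A2 e^{-l2 t'} +
  A3 e^{-l3 t'}`, `t' = t - 0.25 min`, with `A = (600, 30, 25)` kBq/mL
  and `l = (4.0, 0.5, 0.008)` 1/min: a ~110 kBq/mL first-pass peak near
  0.6 min (consistent with a ~240 MBq injection), fast clearance, and a
  slow tail that supports extrapolation to the 2 h/4 h static points.
* **Phantom**: 64x64x32 voxels at 3.9x3.9x3.27 mm.  Liver block with
  `K1 = 0.37`, `Ki = 0.015` (via `k2 = 0.25`), `k4 = 0.01` for the small
  reversible component seen in normal liver, `Vb = 0.12`.  Twelve
  spherical lesions, diameters 30 down to 8 mm, all with delivery below
  the liver's (`K1 = 0.02-0.38`) and net influx spanning receptor-negative
  to strongly positive (`Ki = 0.003-0.095`), `Vb = 0.05`.  An aorta
  cylinder carries the pure blood curve for IDIF extraction.
* **Noise**: Gaussian with `sigma = 0.6 sqrt(C/dt)` per frame (variance
  proportional to concentration over frame duration), giving ~4-5%
  late-frame CV on liver voxels; static volumes are noise-free.
* **Test-retest**: each visit multiplies every lesion's Ki by an
  independent lognormal factor (default wCV 10.8%) implemented through
  `k3`, leaving `K1`, `k2` and the liver untouched, plus an independent
  noise realisation.

Not emulated: point-spread blurring (an optional Gaussian approximating
the ~7-8 mm reconstructed resolution exists for demos but is off by
default), anatomy, motion, scatter.  Passing phantom tests therefore
demonstrates estimator correctness under the stated noise model, not
robustness to partial-volume or motion effects; sub-resolution lesions
(8-12 mm) recover accurately here only because no blurring is applied.

## Problem sizes

The default verification workloads are sized for a desk run: 100-draw
nesting checks, a 6x6x6 recovery grid, 100 noisy AIC replicates, one
64x64x32 phantom for the parametric-vs-VOI comparison, 2000 simulated
test-retest pairs, and 100 cutoff-coverage replicates.  The full suite and
the acceptance script each complete in a few minutes on one core.
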