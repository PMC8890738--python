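# Methods

This note records the model, the numerical choices, and the places where the
design was genuinely open, in enough detail to reproduce or modify any part.

## Geometry and conventions

All world coordinates are LPS millimetres (the DICOM/ITK convention); FCSV
fiducial files, which store RAS, are sign-flipped on the first two axes at
read/write. Voxel indexing is 0-based and refers to voxel centres:
`world = origin + direction @ (spacing * index)`.

The rigid transform is `T(p) = R (p − c) + c + t` with a fixed rotation
centre `c` and Euler angles composed as `R = Rz·Ry·Rx` (intrinsic z-y-x),
in radians. Neither the Euler convention nor the centre is forced by the
problem; both are pinned here because landmark scoring is meaningless
without them. The centre is the world centre of the fixed cropped ROI,
which decouples the rotation and translation scales. The registration
transform follows the *resampling convention* — it maps fixed-domain points
into the moving image — and landmark evaluation therefore maps moving
fiducials back through its inverse.

Parameter scaling: inside the optimisers, rotation parameters are
multiplied by the ROI half-diagonal (mm), so a unit step in any scaled
parameter displaces edge voxels comparably. Without this, gradient methods
see a needlessly ill-conditioned problem.

## Virtual domain

Metric sampling happens on an isotropic grid covering the fixed crop, with
spacing equal to the arithmetic mean of the six input spacing components
(clamped below by the smallest of them). The mean voxel spacing is also the
displacement cap δ — one characteristic length serves both purposes. The
domain never extends beyond the fixed crop's bounding box.

## Similarity metrics

**MSE** (monomodal option): mean of `(I_F(p) − I_M(T(p)))²` over the valid
samples; gradient `2(I_M − I_F)·∇I_M·J_μ` averaged the same way.

**Negative Mattes mutual information** (default): joint density from a
Parzen-windowed histogram over the sample set — a zero-order (box) kernel
on fixed intensities, a cubic B-spline kernel on moving intensities, 32
bins by default. Intensities are windowed to the [p1, p99] percentiles of
each crop, computed once per registration (robust to metal-streak
outliers); moving intensities map into bin coordinates [2, bins−2] so the
4-tap kernel never leaves the table. MI is reported in nats. The gradient
is the exact derivative of the Parzen density through the moving-image
intensity:

    ∂S/∂μ = (1/(n·Δm)) Σ_j [ Σ_l β₃'(l − m̃_j) · L(k_j, l) ] · ∇I_M·J_μ(p_j)

with `L = log(p/p_M)` where the joint density is positive.

Sampling: 2048 points per iteration, uniform over the virtual domain,
re-drawn each iteration with seed + iteration (this per-iteration refresh is
what makes every optimiser here stochastic). Samples mapping outside either
image are dropped; if fewer than 25% survive, the evaluation raises an
overlap error, which the optimisers convert to a failed run — silent
extrapolation corrupts MI.

Interpolation: trilinear for intensity, and the *exact analytic gradient of
the trilinear interpolant* for the spatial gradient (the derivative of the
interpolation weights, not a finite-difference stencil on the grid). This
makes the analytic metric gradient the true derivative of the value the
metric computes, so finite-difference checks measure chain-rule correctness
only. The metric value is continuous but has O(1/n) jumps when a sample
crosses an image border (its validity is discrete) and derivative kinks at
voxel-cell faces; gradient-oracle tests therefore restrict their frozen
plans to samples ≥ 2 voxels inside both images (`interior_plan`) and use
h = 1e-6, small enough that essentially no sample crosses a cell face
inside the difference stencil.

## Optimiser family

All runs share: ≤ 100 iterations; a displacement cap (no ROI corner moves
more than δ per accepted step, enforced by rescaling the step); early stop
when the capped step displacement stays below 0.01·δ for 5 consecutive
iterations; and a failure surrogate — non-finite metric/gradient, loss of
overlap, or a final metric value worse than the initial one by more than
2× its magnitude. The 100-iteration cap is the protocol's fixed budget;
the early-stop and failure rules are this package's operationalisation of
"the metric is still large" and "failed to produce a valid result", which
have no standard definition.

Step-size sequence (first-order methods): λ₀ = 1, then
λ_k = η / ((t_k + 1)/A + 1) with decay speed A = 20 and noise factor
η ∈ [0, 1]. The time variable accumulates
`sigmoid(−gain · corr(g_{k−1}, g_{k−2}))` (gain 5, correlation normalised
to [−1, 1]): consistently correlated gradients keep t near zero and the
step large; anticorrelated gradients — oscillation around a minimum — drive
t up and the step down. The sigmoid's sign and scaling are not standardised;
this choice matches adaptive-SGD practice and is config-exposed.

* **asgd** — direction −a·g with the conversion constant a = δ/rate₀
  calibrated from the first gradient (so the first full-trust step displaces
  the ROI by ≈ δ). The noise factor η is re-estimated *every iteration* from
  a second, independent gradient probe (signal = squared mean, noise =
  squared half-difference, exponentially averaged), costing 2 metric
  evaluations per iteration.
* **fasgd** — the fast, less adaptive variant: η is frozen at an initial
  5-probe estimate and the decay clock is deterministic (t_k = k/2), costing
  1 evaluation per iteration. Which two constants the fast variant freezes
  is not standardised; freezing the noise factor and the adaptation clock
  reproduces the intended cost/adaptivity trade.
* **slbfgs** (default) — direction −H⁻¹g via the two-loop recursion over a
  5-pair memory, initial scaling γ = (s·y)/(y·y) from the newest pair.
  Curvature pairs are (g at μ_k, g at μ_{k+1}) evaluated on one shared
  sample plan (consistent sampling); pairs with y·s ≤ 1e−12·|y||s| are
  skipped, preserving positive definiteness without damping. The descent
  gradient uses a fresh plan each iteration. The first step, taken with an
  empty memory, is normalised and capped at δ. Three evaluations per
  iteration.
* **fpsgd** — μ ← μ − λ_k·M·g with a diagonal preconditioner estimated once
  before iteration 0: m_i = δ / (E[‖J_i‖·|g_i|] + 2·sd[‖J_i‖·|g_i|] + ε),
  expectations over 5 gradient probes and the ROI corner points, ε = 1e−12.
  The spread term is written as twice the standard deviation — a variance
  there would be dimensionally inconsistent with the mean. The noise factor
  for λ is estimated once with the preconditioner as the metric M.

Noise-factor estimator: η = |ḡᵀMḡ| / (|ḡᵀMḡ| + E[εᵀMε]) from repeated
gradient draws at a fixed μ, residuals taken around the probe mean with the
(n−1)/n small-sample correction. Noise-free objectives give η = 1; pure
noise drives η → 0.

## Pipeline

Cochlea localisation is a user-supplied seed fiducial per volume (an
interactive click in practice); no automatic detector is provided, and the
optional intensity-centroid helper is never applied silently. The initial
transform is the seed-to-seed translation with zero rotation. Crop box:
10 mm, config-exposed; metric: Mattes MI for every modality pair by default
(CT-family monomodal pairs may opt into MSE via a legacy flag — in practice
even CBCT-to-MDCT registers better under MI). There is deliberately no
multi-resolution pyramid and no multi-stage schedule. Fusion output always
lives on the fixed grid.

## Phantom generator

The phantom emulates what the pipeline can sense, not cochlear anatomy: a
conical spiral (2.5 turns, 4 mm basal radius tapering by 65%, 0.6 mm tube,
4 mm rise — cochlea-scaled so the 10 mm crop is meaningful) rendered as a
smooth "boniness" field: background 0.3, a Gaussian bony shell (width
0.25 mm) peaking near 1 at tube-radius distance, a fluid lumen dipping
toward 0 on the centreline. CT-like volumes show this field directly
(bone bright); MR-like volumes are its monotone inversion (fluid bright) —
exactly the relationship MI can exploit and MSE cannot; the artefact mode
adds bright planar streaks through the cochlea centre, exceeding the CT
maximum, as a metal-artefact stand-in. Noise is Gaussian (CT modes) or
Rician (MR mode) on the unit field; volumes are quantised to int16 so
fixtures are bit-identical across platforms.

The moving volume is rendered analytically in the moving frame (centreline
mapped through the ground-truth transform) rather than resampled from the
fixed rendering: rigid maps preserve distances to the centreline, so the
two routes agree exactly, and analytic rendering avoids blurring only one
side of the pair. Landmarks ("RW" at the basal entry, "Apex" at the tip)
are analytic in both frames and satisfy `moving = truth(fixed)` to machine
precision. Default grids: fixed 76×76×40 at 0.15×0.15×0.3 mm, moving
58×58×36 at 0.2×0.2×0.35 mm — clinically anisotropic, desk-scale cheap.

Benchmark suites cycle the four modality-pair groups of the clinical
protocol (CT/CT, CT/MR, CT-artefact/CT, MR/CT analogues). Easy pairs:
rotations ≤ 5°, translations ≤ 2 mm, noise σ = 0.02; hard pairs: ≤ 15°,
≤ 8 mm, σ = 0.08, artefact mode on one side. Seed points are the true
helix centre jittered by ≤ 0.4 mm, emulating manual clicks.

What passing phantom tests does **not** show: performance under real
anatomy (no surrounding temporal-bone structure competes with the helix),
real artefact physics (streaks here are smooth and stationary), intensity
inhomogeneity, or patient motion. The phantom establishes that the
machinery — metric, gradients, optimisers, geometry bookkeeping — is
correct, not that clinical accuracy transfers.

## Problem sizes and tolerances

The shipped benchmarks use 20-pair suites, 2048 samples and the 100-iteration
budget (a registration takes ~1.5 s on one CPU; the acceptance script runs
in about a minute). Gradient oracles use 3000-point interior plans and
h = 1e−6. The two-loop/dense quasi-Newton comparison uses SPD-generated
curvature pairs so the 1e−12 agreement measures algorithmic equivalence
rather than conditioning.

## Known limitations

* The failure asymmetry between preconditioned SGD and s-LBFGS reported on
  clinical material does not reproduce on the phantom: the displacement cap
  and the tight 10 mm ROI keep every optimiser from diverging even at high
  noise. The failure *detector* is exercised directly on objectives that
  genuinely blow up.
* The metric treats sample validity discretely, so its value has tiny jumps
  at the image border; harmless in optimisation (the δ-cap bounds steps)
  but visible to finite differences, hence the interior-plan oracle design.
* MI estimates carry the usual positive plug-in bias (~0.03 nats at 32 bins
  / 5000 samples); irrelevant for optimisation, which only compares values.
* Only rigid alignment: no affine or B-spline stage, by design.
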