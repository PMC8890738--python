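# cochreg

Rigid multimodal registration and fusion of cochlea 3D volumes, built around
a **stochastic limited-memory BFGS** optimiser and a **Parzen-windowed
mutual-information** metric.

## The problem

After cochlear implantation, MR imaging is contraindicated or ruined by the
metal artefact of the electrode array, so postoperative assessment relies on
CT-family scans (CBCT/MDCT) that show bone but not the fluid-filled scalae.
Fusing the preoperative MR (soft tissue) with the postoperative CT (electrode
and bone) puts both in one image — but first the studies must be aligned.
Because the anatomy of interest is a ~10 mm spiral inside an ~80 mm field,
and the modalities have unrelated intensity scales, this is a small-target,
multimodal, intra-subject **rigid** registration problem.

## The method

Registration minimises a similarity metric over the 6 rigid parameters
μ = (θx, θy, θz, tx, ty, tz):

    μ̂ = argmin S( I_F(P), I_M(T(P, μ)) )

* Both volumes are cropped to a 10 mm box around a user-supplied cochlea
  seed point; a common isotropic *virtual domain* over the fixed crop
  reconciles the differing resolutions.
* `S` is negative **Mattes mutual information**: a joint Parzen histogram
  (box kernel on fixed intensities, cubic B-spline kernel on moving
  intensities) evaluated on a few thousand random voxels, re-drawn every
  iteration — the stochastic part. Its analytic gradient ∂S/∂μ flows through
  the trilinear interpolant's spatial gradient and the rigid transform's
  Jacobian J_μ.
* The default optimiser is **s-LBFGS**: quasi-Newton search directions from
  the two-loop recursion over a short history of (Δμ, Δg) pairs, with
  curvature pairs evaluated on a *shared* sample plan so they measure
  curvature, not sampling noise. Steps are capped so no point of the region
  of interest moves more than δ mm per iteration, where δ is the mean voxel
  spacing of the pair. The iteration budget is 100.
* Alternatives for comparison: adaptive SGD (`asgd`), its frozen-constant
  fast variant (`fasgd`), and diagonally preconditioned SGD (`fpsgd`).
* Fusion is voxelwise addition of the aligned pair (each operand optionally
  rescaled to [0, 255] over its robust intensity window).

Accuracy is scored as the RMSE in mm between two expert fiducials (round
window, cochlear apex) after mapping the moving-image fiducials into fixed
space; robustness is `N_success / (N_success + N_fail)` over attempts.

Since no clinical data ship with the package, a deterministic **phantom
generator** renders cochlea-scaled helical pairs (CT-like, MR-like and
metal-streak modes) with known ground-truth transforms and analytic
landmarks, so every stage is testable against truth.

## Worked example

Generate a phantom pair, register it, and score the result:

```
$ cochreg phantom --seed 7 --n-pairs 1 --out pairs
wrote 1 phantom pair(s) to pairs

$ cochreg register --fixed pairs/easy-000_fixed.nrrd \
    --moving pairs/easy-000_moving.nrrd \
    --fixed-seed-fcsv pairs/easy-000_fixed.fcsv \
    --moving-seed-fcsv pairs/easy-000_moving.fcsv \
    --optimizer slbfgs --seed 1 --out reg
registration succeeded: metric=mattes_mi elapsed=1.6s -> reg

$ cochreg evaluate --transform reg/transform.txt \
    --fixed-fcsv pairs/easy-000_fixed.fcsv \
    --moving-fcsv pairs/easy-000_moving.fcsv
landmark RMSE: 0.0972 mm over 2 landmarks
```

The recovered alignment is accurate to 0.10 mm — about two thirds of the
smallest voxel dimension (0.15 mm) — on a pair whose true misalignment was
up to 5 degrees and 2 mm. `reg/` also contains the fused volume, the
transform as a plain-text file, the per-iteration metric trace, and a
provenance JSON.

A multi-method sweep over a seeded suite:

```
$ cochreg benchmark --n-pairs 4 --methods slbfgs,asgd --repeats 3 --seed 2 --out bench
method  n_trials  rmse_mean_mm  rmse_sd_mm  time_mean_s  robustness  p_vs_reference
slbfgs        12      0.106026    0.059251     1.495440         1.0             NaN
  asgd        12      0.106737    0.042229     0.949956         1.0         0.97238
```

Each row aggregates 4 phantom pairs x 3 repeats: mean landmark RMSE and its
SD over pairs, mean wall time per registration, the fraction of successful
runs, and a Welch-test p-value against the reference method.

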