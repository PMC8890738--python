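"""End-to-end registration driver and command-line interface.

The driver mirrors the clinical workflow: both volumes are cropped to a
small box (default 10 mm) around a user-supplied cochlea seed point, the
initial transform translates the moving seed onto the fixed one, a common
isotropic virtual domain is built over the cropped fixed extent, and the
configured stochastic optimiser minimises the similarity metric (negative
Mattes mutual information by default) for at most 100 iterations.  The
result transform maps fixed-domain points into the moving image; fusion
resamples the moving volume onto the fixed grid and adds the two.
"""

from __future__ import annotations

import argparse
import dataclasses
import hashlib
import json
import os
import sys
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import metrics as _metrics
from .metrics import (DegenerateIntensityError, MetricOverlapError,
                      draw_samples, intensity_window, mattes_mi_metric,
                      mse_metric)
from .optimizers import (OPTIMIZERS, OptimizerConfig, StochasticObjective,
                         compute_delta)
from .rigid_transform import (DomainOverlapError, RigidTransform,
                              build_virtual_domain, resample_to_image,
                              save_transform, load_transform)
from .volume_model import (Image3D, index_to_world, read_fiducials,
                           read_volume, world_to_index, write_fiducials,
                           write_volume)

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "crop_to_cochlea",
    "select_metric",
    "register",
    "apply_and_fuse",
    "run_cli",
    "main",
]

# Monomodal CT-family tags for which the legacy MSE metric is permitted.
_CT_FAMILY = {"CBCT", "MDCT", "CT"}


@dataclass
class RegistrationConfig:
    optimizer: str = "slbfgs"
    metric: Optional[str] = None      # None = choose from modality tags
    crop_edge_mm: float = 10.0
    samples: int = _metrics.DEFAULT_SAMPLES
    bins: int = _metrics.DEFAULT_BINS
    seed: int = 0
    max_iterations: int = 100
    background: float = 0.0
    normalise_fusion: bool = True
    legacy_mse: bool = False          # allow MSE on monomodal CT pairs
    crop: bool = True

    def __post_init__(self):
        if self.crop_edge_mm <= 0:
            raise ValueError("crop box edge must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}; "
                             f"choose from {sorted(OPTIMIZERS)}")
        if self.metric not in (None, "mse", "mattes_mi"):
            raise ValueError(f"unknown metric {self.metric!r}")

    def with_updates(self, **kw) -> "RegistrationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class RegistrationResult:
    transform: RigidTransform
    status: str                      # "success" | "failed"
    trace: list
    elapsed_s: float
    virtual_spacing: float
    delta: float
    metric_name: str
    provenance: dict = field(default_factory=dict)


def crop_to_cochlea(img: Image3D, seed_point, box_edge_mm: float = 10.0) -> Image3D:
    """Axis-aligned sub-volume of edge ~box_edge_mm centred on the seed.

    The box edge is rounded to whole voxels and clamped at the image
    borders; the cropped origin is updated so every kept voxel retains its
    world position exactly.
    """
    seed = np.asarray(seed_point, dtype=float).reshape(3)
    idx = world_to_index(img, seed)
    shape = np.array(img.shape)
    if np.any(idx < 0) or np.any(idx > shape - 1):
        raise ValueError(
            f"seed point {seed.tolist()} mm maps to voxel index "
            f"{np.round(idx, 2).tolist()} outside the {tuple(shape)} grid"
        )
    half = np.maximum(1, np.round(0.5 * box_edge_mm / img.spacing)).astype(int)
    centre = np.round(idx).astype(int)
    lo = np.clip(centre - half, 0, shape - 2)
    hi = np.clip(centre + half, lo + 2, shape)
    out = img.copy()
    out.intensities = img.intensities[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    out.origin = index_to_world(img, lo.astype(float))
    return out


def select_metric(modality_fixed: str, modality_moving: str,
                  legacy_mse: bool = False) -> str:
    """Metric choice by modality pair.

    The default is Mattes MI for every pair — in practice even CT-family
    monomodal pairs register better under MI.  With the legacy flag,
    identical CT-family tags (CBCT/CBCT, MDCT/MDCT) fall back to MSE.
    """
    f, m = modality_fixed.upper(), modality_moving.upper()
    if legacy_mse and f == m and f in _CT_FAMILY:
        return "mse"
    return "mattes_mi"


def register(fixed: Image3D, moving: Image3D, fixed_seed, moving_seed,
             config: Optional[RegistrationConfig] = None) -> RegistrationResult:
    """Crop, initialise, optimise: the full registration driver.

    Never raises on optimisation failure: the result carries status
    "failed" and the best transform found so far.
    """
    config = config or RegistrationConfig()
    t_start = time.perf_counter()
    fixed_seed = np.asarray(fixed_seed, dtype=float).reshape(3)
    moving_seed = np.asarray(moving_seed, dtype=float).reshape(3)

    if config.crop:
        fixed_c = crop_to_cochlea(fixed, fixed_seed, config.crop_edge_mm)
        moving_c = crop_to_cochlea(moving, moving_seed, config.crop_edge_mm)
    else:
        fixed_c, moving_c = fixed, moving

    # Initial transform: seed-to-seed translation, zero rotation; rotation
    # centre at the world centre of the fixed cropped ROI.
    lo, hi = fixed_c.world_bounds()
    center = 0.5 * (lo + hi)
    mu0 = np.concatenate([np.zeros(3), moving_seed - fixed_seed])
    T0 = RigidTransform(parameters=mu0, center=center)

    metric_name = config.metric or select_metric(
        fixed.modality_tag or "CBCT", moving.modality_tag or "CBCT",
        legacy_mse=config.legacy_mse)

    failure = None
    try:
        domain = build_virtual_domain(fixed_c, moving_c, initial=T0)
        windows = (intensity_window(fixed_c), intensity_window(moving_c))
    except (DomainOverlapError, DegenerateIntensityError) as exc:
        failure = str(exc)
        domain = None

    if failure is not None:
        return RegistrationResult(
            transform=T0, status="failed", trace=[],
            elapsed_s=time.perf_counter() - t_start, virtual_spacing=np.nan,
            delta=np.nan, metric_name=metric_name,
            provenance=_provenance(config, fixed, moving, error=failure))

    if metric_name == "mse":
        def metric_fn(T, plan):
            return mse_metric(fixed_c, moving_c, T, plan)
    else:
        def metric_fn(T, plan):
            return mattes_mi_metric(fixed_c, moving_c, T, plan,
                                    bins=config.bins, windows=windows)

    def evaluate(mu, plan):
        return metric_fn(RigidTransform(parameters=mu, center=center), plan)

    def make_plan(tag):
        return draw_samples(domain, config.samples, int(tag) % (2 ** 31 - 1),
                            refresh_policy="per_iteration")

    corners = np.array([[a, b, c] for a in (lo[0], hi[0])
                        for b in (lo[1], hi[1]) for c in (lo[2], hi[2])])
    objective = StochasticObjective(evaluate=evaluate, make_plan=make_plan,
                                    corner_points=corners, center=center)

    half_diag = 0.5 * float(np.linalg.norm(hi - lo))
    opt_config = OptimizerConfig(
        max_iterations=config.max_iterations,
        delta=compute_delta(fixed_c, moving_c),
        scales=np.array([half_diag] * 3 + [1.0] * 3),
        seed=config.seed,
    )

    state = OPTIMIZERS[config.optimizer](objective, mu0, opt_config)
    status = "failed" if state.status == "failed" else "success"
    transform = RigidTransform(parameters=state.mu, center=center)
    return RegistrationResult(
        transform=transform, status=status, trace=state.trace,
        elapsed_s=time.perf_counter() - t_start,
        virtual_spacing=domain.spacing, delta=opt_config.delta,
        metric_name=metric_name,
        provenance=_provenance(config, fixed, moving,
                               optimizer_status=state.status,
                               eval_count=state.eval_count))


def _provenance(config, fixed, moving, **extra) -> dict:
    def digest(img):
        return hashlib.sha256(np.ascontiguousarray(img.intensities)
                              .tobytes()).hexdigest()[:16]
    p = {"config": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in dataclasses.asdict(config).items()},
         "fixed_sha": digest(fixed), "moving_sha": digest(moving)}
    p.update(extra)
    return p


def _robust_rescale(img: Image3D) -> np.ndarray:
    arr = np.asarray(img.intensities, dtype=float)
    lo, hi = np.percentile(arr, [1, 99])
    if hi <= lo:
        return np.zeros_like(arr)
    return np.clip((arr - lo) / (hi - lo), 0, 1) * 255.0


def apply_and_fuse(fixed: Image3D, moving: Image3D, T: RigidTransform,
                   normalise: bool = True, background: float = 0.0) -> Image3D:
    """Resample the moving image onto the fixed grid via T, then add.

    With ``normalise`` each operand is linearly rescaled to [0, 255] over
    its robust [p1, p99] window first, so modalities with very different
    intensity ranges contribute comparably to the composite.
    """
    resampled = resample_to_image(moving, T, fixed, background=background)
    if normalise:
        a = _robust_rescale(fixed)
        b = _robust_rescale(resampled)
    else:
        a = np.asarray(fixed.intensities, dtype=float)
        b = np.asarray(resampled.intensities, dtype=float)
    out = fixed.copy()
    out.intensities = a + b
    out.modality_tag = "fused"
    return out


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _build_parser() -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(
        prog="cochreg",
        description="Rigid multimodal registration and fusion of cochlea "
                    "volumes (stochastic quasi-Newton optimisation).")
    sub = p.add_subparsers(dest="command", required=True)

    reg = sub.add_parser("register", help="register and fuse a volume pair")
    reg.add_argument("--fixed", required=True)
    reg.add_argument("--moving", required=True)
    reg.add_argument("--fixed-seed-fcsv", required=True,
                     help="fiducial file whose first point seeds the fixed crop")
    reg.add_argument("--moving-seed-fcsv", required=True)
    reg.add_argument("--optimizer", default="slbfgs", choices=sorted(OPTIMIZERS))
    reg.add_argument("--metric", default=None, choices=["mse", "mattes_mi"])
    reg.add_argument("--crop-edge-mm", type=float, default=10.0)
    reg.add_argument("--samples", type=int, default=_metrics.DEFAULT_SAMPLES)
    reg.add_argument("--bins", type=int, default=_metrics.DEFAULT_BINS)
    reg.add_argument("--seed", type=int, default=0)
    reg.add_argument("--max-iterations", type=int, default=100)
    reg.add_argument("--out", required=True, help="output directory")

    fuse = sub.add_parser("fuse", help="fuse a pair with a saved transform")
    fuse.add_argument("--fixed", required=True)
    fuse.add_argument("--moving", required=True)
    fuse.add_argument("--transform", required=True)
    fuse.add_argument("--no-normalise", action="store_true")
    fuse.add_argument("--out", required=True, help="output volume path")

    ev = sub.add_parser("evaluate", help="landmark RMSE of a saved transform")
    ev.add_argument("--transform", required=True)
    ev.add_argument("--fixed-fcsv", required=True)
    ev.add_argument("--moving-fcsv", required=True)

    ph = sub.add_parser("phantom", help="generate a synthetic phantom pair")
    ph.add_argument("--seed", type=int, default=0)
    ph.add_argument("--difficulty", default="easy", choices=["easy", "hard"])
    ph.add_argument("--n-pairs", type=int, default=1)
    ph.add_argument("--out", required=True, help="output directory")

    bench = sub.add_parser("benchmark", help="phantom benchmark sweep")
    bench.add_argument("--n-pairs", type=int, default=8)
    bench.add_argument("--difficulty", default="easy", choices=["easy", "hard"])
    bench.add_argument("--methods", default="slbfgs,asgd")
    bench.add_argument("--repeats", type=int, default=3)
    bench.add_argument("--samples", type=int, default=_metrics.DEFAULT_SAMPLES)
    bench.add_argument("--seed", type=int, default=0)
    bench.add_argument("--out", required=True, help="output directory")
    return p


def _cmd_register(args) -> int:
    fixed = read_volume(args.fixed)
    moving = read_volume(args.moving)
    fseed = read_fiducials(args.fixed_seed_fcsv)
    mseed = read_fiducials(args.moving_seed_fcsv)
    if len(fseed) == 0 or len(mseed) == 0:
        print("error: seed fiducial files must contain at least one point",
              file=sys.stderr)
        return 1
    config = RegistrationConfig(
        optimizer=args.optimizer, metric=args.metric,
        crop_edge_mm=args.crop_edge_mm, samples=args.samples, bins=args.bins,
        seed=args.seed, max_iterations=args.max_iterations)
    result = register(fixed, moving, fseed.points[0], mseed.points[0], config)

    os.makedirs(args.out, exist_ok=True)
    save_transform(result.transform, os.path.join(args.out, "transform.txt"))
    with open(os.path.join(args.out, "trace.csv"), "w") as fh:
        fh.write("k,value,lam,step_norm,n_valid\n")
        for row in result.trace:
            fh.write(f"{row['k']},{row['value']:.10g},{row['lam']:.10g},"
                     f"{row['step_norm']:.10g},{row['n_valid']}\n")
    with open(os.path.join(args.out, "provenance.json"), "w") as fh:
        json.dump({"status": result.status, "metric": result.metric_name,
                   "elapsed_s": result.elapsed_s,
                   "virtual_spacing_mm": result.virtual_spacing,
                   "delta_mm": result.delta,
                   **result.provenance}, fh, indent=2, default=str)
    fused = apply_and_fuse(fixed, moving, result.transform,
                           normalise=config.normalise_fusion)
    write_volume(fused, os.path.join(args.out, "fused.nrrd"))
    if result.status != "success":
        print("registration FAILED; best-so-far transform written",
              file=sys.stderr)
        return 2
    print(f"registration succeeded: metric={result.metric_name} "
          f"elapsed={result.elapsed_s:.1f}s -> {args.out}")
    return 0


def _cmd_fuse(args) -> int:
    fixed = read_volume(args.fixed)
    moving = read_volume(args.moving)
    T = load_transform(args.transform)
    fused = apply_and_fuse(fixed, moving, T, normalise=not args.no_normalise)
    write_volume(fused, args.out)
    print(f"fused volume written to {args.out}")
    return 0


def _cmd_evaluate(args) -> int:
    from .evaluation import landmark_rmse
    T = load_transform(args.transform)
    flms = read_fiducials(args.fixed_fcsv)
    mlms = read_fiducials(args.moving_fcsv)
    rmse = landmark_rmse(T, flms, mlms)
    print(f"landmark RMSE: {rmse:.4f} mm over {len(flms)} landmarks")
    return 0


def _cmd_phantom(args) -> int:
    from .phantom import make_benchmark_suite
    from .rigid_transform import save_transform as save_T
    os.makedirs(args.out, exist_ok=True)
    pairs = make_benchmark_suite(args.n_pairs, args.difficulty, seed=args.seed)
    for pair in pairs:
        stem = os.path.join(args.out, pair.pair_id)
        write_volume(pair.fixed, stem + "_fixed.nrrd")
        write_volume(pair.moving, stem + "_moving.nrrd")
        write_fiducials(pair.fixed_lms, stem + "_fixed.fcsv")
        write_fiducials(pair.moving_lms, stem + "_moving.fcsv")
        save_T(pair.truth, stem + "_truth.txt")
        spec = {"group": list(pair.group),
                "noise_sigma": pair.spec.noise_sigma,
                "seed": pair.spec.seed,
                "spacing": list(pair.spec.spacing),
                "moving_spacing": list(pair.spec.moving_spacing),
                "true_parameters": pair.truth.parameters.tolist(),
                "fixed_seed_point": pair.fixed_seed_point.tolist(),
                "moving_seed_point": pair.moving_seed_point.tolist()}
        with open(stem + "_spec.json", "w") as fh:
            json.dump(spec, fh, indent=2)
    print(f"wrote {len(pairs)} phantom pair(s) to {args.out}")
    return 0


def _cmd_benchmark(args) -> int:
    from .evaluation import run_benchmark, summarize_benchmark
    from .phantom import make_benchmark_suite
    os.makedirs(args.out, exist_ok=True)
    pairs = make_benchmark_suite(args.n_pairs, args.difficulty, seed=args.seed)
    methods = [m.strip() for m in args.methods.split(",") if m.strip()]
    config = RegistrationConfig(samples=args.samples, seed=args.seed)
    records = run_benchmark(pairs, methods, repeats=args.repeats,
                            config=config, seed=args.seed)
    records.to_csv(os.path.join(args.out, "trials.csv"), index=False)
    summary = summarize_benchmark(records)
    summary.to_csv(os.path.join(args.out, "summary.csv"), index=False)
    print(summary.to_string(index=False))
    return 0


_COMMANDS = {"register": _cmd_register, "fuse": _cmd_fuse,
             "evaluate": _cmd_evaluate, "phantom": _cmd_phantom,
             "benchmark": _cmd_benchmark}


def run_cli(argv=None) -> int:
    """Entry point returning an exit code: 0 ok, 1 usage, 2 failed run."""
    parser = _build_parser()
    try:
        args = parser.parse_args(argv)
    except SystemExit as exc:
        return 0 if exc.code in (0, None) else 1
    try:
        return _COMMANDS[args.command](args)
    except (FileNotFoundError, ValueError, MetricOverlapError,
            DomainOverlapError) as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 1


def main() -> None:
    sys.exit(run_cli())
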