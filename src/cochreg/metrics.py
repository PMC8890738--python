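"""Stochastic voxel sampling and similarity metrics with analytic gradients.

Two metrics are provided, both minimised:

* ``mse_metric`` — mean squared intensity error, for monomodal pairs;
* ``mattes_mi_metric`` — negative Mattes mutual information, the multimodal
  workhorse.  The joint density is a Parzen-windowed histogram: a zero-order
  (box) kernel on fixed-image intensities and a cubic B-spline kernel on
  moving-image intensities, which makes the density — and hence the metric —
  differentiable with respect to the transform parameters.

Gradients with respect to the 6 rigid parameters are assembled by the chain
rule: the metric's derivative with respect to the interpolated moving
intensity, times the spatial gradient of the trilinear interpolant, times
the transform Jacobian ``J_mu``.  Because the spatial gradient is the exact
derivative of the interpolant, the analytic gradient matches central finite
differences of the metric value on a frozen sample plan to discretisation
accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .volume_model import Image3D, world_to_index
from .rigid_transform import (RigidTransform, VirtualDomain,
                              jacobian_wrt_parameters, transform_points)

__all__ = [
    "SamplePlan",
    "MetricEvaluation",
    "MetricOverlapError",
    "DegenerateIntensityError",
    "draw_samples",
    "mse_metric",
    "mattes_mi_metric",
    "finite_difference_gradient",
    "intensity_window",
    "interior_plan",
    "joint_parzen_histogram",
]

DEFAULT_BINS = 32
DEFAULT_SAMPLES = 2048
MIN_OVERLAP_FRACTION = 0.25


class MetricOverlapError(RuntimeError):
    """Too few samples land inside both images: overlap has been lost."""


class DegenerateIntensityError(RuntimeError):
    """An image has (near-)constant intensity; MI binning is undefined."""


@dataclass
class SamplePlan:
    """A frozen set of virtual-domain sample points.

    ``refresh_policy`` records how the owner re-draws: ``"fixed"`` plans are
    reused verbatim (test oracles, finite differences), ``"per_iteration"``
    plans are re-drawn by the optimiser with ``seed + iteration``.
    """

    points: np.ndarray
    seed: int
    refresh_policy: str = "per_iteration"
    domain: VirtualDomain | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 1:
            raise ValueError("a sample plan needs at least one point")
        if self.refresh_policy not in ("fixed", "per_iteration"):
            raise ValueError(f"unknown refresh policy {self.refresh_policy!r}")

    @property
    def count(self) -> int:
        return len(self.points)

    def refresh(self, iteration: int) -> "SamplePlan":
        """New plan for the given iteration (identity for fixed plans)."""
        if self.refresh_policy == "fixed" or self.domain is None:
            return self
        return draw_samples(self.domain, self.count, self.seed + iteration,
                            refresh_policy=self.refresh_policy)


@dataclass
class MetricEvaluation:
    value: float
    gradient: np.ndarray
    n_valid: int

    def __post_init__(self):
        self.gradient = np.asarray(self.gradient, dtype=float).reshape(6)
        if not np.all(np.isfinite(self.gradient)):
            raise ValueError("metric gradient must be finite")


def draw_samples(domain: VirtualDomain, n: int, seed: int,
                 refresh_policy: str = "per_iteration") -> SamplePlan:
    """Draw ``n`` points uniformly at random over the domain interior.

    Deterministic in ``seed``.  Sampling is with replacement, so ``n`` may
    exceed the voxel count (a warning is emitted, not an error).
    """
    if n < 1:
        raise ValueError("need at least one sample")
    nvox = int(np.prod(domain.shape))
    if n > nvox:
        warnings.warn(f"drawing {n} samples from a {nvox}-voxel domain "
                      "(sampling with replacement)", stacklevel=2)
    rng = np.random.default_rng(seed)
    upper = np.array(domain.shape, dtype=float) - 1.0
    idx = rng.uniform(low=0.0, high=upper, size=(n, 3))
    pts = domain.origin + (idx * domain.spacing) @ domain.direction.T
    return SamplePlan(points=pts, seed=seed, refresh_policy=refresh_policy,
                      domain=domain)


# ---------------------------------------------------------------------------
# Trilinear interpolation with its exact spatial gradient
# ---------------------------------------------------------------------------

def trilinear_interpolate(img: Image3D, world_points: np.ndarray):
    """Trilinear value, exact world-space gradient and inside-mask.

    Returns ``(values, gradients, inside)`` with shapes (n,), (n, 3), (n,).
    Points outside the grid get value 0 and zero gradient, flagged by the
    mask.  The gradient is the true derivative of the piecewise-trilinear
    interpolant (constant per cell along each axis), which is what the
    metric value actually varies by.
    """
    arr = np.asarray(img.intensities, dtype=float)
    shape = np.array(arr.shape)
    idx = world_to_index(img, np.asarray(world_points, dtype=float).reshape(-1, 3))
    inside = np.all((idx >= 0) & (idx <= shape - 1), axis=1)

    i0 = np.clip(np.floor(idx).astype(int), 0, shape - 2)
    f = idx - i0  # fractional position in the cell, in [0, 1] where inside

    # Gather the 8 cell corners.
    c = np.empty(idx.shape[:1] + (2, 2, 2))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                c[:, dx, dy, dz] = arr[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]

    wx = np.stack([1 - f[:, 0], f[:, 0]], axis=1)
    wy = np.stack([1 - f[:, 1], f[:, 1]], axis=1)
    wz = np.stack([1 - f[:, 2], f[:, 2]], axis=1)
    dwx = np.stack([-np.ones(len(f)), np.ones(len(f))], axis=1)

    values = np.einsum("nxyz,nx,ny,nz->n", c, wx, wy, wz)
    gx = np.einsum("nxyz,nx,ny,nz->n", c, dwx, wy, wz)
    gy = np.einsum("nxyz,nx,ny,nz->n", c, wx, dwx, wz)
    gz = np.einsum("nxyz,nx,ny,nz->n", c, wx, wy, dwx)
    grad_index = np.stack([gx, gy, gz], axis=1)

    # d(index)/d(world) = diag(1/spacing) @ D^T, so grad_w = D @ (g_idx / s).
    grad_world = (grad_index / img.spacing) @ img.direction.T

    values = np.where(inside, values, 0.0)
    grad_world[~inside] = 0.0
    return values, grad_world, inside


# ---------------------------------------------------------------------------
# MSE
# ---------------------------------------------------------------------------

def _sample_pair(fixed: Image3D, moving: Image3D, T: RigidTransform,
                 plan: SamplePlan):
    """Fixed values at plan points; moving values/gradients at T(points)."""
    pts = plan.points
    fvals, _, fin = trilinear_interpolate(fixed, pts)
    mapped = transform_points(T, pts)
    mvals, mgrad, m_in = trilinear_interpolate(moving, mapped)
    valid = fin & m_in
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise MetricOverlapError("no sample landed inside both images")
    if n_valid < MIN_OVERLAP_FRACTION * plan.count:
        raise MetricOverlapError(
            f"only {n_valid}/{plan.count} samples overlap both images "
            f"(< {MIN_OVERLAP_FRACTION:.0%}); registration has lost overlap"
        )
    J = jacobian_wrt_parameters(T, pts[valid])  # (n, 3, 6)
    # dI_M(T(p))/dmu for each valid sample: (n, 6)
    dmove = np.einsum("nc,ncp->np", mgrad[valid], J)
    return fvals[valid], mvals[valid], dmove, n_valid


def mse_metric(fixed: Image3D, moving: Image3D, T: RigidTransform,
               plan: SamplePlan) -> MetricEvaluation:
    """Mean squared error over the valid samples, with its analytic gradient."""
    f, m, dmove, n_valid = _sample_pair(fixed, moving, T, plan)
    diff = m - f
    value = float(np.mean(diff ** 2))
    grad = 2.0 * (diff @ dmove) / n_valid
    return MetricEvaluation(value=value, gradient=grad, n_valid=n_valid)


# ---------------------------------------------------------------------------
# Mattes mutual information
# ---------------------------------------------------------------------------

def intensity_window(img: Image3D, lo_pct: float = 1.0,
                     hi_pct: float = 99.0) -> tuple:
    """Robust [p1, p99] intensity window, guarding degenerate images."""
    lo, hi = np.percentile(np.asarray(img.intensities, dtype=float),
                           [lo_pct, hi_pct])
    if hi - lo <= 0:
        raise DegenerateIntensityError(
            f"intensity window [{lo}, {hi}] is degenerate (constant image?)"
        )
    return float(lo), float(hi)


def _bspline3(x: np.ndarray) -> np.ndarray:
    """Cubic B-spline kernel, support (-2, 2), partition of unity."""
    ax = np.abs(x)
    out = np.zeros_like(ax)
    inner = ax < 1
    outer = (ax >= 1) & (ax < 2)
    out[inner] = 2.0 / 3.0 - ax[inner] ** 2 + 0.5 * ax[inner] ** 3
    out[outer] = ((2.0 - ax[outer]) ** 3) / 6.0
    return out


def _bspline3_deriv(x: np.ndarray) -> np.ndarray:
    ax = np.abs(x)
    out = np.zeros_like(ax)
    inner = ax < 1
    outer = (ax >= 1) & (ax < 2)
    out[inner] = -2.0 * ax[inner] + 1.5 * ax[inner] ** 2
    out[outer] = -0.5 * (2.0 - ax[outer]) ** 2
    return out * np.sign(x)


def _mi_bin_coords(fvals, mvals, fixed_window, moving_window, bins):
    """Fixed hard-bin indices and continuous moving bin coordinates.

    Moving intensities map into [2, bins-2] so the 4-tap cubic kernel never
    leaves the histogram (the standard 2-bin padding).
    """
    flo, fhi = fixed_window
    mlo, mhi = moving_window
    fbw = (fhi - flo) / bins
    fbin = np.clip(np.floor((fvals - flo) / fbw).astype(int), 0, bins - 1)
    mbw = (mhi - mlo) / (bins - 4)
    mcont = 2.0 + (np.clip(mvals, mlo, mhi) - mlo) / mbw
    clipped = (mvals <= mlo) | (mvals >= mhi)
    return fbin, mcont, mbw, clipped


def joint_parzen_histogram(fbin, mcont, bins):
    """Joint Parzen pdf p[k, l]: box kernel in k (fixed), cubic in l (moving).

    Rows/columns each sum to the respective marginal; the whole table sums
    to 1 by the kernel's partition of unity.
    """
    n = len(fbin)
    p = np.zeros((bins, bins))
    t0 = np.minimum(np.floor(mcont).astype(int) - 1, bins - 4)
    for tap in range(4):
        l = t0 + tap
        w = _bspline3(l - mcont)
        np.add.at(p, (fbin, l), w)
    return p / n


def mattes_mi_metric(fixed: Image3D, moving: Image3D, T: RigidTransform,
                     plan: SamplePlan, bins: int = DEFAULT_BINS,
                     windows: tuple | None = None) -> MetricEvaluation:
    """Negative Mattes mutual information and its analytic gradient.

    ``windows`` optionally carries precomputed (fixed, moving) robust
    intensity windows so an optimisation loop bins consistently across
    iterations; by default they are the [p1, p99] percentiles of each image.
    MI is reported in nats.
    """
    if bins < 8:
        raise ValueError("need at least 8 histogram bins")
    fwin = windows[0] if windows else intensity_window(fixed)
    mwin = windows[1] if windows else intensity_window(moving)

    f, m, dmove, n_valid = _sample_pair(fixed, moving, T, plan)
    fbin, mcont, mbw, clipped = _mi_bin_coords(f, m, fwin, mwin, bins)

    p = joint_parzen_histogram(fbin, mcont, bins)
    pf = p.sum(axis=1)
    pm = p.sum(axis=0)

    pos = p > 0
    log_term = np.zeros_like(p)
    outer = pf[:, None] * pm[None, :]
    log_term[pos] = np.log(p[pos] / outer[pos])
    mi = float(np.sum(p[pos] * log_term[pos]))

    # d(-MI)/dmu = sum_j [sum_l beta'(l - mcont_j) * L[fbin_j, l]]
    #              * dI_M/dmu_j / (n * mbw),   L = log(p / pM) where p > 0.
    L = np.zeros_like(p)
    pm_pos = pos & (pm[None, :] > 0)
    L[pm_pos] = np.log(p[pm_pos] / np.broadcast_to(pm, p.shape)[pm_pos])

    t0 = np.minimum(np.floor(mcont).astype(int) - 1, bins - 4)
    coeff = np.zeros(n_valid)
    for tap in range(4):
        l = t0 + tap
        coeff += _bspline3_deriv(l - mcont) * L[fbin, l]
    # Samples clipped to the window edge have zero intensity sensitivity.
    coeff[clipped] = 0.0
    grad = (coeff @ dmove) / (n_valid * mbw)

    return MetricEvaluation(value=-mi, gradient=grad, n_valid=n_valid)


def interior_plan(plan: SamplePlan, fixed: Image3D, moving: Image3D,
                  T: RigidTransform, margin_voxels: float = 2.0) -> SamplePlan:
    """Restrict a plan to samples mapping well inside both images under T.

    The metric value has O(1/n) jumps whenever a sample crosses an image
    boundary (its validity is discrete); a finite-difference gradient
    oracle amplifies those jumps by 1/h.  Filtering to samples at least
    ``margin_voxels`` inside both grids removes every crossing for the
    small parameter perturbations a central difference takes, so the
    comparison isolates the smooth part both gradients share.
    """
    pts = plan.points
    fidx = world_to_index(fixed, pts)
    midx = world_to_index(moving, transform_points(T, pts))
    ok = np.ones(len(pts), dtype=bool)
    for idx, img in ((fidx, fixed), (midx, moving)):
        hi = np.array(img.shape) - 1 - margin_voxels
        ok &= np.all((idx >= margin_voxels) & (idx <= hi), axis=1)
    if not ok.any():
        raise MetricOverlapError("no interior samples under the given transform")
    return replace(plan, points=pts[ok], refresh_policy="fixed")


# ---------------------------------------------------------------------------
# Finite-difference oracle
# ---------------------------------------------------------------------------

def finite_difference_gradient(metric, T: RigidTransform, plan: SamplePlan,
                               h: float = 1e-4) -> np.ndarray:
    """Central-difference gradient of a metric value on a frozen plan.

    ``metric`` is any callable ``(T, plan) -> MetricEvaluation``; the plan is
    reused verbatim on both sides of each difference so only the transform
    parameters move.
    """
    if h <= 0:
        raise ValueError("step h must be positive")
    g = np.zeros(6)
    for j in range(6):
        dp = np.zeros(6)
        dp[j] = h
        hi = metric(T.with_parameters(T.parameters + dp), plan).value
        lo = metric(T.with_parameters(T.parameters - dp), plan).value
        g[j] = (hi - lo) / (2 * h)
    return g
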