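"""Deterministic synthetic cochlea-pair generator.

The phantom is a tapering helical tube — a cochlea-scaled spiral (default
2.5 turns, 4 mm basal radius, 0.6 mm tube radius) rendered into a small 3D
grid with clinical-like anisotropic voxel spacing.  A pair consists of a
fixed and a moving volume related by a known ground-truth rigid transform,
with analytically placed landmarks at the round-window end ("RW") and the
helix tip ("Apex"), so that every stage of the registration pipeline can be
scored against truth without clinical data.

Modality emulation works on a normalised "boniness" field ``u``: the bony
shell around the tube is bright under the CT-like mapping and dark under the
MR-like mapping (a monotone inversion, which is exactly the relationship
mutual information can exploit and mean-squared-error cannot); the
``cbct_artifact`` mode adds bright streaks through the cochlea emulating the
metal artefact of an implanted electrode.  Noise is Gaussian for CT-like
modes and Rician for MR-like ones; volumes are quantised to 16-bit integers
so fixtures are bit-identical across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .volume_model import Image3D, LandmarkSet, index_to_world
from .rigid_transform import RigidTransform, transform_points

__all__ = [
    "HelixSpec",
    "PhantomSpec",
    "PhantomPair",
    "MODALITY_MODES",
    "generate_phantom",
    "modality_remap",
    "make_benchmark_suite",
    "PHANTOM_GROUPS",
]

MODALITY_MODES = ("ct_like", "mr_like", "cbct_artifact")
INTENSITY_SCALE = 1000.0

# Desk-scale analogues of the four clinical modality-pair groups.
PHANTOM_GROUPS = (
    ("ct_like", "ct_like"),        # CBCT-CBCT analogue
    ("ct_like", "mr_like"),        # CBCT-MR analogue
    ("cbct_artifact", "ct_like"),  # CBCT-MDCT analogue (implant side fixed)
    ("mr_like", "ct_like"),        # MR-MDCT analogue
)


@dataclass
class HelixSpec:
    """Geometry of the conical spiral centreline and its tube."""

    turns: float = 2.5
    base_radius: float = 4.0   # mm, radius of the basal turn
    taper: float = 0.65        # fractional radius loss base -> apex
    tube_radius: float = 0.6   # mm
    height: float = 4.0        # mm, axial rise base -> apex

    def centreline(self, n: int = 2000) -> np.ndarray:
        """Points along the spiral, base (s=0) to apex (s=1), centred at 0."""
        s = np.linspace(0.0, 1.0, n)
        phi = 2 * np.pi * self.turns * s
        r = self.base_radius * (1.0 - self.taper * s)
        x = r * np.cos(phi)
        y = r * np.sin(phi)
        z = self.height * (s - 0.5)
        return np.stack([x, y, z], axis=1)

    def radial_extent(self) -> float:
        """Max distance of any tube/shell voxel from the helix axis centre."""
        shell = 2.5 * _SHELL_WIDTH
        return float(np.sqrt((self.base_radius + self.tube_radius + shell) ** 2
                             + (0.5 * self.height + self.tube_radius + shell) ** 2))


_SHELL_WIDTH = 0.25  # mm, Gaussian width of the bony shell around the tube


@dataclass
class PhantomSpec:
    shape: tuple = (76, 76, 40)
    spacing: tuple = (0.15, 0.15, 0.3)
    moving_shape: tuple | None = None
    moving_spacing: tuple | None = None
    helix: HelixSpec = field(default_factory=HelixSpec)
    modality_pair: tuple = ("ct_like", "ct_like")
    true_transform: RigidTransform = field(default_factory=RigidTransform)
    noise_sigma: float = 0.0     # on the unit-scaled field
    seed: int = 0

    def __post_init__(self):
        for mode in self.modality_pair:
            if mode not in MODALITY_MODES:
                raise ValueError(f"unknown modality mode {mode!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.moving_shape is None:
            self.moving_shape = self.shape
        if self.moving_spacing is None:
            self.moving_spacing = self.spacing
        self._check_fit(self.shape, self.spacing)
        self._check_fit(self.moving_shape, self.moving_spacing)

    def _check_fit(self, shape, spacing):
        half_fov = 0.5 * (np.array(shape) - 1) * np.array(spacing)
        margin = 2 * np.array(spacing)
        ext = _axis_extents(self.helix)
        if np.any(half_fov - margin < ext):
            raise ValueError(
                f"helix (per-axis extent {np.round(ext, 2)} mm) does not fit "
                f"inside the {shape} grid at spacing {spacing} with a "
                f"2-voxel margin"
            )


def _axis_extents(h: HelixSpec) -> np.ndarray:
    """Half-extent of the rendered structure along each axis, in mm."""
    shell = 2.5 * _SHELL_WIDTH
    rxy = h.base_radius + h.tube_radius + shell
    rz = 0.5 * h.height + h.tube_radius + shell
    return np.array([rxy, rxy, rz])


def _grid_world_points(shape, spacing, origin):
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    return origin + idx * np.array(spacing)


def _render_base_field(points: np.ndarray, helix: HelixSpec,
                       curve: np.ndarray) -> np.ndarray:
    """Normalised boniness field u(x) in [0, 1] from distance to centreline.

    Background soft tissue sits at 0.3; a Gaussian shell of bone peaks near
    1 at tube-radius distance; the fluid-filled lumen dips towards 0 on the
    centreline.  Smooth everywhere, so metric gradients are informative.
    """
    tree = cKDTree(curve)
    d, _ = tree.query(points, k=1)
    rt = helix.tube_radius
    u = (0.3
         + 0.7 * np.exp(-((d - rt) / _SHELL_WIDTH) ** 2)
         - 0.29 * np.exp(-(d / (0.6 * rt)) ** 2))
    return np.clip(u, 0.0, 1.0)


def _streak_pattern(points: np.ndarray, centre: np.ndarray,
                    seed: int) -> np.ndarray:
    """Bright metal-like streaks: thin planes through the cochlea centre."""
    rng = np.random.default_rng(seed + 77)
    streak = np.zeros(len(points))
    for _ in range(3):
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        dist = (points - centre) @ normal
        streak = np.maximum(streak, np.exp(-(dist / 0.15) ** 2))
    return 0.5 * streak


def _apply_mode(u: np.ndarray, mode: str, points: np.ndarray,
                centre: np.ndarray, seed: int) -> np.ndarray:
    if mode == "ct_like":
        return u
    if mode == "mr_like":
        return 1.0 - u  # monotone inversion: fluid bright, bone dark
    if mode == "cbct_artifact":
        return u + _streak_pattern(points, centre, seed)
    raise ValueError(f"unknown modality mode {mode!r}")


def _apply_noise(vals: np.ndarray, mode: str, sigma: float,
                 rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return vals
    if mode == "mr_like":  # Rician: magnitude of complex Gaussian noise
        n1 = rng.normal(0, sigma, vals.shape)
        n2 = rng.normal(0, sigma, vals.shape)
        return np.sqrt((vals + n1) ** 2 + n2 ** 2)
    return vals + rng.normal(0, sigma, vals.shape)


def _quantise(vals: np.ndarray) -> np.ndarray:
    return np.round(np.clip(vals, -2.0, 4.0) * INTENSITY_SCALE).astype(np.int16)


def modality_remap(img: Image3D, mode: str) -> Image3D:
    """Re-express a normalised label/base field under a modality mapping.

    Operates on the image's unit-scaled field; applying the same mode twice
    is the identity (detected via the modality tag).
    """
    if mode not in MODALITY_MODES:
        raise ValueError(f"unknown modality mode {mode!r}")
    if img.modality_tag == mode:
        return img.copy()
    u = np.asarray(img.intensities, dtype=float) / INTENSITY_SCALE
    shape = img.shape
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    pts = index_to_world(img, idx)
    centre = pts.mean(axis=0)
    vals = _apply_mode(u.reshape(-1), mode, pts, centre, seed=0)
    out = img.copy()
    out.intensities = _quantise(vals).reshape(shape)
    out.modality_tag = mode
    return out


def generate_phantom(spec: PhantomSpec):
    """Render a fixed/moving phantom pair with ground truth.

    Returns ``(fixed, moving, truth, fixed_lms, moving_lms)``.  The truth
    transform maps fixed-frame points to moving-frame points (the
    resampling convention used by the registration driver), so the moving
    anatomy is the fixed anatomy pushed through ``truth``: the helix
    centreline is mapped analytically and re-rendered in the moving frame,
    and the landmarks obey ``moving_lms = truth(fixed_lms)`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    helix = spec.helix
    curve = helix.centreline()
    truth = spec.true_transform

    fixed_mode, moving_mode = spec.modality_pair

    # Fixed grid centred on the helix (world origin at the helix centre).
    f_spacing = np.array(spec.spacing, dtype=float)
    f_origin = -0.5 * (np.array(spec.shape) - 1) * f_spacing
    f_pts = _grid_world_points(spec.shape, f_spacing, f_origin)
    u_f = _render_base_field(f_pts, helix, curve)
    vals_f = _apply_mode(u_f, fixed_mode, f_pts, np.zeros(3), spec.seed)
    vals_f = _apply_noise(vals_f, fixed_mode, spec.noise_sigma, rng)
    fixed = Image3D(intensities=_quantise(vals_f).reshape(spec.shape),
                    spacing=f_spacing, origin=f_origin, direction=np.eye(3),
                    modality_tag=fixed_mode)

    # Moving grid centred on the transformed helix.
    curve_m = transform_points(truth, curve)
    centre_m = transform_points(truth, np.zeros(3))
    m_spacing = np.array(spec.moving_spacing, dtype=float)
    m_origin = centre_m - 0.5 * (np.array(spec.moving_shape) - 1) * m_spacing
    m_pts = _grid_world_points(spec.moving_shape, m_spacing, m_origin)
    u_m = _render_base_field(m_pts, helix, curve_m)
    vals_m = _apply_mode(u_m, moving_mode, m_pts, centre_m, spec.seed)
    vals_m = _apply_noise(vals_m, moving_mode, spec.noise_sigma, rng)
    moving = Image3D(intensities=_quantise(vals_m).reshape(spec.moving_shape),
                     spacing=m_spacing, origin=m_origin, direction=np.eye(3),
                     modality_tag=moving_mode)

    fixed_lms = LandmarkSet(labels=["RW", "Apex"],
                            points=np.array([curve[0], curve[-1]]))
    moving_lms = LandmarkSet(labels=["RW", "Apex"],
                             points=transform_points(truth,
                                                     fixed_lms.points))
    return fixed, moving, truth, fixed_lms, moving_lms


@dataclass
class PhantomPair:
    """One benchmark case: a generated pair plus everything needed to run
    and score a registration."""

    pair_id: str
    group: tuple
    spec: PhantomSpec
    fixed: Image3D
    moving: Image3D
    truth: RigidTransform
    fixed_lms: LandmarkSet
    moving_lms: LandmarkSet
    fixed_seed_point: np.ndarray
    moving_seed_point: np.ndarray


DIFFICULTY = {
    # max |rotation| deg, max |translation| mm, noise sigma, artefacts
    "easy": {"rot_deg": 5.0, "trans_mm": 2.0, "sigma": 0.02, "artifact": False},
    "hard": {"rot_deg": 15.0, "trans_mm": 8.0, "sigma": 0.08, "artifact": True},
}


def make_benchmark_suite(n_pairs: int, difficulty: str = "easy",
                         seed: int = 0) -> list:
    """Seeded suite of phantom pairs cycling the four modality groups.

    Easy pairs have rotations <= 5 degrees, translations <= 2 mm and low
    noise; hard pairs allow 15 degrees / 8 mm, high noise, and put the
    metal-artefact mode on one side of every pair.  Seed points emulate
    manually clicked cochlea centres: the true helix centre jittered by up
    to 0.4 mm.
    """
    if n_pairs < 1:
        raise ValueError("need at least one pair")
    if difficulty not in DIFFICULTY:
        raise ValueError(f"difficulty must be one of {sorted(DIFFICULTY)}")
    d = DIFFICULTY[difficulty]
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_pairs):
        group = PHANTOM_GROUPS[i % len(PHANTOM_GROUPS)]
        if d["artifact"] and "cbct_artifact" not in group:
            group = ("cbct_artifact", group[1])
        angles = np.deg2rad(rng.uniform(-d["rot_deg"], d["rot_deg"], 3))
        trans = rng.uniform(-d["trans_mm"], d["trans_mm"], 3)
        truth = RigidTransform(parameters=np.concatenate([angles, trans]),
                               center=np.zeros(3))
        spec = PhantomSpec(
            modality_pair=group,
            moving_spacing=(0.2, 0.2, 0.35),
            moving_shape=(58, 58, 36),
            true_transform=truth,
            noise_sigma=d["sigma"],
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        fixed, moving, truth, flms, mlms = generate_phantom(spec)
        jitter_f = rng.uniform(-0.4, 0.4, 3)
        jitter_m = rng.uniform(-0.4, 0.4, 3)
        centre_m = transform_points(truth, np.zeros(3))
        pairs.append(PhantomPair(
            pair_id=f"{difficulty}-{i:03d}",
            group=group,
            spec=spec,
            fixed=fixed, moving=moving, truth=truth,
            fixed_lms=flms, moving_lms=mlms,
            fixed_seed_point=jitter_f,
            moving_seed_point=centre_m + jitter_m,
        ))
    return pairs
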