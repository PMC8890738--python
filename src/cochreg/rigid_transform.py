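"""6-parameter 3D rigid transforms, their parameter Jacobian, resampling and
the common virtual domain.

The parameter vector is ``mu = (rx, ry, rz, tx, ty, tz)``: Euler angles in
radians followed by a translation in mm.  The rotation is applied about a
fixed ``center`` (world mm), with matrices composed in Z*Y*X order
(``R = Rz @ Ry @ Rx``), i.e. intrinsic rotations about z, then y, then x:

    T(p) = R (p - c) + c + t

Registration uses the resampling convention: the optimised transform maps
fixed-image (virtual-domain) points into the moving image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .volume_model import Image3D, index_to_world, world_to_index

__all__ = [
    "RigidTransform",
    "VirtualDomain",
    "rotation_matrix",
    "transform_points",
    "compose",
    "invert",
    "jacobian_wrt_parameters",
    "build_virtual_domain",
    "resample",
    "save_transform",
    "load_transform",
]


def _rx(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _ry(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def rotation_matrix(angles) -> np.ndarray:
    """R = Rz(rz) @ Ry(ry) @ Rx(rx) for angles (rx, ry, rz) in radians."""
    rx, ry, rz = angles
    return _rz(rz) @ _ry(ry) @ _rx(rx)


@dataclass
class RigidTransform:
    """Rigid map p -> R(angles) (p - center) + center + translation."""

    parameters: np.ndarray = field(default_factory=lambda: np.zeros(6))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.parameters = np.asarray(self.parameters, dtype=float).reshape(-1)
        if self.parameters.shape != (6,):
            raise ValueError("rigid transform needs exactly 6 parameters")
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    @property
    def angles(self) -> np.ndarray:
        return self.parameters[:3]

    @property
    def translation(self) -> np.ndarray:
        return self.parameters[3:]

    @property
    def rotation(self) -> np.ndarray:
        return rotation_matrix(self.angles)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix equivalent of the transform."""
        R = self.rotation
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = self.center + self.translation - R @ self.center
        return m

    def with_parameters(self, parameters) -> "RigidTransform":
        return RigidTransform(parameters=np.asarray(parameters, float),
                              center=self.center.copy())


def transform_points(T: RigidTransform, points) -> np.ndarray:
    """Apply T to one point or an (n, 3) array of world points (mm)."""
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    p = p.reshape(-1, 3)
    out = (p - T.center) @ T.rotation.T + T.center + T.translation
    return out[0] if single else out


def compose(outer: RigidTransform, inner: RigidTransform) -> "np.ndarray":
    """Homogeneous matrix of outer after inner: outer(inner(p))."""
    return outer.matrix() @ inner.matrix()


def invert(T: RigidTransform) -> RigidTransform:
    """Rigid inverse with the same rotation centre.

    Uses the closed form: R_inv = R^T and the Euler angles of R^T are
    recovered from its matrix; the translation is chosen so that
    invert(T)(T(p)) = p exactly.
    """
    Ri = T.rotation.T
    angles = _euler_from_matrix(Ri)
    t_inv = -Ri @ T.translation
    return RigidTransform(parameters=np.concatenate([angles, t_inv]),
                          center=T.center.copy())


def _euler_from_matrix(R: np.ndarray) -> np.ndarray:
    """Angles (rx, ry, rz) with R = Rz @ Ry @ Rx; gimbal lock handled."""
    sy = -R[2, 0]
    sy = np.clip(sy, -1.0, 1.0)
    ry = np.arcsin(sy)
    if abs(abs(sy) - 1.0) > 1e-12:
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
    else:  # cos(ry) = 0: rx and rz are degenerate, fold into rx
        rx = np.arctan2(-R[1, 2], R[1, 1])
        rz = 0.0
    return np.array([rx, ry, rz])


def jacobian_wrt_parameters(T: RigidTransform, point) -> np.ndarray:
    """3x6 Jacobian dT(p, mu)/dmu at a world point.

    Columns 0-2 are dR/d(rx,ry,rz) @ (p - center); columns 3-5 are the
    identity (translation block).  Supports an (n, 3) batch, returning
    (n, 3, 6).
    """
    p = np.asarray(point, dtype=float)
    single = p.ndim == 1
    p = p.reshape(-1, 3)
    rx, ry, rz = T.angles
    d = p - T.center  # (n, 3)

    Rx, Ry, Rz = _rx(rx), _ry(ry), _rz(rz)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    dRx = np.array([[0, 0, 0], [0, -sx, -cx], [0, cx, -sx]])
    dRy = np.array([[-sy, 0, cy], [0, 0, 0], [-cy, 0, -sy]])
    dRz = np.array([[-sz, -cz, 0], [cz, -sz, 0], [0, 0, 0]])

    A0 = Rz @ Ry @ dRx
    A1 = Rz @ dRy @ Rx
    A2 = dRz @ Ry @ Rx

    n = len(d)
    J = np.zeros((n, 3, 6))
    J[:, :, 0] = d @ A0.T
    J[:, :, 1] = d @ A1.T
    J[:, :, 2] = d @ A2.T
    J[:, :, 3:] = np.eye(3)
    return J[0] if single else J


# ---------------------------------------------------------------------------
# Virtual domain
# ---------------------------------------------------------------------------

@dataclass
class VirtualDomain:
    """Isotropic common resampling grid covering the fixed image's extent.

    Reconciles fixed and moving images of different resolution: the metric
    and optimiser always work on this grid's world coordinates, never on
    either native grid.
    """

    shape: tuple
    spacing: float
    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = float(self.spacing)
        if self.spacing <= 0:
            raise ValueError("virtual-domain spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)

    def as_image(self, fill=0.0, modality_tag="virtual") -> Image3D:
        return Image3D(
            intensities=np.full(self.shape, fill, dtype=float),
            spacing=np.full(3, self.spacing),
            origin=self.origin,
            direction=self.direction,
            modality_tag=modality_tag,
        )

    def grid_world_points(self) -> np.ndarray:
        """World coordinates of every grid node, shape (prod(shape), 3)."""
        idx = np.stack(np.meshgrid(*[np.arange(s) for s in self.shape],
                                   indexing="ij"), axis=-1).reshape(-1, 3)
        return self.origin + (idx * self.spacing) @ self.direction.T

    def corner_points(self) -> np.ndarray:
        n = np.array(self.shape, dtype=float) - 1
        idx = np.array([[i * n[0], j * n[1], k * n[2]]
                        for i in (0, 1) for j in (0, 1) for k in (0, 1)])
        return self.origin + (idx * self.spacing) @ self.direction.T


class DomainOverlapError(RuntimeError):
    """Fixed and moving images share no world-space overlap."""


def build_virtual_domain(fixed: Image3D, moving: Image3D,
                         initial: RigidTransform | None = None) -> VirtualDomain:
    """Common isotropic grid over the fixed image's (cropped) extent.

    Spacing is the arithmetic mean of the six input spacing components,
    clamped below by the smallest of them, so images of very different
    resolution meet at one characteristic length.  Raises
    :class:`DomainOverlapError` when the moving image (mapped through the
    optional initial transform) does not intersect the fixed extent at all.
    """
    all_spacings = np.concatenate([fixed.spacing, moving.spacing])
    spacing = max(float(np.mean(all_spacings)), float(np.min(all_spacings)))

    lo_f, hi_f = fixed.world_bounds()
    # Overlap check in fixed space: map the moving bounds through the inverse
    # of the initial transform (resampling convention: T maps fixed->moving).
    lo_m, hi_m = moving.world_bounds()
    if initial is not None:
        inv = invert(initial)
        corners = np.array([[a, b, c] for a in (lo_m[0], hi_m[0])
                            for b in (lo_m[1], hi_m[1])
                            for c in (lo_m[2], hi_m[2])])
        mapped = transform_points(inv, corners)
        lo_m, hi_m = mapped.min(axis=0), mapped.max(axis=0)
    if np.any(hi_m < lo_f) or np.any(lo_m > hi_f):
        raise DomainOverlapError(
            "fixed and moving images do not overlap in world space; "
            "review the cochlea seed points or the initial alignment"
        )

    extent = hi_f - lo_f
    shape = np.maximum(2, np.floor(extent / spacing).astype(int) + 1)
    # Centre the virtual grid inside the fixed bounding box so it never
    # extends past it (invariant: domain bbox subset of fixed bbox).
    covered = (shape - 1) * spacing
    origin = lo_f + 0.5 * (extent - covered)
    return VirtualDomain(shape=tuple(shape), spacing=spacing, origin=origin,
                         direction=np.eye(3))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

_ORDERS = {"nearest": 0, "linear": 1}


def resample(moving: Image3D, T: RigidTransform, domain: VirtualDomain,
             interpolation: str = "linear", background: float = 0.0) -> Image3D:
    """Sample the moving image at T(p) over the virtual-domain grid.

    Output voxel at domain point p receives ``I_M(T(p))``; points falling
    outside the moving grid take ``background``.
    """
    if interpolation not in _ORDERS:
        raise ValueError(f"interpolation must be one of {sorted(_ORDERS)}")
    pts = domain.grid_world_points()
    mapped = transform_points(T, pts)
    dom_img = domain.as_image()
    idx = world_to_index(moving, mapped)
    values = map_coordinates(
        np.asarray(moving.intensities, dtype=float), idx.T,
        order=_ORDERS[interpolation], mode="constant", cval=background,
    )
    dom_img.intensities = values.reshape(domain.shape)
    dom_img.modality_tag = moving.modality_tag
    return dom_img


def resample_to_image(moving: Image3D, T: RigidTransform, reference: Image3D,
                      interpolation: str = "linear",
                      background: float = 0.0) -> Image3D:
    """Resample the moving image onto the grid of a reference Image3D."""
    shape = reference.shape
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    pts = index_to_world(reference, idx)
    mapped = transform_points(T, pts)
    midx = world_to_index(moving, mapped)
    values = map_coordinates(
        np.asarray(moving.intensities, dtype=float), midx.T,
        order=_ORDERS[interpolation], mode="constant", cval=background,
    )
    out = reference.copy()
    out.intensities = values.reshape(shape)
    out.modality_tag = moving.modality_tag
    return out


# ---------------------------------------------------------------------------
# Plain-text transform serialisation
# ---------------------------------------------------------------------------

def save_transform(T: RigidTransform, path) -> None:
    """Key-value text file: 6-parameter vector, centre and the 4x4 matrix."""
    m = T.matrix()
    with open(path, "w") as fh:
        fh.write("format: cochreg-rigid-v1\n")
        fh.write("parameters: " + " ".join(f"{v:.17g}" for v in T.parameters) + "\n")
        fh.write("center: " + " ".join(f"{v:.17g}" for v in T.center) + "\n")
        for row in m:
            fh.write("matrix_row: " + " ".join(f"{v:.17g}" for v in row) + "\n")


def load_transform(path) -> RigidTransform:
    params = center = None
    with open(path) as fh:
        for line in fh:
            key, _, rest = line.partition(":")
            if key.strip() == "parameters":
                params = np.array([float(v) for v in rest.split()])
            elif key.strip() == "center":
                center = np.array([float(v) for v in rest.split()])
    if params is None or center is None:
        raise ValueError(f"{path}: missing 'parameters' or 'center' line")
    return RigidTransform(parameters=params, center=center)
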