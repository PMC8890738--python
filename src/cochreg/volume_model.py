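"""Geometric image and landmark data model with volume / fiducial file I/O.

The in-memory container is :class:`Image3D`: a scalar intensity grid plus the
physical-space geometry (per-axis spacing in mm, world origin, direction
cosine matrix) that maps voxel indices to world coordinates.  All world
coordinates inside the package are expressed in the LPS frame (the DICOM/ITK
convention); Slicer fiducial files (FCSV), which store RAS points, are
converted on read and write.

Voxel indexing is 0-based and refers to voxel centres, so
``world = origin + direction @ (spacing * index)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Image3D",
    "LandmarkSet",
    "FormatError",
    "read_volume",
    "write_volume",
    "read_fiducials",
    "write_fiducials",
    "index_to_world",
    "world_to_index",
]

_VOLUME_EXTENSIONS = (".nii", ".nii.gz", ".nrrd")


class FormatError(ValueError):
    """Raised when a file's header violates the supported-format contract."""


def _as_float_array(x, shape, name):
    a = np.asarray(x, dtype=float)
    if a.shape != shape:
        raise ValueError(f"{name} must have shape {shape}, got {a.shape}")
    return a


@dataclass
class Image3D:
    """A 3D scalar volume with physical-space geometry.

    Parameters
    ----------
    intensities:
        Array of shape ``(nx, ny, nz)``; axis order matches the index order
        used by :func:`index_to_world`.
    spacing:
        Per-axis voxel size in mm, all components > 0.
    origin:
        World (LPS, mm) position of the centre of voxel ``(0, 0, 0)``.
    direction:
        3x3 orthonormal direction-cosine matrix (columns are the world
        directions of the image axes).
    modality_tag:
        Free-text modality label, e.g. ``"CBCT"``, ``"MR"``.
    """

    intensities: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray
    modality_tag: str = ""

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if min(self.intensities.shape) < 2:
            raise ValueError("grid must have at least 2 voxels per axis")
        self.spacing = _as_float_array(self.spacing, (3,), "spacing")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_float_array(self.origin, (3,), "origin")
        self.direction = _as_float_array(self.direction, (3, 3), "direction")
        if not _is_orthonormal(self.direction):
            raise ValueError(
                "direction matrix is not orthonormal (|det| must be 1 within 1e-6)"
            )

    @property
    def shape(self) -> tuple:
        return self.intensities.shape

    def world_bounds(self) -> tuple:
        """Axis-aligned world bounding box over all 8 grid corners.

        Returns (lower, upper) mm corners of the box containing every voxel
        centre.
        """
        n = np.array(self.shape) - 1
        corners = np.array(
            [[i * n[0], j * n[1], k * n[2]] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
            dtype=float,
        )
        pts = index_to_world(self, corners)
        return pts.min(axis=0), pts.max(axis=0)

    def copy(self) -> "Image3D":
        return replace(self, intensities=self.intensities.copy(),
                       spacing=self.spacing.copy(), origin=self.origin.copy(),
                       direction=self.direction.copy())


def _is_orthonormal(d: np.ndarray, tol: float = 1e-6) -> bool:
    return (np.allclose(d.T @ d, np.eye(3), atol=tol)
            and abs(abs(np.linalg.det(d)) - 1.0) < tol)


@dataclass
class LandmarkSet:
    """Ordered, uniquely labelled fiducial points in world (LPS, mm) space.

    The clinical protocol places two fiducials per study: the round window
    ("RW") and the cochlear apex ("Apex"); the container is generic.
    """

    labels: list = field(default_factory=list)
    points: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    frame: str = "LPS"

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("landmark labels must be unique")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.points[self.labels.index(label)]


# ---------------------------------------------------------------------------
# Volume I/O (NIfTI via .nii/.nii.gz, NRRD via .nrrd; both through SimpleITK)
# ---------------------------------------------------------------------------

def _check_extension(path: str) -> None:
    p = str(path)
    if not any(p.endswith(ext) for ext in _VOLUME_EXTENSIONS):
        raise FormatError(
            f"unsupported volume extension on {path!r}; expected one of "
            f"{_VOLUME_EXTENSIONS}"
        )


def read_volume(path, modality_tag: str = "") -> Image3D:
    """Read a NIfTI (.nii/.nii.gz) or NRRD (.nrrd) volume.

    Geometry is taken from the header and converted to the package's internal
    convention (LPS world frame, index axis order (x, y, z)).  A header with a
    non-orthonormal direction matrix is rejected rather than renormalised.
    """
    _check_extension(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise FormatError(f"{path!r}: expected a 3D volume, got dimension "
                          f"{img.GetDimension()}")
    direction = np.array(img.GetDirection(), dtype=float).reshape(3, 3)
    if not _is_orthonormal(direction):
        raise FormatError(
            f"{path!r}: direction matrix is not orthonormal: {direction.tolist()}"
        )
    # GetArrayFromImage returns (z, y, x); transpose to (x, y, z).
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return Image3D(
        intensities=arr,
        spacing=np.array(img.GetSpacing()),
        origin=np.array(img.GetOrigin()),
        direction=direction,
        modality_tag=modality_tag,
    )


def write_volume(img: Image3D, path) -> None:
    """Write a volume as NIfTI or NRRD; ``read_volume`` round-trips it."""
    _check_extension(path)
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    out = sitk.GetImageFromArray(np.ascontiguousarray(img.intensities.transpose(2, 1, 0)))
    out.SetSpacing(tuple(img.spacing))
    out.SetOrigin(tuple(img.origin))
    out.SetDirection(tuple(img.direction.ravel()))
    sitk.WriteImage(out, str(path))


# ---------------------------------------------------------------------------
# Fiducial I/O (Slicer Markups FCSV, RAS in file -> LPS internally)
# ---------------------------------------------------------------------------

def ras_to_lps(points: np.ndarray) -> np.ndarray:
    """Flip the sign of the first two axes (an involution)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3).copy()
    pts[:, 0] *= -1
    pts[:, 1] *= -1
    return pts


def read_fiducials(path) -> LandmarkSet:
    """Read a Slicer fiducial CSV (.fcsv) into an LPS-frame LandmarkSet.

    FCSV stores RAS coordinates in columns 1-3 (after an id column) and the
    label in column 11; comment lines start with '#'.  A plain CSV dialect
    with columns ``label,x,y,z`` (header optional, coordinates already LPS)
    is also accepted for non-Slicer workflows.
    """
    labels, pts = [], []
    is_fcsv = str(path).endswith(".fcsv")
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split(",")
            if is_fcsv:
                if len(cols) < 4:
                    raise FormatError(
                        f"{path}:{lineno}: expected id,x,y,z,... columns, got {line!r}"
                    )
                try:
                    xyz = [float(c) for c in cols[1:4]]
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric coordinate in {cols[1:4]}"
                    ) from None
                label = cols[11] if len(cols) > 11 and cols[11] else f"F-{len(labels) + 1}"
                pts.append(xyz)
                labels.append(label)
            else:
                if cols[0].lower() in ("label", "name"):
                    continue
                if len(cols) < 4:
                    raise FormatError(
                        f"{path}:{lineno}: expected label,x,y,z columns, got {line!r}"
                    )
                try:
                    xyz = [float(c) for c in cols[1:4]]
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric coordinate in {cols[1:4]}"
                    ) from None
                labels.append(cols[0])
                pts.append(xyz)
    pts = np.asarray(pts, dtype=float).reshape(-1, 3)
    if is_fcsv:
        pts = ras_to_lps(pts)
    return LandmarkSet(labels=labels, points=pts, frame="LPS")


def write_fiducials(lms: LandmarkSet, path) -> None:
    """Write a LandmarkSet as a Slicer Markups FCSV file (RAS in file)."""
    pts = ras_to_lps(lms.points)  # LPS -> RAS is the same sign flip
    with open(path, "w") as fh:
        fh.write("# Markups fiducial file version = 4.10\n")
        fh.write("# CoordinateSystem = 0\n")
        fh.write("# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n")
        for i, (label, p) in enumerate(zip(lms.labels, pts), start=1):
            fh.write(
                f"vtkMRMLMarkupsFiducialNode_{i},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f},"
                f"0,0,0,1,1,1,0,{label},,\n"
            )


# ---------------------------------------------------------------------------
# Index <-> world geometry
# ---------------------------------------------------------------------------

def index_to_world(img: Image3D, index) -> np.ndarray:
    """Map continuous voxel indices to world mm: o + D @ (s * i).

    Indices may be fractional or lie outside the grid.  Accepts a single
    index triple or an (n, 3) array; returns the matching shape.
    """
    idx = np.asarray(index, dtype=float)
    single = idx.ndim == 1
    idx = idx.reshape(-1, 3)
    world = img.origin + (idx * img.spacing) @ img.direction.T
    return world[0] if single else world


def world_to_index(img: Image3D, world) -> np.ndarray:
    """Exact inverse of :func:`index_to_world`."""
    w = np.asarray(world, dtype=float)
    single = w.ndim == 1
    w = w.reshape(-1, 3)
    idx = ((w - img.origin) @ img.direction) / img.spacing
    return idx[0] if single else idx
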