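"""Rasterization of surface-labeled vesicles and tubules on a voxel grid.

A structure (a sphere, or a capsule = cylinder with hemispherical end caps) is
surface-labeled: voxels carry signal only if their center lies within
``shell_halfwidth`` of the ideal geometric surface, emulating antibody
decoration of a membrane.  Rendered grids are orthographically projected along
the optical (z) axis into a 2D image; the objects considered here are far
smaller than the axial resolution of the microscope being emulated, so the
projection is a plain sum.

Coordinate conventions
----------------------
Voxel / pixel centers sit at ``(i + 0.5) * size`` in absolute nm.  Structures
are centered on the *center voxel* (index ``n // 2`` along each axis), so that
a degenerate point source (diameter 0, shell 0) occupies exactly one voxel.
Grid arrays are indexed ``values[ix, iy, iz]``; projection sums over ``iz``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation as _ScipyRotation

from .errors import InvalidSpecError, StructureTooLargeError

__all__ = [
    "StructureSpec",
    "GridParams",
    "VoxelGrid",
    "Image2D",
    "vesicle",
    "tubule",
    "render_structure",
    "sample_orientation",
    "project",
    "is_rotation",
]

_ROT_TOL = 1e-9


@dataclass(frozen=True)
class StructureSpec:
    """Parametric geometry of a surface-labeled structure.

    Parameters
    ----------
    shape:
        ``"vesicle"`` (sphere) or ``"tubule"`` (capsule).
    diameter:
        Sphere / tube diameter in nm.  ``0`` renders a point source.
    length:
        Tubules only: full end-to-end extent in nm, *including* the
        hemispherical caps, so ``length == diameter`` degenerates to a sphere.
    shell_halfwidth:
        Half-width of the labeled shell around the ideal surface, nm.
    """

    shape: str
    diameter: float
    length: Optional[float] = None
    shell_halfwidth: float = 5.0

    def __post_init__(self) -> None:
        if self.shape not in ("vesicle", "tubule"):
            raise InvalidSpecError(f"unknown shape {self.shape!r}")
        if self.diameter < 0:
            raise InvalidSpecError("diameter must be >= 0")
        if self.shell_halfwidth < 0:
            raise InvalidSpecError("shell_halfwidth must be >= 0")
        if self.shape == "tubule":
            if self.length is None:
                raise InvalidSpecError("tubule requires a length")
            if self.length < self.diameter:
                raise InvalidSpecError("tubule length must be >= diameter")

    @property
    def extent(self) -> float:
        """Maximum linear extent of the ideal surface, nm (shell excluded)."""
        if self.shape == "tubule":
            return float(self.length)
        return float(self.diameter)

    @property
    def label(self) -> str:
        if self.shape == "tubule":
            return f"tubule-{self.diameter:g}x{self.length:g}"
        return f"vesicle-{self.diameter:g}"


def vesicle(diameter: float, shell_halfwidth: float = 5.0) -> StructureSpec:
    return StructureSpec("vesicle", diameter, None, shell_halfwidth)


def tubule(diameter: float, length: float, shell_halfwidth: float = 5.0) -> StructureSpec:
    return StructureSpec("tubule", diameter, length, shell_halfwidth)


@dataclass(frozen=True)
class GridParams:
    """Cubic voxel grid: ``n`` voxels per axis of ``voxel_size`` nm."""

    n: int = 200
    voxel_size: float = 5.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidSpecError("n must be >= 1")
        if self.voxel_size <= 0:
            raise InvalidSpecError("voxel_size must be > 0")


@dataclass
class VoxelGrid:
    """Nonnegative 3D label density with physical voxel size in nm."""

    values: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise InvalidSpecError("VoxelGrid requires a 3D array")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise InvalidSpecError("VoxelGrid values must be finite and >= 0")
        if self.voxel_size <= 0:
            raise InvalidSpecError("voxel_size must be > 0")


@dataclass
class Image2D:
    """2D image with physical pixel size in nm.

    ``values[ix, iy]`` follows the grid convention: the first index is x.
    Pixel centers sit at ``(i + 0.5) * pixel_size`` nm.
    """

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise InvalidSpecError("Image2D requires a 2D array")
        if self.pixel_size <= 0:
            raise InvalidSpecError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple:
        return self.values.shape


def is_rotation(matrix: np.ndarray, tol: float = 1e-8) -> bool:
    """True when ``matrix`` is a proper rotation (orthonormal, det +1)."""
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        return False
    return (
        np.allclose(m.T @ m, np.eye(3), atol=tol)
        and abs(np.linalg.det(m) - 1.0) < max(tol, 1e-8)
    )


def sample_orientation(rng) -> np.ndarray:
    """Draw a rotation matrix uniformly from SO(3).

    Uses a uniform unit quaternion (4 iid standard normals, normalized), which
    yields the Haar measure on the rotation group.  ``rng`` may be an integer
    seed or a ``numpy.random.Generator``; passing a Generator advances its
    state, so repeated calls give independent orientations.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return _ScipyRotation.from_quat(q).as_matrix()


def render_structure(
    spec: StructureSpec,
    grid: GridParams = GridParams(),
    rot: Optional[np.ndarray] = None,
) -> VoxelGrid:
    """Rasterize the labeled shell of a structure centered in the grid.

    A voxel is set to 1 when its center lies within ``spec.shell_halfwidth``
    of the ideal surface: a sphere of radius ``diameter/2``, or for tubules a
    capsule whose cylindrical segment has half-length ``(length-diameter)/2``
    along ``rot @ z``.  All other voxels are 0.
    """
    if rot is None:
        rot = np.eye(3)
    rot = np.asarray(rot, dtype=float)
    if not is_rotation(rot):
        raise InvalidSpecError("rot must be a proper rotation matrix")

    vs = grid.voxel_size
    if spec.extent + 2.0 * spec.shell_halfwidth >= grid.n * vs:
        raise StructureTooLargeError(
            f"{spec.label} (+/- {spec.shell_halfwidth} nm shell) does not fit "
            f"inside a {grid.n}^3 grid of {vs} nm voxels"
        )

    c = grid.n // 2
    radius = spec.diameter / 2.0
    # Bounding cube: everything labeled lies within extent/2 + shell of center.
    half = spec.extent / 2.0 + spec.shell_halfwidth + vs
    k = int(np.ceil(half / vs)) + 1
    lo = max(0, c - k)
    hi = min(grid.n, c + k + 1)
    coords = (np.arange(lo, hi) - c) * vs
    x, y, z = np.meshgrid(coords, coords, coords, indexing="ij")

    if spec.shape == "vesicle" or spec.length == spec.diameter:
        dist = np.abs(np.sqrt(x * x + y * y + z * z) - radius)
    else:
        axis = rot @ np.array([0.0, 0.0, 1.0])
        h = (spec.length - spec.diameter) / 2.0
        t = np.clip(x * axis[0] + y * axis[1] + z * axis[2], -h, h)
        dx = x - t * axis[0]
        dy = y - t * axis[1]
        dz = z - t * axis[2]
        dist = np.abs(np.sqrt(dx * dx + dy * dy + dz * dz) - radius)

    values = np.zeros((grid.n,) * 3, dtype=np.float32)
    values[lo:hi, lo:hi, lo:hi] = (dist <= spec.shell_halfwidth + _ROT_TOL).astype(
        np.float32
    )
    return VoxelGrid(values, vs)


def project(vg: VoxelGrid) -> Image2D:
    """Orthographic projection along the optical (z) axis.

    Sums ``values[ix, iy, iz]`` over ``iz``; total intensity is conserved
    exactly and the pixel size equals the voxel size.
    """
    return Image2D(vg.values.sum(axis=2, dtype=np.float64), vg.voxel_size)
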