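"""Voxelized abscess-cavity phantoms and segmentation-mask handling.

The planning analysis works on three-region label volumes: exterior tissue
(label 0), the fibrous abscess wall (label 1), and the drained, fluid-filled
cavity interior (label 2).  Real inputs are segmented CT volumes; for
simulation studies this module generates analytic phantoms (spheres,
ellipsoids, and lobulated unions of ellipsoids) that cover the morphological
range of drained abscesses, from near-spherical to highly irregular, with
cavity diameters up to the 8 cm clinical exclusion limit.

All physical quantities are in cm.  NIfTI-1 headers store spacing in mm and
are converted at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "LabelGrid",
    "PhantomSpec",
    "WallSurface",
    "DegenerateGeometryError",
    "EmptyGeometryError",
    "generate_phantom",
    "extract_wall_shell",
    "load_mask",
    "save_mask",
    "cavity_center_of_mass",
    "wall_surface",
]

EXTERIOR, WALL, CAVITY = 0, 1, 2

#: maximum cavity diameter (cm) — clinical exclusion criterion
MAX_CAVITY_DIAMETER_CM = 8.0

#: default wall-shell thickness (cm); ~2 CT voxels, on the scale of the
#: enhancing rim seen on contrast CT, and > 1 transport mean free path at
#: mu_s = 100 cm^-1 so tissue beyond it is optically shadowed.
DEFAULT_WALL_THICKNESS_CM = 0.2

#: exterior padding (cm) kept around the wall so the absorbing domain
#: boundary does not truncate the diffuse field.
DEFAULT_EXTERIOR_PAD_CM = 1.0

_FACES = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=int,
)

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


class DegenerateGeometryError(ValueError):
    """Phantom or mask geometry too small / malformed to be meaningful."""


class EmptyGeometryError(ValueError):
    """No cavity voxels present."""


@dataclass
class LabelGrid:
    """Three-region voxel volume with physical spacing.

    Attributes
    ----------
    labels : (nx, ny, nz) int array with values in {0 exterior, 1 wall, 2 cavity}
    spacing : per-axis voxel edge length, cm
    origin : physical coordinate of the center of voxel (0, 0, 0), cm
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise DegenerateGeometryError("labels must be a non-empty 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacings must be positive")

    # -- derived quantities -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume, cm^3."""
        return float(np.prod(self.spacing))

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Physical coordinates (cm) of voxel centers for an (n, 3) index array."""
        idx = np.atleast_2d(indices)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def cavity_volume(self) -> float:
        """Cavity volume (cm^3) from the voxel count."""
        return int((self.labels == CAVITY).sum()) * self.voxel_volume

    def cavity_diameter(self) -> float:
        """Maximum cavity extent (cm) over the three axes, voxel-center based."""
        idx = np.argwhere(self.labels == CAVITY)
        if idx.size == 0:
            raise EmptyGeometryError("grid has no cavity voxels")
        span = idx.max(axis=0) - idx.min(axis=0) + 1
        return float(np.max(span * np.asarray(self.spacing)))

    # -- invariant checks ---------------------------------------------------
    def validate(self) -> None:
        """Assert the three-region invariants; raise on violation."""
        vals = np.unique(self.labels)
        if not np.all(np.isin(vals, [EXTERIOR, WALL, CAVITY])):
            raise ValueError(f"unexpected label values {vals}")
        cav = self.labels == CAVITY
        if not cav.any():
            raise EmptyGeometryError("grid has no cavity voxels")
        _, ncomp = ndimage.label(cav, structure=_STRUCT6)
        if ncomp != 1:
            raise ValueError(f"cavity must be one 6-connected component, found {ncomp}")
        if _touches(cav, self.labels == EXTERIOR):
            raise ValueError("cavity voxel 6-adjacent to exterior: wall shell broken")


def _touches(a: np.ndarray, b: np.ndarray) -> bool:
    """True if any True voxel of `a` is 6-adjacent to a True voxel of `b`."""
    return bool((ndimage.binary_dilation(a, structure=_STRUCT6) & b).any())


@dataclass
class PhantomSpec:
    """Analytic phantom description.

    shape : 'sphere' | 'ellipsoid' | 'lobulated'
    radius : sphere radius, cm (sphere only)
    semi_axes : (a, b, c) semi-axes, cm (ellipsoid / lobulated base shape)
    n_lobules : number of jittered ellipsoids unioned (lobulated only)
    lobule_amplitude : center jitter scale, cm (lobulated only)
    wall_thickness : wall shell thickness, cm
    spacing : per-axis voxel size, cm
    seed : RNG seed for the lobulated jitter
    pad : exterior padding beyond the wall, cm
    """

    shape: str = "sphere"
    radius: float = 2.0
    semi_axes: tuple[float, float, float] = (2.0, 1.5, 1.0)
    n_lobules: int = 4
    lobule_amplitude: float = 0.5
    wall_thickness: float = DEFAULT_WALL_THICKNESS_CM
    spacing: tuple[float, float, float] = (0.1, 0.1, 0.1)
    seed: int = 0
    pad: float = DEFAULT_EXTERIOR_PAD_CM

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "ellipsoid", "lobulated"):
            raise ValueError(f"unknown phantom shape {self.shape!r}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.semi_axes = tuple(float(a) for a in self.semi_axes)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.wall_thickness < max(self.spacing):
            raise ValueError(
                "wall thickness must be at least one voxel on every axis "
                f"({self.wall_thickness} < {max(self.spacing)})"
            )
        if self.max_diameter() > MAX_CAVITY_DIAMETER_CM + 1e-9:
            raise ValueError(
                f"cavity diameter {self.max_diameter():.2f} cm exceeds the "
                f"{MAX_CAVITY_DIAMETER_CM:g} cm exclusion limit"
            )
        if self.shape == "sphere" and self.radius < max(self.spacing):
            raise DegenerateGeometryError("sphere radius smaller than one voxel")
        if self.shape != "sphere" and min(self.semi_axes) < max(self.spacing):
            raise DegenerateGeometryError("semi-axis smaller than one voxel")

    def max_diameter(self) -> float:
        """Upper bound on cavity diameter, cm."""
        if self.shape == "sphere":
            return 2.0 * self.radius
        d = 2.0 * max(self.semi_axes)
        if self.shape == "lobulated":
            d += 2.0 * self.lobule_amplitude
        return d

    def to_dict(self) -> dict:
        return {
            "shape": self.shape,
            "radius": self.radius,
            "semi_axes": list(self.semi_axes),
            "n_lobules": self.n_lobules,
            "lobule_amplitude": self.lobule_amplitude,
            "wall_thickness": self.wall_thickness,
            "spacing": list(self.spacing),
            "seed": self.seed,
            "pad": self.pad,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "semi_axes" in d:
            d["semi_axes"] = tuple(d["semi_axes"])
        if "spacing" in d:
            d["spacing"] = tuple(d["spacing"])
        return cls(**d)


@dataclass
class WallSurface:
    """Innermost wall layer: wall voxels 6-adjacent to the cavity.

    indices : (n, 3) voxel indices into the grid
    areas : per-voxel representative surface area, cm^2
    """

    indices: np.ndarray
    areas: np.ndarray
    grid_shape: tuple[int, int, int] = field(default=(0, 0, 0))

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def _cavity_mask_from_spec(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Binary cavity mask on a padded grid; returns (mask, origin)."""
    half = np.array(
        [spec.radius] * 3 if spec.shape == "sphere" else spec.semi_axes, float
    )
    if spec.shape == "lobulated":
        half = half + spec.lobule_amplitude
    half = half + spec.wall_thickness + spec.pad
    sp = np.asarray(spec.spacing)
    n = np.ceil(2 * half / sp).astype(int) + 1
    origin = -(n - 1) / 2.0 * sp  # center of voxel (0,0,0); shape centered at 0
    x = origin[0] + np.arange(n[0]) * sp[0]
    y = origin[1] + np.arange(n[1]) * sp[1]
    z = origin[2] + np.arange(n[2]) * sp[2]
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    def inside_ellipsoid(cx, cy, cz, ax, ay, az):
        return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0

    if spec.shape == "sphere":
        mask = X**2 + Y**2 + Z**2 <= spec.radius**2
    elif spec.shape == "ellipsoid":
        mask = inside_ellipsoid(0, 0, 0, *spec.semi_axes)
    else:  # lobulated: union of jittered ellipsoids, largest 6-connected blob
        rng = np.random.default_rng(spec.seed)
        mask = inside_ellipsoid(0, 0, 0, *spec.semi_axes)
        for _ in range(spec.n_lobules):
            c = rng.uniform(-spec.lobule_amplitude, spec.lobule_amplitude, 3)
            scale = rng.uniform(0.3, 0.8, 3)
            ax = np.maximum(np.asarray(spec.semi_axes) * scale, 2 * sp)
            mask |= inside_ellipsoid(*c, *ax)
        lab, ncomp = ndimage.label(mask, structure=_STRUCT6)
        if ncomp > 1:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, ncomp + 1))
            mask = lab == (1 + int(np.argmax(sizes)))
    return mask, origin


def generate_phantom(spec: PhantomSpec) -> LabelGrid:
    """Voxelize an analytic cavity shape into a three-region LabelGrid.

    Cavity voxels are those whose centers fall inside the analytic shape;
    the wall is the shell of ``spec.wall_thickness`` around the cavity and
    everything else is exterior tissue.  Deterministic for a given seed.
    """
    mask, origin = _cavity_mask_from_spec(spec)
    if not mask.any():
        raise DegenerateGeometryError("analytic shape contains no voxel centers")
    grid = extract_wall_shell(mask, spec.spacing, spec.wall_thickness, origin=tuple(origin))
    if grid.cavity_diameter() > MAX_CAVITY_DIAMETER_CM + max(spec.spacing):
        raise ValueError("generated cavity exceeds the 8 cm diameter limit")
    grid.validate()
    return grid


def extract_wall_shell(
    binary_cavity: np.ndarray,
    spacing,
    thickness: float = DEFAULT_WALL_THICKNESS_CM,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> LabelGrid:
    """Partition a binary cavity mask into exterior / wall / cavity.

    Wall voxels are the non-cavity voxels whose centers lie within Euclidean
    distance ``thickness`` (cm) of the cavity, computed on the anisotropic
    grid via a distance transform.
    """
    spacing = tuple(float(s) for s in spacing)
    if thickness < max(spacing):
        raise ValueError(
            f"wall thickness {thickness} cm is below the largest voxel "
            f"spacing {max(spacing)} cm"
        )
    cav = np.asarray(binary_cavity).astype(bool)
    if cav.ndim != 3:
        raise ValueError("cavity mask must be 3D")
    if not cav.any():
        raise EmptyGeometryError("mask contains no cavity voxels")
    dist = ndimage.distance_transform_edt(~cav, sampling=spacing)
    # the EDT measures to the nearest cavity voxel *center*, which for a
    # smooth shape lies ~h/3 inside the continuum surface; widen the
    # threshold by that sub-voxel offset so the shell volume matches the
    # analytic thickness (verified on spheres) without pulling in diagonal
    # neighbors of a single-voxel cavity.
    eff = thickness + min(spacing) / 3.0
    labels = np.zeros(cav.shape, dtype=np.int8)
    labels[(dist <= eff) & ~cav] = WALL
    labels[cav] = CAVITY
    if not (labels == EXTERIOR).any():
        warnings.warn("wall shell spans the whole domain; no exterior voxels remain")
    return LabelGrid(labels, spacing, origin)


# ---------------------------------------------------------------------------
# NIfTI-1 mask I/O
# ---------------------------------------------------------------------------

def save_mask(grid: LabelGrid, path) -> None:
    """Write the label volume as NIfTI-1 (spacing in mm in the header)."""
    affine = np.diag([grid.spacing[0] * 10, grid.spacing[1] * 10, grid.spacing[2] * 10, 1.0])
    affine[:3, 3] = np.asarray(grid.origin) * 10
    img = nib.Nifti1Image(grid.labels.astype(np.uint8), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def load_mask(path, wall_thickness: float = DEFAULT_WALL_THICKNESS_CM) -> LabelGrid:
    """Read a NIfTI-1 cavity mask or label map as a three-region LabelGrid.

    Volumes with values {0, 1} are treated as binary cavity masks and get a
    wall shell of ``wall_thickness`` cm; volumes with values {0, 1, 2} are
    taken as full label maps.  Header spacing (mm) is converted to cm.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{path}: mask contains non-integer voxel values")
        data = np.round(data).astype(np.int8)
    vals = set(np.unique(data).tolist())
    spacing = tuple(float(z) / 10.0 for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) / 10.0 for t in img.affine[:3, 3])
    if not vals <= {0, 1, 2}:
        raise ValueError(f"{path}: unexpected label values {sorted(vals)}")
    if 2 in vals:  # full three-region label map
        grid = LabelGrid(data, spacing, origin)
        grid.validate()
        return grid
    if 1 not in vals:
        raise EmptyGeometryError(f"{path}: mask contains no cavity voxels")
    return extract_wall_shell(data == 1, spacing, wall_thickness, origin=origin)


# ---------------------------------------------------------------------------
# derived geometry
# ---------------------------------------------------------------------------

def cavity_center_of_mass(grid: LabelGrid) -> tuple[np.ndarray, bool]:
    """Unweighted centroid of cavity voxel centers, physical cm.

    Returns ``(point, inside)`` where ``inside`` is False when the centroid
    falls outside the cavity (possible for concave, e.g. horseshoe, shapes);
    the point is still returned so the caller can decide how to place the
    fiber.
    """
    idx = np.argwhere(grid.labels == CAVITY)
    if idx.size == 0:
        raise EmptyGeometryError("grid has no cavity voxels")
    com = idx.mean(axis=0) * np.asarray(grid.spacing) + np.asarray(grid.origin)
    vox = np.round((com - np.asarray(grid.origin)) / np.asarray(grid.spacing)).astype(int)
    vox = np.clip(vox, 0, np.asarray(grid.shape) - 1)
    inside = grid.labels[tuple(vox)] == CAVITY
    if not inside:
        warnings.warn("cavity centroid falls outside the cavity (concave shape)")
    return com, bool(inside)


def wall_surface(grid: LabelGrid) -> WallSurface:
    """Cavity-facing wall surface with per-voxel representative areas.

    The surface is the set of wall voxels 6-adjacent to a cavity voxel.  Each
    voxel's area is the sum of its cavity-facing face areas projected onto
    the local surface normal (estimated from the gradient of the signed
    Euclidean distance to the cavity boundary).  The projection removes the
    ~1.5x staircase overcount of axis-aligned faces, so total area converges
    to the smooth surface area as spacing shrinks.
    """
    cav = grid.labels == CAVITY
    if not cav.any():
        raise EmptyGeometryError("grid has no cavity voxels")
    wall = grid.labels == WALL
    sp = np.asarray(grid.spacing)

    # signed distance: positive outside the cavity; lightly smoothed so the
    # gradient gives sub-voxel-accurate surface normals
    sd = ndimage.distance_transform_edt(~cav, sampling=sp) - ndimage.distance_transform_edt(
        cav, sampling=sp
    )
    sd = ndimage.gaussian_filter(sd, sigma=1.5)
    grads = np.gradient(sd, *sp)

    face_area = np.array([sp[1] * sp[2], sp[0] * sp[2], sp[0] * sp[1]])
    gnorm = np.sqrt(grads[0] ** 2 + grads[1] ** 2 + grads[2] ** 2)
    area = np.zeros(grid.shape)
    touch = np.zeros(grid.shape, dtype=bool)
    for f in _FACES:
        ax = int(np.argmax(np.abs(f)))
        has_face = wall & _shift(cav, f)
        touch |= has_face
        # |n̂·ê_ax| face projection; flat gradient falls back to full face area
        proj = np.where(gnorm > 0, np.abs(grads[ax]) / np.where(gnorm > 0, gnorm, 1.0), 1.0)
        area += np.where(has_face, face_area[ax] * proj, 0.0)

    idx = np.argwhere(touch)
    areas = area[touch]
    # degenerate normals (flat gradient) fall back to plain face area, already
    # handled by the proj=1 branch above
    return WallSurface(indices=idx, areas=areas, grid_shape=grid.shape)


def _shift(a: np.ndarray, f) -> np.ndarray:
    """Shift boolean array by face vector f with zero fill (no wraparound)."""
    out = np.zeros_like(a)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    ax = int(np.argmax(np.abs(f)))
    step = int(f[ax])
    if step == 1:
        dst[ax] = slice(0, -1)
        src[ax] = slice(1, None)
    else:
        dst[ax] = slice(1, None)
        src[ax] = slice(0, -1)
    out[tuple(dst)] = a[tuple(src)]
    return out
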