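"""Voxel Monte Carlo photon transport: sources, simulation driver, fluence maps.

The simulation launches weighted photon packets from a flat-cleaved optical
fiber (or an isotropic point source, used for validation against closed-form
transport solutions) into a three-region label grid with per-region optical
properties, and tallies a track-length estimate of the fluence rate per unit
delivered power, phi/P, in units of cm^-2 (equivalently (mW/cm^2)/mW).
Fluence maps scale linearly with delivered power.

The fiber model follows the clinical delivery fiber: 400 um core (0.02 cm
radius), NA 0.22, fused-silica index 1.46.  Emission is uniform over the core
disk and uniform in solid angle within the acceptance cone computed in the
launch medium (half-angle asin(NA/n_medium)); Fresnel loss at the fiber face
is folded into the delivered (out-of-fiber) power.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from . import _kernels
from .geometry import CAVITY, LabelGrid
from .optics import RegionOptics

__all__ = [
    "FiberSource",
    "PointSource",
    "PhotonPacket",
    "FluenceMap",
    "SourcePlacementError",
    "launch",
    "sample_hg",
    "fresnel_reflectance",
    "simulate",
    "scale_to_power",
]


class SourcePlacementError(ValueError):
    """Source position incompatible with the geometry."""


@dataclass(frozen=True)
class FiberSource:
    """Flat-cleaved delivery fiber.

    tip : physical position of the fiber face, cm
    axis : emission axis (unit vector)
    core_radius : core radius, cm (default 0.02 = 400 um diameter)
    na : numerical aperture
    n_fiber : fiber core refractive index
    power_mw : delivered (out-of-fiber) power; fluence maps are per mW
    """

    tip: tuple[float, float, float]
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    core_radius: float = 0.02
    na: float = 0.22
    n_fiber: float = 1.46
    power_mw: float = 1.0

    def __post_init__(self) -> None:
        a = np.asarray(self.axis, float)
        norm = np.linalg.norm(a)
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError("fiber axis must be a unit vector")
        if not 0 < self.na < self.n_fiber:
            raise ValueError("require 0 < NA < n_fiber")
        if self.core_radius <= 0:
            raise ValueError("core radius must be positive")

    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal (axis, e1, e2) triad."""
        a = np.asarray(self.axis, float)
        a = a / np.linalg.norm(a)
        helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(a, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(a, e1)
        return a, e1, e2

    def acceptance_half_angle(self, n_medium: float) -> float:
        """Cone half-angle in the launch medium, radians: asin(NA/n_medium)."""
        s = self.na / n_medium
        if s >= 1.0:
            raise ValueError("NA exceeds launch-medium index; cone undefined")
        return float(np.arcsin(s))


@dataclass(frozen=True)
class PointSource:
    """Isotropic point source, for validation against closed-form transport."""

    position: tuple[float, float, float]
    power_mw: float = 1.0


@dataclass
class PhotonPacket:
    """A launched packet (position cm, unit direction, weight in (0, 1])."""

    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0


def launch(source: FiberSource | PointSource, rng: np.random.Generator) -> PhotonPacket:
    """Sample one packet from the source's emission distribution.

    Fiber: position uniform over the core disk perpendicular to the axis;
    direction uniform in solid angle within the acceptance cone in water-like
    cavity medium (n = 1.33).  Point source: isotropic.
    """
    if isinstance(source, PointSource):
        ct = rng.uniform(-1.0, 1.0)
        phi = rng.uniform(0.0, 2 * np.pi)
        st = np.sqrt(1 - ct**2)
        d = np.array([st * np.cos(phi), st * np.sin(phi), ct])
        return PhotonPacket(np.asarray(source.position, float), d, 1.0)
    a, e1, e2 = source.frame()
    r = source.core_radius * np.sqrt(rng.uniform())
    psi = rng.uniform(0.0, 2 * np.pi)
    pos = np.asarray(source.tip, float) + r * (np.cos(psi) * e1 + np.sin(psi) * e2)
    cos_max = np.cos(source.acceptance_half_angle(1.33))
    ct = 1.0 - rng.uniform() * (1.0 - cos_max)
    phi = rng.uniform(0.0, 2 * np.pi)
    st = np.sqrt(1 - ct**2)
    d = st * (np.cos(phi) * e1 + np.sin(phi) * e2) + ct * a
    return PhotonPacket(pos, d / np.linalg.norm(d), 1.0)


def sample_hg(g: float, u) -> np.ndarray | float:
    """Henyey–Greenstein cos(theta) from uniform deviate(s) u in [0, 1).

    Closed-form inverse CDF; isotropic (2u - 1) when g = 0.
    """
    if not -1 < g < 1:
        raise ValueError("anisotropy g must lie in (-1, 1)")
    u = np.asarray(u, float)
    if abs(g) < 1e-6:
        out = 2.0 * u - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        out = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    return np.clip(out, -1.0, 1.0)[()]


def fresnel_reflectance(n_i: float, n_t: float, cos_theta_i: float) -> float:
    """Unpolarized Fresnel reflectance at a planar boundary.

    Returns 1 beyond the critical angle (total internal reflection).
    """
    if n_i < 1 or n_t < 1:
        raise ValueError("refractive indices must be >= 1")
    if not 0 <= cos_theta_i <= 1:
        raise ValueError("cos(theta_i) must lie in [0, 1]")
    return float(_kernels._fresnel(n_i, n_t, cos_theta_i))


@dataclass
class FluenceMap:
    """Per-voxel fluence rate per unit delivered power, cm^-2.

    Carries provenance (photon count, seed) and the energy tallies
    (absorbed/escaped weight fractions, which sum to 1).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    n_photons: int
    seed: int
    absorbed: float
    escaped: float
    meta: dict = field(default_factory=dict)

    def save(self, path) -> None:
        """Write a NIfTI-1 float volume plus a JSON provenance sidecar."""
        affine = np.diag([self.spacing[0] * 10, self.spacing[1] * 10, self.spacing[2] * 10, 1.0])
        affine[:3, 3] = np.asarray(self.origin) * 10
        # float64 so a resumed run reproduces the original bit-for-bit
        img = nib.Nifti1Image(self.values.astype(np.float64), affine)
        img.header.set_xyzt_units("mm")
        nib.save(img, str(path))
        sidecar = {
            "units": "cm^-2 per mW delivered",
            "n_photons": int(self.n_photons),
            "seed": int(self.seed),
            "absorbed": self.absorbed,
            "escaped": self.escaped,
            **self.meta,
        }
        with open(_sidecar_path(path), "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path) -> "FluenceMap":
        img = nib.load(str(path))
        values = np.asanyarray(img.dataobj).astype(np.float64)
        spacing = tuple(float(z) / 10.0 for z in img.header.get_zooms()[:3])
        origin = tuple(float(t) / 10.0 for t in img.affine[:3, 3])
        with open(_sidecar_path(path)) as fh:
            sc = json.load(fh)
        meta = {k: v for k, v in sc.items()
                if k not in ("units", "n_photons", "seed", "absorbed", "escaped")}
        return cls(values, spacing, origin, sc["n_photons"], sc["seed"],
                   sc["absorbed"], sc["escaped"], meta)


def _sidecar_path(path) -> str:
    p = str(path)
    for suff in (".nii.gz", ".nii"):
        if p.endswith(suff):
            return p[: -len(suff)] + ".json"
    return p + ".json"


def simulate(
    grid: LabelGrid,
    optics: dict[int, RegionOptics],
    source: FiberSource | PointSource,
    n_photons: int,
    seed: int,
) -> FluenceMap:
    """Run the voxel Monte Carlo and return the per-mW fluence-rate map.

    Deterministic for a given seed: each packet draws from its own RNG
    substream keyed by (seed, packet index), so the result does not depend
    on execution order.
    """
    if grid.labels.size == 0:
        raise ValueError("empty grid")
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")

    mua = np.zeros(3)
    mus = np.zeros(3)
    gfac = np.zeros(3)
    nidx = np.ones(3)
    present = np.unique(grid.labels)
    for lab in range(3):
        if lab in optics:
            ro = optics[lab]
            mua[lab], mus[lab], gfac[lab], nidx[lab] = ro.mu_a, ro.mu_s, ro.g, ro.n
        elif lab in present:
            raise ValueError(f"no optics supplied for label {lab}")

    sp = np.asarray(grid.spacing)
    corner = np.asarray(grid.origin) - sp / 2.0
    extent = np.asarray(grid.shape) * sp

    if isinstance(source, PointSource):
        pos = np.asarray(source.position, float) - corner
        if np.any(pos <= 0) or np.any(pos >= extent):
            raise SourcePlacementError("point source outside the grid")
        kind = _kernels.SRC_POINT
        a = e1 = e2 = np.array([0.0, 0.0, 1.0])
        core_r, cos_max = 0.0, 1.0
    else:
        pos = np.asarray(source.tip, float) - corner
        if np.any(pos <= 0) or np.any(pos >= extent):
            raise SourcePlacementError("fiber tip outside the grid")
        vox = tuple(np.clip((pos / sp).astype(int), 0, np.asarray(grid.shape) - 1))
        if grid.labels[vox] != CAVITY:
            raise SourcePlacementError("fiber tip must lie inside the cavity")
        kind = _kernels.SRC_FIBER
        a, e1, e2 = source.frame()
        core_r = source.core_radius
        n_medium = float(nidx[CAVITY])
        cos_max = float(np.cos(source.acceptance_half_angle(n_medium)))

    fluence = np.zeros(grid.shape, dtype=np.float64)
    absorbed, escaped = _kernels.run_transport(
        grid.labels, mua, mus, gfac, nidx,
        float(sp[0]), float(sp[1]), float(sp[2]),
        kind,
        float(pos[0]), float(pos[1]), float(pos[2]),
        float(a[0]), float(a[1]), float(a[2]),
        float(e1[0]), float(e1[1]), float(e1[2]),
        float(e2[0]), float(e2[1]), float(e2[2]),
        float(core_r), float(cos_max),
        int(n_photons), int(seed) & 0x7FFFFFFFFFFFFFFF,
        fluence,
    )
    fluence /= grid.voxel_volume * n_photons
    return FluenceMap(
        values=fluence,
        spacing=grid.spacing,
        origin=grid.origin,
        n_photons=int(n_photons),
        seed=int(seed),
        absorbed=absorbed / n_photons,
        escaped=escaped / n_photons,
    )


def scale_to_power(fmap: FluenceMap, power_mw: float) -> np.ndarray:
    """Fluence-rate map (mW/cm^2) at a delivered power; linear scaling."""
    if power_mw < 0:
        raise ValueError("power must be non-negative")
    return fmap.values * power_mw
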