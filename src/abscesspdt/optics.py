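"""Optical-property models at 665 nm for the three-region abscess geometry.

Maps the two clinically tunable agents to transport coefficients:

* methylene blue (MB), the photosensitizer, sets absorption — 0.17 cm^-1 per
  micromolar at 665 nm;
* Intralipid, the intracavity scattering emulsion, sets scattering — anchored
  so that 2.3% (v/v lipid) corresponds to mu_s = 100 cm^-1, i.e.
  100/2.3 ≈ 43.48 cm^-1 per percent.

The fixed per-region assumptions (wall and surrounding tissue: mu_s = 100
cm^-1, g = 0.9, n = 1.4; cavity contents: g = 0.7, n = 1.33, water-like) are
assembled per sweep cell by :func:`assemble_properties`.

A Mie-based wavelength parameterization of Intralipid scattering (van
Staveren-style power law) is included as an independent cross-check of the
linear anchor, not as the model the sweeps use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "RegionOptics",
    "PropertyCell",
    "mb_to_mua",
    "mua_to_mb",
    "intralipid_to_mus",
    "mus_to_intralipid",
    "assemble_properties",
    "intralipid_mus_mie",
    "intralipid_percent_for_mus_mie",
    "intralipid_anisotropy_mie",
]

#: MB absorption at 665 nm, cm^-1 per uM
MUA_PER_UM_MB = 0.17

#: Intralipid scattering at 665 nm, cm^-1 per percent (anchor: 2.3% <-> 100 cm^-1)
MUS_PER_PERCENT_IL = 100.0 / 2.3


class RegionOptics(NamedTuple):
    """Homogeneous optical properties of one region at 665 nm."""

    mu_a: float  # absorption coefficient, cm^-1
    mu_s: float  # scattering coefficient, cm^-1
    g: float     # scattering anisotropy (mean cosine)
    n: float     # refractive index

    def validate(self) -> "RegionOptics":
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if not -1 < self.g < 1:
            raise ValueError("anisotropy g must lie in (-1, 1)")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")
        return self


#: surrounding soft tissue, fixed for all sweeps
EXTERIOR_OPTICS = RegionOptics(mu_a=0.2, mu_s=100.0, g=0.9, n=1.4)

WALL_MU_S = 100.0
WALL_G = 0.9
WALL_N = 1.4
CAVITY_G = 0.7
CAVITY_N = 1.33

# sweep ranges explored in the study; exceeding them is allowed but flagged
_WALL_MUA_RANGE = (0.2, 10.0)
_CAVITY_MUA_RANGE = (0.0, 0.17)
_CAVITY_MUS_RANGE = (0.0, 100.0)


@dataclass(frozen=True)
class PropertyCell:
    """One sweep cell: the three free coefficients (cm^-1).

    mu_a_wall : wall absorption (native tissue + retained MB)
    mu_s_cavity : intracavity scattering (Intralipid concentration)
    mu_a_cavity : intracavity absorption (leaked MB); 0 in the base case
    """

    mu_a_wall: float
    mu_s_cavity: float
    mu_a_cavity: float = 0.0

    @property
    def intralipid_percent(self) -> float:
        return mus_to_intralipid(self.mu_s_cavity)

    @property
    def mb_cavity_um(self) -> float:
        return mua_to_mb(self.mu_a_cavity)

    def key(self) -> tuple[float, float, float]:
        return (self.mu_a_wall, self.mu_s_cavity, self.mu_a_cavity)


def _check_nonneg(x, name: str) -> np.ndarray | float:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return x


def mb_to_mua(concentration_um):
    """MB concentration (uM) -> absorption coefficient (cm^-1) at 665 nm."""
    _check_nonneg(concentration_um, "MB concentration")
    return np.multiply(concentration_um, MUA_PER_UM_MB)


def mua_to_mb(mu_a):
    """Absorption coefficient (cm^-1) -> MB concentration (uM); exact inverse."""
    _check_nonneg(mu_a, "mu_a")
    return np.divide(mu_a, MUA_PER_UM_MB)


def intralipid_to_mus(percent):
    """Intralipid concentration (% v/v lipid) -> mu_s (cm^-1) at 665 nm."""
    _check_nonneg(percent, "Intralipid concentration")
    return np.multiply(percent, MUS_PER_PERCENT_IL)


def mus_to_intralipid(mu_s):
    """mu_s (cm^-1) -> Intralipid concentration (%); exact inverse."""
    _check_nonneg(mu_s, "mu_s")
    return np.divide(mu_s, MUS_PER_PERCENT_IL)


def assemble_properties(cell: PropertyCell) -> dict[int, RegionOptics]:
    """Per-region optics {0: exterior, 1: wall, 2: cavity} for one sweep cell.

    Values outside the studied ranges are allowed (sweeps may explore) but
    emit a warning.
    """
    for val, rng, name in (
        (cell.mu_a_wall, _WALL_MUA_RANGE, "mu_a_wall"),
        (cell.mu_a_cavity, _CAVITY_MUA_RANGE, "mu_a_cavity"),
        (cell.mu_s_cavity, _CAVITY_MUS_RANGE, "mu_s_cavity"),
    ):
        if not rng[0] <= val <= rng[1]:
            warnings.warn(f"{name}={val} outside the studied range {rng}")
    return {
        0: EXTERIOR_OPTICS,
        1: RegionOptics(cell.mu_a_wall, WALL_MU_S, WALL_G, WALL_N).validate(),
        2: RegionOptics(cell.mu_a_cavity, cell.mu_s_cavity, CAVITY_G, CAVITY_N).validate(),
    }


# ---------------------------------------------------------------------------
# Mie-based Intralipid cross-check (van Staveren-style power law)
# ---------------------------------------------------------------------------

#: mu_s of undiluted 10%-lipid Intralipid stock: 16 * lambda_um^-2.4 mm^-1,
#: i.e. per percent lipid: 16 * lambda_um^-2.4 cm^-1.
_VS_COEFF = 16.0
_VS_EXPONENT = -2.4


def intralipid_mus_mie(percent, wavelength_nm: float = 665.0):
    """Mie-based Intralipid scattering coefficient, cm^-1.

    Power-law fit to Mie calculations for Intralipid-10% over 400–1100 nm:
    mu_s scales linearly with lipid volume fraction and as lambda^-2.4.
    Used only as an independent cross-check of the linear 2.3% <-> 100 cm^-1
    anchor employed by the sweeps.
    """
    _check_nonneg(percent, "Intralipid concentration")
    lam_um = wavelength_nm / 1000.0
    return np.multiply(percent, _VS_COEFF * lam_um**_VS_EXPONENT)


def intralipid_percent_for_mus_mie(mu_s, wavelength_nm: float = 665.0):
    """Concentration (%) whose Mie-based mu_s equals the given value (cm^-1)."""
    _check_nonneg(mu_s, "mu_s")
    lam_um = wavelength_nm / 1000.0
    return np.divide(mu_s, _VS_COEFF * lam_um**_VS_EXPONENT)


def intralipid_anisotropy_mie(wavelength_nm: float = 665.0) -> float:
    """Mie-based Intralipid anisotropy g(lambda) = 1.1 - 0.58*lambda_um.

    At 665 nm this gives ~0.71, consistent with the fixed cavity g of 0.7.
    """
    return 1.1 - 0.58 * (wavelength_nm / 1000.0)
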