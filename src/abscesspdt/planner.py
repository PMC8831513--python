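"""Treatment planning: wall dose statistics, threshold power, eligibility.

The planning target is a fluence rate of T = 4 mW/cm^2 over at least 95% of
the cavity-facing wall surface, subject to a thermal-safety hotspot limit
(no more than 5% of the wall at or above 400 mW/cm^2) and the 2000 mW
out-of-fiber power ceiling of the clinical laser.  Because fluence scales
linearly with delivered power, the threshold power is T divided by the
area-weighted 5th-percentile per-mW wall fluence.

Percentile convention (pinned by the direct-counting oracle in the test
suite): area-weighted lower inverted-CDF quantiles; the coverage condition
is "area fraction below target strictly less than 5%", which makes
P_th = T / q05 exactly the minimum feasible power; the hotspot condition
counts voxels at or above the limit (closed inequality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import LabelGrid, WallSurface, cavity_center_of_mass, wall_surface
from .optics import PropertyCell, assemble_properties, mus_to_intralipid
from .provenance import task_seed
from .transport import FiberSource, FluenceMap, simulate

__all__ = [
    "DoseTargets",
    "WallFluenceDistribution",
    "PlanResult",
    "SweepResult",
    "area_quantile",
    "wall_distribution",
    "threshold_power",
    "coverage_met",
    "hotspot_feasible",
    "eligibility",
    "plan_from_distribution",
    "optimal_intralipid",
    "uniform_dose_plan",
    "simulate_cell",
    "run_sweep_case1",
    "run_sweep_case2",
    "CASE2_MODES",
]

CASE2_MODES = ("fixed-plan", "power-only", "full")


@dataclass(frozen=True)
class DoseTargets:
    """Treatment-planning dose constraints.

    target : wall fluence-rate goal T, mW/cm^2
    coverage : fraction of wall area that must reach T
    hotspot_limit : fluence rate H defining a hotspot, mW/cm^2
    hotspot_fraction : maximum wall-area fraction allowed at >= H
    max_power : laser out-of-fiber power ceiling, mW
    """

    target: float = 4.0
    coverage: float = 0.95
    hotspot_limit: float = 400.0
    hotspot_fraction: float = 0.05
    max_power: float = 2000.0

    def __post_init__(self) -> None:
        if not 0 < self.coverage < 1 or not 0 < self.hotspot_fraction < 1:
            raise ValueError("coverage and hotspot fraction must lie in (0, 1)")
        if not self.target < self.hotspot_limit:
            raise ValueError("target must be below the hotspot limit")
        if self.max_power <= 0:
            raise ValueError("max power must be positive")


@dataclass
class WallFluenceDistribution:
    """Per-surface-voxel fluence rate per mW (cm^-2) with matching areas (cm^2)."""

    phi_per_mw: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.phi_per_mw = np.asarray(self.phi_per_mw, float)
        self.areas = np.asarray(self.areas, float)
        if self.phi_per_mw.shape != self.areas.shape:
            raise ValueError("fluence values and areas must have the same length")
        if len(self.phi_per_mw) == 0:
            raise ValueError("empty wall distribution")
        if np.any(self.phi_per_mw < 0) or np.any(self.areas <= 0):
            raise ValueError("fluence must be >= 0 and areas > 0")


@dataclass
class PlanResult:
    """Planning outcome for one (geometry, property-cell) combination."""

    geometry_id: str
    cell: PropertyCell
    p_threshold: float          # mW; math.inf when the goal is unattainable
    hotspot_ok: bool
    eligible: bool
    q05: float                  # per-mW wall fluence, cm^-2
    q95: float
    intralipid_pct: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if math.isnan(self.intralipid_pct):
            self.intralipid_pct = float(mus_to_intralipid(self.cell.mu_s_cavity))


# ---------------------------------------------------------------------------
# dose statistics
# ---------------------------------------------------------------------------

def area_quantile(values, areas, p: float) -> float:
    """Area-weighted lower inverted-CDF quantile.

    Smallest sample value v with (area fraction of samples <= v) >= p.
    """
    values = np.asarray(values, float)
    areas = np.asarray(areas, float)
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(areas[order])
    frac = cum / cum[-1]
    # 1e-12 guard so exact-boundary fractions (e.g. 5 of 100 voxels) are not
    # flipped by floating-point noise in p = 1 - coverage
    i = int(np.searchsorted(frac, p - 1e-12, side="left"))
    i = min(i, len(values) - 1)
    return float(values[order][i])


def wall_distribution(fmap: FluenceMap, surface: WallSurface) -> WallFluenceDistribution:
    """Sample a fluence map on the cavity-facing wall surface."""
    if surface.grid_shape != fmap.values.shape:
        raise ValueError("fluence map and wall surface come from different grids")
    if len(surface) == 0:
        raise ValueError("empty wall surface")
    idx = surface.indices
    phi = fmap.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    return WallFluenceDistribution(phi_per_mw=phi, areas=surface.areas)


def threshold_power(dist: WallFluenceDistribution, targets: DoseTargets) -> float:
    """Minimum power (mW) achieving the coverage goal: T / q_{1-C}.

    Returns ``math.inf`` when the (1-C) area quantile of the per-mW wall
    fluence is zero (part of the wall receives no light at any power).
    """
    q = area_quantile(dist.phi_per_mw, dist.areas, 1.0 - targets.coverage)
    if q <= 0.0:
        return math.inf
    return targets.target / q


def coverage_met(dist: WallFluenceDistribution, targets: DoseTargets, power_mw: float) -> bool:
    """Direct-counting coverage check at a given power.

    True when the wall-area fraction below the target fluence rate is
    strictly less than 1 - C.
    """
    # relative guard: a voxel within 1e-9 of the target counts as reaching it
    # (P_th * q05 can land one ulp below T)
    below = power_mw * dist.phi_per_mw < targets.target * (1.0 - 1e-9)
    frac = dist.areas[below].sum() / dist.areas.sum()
    return bool(frac < (1.0 - targets.coverage) - 1e-12)


def hotspot_feasible(dist: WallFluenceDistribution, targets: DoseTargets, power_mw: float) -> bool:
    """True when the area fraction receiving >= H is at most F (direct count)."""
    if power_mw < 0:
        raise ValueError("power must be non-negative")
    hot = power_mw * dist.phi_per_mw >= targets.hotspot_limit * (1.0 - 1e-9)
    frac = dist.areas[hot].sum() / dist.areas.sum()
    return bool(frac <= targets.hotspot_fraction + 1e-12)


def eligibility(dist: WallFluenceDistribution, targets: DoseTargets) -> tuple[float, bool]:
    """(threshold power, eligible) for one wall distribution.

    Eligible when the coverage goal is attainable strictly below the laser
    ceiling and the hotspot constraint holds at the threshold power.
    """
    p_th = threshold_power(dist, targets)
    ok = math.isfinite(p_th) and p_th < targets.max_power and hotspot_feasible(dist, targets, p_th)
    return p_th, bool(ok)


def plan_from_distribution(
    geometry_id: str,
    cell: PropertyCell,
    dist: WallFluenceDistribution,
    targets: DoseTargets,
) -> PlanResult:
    """Assemble the PlanResult for one simulated cell."""
    p_th, ok = eligibility(dist, targets)
    hs = hotspot_feasible(dist, targets, p_th) if math.isfinite(p_th) else False
    return PlanResult(
        geometry_id=geometry_id,
        cell=cell,
        p_threshold=p_th,
        hotspot_ok=hs,
        eligible=ok,
        q05=area_quantile(dist.phi_per_mw, dist.areas, 1.0 - targets.coverage),
        q95=area_quantile(dist.phi_per_mw, dist.areas, targets.coverage),
    )


# ---------------------------------------------------------------------------
# plan selection
# ---------------------------------------------------------------------------

def optimal_intralipid(results: list[PlanResult]) -> PlanResult:
    """Pick the Intralipid concentration minimizing threshold power.

    Operates on the simulated concentrations only (no interpolation); ties
    break toward the lowest concentration.  Ineligible cells are excluded
    unless every cell is ineligible, in which case the minimum-threshold
    cell is returned with ``eligible=False``.
    """
    if not results:
        raise ValueError("empty result list")
    geoms = {r.geometry_id for r in results}
    walls = {r.cell.mu_a_wall for r in results}
    if len(geoms) > 1 or len(walls) > 1:
        raise ValueError("results must share geometry and mu_a_wall")
    pool = [r for r in results if r.eligible] or list(results)
    return min(pool, key=lambda r: (r.p_threshold, r.intralipid_pct))


def uniform_dose_plan(
    results: list[PlanResult], concentration_pct: float = 1.0
) -> PlanResult:
    """Plan at the simulated concentration nearest the fixed clinical 1%.

    The power is still optimized (threshold power of that cell).  Raises
    when no simulated concentration lies within 0.5 percentage points of
    the requested one.
    """
    if not results:
        raise ValueError("empty result list")
    best = min(results, key=lambda r: abs(r.intralipid_pct - concentration_pct))
    if abs(best.intralipid_pct - concentration_pct) > 0.5:
        raise ValueError(
            f"no simulated Intralipid concentration near {concentration_pct}% "
            f"(closest: {best.intralipid_pct:.2f}%)"
        )
    return best


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Tabular sweep output.

    cells : one row per (geometry, property cell) with planning quantities
    plans : per-(geometry, mu_a_wall[, mu_a_cavity]) selected plans by strategy/mode
    eligibility : eligibility fractions across geometries
    """

    cells: pd.DataFrame
    plans: pd.DataFrame
    eligibility: pd.DataFrame


def simulate_cell(
    grid: LabelGrid,
    cell: PropertyCell,
    n_photons: int,
    seed: int,
    surface: WallSurface | None = None,
    fiber_axis=(0.0, 0.0, 1.0),
) -> WallFluenceDistribution:
    """Simulate one property cell with the fiber at the cavity centroid."""
    com, _ = cavity_center_of_mass(grid)
    source = FiberSource(tip=tuple(com), axis=tuple(fiber_axis))
    fmap = simulate(grid, assemble_properties(cell), source, n_photons, seed)
    if surface is None:
        surface = wall_surface(grid)
    return wall_distribution(fmap, surface)


class _SimCache:
    """Memoizes wall distributions per (geometry, cell); shares surfaces."""

    def __init__(self, geometries, n_photons: int, master_seed: int):
        self.geometries = dict(geometries)
        self.n_photons = int(n_photons)
        self.master_seed = int(master_seed)
        self.surfaces = {gid: wall_surface(g) for gid, g in self.geometries.items()}
        self._dists: dict[tuple, WallFluenceDistribution] = {}

    def put(self, gid: str, cell: PropertyCell, dist: WallFluenceDistribution) -> None:
        """Inject a precomputed wall distribution (e.g. from a saved map)."""
        self._dists[(gid, cell.key())] = dist

    def dist(self, gid: str, cell: PropertyCell) -> WallFluenceDistribution:
        key = (gid, cell.key())
        if key not in self._dists:
            seed = task_seed(self.master_seed, gid, *cell.key(), self.n_photons)
            self._dists[key] = simulate_cell(
                self.geometries[gid], cell, self.n_photons, seed,
                surface=self.surfaces[gid],
            )
        return self._dists[key]

    def plan(self, gid: str, cell: PropertyCell, targets: DoseTargets) -> PlanResult:
        return plan_from_distribution(gid, cell, self.dist(gid, cell), targets)


def _cells_frame(plans: list[PlanResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "geometry_id": [p.geometry_id for p in plans],
            "mu_a_wall": [p.cell.mu_a_wall for p in plans],
            "mu_s_cavity": [p.cell.mu_s_cavity for p in plans],
            "mu_a_cavity": [p.cell.mu_a_cavity for p in plans],
            "intralipid_pct": [p.intralipid_pct for p in plans],
            "p_threshold_mw": [p.p_threshold for p in plans],
            "q05_per_mw": [p.q05 for p in plans],
            "q95_per_mw": [p.q95 for p in plans],
            "hotspot_ok": [p.hotspot_ok for p in plans],
            "eligible": [p.eligible for p in plans],
        }
    )


def run_sweep_case1(
    geometries,
    mua_wall_list,
    mus_cavity_list,
    targets: DoseTargets | None = None,
    n_photons: int = 100_000,
    seed: int = 0,
    cache: _SimCache | None = None,
) -> SweepResult:
    """Case 1: sweep wall absorption x intracavity scattering, no cavity absorption.

    For every geometry and (mu_a_wall, mu_s_cavity) cell one fluence map is
    simulated and planned; per (geometry, mu_a_wall) the optimized-Intralipid
    and uniform-dose (fixed ~1%) strategies are compared, and eligibility
    fractions across geometries are tabulated.
    """
    targets = targets or DoseTargets()
    cache = cache or _SimCache(geometries, n_photons, seed)

    all_plans: list[PlanResult] = []
    strat_rows = []
    for gid in cache.geometries:
        for mw in mua_wall_list:
            row_plans = [
                cache.plan(gid, PropertyCell(mw, ms, 0.0), targets)
                for ms in mus_cavity_list
            ]
            all_plans.extend(row_plans)
            strategies = [("optimized", optimal_intralipid(row_plans))]
            try:  # uniform comparator only exists when a ~1% cell is simulated
                strategies.append(("uniform", uniform_dose_plan(row_plans)))
            except ValueError:
                pass
            for strategy, plan in strategies:
                strat_rows.append(
                    {
                        "geometry_id": gid,
                        "mu_a_wall": mw,
                        "strategy": strategy,
                        "intralipid_pct": plan.intralipid_pct,
                        "p_threshold_mw": plan.p_threshold,
                        "eligible": plan.eligible,
                    }
                )

    cells = _cells_frame(all_plans)
    plans = pd.DataFrame(strat_rows)
    elig_cells = (
        cells.groupby(["mu_a_wall", "mu_s_cavity"])["eligible"].mean().reset_index()
        .rename(columns={"eligible": "eligible_fraction"})
    )
    elig_strat = (
        plans.groupby(["mu_a_wall", "strategy"])["eligible"].mean().reset_index()
        .rename(columns={"eligible": "eligible_fraction"})
    )
    elig = pd.concat(
        [elig_cells.assign(strategy="per-cell"), elig_strat], ignore_index=True
    )
    return SweepResult(cells=cells, plans=plans, eligibility=elig)


def run_sweep_case2(
    geometries,
    mua_wall_list,
    mus_cavity_list,
    mua_cavity_list,
    targets: DoseTargets | None = None,
    n_photons: int = 100_000,
    seed: int = 0,
    modes=CASE2_MODES,
    cache: "_SimCache | None" = None,
) -> SweepResult:
    """Case 2: add intracavity absorption (leaked MB) to the sweep.

    Three planning modes quantify how much of the lost eligibility each
    level of knowledge recovers:

    * ``fixed-plan`` — power and Intralipid frozen at the mu_a_cavity = 0
      plan; eligibility asks whether that frozen plan still meets both dose
      constraints under the new cavity absorption;
    * ``power-only`` — Intralipid frozen at the baseline optimum, power
      re-optimized;
    * ``full`` — both re-optimized with knowledge of mu_a_cavity.
    """
    targets = targets or DoseTargets()
    for m in modes:
        if m not in CASE2_MODES:
            raise ValueError(f"unknown planning mode {m!r}")
    cache = cache or _SimCache(geometries, n_photons, seed)

    all_plans: list[PlanResult] = []
    mode_rows = []
    for gid in cache.geometries:
        for mw in mua_wall_list:
            base_plans = [
                cache.plan(gid, PropertyCell(mw, ms, 0.0), targets)
                for ms in mus_cavity_list
            ]
            base = optimal_intralipid(base_plans)
            for mc in mua_cavity_list:
                cell_plans = [
                    cache.plan(gid, PropertyCell(mw, ms, mc), targets)
                    for ms in mus_cavity_list
                ]
                all_plans.extend(cell_plans)
                at_base_il = next(
                    p for p in cell_plans
                    if p.cell.mu_s_cavity == base.cell.mu_s_cavity
                )
                for mode in modes:
                    if mode == "full":
                        chosen = optimal_intralipid(cell_plans)
                        p_rep, elig_flag = chosen.p_threshold, chosen.eligible
                        il = chosen.intralipid_pct
                    elif mode == "power-only":
                        p_rep, elig_flag = at_base_il.p_threshold, at_base_il.eligible
                        il = at_base_il.intralipid_pct
                    else:  # fixed-plan
                        il = base.intralipid_pct
                        p_rep = base.p_threshold
                        dist = cache.dist(gid, at_base_il.cell)
                        elig_flag = (
                            base.eligible
                            and math.isfinite(p_rep)
                            and coverage_met(dist, targets, p_rep)
                            and hotspot_feasible(dist, targets, p_rep)
                        )
                    mode_rows.append(
                        {
                            "geometry_id": gid,
                            "mu_a_wall": mw,
                            "mu_a_cavity": mc,
                            "mode": mode,
                            "intralipid_pct": il,
                            "p_threshold_mw": p_rep,
                            "eligible": bool(elig_flag),
                        }
                    )

    cells = _cells_frame(all_plans).drop_duplicates(
        subset=["geometry_id", "mu_a_wall", "mu_s_cavity", "mu_a_cavity"]
    )
    plans = pd.DataFrame(mode_rows)
    elig = (
        plans.groupby(["mu_a_wall", "mu_a_cavity", "mode"])["eligible"]
        .mean().reset_index().rename(columns={"eligible": "eligible_fraction"})
    )
    return SweepResult(cells=cells, plans=plans, eligibility=elig)
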