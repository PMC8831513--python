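"""Dose statistics, plan selection, sweeps, and the paired statistical tests."""

import itertools
import math

import numpy as np
import pytest

from abscesspdt.geometry import PhantomSpec, generate_phantom
from abscesspdt.optics import PropertyCell
from abscesspdt.planner import (
    DoseTargets,
    PlanResult,
    WallFluenceDistribution,
    area_quantile,
    coverage_met,
    eligibility,
    hotspot_feasible,
    optimal_intralipid,
    plan_from_distribution,
    run_sweep_case1,
    run_sweep_case2,
    threshold_power,
    uniform_dose_plan,
    wall_distribution,
)
from abscesspdt.stats import friedman_test, wilcoxon_signed_rank
from abscesspdt.transport import FluenceMap


def _dist(values, areas=None):
    values = np.asarray(values, float)
    areas = np.ones_like(values) if areas is None else np.asarray(areas, float)
    return WallFluenceDistribution(values, areas)


def _brute_force_threshold(dist, targets, p_max=6000.0, step=0.1):
    """Oracle: scan powers on a lattice, counting wall area directly."""
    total = dist.areas.sum()
    for p in np.arange(step, p_max + step, step):
        frac_below = dist.areas[p * dist.phi_per_mw < targets.target].sum() / total
        # convention: the under-dosed fraction must be *strictly* below 1 - C
        # (guard keeps exact-boundary fractions from flipping on float noise)
        if frac_below + 1e-12 < 1.0 - targets.coverage:
            return p
    return math.inf


class TestThresholdPower:
    def test_uniform_distribution_arithmetic(self, targets):
        d = _dist([0.002] * 50)
        assert threshold_power(d, targets) == pytest.approx(2000.0)

    def test_doubling_fluence_halves_power(self, targets, rng):
        v = rng.uniform(0.001, 0.1, 200)
        d1, d2 = _dist(v), _dist(2 * v)
        assert threshold_power(d2, targets) == pytest.approx(threshold_power(d1, targets) / 2)

    def test_boundary_quantile_convention(self, targets):
        # 5 of 100 equal-area voxels at the low value: q05 picks it up
        d = _dist([0.001] * 5 + [0.01] * 95)
        assert area_quantile(d.phi_per_mw, d.areas, 0.05) == pytest.approx(0.001)
        p = threshold_power(d, targets)
        assert p == pytest.approx(4000.0)
        assert abs(p - _brute_force_threshold(d, targets)) <= 0.1

    def test_closed_form_matches_power_scan_on_random_distributions(self, targets, rng):
        for _ in range(25):
            n = rng.integers(20, 200)
            v = rng.lognormal(-4, 1, n)
            a = rng.uniform(0.5, 2.0, n)
            d = _dist(v, a)
            p = threshold_power(d, targets)
            if math.isfinite(p) and p < 6000:
                assert abs(p - _brute_force_threshold(d, targets)) <= 0.1 + 1e-9
                assert coverage_met(d, targets, p)

    def test_dark_wall_fraction_gives_infinite_threshold(self, targets):
        d = _dist([0.0] * 10 + [0.01] * 90)
        assert threshold_power(d, targets) == math.inf
        _, ok = eligibility(d, targets)
        assert not ok


class TestHotspot:
    def test_zero_power_always_safe(self, targets, rng):
        d = _dist(rng.uniform(0, 1, 50))
        assert hotspot_feasible(d, targets, 0.0)

    def test_uniform_at_limit_is_hot(self, targets):
        # every voxel "receiving >= 400" (closed inequality) -> 100% > 5%
        d = _dist([0.2] * 30)
        assert not hotspot_feasible(d, targets, 2000.0)
        assert hotspot_feasible(d, targets, 1999.0)

    def test_counting_agrees_with_quantile_form(self, targets, rng):
        for _ in range(10):
            v = rng.lognormal(-4, 1.5, 100)
            d = _dist(v)
            q95 = area_quantile(v, d.areas, targets.coverage)
            for p in rng.uniform(1, 5000, 50):
                direct = hotspot_feasible(d, targets, p)
                closed = p * q95 < targets.hotspot_limit
                assert direct == closed


class TestEligibility:
    def test_threshold_at_ceiling_is_ineligible(self, targets):
        d = _dist([0.002] * 5 + [0.19] * 90 + [0.5] * 5)
        p, ok = eligibility(d, targets)
        assert p == pytest.approx(2000.0)
        assert not ok  # "less than 2000 mW" is strict

    def test_wide_dynamic_range_ineligible_at_any_power(self, targets):
        # q95/q05 = 150 > H/T = 100
        d = _dist([0.001] * 5 + [0.15] * 90 + [1.0] * 5)
        _, ok = eligibility(d, targets)
        assert not ok
        # oracle: no lattice power below the cap satisfies both constraints
        for p in np.arange(0.5, 2000.0, 0.5):
            assert not (coverage_met(d, targets, p) and hotspot_feasible(d, targets, p))

    def test_moderate_range_eligible(self, targets):
        d = _dist([0.01] * 5 + [0.3] * 89 + [0.5] * 6)
        p, ok = eligibility(d, targets)
        assert p == pytest.approx(400.0)
        assert ok

    def test_closed_form_ratio_rule_matches_direct_rule(self, targets, rng):
        for _ in range(200):
            v = rng.lognormal(rng.uniform(-6, -3), rng.uniform(0.3, 2.0), 80)
            d = _dist(v)
            q05 = area_quantile(v, d.areas, 0.05)
            q95 = area_quantile(v, d.areas, 0.95)
            _, ok = eligibility(d, targets)
            closed = (
                q05 > 0
                and targets.target / q05 < targets.max_power
                and q95 / q05 < targets.hotspot_limit / targets.target
            )
            assert ok == closed


def _plan(gid, mus, p_th, eligible=True, mua_wall=0.2):
    return PlanResult(
        geometry_id=gid, cell=PropertyCell(mua_wall, mus, 0.0),
        p_threshold=p_th, hotspot_ok=eligible, eligible=eligible,
        q05=4.0 / p_th if p_th > 0 else 0.0, q95=0.0,
    )


class TestPlanSelection:
    def test_single_entry(self):
        r = _plan("g", 0.0, 5.0)
        assert optimal_intralipid([r]) is r

    def test_argmin_over_concentrations(self):
        rs = [_plan("g", m, p) for m, p in [(0.0, 5.0), (21.7, 3.0), (43.5, 7.0)]]
        best = optimal_intralipid(rs)
        assert best.p_threshold == 3.0
        assert best.intralipid_pct == pytest.approx(0.5, abs=0.01)

    def test_tie_breaks_to_lowest_concentration(self):
        rs = [_plan("g", 21.7, 3.0), _plan("g", 0.0, 3.0)]
        assert optimal_intralipid(rs).intralipid_pct == 0.0

    def test_all_ineligible_reports_best_with_flag(self):
        rs = [_plan("g", 0.0, 5000.0, eligible=False), _plan("g", 21.7, 4000.0, eligible=False)]
        best = optimal_intralipid(rs)
        assert best.p_threshold == 4000.0
        assert not best.eligible

    def test_mixed_geometry_rejected(self):
        with pytest.raises(ValueError):
            optimal_intralipid([_plan("a", 0.0, 1.0), _plan("b", 0.0, 2.0)])

    def test_uniform_plan_picks_cell_nearest_one_percent(self):
        rs = [_plan("g", m, p) for m, p in [(0.0, 2.0), (43.48, 9.0), (87.0, 1.0)]]
        assert uniform_dose_plan(rs).p_threshold == 9.0  # 43.48 cm^-1 == 1%

    def test_uniform_plan_missing_cell_rejected(self):
        with pytest.raises(ValueError, match="near 1"):
            uniform_dose_plan([_plan("g", 0.0, 2.0)])

    def test_optimized_never_worse_than_uniform(self, rng):
        for _ in range(50):
            mus = [0.0, 21.7, 43.48, 65.2]
            rs = [_plan("g", m, float(rng.uniform(1, 100))) for m in mus]
            assert optimal_intralipid(rs).p_threshold <= uniform_dose_plan(rs).p_threshold


class TestWallDistribution:
    def test_uniform_map_gives_uniform_distribution(self, small_sphere_grid, small_sphere_surface):
        fm = FluenceMap(
            values=np.full(small_sphere_grid.shape, 0.25),
            spacing=small_sphere_grid.spacing, origin=small_sphere_grid.origin,
            n_photons=1, seed=0, absorbed=1.0, escaped=0.0,
        )
        d = wall_distribution(fm, small_sphere_surface)
        assert np.all(d.phi_per_mw == 0.25)
        assert len(d.phi_per_mw) == len(small_sphere_surface)

    def test_mismatched_grid_rejected(self, small_sphere_surface):
        fm = FluenceMap(np.zeros((5, 5, 5)), (0.1,) * 3, (0, 0, 0), 1, 0, 1.0, 0.0)
        with pytest.raises(ValueError, match="different grids"):
            wall_distribution(fm, small_sphere_surface)

    def test_point_source_in_empty_sphere_is_nearly_uniform(
        self, small_sphere_grid, small_sphere_surface
    ):
        from abscesspdt.optics import assemble_properties
        from abscesspdt.transport import PointSource, simulate

        fm = simulate(small_sphere_grid, assemble_properties(PropertyCell(0.2, 0.0, 0.0)),
                      PointSource((0, 0, 0)), 100_000, 5)
        d = wall_distribution(fm, small_sphere_surface)
        cv = d.phi_per_mw.std() / d.phi_per_mw.mean()
        assert cv < 0.15


@pytest.fixture(scope="module")
def tiny_sphere():
    return {"s0": generate_phantom(
        PhantomSpec(shape="sphere", radius=0.8, spacing=(0.1,) * 3, pad=0.6)
    )}


class TestSweeps:
    def test_case1_bookkeeping_and_determinism(self, tiny_sphere, targets):
        kw = dict(mua_wall_list=[0.2, 1.0], mus_cavity_list=[0.0, 43.48],
                  targets=targets, n_photons=3000, seed=5)
        r1 = run_sweep_case1(tiny_sphere, **kw)
        r2 = run_sweep_case1(tiny_sphere, **kw)
        assert len(r1.cells) == 4
        assert set(r1.plans["strategy"]) == {"optimized", "uniform"}
        assert r1.cells.equals(r2.cells)
        assert r1.plans.equals(r2.plans)

    def test_case2_zero_cavity_absorption_reduces_to_case1(self, tiny_sphere, targets):
        r1 = run_sweep_case1(tiny_sphere, [0.2], [0.0, 43.48], targets, 3000, 5)
        r2 = run_sweep_case2(tiny_sphere, [0.2], [0.0, 43.48], [0.0], targets, 3000, 5)
        opt1 = r1.plans.query("strategy == 'optimized'").iloc[0]
        for mode in ("fixed-plan", "power-only", "full"):
            row = r2.plans.query(f"mode == '{mode}'").iloc[0]
            assert row["p_threshold_mw"] == pytest.approx(opt1["p_threshold_mw"])
            assert row["eligible"] == opt1["eligible"]

    def test_case2_mode_dominance_on_every_cell(self, tiny_sphere, targets):
        r = run_sweep_case2(tiny_sphere, [0.2, 1.0], [0.0, 43.48], [0.0, 0.17],
                            targets, 3000, 5)
        rank = {"fixed-plan": 0, "power-only": 1, "full": 2}
        piv = r.plans.pivot_table(index=["geometry_id", "mu_a_wall", "mu_a_cavity"],
                                  columns="mode", values="eligible")
        assert np.all(piv["full"] >= piv["power-only"])
        assert np.all(piv["power-only"] >= piv["fixed-plan"])

    def test_unknown_mode_rejected(self, tiny_sphere, targets):
        with pytest.raises(ValueError, match="mode"):
            run_sweep_case2(tiny_sphere, [0.2], [0.0], [0.0], targets, 1000, 1,
                            modes=("bogus",))


class TestFriedman:
    def test_identical_columns_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            stat, p = friedman_test([[1, 1, 1], [2, 2, 2], [3, 3, 3]])
        assert stat == 0.0 and p == 1.0

    def test_matches_scipy_for_three_treatments(self, rng):
        from scipy.stats import friedmanchisquare

        m = rng.normal(size=(8, 3))
        stat, p = friedman_test(m)
        ref = friedmanchisquare(*[m[:, j] for j in range(3)])
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_statistic_against_exhaustive_permutation(self):
        # 4 blocks x 3 treatments; enumerate all within-block orderings
        m = np.array([[1.0, 2.0, 4.0], [3.0, 1.0, 2.0], [2.0, 5.0, 6.0], [1.0, 4.0, 2.0]])
        stat, p = friedman_test(m)
        perms = list(itertools.permutations(range(3)))
        stats = []
        for combo in itertools.product(perms, repeat=4):
            pm = np.array([m[i, list(combo[i])] for i in range(4)])
            s, _ = friedman_test(pm)
            stats.append(s)
        stats = np.asarray(stats)
        exact_p = np.mean(stats >= stat - 1e-12)
        # observed statistic sits in its own permutation distribution, and the
        # chi-square approximation tracks the exact tail probability
        assert stat in np.round(stats, 12)
        assert abs(p - exact_p) < 0.12

    def test_two_treatment_case_supported(self):
        stat, p = friedman_test([[1, 2], [1, 3], [2, 4], [1, 5], [2, 6]])
        assert stat > 0 and 0 < p < 1


class TestWilcoxon:
    def test_all_positive_differences_exact_p(self):
        x = np.array([1.0, 2.0, 0.5, 3.0, 1.5, 2.5])
        stat, p = wilcoxon_signed_rank(x, alternative="greater", method="exact")
        assert p == pytest.approx(1 / 64)

    def test_matches_sign_enumeration(self, rng):
        d = rng.normal(0.4, 1.0, 8)
        d = d[d != 0]
        _, p = wilcoxon_signed_rank(d, alternative="greater", method="exact")
        # oracle: exhaust all 2^n sign assignments of |d|
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_obs = ranks[d > 0].sum()
        count = 0
        n = len(d)
        for signs in itertools.product([0, 1], repeat=n):
            w = ranks[np.array(signs, bool)].sum()
            if w >= w_obs:
                count += 1
        assert p == pytest.approx(count / 2**n)

    def test_all_zero_differences_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            stat, p = wilcoxon_signed_rank(np.zeros(6))
        assert p == 1.0
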