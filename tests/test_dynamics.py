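"""Growth laws, event rates, Gillespie sampling, and the replacement loop."""

import numpy as np
import pytest
import scipy.stats

from diffgoods import (
    ConfigurationError,
    GrowthParams,
    InitialCondition,
    NONPRODUCER,
    PRODUCER,
    ResourceParams,
    Simulation,
    growth_rate,
    growth_rate_mutualism,
    growth_rate_saturating,
    make_grid,
    simulate,
    steady_state_field,
    solve_direct,
)
from tests.conftest import random_grids


class TestGrowthLaws:
    def test_nonproducer_basal(self):
        assert growth_rate(NONPRODUCER, 0.0, GrowthParams(alpha=5.0)) == 1.0

    def test_producer_zero_at_full_cost_no_resource(self):
        assert growth_rate(PRODUCER, 0.0, GrowthParams(alpha=5.0, kappa=1.0)) == 0.0

    def test_one_unit_of_resource_gives_49_fold_speedup(self):
        # alpha = 49: one unit of resource adds 49x the basal rate
        assert growth_rate(NONPRODUCER, 1.0, GrowthParams(alpha=49.0)) == 50.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            growth_rate(PRODUCER, -0.1, GrowthParams(alpha=1.0))

    def test_mutualism_zero_at_no_complementary_resource(self):
        p = GrowthParams(alpha=3.0, variant="mutualism")
        assert growth_rate_mutualism(PRODUCER, 0.0, p) == 0.0
        assert growth_rate_mutualism(NONPRODUCER, 0.0, p) == 0.0

    def test_mutualism_symmetric_under_type_swap(self):
        p = GrowthParams(alpha=3.0, variant="mutualism")
        c = np.array([0.2, 0.7])
        np.testing.assert_array_equal(
            growth_rate_mutualism(PRODUCER, c, p), growth_rate_mutualism(NONPRODUCER, c, p)
        )

    def test_saturating_limits(self):
        p = GrowthParams(alpha=6.0, kappa=0.5)
        c = np.array([0.0, 0.3, 2.0])
        np.testing.assert_allclose(
            growth_rate_saturating(NONPRODUCER, c, p, np.inf),
            growth_rate(NONPRODUCER, c, p))
        # benefit saturates at alpha*k_s as c -> inf
        assert growth_rate_saturating(NONPRODUCER, 1e12, p, 2.0) == pytest.approx(
            1.0 + 6.0 * 2.0, rel=1e-9)
        # half-saturation at c = k_s
        assert growth_rate_saturating(NONPRODUCER, 2.0, p, 2.0) == pytest.approx(
            1.0 + 6.0 * 1.0)

    def test_param_validation(self):
        with pytest.raises(ConfigurationError):
            GrowthParams(alpha=1.0, kappa=2.0)  # kappa > g0
        with pytest.raises(ConfigurationError):
            GrowthParams(alpha=-1.0)
        with pytest.raises(ConfigurationError):
            GrowthParams(alpha=1.0, variant="neutral")
        with pytest.raises(ConfigurationError):
            GrowthParams(variant="snowdrift")


def brute_force_event_table(grid, growth, resource):
    """Exhaustive event enumeration with a per-rate fresh direct solve."""
    L = grid.shape[0]
    events = {}
    for r in range(L):
        for c in range(L):
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = (r + dr) % L, (c + dc) % L
                if grid[rr, cc] == grid[r, c]:
                    continue
                field = solve_direct(grid, resource)
                g = growth_rate(grid[rr, cc], field[rr, cc], growth)
                events[((rr, cc), (r, c))] = g / 4.0
    return events


class TestEventTable:
    def test_uniform_grid_empty(self):
        sim = Simulation(np.ones((5, 5), dtype=np.int8), GrowthParams(variant="neutral"))
        table = sim.event_table()
        assert table.total_rate == 0.0 and table.rates.size == 0

    def test_neutral_single_invader(self, rng):
        grid = make_grid(5, InitialCondition("single_invader", NONPRODUCER), rng)
        sim = Simulation(grid, GrowthParams(variant="neutral"))
        table = sim.event_table()
        assert table.rates.size == 8
        np.testing.assert_allclose(table.rates, 0.25)
        assert table.total_rate == pytest.approx(2.0)

    def test_rates_match_exhaustive_enumeration(self):
        growth = GrowthParams(alpha=2.5)
        resource = ResourceParams(lam=1.0)
        grid = np.array([[1, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=np.int8)
        sim = Simulation(grid, growth, resource)
        table = sim.event_table()
        expected = brute_force_event_table(grid, growth, resource)
        got = {
            ((d // 3, d % 3), (t // 3, t % 3)): rate
            for d, t, rate in zip(table.dividers, table.targets, table.rates)
        }
        assert set(got) == set(expected)
        for key in expected:
            assert got[key] == pytest.approx(expected[key], rel=1e-9)


class TestSampling:
    def test_event_frequencies_match_rates(self):
        # discrete event choice: chi-square against rate/total on a fixed table
        sim = Simulation(np.ones((4, 4), dtype=np.int8), GrowthParams(variant="neutral"),
                         rng=42)
        rates = np.array([1.0, 2.0, 3.0, 4.0, 0.0, 10.0])
        n = 100_000
        counts = np.bincount([sim._sample(rates, rates.sum()) for _ in range(n)],
                             minlength=rates.size)
        assert counts[4] == 0
        expected = rates / rates.sum() * n
        chi2 = scipy.stats.chisquare(counts[expected > 0], expected[expected > 0])
        assert chi2.pvalue > 1e-4

    def test_waiting_time_mean(self):
        # first waiting time of a fresh single-invader neutral system: rate 2*g0
        taus = []
        for i in range(3000):
            rng = np.random.default_rng(1000 + i)
            grid = make_grid(3, InitialCondition("single_invader", NONPRODUCER), rng)
            sim = Simulation(grid, GrowthParams(variant="neutral"), rng=rng)
            sim.step()
            taus.append(sim.time)
        mean, se = np.mean(taus), np.std(taus) / np.sqrt(len(taus))
        assert abs(mean - 0.5) < 3 * se

    def test_single_event_table_certain_choice(self):
        sim = Simulation(np.ones((4, 4), dtype=np.int8), GrowthParams(variant="neutral"),
                         rng=0)
        rates = np.array([3.0])
        assert sim._sample(rates, 3.0) == 0


class TestApplyAndRun:
    def test_apply_then_reverse_restores_grid_and_field(self, mixed16):
        growth = GrowthParams(alpha=5.0)
        resource = ResourceParams(lam=3.0)
        sim = Simulation(mixed16, growth, resource, rng=1)
        table = sim.event_table()
        grid0, field0 = sim.grid.copy(), sim.field.copy()
        flat = grid0.ravel()
        # choose an edge whose target keeps a same-type neighbor, so the
        # replacement can be undone by a second (reverse) event
        for d, t in zip(table.dividers, table.targets):
            others = [n for n in sim.nbr[:, t] if n != d and flat[n] == flat[t]]
            if others:
                sim._apply(int(d), int(t))
                sim._apply(int(others[0]), int(t))
                break
        np.testing.assert_array_equal(sim.grid, grid0)
        np.testing.assert_allclose(sim.field, field0, atol=1e-12)

    def test_stale_event_rejected(self, mixed16):
        sim = Simulation(mixed16, GrowthParams(variant="neutral"), rng=1)
        flat = sim.grid.ravel()
        same = np.nonzero(flat[sim.nbr[0]] == flat)[0][0]
        with pytest.raises(ValueError):
            sim._apply(int(sim.nbr[0, same]), int(same))

    def test_field_consistent_after_50_events(self, mixed16):
        resource = ResourceParams(lam=3.0)
        sim = Simulation(mixed16, GrowthParams(alpha=5.0), resource, rng=7)
        for _ in range(50):
            sim.step()
        fresh = steady_state_field(sim.grid, resource)
        assert np.abs(sim.field - fresh).max() < 1e-9 * fresh.max()

    def test_mutualism_fields_consistent_after_events(self, mixed16):
        resource = ResourceParams(lam=2.0)
        sim = Simulation(mixed16, GrowthParams(alpha=2.0, variant="mutualism"),
                         resource, rng=3)
        for _ in range(40):
            sim.step()
        np.testing.assert_allclose(
            sim.field, steady_state_field(sim.grid, resource), atol=1e-10)
        np.testing.assert_allclose(
            sim.field_b,
            steady_state_field((sim.grid == NONPRODUCER).astype(np.int8), resource),
            atol=1e-10)

    def test_np_fraction_changes_by_one_cell_per_event(self, mixed16):
        sim = Simulation(mixed16, GrowthParams(variant="neutral"), rng=9)
        prev = sim.np_fraction
        for _ in range(200):
            if sim.step() is None:
                break
            assert abs(sim.np_fraction - prev) * sim.n == pytest.approx(1.0)
            prev = sim.np_fraction

    def test_uniform_initial_grid_absorbs_immediately(self):
        sim = Simulation(np.zeros((4, 4), dtype=np.int8), GrowthParams(variant="neutral"),
                         rng=0)
        res, traj = sim.run_until_fixation()
        assert res.absorbed and res.fixation_time == 0.0 and res.winner == NONPRODUCER

    def test_costly_useless_production_always_loses(self):
        # alpha=0, kappa=g0: producer rates are zero, nonproducers must fix
        for seed in range(5):
            res, _ = simulate(8, GrowthParams(alpha=0.0), ResourceParams(lam=2.0),
                              seed=seed)
            assert res.absorbed and res.winner == NONPRODUCER

    def test_replay_determinism(self):
        out = []
        for _ in range(2):
            res, traj = simulate(8, GrowthParams(alpha=3.0), ResourceParams(lam=2.0),
                                 seed=2024, record_stride=16)
            out.append((res, traj))
        assert out[0][0] == out[1][0]
        np.testing.assert_array_equal(out[0][1].time, out[1][1].time)
        np.testing.assert_array_equal(out[0][1].np_fraction, out[1][1].np_fraction)

    def test_max_events_flagged_not_silent(self, mixed16):
        sim = Simulation(mixed16, GrowthParams(variant="neutral"), rng=5)
        res, _ = sim.run_until_fixation(max_events=10)
        assert not res.absorbed and res.winner is None and res.event_count == 10

    def test_only_boundary_cells_divide(self, mixed16):
        sim = Simulation(mixed16, GrowthParams(variant="neutral"), rng=11)
        from diffgoods.lattice import boundary_mask
        for _ in range(100):
            bm = boundary_mask(sim.grid, sim.nbr).ravel()
            out = sim.step()
            if out is None:
                break
            divider, target, _ = out
            assert bm[divider] and bm[target]

    def test_saturating_variant_resolves_field_each_event(self):
        from diffgoods.resource import residual_saturating
        resource = ResourceParams(lam=2.0, k_s=5.0)
        grid = (np.random.default_rng(2).random((8, 8)) < 0.3).astype(np.int8)
        sim = Simulation(grid, GrowthParams(alpha=2.0, variant="competition_saturating"),
                         resource, rng=4)
        for _ in range(10):
            if sim.step() is None:
                break
        assert np.abs(residual_saturating(sim.grid, sim.field, resource)).max() < 1e-9

    def test_noop_clock_rescales_time_but_not_configurations(self, mixed16):
        # summing the full growth rate of boundary cells (counting same-type
        # no-op replacements) changes only the waiting times
        sims = [Simulation(mixed16, GrowthParams(alpha=3.0), ResourceParams(lam=2.0),
                           rng=77, include_noop_clock=flag) for flag in (False, True)]
        for _ in range(100):
            for s in sims:
                s.step()
        np.testing.assert_array_equal(sims[0].grid, sims[1].grid)
        assert sims[1].time < sims[0].time

    def test_neutral_invader_fixation_one_over_N(self):
        # vertex-transitive lattice: invader fixes with probability 1/L^2
        wins = n = 0
        for i in range(4000):
            res, _ = simulate(3, GrowthParams(variant="neutral"),
                              init=InitialCondition("single_invader", NONPRODUCER),
                              seed=50_000 + i, record_stride=10 ** 9)
            n += 1
            wins += res.winner == NONPRODUCER
        p = wins / n
        se = np.sqrt((1 / 9) * (8 / 9) / n)
        assert abs(p - 1 / 9) < 3 * se
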