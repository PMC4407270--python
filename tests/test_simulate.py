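"""Stochastic per-cell timelines: determinism, event order, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfbsim.locus import (
    LocusMap,
    Origin,
    Side,
    TimingParams,
    window_distribution_enumerate,
    delete_origin,
)
from rfbsim.simulate import (
    CellTimeline,
    Outcome,
    SimulationParams,
    reporter_hit_rates,
    restart_fraction,
    simulate_cell,
    simulate_population,
    timelines_to_frame,
)


def deterministic_params(**overrides):
    base = dict(
        s_start_min=10.0,
        recruitment_lag_min=5.0,
        restart_delay_min=10.0,
        pcna_end_min=50.0,
    )
    base.update(overrides)
    return SimulationParams(**base)


class TestSimulateCell:
    def test_no_blockage_when_blocking_never_fires(self, timing):
        m = LocusMap("AO", (
            Origin("b", Side.BLOCKING, 3000, 0.0),
            Origin("c", Side.CONVERGING, 30000, 1.0),
        ))
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = simulate_cell(m, timing, SimulationParams(), rng)
            assert c.outcome is Outcome.NO_BLOCKAGE
            assert not c.has_rad52_interval

    def test_deterministic_toy_arithmetic(self, timing):
        # blockage at s+1.0, window 30 (converging at 93 kb), lag 5, delay 10:
        # focus appears at blockage+5 and resolves at restart = blockage+10.
        m = LocusMap("AO", (
            Origin("b", Side.BLOCKING, 3000, 1.0),
            Origin("c", Side.CONVERGING, 93000, 1.0),
        ))
        c = simulate_cell(m, timing, deterministic_params(), np.random.default_rng(1))
        assert c.outcome is Outcome.RESTARTED
        assert c.blockage_min == pytest.approx(11.0)
        assert c.restart_min == pytest.approx(21.0)
        assert c.rad52_start_min == pytest.approx(16.0)
        assert c.rad52_end_min == pytest.approx(21.0)

    def test_rad52_ends_at_convergence_when_converged(self, timing):
        # window 9 < delay 20: convergence wins, persistence 0
        m = LocusMap("AO", (
            Origin("b", Side.BLOCKING, 3000, 1.0),
            Origin("c", Side.CONVERGING, 30000, 1.0),
        ))
        c = simulate_cell(
            m, timing, deterministic_params(restart_delay_min=20.0),
            np.random.default_rng(1),
        )
        assert c.outcome is Outcome.CONVERGED
        assert c.rad52_end_min == pytest.approx(c.convergence_min)

    def test_short_window_gives_no_rad52_interval(self, timing):
        # window 9 < lag 12: recruitment never completes before merging
        m = LocusMap("AO", (
            Origin("b", Side.BLOCKING, 3000, 1.0),
            Origin("c", Side.CONVERGING, 30000, 1.0),
        ))
        c = simulate_cell(
            m, timing, deterministic_params(recruitment_lag_min=12.0),
            np.random.default_rng(1),
        )
        assert not c.has_rad52_interval

    def test_restart_fraction_matches_enumeration_oracle(self, timing):
        # point-mass delay 20; windows are 10 (c1 fires, p=0.5) or 29:
        # P(restart) = P(window > 20) = 0.5 exactly
        m = LocusMap("AO", (
            Origin("b", Side.BLOCKING, 3000, 1.0),
            Origin("c1", Side.CONVERGING, 33000, 0.5),
            Origin("c2", Side.CONVERGING, 90000, 1.0),
        ))
        dist = window_distribution_enumerate(m, timing)
        p_true = sum(p for w, p in dist.numeric_support if w > 20.0)
        assert p_true == pytest.approx(0.5)
        n = 10_000
        pop = simulate_population(
            n, m, timing, deterministic_params(restart_delay_min=20.0), seed=3
        )
        se = math.sqrt(p_true * (1 - p_true) / n)
        assert abs(restart_fraction(pop) - p_true) < 3 * se


class TestSimulatePopulation:
    def test_reproducible_under_seed(self, barrier_map):
        a = simulate_population(50, barrier_map, seed=9)
        b = simulate_population(50, barrier_map, seed=9)
        assert timelines_to_frame(a).equals(timelines_to_frame(b))

    def test_growing_population_keeps_earlier_cells(self, barrier_map):
        small = simulate_population(5, barrier_map, seed=4)
        large = simulate_population(10, barrier_map, seed=4)
        assert timelines_to_frame(large).iloc[:5].equals(timelines_to_frame(small))

    def test_nonpositive_n_rejected(self, barrier_map):
        with pytest.raises(ValueError):
            simulate_population(0, barrier_map)

    def test_degenerate_all_efficiencies_one(self, timing):
        m = LocusMap("AO", (
            Origin("b", Side.BLOCKING, 3000, 1.0),
            Origin("c", Side.CONVERGING, 30000, 1.0),
        ))
        pop = simulate_population(
            200, m, timing, deterministic_params(restart_delay_min=math.inf), seed=0
        )
        blocks = {c.blockage_min for c in pop}
        assert blocks == {11.0}  # s_start 10 + arrival 1.0, every cell

    def test_io_orientation_never_blocks(self, barrier_map_io):
        pop = simulate_population(200, barrier_map_io, seed=1)
        assert all(c.outcome is Outcome.NO_BLOCKAGE for c in pop)

    def test_window_histogram_matches_enumeration(self, toy_map, timing):
        # Monte-Carlo windows vs exact enumeration, 3 binomial SE per bin
        dist = window_distribution_enumerate(toy_map, timing)
        n = 10_000
        pop = simulate_population(n, toy_map, timing, SimulationParams(), seed=12)
        counts = {"undefined": 0, "censored": 0}
        for c in pop:
            if c.blockage_min is None:
                counts["undefined"] += 1
            elif c.convergence_min is None:
                counts["censored"] += 1
            else:
                w = round(c.convergence_min - c.blockage_min, 6)
                counts[w] = counts.get(w, 0) + 1
        for w, p in dist.support:
            key = repr(w).lower() if not isinstance(w, float) else round(w, 6)
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts.get(key, 0) / n - p) < 3 * se, f"bin {w}"


class TestRestartFraction:
    def test_infinite_delay_never_restarts(self, toy_map, timing):
        pop = simulate_population(
            500, toy_map, timing, deterministic_params(restart_delay_min=math.inf),
            seed=0,
        )
        assert restart_fraction(pop) == 0.0

    def test_zero_delay_always_restarts_given_window(self, toy_map, timing):
        pop = simulate_population(
            500, toy_map, timing, deterministic_params(restart_delay_min=0.0), seed=0
        )
        blocked_open = [
            c for c in pop
            if c.blockage_min is not None
            and (c.convergence_min is None or c.convergence_min > c.blockage_min)
        ]
        assert blocked_open
        assert all(c.outcome is Outcome.RESTARTED for c in blocked_open)

    def test_undefined_without_blocked_cells(self, timing):
        m = LocusMap("AO", (
            Origin("b", Side.BLOCKING, 3000, 0.0),
            Origin("c", Side.CONVERGING, 30000, 1.0),
        ))
        pop = simulate_population(20, m, timing, seed=0)
        with pytest.raises(ValueError):
            restart_fraction(pop)

    def test_monotone_in_restart_delay(self, barrier_map):
        fracs = []
        for delay in (10.0, 25.0, 40.0):
            pop = simulate_population(
                4000, barrier_map,
                params=SimulationParams(restart_delay_min=delay), seed=21,
            )
            fracs.append(restart_fraction(pop))
        assert fracs[0] > fracs[1] > fracs[2]


class TestReporterHits:
    @staticmethod
    def _map_with_sites(hazard_sites):
        return LocusMap(
            "AO",
            (Origin("b", Side.BLOCKING, 3000, 1.0),),
            hazard_sites,
        )

    def test_zero_hazard_zero_rates(self, timing, barrier_map):
        pop = simulate_population(500, barrier_map, seed=5)
        rates = reporter_hit_rates(pop, barrier_map)
        assert all(v == 0.0 for v in rates.values())

    def test_closed_form_poisson_rate(self, timing):
        # no converging origin: every restarted fork runs to the horizon and
        # passes the site; P(>=1 hit in a w-kb window) = 1 - exp(-h*w)
        m = self._map_with_sites((("site", 3000),))
        h, w_kb = 0.6, 1.0
        params = deterministic_params(collapse_hazard_per_kb=h)
        n = 6000
        pop = simulate_population(n, m, timing, params, seed=8)
        assert all(c.outcome is Outcome.RESTARTED for c in pop)
        rate = reporter_hit_rates(pop, m, window_bp=1000 * w_kb)["site"]
        p = 1 - math.exp(-h * w_kb)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(rate - p) < 3 * se

    def test_monotone_in_hazard(self, timing):
        m = self._map_with_sites((("site", 3000),))
        rates = []
        for h in (0.05, 0.2, 0.8):
            pop = simulate_population(
                3000, m, timing, deterministic_params(collapse_hazard_per_kb=h),
                seed=13,
            )
            rates.append(reporter_hit_rates(pop, m)["site"])
        assert rates[0] < rates[1] < rates[2]

    def test_origin_deletion_raises_site_b_rate(self, barrier_map):
        params = SimulationParams(collapse_hazard_per_kb=0.05)
        pop_full = simulate_population(6000, barrier_map, params=params, seed=17)
        deleted = delete_origin(barrier_map, "ori-1253")
        pop_del = simulate_population(6000, deleted, params=params, seed=17)
        rate_full = reporter_hit_rates(pop_full, barrier_map)["siteB"]
        rate_del = reporter_hit_rates(pop_del, deleted)["siteB"]
        assert rate_del >= rate_full

    def test_unknown_site_label(self, barrier_map):
        pop = simulate_population(10, barrier_map, seed=0)
        with pytest.raises(KeyError):
            barrier_map.reporter("siteZ")


@given(
    s_lo=st.floats(5, 20), s_width=st.floats(0, 10),
    lag_lo=st.floats(1, 15), lag_width=st.floats(0, 10),
    delay_lo=st.floats(0, 40), delay_width=st.floats(0, 40),
    persistence=st.floats(0, 10),
    hazard=st.floats(0, 0.3),
    seed=st.integers(0, 2**31 - 1),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_event_order_invariants(s_lo, s_width, lag_lo, lag_width, delay_lo,
                                delay_width, persistence, hazard, seed):
    """Every simulated timeline respects the event-order constraints for any
    admissible parameter draw (the dataclass re-asserts them on build)."""
    m = LocusMap("AO", (
        Origin("b1", Side.BLOCKING, 3000, 0.6),
        Origin("b2", Side.BLOCKING, 25000, 0.4),
        Origin("c1", Side.CONVERGING, 40000, 0.7),
    ))
    params = SimulationParams(
        s_start_min=(s_lo, s_lo + s_width),
        recruitment_lag_min=(lag_lo, lag_lo + lag_width),
        restart_delay_min=(delay_lo, delay_lo + delay_width),
        rad52_persistence_min=persistence,
        collapse_hazard_per_kb=hazard,
    )
    rng = np.random.default_rng(seed)
    for _ in range(10):
        c = simulate_cell(m, TimingParams(), params, rng)
        if c.outcome is Outcome.NO_BLOCKAGE:
            assert c.blockage_min is None and c.restart_min is None
        if c.outcome is Outcome.RESTARTED:
            assert c.restart_min is not None
            if c.convergence_min is not None:
                assert c.restart_min < c.convergence_min
        if c.outcome is Outcome.CONVERGED:
            assert c.restart_min is None and c.blockage_min is not None
        for pos_kb, t in c.downstream_collapses:
            assert pos_kb >= 0 and t >= c.restart_min
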