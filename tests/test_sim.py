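"""Simulator unit and property tests against closed-form Markov oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from flctools.sim import (
    Cell,
    CellCycleModel,
    CellFileState,
    CellState,
    EmissionParams,
    SimulationConfig,
    SwitchingParams,
    advance_file,
    census,
    draw_cycle_duration,
    sample_intensity,
    simulate_root,
    switch_cell,
    transition_matrix,
)


def make_file(states, remaining):
    return CellFileState(states=np.asarray(states), remaining=np.asarray(remaining))


class TestSwitchCell:
    def test_zero_probabilities_identity(self):
        p = SwitchingParams(0.0, 0.0)
        for s in CellState:
            for r in (0.0, 0.5, 0.999):
                assert switch_cell(s, p, r) == s

    def test_onon_cumulative_intervals(self):
        # p_off=0.5: double switch below 0.25, single switch below 0.75, else stay
        p = SwitchingParams(0.5, 0.0)
        assert switch_cell(CellState.ON_ON, p, 0.2) == CellState.OFF_OFF
        assert switch_cell(CellState.ON_ON, p, 0.3) == CellState.ON_OFF
        assert switch_cell(CellState.ON_ON, p, 0.8) == CellState.ON_ON

    def test_r_domain_error(self):
        with pytest.raises(ValueError):
            switch_cell(CellState.ON_ON, SwitchingParams(0.1, 0.1), 1.0)
        with pytest.raises(ValueError):
            switch_cell(CellState.ON_ON, SwitchingParams(0.1, 0.1), -0.1)

    def test_onoff_trinomial_frequencies(self, rng):
        # Monte-Carlo frequencies vs the analytic trinomial for the mixed state
        p = SwitchingParams(p_off=0.2, p_on=0.1)
        n = 100_000
        draws = rng.random(n)
        out = np.array([int(switch_cell(CellState.ON_OFF, p, float(r))) for r in draws])
        expect = {0: 0.2 * 0.9, 2: 0.1 * 0.8, 1: 1 - 0.18 - 0.08}
        for k, pk in expect.items():
            se = np.sqrt(pk * (1 - pk) / n)
            assert abs((out == k).mean() - pk) < 3 * se

    def test_vectorized_switch_matches_scalar(self, rng):
        from flctools.sim import switch_states

        p = SwitchingParams(p_off=0.3, p_on=0.15)
        states = rng.integers(0, 3, 500).astype(np.int8)
        draws = rng.random(500)
        vec = switch_states(states, p, draws)
        scalar = [switch_cell(CellState(int(s)), p, float(r)) for s, r in zip(states, draws)]
        assert np.array_equal(vec, np.array(scalar, dtype=np.int8))

    @given(
        p_off=st.floats(0.0, 1.0, allow_nan=False),
        p_on=st.floats(0.0, 1.0, allow_nan=False),
    )
    @settings(deadline=None, max_examples=100)
    def test_outgoing_probabilities_sum_to_one(self, p_off, p_on):
        M = transition_matrix(SwitchingParams(p_off, p_on))
        assert np.all(np.abs(M.sum(axis=1) - 1.0) < 1e-12)
        assert np.all(M >= -1e-15)


class TestCellCycle:
    def test_degenerate_sd_returns_mean(self, rng):
        model = CellCycleModel(mean_by_position=np.array([20.0]), sd_by_position=np.array([0.0]))
        assert draw_cycle_duration(model, 5, rng) == 20.0

    def test_minimum_duration_enforced(self, rng):
        model = CellCycleModel(mean_by_position=np.array([14.0]), sd_by_position=np.array([5.0]))
        draws = [draw_cycle_duration(model, 1, rng) for _ in range(500)]
        assert min(draws) >= 13.0

    def test_truncated_mean_matches_closed_form(self, rng):
        mean, sd, lo = 14.0, 5.0, 13.0
        model = CellCycleModel(mean_by_position=np.array([mean]), sd_by_position=np.array([sd]))
        n = 100_000
        from flctools.sim import _draw_durations

        draws = _draw_durations(model, np.ones(n, dtype=int), rng)
        alpha = (lo - mean) / sd
        expected = mean + sd * sps.norm.pdf(alpha) / (1 - sps.norm.cdf(alpha))
        trunc_sd = draws.std()
        assert abs(draws.mean() - expected) < 3 * trunc_sd / np.sqrt(n)

    def test_position_table_clamps(self, rng):
        model = CellCycleModel(
            mean_by_position=np.array([16.0, 20.0, 24.0]),
            sd_by_position=np.array([0.0]),
        )
        assert draw_cycle_duration(model, 1, rng) == 16.0
        assert draw_cycle_duration(model, 99, rng) == 24.0

    def test_invalid_mean_rejected(self):
        with pytest.raises(ValueError):
            CellCycleModel(mean_by_position=np.array([-1.0]))


class TestAdvanceFile:
    def test_no_divisions_only_ages(self, rng):
        f = make_file([2] * 5, [10.0, 9.0, 8.0, 7.0, 6.0])
        out = advance_file(f, SwitchingParams(0, 0), CellCycleModel(), dt=1.0, rng=rng)
        assert np.array_equal(out.states, f.states)
        assert np.allclose(out.remaining, f.remaining - 1.0)

    def test_division_shifts_and_inherits(self, rng):
        # one division at position 10 of a full 30-cell file: daughters share
        # the mother's state and the former top cell is pushed out
        states = np.full(30, 2, dtype=np.int8)
        states[9] = 1
        states[29] = 0
        remaining = np.full(30, 100.0)
        remaining[9] = 0.5  # divides this step
        f = make_file(states, remaining)
        cyc = CellCycleModel(sd_by_position=np.array([0.0]))
        out = advance_file(f, SwitchingParams(0, 0), cyc, dt=1.0, rng=rng, file_length=30)
        assert len(out) == 30
        assert out.states[9] == 1 and out.states[10] == 1
        assert out.states[-1] == 2  # the OFF top cell fell off the file
        assert out.remaining[9] == 20.0 and out.remaining[10] == 20.0

    def test_state_fractions_invariant_without_switching(self, rng):
        # division is state-independent in expectation; with zero switching
        # each lineage keeps its state forever, so a homogeneous-state tally
        # per state never changes for surviving cells of that lineage
        f = make_file([0, 1, 2] * 10, rng.uniform(5, 25, 30))
        counts0 = np.bincount(f.states, minlength=3)
        for _ in range(200):
            f = advance_file(f, SwitchingParams(0, 0), CellCycleModel(), dt=1.0, rng=rng)
        # states present can only be inherited copies of the initial ones
        assert set(np.unique(f.states)) <= {0, 1, 2}
        assert len(f) == 30
        assert counts0.sum() == 30

    def test_empty_file(self, rng):
        f = make_file(np.empty(0, dtype=np.int8), np.empty(0))
        out = advance_file(f, SwitchingParams(0.1, 0.1), CellCycleModel(), 1.0, rng)
        assert len(out) == 0


class TestSampleIntensity:
    def test_degenerate_lognormals(self, rng):
        em = EmissionParams(mu_on=np.log(2.0), sigma_on=0.0, mu_off=0.0, sigma_off=0.0)
        assert sample_intensity(CellState.ON_ON, em, rng) == pytest.approx(5.0)
        assert sample_intensity(CellState.ON_OFF, em, rng) == pytest.approx(3.0)
        assert sample_intensity(CellState.OFF_OFF, em, rng) == pytest.approx(1.0)

    def test_offoff_median_is_lognormal_median(self, rng):
        em = EmissionParams(mu_on=0.0, sigma_on=0.5, mu_off=-1.0, sigma_off=0.7)
        n = 100_000
        x = sample_intensity(np.zeros(n, dtype=np.int8), em, rng)
        # sample median of log intensity ~ N(mu_off, sigma^2 * pi / (2n))
        se = em.sigma_off * np.sqrt(np.pi / (2 * n))
        assert abs(np.median(np.log(x)) - em.mu_off) < 3 * se

    def test_intensities_positive(self, rng):
        em = EmissionParams(mu_on=-3.0, sigma_on=2.0, mu_off=-5.0, sigma_off=2.0)
        x = sample_intensity(rng.integers(0, 3, 1000).astype(np.int8), em, rng)
        assert np.all(x > 0)

    def test_iid_copies_option(self, rng):
        em = EmissionParams(mu_on=np.log(2.0), sigma_on=0.0, mu_off=0.0, sigma_off=0.0, iid_copies=True)
        assert sample_intensity(CellState.ON_ON, em, rng) == pytest.approx(5.0)


class TestSimulateRoot:
    def test_zero_switching_stays_all_on(self):
        cfg = SimulationConfig(n_files=20, duration=48.0, output_times=(24.0, 48.0), seed=3)
        res = simulate_root(cfg, SwitchingParams(0, 0), None)
        for t in cfg.output_times:
            fr, _ = census(res, t)
            assert fr[2] == 1.0

    def test_geometric_survival_with_one_way_switching(self):
        # per-copy survival (1 - p_off)^k; ON/ON fraction is its square
        p_off, t = 0.01, 168.0
        cfg = SimulationConfig(n_files=1000, duration=t, output_times=(t,), seed=11)
        res = simulate_root(cfg, SwitchingParams(p_off, 0.0), None)
        s = res.states[t][:, cfg.exclude_bottom:]
        per_file = (s == 2).mean(axis=1)
        expected = (1 - p_off) ** (2 * t)
        se = per_file.std(ddof=1) / np.sqrt(cfg.n_files)
        assert abs(per_file.mean() - expected) < 3 * se

    def test_census_counts_before_and_after_exclusion(self):
        cfg = SimulationConfig(n_files=50, duration=24.0, output_times=(24.0,), seed=1)
        em = EmissionParams(0.0, 0.5, -1.5, 0.4)
        res = simulate_root(cfg, SwitchingParams(0.01, 0.001), em)
        _, all_cells = census(res, 24.0, exclude_bottom=0)
        _, kept = census(res, 24.0, exclude_bottom=4)
        assert all_cells.size == 50 * 30
        assert kept.size == 50 * 26

    def test_unreachable_output_time_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(timestep=1.0, duration=10.0, output_times=(2.5,))

    def test_census_matches_naive_recount(self):
        cfg = SimulationConfig(n_files=30, duration=48.0, output_times=(48.0,), seed=7)
        res = simulate_root(cfg, SwitchingParams(0.05, 0.01), None)
        fr, _ = census(res, 48.0)
        s = res.states[48.0]
        counts = [0, 0, 0]
        total = 0
        for f in range(s.shape[0]):
            for pos in range(s.shape[1]):
                if pos + 1 <= cfg.exclude_bottom:
                    continue
                counts[s[f, pos]] += 1
                total += 1
        assert np.allclose(fr, np.array(counts) / total)

    def test_census_unknown_time_raises(self):
        cfg = SimulationConfig(n_files=5, duration=24.0, output_times=(24.0,), seed=0)
        res = simulate_root(cfg, SwitchingParams(0, 0), None)
        with pytest.raises(KeyError):
            census(res, 12.0)

    def test_seed_reproducibility_and_nondegeneracy(self):
        cfg = SimulationConfig(n_files=30, duration=72.0, output_times=(72.0,), seed=42)
        em = EmissionParams(0.0, 0.5, -1.5, 0.4)
        a = simulate_root(cfg, SwitchingParams(0.02, 0.001), em)
        b = simulate_root(cfg, SwitchingParams(0.02, 0.001), em)
        assert np.array_equal(a.states[72.0], b.states[72.0])
        assert np.array_equal(a.intensities[72.0], b.intensities[72.0])
        c = simulate_root(
            SimulationConfig(n_files=30, duration=72.0, output_times=(72.0,), seed=43),
            SwitchingParams(0.02, 0.001), em,
        )
        assert not np.array_equal(a.states[72.0], c.states[72.0])

    def test_fraction_dynamics_match_markov_chain(self):
        # state fractions across time follow the 3-state chain despite divisions
        sw = SwitchingParams(0.03, 0.004)
        times = (24.0, 96.0, 240.0)
        cfg = SimulationConfig(n_files=1000, duration=240.0, output_times=times, seed=5)
        res = simulate_root(cfg, sw, None)
        M = transition_matrix(sw)
        for t in times:
            k = int(t / cfg.timestep)
            pi = np.array([0.0, 0.0, 1.0]) @ np.linalg.matrix_power(M, k)
            s = res.states[t][:, cfg.exclude_bottom:]
            for state in range(3):
                per_file = (s == state).mean(axis=1)
                se = max(per_file.std(ddof=1) / np.sqrt(cfg.n_files), 1e-4)
                assert abs(per_file.mean() - pi[state]) < 3 * se

    def test_adjacent_cells_more_similar_than_shuffled(self):
        # clonal inheritance creates runs of same-state cells within files
        sw = SwitchingParams(0.02, 0.0)
        cfg = SimulationConfig(n_files=400, duration=336.0, output_times=(336.0,), seed=9)
        res = simulate_root(cfg, sw, None)
        s = res.states[336.0]
        adjacent = (s[:, :-1] == s[:, 1:]).mean()
        rng = np.random.default_rng(0)
        shuffled_vals = []
        for _ in range(5):
            flat = rng.permutation(s.ravel()).reshape(s.shape)
            shuffled_vals.append((flat[:, :-1] == flat[:, 1:]).mean())
        assert adjacent > max(shuffled_vals)

    def test_dataframe_roundtrip_shape(self):
        cfg = SimulationConfig(n_files=4, duration=24.0, output_times=(12.0, 24.0), seed=2)
        em = EmissionParams(0.0, 0.5, -1.5, 0.4)
        res = simulate_root(cfg, SwitchingParams(0.01, 0.001), em)
        df = res.to_dataframe()
        assert len(df) == 4 * 30 * 2
        assert set(df.columns) == {"file_id", "position", "time_h", "n_active_copies", "intensity"}
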