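"""Gillespie turnover simulation: initialization, stepping, ensembles, tFT."""

import math

import numpy as np
import pytest

from pexflux import simulation as M

LN2 = math.log(2.0)


class TestInitPopulation:
    def test_exponential_age_distribution_mean(self):
        cfg = M.SimConfig(n_initial=1000, half_life_min=58.0)
        pop = M.init_steady_state_population(cfg, np.random.default_rng(0))
        mean_age = pop.ages().mean()
        theory = 58.0 / LN2
        assert abs(mean_age - theory) < 3 * theory / math.sqrt(1000)

    def test_one_state_regime_has_no_unstable_molecules(self):
        cfg = M.SimConfig(regime="one_state")
        pop = M.init_steady_state_population(cfg, np.random.default_rng(1))
        assert pop.n_unstable == 0
        assert pop.n_stable == 1000

    def test_two_state_unstable_count_matches_fraction(self):
        cfg = M.SimConfig(regime="two_state")
        pop = M.init_steady_state_population(cfg, np.random.default_rng(2))
        assert pop.n_unstable == 600

    def test_infinite_maturation_weight_selects_youngest(self):
        cfg = M.SimConfig(regime="two_state", n_initial=200, k_mat_hr=1e9)
        pop = M.init_steady_state_population(cfg, np.random.default_rng(3))
        unstable_ages = np.array([pop.now - b for b in pop.unstable_birth])
        stable_ages = np.array([pop.now - b for b in pop.stable_birth])
        assert unstable_ages.max() < stable_ages.min()

    def test_unstable_draws_favor_young_molecules(self):
        cfg = M.SimConfig(regime="two_state")
        pop = M.init_steady_state_population(cfg, np.random.default_rng(4))
        unstable_ages = np.array([pop.now - b for b in pop.unstable_birth])
        stable_ages = np.array([pop.now - b for b in pop.stable_birth])
        assert unstable_ages.mean() < stable_ages.mean()


class TestGillespieStep:
    def test_import_only_grows_population_by_one_per_step(self):
        rng = np.random.default_rng(5)
        pop = M.Population()
        rates = M.EventRates(import_rate=2.0)
        waits = []
        for _ in range(2000):
            _, dt = M.gillespie_step(pop, rates, rng)
            waits.append(dt)
        assert len(pop) == 2000
        assert np.mean(waits) == pytest.approx(0.5, rel=0.1)  # 1/lambda

    def test_pure_death_waiting_time(self):
        rng = np.random.default_rng(6)
        k, n = 0.01, 500
        waits = []
        for _ in range(400):
            pop = M.Population(stable_birth=[0.0] * n)
            _, dt = M.gillespie_step(pop, M.EventRates(k_deg_stable=k), rng)
            assert len(pop) == n - 1
            waits.append(dt)
        expected = 1.0 / (n * k)
        assert np.mean(waits) == pytest.approx(expected, rel=3 / math.sqrt(400))

    def test_event_frequencies_match_rate_proportions(self):
        """On a near-static large pool, channel frequencies follow the rates."""
        rng = np.random.default_rng(7)
        n = 20000
        pop = M.Population(stable_birth=[0.0] * n)
        k = 0.001
        rates = M.EventRates(import_rate=n * k, k_deg_stable=k)  # 50/50 split
        n0 = len(pop)
        steps = 4000
        for _ in range(steps):
            M.gillespie_step(pop, rates, rng)
        imports = (len(pop) - n0 + steps) / 2  # net change decomposition
        p_hat = imports / steps
        assert abs(p_hat - 0.5) < 3 * math.sqrt(0.25 / steps)

    def test_zero_total_rate_halts_cleanly(self):
        pop = M.Population()
        _, dt = M.gillespie_step(pop, M.EventRates(), np.random.default_rng(8))
        assert math.isinf(dt)

    def test_ages_advance_with_the_clock(self):
        rng = np.random.default_rng(9)
        pop = M.Population(stable_birth=[0.0, -10.0])
        _, dt = M.gillespie_step(pop, M.EventRates(import_rate=1.0), rng)
        ages = pop.ages()
        assert pop.now == pytest.approx(dt)
        assert ages.max() == pytest.approx(10.0 + dt)


class TestComputeFluorescence:
    def test_age_zero_gives_zero_totals(self):
        cfg = M.SimConfig()
        y, m, r = M.compute_fluorescence(np.zeros(10), cfg)
        assert y == 0.0 and m == 0.0

    def test_old_population_ratio_saturates_at_one(self):
        cfg = M.SimConfig()
        _, _, r = M.compute_fluorescence(np.full(10, 1e6), cfg)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_uniform_age_closed_form(self):
        cfg = M.SimConfig(sfyfp_halftime_min=15.0, mcherry_halftime_min=40.0)
        a = 25.0
        _, _, r = M.compute_fluorescence(np.full(7, a), cfg)
        expected = (1 - 2 ** (-a / 40.0)) / (1 - 2 ** (-a / 15.0))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_empty_population_is_nan_sentinel(self):
        _, _, r = M.compute_fluorescence(np.array([]), M.SimConfig())
        assert math.isnan(r)

    def test_ratio_monotone_in_uniform_age(self):
        cfg = M.SimConfig()
        ages = np.linspace(1, 300, 60)
        ratios = [M.compute_fluorescence(np.full(5, a), cfg)[2] for a in ages]
        assert np.all(np.diff(ratios) > 0)


class TestRunSimulation:
    def test_zero_duration_yields_single_record(self):
        cfg = M.SimConfig(duration_hr=0.0, n_initial=100)
        tr = M.run_simulation(cfg)
        assert len(tr) == 1
        assert tr.abundance[0] == 100

    def test_deterministic_per_seed(self):
        cfg = M.SimConfig(n_initial=200, duration_hr=0.5, seed=42)
        a = M.run_simulation(cfg)
        b = M.run_simulation(cfg)
        np.testing.assert_array_equal(a.abundance, b.abundance)
        np.testing.assert_array_equal(a.tft_ratio, b.tft_ratio)

    def test_empty_pool_without_import_freezes(self):
        cfg = M.SimConfig(n_initial=0, duration_hr=0.1)
        tr = M.run_simulation(M.SimConfig(n_initial=0, duration_hr=0.1))
        # import continues (rate N0*k_ss = 0), population stays empty
        assert np.all(tr.abundance == 0)

    def test_record_count_matches_duration_and_interval(self):
        cfg = M.SimConfig(n_initial=50, duration_hr=1.0, record_interval_min=5.0)
        tr = M.run_simulation(cfg)
        assert len(tr) == 13

    def test_activated_one_state_decays_toward_import_floor(self):
        cfg = M.SimConfig(n_initial=500, duration_hr=2.0, seed=3)
        tr = M.run_simulation(cfg, perturbed=True)
        k = 2.82 / 60.0
        k_ss = LN2 / 58.0
        floor = 500 * k_ss / k
        theory = floor + (500 - floor) * math.exp(-k * 120.0)
        assert tr.abundance[-1] == pytest.approx(theory, rel=0.25)


class TestEnsemble:
    def test_single_trajectory_summary_is_itself_normalized(self):
        tr = M.run_simulation(M.SimConfig(n_initial=100, duration_hr=0.2, seed=1))
        out = M.ensemble_summarize([tr])
        np.testing.assert_allclose(out.abundance, tr.abundance / tr.abundance[0])

    def test_mean_is_pointwise_average(self):
        cfg = M.SimConfig(n_initial=100, duration_hr=0.2)
        trs = [
            M.run_simulation(cfg, rng=np.random.default_rng(s)) for s in (1, 2)
        ]
        out = M.ensemble_summarize(trs, normalize=False)
        np.testing.assert_allclose(
            out.abundance, (trs[0].abundance + trs[1].abundance) / 2
        )

    def test_mismatched_lengths_rejected(self):
        a = M.run_simulation(M.SimConfig(n_initial=50, duration_hr=0.2))
        b = M.run_simulation(M.SimConfig(n_initial=50, duration_hr=0.4))
        with pytest.raises(ValueError, match="mismatched"):
            M.ensemble_summarize([a, b])

    def test_master_seed_reproduces_ensemble_bitwise(self):
        cfg = M.SimConfig(n_initial=100, duration_hr=0.3, replicates=4, seed=11)
        a = M.ensemble_summarize(M.run_ensemble(cfg))
        b = M.ensemble_summarize(M.run_ensemble(cfg))
        np.testing.assert_array_equal(a.abundance, b.abundance)
        np.testing.assert_array_equal(a.tft_ratio, b.tft_ratio)

    def test_unperturbed_steady_state_age_distribution_holds(self):
        """After 1 hr unperturbed, ages stay exponential with the theory mean."""
        cfg = M.SimConfig(n_initial=1000, duration_hr=1.0, seed=5)
        tr = M.run_simulation(cfg, perturbed=False)
        theory = 58.0 / LN2
        assert tr.mean_age_min[-1] == pytest.approx(theory, rel=0.15)


class TestConfigValidation:
    def test_invalid_regime_rejected(self):
        with pytest.raises(ValueError):
            M.SimConfig(regime="three_state")

    def test_nonpositive_halftimes_rejected(self):
        with pytest.raises(ValueError):
            M.SimConfig(sfyfp_halftime_min=0.0)

    def test_default_k_mat_reproduces_unstable_fraction(self):
        """k_mat default satisfies the steady-state balance for f_u = 0.6."""
        cfg = M.SimConfig(regime="two_state")
        k_ss = cfg.k_ss_per_min
        f_u = k_ss / (cfg.k_mat_per_min + k_ss)
        assert f_u == pytest.approx(0.6, abs=1e-12)

    def test_mature_decay_equals_steady_state_constant(self):
        cfg = M.SimConfig(half_life_min=58.0)
        assert cfg.k_decay2_hr == pytest.approx(60.0 * LN2 / 58.0)
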