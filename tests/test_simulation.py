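"""Gillespie selection, shielding, ODE integration, and diagnostics."""

import numpy as np
import pytest
from scipy import stats

from pegkin.simulation import (KineticParameters, ShieldingState,
                               apply_shielding, diffusion_modifier,
                               pegmer_distribution, reaction_sequence,
                               rfd_ratio, select_site, simulate)


class TestSelectSite:
    def test_cumulative_arithmetic(self):
        rates = {"a": 2.0, "b": 1.0, "c": 1.0}
        assert select_site(rates, 0.4) == "a"   # cumulative 0.5 >= 0.4
        assert select_site(rates, 0.9) == "c"
        assert select_site(rates, 0.5) == "a"   # exact boundary belongs to a
        assert select_site(rates, 0.75) == "b"

    def test_single_site_any_draw(self):
        assert select_site({"only": 3.0}, 0.999) == "only"

    def test_all_nonpositive_raises(self):
        with pytest.raises(ValueError):
            select_site({"a": 0.0, "b": -1.0}, 0.5)

    def test_zero_rate_site_never_selected(self):
        rates = {"a": 0.0, "b": 1.0}
        assert all(select_site(rates, u) == "b" for u in (0.0, 0.5, 0.99))

    def test_empirical_frequencies_match_rates(self):
        rates = {"a": 2.0, "b": 1.0, "c": 1.0, "d": 4.0}
        rng = np.random.default_rng(17)
        draws = rng.random(20_000)
        counts = {k: 0 for k in rates}
        for u in draws:
            counts[select_site(rates, float(u))] += 1
        total = sum(rates.values())
        expected = [len(draws) * r / total for r in rates.values()]
        _chi2, p = stats.chisquare(list(counts.values()), expected)
        assert p > 0.01


class TestApplyShielding:
    def coords(self):
        return {"a": np.zeros(3), "near": np.array([5.0, 0, 0]),
                "far": np.array([20.0, 0, 0])}

    def test_neighbor_inside_radius_blocked(self):
        state = ShieldingState.initial(["a", "near", "far"], 11.0)
        out = apply_shielding(state, "a", self.coords())
        assert out.modified_sites == ["a"]
        assert out.blocked_sites == {"near"}
        assert out.reactive_sites == {"far"}
        out.check_partition({"a", "near", "far"})

    def test_small_radius_blocks_nothing(self):
        state = ShieldingState.initial(["a", "near", "far"], 4.0)
        out = apply_shielding(state, "a", self.coords())
        assert out.blocked_sites == set()
        assert out.reactive_sites == {"near", "far"}

    def test_huge_radius_saturates(self):
        state = ShieldingState.initial(["a", "near", "far"], 100.0)
        out = apply_shielding(state, "a", self.coords())
        assert out.reactive_sites == set()

    def test_non_reactive_choice_raises(self):
        state = ShieldingState.initial(["a", "near"], 11.0)
        out = apply_shielding(state, "a", self.coords())
        with pytest.raises(ValueError):
            apply_shielding(out, "a", self.coords())


class TestReactionSequence:
    def test_far_apart_equal_rates(self, site_factory, linear_model):
        sites = site_factory([8.0, 8.0], [[0, 0, 0], [50, 0, 0]])
        seq, k_avg = reaction_sequence(sites, linear_model, 11.0, seed=0)
        assert len(seq) == 2
        assert k_avg == pytest.approx([8.0, 8.0])

    def test_radius_covering_everything_gives_one_step(self, site_factory, linear_model):
        sites = site_factory([8.0, 8.0, 8.0],
                             [[0, 0, 0], [10, 0, 0], [20, 0, 0]])
        seq, _ = reaction_sequence(sites, linear_model, 100.0, seed=0)
        assert len(seq) == 1

    def test_seeded_replay_is_deterministic(self, site_factory, linear_model):
        sites = site_factory([10.0, 8.0, 6.0, 4.0],
                             [[0, 0, 0], [13, 0, 0], [26, 0, 0], [39, 0, 0]])
        a = reaction_sequence(sites, linear_model, 11.0, seed=42)
        b = reaction_sequence(sites, linear_model, 11.0, seed=42)
        assert a == b

    def test_cutoff_removes_sites_up_front(self, site_factory, linear_model):
        sites = site_factory([10.0, 2.0], [[0, 0, 0], [50, 0, 0]])
        seq, k_avg = reaction_sequence(sites, linear_model, 11.0, seed=0)
        assert seq == ["A:K1"]
        assert k_avg == pytest.approx([10.0])

    def test_no_site_above_cutoff_means_no_reaction(self, site_factory, linear_model):
        sites = site_factory([1.0, 2.0], [[0, 0, 0], [50, 0, 0]])
        assert reaction_sequence(sites, linear_model, 11.0, seed=0) == ([], [])

    def test_neff_nonincreasing_in_radius(self, site_factory, linear_model):
        rng = np.random.default_rng(8)
        n = 6
        ring = [[20 * np.cos(2 * np.pi * i / n), 20 * np.sin(2 * np.pi * i / n), 0]
                for i in range(n)]
        sites = site_factory(list(rng.uniform(5, 15, n)), ring)
        lengths = [len(reaction_sequence(sites, linear_model, r, seed=5)[0])
                   for r in (1.0, 8.0, 15.0, 25.0, 45.0)]
        assert lengths == sorted(lengths, reverse=True)
        assert lengths[0] == n  # radius below the minimum spacing blocks nothing


class TestDiffusionModifier:
    def test_first_step_unmodified(self):
        params = KineticParameters(kappa=5.0, shield_radius=30.0)
        assert diffusion_modifier(1, params) == 1.0

    def test_zero_kappa_is_identity(self):
        params = KineticParameters(kappa=0.0, shield_radius=30.0)
        assert all(diffusion_modifier(j, params) == 1.0 for j in range(1, 6))

    def test_covered_area_form(self):
        params = KineticParameters(kappa=2.8e-3, shield_radius=11.0)
        assert diffusion_modifier(2, params) == pytest.approx(
            np.exp(-2.8e-3 * np.pi * 121.0), rel=1e-12)
        assert diffusion_modifier(2, params) == pytest.approx(0.345, abs=5e-4)

    def test_pluggable_strategy(self):
        params = KineticParameters(kappa=1.0, shield_radius=10.0)
        assert diffusion_modifier(3, params, lambda j, p: 1.0 / j) == pytest.approx(1 / 3)

    def test_invalid_step_raises(self):
        with pytest.raises(ValueError):
            diffusion_modifier(0, KineticParameters())


class TestSimulate:
    def params(self, **kw):
        defaults = dict(k_d=0.21, kappa=2.8e-3, epsilon=100.0,
                        shield_radius=11.0, protein0=1e-5, peg0=1e-3)
        defaults.update(kw)
        return KineticParameters(**defaults)

    def test_hydrolysis_only_matches_exponential(self):
        params = self.params()
        half_life = np.log(2) / 0.21
        result = simulate(params, [], np.linspace(0, 4 * half_life, 60))
        expected = params.peg0 * np.exp(-0.21 * result.times)
        np.testing.assert_allclose(result.peg_conc, expected, rtol=1e-6)
        assert float(result._dense(half_life)[1]) / params.peg0 == pytest.approx(0.5, rel=1e-6)

    def test_zero_prefactor_keeps_protein_native(self):
        params = self.params(epsilon=0.0)
        result = simulate(params, [10.0, 8.0], np.linspace(0, 60, 30))
        np.testing.assert_allclose(result.pegmer_conc[0], params.protein0, rtol=1e-9)
        np.testing.assert_allclose(result.pegmer_conc[1:], 0.0, atol=1e-20)

    def test_conservation_invariants(self):
        params = self.params()
        result = simulate(params, [10.0, 8.0, 6.0], np.linspace(0, 120, 50))
        protein_total = result.pegmer_conc.sum(axis=0)
        np.testing.assert_allclose(protein_total, params.protein0, rtol=1e-6)
        j = np.arange(result.pegmer_conc.shape[0])[:, None]
        peg_total = (result.peg_conc + result.peg_hydrolyzed
                     + (j * result.pegmer_conc).sum(axis=0))
        np.testing.assert_allclose(peg_total, params.peg0, rtol=1e-6)
        assert np.all(result.pegmer_conc >= -1e-12)

    def test_single_site_matches_euler_oracle(self):
        params = self.params(k_d=0.01, epsilon=25.0)
        k = [8.0]
        t_grid = np.linspace(0, 20, 21)
        result = simulate(params, k, t_grid)
        # brute-force explicit Euler at fine step (first-order error ~ rate²·t·dt/2 ≪ 1e-4)
        dt = 2e-5
        p0, p1, peg = params.protein0, 0.0, params.peg0
        keff = params.epsilon * k[0]
        traj = [p0]
        checkpoints = iter(t_grid[1:])
        nxt = next(checkpoints)
        t = 0.0
        while True:
            r = keff * peg * p0
            p0 -= dt * r
            p1 += dt * r
            peg -= dt * (params.k_d * peg + r)
            t += dt
            if t >= nxt - dt / 2:
                traj.append(p0)
                try:
                    nxt = next(checkpoints)
                except StopIteration:
                    break
        np.testing.assert_allclose(result.pegmer_conc[0], traj, rtol=1e-4)

    def test_pseudo_first_order_limit(self):
        # protein ≪ reagent: P0(t) = protein0·exp(-ε·k·(peg0/k_d)(1-e^{-k_d t}))
        params = self.params(protein0=1e-8, peg0=1e-3, epsilon=20.0, k_d=0.05)
        k = [5.0]
        t_grid = np.linspace(0, 30, 40)
        result = simulate(params, k, t_grid)
        lam = params.epsilon * k[0] * params.peg0 / params.k_d
        expected = params.protein0 * np.exp(-lam * (1 - np.exp(-params.k_d * t_grid)))
        np.testing.assert_allclose(result.pegmer_conc[0], expected, rtol=0.01)

    def test_kappa_monotonically_reduces_peg_incorporation(self):
        t_grid = np.linspace(0, 120, 40)
        totals = []
        for kappa in (0.0, 1e-3, 3e-3, 1e-2):
            result = simulate(self.params(kappa=kappa), [10.0, 8.0, 6.0], t_grid)
            j = np.arange(result.pegmer_conc.shape[0])
            totals.append(float(j @ result.pegmer_conc[:, -1]))
        assert totals == sorted(totals, reverse=True)

    def test_bad_time_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate(self.params(), [5.0], np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            simulate(self.params(), [5.0, -1.0], np.linspace(0, 10, 5))


class TestPegmerDistribution:
    def result(self):
        params = KineticParameters(k_d=0.01, kappa=1e-3, epsilon=100.0,
                                   shield_radius=11.0, protein0=1e-5, peg0=1e-3)
        return simulate(params, [10.0, 6.0], np.linspace(0, 90, 40))

    def test_starts_all_native(self):
        dist = pegmer_distribution(self.result(), 0.0)
        assert dist.tolist() == pytest.approx([1.0, 0.0, 0.0])

    def test_sums_to_one_everywhere(self):
        result = self.result()
        for t in (0.0, 7.3, 30.0, 89.9):
            assert pegmer_distribution(result, t).sum() == pytest.approx(1.0, abs=1e-9)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            pegmer_distribution(self.result(), 91.0)

    def test_dominant_first_step_gives_mostly_monopeg(self):
        # one fast step then strongly attenuated second step
        params = KineticParameters(k_d=0.21, kappa=6e-3, epsilon=300.0,
                                   shield_radius=20.0, protein0=1e-5, peg0=1e-3)
        result = simulate(params, [10.0, 10.0], np.linspace(0, 120, 60))
        dist = pegmer_distribution(result, 120.0)
        assert dist[1] > dist[2]


class TestRfdRatio:
    def coords(self, d=40.0):
        return {"a": np.zeros(3), "b": np.array([d, 0, 0]), "c": np.array([0, d, 0])}

    def test_doubling_mw_scales_by_two_to_three_fifths(self):
        r5, _ = rfd_ratio(["a", "b", "c"], self.coords(), 5.0)
        r10, _ = rfd_ratio(["a", "b", "c"], self.coords(), 10.0)
        assert r10 / r5 == pytest.approx(2 ** 0.6, rel=1e-12)

    def test_threshold_classification(self):
        # scale the graft spacing so the ratio brackets the brush threshold
        r, conf = rfd_ratio(["a", "b", "c"], self.coords(), 5.0)
        d_at_2 = 40.0 * r / 2.0
        just_brush = rfd_ratio(["a", "b", "c"], self.coords(d_at_2 * 0.999), 5.0)
        just_dumbbell = rfd_ratio(["a", "b", "c"], self.coords(d_at_2 * 1.001), 5.0)
        assert just_brush[1] == "brush" and just_brush[0] > 2
        assert just_dumbbell[1] == "dumbbell" and just_dumbbell[0] < 2

    def test_distant_grafts_are_dumbbell(self):
        ratio, conf = rfd_ratio(["a", "b"], {"a": np.zeros(3),
                                             "b": np.array([1000.0, 0, 0])}, 5.0)
        assert ratio < 1 and conf == "dumbbell"

    def test_fewer_than_two_grafts_raises(self):
        with pytest.raises(ValueError):
            rfd_ratio(["a"], {"a": np.zeros(3)}, 5.0)


class TestStochasticEnvelope:
    def test_different_seeds_produce_envelope_identical_seeds_identical(
            self, site_factory, linear_model):
        sites = site_factory([12.0, 9.0, 7.0, 5.0],
                             [[0, 0, 0], [13, 0, 0], [26, 0, 0], [39, 0, 0]])
        params = KineticParameters(k_d=0.01, kappa=2.8e-3, epsilon=100.0,
                                   shield_radius=14.0, protein0=1e-5, peg0=2e-4)
        t_grid = np.linspace(0, 60, 30)

        def run(seed):
            seq, k_avg = reaction_sequence(sites, linear_model,
                                           params.shield_radius, seed=seed)
            return simulate(params, k_avg, t_grid).pegmer_conc

        replicates = [run(seed) for seed in range(6)]
        np.testing.assert_array_equal(run(3), run(3))
        spread = np.ptp([r[0, -1] for r in replicates])
        assert spread > 0  # stochastic site order changes the trajectories
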