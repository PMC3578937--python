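"""Coalescent simulator: closed forms, demography, msprime cross-check."""

import numpy as np
import pytest

from sweepvalley.coalsim import (
    DemographicModel,
    ModelError,
    Schedule,
    calibrate_thresholds,
    simulate,
)
from sweepvalley.popgen_stats import stat_constants


def _const_pop(N, mu, r=0.0):
    return Schedule(["P"], {"P": [(0.0, float(N))]}, [], mu=mu, r=r)


class TestClosedForms:
    def test_pairwise_diversity_matches_theta(self):
        # E[pi per site] = 4 N mu for n = 2
        N, mu, L = 1e4, 1e-7, 1000
        sched = _const_pop(N, mu)
        pi = [simulate(sched, {"P": 2}, L, seed=s, recombination=False
                       ).pop_pi_total("P") for s in range(3000)]
        expect = 4 * N * mu * L
        se = np.std(pi, ddof=1) / np.sqrt(len(pi))
        assert abs(np.mean(pi) - expect) < 3 * se

    def test_segregating_sites_match_watterson(self):
        # E[S] = 4 N mu L a1(n)
        N, mu, L, n = 1e4, 1e-7, 1000, 12
        sched = _const_pop(N, mu)
        S = [simulate(sched, {"P": n}, L, seed=s, recombination=False).S
             for s in range(2000)]
        expect = 4 * N * mu * L * stat_constants(n).a1
        se = np.std(S, ddof=1) / np.sqrt(len(S))
        assert abs(np.mean(S) - expect) < 3 * se

    def test_recombination_leaves_mean_S_unchanged(self):
        # E[S] does not depend on r; checks the SMC' pass against the
        # single-genealogy path
        N, mu, L, n = 1e4, 2e-7, 2000, 6
        s_norec = [simulate(_const_pop(N, mu), {"P": n}, L, seed=s,
                            recombination=False).S for s in range(400)]
        s_rec = [simulate(_const_pop(N, mu, r=5e-7), {"P": n}, L, seed=s).S
                 for s in range(400)]
        se = np.sqrt(np.var(s_norec, ddof=1) / 400 + np.var(s_rec, ddof=1) / 400)
        assert abs(np.mean(s_norec) - np.mean(s_rec)) < 3 * se

    def test_two_population_split_divergence(self):
        # after a clean split T generations ago with tiny N, the mean
        # between-population pairwise difference exceeds the within one
        # by ~ 2 mu T per site
        N, T, mu, L = 1000.0, 200_000.0, 1e-7, 500
        sched = Schedule(["A", "B"],
                         {"A": [(0.0, N)], "B": [(0.0, N)]},
                         [(T, "B", "A")], mu=mu, r=0.0)
        between, within = [], []
        for s in range(800):
            rep = simulate(sched, {"A": 2, "B": 2}, L, seed=s,
                           recombination=False)
            ha, hb = rep.haplotypes["A"], rep.haplotypes["B"]
            between.append(np.mean([np.sum(ha[i] != hb[j])
                                    for i in range(2) for j in range(2)]))
            within.append(0.5 * (np.sum(ha[0] != ha[1]) + np.sum(hb[0] != hb[1])))
        gap = np.mean(between) - np.mean(within)
        expect = 2 * mu * T * L
        se = np.std(np.array(between) - np.array(within), ddof=1) / np.sqrt(800)
        assert abs(gap - expect) < 3 * se

    def test_doubling_mu_doubles_mean_S(self):
        N, L, n = 1e4, 1000, 8
        s1 = np.mean([simulate(_const_pop(N, 1e-7), {"P": n}, L, seed=s,
                               recombination=False).S for s in range(1500)])
        s2 = np.mean([simulate(_const_pop(N, 2e-7), {"P": n}, L, seed=s,
                               recombination=False).S for s in range(1500)])
        assert s2 / s1 == pytest.approx(2.0, rel=0.1)


class TestReproducibilityAndValidation:
    def test_identical_seed_identical_replicate(self, model):
        a = simulate(model, {"EU": 6, "AF": 4}, 3000, seed=123)
        b = simulate(model, {"EU": 6, "AF": 4}, 3000, seed=123)
        assert np.array_equal(a.positions, b.positions)
        for p in a.haplotypes:
            assert np.array_equal(a.haplotypes[p], b.haplotypes[p])

    def test_distinct_seeds_differ(self, model):
        a = simulate(model, {"EU": 6}, 3000, seed=1)
        b = simulate(model, {"EU": 6}, 3000, seed=2)
        assert a.S != b.S or not np.array_equal(a.positions, b.positions)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ModelError):
            DemographicModel(N_eur_cur=-5)
        with pytest.raises(ModelError):
            DemographicModel(T_exit=1000, T_asia=2000)
        with pytest.raises(ModelError):
            simulate(DemographicModel(), {"EU": 1}, 100, seed=0)
        with pytest.raises(ModelError):
            simulate(DemographicModel(), {"XX": 4}, 100, seed=0)

    def test_positions_within_bounds_and_unique(self, model):
        rep = simulate(model, {"EU": 12}, 5000, seed=9)
        assert rep.positions.min() >= 1
        assert rep.positions.max() <= rep.L
        assert len(np.unique(rep.positions)) == rep.S


class TestAgainstMsprime:
    """Independent oracle: the same demography in msprime."""

    @staticmethod
    def _msprime_demography(m: DemographicModel):
        import msprime

        g = m.gen_per_year
        dem = msprime.Demography()
        dem.add_population(name="AF", initial_size=m.N_afr_cur)
        dem.add_population(name="EU", initial_size=m.N_eur_cur)
        dem.add_population(name="AS", initial_size=m.N_asia_cur)
        dem.add_population_parameters_change(time=m.T_asia * g / 2,
                                             population="AS",
                                             initial_size=m.N_asia_bot)
        dem.add_population_parameters_change(time=m.T_exit * g / 2,
                                             population="EU",
                                             initial_size=m.N_eur_bot)
        dem.add_population_parameters_change(time=m.T_afr_exp * g,
                                             population="AF",
                                             initial_size=m.N_afr_anc)
        dem.add_population_split(time=m.T_asia * g, derived=["AS"],
                                 ancestral="EU")
        dem.add_population_split(time=m.T_exit * g, derived=["EU"],
                                 ancestral="AF")
        dem.sort_events()
        return dem

    def test_fragment_means_match(self, model):
        import msprime

        reps, L = 250, 500
        samples = {"AF": 12, "EU": 12, "AS": 12}
        mine = {p: [] for p in samples}
        pi_mine = {p: [] for p in samples}
        for s in range(reps):
            rep = simulate(model, samples, L, seed=50_000 + s,
                           recombination=False)
            for p in samples:
                mine[p].append(rep.pop_segregating(p))
                pi_mine[p].append(rep.pop_pi_total(p))

        dem = self._msprime_demography(model)
        theirs = {p: [] for p in samples}
        pi_theirs = {p: [] for p in samples}
        it = msprime.sim_ancestry(
            samples=[msprime.SampleSet(n, population=p, ploidy=1)
                     for p, n in samples.items()],
            demography=dem, sequence_length=L, recombination_rate=0,
            num_replicates=reps, random_seed=4242)
        for i, ts in enumerate(it):
            # infinite-sites mutations: matches the simulator's model
            mts = msprime.sim_mutations(ts, rate=model.mu,
                                        random_seed=1000 + i,
                                        discrete_genome=False)
            G = mts.genotype_matrix().T  # (samples, sites)
            row = 0
            for p, n in samples.items():
                h = np.minimum(G[row:row + n], 1)
                k = h.sum(axis=0)
                theirs[p].append(int(np.sum((k > 0) & (k < n))))
                pi_theirs[p].append(float(np.sum(2 * k * (n - k)) /
                                          (n * (n - 1))))
                row += n

        for p in samples:
            a, b = np.asarray(mine[p], float), np.asarray(theirs[p], float)
            se = np.sqrt(a.var(ddof=1) / reps + b.var(ddof=1) / reps)
            assert abs(a.mean() - b.mean()) < 3.5 * se + 1e-9, \
                f"S mismatch for {p}: {a.mean():.2f} vs {b.mean():.2f}"
            a, b = np.asarray(pi_mine[p], float), np.asarray(pi_theirs[p], float)
            se = np.sqrt(a.var(ddof=1) / reps + b.var(ddof=1) / reps)
            assert abs(a.mean() - b.mean()) < 3.5 * se + 1e-9, \
                f"pi mismatch for {p}"


class TestBottleneckEffects:
    def test_bottleneck_drives_fragment_monomorphism(self, model):
        # fitted model: European fragments are often monomorphic;
        # without the bottleneck (N_eur_bot = N_afr_cur) they are not
        mono_fit = mono_flat = 0
        flat = model.with_params(N_eur_bot=model.N_afr_cur,
                                 N_eur_cur=model.N_afr_cur)
        for s in range(150):
            rep = simulate(model, {"EU": 12}, 500, seed=s,
                           recombination=False)
            mono_fit += rep.pop_segregating("EU") == 0
            rep = simulate(flat, {"EU": 12}, 500, seed=s,
                           recombination=False)
            mono_flat += rep.pop_segregating("EU") == 0
        assert mono_fit > 0
        assert mono_flat == 0


class TestCalibration:
    def test_constant_statistic_threshold(self, model):
        thr, null = calibrate_thresholds(
            model, {"EU": 4}, 200, {"c": lambda rep: 3.5}, reps=100, seed=0,
            recombination=False)
        assert thr["c"] == 3.5
        assert np.all(null["c"] == 3.5)

    def test_thresholds_nondecreasing_in_q(self, model):
        stats = {"s": lambda rep: float(rep.S)}
        t50, _ = calibrate_thresholds(model, {"EU": 6}, 500, stats, reps=120,
                                      q=0.5, seed=3, recombination=False)
        t95, _ = calibrate_thresholds(model, {"EU": 6}, 500, stats, reps=120,
                                      q=0.95, seed=3, recombination=False)
        assert t95["s"] >= t50["s"]

    def test_undefined_statistic_counts_as_zero(self, model):
        def bad(rep):
            return float("nan")
        thr, null = calibrate_thresholds(model, {"EU": 4}, 200, {"b": bad},
                                         reps=100, seed=1, recombination=False)
        assert thr["b"] == 0.0
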