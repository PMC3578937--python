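"""Summary statistics: theta_W, pi, Tajima's D, windows, SFS, tests."""

import numpy as np
import pytest

from sweepvalley.alignment_io import OUTGROUP, RegionAlignment, classify_sites
from sweepvalley.popgen_stats import (
    SFS,
    binomial_cluster_test,
    divergence,
    nucleotide_diversity,
    segregating_sites,
    sfs_from_table,
    sliding_windows,
    stat_constants,
    tajimas_d,
    watterson_theta,
    wilcoxon_window_test,
    _window_bounds,
)
from sweepvalley.synthetic_data import table2_fixture


def _table(seq_by_pop: dict[str, list[str]]):
    seqs, labels, pops = [], [], []
    for pop, ss in seq_by_pop.items():
        for i, s in enumerate(ss):
            seqs.append(s)
            labels.append(f"{pop}{i}")
            pops.append(pop)
    return classify_sites(RegionAlignment(seqs, labels, pops))


class TestWatterson:
    @pytest.mark.parametrize("S,n,L,expect", [
        (0, 12, 1000, 0.0),
        (5, 2, 100, 0.05),           # a1(2) = 1
        (20, 12, 1000, 0.0066228),   # a1(12) = 3.019877...
    ])
    def test_values(self, S, n, L, expect):
        assert watterson_theta(S, n, L) == pytest.approx(expect, abs=5e-8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            watterson_theta(1, 1, 100)
        with pytest.raises(ValueError):
            watterson_theta(1, 4, 0)


class TestPi:
    def test_monomorphic_is_zero(self):
        t = _table({"p": ["AAAA", "AAAA"]})
        assert nucleotide_diversity(t, "p", 4) == 0.0

    def test_single_pair_single_site(self):
        t = _table({"p": ["A", "T"]})
        assert nucleotide_diversity(t, "p", 1) == pytest.approx(1.0)

    def test_two_sites_n4_enumerated_pairs(self):
        # derived counts 1 and 2 among n=4; all 6 pairs enumerated by hand
        t = _table({"p": ["AA", "AC", "GC", "AA"]})
        assert nucleotide_diversity(t, "p", 100) == pytest.approx(0.0116667, abs=1e-7)


class TestTajimasD:
    def test_zero_when_pi_equals_watterson_expectation(self):
        a1 = stat_constants(10).a1
        assert tajimas_d(7, 7 / a1, 10) == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_exact_arithmetic_oracle(self):
        # n=12, S=10, pi_total=2.0 evaluated with Fraction arithmetic
        assert tajimas_d(10, 2.0, 12) == pytest.approx(-1.6292648153208884,
                                                       rel=1e-9)

    def test_undefined_at_zero_segregating_sites(self):
        assert tajimas_d(0, 0.0, 12) is None


class TestSlidingWindows:
    def test_window_bounds_enumeration(self):
        assert _window_bounds(2000, 1000, 500) == [(1, 1000), (501, 1500),
                                                   (1001, 2000)]

    def test_single_window_when_region_fits(self):
        assert _window_bounds(1000, 1000, 500) == [(1, 1000)]
        assert _window_bounds(600, 1000, 500) == [(1, 600)]

    def test_short_tail_merges_into_previous(self):
        # tail of 300 < 500 merges; tail of 800 >= 500 stays
        assert _window_bounds(1300, 1000, 500)[-1] == (501, 1300)
        assert _window_bounds(1800, 1000, 500)[-1] == (1001, 1800)

    def test_window_theta_matches_whole_region(self):
        rng = np.random.default_rng(4)
        L = 2000
        base = rng.choice(list("ACGT"), L)
        seqs = []
        for _ in range(6):
            s = base.copy()
            mut = rng.random(L) < 0.02
            s[mut] = rng.choice(list("ACGT"), int(mut.sum()))
            seqs.append("".join(s))
        t = _table({"p": seqs})
        ws = sliding_windows(t, "p", 1000, 500)
        S_whole = segregating_sites(t, "p")
        assert ws[0].S + ws[2].S == S_whole  # non-overlapping windows tile L
        for w in ws:
            assert w.theta_w == pytest.approx(
                watterson_theta(w.S, 6, w.n_sites))


class TestSFS:
    def test_all_ancestral_sites_fall_in_class_zero(self):
        t = _table({"p1": ["A" * 100] * 4, "p2": ["A" * 100] * 4,
                    OUTGROUP: ["A" * 100]})
        sfs = sfs_from_table(t, "p1")
        assert sfs.counts[0] == 100
        assert sfs.counts[1:].sum() == 0

    def test_fixture_fixed_derived_sites_fill_class_n(self):
        table = classify_sites(table2_fixture())
        sfs = sfs_from_table(table, "EU", include_invariant=True)
        assert sfs.counts[12] == 8   # derived-private fixed differences
        # conservation: every classified (non-indel) column is counted
        assert sfs.counts.sum() == table.L - 1  # one indel column excluded

    def test_invariant_classes_droppable(self):
        table = classify_sites(table2_fixture())
        sfs = sfs_from_table(table, "EU", include_invariant=False)
        assert sfs.counts[0] == 0 and sfs.counts[-1] == 0


class TestWilcoxon:
    def test_identical_singletons_give_p_one(self):
        _, p = wilcoxon_window_test([1.0], [1.0])
        assert p == 1.0

    def test_disjoint_triples_exact_two_sided(self):
        _, p = wilcoxon_window_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(300):
            x, y = rng.normal(size=12), rng.normal(size=30)
            ps.append(wilcoxon_window_test(x, y)[1])
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_window_test([], [1.0])


class TestBinomialClusterTest:
    def test_printed_value_for_eight_of_eight(self):
        assert binomial_cluster_test(8, 8, 0.5) == pytest.approx(0.00390625,
                                                                 abs=0)

    def test_full_segment_always_one(self):
        for obs in range(6):
            assert binomial_cluster_test(5, obs, 1.0) == pytest.approx(1.0)

    def test_single_trial(self):
        assert binomial_cluster_test(1, 1, 0.25) == pytest.approx(0.25)

    @pytest.mark.parametrize("m", [1, 3, 8, 20])
    def test_all_in_half_segment_is_two_to_minus_m(self, m):
        assert binomial_cluster_test(m, m, 0.5) == pytest.approx(2.0 ** -m,
                                                                 rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            binomial_cluster_test(5, 6, 0.5)
        with pytest.raises(ValueError):
            binomial_cluster_test(5, 2, 0.0)


class TestDivergence:
    def test_identical_outgroup_gives_zero(self):
        t = _table({"p": ["ACGT" * 5] * 3, OUTGROUP: ["ACGT" * 5]})
        assert divergence(t, "p") == 0.0

    def test_six_of_hundred_differences(self):
        ingroup = "A" * 100
        out = "G" * 6 + "A" * 94
        t = _table({"p": [ingroup] * 4, OUTGROUP: [out]})
        assert divergence(t, "p") == pytest.approx(0.06)

    def test_missing_outgroup_rejected(self):
        t = _table({"p": ["ACGT"] * 3})
        with pytest.raises(ValueError):
            divergence(t, "p")


class TestSFSContainer:
    def test_normalize_and_validation(self):
        s = SFS(4, [2, 1, 1, 0, 0]).normalize()
        assert s.counts.sum() == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            SFS(4, [1, 2, 3])
        with pytest.raises(ValueError):
            SFS(4, [-1, 0, 0, 0, 0])
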