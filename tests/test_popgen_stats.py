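import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beringia import popgen_stats as ps
from beringia.errors import InputError, SaturationError, StatisticError
from beringia.io_manifest import DemeAlignment, encode_sequence

from conftest import make_pair, random_sequences


def mat(*seqs):
    return np.stack([encode_sequence(s) for s in seqs])


class TestMeanPairwiseP:
    def test_identical_within_set(self):
        p, _ = ps.mean_pairwise_p(mat("AAAA", "AAAA"))
        assert p == 0.0

    def test_cross_set_half_diverged(self):
        p, eff = ps.mean_pairwise_p(mat("AAAA"), mat("AATT"))
        assert p == 0.5
        assert eff == 4

    def test_pairwise_deletion_drops_missing_sites(self):
        p, eff = ps.mean_pairwise_p(mat("AANA"), mat("AATA"))
        assert p == 0.0
        assert eff == 3

    def test_gap_treated_like_n(self):
        p_gap, _ = ps.mean_pairwise_p(mat("AA-A"), mat("AATA"))
        p_n, _ = ps.mean_pairwise_p(mat("AANA"), mat("AATA"))
        assert p_gap == p_n == 0.0

    def test_single_sequence_within_errors(self):
        with pytest.raises(StatisticError):
            ps.mean_pairwise_p(mat("ACGT"))

    def test_all_pairs_incomparable_errors(self):
        with pytest.raises(StatisticError):
            ps.mean_pairwise_p(mat("NNNN"), mat("ACGT"))


class TestJukesCantor:
    def test_zero_distance_any_shape(self):
        assert ps.jc_distance(0.0) == 0.0
        assert ps.jc_distance(0.0, gamma_shape=0.5) == 0.0

    def test_plain_closed_form(self):
        assert ps.jc_distance(0.05) == pytest.approx(
            -0.75 * math.log(1 - 4 * 0.05 / 3), abs=1e-15
        )
        assert ps.jc_distance(0.05) == pytest.approx(0.051744653, abs=1e-9)

    def test_gamma_shape_one_closed_form(self):
        # with a = 1 the correction reduces to (3/4)(1/(1-4p/3) - 1)
        assert ps.jc_distance(0.05, 1.0) == pytest.approx(
            0.75 * (1 / (1 - 4 * 0.05 / 3) - 1), abs=1e-15
        )
        assert ps.jc_distance(0.05, 1.0) == pytest.approx(0.053571428, abs=1e-9)

    def test_saturation_error(self):
        with pytest.raises(SaturationError):
            ps.jc_distance(0.80)

    def test_bad_shape(self):
        with pytest.raises(InputError):
            ps.jc_distance(0.1, gamma_shape=0.0)

    @given(st.floats(min_value=1e-6, max_value=0.74))
    @settings(deadline=None, derandomize=True)
    def test_correction_dominates_p_and_gamma_dominates_plain(self, p):
        d = ps.jc_distance(p)
        assert d >= p
        assert ps.jc_distance(p, gamma_shape=1.0) >= d

    def test_monotone_in_p(self):
        grid = np.linspace(0.001, 0.74, 200)
        vals = [ps.jc_distance(p) for p in grid]
        assert np.all(np.diff(vals) > 0)


class TestDiversityAndNetDivergence:
    def test_identical_sequences_zero(self):
        d = DemeAlignment("OW", [("a", "ACGT"), ("b", "ACGT")])
        assert ps.nucleotide_diversity(d) == 0.0

    def test_three_sequence_brute_force_value(self):
        # pairs: (AAAA,AATT)=0.5, (AAAA,AAAA)=0, (AATT,AAAA)=0.5 -> 1/3
        assert ps.nucleotide_diversity(mat("AAAA", "AATT", "AAAA")) == pytest.approx(1 / 3)

    def test_single_sequence_errors(self):
        with pytest.raises(StatisticError):
            ps.nucleotide_diversity(mat("ACGT"))

    def test_monomorphic_demes_fixed_differences(self):
        pair = make_pair(["AAAA", "AAAA"], ["AATA", "AATA"])
        pi_b, d_a = ps.net_divergence(pair)
        assert pi_b == pytest.approx(0.25)
        assert d_a == pytest.approx(0.25)

    def test_same_composition_nonpositive_net(self):
        # identical deme compositions: within-π (distinct pairs only) exceeds
        # between-π (which counts identical cross pairs), so D_A ≤ 0; exact
        # zero holds only in expectation over label-exchangeable sampling
        pair = make_pair(["AAAA", "AATT"], ["AAAA", "AATT"])
        pi_b, d_a = ps.net_divergence(pair)
        assert d_a <= 0.0
        assert pi_b == pytest.approx(0.25)
        assert d_a == pytest.approx(0.25 - 0.5)

    def test_cross_pair_enumeration(self):
        # cross pairs: (AAAA,TTAA)=0.5, (AATA,TTAA)=0.75 -> mean 0.625
        pair = make_pair(["AAAA", "AATA"], ["TTAA"])
        pi_b, d_a = ps.net_divergence(pair)
        assert pi_b == pytest.approx((0.5 + 0.75) / 2)
        assert d_a == pytest.approx(0.625 - (0.25 + 0.0) / 2)

    def test_net_never_exceeds_between(self, rng):
        for _ in range(25):
            pair = make_pair(
                random_sequences(rng, 4, 30, 0.1), random_sequences(rng, 3, 30, 0.1)
            )
            pi_b, d_a = ps.net_divergence(pair)
            assert d_a <= pi_b + 1e-12

    def test_corrected_variant_dominates_raw(self, rng):
        # closely related sequences (random pairs would saturate the correction)
        base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])

        def mutate(s, k):
            s = list(s)
            for pos in rng.choice(60, size=k, replace=False):
                s[pos] = "ACGT"[(("ACGT".index(s[pos])) + 1) % 4]
            return "".join(s)

        pair = make_pair([base, mutate(base, 2)], [mutate(base, 5), mutate(base, 6)])
        raw_b, _ = ps.net_divergence(pair)
        cor_b, _ = ps.net_divergence(pair, corrected=True)
        assert cor_b >= raw_b


class TestSfsStats:
    def test_monomorphic(self):
        theta, d = ps.sfs_stats(mat("AAAA", "AAAA", "AAAA"))
        assert theta == 0.0
        assert d is None

    def test_two_sequences_theta_equals_pi(self):
        m = mat("AAAATT", "AATATT")
        theta, d = ps.sfs_stats(m)
        assert theta == pytest.approx(ps.nucleotide_diversity(m))
        assert d is None  # variance normalization degenerates at n = 2

    def test_textbook_value(self):
        # 4 sequences, 100 bp, 3 segregating sites
        base = "A" * 100
        seqs = [base, "T" + base[1:], base[:50] + "C" + base[51:], base[:99] + "G"]
        theta, d = ps.sfs_stats(mat(*seqs))
        a1 = 1 + 1 / 2 + 1 / 3
        assert theta == pytest.approx(3 / (100 * a1))
        assert d is not None


class TestHudsonFst:
    def test_fixed_difference_is_one(self):
        pair = make_pair(["AAAA", "AAAA"], ["TTTT", "TTTT"])
        assert ps.hudson_fst(pair) == pytest.approx(1.0)

    def test_identical_demes_nonpositive(self):
        # brute force over the 4 cross pairs (mean 0.25) and 2 within pairs
        # (mean 0.5 each): F_ST = 1 − 0.5/0.25 = −1 for literally identical
        # compositions; zero is the expectation under label exchange only
        pair = make_pair(["AA", "AT"], ["AA", "AT"])
        assert ps.hudson_fst(pair) == pytest.approx(-1.0)

    def test_negative_values_are_legal(self):
        # more diversity within than between
        pair = make_pair(["AAAA", "TTTT"], ["AATT", "TTAA"])
        fst = ps.hudson_fst(pair)
        assert fst is not None and fst < 0

    def test_undefined_when_everything_identical(self):
        pair = make_pair(["AAAA", "AAAA"], ["AAAA", "AAAA"])
        assert ps.hudson_fst(pair) is None


class TestFstPermutation:
    def test_seed_determinism_and_range(self):
        seqs_a = ["AAAA", "AAAA", "AAAA"]
        seqs_b = ["AAAT", "AAAA", "AAAA"]
        pair = make_pair(seqs_a, seqs_b)
        p1 = ps.fst_permutation_test(pair, n_permutations=1000, seed=5)
        p2 = ps.fst_permutation_test(pair, n_permutations=1000, seed=5)
        assert p1 == p2
        assert 0.0 <= p1 <= 1.0

    def test_fixed_difference_five_v_five_small_p(self):
        pair = make_pair(["A" * 20] * 5, ["T" * 20] * 5)
        p = ps.fst_permutation_test(pair, n_permutations=10_000, seed=1)
        # only the 2 label assignments reproducing the split reach F_ST = 1:
        # exact p = 2 / C(10,5) = 0.0079
        assert p <= 0.05

    def test_three_v_three_exact_enumeration(self):
        # fixed difference, 3v3: F_ST = 1 occurs for exactly 2 of the
        # C(6,3) = 20 deme-size-preserving partitions -> exact p = 0.1
        pair = make_pair(["AC", "AC", "AC"], ["TG", "TG", "TG"])
        p = ps.fst_permutation_test(pair, n_permutations=40_000, seed=3)
        assert p == pytest.approx(2 / 20, abs=0.008)

    def test_plus_one_convention(self):
        pair = make_pair(["A" * 8] * 3, ["T" * 8] * 3)
        p = ps.fst_permutation_test(pair, n_permutations=100, seed=2, plus_one=True)
        assert p >= 1 / 101

    def test_undefined_observed_gives_none(self):
        pair = make_pair(["AAAA"] * 2, ["AAAA"] * 2)
        assert ps.fst_permutation_test(pair, n_permutations=10, seed=0) is None

    def test_null_pvalues_uniform(self, rng):
        # label-exchangeable data: p-values approximately U(0,1)
        from scipy.stats import kstest

        pvals = []
        for _ in range(500):
            pooled = random_sequences(rng, 12, 30)
            pair = make_pair(pooled[:6], pooled[6:])
            pvals.append(
                ps.fst_permutation_test(pair, n_permutations=200, seed=int(rng.integers(2**31)))
            )
        stat = kstest(pvals, "uniform")
        assert stat.pvalue > 0.01


class TestBhFdr:
    def test_all_tiny_p_rejected(self):
        assert ps.bh_fdr([0.001] * 10, q=0.05) == [True] * 10

    def test_step_up_hand_example(self):
        # thresholds 0.0167/0.0333/0.05: only 0.01 survives
        assert ps.bh_fdr([0.01, 0.04, 0.20], q=0.05) == [True, False, False]

    def test_single_large_p(self):
        assert ps.bh_fdr([0.9], q=0.05) == [False]

    def test_empty(self):
        assert ps.bh_fdr([], q=0.05) == []

    def test_out_of_range_p_errors(self):
        with pytest.raises(InputError):
            ps.bh_fdr([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30),
        st.floats(min_value=0.01, max_value=0.2),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_step_up_oracle_and_bonferroni_domination(self, pvals, q):
        rejected = ps.bh_fdr(pvals, q=q)
        m = len(pvals)
        # independent step-up evaluation
        order = sorted(range(m), key=lambda i: pvals[i])
        k_max = 0
        for rank, idx in enumerate(order, start=1):
            if pvals[idx] <= rank * q / m:
                k_max = rank
        expected = [False] * m
        for rank, idx in enumerate(order, start=1):
            if rank <= k_max:
                expected[idx] = True
        assert rejected == expected
        # BH rejects at least everything Bonferroni rejects, nothing above q
        for p, r in zip(pvals, rejected):
            if p <= q / m:
                assert r
            if p > q:
                assert not r
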