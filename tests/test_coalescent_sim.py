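import numpy as np
import pytest

from beringia import coalescent_sim as cs
from beringia.errors import ConfigError, InputError


def demog(**kw):
    base = dict(n_a=3, n_b=3, theta=0.02, tau=0.3, anc_ratio=0.5, locus_length=200)
    base.update(kw)
    return cs.PairDemography(**base)


class TestGenealogy:
    def test_height_at_least_tau_for_singletons(self):
        d = demog(n_a=1, n_b=1, tau=1.5, mig=0.0)
        for seed in range(200):
            tree = cs.simulate_genealogy(d, seed=seed)
            assert tree.height >= 1.5

    def test_tau_zero_is_panmictic_ancestor(self):
        # with tau = 0 two lineages coalesce at rate 1/anc: E[T] = anc
        d = demog(n_a=1, n_b=1, tau=0.0, anc_ratio=0.4)
        rng = np.random.default_rng(3)
        heights = [cs.simulate_genealogy(d, seed=rng).height for _ in range(4000)]
        se = np.std(heights) / np.sqrt(len(heights))
        assert abs(np.mean(heights) - 0.4) < 4 * se

    def test_singleton_pair_mean_coalescence_time(self):
        # mig = 0: T = tau + Exp(rate 1/anc), so E[T] = tau + anc
        d = demog(n_a=1, n_b=1, tau=2.0, anc_ratio=0.5, mig=0.0)
        rng = np.random.default_rng(11)
        heights = np.array([cs.simulate_genealogy(d, seed=rng).height for _ in range(20_000)])
        se = heights.std() / np.sqrt(len(heights))
        assert abs(heights.mean() - 2.5) < 3 * se

    def test_branch_lengths_positive_and_leaf_sets_partition(self):
        tree = cs.simulate_genealogy(demog(), seed=4)
        assert (tree.branch_lengths() >= 0).all()
        desc = tree.leaf_sets()
        root = len(tree.parent) - 1
        assert desc[root].all()
        kids = np.flatnonzero(tree.parent == root)
        assert not (desc[kids[0]] & desc[kids[1]]).any()

    def test_invalid_demography(self):
        with pytest.raises(InputError):
            demog(theta=0.0)
        with pytest.raises(InputError):
            demog(n_a=0)
        with pytest.raises(InputError):
            demog(tau=-1.0)


class TestMutations:
    def test_theta_zero_gives_identical_sequences(self):
        tree = cs.simulate_genealogy(demog(), seed=0)
        sim = cs.drop_mutations(tree, theta=0.0, locus_length=50, seed=1)
        seqs = {s for _, s in sim.deme_a.sequences} | {s for _, s in sim.deme_b.sequences}
        assert len(seqs) == 1

    def test_infinite_sites_segregating_equals_mutations(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            tree = cs.simulate_genealogy(demog(tau=0.5), seed=rng)
            sim = cs.drop_mutations(tree, theta=0.05, locus_length=500, seed=rng)
            mat = np.concatenate([sim.deme_a.matrix(), sim.deme_b.matrix()])
            seg = sum(len(np.unique(mat[:, c])) > 1 for c in range(mat.shape[1]))
            assert seg == sim.n_mutations

    def test_poisson_mean_identity(self):
        # E[#mutations] = (theta/2) * L * total branch length
        tree = cs.simulate_genealogy(demog(tau=0.5), seed=5)
        theta, L = 0.02, 300
        expected = 0.5 * theta * L * tree.total_branch_length
        rng = np.random.default_rng(6)
        counts = [
            cs.drop_mutations(tree, theta, L, seed=rng).n_mutations for _ in range(4000)
        ]
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3.5 * se

    def test_finite_sites_converges_to_infinite_at_low_theta(self):
        # θL = 0.5: repeat hits are rare, segregating-site counts agree < 2 %
        rng = np.random.default_rng(9)
        d = demog(theta=0.005, locus_length=100, tau=0.5)
        s_inf, s_fin = [], []
        for _ in range(4000):
            tree = cs.simulate_genealogy(d, seed=rng)
            s_inf.append(cs.drop_mutations(tree, d.theta, 100, "infinite_sites", rng).n_mutations)
            sim = cs.drop_mutations(tree, d.theta, 100, "finite_sites_jc", rng)
            mat = np.concatenate([sim.deme_a.matrix(), sim.deme_b.matrix()])
            s_fin.append(sum(len(np.unique(mat[:, c])) > 1 for c in range(100)))
        m_inf, m_fin = np.mean(s_inf), np.mean(s_fin)
        assert abs(m_fin - m_inf) / m_inf < 0.02 + 3 * np.std(s_inf) / np.sqrt(4000) / m_inf

    def test_unknown_model(self):
        tree = cs.simulate_genealogy(demog(), seed=0)
        with pytest.raises(ConfigError):
            cs.drop_mutations(tree, 0.01, 100, model="hky")

    def test_determinism(self):
        d = demog()
        s1 = cs.simulate_pair(d, seed=33)
        s2 = cs.simulate_pair(d, seed=33)
        assert s1.deme_a.sequences == s2.deme_a.sequences
        assert s1.deme_b.sequences == s2.deme_b.sequences


class TestSummaryVector:
    def test_near_zero_theta_vector(self):
        tree = cs.simulate_genealogy(demog(), seed=0)
        sim = cs.drop_mutations(tree, theta=0.0, locus_length=60, seed=1)
        vec = cs.pair_summary_vector(sim)
        assert np.allclose(vec, 0.0)  # monomorphic: Tajima's D imputed 0

    def test_fixed_difference_structure(self):
        from conftest import make_pair

        pair = make_pair(["AATT", "AATT"], ["AAAA", "AAAA"])
        vec = cs.summary_vector_from_matrices(pair.deme_a.matrix(), pair.deme_b.matrix())
        assert vec[0] == vec[1] == 0.0  # monomorphic within
        assert vec[3] == pytest.approx(vec[2])  # D_A = pi_between

    def test_net_divergence_tracks_split_time(self):
        # E[T_within] = x + (anc − x)·exp(−τ/x): with unit deme and ancestral
        # sizes the within and ancestral terms cancel and E[D_A] = θ·τ
        out = cs.simulate_pair_batch(
            demog(n_a=2, n_b=2, theta=0.01, tau=2.0, anc_ratio=1.0, locus_length=500),
            n_reps=20_000,
            seed=12,
        )
        d_a = out[:, 3]
        se = d_a.std() / np.sqrt(len(d_a))
        assert abs(d_a.mean() - 0.01 * 2.0) < 3 * se


class TestBatchKernel:
    def test_determinism(self):
        d = demog()
        a = cs.simulate_pair_batch(d, 50, seed=77)
        b = cs.simulate_pair_batch(d, 50, seed=77)
        assert np.array_equal(a, b)

    def test_matches_python_path_moments(self):
        # the njit branch-wise kernel and the alignment-building path simulate
        # the same process: compare summary-statistic means
        d = demog(n_a=4, n_b=4, theta=0.03, tau=0.4, mig=0.5, anc_ratio=0.3,
                  locus_length=300)
        batch = cs.simulate_pair_batch(d, 6000, seed=21)
        rng = np.random.default_rng(22)
        py = np.array([
            cs.pair_summary_vector(cs.simulate_pair(d, seed=rng, model="infinite_sites"))
            for _ in range(3000)
        ])
        for k in range(6):
            se = np.sqrt(batch[:, k].var() / 6000 + py[:, k].var() / 3000)
            assert abs(batch[:, k].mean() - py[:, k].mean()) < 4.5 * se, k

    def test_monotone_net_divergence_in_tau(self):
        means = []
        for tau in (0.02, 0.05, 0.1, 0.2):
            out = cs.simulate_pair_batch(
                demog(n_a=5, n_b=5, theta=0.2, tau=tau, size_ratio_a=0.05,
                      size_ratio_b=0.05, anc_ratio=0.02, locus_length=500),
                2000,
                seed=int(tau * 1000),
            )
            means.append(out[:, 3].mean())
        assert means == sorted(means)

    def test_tau_zero_exchangeable_fst(self):
        out = cs.simulate_pair_batch(
            demog(n_a=10, n_b=10, theta=0.04, tau=0.0, anc_ratio=1.0, locus_length=500),
            5000,
            seed=2,
        )
        ok = out[:, 2] > 0
        fst = 1 - 0.5 * (out[ok, 0] + out[ok, 1]) / out[ok, 2]
        assert abs(fst.mean()) < 0.02

    def test_layout_validation(self):
        with pytest.raises(InputError):
            cs.simulate_summaries_batch(
                [(0, 2, 100)], np.zeros((2, 1)), np.zeros((2, 1)),
                np.full((2, 1), 0.01), np.ones((2, 1)),
            )


class TestMsprimeOracle:
    def test_tmrca_distribution_matches_msprime(self):
        """Structured IM coalescent against an independent simulator (KS)."""
        import msprime
        from scipy.stats import ks_2samp

        n_a, n_b, tau, mig, sa, sb, anc = 3, 3, 0.3, 2.0, 1.0, 0.5, 0.5
        d = demog(n_a=n_a, n_b=n_b, tau=tau, mig=mig, size_ratio_a=sa,
                  size_ratio_b=sb, anc_ratio=anc)
        rng = np.random.default_rng(31)
        mine = np.array([cs.simulate_genealogy(d, seed=rng).height for _ in range(1500)])

        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=sa)
        dem.add_population(name="B", initial_size=sb)
        dem.add_population(name="ANC", initial_size=anc)
        dem.set_symmetric_migration_rate(["A", "B"], mig / 2.0)
        dem.add_population_split(time=tau, derived=["A", "B"], ancestral="ANC")
        theirs = []
        for i, ts in enumerate(
            msprime.sim_ancestry(
                samples={"A": n_a, "B": n_b}, demography=dem, ploidy=1,
                num_replicates=1500, random_seed=97,
            )
        ):
            theirs.append(ts.max_root_time)
        stat = ks_2samp(mine, np.array(theirs))
        assert stat.pvalue > 0.01
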