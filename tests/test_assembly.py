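import io
import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from continuum_assembly.assembly import (aggregate_processes,
                                         assembly_analysis,
                                         beta_phylo_metric, classify_process,
                                         null_z, pair_fractions,
                                         patristic_matrix, phylo_bins,
                                         raup_crick_bray)
from continuum_assembly.datamodel import CommunityTable
from tests.conftest import balanced_newick, caterpillar_newick


def table_of(rows, samples=None, taxa=None):
    rows = np.atleast_2d(rows)
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    taxa = taxa or [f"t{i}" for i in range(rows.shape[1])]
    return CommunityTable(pd.DataFrame(rows, index=samples, columns=taxa))


class TestPhyloBins:
    def test_balanced_128_limit_64_two_bins(self):
        tree = TreeNode.read(io.StringIO(balanced_newick(128)))
        bins = phylo_bins(tree, 64)
        assert sorted(len(b) for b in bins) == [64, 64]
        all_taxa = sorted(t for b in bins for t in b.taxa)
        assert all_taxa == sorted(t.name for t in tree.tips())

    def test_small_tree_single_bin(self):
        tree = TreeNode.read(io.StringIO(balanced_newick(8)))
        bins = phylo_bins(tree, 64)
        assert len(bins) == 1 and len(bins[0]) == 8

    def test_caterpillar_hand_trace(self):
        """10-tip caterpillar, limit 4: first clade of 4 bins; next 4
        unassigned bin at the C1..C8 ancestor; C9, C10 merge into the
        nearest (second) bin."""
        tree = TreeNode.read(io.StringIO(caterpillar_newick(10)))
        bins = phylo_bins(tree, 4)
        sets = sorted((sorted(b.taxa) for b in bins), key=len)
        assert sets[0] == ["C1", "C2", "C3", "C4"]
        assert sets[1] == ["C10", "C5", "C6", "C7", "C8", "C9"]

    def test_caterpillar_100_limit_64_partition(self):
        tree = TreeNode.read(io.StringIO(caterpillar_newick(100)))
        bins = phylo_bins(tree, 64)
        sizes = [len(b) for b in bins]
        assert sum(sizes) == 100
        assert all(s >= 36 for s in sizes)
        names = sorted(t for b in bins for t in b.taxa)
        assert names == sorted(t.name for t in tree.tips())

    def test_deterministic(self):
        tree = TreeNode.read(io.StringIO(balanced_newick(64)))
        a = [b.taxa for b in phylo_bins(tree, 16)]
        b = [b.taxa for b in phylo_bins(tree, 16)]
        assert a == b


def oracle_mpd(fa, fb, d):
    total = 0.0
    for i in range(len(fa)):
        for j in range(len(fb)):
            total += fa[i] * fb[j] * d[i, j]
    return total


def oracle_mntd(fa, fb, d):
    ia = [i for i in range(len(fa)) if fa[i] > 0]
    ib = [j for j in range(len(fb)) if fb[j] > 0]
    left = sum(fa[i] * min(d[i, j] for j in ib) for i in ia)
    right = sum(fb[j] * min(d[i, j] for i in ia) for j in ib)
    return 0.5 * (left + right)


class TestBetaPhyloMetric:
    def test_single_taxon_samples_reduce_to_distance(self, three_tip_tree):
        ct = table_of([[5, 0, 0], [0, 0, 3]], taxa=["A", "B", "C"])
        for metric in ("beta_mpd", "beta_mntd"):
            val = beta_phylo_metric(ct, three_tip_tree, ("s0", "s1"), metric)
            assert val == pytest.approx(4.0)  # patristic A-C

    def test_identical_composition_mntd_zero(self, three_tip_tree):
        ct = table_of([[2, 1, 0], [2, 1, 0]], taxa=["A", "B", "C"])
        assert beta_phylo_metric(ct, three_tip_tree, ("s0", "s1"),
                                 "beta_mntd") == pytest.approx(0.0)

    def test_star_tree_mpd_hand_value(self):
        tree = TreeNode.read(io.StringIO("(A:1,B:1,C:1,D:1):0;"))
        ct = table_of([[1, 1, 0, 0], [0, 0, 1, 1]], taxa=list("ABCD"))
        assert beta_phylo_metric(ct, tree, ("s0", "s1"), "beta_mpd") == \
            pytest.approx(2.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        from continuum_assembly.simulate import simulate_phylogeny
        tree, _ = simulate_phylogeny(10, seed=3)
        d, names = patristic_matrix(tree)
        counts = rng.integers(0, 8, (4, 10))
        counts[:, 0] += 1
        ct = table_of(counts, taxa=names)
        for a, b in itertools.combinations(ct.sample_ids, 2):
            fa = ct.data.loc[a].to_numpy(float)
            fa /= fa.sum()
            fb = ct.data.loc[b].to_numpy(float)
            fb /= fb.sum()
            assert beta_phylo_metric(ct, (d, names), (a, b), "beta_mpd") == \
                pytest.approx(oracle_mpd(fa, fb, d), abs=1e-12)
            assert beta_phylo_metric(ct, (d, names), (a, b), "beta_mntd") == \
                pytest.approx(oracle_mntd(fa, fb, d), abs=1e-12)


class TestNullZ:
    def test_two_taxon_subset_degenerate(self, cherry_tree):
        ct = table_of([[3, 1], [1, 3]], taxa=["A", "B"])
        z = null_z(ct, cherry_tree, ("s0", "s1"), n_rand=49, seed=0)
        assert np.isnan(z)

    def test_equal_distance_tree_degenerate(self):
        tree = TreeNode.read(io.StringIO("(A:1,B:1,C:1,D:1):0;"))
        ct = table_of([[1, 2, 3, 4], [4, 3, 2, 1]], taxa=list("ABCD"))
        z = null_z(ct, tree, ("s0", "s1"), n_rand=49, seed=0)
        assert np.isnan(z)  # every shuffle reproduces the observed value

    def test_seeded_determinism(self):
        from continuum_assembly.simulate import simulate_phylogeny
        tree, _ = simulate_phylogeny(20, seed=1)
        rng = np.random.default_rng(2)
        ct = table_of(rng.integers(0, 10, (2, 20)) + 1,
                      taxa=[t.name for t in tree.tips()])
        z1 = null_z(ct, tree, ("s0", "s1"), n_rand=99, seed=7)
        z2 = null_z(ct, tree, ("s0", "s1"), n_rand=99, seed=7)
        assert z1 == z2


class TestRaupCrick:
    def _pool_table(self, seed, n_samples=12, n_taxa=25, reads=150):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(n_taxa))
        counts = rng.multinomial(reads, p, size=n_samples)
        return table_of(counts)

    def test_identical_samples_rc_minus_one(self):
        base = np.array([4, 3, 2, 1, 0, 5])
        ct = table_of([base, base] + [np.roll(base, k) for k in range(1, 5)])
        rc = raup_crick_bray(ct, ("s0", "s1"), n_rand=199, seed=0)
        assert rc == pytest.approx(-1.0)

    def test_disjoint_samples_from_shared_pool_rc_high(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_taxa = 30
            pool = rng.dirichlet(np.ones(n_taxa))
            counts = rng.multinomial(200, pool, size=10)
            # make the focal pair strictly disjoint
            counts[0, n_taxa // 2:] = 0
            counts[1, :n_taxa // 2] = 0
            counts[0, 0] += 1
            counts[1, -1] += 1
            ct = table_of(counts)
            rc = raup_crick_bray(ct, ("s0", "s1"), n_rand=199, seed=seed)
            if rc >= 0.95:
                hits += 1
        assert hits >= 18

    def test_rank_construction_centers_near_zero(self):
        """A pair generated by the null procedure itself is exchangeable
        with the null draws, so RC should straddle 0 across seeds."""
        from continuum_assembly.assembly import _null_community_draws
        values = []
        for seed in range(20):
            ct = self._pool_table(seed)
            sub = ct.data.to_numpy()
            occ = (sub > 0).sum(axis=0).astype(float)
            ab = sub.sum(axis=0).astype(float)
            rng = np.random.default_rng(1000 + seed)
            draws = [_null_community_draws(sub[i], occ / occ.sum(),
                                           ab / ab.sum(), 1, rng)[0]
                     for i in (0, 1)]
            data = ct.data.copy()
            data.iloc[0] = draws[0]
            data.iloc[1] = draws[1]
            from continuum_assembly.datamodel import CommunityTable
            rc = raup_crick_bray(CommunityTable(data), ("s0", "s1"),
                                 n_rand=199, seed=seed)
            values.append(rc)
        assert abs(np.mean(values)) < 0.35
        assert min(values) < 0 < max(values)

    def test_single_taxon_metacommunity_errors(self):
        ct = table_of([[5], [3]])
        with pytest.raises(ValueError, match="2 taxa"):
            raup_crick_bray(ct, ("s0", "s1"), n_rand=9, seed=0)

    def test_seeded_determinism(self):
        ct = self._pool_table(3)
        a = raup_crick_bray(ct, ("s0", "s1"), n_rand=99, seed=5)
        b = raup_crick_bray(ct, ("s0", "s1"), n_rand=99, seed=5)
        assert a == b


class TestClassifyProcess:
    @pytest.mark.parametrize("z,rc,expected", [
        (2.5, 0.0, "heterogeneous_selection"),
        (-3.0, 0.0, "homogeneous_selection"),
        (0.5, 0.99, "dispersal_limitation"),
        (0.0, 0.0, "drift"),
        (1.0, -0.99, "homogenizing_dispersal"),
        (np.nan, 0.99, "dispersal_limitation"),
        (np.nan, np.nan, "unclassified"),
        (0.3, np.nan, "unclassified"),
    ])
    def test_decision_rules(self, z, rc, expected):
        assert classify_process(z, rc) == expected


class TestAggregation:
    def _pair_bin_table(self, rows):
        return pd.DataFrame(rows, columns=["i", "j", "bin_id", "z", "rc",
                                           "label", "weight"])

    def test_single_bin_single_label(self):
        t = self._pair_bin_table(
            [("a", "b", 1, -3.0, 0.0, "homogeneous_selection", 1.0)])
        out = aggregate_processes(t)
        assert out.loc["all", "homogeneous_selection"] == pytest.approx(1.0)

    def test_two_bins_even_split(self):
        t = self._pair_bin_table([
            ("a", "b", 1, -3.0, 0.0, "homogeneous_selection", 0.5),
            ("a", "b", 2, 0.0, 0.99, "dispersal_limitation", 0.5)])
        out = aggregate_processes(t)
        assert out.loc["all", "homogeneous_selection"] == pytest.approx(0.5)
        assert out.loc["all", "dispersal_limitation"] == pytest.approx(0.5)

    def test_weighted_split_hand_arithmetic(self):
        t = self._pair_bin_table([
            ("a", "b", 1, 2.5, 0.0, "heterogeneous_selection", 0.75),
            ("a", "b", 2, 0.0, 0.0, "drift", 0.25)])
        out = aggregate_processes(t)
        assert out.loc["all", "heterogeneous_selection"] == pytest.approx(0.75)
        assert out.loc["all", "drift"] == pytest.approx(0.25)

    def test_group_means_and_closure(self):
        t = self._pair_bin_table([
            ("a", "b", 1, 0.0, 0.0, "drift", 1.0),
            ("c", "d", 1, 2.5, 0.0, "heterogeneous_selection", 1.0)])
        out = aggregate_processes(t, {("a", "b"): "g1", ("c", "d"): "g2"})
        assert out.loc["g1", "drift"] == 1.0
        assert out.loc["g2", "heterogeneous_selection"] == 1.0
        assert np.allclose(out.sum(axis=1), 1.0)


class TestAssemblyAnalysis:
    @pytest.fixture(scope="class")
    def small_run(self):
        from continuum_assembly.simulate import (SimulationParams,
                                                 simulate_metacommunity)
        p = SimulationParams(n_sites=8, n_taxa=40, seed=5, read_depth=400,
                             fractions={"FL": 1.0})
        table, meta, tree, truth = simulate_metacommunity(p)
        return table, tree

    def test_weights_sum_to_one_per_pair(self, small_run):
        table, tree = small_run
        pb = assembly_analysis(table, tree, n_rand=49, seed=0,
                               bin_size_limit=12)
        sums = pb.groupby(["i", "j"])["weight"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)
        fr = pair_fractions(pb)
        assert np.allclose(fr.sum(axis=1), 1.0, atol=1e-9)

    def test_seeded_determinism(self, small_run):
        table, tree = small_run
        a = assembly_analysis(table, tree, n_rand=49, seed=3,
                              bin_size_limit=12)
        b = assembly_analysis(table, tree, n_rand=49, seed=3,
                              bin_size_limit=12)
        pd.testing.assert_frame_equal(a, b)

    def test_batch_z_matches_scalar_op(self, small_run):
        """The vectorized driver and the single-pair op agree exactly when
        fed the same permutation stream."""
        table, tree = small_run
        bins = phylo_bins(tree, 12)
        pair = (table.sample_ids[0], table.sample_ids[3])
        pb = assembly_analysis(table, tree, pairs=[pair], n_rand=99, seed=4,
                               bin_size_limit=12)
        d, names = patristic_matrix(tree)
        for bi, b in enumerate(bins):
            want = pb[(pb.bin_id == b.bin_id)].iloc[0]["z"]
            # reproduce the driver's per-bin stream
            rng = np.random.default_rng([4, 10 + bi])
            cols = b.taxa
            idx = [names.index(t) for t in cols]
            dsub = d[np.ix_(idx, idx)]
            fa = table.data.loc[pair[0], cols].to_numpy(float)
            fb = table.data.loc[pair[1], cols].to_numpy(float)
            if fa.sum() == 0 or fb.sum() == 0:
                assert np.isnan(want)
                continue
            fa, fb = fa / fa.sum(), fb / fb.sum()
            obs = oracle_mpd(fa, fb, dsub)
            nulls = []
            for _ in range(99):
                perm = rng.permutation(len(cols))
                nulls.append(oracle_mpd(fa, fb, dsub[np.ix_(perm, perm)]))
            z = (obs - np.mean(nulls)) / np.std(nulls)
            assert want == pytest.approx(z, abs=1e-9)

    def test_mntd_mode_runs(self, small_run):
        table, tree = small_run
        pairs = [(table.sample_ids[0], table.sample_ids[1])]
        pb = assembly_analysis(table, tree, pairs=pairs, metric="beta_mntd",
                               n_rand=29, seed=0, bin_size_limit=12)
        assert set(pb.columns) >= {"z", "rc", "label", "weight"}

    def test_tree_scope_shuffle_runs(self, small_run):
        table, tree = small_run
        pairs = [(table.sample_ids[0], table.sample_ids[1])]
        pb = assembly_analysis(table, tree, pairs=pairs, n_rand=29, seed=0,
                               bin_size_limit=12, shuffle_scope="tree")
        assert len(pb) > 0
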