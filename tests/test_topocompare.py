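"""RF/PC statistics, CADM concordance, embeddings, clade/subset tables."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from phylocompare import (
    DistanceMatrix,
    cadm_w,
    clade_pc_table,
    parse_newick,
    pc_similarity,
    random_topology,
    rf_distance,
    similarity_matrix,
    strain_space_embed,
    subset_pc,
    tree_space_embed,
)
from phylocompare.inference import enumerate_topologies

from conftest import brute_force_rf, random_tree


def all_five_tip_trees():
    """All 15 binary unrooted topologies on five labels, as PhyloTrees."""
    labels = list("ABCDE")
    seen, trees = set(), []
    seed = 0
    while len(trees) < 15:
        t = random_topology(labels, seed=seed)
        key = frozenset(frozenset((b.side_a, b.side_b)) for b in t.bipartitions())
        if key not in seen:
            seen.add(key)
            trees.append(t)
        seed += 1
    return trees


class TestRF:
    def test_identity(self):
        t = random_tree(9, seed=0)
        assert rf_distance(t, t) == 0

    def test_hand_enumerated_five_tip_pair(self):
        t1 = parse_newick("((A,B),C,(D,E));")
        t2 = parse_newick("((A,C),B,(D,E));")
        assert rf_distance(t1, t2) == 2  # AB vs AC differ; DE shared

    def test_distinct_four_tip_trees_always_two(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        t3 = parse_newick("((A,D),(B,C));")
        for a, b in itertools.combinations((t1, t2, t3), 2):
            assert rf_distance(a, b) == 2

    def test_tip_mismatch_lists_difference(self):
        with pytest.raises(ValueError, match="E"):
            rf_distance(parse_newick("((A,B),(C,D));"), parse_newick("((A,B),(C,E));"))

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(4, 13))
        t1, t2 = random_tree(m, seed=2 * seed), random_tree(m, seed=2 * seed + 1)
        assert rf_distance(t1, t2) == brute_force_rf(t1, t2)

    def test_agrees_with_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        from dendropy.calculate import treecompare

        for seed in range(10):
            m = 6 + seed
            t1, t2 = random_tree(m, seed=100 + seed), random_tree(m, seed=200 + seed)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick", taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick", taxon_namespace=tns)
            assert rf_distance(t1, t2) == treecompare.symmetric_difference(d1, d2)

    def test_metric_on_all_five_tip_topologies(self):
        trees = all_five_tip_trees()
        n = len(trees)
        d = np.zeros((n, n), dtype=int)
        for i in range(n):
            for j in range(n):
                d[i, j] = rf_distance(trees[i], trees[j])
        assert (d == d.T).all()
        assert all(d[i, i] == 0 for i in range(n))
        assert all(d[i, j] > 0 for i in range(n) for j in range(n) if i != j)
        for i, j, k in itertools.permutations(range(n), 3):
            assert d[i, k] <= d[i, j] + d[j, k]


class TestPC:
    def test_identical_trees_are_100(self):
        for m in (4, 9, 33):
            t = random_tree(m, seed=m)
            assert pc_similarity(t, t) == 100.0

    def test_five_tip_half_similarity(self):
        t1 = parse_newick("((A,B),C,(D,E));")
        t2 = parse_newick("((A,C),B,(D,E));")
        assert pc_similarity(t1, t2) == 50.0  # RF=2, 2m-6=4

    def test_four_tips_all_or_nothing(self):
        labels = ["w", "x", "y", "z"]
        topos = [parse_newick(s) for s in ("((w,x),(y,z));", "((w,y),(x,z));", "((w,z),(x,y));")]
        for a, b in itertools.product(topos, repeat=2):
            assert pc_similarity(a, b) in (0.0, 100.0)

    def test_small_tip_sets_rejected(self):
        t = parse_newick("(A,B,C);")
        with pytest.raises(ValueError, match="4"):
            pc_similarity(t, t)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_complement_identity(self, seed):
        # PC + 100*RF/(2m-6) == 100 in exact rational arithmetic
        m = 5 + seed
        t1, t2 = random_tree(m, seed=seed), random_tree(m, seed=seed + 50)
        rf = rf_distance(t1, t2)
        denom = 2 * m - 6
        assert Fraction(pc_similarity(t1, t2)).limit_denominator(10**9) + Fraction(
            100 * rf, denom
        ) == 100


class TestSimilarityMatrix:
    def test_identical_trees_all_100(self):
        t = random_tree(8, seed=1)
        sim = similarity_matrix({"a": t, "b": t.copy(), "c": t.copy()})
        assert (sim.values == 100.0).all()

    def test_random_tree_near_zero_at_m50(self):
        t = random_tree(50, seed=5)
        out = random_topology(sorted(t.tips), seed=77)
        sim = similarity_matrix({"t": t, "OUT": out})
        assert sim[("t", "OUT")] <= 10

    def test_shape_and_symmetry(self):
        trees = {f"g{i}": random_tree(10, seed=i) for i in range(6)}
        sim = similarity_matrix(trees)
        assert sim.values.shape == (6, 6)
        assert np.allclose(sim.values, sim.values.T)
        assert (np.diag(sim.values) == 100).all()


def random_dm(n, seed, labels=None):
    rng = np.random.default_rng(seed)
    a = rng.random((n, n))
    a = a + a.T
    np.fill_diagonal(a, 0)
    labels = labels or tuple(f"s{i}" for i in range(n))
    return DistanceMatrix(labels, a)


def kendall_w_reference(rank_rows):
    """Direct textbook Kendall W with tie correction, from a rank table."""
    ranks = np.asarray(rank_rows, dtype=float)
    p, N = ranks.shape
    R = ranks.sum(axis=0)
    S = ((R - R.mean()) ** 2).sum()
    T = sum(
        float((c**3 - c).sum())
        for c in (np.unique(row, return_counts=True)[1] for row in ranks)
    )
    return 12 * S / (p**2 * (N**3 - N) - p * T)


class TestCadm:
    def test_identical_matrices_full_agreement(self):
        m = random_dm(6, seed=0)
        for p in (2, 3, 5):
            assert cadm_w([m] * p).w == pytest.approx(1.0)

    def test_rank_reversed_matrices_zero(self):
        n = 6
        m1 = random_dm(n, seed=1)
        iu = np.triu_indices(n, 1)
        vals = m1.values.copy()
        # map each entry to (max+min) - entry: exactly reverses the ranking
        rev = np.zeros_like(vals)
        rev[iu] = vals[iu].max() + vals[iu].min() - vals[iu]
        rev = rev + rev.T
        m2 = DistanceMatrix(m1.labels, rev)
        assert cadm_w([m1, m2]).w == pytest.approx(0.0, abs=1e-12)

    def test_ties_match_reference_formula(self):
        from scipy.stats import rankdata

        n = 6
        rng = np.random.default_rng(3)
        mats = []
        for k in range(3):
            a = rng.integers(0, 4, size=(n, n)).astype(float)  # many ties
            a = a + a.T
            np.fill_diagonal(a, 0)
            mats.append(DistanceMatrix(tuple(f"s{i}" for i in range(n)), a))
        iu = np.triu_indices(n, 1)
        expected = kendall_w_reference([rankdata(m.values[iu]) for m in mats])
        assert cadm_w(mats).w == pytest.approx(expected)

    def test_tied_identical_matrices_are_one(self):
        a = np.ones((5, 5)) - np.eye(5)
        m = DistanceMatrix(tuple("abcde"), a)
        assert cadm_w([m, m, m]).w == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        m1, m2 = random_dm(7, seed=4), random_dm(7, seed=5)
        w0 = cadm_w([m1, m2]).w
        transformed = DistanceMatrix(m2.labels, np.sqrt(m2.values) * 3.7)
        assert cadm_w([m1, transformed]).w == pytest.approx(w0)

    def test_agrees_with_r_ape_cadm(self, tmp_path):
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        mats = [random_dm(6, seed=s) for s in (10, 11, 12)]
        stacked = np.vstack([m.values for m in mats])
        np.savetxt(tmp_path / "dm.txt", stacked)
        script = tmp_path / "cadm.R"
        script.write_text(
            "suppressMessages(library(ape))\n"
            f'x <- as.matrix(read.table("{tmp_path / "dm.txt"}"))\n'
            "res <- CADM.global(x, 3, 6, nperm=0)\n"
            "cat(res$congruence_analysis[1,1])\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        if out.returncode != 0:
            pytest.skip(f"Rscript failed: {out.stderr[:200]}")
        w_ref = float(out.stdout.strip().split()[-1])
        assert cadm_w(mats).w == pytest.approx(w_ref, abs=1e-6)

    def test_permutation_p_value_for_concordant_matrices(self):
        base = random_dm(8, seed=21)
        noisy = DistanceMatrix(
            base.labels, np.abs(base.values + random_dm(8, seed=22).values * 0.01)
        )
        res = cadm_w([base, noisy], permutations=199, seed=0)
        assert res.p_value is not None and res.p_value < 0.05

    def test_input_validation(self):
        m = random_dm(6, seed=0)
        with pytest.raises(ValueError):
            cadm_w([m])
        other = random_dm(6, seed=1, labels=tuple(f"z{i}" for i in range(6)))
        with pytest.raises(ValueError):
            cadm_w([m, other])


class TestEmbeddings:
    def test_three_trees_embed_exactly(self):
        trees = {f"t{i}": random_tree(8, seed=i) for i in range(3)}
        emb = tree_space_embed(trees)
        rf = np.zeros((3, 3))
        ids = list(trees)
        for i in range(3):
            for j in range(3):
                rf[i, j] = 0 if i == j else float(
                    __import__("phylocompare").rf_distance(trees[ids[i]], trees[ids[j]])
                )
        assert np.allclose(emb.distances(), rf, atol=1e-6)
        assert emb.stress < 1e-6

    def test_duplicate_trees_coincide(self):
        t = random_tree(8, seed=3)
        emb = tree_space_embed({"a": t, "b": t.copy(), "c": random_tree(8, seed=4)})
        assert np.allclose(emb.coords[0], emb.coords[1], atol=1e-6)

    def test_te_like_closer_to_ref_than_out(self):
        ref = random_tree(40, seed=0)
        te = ref.copy()  # zero RF to REF
        out = random_topology(sorted(ref.tips), seed=9)
        emb = tree_space_embed({"REF": ref, "TE": te, "OUT": out})
        d = emb.distances()
        assert d[0, 1] < d[0, 2]

    def test_reproducible_bitwise(self):
        trees = {f"t{i}": random_tree(10, seed=i) for i in range(5)}
        e1 = tree_space_embed(trees, method="smacof")
        e2 = tree_space_embed(trees, method="smacof")
        assert (e1.coords == e2.coords).all()

    def test_strain_space_three_tips_exact(self):
        emb = strain_space_embed(parse_newick("(A:1,B:2,C:3);"))
        assert emb.stress < 1e-8

    def test_strain_space_clade_structure(self):
        # two shallow clades separated by a deep internal branch
        t = parse_newick("((A:0.1,B:0.1):5,(C:0.1,D:0.1):5);")
        emb = strain_space_embed(t)
        ids = list(emb.ids)
        d = emb.distances()
        within = d[ids.index("A"), ids.index("B")]
        across = d[ids.index("A"), ids.index("C")]
        assert within < across

    def test_star_tree_symmetric_configuration(self):
        emb = strain_space_embed(parse_newick("(A:1,B:1,C:1);"))
        d = emb.distances()
        offdiag = d[np.triu_indices(3, 1)]
        assert np.allclose(offdiag, offdiag[0], atol=1e-8)

    def test_requires_three_trees(self):
        t = random_tree(6, seed=0)
        with pytest.raises(ValueError):
            tree_space_embed({"a": t, "b": t.copy()})


class TestCladeTable:
    def _setup(self, seed=0):
        from phylocompare import simulate_gene_tree, simulate_species_tree

        sp, clade_map = simulate_species_tree(3, [8, 8, 8], 1.0, 0.1, seed=seed)
        clades = {}
        for s, c in clade_map.items():
            clades.setdefault(c, set()).add(s)
        return sp, clades

    def test_identical_gene_tree_scores_100(self):
        sp, clades = self._setup()
        out = random_topology(sorted(sp.tips), seed=1)
        table = clade_pc_table({"g1": sp.copy()}, sp.copy(), sp, out, clades)
        assert (table.table["g1"] == 100.0).all()
        assert (table.table["TE"] == 100.0).all()

    def test_nni_within_clade_matches_brute_force(self):
        from phylocompare import simulate_gene_tree

        sp, clades = self._setup(seed=2)
        gene = simulate_gene_tree(sp, 4, seed=3)
        out = random_topology(sorted(sp.tips), seed=4)
        table = clade_pc_table({"g": gene}, sp.copy(), sp, out, clades)
        for clade, tips in clades.items():
            sub_g = gene.restrict(tips)
            sub_r = sp.restrict(tips)
            rf = brute_force_rf(sub_g, sub_r)
            expect = 100 * (1 - rf / (2 * len(tips) - 6))
            assert table.table.loc[clade, "g"] == pytest.approx(expect)
            assert 0 <= table.table.loc[clade, "g"] <= 100

    def test_out_column_near_zero_for_20_tip_clade(self):
        from phylocompare import simulate_species_tree

        sp, clade_map = simulate_species_tree(2, [20, 20], 1.0, 0.1, seed=5)
        clades = {}
        for s, c in clade_map.items():
            clades.setdefault(c, set()).add(s)
        vals = []
        for seed in range(10):
            out = random_topology(sorted(sp.tips), seed=seed)
            table = clade_pc_table({}, sp.copy(), sp, out, clades)
            vals.extend(table.table["OUT"].tolist())
        assert np.mean(vals) <= 15

    def test_small_clades_flagged_undefined(self):
        sp, clades = self._setup()
        clades["tiny"] = set(sorted(sp.tips)[:3])
        out = random_topology(sorted(sp.tips), seed=1)
        table = clade_pc_table({}, sp.copy(), sp, out, clades)
        assert np.isnan(table.table.loc["tiny", "TE"])
        assert table.clade_sizes["tiny"] == 3

    def test_unknown_tips_rejected(self):
        sp, clades = self._setup()
        clades["bad"] = {"nope1", "nope2", "nope3", "nope4"}
        out = random_topology(sorted(sp.tips), seed=1)
        with pytest.raises(ValueError, match="nope"):
            clade_pc_table({}, sp.copy(), sp, out, clades)


class TestSubsetPC:
    def test_one_tip_per_clade_concordant_trees(self):
        from phylocompare import simulate_species_tree

        sp, clade_map = simulate_species_tree(5, [4] * 5, 1.0, 0.05, seed=6)
        reps = sorted({c: s for s, c in sorted(clade_map.items())}.values())
        res = subset_pc({"TE": sp.copy(), "g": sp.copy()}, sp, reps)
        assert res == {"TE": 100.0, "g": 100.0}

    def test_four_tip_subsets_are_binary(self):
        ref = random_tree(12, seed=0)
        subsetted = sorted(ref.tips)[:4]
        for seed in range(20):
            t = random_topology(sorted(ref.tips), seed=seed)
            val = subset_pc({"t": t}, ref, subsetted)["t"]
            assert val in (0.0, 100.0)

    def test_random_tree_mean_near_one_third(self):
        # a uniform random topology matches any fixed 4-tip split 1/3 of the
        # time, so the mean PC over many draws approaches 100/3
        ref = random_tree(8, seed=1)
        four = sorted(ref.tips)[:4]
        vals = [
            subset_pc({"t": random_topology(sorted(ref.tips), seed=s)}, ref, four)["t"]
            for s in range(300)
        ]
        assert 25 <= np.mean(vals) <= 41

    def test_unknown_strain_named(self):
        ref = random_tree(8, seed=1)
        with pytest.raises(ValueError, match="ghost"):
            subset_pc({"t": ref.copy()}, ref, ["ghost"] + sorted(ref.tips)[:3])
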