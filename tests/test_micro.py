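import io
import math

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from dietrhythm import micro
from dietrhythm.micro import FeatureTable


def _table(counts, samples=None, taxa=None):
    counts = np.asarray(counts)
    samples = samples or [f"S{i}" for i in range(counts.shape[0])]
    taxa = taxa or [f"T{j}" for j in range(counts.shape[1])]
    return FeatureTable(pd.DataFrame(counts, index=samples, columns=taxa))


# ---------------------------------------------------------------- oracles

def brute_faith_pd(tree: TreeNode, observed: set[str]) -> float:
    """Sum branch lengths of nodes whose subtree holds an observed tip."""
    total = 0.0
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} or {node.name}
        if tips & observed:
            total += node.length or 0.0
    return total


def brute_unifrac(tree: TreeNode, obs_a: set[str], obs_b: set[str]) -> float:
    """Exhaustive branch walk: unique / observed branch length."""
    unique = shared = 0.0
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} or {node.name}
        in_a, in_b = bool(tips & obs_a), bool(tips & obs_b)
        if in_a and in_b:
            shared += node.length or 0.0
        elif in_a or in_b:
            unique += node.length or 0.0
    denom = unique + shared
    return unique / denom if denom else 0.0


def _random_tree(rng, n_leaves):
    from dietrhythm.synth import generate_tree
    return generate_tree(n_leaves, int(rng.integers(0, 2**31)))


# ---------------------------------------------------------------- rarefy

class TestRarefy:
    def test_sums_equal_depth(self):
        t = _table(np.random.default_rng(0).integers(0, 50, (5, 10)) + 5)
        r = micro.rarefy(t, depth=60, seed=1)
        assert (r.data.sum(axis=1) == 60).all()

    def test_shallow_sample_dropped(self):
        t = _table([[10000, 4999], [10000, 5001]])
        r = micro.rarefy(t, depth=15000, seed=0)
        assert r.sample_ids == ["S1"]

    def test_seed_reproducible(self):
        t = _table(np.random.default_rng(1).integers(0, 40, (4, 8)) + 2)
        r1 = micro.rarefy(t, depth=50, seed=42)
        r2 = micro.rarefy(t, depth=50, seed=42)
        pd.testing.assert_frame_equal(r1.data, r2.data)

    def test_expected_proportions_preserved(self):
        counts = np.array([[400, 300, 200, 100]])
        t = _table(counts)
        depth = 100
        acc = np.zeros(4)
        n_rep = 200
        for seed in range(n_rep):
            acc += micro.rarefy(t, depth=depth, seed=seed).data.to_numpy()[0]
        mean = acc / n_rep
        expected = counts[0] / counts.sum() * depth  # hypergeometric mean
        # 4 sigma of the hypergeometric, per taxon
        n_tot = counts.sum()
        var = depth * (counts[0] / n_tot) * (1 - counts[0] / n_tot) \
            * (n_tot - depth) / (n_tot - 1)
        assert (np.abs(mean - expected) < 4 * np.sqrt(var / n_rep)).all()


class TestPrevalenceFilter:
    def test_below_threshold_removed(self):
        t = _table([[1, 1], [1, 0], [1, 0]])
        f = micro.prevalence_filter(t, min_samples=2)
        assert f.taxon_ids == ["T0"]

    def test_min_one_drops_only_all_zero(self):
        t = _table([[1, 0], [2, 0]])
        f = micro.prevalence_filter(t, min_samples=1)
        assert f.taxon_ids == ["T0"]


class TestClr:
    def test_rows_center_to_zero(self):
        t = _table(np.random.default_rng(0).integers(0, 100, (6, 12)))
        clr = micro.clr_transform(t)
        assert np.allclose(clr.sum(axis=1), 0, atol=1e-9)

    def test_uniform_sample_all_zero(self):
        clr = micro.clr_transform(_table([[7, 7, 7]]))
        assert np.allclose(clr, 0)

    def test_two_taxon_hand_computation(self):
        clr = micro.clr_transform(_table([[9, 99]]), pseudocount=1)
        assert clr.iloc[0, 0] == pytest.approx(-0.5 * math.log(10))
        assert clr.iloc[0, 1] == pytest.approx(0.5 * math.log(10))

    def test_bad_pseudocount(self):
        with pytest.raises(ValueError):
            micro.clr_transform(_table([[1, 2]]), pseudocount=0)


class TestAlpha:
    def test_single_taxon_sample(self):
        out = micro.alpha_metrics(_table([[50, 0, 0]]))
        assert out["shannon"].iloc[0] == 0.0
        assert out["observed_features"].iloc[0] == 1
        assert math.isnan(out["pielou"].iloc[0])

    def test_uniform_four_taxa(self):
        out = micro.alpha_metrics(_table([[25, 25, 25, 25]]))
        assert out["shannon"].iloc[0] == pytest.approx(2.0)
        assert out["pielou"].iloc[0] == pytest.approx(1.0)

    def test_hand_proportions(self):
        out = micro.alpha_metrics(_table([[2, 1, 1]]))
        assert out["shannon"].iloc[0] == pytest.approx(1.5)

    def test_faith_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            tree = _random_tree(rng, n)
            taxa = [t.name for t in tree.tips()]
            counts = rng.integers(0, 3, size=(4, n))
            counts[:, 0] += 1  # no empty samples
            t = _table(counts, taxa=taxa)
            out = micro.alpha_metrics(t, tree=tree)
            for i, sid in enumerate(t.sample_ids):
                observed = {taxa[j] for j in range(n) if counts[i, j] > 0}
                assert out.loc[sid, "faith_pd"] == pytest.approx(
                    brute_faith_pd(tree, observed), abs=1e-9)

    def test_faith_monotone_in_observed_taxa(self):
        rng = np.random.default_rng(1)
        tree = _random_tree(rng, 8)
        taxa = [t.name for t in tree.tips()]
        counts = np.zeros((8, 8), dtype=int)
        for i in range(8):
            counts[i, : i + 1] = 1  # nested presence sets
        out = micro.alpha_metrics(_table(counts, taxa=taxa), tree=tree)
        assert (np.diff(out["faith_pd"].to_numpy()) >= -1e-12).all()

    def test_faith_bounded_by_total_length(self):
        rng = np.random.default_rng(2)
        tree = _random_tree(rng, 6)
        taxa = [t.name for t in tree.tips()]
        total = sum(n.length or 0 for n in tree.traverse(include_self=False))
        out = micro.alpha_metrics(_table(np.ones((1, 6), dtype=int), taxa=taxa),
                                  tree=tree)
        assert out["faith_pd"].iloc[0] == pytest.approx(total)

    def test_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            micro.alpha_metrics(_table([[0, 0]]))


class TestUnifrac:
    def test_identical_presence_zero(self):
        rng = np.random.default_rng(0)
        tree = _random_tree(rng, 5)
        taxa = [t.name for t in tree.tips()]
        t = _table([[1, 2, 0, 3, 0], [9, 1, 0, 7, 0]], taxa=taxa)
        d = micro.unweighted_unifrac(t, tree)
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_on_star_tree(self):
        star = TreeNode.read(io.StringIO("(A:1,B:1,C:1,D:1):0;"))
        t = _table([[1, 1, 0, 0], [0, 0, 1, 1]], taxa=["A", "B", "C", "D"])
        d = micro.unweighted_unifrac(t, star)
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_four_leaf_toy_vs_brute_force(self):
        tree = TreeNode.read(io.StringIO("((A:0.5,B:1.5):0.7,(C:0.3,D:1.1):0.9):0;"))
        counts = np.array([[1, 0, 1, 0], [0, 1, 1, 1], [1, 1, 0, 0]])
        t = _table(counts, taxa=["A", "B", "C", "D"])
        d = micro.unweighted_unifrac(t, tree)
        names = ["A", "B", "C", "D"]
        for i in range(3):
            for j in range(3):
                oa = {names[k] for k in range(4) if counts[i, k]}
                ob = {names[k] for k in range(4) if counts[j, k]}
                assert d.iloc[i, j] == pytest.approx(
                    brute_unifrac(tree, oa, ob), abs=1e-12)

    def test_metric_axioms_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = int(rng.integers(4, 9))
            tree = _random_tree(rng, n)
            taxa = [t.name for t in tree.tips()]
            counts = rng.integers(0, 2, size=(6, n))
            counts[:, 0] = 1
            d = micro.unweighted_unifrac(_table(counts, taxa=taxa), tree).to_numpy()
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0)
            for i in range(6):
                for j in range(6):
                    for k in range(6):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_empty_sample_rejected(self):
        rng = np.random.default_rng(4)
        tree = _random_tree(rng, 4)
        taxa = [t.name for t in tree.tips()]
        with pytest.raises(ValueError):
            micro.unweighted_unifrac(_table([[0, 0, 0, 0]], taxa=taxa), tree)


class TestPcoa:
    def test_line_recovered(self):
        x = np.array([0.0, 1.0, 2.5, 7.0])
        D = pd.DataFrame(np.abs(x[:, None] - x[None, :]))
        coords, prop = micro.pcoa(D)
        pc1 = coords["PC1"].to_numpy()
        # centered line up to sign
        centered = x - x.mean()
        err = min(np.abs(pc1 - centered).max(), np.abs(pc1 + centered).max())
        assert err < 1e-6
        assert prop.iloc[0] == pytest.approx(1.0)

    def test_proportions_nonincreasing_and_bounded(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 3))
        D = pd.DataFrame(np.linalg.norm(pts[:, None] - pts[None, :], axis=2))
        _, prop = micro.pcoa(D)
        assert prop.sum() <= 1 + 1e-9
        assert (np.diff(prop.to_numpy()) <= 1e-12).all()

    def test_euclidean_distances_reconstructed(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(4, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords, _ = micro.pcoa(pd.DataFrame(D))
        C = coords.to_numpy()
        D2 = np.linalg.norm(C[:, None] - C[None, :], axis=2)
        assert np.allclose(D, D2, atol=1e-8)

    def test_asymmetry_rejected(self):
        D = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="asymmetric"):
            micro.pcoa(D)


def test_feature_table_tsv_roundtrip(tmp_path):
    t = _table(np.random.default_rng(0).integers(0, 9, (3, 4)))
    path = tmp_path / "t.tsv"
    t.to_tsv(path)
    back = FeatureTable.from_tsv(path)
    pd.testing.assert_frame_equal(t.data, back.data)


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError, match="unique"):
        FeatureTable(pd.DataFrame([[1, 2], [3, 4]], index=["S", "S"],
                                  columns=["A", "B"]))
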