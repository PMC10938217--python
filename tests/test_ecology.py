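"""Rarefaction, diversity, ordination and PERMANOVA against independent
oracles (closed forms, brute-force enumeration, scikit-bio)."""

import io
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix as SkbioDM
from skbio.stats.distance import permanova as skbio_permanova

import cadmb
from cadmb.ecology import Rarefier, pcoa, permanova, rarefy


def _table(rows, index=None, columns=None):
    rows = np.atleast_2d(rows)
    index = index or [f"s{i}" for i in range(rows.shape[0])]
    columns = columns or [f"a{i}" for i in range(rows.shape[1])]
    return pd.DataFrame(rows, index=index, columns=columns)


# --- rarefaction -----------------------------------------------------------

class TestRarefy:
    def test_exact_depth_returned_unchanged(self):
        t = _table([[50, 30, 20]])
        out = rarefy(t, depth=100, seed=0)
        pd.testing.assert_frame_equal(out, t.astype(np.int64))

    def test_single_taxon(self):
        out = rarefy(_table([[1000, 0, 0]]), depth=100, seed=0)
        assert out.to_numpy().tolist() == [[100, 0, 0]]

    def test_row_sums_equal_depth(self, default_cohort):
        out = rarefy(default_cohort.counts, 6247, seed=1)
        assert (out.sum(axis=1) == 6247).all()

    def test_shallow_samples_dropped_with_warning(self):
        t = _table([[5, 5, 5], [100, 100, 100]])
        with pytest.warns(UserWarning, match="s0"):
            out = rarefy(t, depth=50, seed=0)
        assert list(out.index) == ["s1"]

    def test_invalid_depth(self):
        with pytest.raises(ValueError):
            rarefy(_table([[10, 10]]), depth=0)

    def test_expected_counts_proportional(self):
        """Mean over many rarefactions approaches depth × proportion."""
        row = np.array([[600, 300, 100]])
        t = _table(row)
        acc = np.zeros(3)
        n_rep = 500
        for seed in range(n_rep):
            acc += rarefy(t, depth=100, seed=seed).to_numpy()[0]
        expected = 100 * row[0] / row.sum()
        assert np.allclose(acc / n_rep, expected, atol=1.0)

    def test_transformer_reports_dropped(self):
        t = _table([[5, 5, 5], [100, 100, 100]])
        r = Rarefier(depth=50, random_state=0).fit(t)
        assert r.dropped_samples_ == ["s0"]


# --- alpha diversity -------------------------------------------------------

def test_observed_matches_bruteforce():
    rng = np.random.default_rng(0)
    rows = rng.integers(0, 4, size=(100, 30))
    t = _table(rows)
    expected = [sum(1 for v in row if v > 0) for row in rows]
    assert cadmb.alpha_observed(t).tolist() == expected


@pytest.mark.parametrize("row,expected", [
    ([25, 25, 25, 25], math.log(4)),
    ([100, 0, 0, 0], 0.0),
])
def test_shannon_closed_forms(row, expected):
    assert cadmb.alpha_shannon(_table([row])).iloc[0] == pytest.approx(
        expected, abs=1e-12)


def test_shannon_matches_direct_sum():
    row = np.array([1, 2, 3], dtype=float)
    p = row / row.sum()
    oracle = -sum(pi * math.log(pi) for pi in p)
    assert cadmb.alpha_shannon(_table([row])).iloc[0] == pytest.approx(
        oracle, abs=1e-12)


def test_shannon_empty_row_errors():
    with pytest.raises(ValueError):
        cadmb.alpha_shannon(_table([[0, 0, 0]]))


FOUR_TIP_TREE = "((A:1,B:1):1,(C:1,D:1):1);"


class TestFaithPD:
    def tree(self):
        return TreeNode.read(io.StringIO(FOUR_TIP_TREE))

    def test_examples(self):
        t = _table([[1, 0, 0, 0], [1, 1, 1, 1], [0, 0, 0, 0]],
                   columns=list("ABCD"))
        vals = cadmb.alpha_faith_pd(t, self.tree())
        assert vals.tolist() == [2.0, 6.0, 0.0]

    def test_matches_pathsum_oracle(self):
        """PD equals the branch-length sum of the union of root paths."""
        rng = np.random.default_rng(5)
        tips = [f"a{i}" for i in range(12)]
        from cadmb.simulate import _random_bifurcating_tree
        tree = _random_bifurcating_tree(list(tips), rng)
        rows = (rng.random((20, 12)) < 0.4).astype(int)
        t = _table(rows, columns=tips)
        got = cadmb.alpha_faith_pd(t, tree)
        for i, row in enumerate(rows):
            observed = [tips[j] for j in np.flatnonzero(row)]
            edges = set()
            for name in observed:
                node = tree.find(name)
                while node.parent is not None:
                    edges.add(id(node))
                    node = node.parent
            oracle = sum(n.length for n in tree.traverse()
                         if id(n) in edges)
            assert got.iloc[i] == pytest.approx(oracle, abs=1e-9)

    def test_monotone_in_observed_taxa(self):
        t1 = _table([[1, 0, 1, 0]], columns=list("ABCD"))
        t2 = _table([[1, 1, 1, 0]], columns=list("ABCD"))
        tree = self.tree()
        assert (cadmb.alpha_faith_pd(t2, tree).iloc[0]
                >= cadmb.alpha_faith_pd(t1, tree).iloc[0])

    def test_missing_tip_listed(self):
        t = _table([[1, 1]], columns=["A", "ZZZ"])
        with pytest.raises(ValueError, match="ZZZ"):
            cadmb.alpha_faith_pd(t, self.tree())


# --- Bray-Curtis -----------------------------------------------------------

class TestBrayCurtis:
    @pytest.mark.parametrize("x,y,expected", [
        ([5, 5, 0], [5, 5, 0], 0.0),
        ([5, 5, 0], [0, 0, 7], 1.0),
        ([5, 5, 0], [0, 5, 5], 0.5),
    ])
    def test_closed_forms(self, x, y, expected):
        d = cadmb.bray_curtis(_table([x, y]))
        assert d.iloc[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_matches_minsum_formula(self):
        rng = np.random.default_rng(1)
        t = _table(rng.integers(0, 50, size=(8, 15)) + 1)
        d = cadmb.bray_curtis(t)
        x = t.to_numpy(float)
        for i in range(8):
            for j in range(8):
                oracle = 1 - 2 * np.minimum(x[i], x[j]).sum() / (
                    x[i].sum() + x[j].sum())
                assert d.iloc[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_metric_properties_random(self):
        rng = np.random.default_rng(2)
        t = _table(rng.integers(0, 30, size=(12, 20)) + 1)
        d = cadmb.bray_curtis(t).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert ((d >= 0) & (d <= 1)).all()

    def test_zero_row_errors(self):
        with pytest.raises(ValueError):
            cadmb.bray_curtis(_table([[1, 1], [0, 0]]))


# --- PCoA ------------------------------------------------------------------

class TestPcoa:
    def test_line_points_recovered(self):
        coords_1d = np.array([0.0, 1.0, 3.0, 6.0])
        d = np.abs(coords_1d[:, None] - coords_1d[None, :])
        res = pcoa(_square(d), n_axes=2)
        axis1 = res.coordinates.iloc[:, 0].to_numpy()
        rec = np.abs(axis1[:, None] - axis1[None, :])
        assert np.allclose(rec, d, atol=1e-8)

    def test_zero_matrix_gives_zero_coordinates(self):
        res = pcoa(_square(np.zeros((4, 4))), n_axes=2)
        assert np.allclose(res.coordinates.to_numpy(), 0)

    def test_euclidean_distances_preserved(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 4))
        d = squareform(pdist(pts))
        res = pcoa(_square(d), n_axes=4)
        emb = res.coordinates.to_numpy()
        d_emb = squareform(pdist(emb))
        assert np.allclose(d_emb, d, atol=1e-8)

    def test_asymmetric_rejected(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            pcoa(_square(d))

    def test_negative_eigenvalues_reported_not_counted(self):
        rng = np.random.default_rng(4)
        t = _table(rng.integers(0, 20, size=(10, 6)) + 1)
        res = pcoa(cadmb.bray_curtis(t), n_axes=3)
        assert (res.eigenvalues < 0).any()  # BC is non-Euclidean
        pos = res.eigenvalues[res.eigenvalues > 0]
        assert np.allclose(res.proportion_explained,
                           res.eigenvalues[:3] / pos.sum())

    def test_matches_skbio_proportions(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(9, 3))
        d = squareform(pdist(pts))
        ours = pcoa(_square(d), n_axes=2)
        from skbio.stats.ordination import pcoa as skbio_pcoa
        theirs = skbio_pcoa(SkbioDM(d), number_of_dimensions=2)
        assert np.allclose(
            ours.proportion_explained,
            theirs.proportion_explained.to_numpy()[:2], atol=1e-8)


def _square(d):
    ids = [f"s{i}" for i in range(d.shape[0])]
    return pd.DataFrame(d, index=ids, columns=ids)


# --- PERMANOVA -------------------------------------------------------------

def _bruteforce_permanova_p(d, labels):
    """Exact enumeration oracle for a two-group design."""
    labels = np.asarray(labels)
    groups = np.unique(labels)
    n = len(labels)
    n1 = int((labels == groups[0]).sum())

    def pseudo_f(lab):
        d2 = d ** 2
        ss_t = d2.sum() / (2 * n)
        ss_w = 0.0
        for g in groups:
            m = lab == g
            ss_w += d2[np.ix_(m, m)].sum() / (2 * m.sum())
        return ((ss_t - ss_w) / 1) / (ss_w / (n - 2))

    f_obs = pseudo_f(labels)
    count = total = 0
    for members in itertools.combinations(range(n), n1):
        lab = np.full(n, groups[1], dtype=labels.dtype)
        lab[list(members)] = groups[0]
        count += pseudo_f(lab) >= f_obs - 1e-12
        total += 1
    return count / total


class TestPermanova:
    def test_six_sample_exact_matches_enumeration(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(6, 3))
        pts[3:] += 1.2
        d = squareform(pdist(pts))
        labels = np.array(["g1"] * 3 + ["g2"] * 3)
        res = permanova(_square(d), labels, n_permutations=999)
        assert res.method == "exact"
        assert res.n_permutations == 20
        assert res.p == pytest.approx(_bruteforce_permanova_p(d, labels),
                                      abs=1e-12)

    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(7)
        t = _table(rng.integers(0, 40, size=(16, 12)) + 1)
        d = cadmb.bray_curtis(t)
        labels = ["a"] * 8 + ["b"] * 8
        ours = permanova(d, labels, n_permutations=99, seed=0)
        theirs = skbio_permanova(SkbioDM(d.to_numpy(), ids=list(d.index)),
                                 grouping=labels, permutations=9)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"],
                                              abs=1e-9)

    def test_separated_clusters_hit_p_floor(self):
        rng = np.random.default_rng(8)
        pts = np.vstack([rng.normal(0, 0.01, size=(10, 2)),
                         rng.normal(10, 0.01, size=(10, 2))])
        d = squareform(pdist(pts))
        labels = ["a"] * 10 + ["b"] * 10
        res = permanova(_square(d), labels, n_permutations=999, seed=1)
        assert res.method == "permutation"
        assert res.p == pytest.approx(1 / 1000)

    def test_null_rejection_calibrated(self):
        rng = np.random.default_rng(9)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            pts = rng.normal(size=(14, 3))
            d = squareform(pdist(pts))
            labels = np.array(["a"] * 7 + ["b"] * 7)
            rng.shuffle(labels)
            res = permanova(_square(d), labels, n_permutations=99,
                            seed=int(rng.integers(2**31)))
            rejections += res.p <= 0.05
        lo, hi = stats.binom.interval(0.95, n_rep, 0.05)
        assert lo <= rejections <= hi

    def test_r2_invariant_to_sample_order_and_relabeling(self):
        rng = np.random.default_rng(10)
        t = _table(rng.integers(0, 30, size=(12, 10)) + 1)
        d = cadmb.bray_curtis(t)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        base = permanova(d, labels, 99, seed=0).r2
        # swap group names (same partition)
        swapped = np.where(labels == "a", "b", "a")
        assert permanova(d, swapped, 99, seed=0).r2 == pytest.approx(base)
        # reorder samples consistently
        perm = rng.permutation(12)
        d2 = d.iloc[perm, perm]
        assert permanova(d2, labels[perm], 99, seed=0).r2 == pytest.approx(
            base)

    def test_single_group_rejected(self):
        d = _square(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            permanova(d, ["a"] * 4, 99)
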