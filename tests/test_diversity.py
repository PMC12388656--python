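"""Alpha/beta diversity, NMDS, ANOSIM and PERMANOVA."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import permanova as skbio_permanova

import assemblyscape as asc
from assemblyscape import alpha_diversity, anosim, beta_matrix, nmds, permanova
from assemblyscape.datamodel import as_distance_matrix

from conftest import make_table


class TestAlpha:
    def test_closed_form_chao1_goods(self):
        t = make_table([[5, 1, 1, 2]])
        a = alpha_diversity(t)
        assert a["Sobs"].iloc[0] == 4
        assert a["Chao1"].iloc[0] == pytest.approx(4 + 2 * 1 / (2 * 2))
        assert a["Goods_coverage"].iloc[0] == pytest.approx(1 - 2 / 9)

    def test_uniform_counts(self):
        k = 7
        a = alpha_diversity(make_table([[10] * k]))
        assert a["Shannon"].iloc[0] == pytest.approx(np.log(k))
        assert a["Pielou"].iloc[0] == pytest.approx(1.0)

    def test_chao1_equals_sobs_without_singletons(self):
        a = alpha_diversity(make_table([[5, 2, 9, 3]]))
        assert a["Chao1"].iloc[0] == a["Sobs"].iloc[0]

    def test_single_taxon_faith_pd(self, toy_tree):
        t = make_table([[0, 0, 4]], taxa=["A", "B", "C"])
        a = alpha_diversity(t, toy_tree)
        assert a["Shannon"].iloc[0] == 0.0
        # C hangs directly off the root at branch length 2
        assert a["Faith_PD"].iloc[0] == pytest.approx(2.0)


def brute_force_weighted_unifrac(tree, taxa, x, y):
    """Normalized weighted UniFrac by explicit branch enumeration."""
    x = x / x.sum()
    y = y / y.sum()
    rel = dict(zip(taxa, zip(x, y)))
    num = den = 0.0
    for node in tree.traverse(include_self=False):
        names = [t.name for t in node.tips()] or [node.name]
        a = sum(rel[n][0] for n in names if n in rel)
        b = sum(rel[n][1] for n in names if n in rel)
        num += node.length * abs(a - b)
        den += node.length * (a + b)
    return num / den if den else 0.0


class TestBeta:
    def test_identical_samples_zero(self, toy_tree):
        t = make_table([[3, 2, 1], [3, 2, 1]], taxa=["A", "B", "C"])
        assert beta_matrix(t, "bray_curtis")[0, 1] == 0.0
        assert beta_matrix(t, "weighted_unifrac", toy_tree)[0, 1] == \
            pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_bc_one(self):
        t = make_table([[4, 0], [0, 9]])
        assert beta_matrix(t, "bray_curtis")[0, 1] == 1.0

    def test_unifrac_hand_value(self, toy_tree):
        t = make_table([[1, 0, 0], [0, 1, 0]], taxa=["A", "B", "C"])
        wu = beta_matrix(t, "weighted_unifrac", toy_tree)[0, 1]
        # branches: A(1), B(1) differ fully; shared stem(1) and C(2) cancel
        assert wu == pytest.approx(0.5, abs=1e-12)

    def test_unifrac_matches_branch_enumeration(self):
        rng = np.random.default_rng(4)
        tree = asc.simulate_tree(12, seed=5)
        taxa = [t.name for t in tree.tips()]
        counts = rng.integers(0, 20, (5, 12))
        counts[:, 0] += 1
        t = make_table(counts, taxa=taxa)
        wu = beta_matrix(t, "weighted_unifrac", tree)
        for i in range(5):
            for j in range(i + 1, 5):
                ref = brute_force_weighted_unifrac(
                    tree, taxa, counts[i].astype(float),
                    counts[j].astype(float))
                assert wu[i, j] == pytest.approx(ref, abs=1e-12)

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(8)
        t = make_table(rng.integers(0, 30, (6, 15)) + 1)
        dm = beta_matrix(t, "bray_curtis")
        assert (dm.data >= 0).all() and (dm.data <= 1).all()
        assert np.allclose(dm.data, dm.data.T)


class TestNMDS:
    def test_embeddable_input_low_stress(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 2))
        dm = as_distance_matrix(
            np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)),
            [f"p{i}" for i in range(12)])
        _, stress = nmds(dm, k=2, seed=1)
        assert stress < 0.01

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        dm = as_distance_matrix(
            np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)),
            [f"p{i}" for i in range(10)])
        c1, s1 = nmds(dm, seed=4)
        c2, s2 = nmds(dm, seed=4)
        assert s1 == s2
        assert np.array_equal(c1.to_numpy(), c2.to_numpy())

    def test_unit_square_rank_recovery(self):
        """A perfectly 2-D metric is recovered with the exact distance ranks."""
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = as_distance_matrix(d, list("abcd"))
        coords, stress = nmds(dm, k=2, n_starts=8, seed=0)
        emb = coords.to_numpy()
        d_emb = np.sqrt(((emb[:, None] - emb[None]) ** 2).sum(-1))
        iu = np.triu_indices(4, k=1)
        # the two diagonals must out-rank every edge (ties within each
        # group make a full rank comparison ill-posed)
        edges = d[iu] < np.sqrt(2) - 1e-9
        assert d_emb[iu][~edges].min() > d_emb[iu][edges].max()
        assert stress < 0.01

    def test_k_too_large(self):
        dm = as_distance_matrix(np.array([[0, 1], [1, 0.0]]), ["a", "b"])
        with pytest.raises(ValueError):
            nmds(dm, k=2)


def _two_group_dm(within, between, n_per=4):
    n = 2 * n_per
    d = np.full((n, n), between, dtype=float)
    d[:n_per, :n_per] = within
    d[n_per:, n_per:] = within
    np.fill_diagonal(d, 0.0)
    ids = [f"s{i}" for i in range(n)]
    groups = pd.Series(["a"] * n_per + ["b"] * n_per, index=ids)
    return as_distance_matrix(d, ids), groups


class TestGroupTests:
    def test_anosim_perfect_separation(self):
        dm, g = _two_group_dm(0.1, 0.9)
        r, p = anosim(dm, g, n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_anosim_degenerate_ties(self):
        dm, g = _two_group_dm(0.5, 0.5)
        with pytest.warns(UserWarning):
            r, p = anosim(dm, g, n_perm=99, seed=0)
        assert r == 0.0

    def test_permanova_hand_computed_toy(self):
        """4 samples, 2 groups, within=0.1, between=0.9: SS partitions by hand.

        SS_total = sum d^2 / n = (2*0.01 + 4*0.81)/4 = 0.815;
        SS_within = 0.01/2 + 0.01/2 = 0.01; F = 0.805/1 / (0.01/2) = 161.
        """
        dm, g = _two_group_dm(0.1, 0.9, n_per=2)
        f, r2, _ = permanova(dm, g, n_perm=99, seed=0)
        assert f == pytest.approx(161.0, abs=1e-9)
        assert r2 == pytest.approx(0.805 / 0.815, abs=1e-12)

    def test_permanova_perfect_partition(self):
        dm, g = _two_group_dm(0.0, 0.7, n_per=3)
        f, r2, p = permanova(dm, g, n_perm=99, seed=0)
        assert r2 == pytest.approx(1.0)

    def test_matches_skbio_statistics(self):
        """Cross-check observed R and pseudo-F against scikit-bio."""
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 4))
        pts[6:] += 1.0
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(12)]
        dm = as_distance_matrix(d, ids)
        g = pd.Series(["a"] * 6 + ["b"] * 6, index=ids, name="group")
        r, _ = anosim(dm, g, n_perm=99, seed=0)
        f, _, _ = permanova(dm, g, n_perm=99, seed=0)
        skdm = DistanceMatrix(d, ids)
        ref_r = skbio_anosim(skdm, list(g), permutations=0)["test statistic"]
        ref_f = skbio_permanova(skdm, list(g),
                                permutations=0)["test statistic"]
        assert r == pytest.approx(ref_r, abs=1e-10)
        assert f == pytest.approx(ref_f, abs=1e-10)

    def test_relabeling_invariance(self):
        dm, g = _two_group_dm(0.2, 0.6)
        g2 = g.map({"a": "group_zebra", "b": "group_ant"})
        r1, p1 = anosim(dm, g, n_perm=199, seed=3)
        r2, p2 = anosim(dm, g2, n_perm=199, seed=3)
        assert (r1, p1) == (r2, p2)
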