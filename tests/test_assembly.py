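"""βMNTD, βNTI, RC-bray and the five-process classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

import assemblyscape as asc
from assemblyscape import beta_mntd, beta_nti, classify_pair, classify_processes, rc_bray
from assemblyscape.assembly import PROCESSES
from assemblyscape.datamodel import patristic_distances

from conftest import make_table


def brute_beta_mntd(counts, dist, weighted=True):
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    out = np.zeros((n, n))
    for k in range(n):
        for l in range(n):
            if k == l:
                continue
            ik = np.flatnonzero(counts[k] > 0)
            il = np.flatnonzero(counts[l] > 0)
            if weighted:
                fk = counts[k] / counts[k].sum()
                fl = counts[l] / counts[l].sum()
            else:
                fk = (counts[k] > 0) / (counts[k] > 0).sum()
                fl = (counts[l] > 0) / (counts[l] > 0).sum()
            s1 = sum(fk[i] * min(dist[i, j] for j in il) for i in ik)
            s2 = sum(fl[j] * min(dist[j, i] for i in ik) for j in il)
            out[k, l] = 0.5 * (s1 + s2)
    return out


class TestBetaMNTD:
    def test_identical_communities_zero(self, toy_tree):
        t = make_table([[2, 1, 3], [2, 1, 3]], taxa=["A", "B", "C"])
        assert beta_mntd(t, toy_tree).iloc[0, 1] == 0.0

    def test_hand_value_single_taxon_pair(self, toy_tree):
        t = make_table([[1, 0, 0], [0, 0, 1]], taxa=["A", "B", "C"])
        # d(A, C) = 1 + 1 + 2 = 4 in both directions
        assert beta_mntd(t, toy_tree).iloc[0, 1] == pytest.approx(4.0)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_bruteforce(self, weighted):
        rng = np.random.default_rng(0)
        for rep in range(10):
            n_taxa = int(rng.integers(3, 7))
            tree = asc.simulate_tree(n_taxa, seed=100 + rep)
            taxa = [t.name for t in tree.tips()]
            counts = rng.integers(0, 6, (4, n_taxa))
            counts[counts.sum(axis=1) == 0, 0] = 1
            t = make_table(counts, taxa=taxa)
            d = patristic_distances(tree, taxa)
            got = beta_mntd(t, tree, weighted=weighted).to_numpy()
            ref = brute_beta_mntd(counts, d, weighted=weighted)
            assert np.abs(got - ref).max() < 1e-10


class TestBetaNTI:
    def test_star_tree_degenerate_nan(self):
        root = TreeNode(name=None)
        root.extend([TreeNode(name=n, length=1.0) for n in "ABCD"])
        t = make_table([[1, 2, 0, 0], [0, 0, 3, 1], [1, 0, 1, 0]],
                       taxa=list("ABCD"))
        with pytest.warns(UserWarning, match="sd is zero"):
            z = beta_nti(t, root, n_null=99, seed=0)
        off = z.to_numpy()[np.triu_indices(3, k=1)]
        assert np.isnan(off).all()

    def test_low_n_null_rejected(self, toy_tree):
        t = make_table([[1, 1, 0], [0, 1, 1]], taxa=["A", "B", "C"])
        with pytest.raises(ValueError):
            beta_nti(t, toy_tree, n_null=10)

    def test_deterministic(self):
        tree = asc.simulate_tree(30, seed=1)
        rng = np.random.default_rng(2)
        t = make_table(rng.integers(0, 10, (5, 30)) + (rng.random((5, 30)) < 0.3),
                       taxa=[x.name for x in tree.tips()])
        a = beta_nti(t, tree, n_null=99, seed=5).to_numpy()
        b = beta_nti(t, tree, n_null=99, seed=5).to_numpy()
        assert np.array_equal(a, b, equal_nan=True)


class TestRCBray:
    def test_identical_rare_samples_rc_minus_one(self):
        # two identical samples of regionally rare taxa: observed BC = 0,
        # null pairs differ almost surely -> RC pinned at -1
        counts = np.zeros((6, 10), dtype=int)
        counts[0, :3] = [40, 30, 30]
        counts[1, :3] = [40, 30, 30]
        for i in range(2, 6):
            counts[i, 3:] = np.random.default_rng(i).multinomial(
                100, np.ones(7) / 7)
        t = make_table(counts)
        rc = rc_bray(t, n_null=199, seed=1)
        assert rc.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_exhaustive_enumeration(self):
        """Richness-1, reads-1 toy: the null space enumerates exactly.

        Each null community is one taxon drawn with probability proportional
        to occupancy; the pair's null Bray-Curtis is 0 (same taxon) or 1.
        """
        counts = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 0, 0]])
        t = make_table(counts)
        occ = (counts > 0).mean(axis=0)
        w = occ / occ.sum()
        rng = np.random.default_rng(0)
        rc = rc_bray(t, n_null=9999, seed=3)
        p_same = (w ** 2).sum()  # P(null pair draws the same taxon)
        for i, j in itertools.combinations(range(4), 2):
            obs_same = (counts[i] == counts[j]).all()
            if obs_same:  # obs BC = 0: nulls are never smaller
                expected = 2 * (0.5 * p_same) - 1
            else:         # obs BC = 1: ties at 1, smaller at 0
                expected = 2 * (p_same + 0.5 * (1 - p_same)) - 1
            assert rc.iloc[i, j] == pytest.approx(expected, abs=0.02)

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(9)
        t = make_table(rng.integers(0, 12, (6, 20)) + 1)
        rc = rc_bray(t, n_null=199, seed=2).to_numpy()
        assert np.allclose(rc, rc.T)
        assert (rc >= -1).all() and (rc <= 1).all()


class TestClassification:
    @pytest.mark.parametrize("bnti,rc,expected", [
        (-3.0, 0.99, "homogeneous_selection"),
        (-3.0, -0.99, "homogeneous_selection"),
        (3.0, 0.0, "variable_selection"),
        (0.0, 0.96, "dispersal_limitation"),
        (0.0, -0.96, "homogeneous_dispersal"),
        (0.0, 0.0, "drift"),
        # boundary values fall to the stochastic / drift side
        (-2.0, 0.0, "drift"),
        (2.0, 0.0, "drift"),
        (0.0, 0.95, "drift"),
        (0.0, -0.95, "drift"),
    ])
    def test_threshold_logic(self, bnti, rc, expected):
        assert classify_pair(bnti, rc) == expected

    def test_fractions_sum_to_one_and_grouping(self):
        ids = [f"s{i}" for i in range(6)]
        rng = np.random.default_rng(4)
        z = rng.normal(0, 3, (6, 6))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        r = np.clip((rng.random((6, 6)) * 2 - 1), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0)
        bnti = pd.DataFrame(z, index=ids, columns=ids)
        rc = pd.DataFrame(r, index=ids, columns=ids)
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=ids)
        res = classify_processes(bnti, rc, groups=groups)
        assert np.allclose(res.fractions.sum(axis=1), 1.0, atol=1e-12)
        assert len(res.pairs) == 6  # 3 within-group pairs per group
        assert set(res.fractions.columns) == set(PROCESSES)

    def test_nan_pairs_excluded_and_counted(self):
        ids = ["a", "b", "c"]
        z = pd.DataFrame([[0, np.nan, 1], [np.nan, 0, -3], [1, -3, 0]],
                         index=ids, columns=ids, dtype=float)
        r = pd.DataFrame(np.zeros((3, 3)), index=ids, columns=ids)
        with pytest.warns(UserWarning, match="excluded"):
            res = classify_processes(z, r)
        assert res.n_excluded == 1
        assert len(res.pairs) == 2
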