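from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from scipy.spatial.distance import squareform
from skbio import TreeNode

from micropod.diversity import (
    DistanceMatrix,
    ace_index,
    ace_index_full,
    bray_curtis,
    compare_groups,
    observed_otus,
    rarefy,
    unifrac,
)
from micropod.otu_io import OtuTable, OtuTableError


# ---------------------------------------------------------------------------
# independent oracles


def ace_oracle(counts, thr=10):
    """Symbolic substitution of the ACE closed form with exact fractions."""
    counts = [c for c in counts if c > 0]
    abund = [c for c in counts if c > thr]
    rare = [c for c in counts if c <= thr]
    if not rare:
        return float(len(abund))
    s_rare, n_rare = len(rare), sum(rare)
    f = {i: sum(1 for c in rare if c == i) for i in range(1, thr + 1)}
    c_ace = 1 - Fraction(f[1], n_rare)
    assert c_ace > 0
    gamma2 = max(
        Fraction(s_rare, 1) / c_ace
        * Fraction(sum(i * (i - 1) * f[i] for i in f), n_rare * (n_rare - 1))
        - 1,
        Fraction(0),
    )
    return float(len(abund) + Fraction(s_rare, 1) / c_ace
                 + Fraction(f[1], 1) / c_ace * gamma2)


def mannwhitney_exact_oracle(x, y):
    """Two-sided exact p by full enumeration of label arrangements."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}

    def u_of(idx):
        r1 = sum(ranks[pooled[i]] for i in idx)
        u1 = r1 - n1 * (n1 + 1) / 2
        return min(u1, len(x) * len(y) - u1)

    obs = u_of(range(n1))
    total = count = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        if u_of(idx) <= obs + 1e-9:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# alpha diversity


class TestObserved:
    def test_simple(self):
        assert observed_otus([5, 0, 1, 0]) == 2

    def test_all_positive(self):
        assert observed_otus(np.arange(1, 11)) == 10

    def test_zero_vector_rejected_upstream(self):
        with pytest.raises(OtuTableError):
            OtuTable(["s"], ["a"], np.array([[0]]))


class TestAce:
    def test_no_rare_equals_observed(self):
        assert ace_index([11, 20, 100]) == 3.0

    def test_hand_evaluated_closed_form(self):
        counts = [1, 1, 2, 3, 11, 20]
        # S_abund=2, S_rare=4, N_rare=7, F1=2, C=5/7, gamma^2=1/15:
        # ACE = 2 + 28/5 + (14/5)(1/15) = 7.78666...
        expected = 2 + Fraction(28, 5) + Fraction(14, 5) * Fraction(1, 15)
        assert ace_index(counts) == pytest.approx(float(expected), abs=1e-12)
        assert ace_index(counts) == pytest.approx(ace_oracle(counts), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 40, size=12)
        if np.all(counts[counts <= 10] == 1) and np.any(counts <= 10):
            counts[0] = 2  # keep the estimator in its defined regime
        assert ace_index(counts) == pytest.approx(ace_oracle(counts), rel=1e-12)

    def test_duplicated_counts_against_oracle(self):
        counts = [1, 1, 2, 3, 11, 20]
        doubled = counts + counts
        assert ace_index(doubled) == pytest.approx(ace_oracle(doubled), rel=1e-12)

    def test_singleton_only_fallback_flagged(self):
        val, flagged = ace_index_full([1, 1, 1, 42])
        assert flagged
        assert val == pytest.approx(4 + 3 * 2 / 2.0)  # Chao1 bias-corrected

    def test_ace_at_least_abundant_count(self):
        counts = [1, 2, 5, 11, 13, 40]
        assert ace_index(counts) >= 3  # S_abund = 3


class TestCompareGroups:
    def test_exact_small_sample(self):
        res = compare_groups([1, 2, 3, 4, 5, 6],
                             ["a", "a", "a", "b", "b", "b"], "two-group")
        assert res["statistic"] == 0.0
        assert res["p"] == pytest.approx(0.1, abs=1e-12)
        assert res["method"] == "mann-whitney-exact"

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.choice(1000, size=4, replace=False).tolist()
            y = rng.choice(np.arange(1000, 2000), size=5, replace=False).tolist()
            res = compare_groups(x + y, ["a"] * 4 + ["b"] * 5, "two-group")
            assert res["p"] == pytest.approx(
                mannwhitney_exact_oracle(x, y), abs=1e-12)

    def test_identical_groups_p_one(self):
        vals = list(range(10)) * 2
        labels = ["a"] * 10 + ["b"] * 10
        assert compare_groups(vals, labels, "two-group")["p"] > 0.9

    def test_ties_force_asymptotic(self):
        res = compare_groups([1, 1, 2, 3], ["a", "a", "b", "b"], "two-group")
        assert res["method"] == "mann-whitney-asymptotic"

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2, 3], ["a", "a", "a"], "two-group")

    def test_kruskal_multigroup(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=30)
        labels = np.repeat(["a", "b", "c"], 10)
        res = compare_groups(vals, labels, "multi-group")
        assert res["method"] == "kruskal-wallis"
        assert 0 <= res["p"] <= 1

    def test_kruskal_null_calibration(self):
        # three groups from one distribution: rejection rate near alpha
        rng = np.random.default_rng(42)
        labels = np.repeat(["a", "b", "c"], 8)
        rejections = sum(
            compare_groups(rng.normal(size=24), labels, "multi-group")["p"] < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07


# ---------------------------------------------------------------------------
# beta diversity


class TestBrayCurtis:
    def test_identical_zero(self):
        t = OtuTable(["a", "b"], ["x", "y"], np.array([[3, 4], [3, 4]]))
        assert bray_curtis(t).values[0, 1] == 0.0

    def test_disjoint_one(self):
        t = OtuTable(["a", "b"], ["x", "y"], np.array([[2, 0], [0, 2]]))
        assert bray_curtis(t).values[0, 1] == 1.0

    def test_range_and_axioms(self, small_cohort):
        dm = bray_curtis(small_cohort[0])
        v = dm.values
        assert np.all(v >= 0) and np.all(v <= 1)
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 0)


def _newick(s):
    return TreeNode.read([s])


def unifrac_oracle(table, tree, weighted, normalized):
    """Brute-force per-branch summation straight from the definition."""
    tips_below = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            tips_below[id(node)] = {node.name}
        else:
            s = set()
            for c in node.children:
                s |= tips_below[id(c)]
            tips_below[id(node)] = s
    branches = [(node.length or 0.0, tips_below[id(node)])
                for node in tree.postorder(include_self=False)]
    pos = {o: j for j, o in enumerate(table.otu_ids)}
    n = table.n_samples
    out = np.zeros((n, n))
    totals = table.counts.sum(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            if weighted:
                num = den = 0.0
                for b, tips in branches:
                    pa = sum(table.counts[i, pos[t]] for t in tips if t in pos) / totals[i]
                    pb = sum(table.counts[j, pos[t]] for t in tips if t in pos) / totals[j]
                    num += b * abs(pa - pb)
                    den += b * (pa + pb)
                out[i, j] = out[j, i] = (num / den if normalized and den > 0
                                         else num)
            else:
                uniq = shared = 0.0
                for b, tips in branches:
                    ina = any(table.counts[i, pos[t]] > 0 for t in tips if t in pos)
                    inb = any(table.counts[j, pos[t]] > 0 for t in tips if t in pos)
                    if ina != inb:
                        uniq += b
                    if ina or inb:
                        shared += b
                out[i, j] = out[j, i] = uniq / shared if shared else 0.0
    return out


class TestUnifrac:
    def test_identical_samples_zero(self):
        tree = _newick("((a:1,b:2):0.5,(c:1,d:1):0.5):0;")
        t = OtuTable(["s1", "s2"], list("abcd"),
                     np.array([[1, 2, 3, 4], [1, 2, 3, 4]]))
        for w in (True, False):
            assert unifrac(t, tree, weighted=w).values[0, 1] == pytest.approx(0.0)

    def test_disjoint_subtrees_unweighted_one(self):
        tree = _newick("((a:1,b:2):0.5,(c:1,d:1):0.5):0;")
        t = OtuTable(["s1", "s2"], list("abcd"),
                     np.array([[3, 1, 0, 0], [0, 0, 2, 5]]))
        assert unifrac(t, tree, weighted=False).values[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("weighted,normalized",
                             [(False, False), (True, False), (True, True)])
    def test_against_bruteforce_oracle(self, weighted, normalized):
        tree = _newick("((a:0.3,b:0.7):0.25,(c:1.1,(d:0.4,e:0.2):0.6):0.15):0;")
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 30, size=(4, 5))
        counts[:, 0] += 1
        t = OtuTable([f"s{i}" for i in range(4)], list("abcde"), counts)
        got = unifrac(t, tree, weighted=weighted, normalized=normalized)
        want = unifrac_oracle(t, tree, weighted, normalized)
        np.testing.assert_allclose(got.values, want, atol=1e-12)

    def test_unweighted_invariant_to_magnitude(self):
        tree = _newick("((a:1,b:2):0.5,(c:1,d:1):0.5):0;")
        t1 = OtuTable(["s1", "s2"], list("abcd"),
                      np.array([[1, 0, 2, 0], [0, 3, 1, 1]]))
        t2 = OtuTable(["s1", "s2"], list("abcd"),
                      np.array([[9, 0, 70, 0], [0, 1, 40, 17]]))
        np.testing.assert_allclose(unifrac(t1, tree, weighted=False).values,
                                   unifrac(t2, tree, weighted=False).values)

    def test_weighted_normalized_scale_invariance(self):
        tree = _newick("((a:1,b:2):0.5,(c:1,d:1):0.5):0;")
        t1 = OtuTable(["s1", "s2"], list("abcd"),
                      np.array([[1, 2, 3, 4], [4, 3, 2, 1]]))
        t2 = OtuTable(["s1", "s2"], list("abcd"),
                      np.array([[10, 20, 30, 40], [4, 3, 2, 1]]))
        np.testing.assert_allclose(
            unifrac(t1, tree, weighted=True, normalized=True).values,
            unifrac(t2, tree, weighted=True, normalized=True).values,
            atol=1e-12)

    def test_missing_otu_error_lists_ids(self):
        tree = _newick("(a:1,b:1):0;")
        t = OtuTable(["s1", "s2"], ["a", "zz"], np.array([[1, 1], [2, 1]]))
        with pytest.raises(OtuTableError, match="zz"):
            unifrac(t, tree)

    def test_unweighted_in_unit_interval(self, small_cohort):
        table, _, tree, _ = small_cohort
        sub = table.select_samples(table.sample_ids[:6])
        v = unifrac(sub, tree, weighted=False).values
        assert np.all(v >= 0) and np.all(v <= 1 + 1e-12)


class TestDistanceMatrix:
    def test_asymmetry_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[1, 1], [1, 0]]))

    def test_tsv_round_trip(self, tmp_path):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.4], [0.4, 0.0]]))
        p = tmp_path / "d.tsv"
        dm.write_tsv(p)
        again = DistanceMatrix.read_tsv(p)
        np.testing.assert_allclose(again.values, dm.values)


def test_rarefy_equal_depths(small_cohort):
    table = small_cohort[0]
    depth = int(table.sample_totals().min())
    r = rarefy(table, depth, seed=0)
    assert np.all(r.sample_totals() == depth)
    assert np.all(r.counts <= table.counts.max())
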