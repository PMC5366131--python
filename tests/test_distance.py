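import io

import numpy as np
import pandas as pd
import pytest
import skbio

from mbtraj.core import ValidationError, to_fractional
from mbtraj.distance import (
    _l1_fit,
    inter_subject_distance_series,
    jensen_shannon_distance,
    jsd_matrix,
    median_regression_trend,
    unifrac,
)


def read_tree(newick: str) -> skbio.TreeNode:
    return skbio.TreeNode.read(io.StringIO(newick))


def unifrac_oracle(a, b, otu_ids, tree, weighted=False):
    """Exhaustive branch enumeration: for every branch, collect its
    descendant tips and accumulate the UniFrac sums directly."""
    a = dict(zip(otu_ids, np.asarray(a, dtype=float)))
    b = dict(zip(otu_ids, np.asarray(b, dtype=float)))
    ta, tb = sum(a.values()), sum(b.values())
    num = den = 0.0
    wnum = wden = 0.0
    for node in tree.traverse(include_self=False):
        L = node.length or 0.0
        tips = [t.name for t in node.tips()] or [node.name]
        in_a = any(a.get(t, 0) > 0 for t in tips)
        in_b = any(b.get(t, 0) > 0 for t in tips)
        if in_a or in_b:
            den += L
            if in_a != in_b:
                num += L
        fa = sum(a.get(t, 0) for t in tips) / ta
        fb = sum(b.get(t, 0) for t in tips) / tb
        wnum += L * abs(fa - fb)
        wden += L * (fa + fb)
    return (wnum / wden) if weighted else (num / den)


class TestJensenShannon:
    def test_identity(self):
        assert jensen_shannon_distance([0.2, 0.8], [0.2, 0.8]) == 0.0

    def test_disjoint_supports_max_one(self):
        assert jensen_shannon_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_direct_kl_evaluation(self):
        d = jensen_shannon_distance([0.5, 0.5, 0], [0, 0.5, 0.5])
        assert d == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_metric_properties_on_random_triples(self, rng):
        x = rng.dirichlet(np.ones(5), size=300)
        for _ in range(1000):
            i, j, k = rng.integers(0, 300, size=3)
            dij = jensen_shannon_distance(x[i], x[j])
            dji = jensen_shannon_distance(x[j], x[i])
            assert dij == pytest.approx(dji, abs=1e-12)
            dik = jensen_shannon_distance(x[i], x[k])
            dkj = jensen_shannon_distance(x[k], x[j])
            assert dij <= dik + dkj + 1e-12

    def test_matrix_matches_pairwise(self, rng):
        x = rng.dirichlet(np.ones(4), size=5)
        df = pd.DataFrame(x, index=[f"s{i}" for i in range(5)])
        dm = jsd_matrix(df)
        for i in range(5):
            for j in range(5):
                assert dm[i, j] == pytest.approx(
                    jensen_shannon_distance(x[i], x[j]), abs=1e-9)


class TestUniFrac:
    tree4 = "((A:1,B:1):1,(C:1,D:1):1):0;"

    def test_identity(self):
        tree = read_tree(self.tree4)
        v = np.array([0.5, 0.5, 0.0, 0.0])
        ids = list("ABCD")
        assert unifrac(v, v, tree, ids) == 0.0
        assert unifrac(v, v, tree, ids, weighted=True) == 0.0

    def test_star_tree_disjoint_max(self):
        tree = read_tree("(A:1,B:1,C:1,D:1):0;")
        a = np.array([1.0, 1.0, 0, 0])
        b = np.array([0, 0, 1.0, 1.0])
        assert unifrac(a, b, tree, list("ABCD")) == pytest.approx(1.0)

    def test_four_leaf_disjoint_clades(self):
        tree = read_tree(self.tree4)
        a = np.array([1.0, 0, 0, 0])
        b = np.array([0, 0, 1.0, 0])
        assert unifrac(a, b, tree, list("ABCD")) == pytest.approx(1.0)

    def test_matches_branch_enumeration_oracle(self, rng):
        tree = read_tree("((A:0.5,B:1.2):0.3,((C:1,D:0.7):0.4,E:2):0.1):0;")
        ids = list("ABCDE")
        for _ in range(25):
            a = rng.random(5) * (rng.random(5) > 0.3)
            b = rng.random(5) * (rng.random(5) > 0.3)
            if a.sum() == 0 or b.sum() == 0:
                continue
            a, b = a / a.sum(), b / b.sum()
            assert unifrac(a, b, tree, ids) == pytest.approx(
                unifrac_oracle(a, b, ids, tree), abs=1e-9)
            assert unifrac(a, b, tree, ids, weighted=True) == pytest.approx(
                unifrac_oracle(a, b, ids, tree, weighted=True), abs=1e-9)

    def test_unweighted_agrees_with_skbio_on_presence(self, rng):
        from skbio.diversity.beta import unweighted_unifrac

        tree = read_tree("((A:0.5,B:1.2):0.3,((C:1,D:0.7):0.4,E:2):0.1):0;")
        ids = list("ABCDE")
        for _ in range(10):
            a = (rng.random(5) > 0.4).astype(int)
            b = (rng.random(5) > 0.4).astype(int)
            if a.sum() == 0 or b.sum() == 0:
                continue
            assert unifrac(a, b, tree, ids) == pytest.approx(
                float(unweighted_unifrac(a, b, ids, tree)), abs=1e-12)

    def test_weighted_zero_iff_identical(self, rng):
        tree = read_tree(self.tree4)
        ids = list("ABCD")
        v = rng.dirichlet(np.ones(4))
        assert unifrac(v, v, tree, ids, weighted=True) == pytest.approx(0.0, abs=1e-12)
        w = rng.dirichlet(np.ones(4))
        assert unifrac(v, w, tree, ids, weighted=True) > 1e-6

    def test_unweighted_scale_invariance(self, rng):
        tree = read_tree(self.tree4)
        ids = list("ABCD")
        a = np.array([0.7, 0.3, 0, 0])
        b = np.array([0.2, 0, 0.8, 0])
        assert unifrac(a, b, tree, ids) == pytest.approx(
            unifrac(a * 100, b * 0.01, tree, ids))

    def test_missing_leaf_listed(self):
        tree = read_tree(self.tree4)
        a = np.array([0.5, 0.5])
        with pytest.raises(ValidationError, match="ZZZ"):
            unifrac(a, a, tree, ["A", "ZZZ"])


class TestInterSubjectSeries:
    def test_pair_counts(self, small_cohort, small_fractional):
        series = inter_subject_distance_series(
            small_fractional, small_cohort.metadata, metric="jsd")
        assert len(series) == len(set(small_cohort.metadata["day"]))
        for _, dists in series:
            assert len(dists) == 3  # C(3,2)

    def test_convergent_cohort_trends_downward(self):
        from mbtraj.simulate import CohortSpec, generate_cohort

        spec = CohortSpec(n_subjects=4, n_otus=90, regimes_per_subject=1,
                          day_grid=tuple(range(0, 520, 30)),
                          depth_range=(4000, 8000), injection_events=[],
                          convergence_rate=2e-4,
                          return_to_initial_subjects=(), seed=21)
        c = generate_cohort(spec)
        series = inter_subject_distance_series(
            to_fractional(c.table), c.metadata, metric="unifrac-u",
            tree=c.tree)
        days = [d for d, _ in series]
        med = [np.median(v) for _, v in series]
        from scipy.stats import spearmanr
        rho, _ = spearmanr(days, med)
        assert rho < 0


class TestMedianRegressionTrend:
    def test_noiseless_line_recovered_exactly(self):
        days = np.arange(0, 120, 10, dtype=float)
        y = 3 - 0.01 * days
        res = median_regression_trend((days, y), n_boot=199, seed=1)
        assert res.slope == pytest.approx(-0.01, abs=1e-12)
        assert res.p_value <= 2 / (199 + 1) + 1e-12

    def test_l1_objective_beats_all_pairwise_lines(self, rng):
        x = rng.random(12) * 100
        y = rng.random(12)
        b, a = _l1_fit(x, y)
        obj = np.abs(y - a - b * x).sum()
        for i in range(12):
            for j in range(i + 1, 12):
                if x[i] == x[j]:
                    continue
                bb = (y[j] - y[i]) / (x[j] - x[i])
                aa = y[i] - bb * x[i]
                assert obj <= np.abs(y - aa - bb * x).sum() + 1e-9

    def test_slope_equivariant_under_y_scaling(self, rng):
        x = np.arange(15, dtype=float)
        y = rng.random(15)
        b1, _ = _l1_fit(x, y)
        b2, _ = _l1_fit(x, 5.0 * y)
        assert b2 == pytest.approx(5.0 * b1, rel=1e-9)

    def test_null_calibration_small(self, rng):
        """Smaller version of the full null calibration (acceptance suite
        runs 200 reps at n_boot=999)."""
        hits = 0
        reps = 40
        for rep in range(reps):
            x = np.tile(np.arange(10, dtype=float), 2)
            y = rng.random(20)
            res = median_regression_trend((x, y), n_boot=199, seed=rep)
            hits += res.p_value < 0.05
        assert hits / reps <= 0.15

    def test_single_day_rejected(self):
        with pytest.raises(ValidationError, match="single"):
            median_regression_trend(
                (np.ones(12), np.random.default_rng(0).random(12)),
                n_boot=199, seed=0)
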