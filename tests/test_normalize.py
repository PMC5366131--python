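import itertools

import numpy as np
import pandas as pd
import pytest

from mbtraj.core import ValidationError
from mbtraj.distance import _jsd_fast
from mbtraj.normalize import (
    HighAbundanceSet,
    SubjectSeries,
    horizon_transform,
    reference_normalize,
    select_high_abundance,
    shared_otu_sets,
    weighted_median,
)


def make_series(rows, days=None, subject="X"):
    df = pd.DataFrame(
        np.asarray(rows, dtype=float),
        index=[f"s{i}" for i in range(len(rows))],
        columns=[f"O{j}" for j in range(len(rows[0]))],
    )
    df = df.div(df.sum(axis=1), axis=0)
    days = days if days is not None else list(range(len(rows)))
    return SubjectSeries(subject, df, np.asarray(days), ["confinement"] * len(rows))


class TestSelectHighAbundance:
    def test_cumulative_rule(self):
        s = make_series([[0.6, 0.3, 0.1]] * 4)
        h = select_high_abundance(s)
        assert h.otu_ids == ["O0", "O1"]
        assert h.coverage == pytest.approx(0.9)

    def test_single_otu(self):
        s = make_series([[1.0]] * 4)
        h = select_high_abundance(s)
        assert h.otu_ids == ["O0"] and h.coverage == 1.0

    def test_matches_brute_force_prefix_oracle(self, rng):
        for _ in range(20):
            x = rng.dirichlet(np.ones(20) * 0.5, size=6)
            s = make_series(x)
            h = select_high_abundance(s)
            # oracle: enumerate all prefixes of the median-ranked order
            med = s.data.median(axis=0)
            order = sorted(med.index, key=lambda o: (-med[o], o))
            total = med.sum()
            best = None
            for k in range(1, len(order) + 1):
                if med[order[:k]].sum() >= 0.9 * total - 1e-12:
                    best = order[:k]
                    break
            assert h.otu_ids == best
            # minimality: one fewer OTU drops below the threshold
            if len(best) > 1:
                assert med[best[:-1]].sum() < 0.9 * total

    def test_all_zero_rejected(self):
        df = pd.DataFrame(np.zeros((4, 3)), index=list("abcd"),
                          columns=["x", "y", "z"])
        s = SubjectSeries.__new__(SubjectSeries)
        s.subject_id, s.data = "X", df
        s.days = np.arange(4)
        s.phases = ["pre"] * 4
        with pytest.raises(ValidationError):
            select_high_abundance(s)


class TestWeightedMedian:
    @pytest.mark.parametrize("values,weights,expected", [
        ((1, 2, 3), (1, 1, 1), 2),          # reduces to the median
        ((1, 2, 10), (0.1, 0.2, 0.7), 10),  # cumulative rule direct eval
        ((7.5,), (1,), 7.5),                # degenerate single value
        ((3, 1, 2), (1, 1, 1), 2),          # order-independent
    ])
    def test_cumulative_weight_rule(self, values, weights, expected):
        assert weighted_median(values, weights) == expected

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValidationError):
            weighted_median([1, 2], [0, 0])


def _reference_normalize_oracle(data: np.ndarray):
    """Straight-line re-implementation: JSD weights, weighted median
    reference, median-of-ratios scale."""
    frac = data / data.sum(axis=1, keepdims=True)
    n, m = data.shape
    refs = np.zeros((n, m))
    scales = np.zeros(n)
    out = np.zeros((n, m))
    for s in range(n):
        w = np.array([(1 - _jsd_fast(frac[t], frac[s])) ** 2 for t in range(n)])
        for o in range(m):
            pairs = sorted(zip(data[:, o], w))
            cum, half = 0.0, 0.5 * w.sum()
            for v, wt in pairs:
                cum += wt
                if cum >= half - 1e-12 * w.sum():
                    refs[s, o] = v
                    break
        both = (refs[s] > 0) & (data[s] > 0)
        scales[s] = np.median(refs[s][both] / data[s][both])
        out[s] = scales[s] * data[s]
    return out, refs, scales


class TestReferenceNormalize:
    def test_identical_samples_fixed_point(self):
        s = make_series([[0.5, 0.3, 0.2]] * 6)
        h = select_high_abundance(s)
        r = reference_normalize(s, h)
        assert np.allclose(r.scale_factors, 1.0)
        assert np.allclose(r.normalized, s.data[h.otu_ids])
        assert np.allclose(r.weights, 1.0)

    def test_outlier_reference_is_majority_profile(self):
        rows = [[0.5, 0.3, 0.2]] * 9 + [[0.05, 0.05, 0.9]]
        s = make_series(rows)
        h = HighAbundanceSet("X", ["O0", "O1", "O2"], 1.0)
        r = reference_normalize(s, h)
        assert np.allclose(r.references.iloc[-1], [0.5, 0.3, 0.2], atol=1e-9)

    def test_matches_independent_reimplementation(self, rng):
        x = rng.dirichlet(np.ones(8), size=7)
        s = make_series(x)
        h = HighAbundanceSet("X", list(s.data.columns), 1.0)
        r = reference_normalize(s, h)
        out, refs, scales = _reference_normalize_oracle(s.data.to_numpy())
        assert np.allclose(r.normalized.to_numpy(), out)
        assert np.allclose(r.references.to_numpy(), refs)
        assert np.allclose(r.scale_factors.to_numpy(), scales)

    def test_commutes_with_otu_relabeling(self, rng):
        x = rng.dirichlet(np.ones(6), size=6)
        s = make_series(x)
        h = HighAbundanceSet("X", list(s.data.columns), 1.0)
        r1 = reference_normalize(s, h)
        perm = list(rng.permutation(s.data.columns))
        s2 = SubjectSeries("X", s.data[perm], s.days, s.phases)
        r2 = reference_normalize(s2, HighAbundanceSet("X", perm, 1.0))
        assert np.allclose(r1.normalized[perm].to_numpy(),
                           r2.normalized.to_numpy())

    def test_weights_bounds_and_identity(self, rng):
        x = rng.dirichlet(np.ones(6), size=6)
        s = make_series(x)
        h = HighAbundanceSet("X", list(s.data.columns), 1.0)
        r = reference_normalize(s, h)
        w = r.weights.to_numpy()
        assert (w >= 0).all() and (w <= 1).all()
        assert np.allclose(np.diag(w), 1.0)  # self-JSD = 0 -> weight 1


class TestHorizonTransform:
    def test_direct_evaluation_with_cap(self):
        hz = horizon_transform(pd.DataFrame({"o": [1, 2, 3, 4, 100]}))
        assert hz.medians["o"] == 3
        assert hz.mads["o"] == 1
        assert list(hz.bands["o"]) == [-2, -1, 0, 1, 4]

    def test_constant_series_all_zero_bands(self):
        hz = horizon_transform(pd.DataFrame({"o": [2.0, 2.0, 2.0]}))
        assert (hz.bands["o"] == 0).all()
        assert hz.mads["o"] == 0

    def test_mirror_symmetry(self, rng):
        x = rng.random(9)
        hz1 = horizon_transform(pd.DataFrame({"o": x}))
        hz2 = horizon_transform(pd.DataFrame({"o": 2 * np.median(x) - x}))
        assert list(hz1.bands["o"]) == list(-hz2.bands["o"])

    def test_zero_mad_nonzero_deviation_hits_outer_band(self):
        hz = horizon_transform(pd.DataFrame({"o": [1.0, 1.0, 1.0, 5.0]}))
        assert list(hz.bands["o"]) == [0, 0, 0, 4]


class TestSharedOtuSets:
    def _hset(self, subject, otus):
        return HighAbundanceSet(subject, list(otus), 1.0)

    def test_disjoint_sets_empty_core(self):
        res = shared_otu_sets([self._hset("a", ["x"]), self._hset("b", ["y"])])
        assert res["core_otus"] == []

    def test_identical_sets(self):
        res = shared_otu_sets([self._hset(s, ["x", "y", "z"]) for s in "abc"])
        assert all(v == 3 for v in res["subset_counts"].values())
        assert res["core_fraction_per_subject"] == {"a": 1.0, "b": 1.0, "c": 1.0}

    def test_matches_brute_force_subset_oracle(self, rng):
        universe = [f"O{i}" for i in range(15)]
        sets = {s: set(rng.choice(universe, size=8, replace=False))
                for s in "abcdef"}
        res = shared_otu_sets({s: self._hset(s, sorted(v))
                               for s, v in sets.items()})
        assert len(res["subset_counts"]) == 63
        for r in range(1, 7):
            for combo in itertools.combinations(sorted(sets), r):
                expected = len(set.intersection(*(sets[s] for s in combo)))
                assert res["subset_counts"][frozenset(combo)] == expected
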