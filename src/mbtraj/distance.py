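"""Community distances and the beta-diversity temporal trend test.

Jensen-Shannon distance (JSD) is the square root of the Jensen-Shannon
divergence with base-2 logarithms, so it is a metric bounded by 1 — the
bound the (1 - j)^2 reference-normalization weights rely on. UniFrac
(unweighted and normalized weighted) is delegated to scikit-bio. The trend
test is an L1 (median) regression of pairwise inter-subject distances on
collection day, with a bootstrap p-value for the slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

from .core import FractionalTable, ValidationError, check_leaf_coverage


def jensen_shannon_distance(p: np.ndarray, q: np.ndarray) -> float:
    """sqrt(JS divergence) with log base 2; inputs renormalized internally."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if (p < 0).any() or (q < 0).any():
        raise ValidationError("compositions must be non-negative")
    ps, qs = p.sum(), q.sum()
    if ps <= 0 or qs <= 0:
        raise ValidationError("compositions must have positive mass")
    d = float(jensenshannon(p / ps, q / qs, base=2))
    return 0.0 if np.isnan(d) else min(d, 1.0)


def jsd_matrix(table: FractionalTable | pd.DataFrame) -> DistanceMatrix:
    """All-pairs JSD over the rows of a composition table."""
    df = table.data if isinstance(table, FractionalTable) else table
    x = df.to_numpy(dtype=float)
    x = x / x.sum(axis=1, keepdims=True)
    n = x.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _jsd_fast(x[i], x[j])
    return DistanceMatrix(out, ids=list(df.index))


def _jsd_fast(p: np.ndarray, q: np.ndarray) -> float:
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(p > 0, p * np.log2(p / m), 0.0)
        t2 = np.where(q > 0, q * np.log2(q / m), 0.0)
    div = 0.5 * (t1.sum() + t2.sum())
    return float(np.sqrt(max(div, 0.0)))


def _branch_structure(tree: TreeNode, otu_ids: list[str]):
    """Branch lengths and per-branch descendant-taxon indicator matrix.

    One row per non-root branch; entry (b, t) = 1 if taxon t descends
    through branch b. A single postorder pass, cached per (tree, taxa).
    """
    col = {o: i for i, o in enumerate(otu_ids)}
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            vec = np.zeros(len(otu_ids))
            if node.name in col:
                vec[col[node.name]] = 1.0
        else:
            vec = np.zeros(len(otu_ids))
            for child in node.children:
                vec += below[id(child)]
        below[id(node)] = vec
        if node.parent is not None:  # non-root branch
            lengths.append(float(node.length or 0.0))
            rows.append(vec)
    return np.asarray(lengths), np.asarray(rows)


def unifrac(
    a: pd.Series | np.ndarray,
    b: pd.Series | np.ndarray,
    tree: TreeNode,
    otu_ids: list[str] | None = None,
    weighted: bool = False,
    normalized: bool = True,
) -> float:
    """Pairwise UniFrac between two abundance vectors.

    Unweighted: fraction of branch length leading exclusively to leaves
    present in one sample, over branch length leading to leaves present in
    either. Weighted: sum_b L_b |A_b - B_b| with A_b, B_b the fraction of
    each sample's abundance descending branch b; ``normalized`` divides by
    sum_b L_b (A_b + B_b). Every OTU with nonzero abundance must be a tree
    leaf.
    """
    if otu_ids is None:
        if not isinstance(a, pd.Series):
            raise ValidationError("otu_ids required for bare arrays")
        otu_ids = list(a.index)
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    present = [o for o, x, y in zip(otu_ids, av, bv) if x > 0 or y > 0]
    missing = check_leaf_coverage(tree, present)
    if missing:
        raise ValidationError(f"OTUs absent from tree: {missing[:10]}")
    lengths, branch = _branch_structure(tree, otu_ids)
    if weighted:
        fa = branch @ (av / av.sum())
        fb = branch @ (bv / bv.sum())
        num = float(np.sum(lengths * np.abs(fa - fb)))
        if not normalized:
            return num
        den = float(np.sum(lengths * (fa + fb)))
        return num / den if den > 0 else 0.0
    pa = (branch @ (av > 0)) > 0
    pb = (branch @ (bv > 0)) > 0
    num = float(np.sum(lengths * (pa ^ pb)))
    den = float(np.sum(lengths * (pa | pb)))
    return num / den if den > 0 else 0.0


def unifrac_matrix(
    table: FractionalTable | pd.DataFrame,
    tree: TreeNode,
    weighted: bool = False,
    normalized: bool = True,
) -> DistanceMatrix:
    """All-pairs UniFrac over the rows of a composition table."""
    df = table.data if isinstance(table, FractionalTable) else table
    missing = check_leaf_coverage(tree, df.columns)
    if missing:
        raise ValidationError(f"OTUs absent from tree: {missing[:10]}")
    lengths, branch = _branch_structure(tree, list(df.columns))
    x = df.to_numpy(dtype=float).T  # taxa x samples
    n = x.shape[1]
    out = np.zeros((n, n))
    if weighted:
        f = branch @ (x / x.sum(axis=0, keepdims=True))  # branches x samples
        for i in range(n):
            diff = np.sum(lengths[:, None] * np.abs(f[:, i:i + 1] - f[:, i + 1:]),
                          axis=0)
            if normalized:
                den = np.sum(lengths[:, None] * (f[:, i:i + 1] + f[:, i + 1:]),
                             axis=0)
                diff = np.where(den > 0, diff / np.where(den > 0, den, 1.0), 0.0)
            out[i, i + 1:] = diff
            out[i + 1:, i] = diff
    else:
        p = ((branch @ (x > 0)) > 0).astype(float)
        lp = lengths[:, None] * p
        s = lp.sum(axis=0)
        cross = p.T @ lp  # C_ij = sum_b L_b p_bi p_bj
        num = s[:, None] + s[None, :] - 2 * cross
        den = s[:, None] + s[None, :] - cross
        with np.errstate(invalid="ignore"):
            out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        np.fill_diagonal(out, 0.0)
        out = np.clip((out + out.T) / 2, 0.0, 1.0)
    return DistanceMatrix(out, ids=list(df.index))


def inter_subject_distance_series(
    table: FractionalTable,
    meta: pd.DataFrame,
    metric: str = "unifrac-u",
    tree: TreeNode | None = None,
    day_tolerance: int = 3,
) -> list[tuple[int, list[float]]]:
    """Per matched collection day, the pairwise inter-subject distances.

    Sample days are binned greedily (consecutive days within ``day_tolerance``
    share a bin); for each bin every subject contributes its sample nearest
    the bin center, and all C(k,2) pairwise distances among the k >= 2
    contributing subjects are reported. ``metric`` is one of ``jsd``,
    ``unifrac-u``, ``unifrac-w``.
    """
    if metric not in ("jsd", "unifrac-u", "unifrac-w"):
        raise ValidationError(f"unknown metric {metric!r}")
    if metric.startswith("unifrac") and tree is None:
        raise ValidationError("UniFrac requires a tree")
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    days = np.sort(meta["day"].unique())
    bins: list[list[int]] = [[int(days[0])]]
    for d in days[1:]:
        if d - bins[-1][-1] <= day_tolerance:
            bins[-1].append(int(d))
        else:
            bins.append([int(d)])

    if metric == "jsd":
        dm = jsd_matrix(table)
    else:
        dm = unifrac_matrix(table, tree, weighted=(metric == "unifrac-w"))

    out: list[tuple[int, list[float]]] = []
    for b in bins:
        center = int(round(float(np.mean(b))))
        chosen: dict[str, str] = {}
        for subj, sub in meta.groupby("subject_id"):
            in_bin = sub[sub["day"].isin(b)]
            if in_bin.empty:
                continue
            nearest = (in_bin["day"] - center).abs().idxmin()
            chosen[subj] = nearest
        if len(chosen) < 2:
            continue
        sids = sorted(chosen.values())
        dists = [float(dm[si, sj]) for i, si in enumerate(sids) for sj in sids[i + 1:]]
        out.append((center, dists))
    if not out:
        raise ValidationError("no collection days matched across subjects")
    return out


# ---------------------------------------------------------------------------
# Median (L1) regression trend with bootstrap p


@dataclass
class TrendResult:
    """L1 regression of distance on day.

    ``rc_range``: slope rescaled by (day span)/(observed distance range) —
    the fitted change over the whole study, in units of the full distance
    variation. ``rc_sd``: same but scaled to one standard deviation of the
    distances. ``p_value`` is a two-sided bootstrap sign test on the slope.
    """

    slope: float
    intercept: float
    rc_range: float
    rc_sd: float
    p_value: float
    n_boot: int
    n: int


def _l1_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Minimize sum |y - a - b x|.

    For n <= 200, exhaustive search over lines through data-point pairs (an
    optimal L1 line always passes through two points in general position),
    plus the flat median line as a degenerate candidate. Larger n falls back
    to quantile regression (statsmodels, q = 0.5).
    """
    n = len(x)
    if n > 200:
        import statsmodels.api as sm

        X = np.column_stack([np.ones(n), x])
        fit = sm.QuantReg(y, X).fit(q=0.5)
        return float(fit.params[1]), float(fit.params[0])
    ii, jj = np.triu_indices(n, k=1)
    dx = x[jj] - x[ii]
    ok = dx != 0
    ii, jj, dx = ii[ok], jj[ok], dx[ok]
    slopes = (y[jj] - y[ii]) / dx
    intercepts = y[ii] - slopes * x[ii]
    # candidate objective matrix: lines x points
    resid = np.abs(y[None, :] - intercepts[:, None] - slopes[:, None] * x[None, :])
    obj = resid.sum(axis=1)
    flat_obj = np.abs(y - np.median(y)).sum()
    if len(obj) == 0 or flat_obj <= obj.min():
        return 0.0, float(np.median(y))
    k = int(np.argmin(obj))
    return float(slopes[k]), float(intercepts[k])


def median_regression_trend(
    series: list[tuple[int, list[float]]] | tuple[np.ndarray, np.ndarray],
    n_boot: int = 999,
    seed: int = 0,
) -> TrendResult:
    """Fit distance = a + b*day by L1 regression; bootstrap p for b.

    ``series`` is either the (day, distances) list from
    :func:`inter_subject_distance_series` or a flat (days, distances) pair.
    p = 2 * min(frac(b* <= 0), frac(b* >= 0)) with a +1/(n_boot+1)
    continuity correction.
    """
    if isinstance(series, tuple):
        x = np.asarray(series[0], dtype=float)
        y = np.asarray(series[1], dtype=float)
    else:
        x = np.array([d for d, vals in series for _ in vals], dtype=float)
        y = np.array([v for _, vals in series for v in vals], dtype=float)
    if len(x) < 10:
        raise ValidationError("trend test needs >= 10 (day, distance) pairs")
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    if np.unique(x).size < 2:
        raise ValidationError("degenerate day axis: a single collection day")
    b, a = _l1_fit(x, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    boots = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if np.unique(xb).size < 2:
            boots[k] = 0.0
            continue
        boots[k], _ = _l1_fit(xb, yb)
    lo = (np.sum(boots <= 0) + 1) / (n_boot + 1)
    hi = (np.sum(boots >= 0) + 1) / (n_boot + 1)
    p = min(1.0, 2.0 * min(lo, hi))
    day_span = float(x.max() - x.min())
    y_range = float(y.max() - y.min())
    y_sd = float(np.std(y))
    rc_range = b * day_span / y_range if y_range > 0 else np.nan
    rc_sd = b * day_span / y_sd if y_sd > 0 else np.nan
    return TrendResult(b, a, rc_range, rc_sd, p, n_boot, n)
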