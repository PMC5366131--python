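"""Steady-state detection, validation and ecological succession.

A subject's samples are clustered in a hierarchical Ward-linkage tree built
on the Jensen-Shannon distance matrix; cutting the tree at a height h yields
candidate steady states — subject-specific clusters of similar community
configurations recurring in time. Candidate states are validated by (i)
within-state pairwise Spearman correlations with Benjamini-Hochberg q-values
and (ii) PERMANOVA (Anderson's pseudo-F on the distance matrix, label
permutations) overall and for every state pair. An ``auto`` height mode
scans the merge-height grid bottom-up and keeps the lowest height at which
every resulting state passes both checks.

Ward linkage is computed by the Lance-Williams update applied to squared
distances, with merge heights reported as the square root of the criterion
(the ward.D2 convention); ties are broken by the smallest cluster-index
pair, so the merge order is fully deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.distance import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .core import FractionalTable, ValidationError


# ---------------------------------------------------------------------------
# Ward linkage


@dataclass
class LinkageTree:
    """Agglomerative merge list: rows (i, j, height, size), scipy numbering
    (leaves 0..n-1, merge k creates node n+k)."""

    merges: np.ndarray  # (n-1, 4)
    n: int

    def __post_init__(self) -> None:
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValidationError("merge heights must be non-decreasing")


def ward_linkage(d: DistanceMatrix | np.ndarray) -> LinkageTree:
    """Ward agglomeration from a distance matrix.

    Lance-Williams on squared distances:
    D2(k, i+j) = ((n_i+n_k) D2(k,i) + (n_j+n_k) D2(k,j) - n_k D2(i,j)) / N
    with N = n_i + n_j + n_k; reported height = sqrt(D2) of the merge.
    """
    mat = d.data if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    n = mat.shape[0]
    if n < 2:
        raise ValidationError("need >= 2 samples")
    if np.isnan(mat).any():
        raise ValidationError("distance matrix contains NaN")
    total = 2 * n - 1  # leaves + internal nodes, scipy numbering
    d2 = np.full((total, total), np.inf)
    d2[:n, :n] = mat.astype(float) ** 2
    # search only the upper triangle so argmin's row-major scan implements
    # the smallest-(i, j) tie-break
    d2[np.tril_indices(total)] = np.inf
    sizes = np.zeros(total)
    sizes[:n] = 1
    alive = np.zeros(total, dtype=bool)
    alive[:n] = True
    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        flat = np.argmin(d2)
        bi, bj = divmod(flat, total)
        best = d2[bi, bj]
        new = n + step
        ni, nj = sizes[bi], sizes[bj]
        ks = np.flatnonzero(alive)
        ks = ks[(ks != bi) & (ks != bj)]
        if len(ks):
            dik = np.where(ks < bi, d2[ks, bi], d2[bi, ks])
            djk = np.where(ks < bj, d2[ks, bj], d2[bj, ks])
            nk = sizes[ks]
            d2[ks, new] = ((ni + nk) * dik + (nj + nk) * djk - nk * best) \
                / (ni + nj + nk)
        d2[bi, :] = d2[:, bi] = np.inf
        d2[bj, :] = d2[:, bj] = np.inf
        alive[bi] = alive[bj] = False
        alive[new] = True
        sizes[new] = ni + nj
        merges[step] = (bi, bj, np.sqrt(max(best, 0.0)), ni + nj)
    return LinkageTree(merges, n)


def cut_tree(tree: LinkageTree, h: float) -> np.ndarray:
    """Flat cluster assignment: keep merges with height <= h."""
    parent = list(range(2 * tree.n - 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for k, (i, j, height, _) in enumerate(tree.merges):
        if height <= h:
            node = tree.n + k
            parent[find(int(i))] = node
            parent[find(int(j))] = node
    roots = [find(i) for i in range(tree.n)]
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def cut_to_k(tree: LinkageTree, k: int) -> np.ndarray:
    """Flat assignment into exactly k clusters (undo the last k-1 merges)."""
    if not 1 <= k <= tree.n:
        raise ValidationError(f"k must be in [1, {tree.n}]")
    if k == tree.n:
        return np.arange(tree.n)
    h = float(tree.merges[tree.n - 1 - k, 2])
    return cut_tree(tree, h)


# ---------------------------------------------------------------------------
# PERMANOVA (Anderson's pseudo-F on a distance matrix)


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    groups = np.unique(labels)
    a = len(groups)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    if a == 1 or n == a:
        return np.nan
    if ss_within <= 0:
        return np.inf  # perfectly tight groups
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    d: DistanceMatrix | np.ndarray,
    labels,
    n_perm: int = 9999,
    seed: int = 0,
    exact: bool = False,
) -> dict:
    """Permutation test of group separation on a distance matrix.

    ``exact=True`` enumerates all distinct label assignments (small n only)
    and returns the exact p; otherwise ``n_perm`` random label permutations,
    p = (#{F_perm >= F_obs} + 1) / (n_perm + 1).
    """
    mat = d.data if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    d2 = mat ** 2
    f_obs = _pseudo_f(d2, labels)
    if np.isnan(f_obs):
        raise ValidationError("PERMANOVA needs >= 2 groups with replication")
    n = len(labels)
    if exact:
        groups = np.unique(labels)
        ge = 0
        total = 0
        if len(groups) == 2:
            # enumerate the C(n, n1) distinct binary assignments
            n1 = int(np.sum(labels == groups[0]))
            for pos in itertools.combinations(range(n), n1):
                lab = np.full(n, groups[1])
                lab[list(pos)] = groups[0]
                total += 1
                if _pseudo_f(d2, lab) >= f_obs - 1e-12:
                    ge += 1
        else:
            seen = set()
            for perm in itertools.permutations(range(n)):
                key = tuple(labels[list(perm)])
                if key in seen:
                    continue
                seen.add(key)
                total += 1
                if _pseudo_f(d2, np.asarray(key)) >= f_obs - 1e-12:
                    ge += 1
        p = ge / total
        return {"pseudo_f": float(f_obs), "p_value": float(p),
                "n_perm": total, "method": "exact"}
    rng = np.random.default_rng(seed)
    # vectorized permutations: SS_within(g) = sum_{i<j in g} d2 / n_g via
    # one-hot indicator products
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    groups = np.unique(labels)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = np.zeros(n_perm)
    for g in groups:
        mask = (labels[perms] == g).astype(float)  # n_perm x n
        n_g = mask[0].sum()
        if n_g > 1:
            ss_within += 0.5 * np.einsum("pi,ij,pj->p", mask, d2, mask) / n_g
    a = len(groups)
    f_perm = ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))
    ge = int(np.sum(f_perm >= f_obs - 1e-12))
    p = (ge + 1) / (n_perm + 1)
    return {"pseudo_f": float(f_obs), "p_value": float(p),
            "n_perm": n_perm, "method": "permutation"}


# ---------------------------------------------------------------------------
# Steady-state map


@dataclass
class Episode:
    state: int
    start_day: int
    end_day: int
    n_samples: int


@dataclass
class SteadyStateMap:
    subject_id: str
    labels: pd.Series            # sample_id -> state label (1..K), day order
    days: np.ndarray
    cut_height: float
    episodes: list[Episode] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return int(self.labels.nunique())

    def members(self, state: int) -> list[str]:
        return list(self.labels.index[self.labels == state])


def cut_states(
    tree: LinkageTree,
    h: float,
    sample_ids: list[str],
    days: np.ndarray,
    subject_id: str = "",
) -> SteadyStateMap:
    """Cut the linkage tree at height h; states numbered by first appearance
    in time; episodes = maximal runs of consecutive same-state samples."""
    if h <= 0:
        raise ValidationError("cut height must be > 0")
    days = np.asarray(days, dtype=int)
    order = np.argsort(days, kind="stable")
    raw = cut_tree(tree, h)
    # renumber by first appearance in day order
    mapping: dict[int, int] = {}
    for idx in order:
        if raw[idx] not in mapping:
            mapping[raw[idx]] = len(mapping) + 1
    labels = np.array([mapping[r] for r in raw])
    s = pd.Series(labels[order], index=np.asarray(sample_ids)[order])
    d_sorted = days[order]
    episodes: list[Episode] = []
    start = 0
    lab = s.iloc[0]
    for i in range(1, len(s) + 1):
        if i == len(s) or s.iloc[i] != lab:
            episodes.append(Episode(int(lab), int(d_sorted[start]),
                                    int(d_sorted[i - 1]), i - start))
            if i < len(s):
                start, lab = i, s.iloc[i]
    return SteadyStateMap(subject_id, s, d_sorted, float(h), episodes)


@dataclass
class StateValidation:
    pair_qvalues: dict[int, float]       # state -> max within-pair q
    states_passing_q: list[int]
    pairwise_permanova: dict[tuple[int, int], dict]
    overall_permanova: dict
    all_pass: bool
    singleton_states: list[int]


def validate_states(
    smap: SteadyStateMap,
    table: FractionalTable | pd.DataFrame,
    d: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    alpha_q: float = 0.05,
    alpha_p: float = 0.05,
    otu_subset: list[str] | None = None,
) -> StateValidation:
    """Certify states: within-state Spearman q < alpha_q for every pair, and
    pairwise PERMANOVA p < alpha_p for every state pair. Singleton states are
    flagged and excluded from the correlation check."""
    df = table.data if isinstance(table, FractionalTable) else table
    if otu_subset is not None:
        df = df[otu_subset]
    states = sorted(smap.labels.unique())
    if len(states) < 2:
        raise ValidationError("validation needs >= 2 states")
    singletons = [s for s in states if len(smap.members(s)) < 2]
    multi = [s for s in states if s not in singletons]
    # (i) within-state pairwise Spearman with BH q-values across all pairs
    pvals: list[float] = []
    owners: list[int] = []
    for s in multi:
        for a, b in itertools.combinations(smap.members(s), 2):
            rho, p = stats.spearmanr(df.loc[a], df.loc[b])
            pvals.append(1.0 if np.isnan(p) else float(p))
            owners.append(s)
    q_by_state: dict[int, float] = {}
    if pvals:
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for s in multi:
            qs = [q for q, o in zip(qvals, owners) if o == s]
            q_by_state[s] = float(max(qs))
    passing_q = [s for s in multi if q_by_state.get(s, 1.0) < alpha_q]
    # (ii) PERMANOVA: overall and per state pair (multi-sample states only)
    ids = list(smap.labels.index)
    dm = np.asarray([[d[a, b] for b in ids] for a in ids])
    labels = smap.labels.to_numpy()
    keep = np.isin(labels, multi)
    overall = permanova(dm[np.ix_(keep, keep)], labels[keep],
                        n_perm=n_perm, seed=seed)
    pairwise: dict[tuple[int, int], dict] = {}
    from math import comb

    for s1, s2 in itertools.combinations(multi, 2):
        sel = np.isin(labels, [s1, s2])
        n_sel = int(sel.sum())
        n1 = int(np.sum(labels[sel] == s1))
        n_distinct = comb(n_sel, n1)
        res = permanova(
            dm[np.ix_(sel, sel)], labels[sel], n_perm=n_perm,
            seed=seed + 7919 * s1 + 104729 * s2,
            exact=n_distinct <= 500,
        )
        # small pairs cannot attain alpha_p at all (exact-p floor above it);
        # such a pair passes when its exact p IS the floor, i.e. the observed
        # separation is the most extreme achievable at that size. For equal
        # group sizes the complementary assignment ties F, so the floor is
        # 2/n_distinct.
        floor = (2.0 if n1 * 2 == n_sel else 1.0) / n_distinct
        res["p_floor"] = floor
        res["passes"] = bool(
            res["p_value"] < alpha_p
            or (res["method"] == "exact" and floor > alpha_p
                and res["p_value"] <= floor + 1e-12)
        )
        pairwise[(s1, s2)] = res
    # certification requires every state to be a genuine sample group:
    # no singletons, every group internally correlated, all pairs separated
    all_pass = (
        not singletons
        and len(multi) >= 2
        and all(s in passing_q for s in multi)
        and all(r["passes"] for r in pairwise.values())
    )
    return StateValidation(q_by_state, passing_q, pairwise, overall,
                           bool(all_pass), singletons)


def auto_height(
    tree: LinkageTree,
    sample_ids: list[str],
    days: np.ndarray,
    table: FractionalTable | pd.DataFrame,
    d: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    subject_id: str = "",
    otu_subset: list[str] | None = None,
) -> tuple[SteadyStateMap, StateValidation | None]:
    """Choose the cut height automatically.

    Candidate heights are the merge-height grid. A candidate cut must give
    >= 2 states with no singletons; candidates are ranked by mean silhouette
    width on the distance matrix (a cut-height scan certified only by
    PERMANOVA over-splits, because the labels are chosen by the clustering
    itself — the silhouette ranking removes that selection effect), and the
    best-ranked cut whose states all pass validation is returned. If no cut
    certifies, the silhouette-best cut is returned with its failed
    validation; if no candidate exists at all, the single-state cut with
    validation None.
    """
    from sklearn.metrics import silhouette_score

    mat = d.data if hasattr(d, "data") else np.asarray(d)
    heights = sorted(set(float(h) for h in tree.merges[:, 2]))
    candidates: list[tuple[float, float]] = []  # (silhouette, height)
    for h in heights:
        hh = h * (1 + 1e-12) + 1e-15
        labels = cut_tree(tree, hh)
        k = len(np.unique(labels))
        if k < 2 or k >= tree.n:
            continue
        if np.min(np.bincount(labels)) < 2:
            continue
        sil = float(silhouette_score(mat, labels, metric="precomputed"))
        candidates.append((sil, hh))
    fallback: tuple[SteadyStateMap, StateValidation | None] | None = None
    for sil, hh in sorted(candidates, key=lambda t: -t[0]):
        smap = cut_states(tree, hh, sample_ids, days, subject_id)
        try:
            val = validate_states(smap, table, d, n_perm=n_perm, seed=seed,
                                  otu_subset=otu_subset)
        except ValidationError:
            continue
        if val.all_pass:
            return smap, val
        if fallback is None:
            fallback = (smap, val)
    if fallback is not None:
        return fallback
    root_h = float(tree.merges[-1, 2]) + 1.0
    return cut_states(tree, root_h, sample_ids, days, subject_id), None


def state_profiles(
    smap: SteadyStateMap, table: FractionalTable | pd.DataFrame
) -> pd.DataFrame:
    """Per-state, per-OTU median relative abundance, renormalized to sum 1."""
    df = table.data if isinstance(table, FractionalTable) else table
    rows = {}
    for s in sorted(smap.labels.unique()):
        med = df.loc[smap.members(s)].median(axis=0)
        total = med.sum()
        rows[s] = med / total if total > 0 else med
    return pd.DataFrame(rows).T


def succession_summary(smap: SteadyStateMap) -> dict:
    """Episode persistence, recurrence counts and return-to-initial flag."""
    per_state: dict[int, dict] = {}
    for s in sorted(int(v) for v in smap.labels.unique()):
        eps = [e for e in smap.episodes if e.state == s]
        durations = [e.end_day - e.start_day for e in eps]
        per_state[s] = {
            "episodes": [(e.start_day, e.end_day) for e in eps],
            "recurrences": len(eps),
            "persistence_days": durations,
            "mean_persistence": float(np.mean(durations)) if durations else 0.0,
        }
    first = int(smap.labels.iloc[0])
    last = int(smap.labels.iloc[-1])
    return {
        "subject_id": smap.subject_id,
        "n_states": smap.n_states,
        "states": per_state,
        "returned_to_initial": first == last,
        "label_sequence": [int(v) for v in smap.labels],
    }
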