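"""Co-abundance group (CAO) inference over steady-state profiles.

For one subject, the observations are the steady-state median profiles
(n = number of states — deliberately small; exact p-values are used where
feasible and the small-n caveat is recorded). OTUs with mean relative
abundance across state profiles above 0.1% are included. Pairwise Kendall
tau-b across states gives the correlation/edge structure; OTUs are
clustered by Ward linkage on (1 - Spearman rho) into k in {3, 4} groups,
k chosen by mean silhouette width, and the grouping is certified by
PERMANOVA on the same distance matrix (p < 0.001). Network edges are the
positive, significant (p < 0.05) Kendall correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_score

from .core import ValidationError
from .states import LinkageTree, _pseudo_f, cut_to_k, permanova, ward_linkage

MIN_MEAN_ABUNDANCE = 0.001  # inclusion filter: mean > 0.1% across states
OVERABUNDANCE_EPS = 1e-6


@dataclass
class CaoModel:
    otu_ids: list[str]
    tau: pd.DataFrame
    pvalues: pd.DataFrame
    groups: pd.Series               # otu_id -> group label (1..k)
    k: int
    silhouette: float
    permanova_result: dict          # calibrated (re-clustered null) test
    certified: bool                 # calibrated p < 0.001
    small_n: bool                   # < 10 state observations
    n_states: int


def filter_included_otus(profiles: pd.DataFrame,
                         threshold: float = MIN_MEAN_ABUNDANCE) -> list[str]:
    """OTUs with mean relative abundance across state profiles > threshold."""
    means = profiles.mean(axis=0)
    return [o for o in profiles.columns if means[o] > threshold]


def kendall_matrix(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Kendall tau-b and two-sided p across state profiles.

    Exact p for n <= 10 observations (scipy enumeration), normal
    approximation above. Constant vectors give NaN (recorded missing).
    """
    n_states = len(profiles)
    if n_states < 3:
        raise ValidationError("Kendall structure needs >= 3 state profiles")
    method = "exact" if n_states <= 10 else "asymptotic"
    cols = list(profiles.columns)
    m = len(cols)
    tau = np.eye(m)
    pv = np.zeros((m, m))
    x = profiles.to_numpy(dtype=float)
    for i in range(m):
        for j in range(i + 1, m):
            if np.ptp(x[:, i]) == 0 or np.ptp(x[:, j]) == 0:
                tau[i, j] = tau[j, i] = np.nan
                pv[i, j] = pv[j, i] = np.nan
                continue
            has_ties = (len(np.unique(x[:, i])) < n_states
                        or len(np.unique(x[:, j])) < n_states)
            res = stats.kendalltau(
                x[:, i], x[:, j],
                method="asymptotic" if has_ties else method,
            )
            tau[i, j] = tau[j, i] = res.statistic
            pv[i, j] = pv[j, i] = res.pvalue
    return (pd.DataFrame(tau, index=cols, columns=cols),
            pd.DataFrame(pv, index=cols, columns=cols))


def assign_cao(
    profiles: pd.DataFrame,
    k_candidates: tuple[int, ...] = (3, 4),
    n_perm: int = 999,
    seed: int = 0,
    threshold: float = MIN_MEAN_ABUNDANCE,
) -> CaoModel:
    """Infer co-abundance groups for one subject's state profiles.

    ``profiles`` is states x OTUs (rows sum to ~1). Distance between OTUs is
    1 - Spearman rho of their abundance vectors across states; Ward linkage
    is cut at each candidate k and the k with the best mean silhouette wins
    (ties -> smaller k).

    Certification uses a selection-aware permutation test: because the
    group labels are produced by the clustering, naive label-permutation
    PERMANOVA is maximally significant even for independent noise. Instead,
    each OTU's values are permuted independently across states (destroying
    inter-OTU correlation while keeping marginals), the full
    distance/Ward/silhouette pipeline is re-run on the permuted data, and
    the observed pseudo-F is compared against the pseudo-F of those
    re-clustered nulls; certified means p < 0.001.
    """
    included = filter_included_otus(profiles, threshold)
    if len(included) < 6:
        raise ValidationError(
            f"need >= 6 OTUs above the {threshold:.1%} inclusion filter, "
            f"got {len(included)}"
        )
    included = sorted(included)
    sub = profiles[included]
    tau, pv = kendall_matrix(sub)
    rho, _ = stats.spearmanr(sub.to_numpy(dtype=float))
    rho = np.nan_to_num(np.atleast_2d(rho), nan=0.0)  # constant OTU -> rho 0
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    dist = (dist + dist.T) / 2
    tree = ward_linkage(dist)
    best: tuple[float, int, np.ndarray] | None = None
    for k in sorted(k_candidates):
        if k >= len(included):
            raise ValidationError("k must be smaller than the number of OTUs")
        labels = cut_to_k(tree, k)
        if len(np.unique(labels)) < k:
            continue
        try:
            sil = float(silhouette_score(dist, labels, metric="precomputed"))
        except ValueError as exc:
            raise ValidationError(f"silhouette undefined: {exc}") from None
        if best is None or sil > best[0] + 1e-12:
            best = (sil, k, labels)
    if best is None:
        raise ValidationError("no candidate k produced a valid grouping")
    sil, k, labels = best
    f_obs = _pseudo_f(dist ** 2, labels)
    rng = np.random.default_rng(seed)
    x = sub.to_numpy(dtype=float)
    ge = 0
    for _ in range(n_perm):
        xp = np.empty_like(x)
        for col in range(x.shape[1]):
            xp[:, col] = x[rng.permutation(x.shape[0]), col]
        f_null = _null_pipeline_f(xp, k_candidates)
        if f_null >= f_obs - 1e-12:
            ge += 1
    perm = {
        "pseudo_f": float(f_obs),
        "p_value": float((ge + 1) / (n_perm + 1)),
        "n_perm": n_perm,
        "method": "reclustered-null permutation",
    }
    groups = pd.Series(labels + 1, index=included)
    return CaoModel(
        otu_ids=included,
        tau=tau,
        pvalues=pv,
        groups=groups,
        k=k,
        silhouette=sil,
        permanova_result=perm,
        certified=bool(perm["p_value"] < 0.001),
        small_n=len(profiles) < 10,
        n_states=len(profiles),
    )


def _null_pipeline_f(x: np.ndarray, k_candidates: tuple[int, ...]) -> float:
    """Re-run distance/Ward/silhouette on permuted data; return its pseudo-F."""
    from sklearn.metrics import silhouette_score as _sil

    rho, _ = stats.spearmanr(x)
    rho = np.nan_to_num(np.atleast_2d(rho), nan=0.0)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, 2.0)
    tree = ward_linkage(dist)
    best_sil, best_labels = -np.inf, None
    for k in sorted(k_candidates):
        if k >= x.shape[1]:
            continue
        labels = cut_to_k(tree, k)
        if len(np.unique(labels)) < k:
            continue
        try:
            s = float(_sil(dist, labels, metric="precomputed"))
        except ValueError:
            continue
        if s > best_sil + 1e-12:
            best_sil, best_labels = s, labels
    if best_labels is None:
        return -np.inf
    return _pseudo_f(dist ** 2, best_labels)


def cao_edges(model: CaoModel) -> pd.DataFrame:
    """Edges where tau > 0 and p < 0.05; weight = tau."""
    rows = []
    otus = model.otu_ids
    t = model.tau.to_numpy()
    p = model.pvalues.to_numpy()
    for i in range(len(otus)):
        for j in range(i + 1, len(otus)):
            if np.isnan(t[i, j]):
                continue
            if t[i, j] > 0 and p[i, j] < 0.05:
                rows.append({"source": otus[i], "target": otus[j],
                             "weight": float(t[i, j])})
    return pd.DataFrame(rows, columns=["source", "target", "weight"])


def state_overabundance(
    model: CaoModel,
    profiles: pd.DataFrame,
    background: pd.Series | None = None,
    eps: float = OVERABUNDANCE_EPS,
) -> pd.DataFrame:
    """ratio(state, otu) = (state + eps) / (background + eps); background
    defaults to the across-state median profile."""
    sub = profiles[model.otu_ids]
    if background is None:
        background = sub.median(axis=0)
    else:
        background = background[model.otu_ids]
    return (sub + eps).div(background + eps, axis=1)
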