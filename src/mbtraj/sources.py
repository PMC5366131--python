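"""Bayesian microbial source tracking and major-change scoring.

Each steady-state profile (the sink) is modelled as a mixture of candidate
source communities — the subject's immediately preceding steady state and
every other subject's state profiles — plus an implicit "unknown" source.
A collapsed Gibbs sampler assigns each sink read a latent source: for read
of taxon t the full conditional is

    P(z = k)  proportional to  (c_kt + a1) / (C_k + a1 T) * (n_k + b)
    P(z = unk) proportional to (u_t + a2) / (U + a2 T)    * (n_unk + b)

where c are the (fixed) source taxon counts, u the taxon counts currently
assigned to unknown, n the per-source sink assignment counts, T the taxon
universe size, and (a1, a2, b) the Dirichlet smoothing hyperparameters.
Mixing proportions are posterior means of assignment fractions over retained
draws, averaged over independent restarts.

The exogenous score of a state transition is e = 1 - pi(own preceding
state); within each subject the e values are z-scored (population sd), so
z = 0 means the transition changed the microbiota as much as that subject's
average transition did, and large positive z flags a major change event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .core import ValidationError


@dataclass
class GibbsSettings:
    """Sampler hyperparameters (published source-tracking defaults)."""

    alpha1: float = 0.001   # known-source taxon smoothing
    alpha2: float = 0.1     # unknown-source taxon smoothing
    beta: float = 10.0      # mixing-proportion smoothing
    burnin: int = 100       # discarded sweeps
    n_draws: int = 10       # retained draws per restart
    thin: int = 10          # sweeps between retained draws
    restarts: int = 10      # independent chains
    sink_depth: int = 10000  # pseudo-depth used to rescale compositions


@dataclass
class MixingEstimate:
    proportions: pd.Series        # over sources + 'unknown'; sums to 1
    trace: np.ndarray             # (restarts * n_draws, K+1)
    settings: GibbsSettings
    seed: int


def composition_to_counts(profile: np.ndarray, depth: int) -> np.ndarray:
    """Largest-remainder rounding of depth * profile to integer counts."""
    profile = np.asarray(profile, dtype=float)
    total = profile.sum()
    if total <= 0:
        raise ValidationError("profile has no mass")
    target = profile / total * depth
    base = np.floor(target).astype(np.int64)
    short = depth - int(base.sum())
    if short > 0:
        order = np.argsort(-(target - base), kind="stable")
        base[order[:short]] += 1
    return base


@njit(cache=True)
def _gibbs_chain(sink_taxa, source_probs, n_taxa, alpha2, beta,
                 burnin, n_draws, thin, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_reads = sink_taxa.shape[0]
    k_src = source_probs.shape[0]
    k_tot = k_src + 1  # + unknown
    z = np.empty(n_reads, dtype=np.int64)
    n_k = np.zeros(k_tot, dtype=np.int64)
    u_t = np.zeros(n_taxa, dtype=np.int64)
    for r in range(n_reads):
        k = np.random.randint(0, k_tot)
        z[r] = k
        n_k[k] += 1
        if k == k_src:
            u_t[sink_taxa[r]] += 1
    draws = np.zeros((n_draws, k_tot))
    probs = np.empty(k_tot)
    total_sweeps = burnin + n_draws * thin
    kept = 0
    for sweep in range(total_sweeps):
        for r in range(n_reads):
            t = sink_taxa[r]
            old = z[r]
            n_k[old] -= 1
            if old == k_src:
                u_t[t] -= 1
            u_minus = n_k[k_src]
            acc = 0.0
            for k in range(k_src):
                p = source_probs[k, t] * (n_k[k] + beta)
                probs[k] = p
                acc += p
            p_unk = ((u_t[t] + alpha2) / (u_minus + alpha2 * n_taxa)) \
                * (n_k[k_src] + beta)
            probs[k_src] = p_unk
            acc += p_unk
            u = np.random.random() * acc
            cum = 0.0
            new = k_tot - 1
            for k in range(k_tot):
                cum += probs[k]
                if u < cum:
                    new = k
                    break
            z[r] = new
            n_k[new] += 1
            if new == k_src:
                u_t[t] += 1
        if sweep >= burnin and (sweep - burnin) % thin == thin - 1:
            for k in range(k_tot):
                draws[kept, k] = n_k[k] / n_reads
            kept += 1
    return draws


@dataclass
class SourceSet:
    """Sink + named sources on a common OTU universe."""

    sink: np.ndarray
    sources: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValidationError("need >= 1 source")
        t = len(self.sink)
        for name, s in self.sources.items():
            if len(s) != t:
                raise ValidationError(
                    f"source {name!r} not on the sink's OTU universe"
                )


def gibbs_mixing(
    source_set: SourceSet,
    settings: GibbsSettings | None = None,
    seed: int = 0,
) -> MixingEstimate:
    """Estimate mixing proportions of the sink over sources + unknown."""
    settings = settings or GibbsSettings()
    raw = np.asarray(source_set.sink)
    sink = raw.astype(float)
    if sink.sum() <= 0:
        raise ValidationError("empty sink")
    if np.issubdtype(raw.dtype, np.integer) and raw.sum() >= 100:
        sink_counts = raw.astype(np.int64)
    else:
        sink_counts = composition_to_counts(sink, settings.sink_depth)
    if sink_counts.sum() < 100:
        raise ValidationError("sink total count must be >= 100")
    names = list(source_set.sources)
    n_taxa = len(sink)
    a1 = settings.alpha1
    src_probs = np.empty((len(names), n_taxa))
    for i, name in enumerate(names):
        prof = np.asarray(source_set.sources[name], dtype=float)
        c = composition_to_counts(prof, settings.sink_depth).astype(float)
        src_probs[i] = (c + a1) / (c.sum() + a1 * n_taxa)
    sink_taxa = np.repeat(
        np.arange(n_taxa, dtype=np.int64), sink_counts
    )
    rng = np.random.default_rng(seed)
    all_draws = []
    for _ in range(settings.restarts):
        chain_seed = int(rng.integers(0, 2**31 - 1))
        draws = _gibbs_chain(
            sink_taxa, src_probs, n_taxa, settings.alpha2, settings.beta,
            settings.burnin, settings.n_draws, settings.thin, chain_seed,
        )
        all_draws.append(draws)
    trace = np.vstack(all_draws)
    pi = trace.mean(axis=0)
    pi = pi / pi.sum()
    return MixingEstimate(
        proportions=pd.Series(pi, index=names + ["unknown"]),
        trace=trace,
        settings=settings,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Exogenous scores over state transitions


@dataclass
class TransitionScore:
    subject_id: str
    from_state: int
    to_state: int
    proportions: pd.Series
    exogenous: float          # e = 1 - pi(own preceding state)
    z: float = np.nan
    major_change: bool = False


def exogenous_scores(
    profiles: dict[str, pd.DataFrame],
    state_order: dict[str, list[int]] | None = None,
    settings: GibbsSettings | None = None,
    seed: int = 0,
    z_threshold: float = 1.5,
) -> list[TransitionScore]:
    """Score every state transition of every subject.

    ``profiles`` maps subject -> (states x OTUs) composition DataFrame on a
    common OTU universe; ``state_order`` gives each subject's temporal state
    sequence (defaults to ascending state labels, which match first
    appearance in time). For the transition to state s_{i+1}, the sink is
    that state's profile and the sources are the subject's state s_i profile
    plus all other subjects' state profiles. z-scores use the population sd
    within each subject; transitions with z > ``z_threshold`` are flagged.
    """
    settings = settings or GibbsSettings()
    rng = np.random.default_rng(seed)
    universe: list[str] | None = None
    for df in profiles.values():
        cols = list(df.columns)
        if universe is None:
            universe = cols
        elif cols != universe:
            raise ValidationError("state profiles must share an OTU universe")
    scores: list[TransitionScore] = []
    for subj, df in profiles.items():
        order = (state_order or {}).get(subj, sorted(df.index))
        if len(order) < 2:
            continue  # skipped with a single state
        others = {
            f"{o}:state{s}": odf.loc[s].to_numpy()
            for o, odf in profiles.items() if o != subj
            for s in odf.index
        }
        for prev, nxt in zip(order[:-1], order[1:]):
            own_name = f"own:state{prev}"
            sources = {own_name: df.loc[prev].to_numpy(), **others}
            sset = SourceSet(sink=df.loc[nxt].to_numpy(), sources=sources)
            est = gibbs_mixing(sset, settings,
                               seed=int(rng.integers(0, 2**31 - 1)))
            e = float(1.0 - est.proportions[own_name])
            scores.append(TransitionScore(subj, int(prev), int(nxt),
                                          est.proportions, e))
    # per-subject z-scores (population sd)
    by_subject: dict[str, list[TransitionScore]] = {}
    for sc in scores:
        by_subject.setdefault(sc.subject_id, []).append(sc)
    for subj, group in by_subject.items():
        es = np.array([sc.exogenous for sc in group])
        if len(es) >= 2 and np.std(es) > 0:
            zs = (es - es.mean()) / np.std(es)
        else:
            zs = np.zeros(len(es))
        for sc, z in zip(group, zs):
            sc.z = float(z)
            sc.major_change = bool(z > z_threshold)
    return scores


def scores_table(scores: list[TransitionScore]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": sc.subject_id,
            "from_state": sc.from_state,
            "to_state": sc.to_state,
            "exogenous": sc.exogenous,
            "z": sc.z,
            "major_change": sc.major_change,
            "pi_unknown": float(sc.proportions["unknown"]),
        }
        for sc in scores
    ]
    return pd.DataFrame(rows)
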