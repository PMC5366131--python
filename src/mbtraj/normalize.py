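"""Per-subject time-series normalization, horizon bands, shared-OTU sets.

The normalization is a three-step procedure. (i) Counts are made fractional
so each time point sums to 1. (ii) Highly abundant OTUs are selected: each
OTU's median fractional abundance across the subject's time points is
computed, OTUs are ranked by that median, and the smallest prefix whose
summed medians reach 90% of the total is kept. (iii) Each time point is
normalized to a reference community built from time points with a similar
community structure: for target sample s, every time point t gets weight
w = (1 - j)^2 with j the Jensen-Shannon distance between t and s (computed
over the selected OTUs, renormalized), the per-OTU reference value is the
weighted median of abundances across time points, and the sample is rescaled
by the median reference/observed ratio over mutually nonzero OTUs.

The horizon transform median-centers each OTU's (normalized) series and
assigns each value to a signed band of width one median absolute deviation,
capped at four bands per side — the numeric backbone of horizon graphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import FractionalTable, ValidationError
from .distance import _jsd_fast


@dataclass
class SubjectSeries:
    """One subject's day-ordered fractional profiles."""

    subject_id: str
    data: pd.DataFrame  # samples x OTUs, fractional, day-ordered
    days: np.ndarray
    phases: list[str]

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        if len(self.days) != len(self.data):
            raise ValidationError("days and data length mismatch")
        if not np.all(np.diff(self.days) > 0):
            raise ValidationError("days must be strictly increasing")
        if len(self.data) < 4:
            raise ValidationError(
                f"subject {self.subject_id!r}: need >= 4 time points, "
                f"got {len(self.data)}"
            )

    @classmethod
    def from_table(
        cls, table: FractionalTable, meta: pd.DataFrame, subject_id: str
    ) -> "SubjectSeries":
        sub = meta[meta["subject_id"] == subject_id].sort_values("day")
        if sub.empty:
            raise ValidationError(f"unknown subject {subject_id!r}")
        data = table.data.loc[sub["sample_id"]]
        return cls(subject_id, data, sub["day"].to_numpy(), list(sub["phase"]))


@dataclass
class HighAbundanceSet:
    subject_id: str
    otu_ids: list[str]
    coverage: float  # fraction of summed per-OTU medians captured

    def __post_init__(self) -> None:
        if not self.otu_ids:
            raise ValidationError("high-abundance set is empty")
        if self.coverage < 0.9 - 1e-12:
            raise ValidationError("coverage below the 90% contract")


def select_high_abundance(
    series: SubjectSeries, threshold: float = 0.9
) -> HighAbundanceSet:
    """Smallest prefix of median-ranked OTUs reaching ``threshold`` of the
    summed per-OTU medians; ties broken by otu_id (lexicographic)."""
    medians = series.data.median(axis=0)
    total = float(medians.sum())
    if total <= 0:
        raise ValidationError("all per-OTU medians are zero")
    order = sorted(medians.index, key=lambda o: (-medians[o], o))
    cum = 0.0
    chosen: list[str] = []
    for o in order:
        chosen.append(o)
        cum += float(medians[o])
        if cum >= threshold * total - 1e-12:
            break
    return HighAbundanceSet(series.subject_id, chosen, cum / total)


def weighted_median(values, weights) -> float:
    """Smallest value whose cumulative weight reaches half the total weight."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValidationError("weighted_median of empty input")
    if (w < 0).any():
        raise ValidationError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValidationError("at least one weight must be positive")
    order = np.argsort(v, kind="stable")
    cw = np.cumsum(w[order])
    idx = int(np.searchsorted(cw, 0.5 * total - 1e-12 * total))
    return float(v[order][idx])


@dataclass
class ReferenceNormalizedSeries:
    subject_id: str
    normalized: pd.DataFrame          # samples x hset OTUs, rescaled
    references: pd.DataFrame          # per-sample reference profile
    scale_factors: pd.Series          # per-sample c_s
    weights: pd.DataFrame             # w(t, s) = (1 - j(t, s))^2


def reference_normalize(
    series: SubjectSeries, hset: HighAbundanceSet
) -> ReferenceNormalizedSeries:
    """Normalize each time point to its similarity-weighted reference.

    The target's own time point is a reference candidate with weight 1.
    The scale factor is the median of reference/observed ratios over OTUs
    nonzero in both."""
    sub = series.data[hset.otu_ids].to_numpy(dtype=float)
    row_sums = sub.sum(axis=1, keepdims=True)
    if (row_sums <= 0).any():
        bad = series.data.index[np.argmin(row_sums[:, 0])]
        raise ValidationError(f"sample {bad!r} has no high-abundance signal")
    frac = sub / row_sums  # renormalized over the hset support
    n, m = sub.shape
    jsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            jsd[i, j] = jsd[j, i] = _jsd_fast(frac[i], frac[j])
    weights = (1.0 - jsd) ** 2
    refs = np.empty((n, m))
    scales = np.empty(n)
    normalized = np.empty((n, m))
    for s in range(n):
        w = weights[:, s]
        for o in range(m):
            refs[s, o] = weighted_median(sub[:, o], w)
        both = (refs[s] > 0) & (sub[s] > 0)
        if not both.any():
            raise ValidationError(
                f"sample {series.data.index[s]!r} shares no OTU with its reference"
            )
        scales[s] = float(np.median(refs[s][both] / sub[s][both]))
        normalized[s] = scales[s] * sub[s]
    idx = series.data.index
    return ReferenceNormalizedSeries(
        series.subject_id,
        normalized=pd.DataFrame(normalized, index=idx, columns=hset.otu_ids),
        references=pd.DataFrame(refs, index=idx, columns=hset.otu_ids),
        scale_factors=pd.Series(scales, index=idx),
        weights=pd.DataFrame(weights, index=idx, columns=idx),
    )


@dataclass
class HorizonSeries:
    """Per-OTU median/MAD centering and signed band indices in [-4, 4]."""

    centered: pd.DataFrame
    bands: pd.DataFrame
    medians: pd.Series
    mads: pd.Series


def horizon_transform(series: pd.DataFrame | np.ndarray) -> HorizonSeries:
    """Median-center each OTU series; band = sign * ceil(|centered| / MAD),
    capped at 4. MAD is unscaled (no consistency factor). A zero MAD sends
    any nonzero deviation to the outermost band."""
    df = pd.DataFrame(series)
    if len(df) < 3:
        raise ValidationError("horizon transform needs >= 3 time points")
    x = df.to_numpy(dtype=float)
    med = np.median(x, axis=0)
    centered = x - med
    mad = np.median(np.abs(centered), axis=0)
    bands = np.zeros_like(centered, dtype=int)
    nz = centered != 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(centered) / mad
    mag = np.where(np.isfinite(ratio), np.minimum(4, np.ceil(ratio)), 4)
    bands[nz] = (np.sign(centered[nz]) * mag[nz]).astype(int)
    return HorizonSeries(
        centered=pd.DataFrame(centered, index=df.index, columns=df.columns),
        bands=pd.DataFrame(bands, index=df.index, columns=df.columns),
        medians=pd.Series(med, index=df.columns),
        mads=pd.Series(mad, index=df.columns),
    )


def shared_otu_sets(
    hsets: dict[str, HighAbundanceSet] | list[HighAbundanceSet],
) -> dict:
    """Exact intersection counts for every subject subset.

    Returns ``subset_counts`` mapping each subject subset (frozenset) to the
    size of the intersection of those subjects' high-abundance sets, the
    all-subjects intersection itself, and per subject the fraction of its set
    found in every other subject."""
    if isinstance(hsets, list):
        hsets = {h.subject_id: h for h in hsets}
    if len(hsets) < 2:
        raise ValidationError("need >= 2 subjects")
    sets = {s: set(h.otu_ids) for s, h in hsets.items()}
    subjects = sorted(sets)
    counts: dict[frozenset, int] = {}
    for r in range(1, len(subjects) + 1):
        for combo in combinations(subjects, r):
            inter = set.intersection(*(sets[s] for s in combo))
            counts[frozenset(combo)] = len(inter)
    core = set.intersection(*sets.values())
    fractions = {s: len(core) / len(sets[s]) for s in subjects}
    return {
        "subset_counts": counts,
        "core_otus": sorted(core),
        "core_fraction_per_subject": fractions,
    }
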