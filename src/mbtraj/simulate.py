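"""Synthetic multi-subject longitudinal cohort generator with planted truth.

Emulates the shape of a six-man, 520-day confinement study: ~27 stool samples
per subject spanning pre-entry, confinement and up to six months post-exit;
sequencing depths in the printed range 7,759-91,366 reads; individual-specific
phylum signatures; planted steady-state regimes with recurrence; allochthonous
injection events around day 340; and a slow confinement-driven sharing of rare
taxa across subjects.

The noise model is Dirichlet-multinomial: each regime has a Dirichlet-drawn
baseline composition, each sample's composition is drawn
Dirichlet(concentration x baseline), and reads are multinomial at a depth
uniform in the depth range. ``dirichlet_concentration`` is the single
overdispersion knob. Every draw flows from one generator seeded by
``spec.seed``, so output is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from .core import (
    FractionalTable,
    OtuTable,
    Taxonomy,
    ValidationError,
    phase_for_day,
)

PHYLA = (
    "Firmicutes",
    "Bacteroidetes",
    "Proteobacteria",
    "Actinobacteria",
    "Verrucomicrobia",
)

# Per-subject phylum frequencies for subject-private OTUs: each subject leans
# on a distinctive non-Firmicutes phylum, mirroring individual signatures.
_SUBJECT_PHYLUM_WEIGHTS = np.array(
    [
        [0.55, 0.25, 0.05, 0.10, 0.05],
        [0.45, 0.15, 0.30, 0.05, 0.05],
        [0.60, 0.25, 0.05, 0.10, 0.00],
        [0.70, 0.02, 0.08, 0.15, 0.05],
        [0.55, 0.20, 0.05, 0.10, 0.10],
        [0.65, 0.20, 0.05, 0.10, 0.00],
    ]
)


def _default_day_grid() -> tuple[int, ...]:
    """27 collection days: 2 pre-entry, 21 in-module, 4 post-exit."""
    confinement = tuple(range(13, 520, 25))  # 21 time points
    return (-10, -3) + confinement + (530, 560, 620, 700)


@dataclass
class InjectionEvent:
    """An allochthonous inclusion: from ``day`` to the next regime switch the
    subject's composition is (1-f)*own + f*source."""

    subject: str
    day: int
    allochthonous_fraction: float
    source: str = "other_subject"  # or "environment"

    def __post_init__(self) -> None:
        if not 0.0 <= self.allochthonous_fraction <= 1.0:
            raise ValidationError("allochthonous_fraction must lie in [0, 1]")
        if self.source not in ("other_subject", "environment"):
            raise ValidationError(f"unknown injection source {self.source!r}")


def _default_subjects(n: int) -> list[str]:
    return [str(5001 + i) for i in range(n)]


def _default_events(
    subjects: list[str],
    schedule: dict[str, list[tuple[int, int]]] | None = None,
) -> list[InjectionEvent]:
    # Major-change events for three of six subjects, around day 340
    # (range 330-360), with ~90% allochthonous contribution. When the
    # regime schedule is known, each event snaps to the subject's nearest
    # switch day so the injected community spans a whole episode.
    days = {1: 340, 3: 330, 5: 360}
    events = []
    for i, d in days.items():
        if i >= len(subjects):
            continue
        subj = subjects[i]
        if schedule is not None:
            switches = [s for s, _ in schedule[subj][1:]]
            if switches:
                d = min(switches, key=lambda s: abs(s - d))
        events.append(InjectionEvent(subj, d, 0.9, "other_subject"))
    return events


@dataclass
class CohortSpec:
    """Generator parameters; the defaults mirror the study's printed shape:
    6 subjects, 27 samples each over days -10..700 (entry 0, exit 520),
    depths 7,759-91,366, and per-subject regime counts (6,5,6,5,6,7)."""

    n_subjects: int = 6
    n_otus: int = 300
    shared_otu_fraction: float = 0.3
    day_grid: tuple[int, ...] = field(default_factory=_default_day_grid)
    depth_range: tuple[int, int] = (7759, 91366)
    regimes_per_subject: tuple[int, ...] | int = (6, 5, 6, 5, 6, 7)
    regime_schedule: dict[str, list[tuple[int, int]]] | None = None
    dirichlet_concentration: float = 500.0
    # regimes are rearrangements of a per-subject master profile: this
    # fraction of the subject's taxa is rescaled by lognormal factors
    # (sigma below) at each regime — states differ by abundance shifts of
    # autochthonous members, not by community replacement
    regime_rearranged_fraction: float = 0.3
    regime_rearrangement_sigma: float = 2.0
    # Dirichlet weights for the subject master profile: cohort-shared core
    # taxa carry more expected mass than subject-private ones, so a tranche
    # of every subject's highly abundant OTUs is shared cohort-wide
    shared_alpha: float = 1.5
    private_alpha: float = 0.4
    injection_events: list[InjectionEvent] | None = None
    return_to_initial_subjects: tuple[int, ...] = (3, 5)  # 0-based: 5004, 5006
    convergence_rate: float = 5e-5  # per-day growth of shared rare-taxon mass
    rare_pool_cap: float = 0.05
    seed: int = 0

    @property
    def samples_per_subject(self) -> int:
        return len(self.day_grid)

    def __post_init__(self) -> None:
        if isinstance(self.regimes_per_subject, int):
            self.regimes_per_subject = (self.regimes_per_subject,) * self.n_subjects
        if len(self.regimes_per_subject) < self.n_subjects:
            raise ValidationError("regimes_per_subject shorter than n_subjects")
        if any(k < 1 for k in self.regimes_per_subject):
            raise ValidationError("regimes_per_subject must be >= 1")
        if not 0.0 <= self.shared_otu_fraction <= 1.0:
            raise ValidationError("shared_otu_fraction must lie in [0, 1]")
        lo, hi = self.depth_range
        if lo <= 0 or hi < lo:
            raise ValidationError("depth_range must be positive and ordered")
        if self.convergence_rate < 0:
            raise ValidationError("convergence_rate must be >= 0")


@dataclass
class CohortTruth:
    """Planted ground truth emitted alongside the tables."""

    regime_labels: dict[str, int]          # sample_id -> regime label
    baselines: dict[str, dict[int, np.ndarray]]  # subject -> regime -> profile
    events: list[dict]                      # per injection event, with truth
    schedule: dict[str, list[tuple[int, int]]]
    otu_ids: list[str]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "regime_labels": self.regime_labels,
            "baselines": {
                s: {str(r): b.tolist() for r, b in regs.items()}
                for s, regs in self.baselines.items()
            },
            "events": self.events,
            "schedule": {s: [list(p) for p in v] for s, v in self.schedule.items()},
            "otu_ids": self.otu_ids,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


@dataclass
class Cohort:
    table: OtuTable
    metadata: pd.DataFrame
    taxonomy: Taxonomy
    tree: skbio.TreeNode
    truth: CohortTruth


def inject_event(
    profile: np.ndarray, source_profile: np.ndarray, fraction: float
) -> np.ndarray:
    """Convex mixture (1-fraction)*profile + fraction*source_profile."""
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError("fraction must lie in [0, 1]")
    return (1.0 - fraction) * np.asarray(profile) + fraction * np.asarray(source_profile)


def _build_schedule(
    spec: CohortSpec, rng: np.random.Generator
) -> dict[str, list[tuple[int, int]]]:
    """Per subject: ordered (switch day, regime) pairs.

    Episode sequence starts in regime 1 (covering pre-entry), introduces the
    remaining regimes in order with 1-3 revisits of already-seen regimes, and
    for flagged subjects ends back in regime 1 (post-exit return).
    """
    subjects = _default_subjects(spec.n_subjects)
    days = sorted(spec.day_grid)
    schedule: dict[str, list[tuple[int, int]]] = {}
    for si, subj in enumerate(subjects):
        k = spec.regimes_per_subject[si]
        n_recur = int(rng.integers(1, 4)) if k > 1 else 0
        seq = [1]
        pending = list(range(2, k + 1))
        while pending:
            seq.append(pending.pop(0))
            if n_recur > 0 and len(seq) >= 2 and rng.random() < 0.5:
                prev = int(rng.integers(1, len(seq)))
                cand = seq[prev - 1]
                if cand != seq[-1]:
                    seq.append(cand)
                    n_recur -= 1
        if si in spec.return_to_initial_subjects and seq[-1] != 1:
            seq.append(1)
        # spread episode starts over the post-entry day grid; episode 1 starts
        # before the first sample so pre-entry days are covered
        post_days = [d for d in days if d >= 0]
        n_ep = len(seq)
        if n_ep == 1:
            starts = [days[0]]
        else:
            cut_idx = np.linspace(0, len(post_days), n_ep, endpoint=False)[1:]
            starts = [days[0]] + [post_days[int(np.ceil(c))] for c in cut_idx]
        schedule[subj] = list(zip(starts, seq))
    return schedule


def _regime_at(schedule: list[tuple[int, int]], day: int) -> int:
    regime = schedule[0][1]
    for start, r in schedule:
        if day >= start:
            regime = r
    return regime


def _random_tree(otu_ids: list[str], rng: np.random.Generator) -> skbio.TreeNode:
    """Random topology by coalescent-style pairwise joining, exponential
    branch lengths. Not taxonomy-constrained; exercises UniFrac code paths."""
    nodes = [skbio.TreeNode(name=o, length=float(rng.exponential(0.1)))
             for o in otu_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = skbio.TreeNode(length=float(rng.exponential(0.1)))
        parent.extend([nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = None
    return root


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate (OtuTable, metadata, Taxonomy, PhyloTree, CohortTruth)."""
    rng = np.random.default_rng(spec.seed)
    subjects = _default_subjects(spec.n_subjects)
    otu_ids = [f"OTU_{i:04d}" for i in range(spec.n_otus)]
    n = spec.n_otus

    # --- OTU partition: cohort-shared pool (incl. a rare-sharing subpool)
    n_shared = int(round(spec.shared_otu_fraction * n))
    shared_idx = np.arange(n_shared)
    n_rare = n_shared // 3
    rare_idx = shared_idx[:n_rare]            # confinement-shared rare taxa
    core_shared_idx = shared_idx[n_rare:]
    private_idx = np.arange(n_shared, n)
    per_subject_private = np.array_split(private_idx, max(spec.n_subjects, 1))

    # --- taxonomy: shared pool mostly Firmicutes; private OTUs subject-skewed
    phylum = np.empty(n, dtype=object)
    phylum[shared_idx] = rng.choice(PHYLA, size=n_shared, p=[0.8, 0.1, 0.04, 0.05, 0.01])
    for si, idx in enumerate(per_subject_private):
        w = _SUBJECT_PHYLUM_WEIGHTS[si % len(_SUBJECT_PHYLUM_WEIGHTS)]
        phylum[idx] = rng.choice(PHYLA, size=len(idx), p=w / w.sum())
    taxonomy = Taxonomy({
        o: ("Bacteria", str(phylum[i]), "", "", f"Family_{i % 17}",
            f"Genus_{i % 53}")
        for i, o in enumerate(otu_ids)
    })

    schedule = spec.regime_schedule or _build_schedule(spec, rng)
    for subj in schedule:
        if subj not in subjects:
            raise ValidationError(f"schedule references unknown subject {subj!r}")
    days = sorted(spec.day_grid)
    known_days = set(days)
    for subj, sched in schedule.items():
        for start, _ in sched[1:]:
            if start not in known_days:
                raise ValidationError(
                    f"schedule for {subj!r} references day {start} not on the grid"
                )

    # --- per-subject baselines: regime 1 is the subject's master profile,
    # later regimes rearrange a fraction of its taxa by lognormal factors.
    # Shared-core taxa follow a cohort-level weight profile (the same taxa
    # dominate the shared fraction in every subject), private taxa are
    # subject-specific.
    core_weights = (rng.dirichlet(np.full(len(core_shared_idx), 1.0))
                    if len(core_shared_idx) else np.array([]))
    baselines: dict[str, dict[int, np.ndarray]] = {}
    for si, subj in enumerate(subjects):
        support = np.concatenate([core_shared_idx, per_subject_private[si]])
        regs = sorted({r for _, r in schedule[subj]})
        master = np.zeros(n)
        alpha = np.concatenate([
            spec.shared_alpha * len(core_shared_idx) * core_weights,
            np.full(len(per_subject_private[si]), spec.private_alpha),
        ])
        master[support] = rng.dirichlet(np.maximum(alpha, 1e-3))
        baselines[subj] = {}
        n_move = max(1, int(round(spec.regime_rearranged_fraction * len(support))))
        for r in regs:
            if r == regs[0]:
                baselines[subj][r] = master
                continue
            base = master.copy()
            # abundance-weighted choice: states differ by shifts of the
            # subject's prominent members, as observed in real trajectories
            w = master[support] / master[support].sum()
            idx = rng.choice(support, size=n_move, replace=False, p=w)
            base[idx] *= np.exp(
                rng.normal(0.0, spec.regime_rearrangement_sigma, size=n_move))
            baselines[subj][r] = base / base.sum()

    rare_profile = np.zeros(n)
    if n_rare:
        rare_profile[rare_idx] = 1.0 / n_rare

    events = spec.injection_events
    if events is None:
        events = _default_events(subjects, schedule)
    event_truth: list[dict] = []
    # event -> effective baseline override per (subject, day window)
    overrides: dict[str, list[tuple[int, int, np.ndarray, dict]]] = {s: [] for s in subjects}
    for ev in events:
        if ev.subject not in subjects:
            raise ValidationError(f"injection event references unknown subject {ev.subject!r}")
        sched = schedule[ev.subject]
        own = baselines[ev.subject][_regime_at(sched, ev.day)]
        if ev.source == "other_subject":
            others = [s for s in subjects if s != ev.subject]
            src_subj = others[int(rng.integers(len(others)))]
            src = baselines[src_subj][_regime_at(schedule[src_subj], ev.day)]
            src_name = src_subj
        else:
            env_support = rng.choice(n, size=max(5, n // 10), replace=False)
            src = np.zeros(n)
            src[env_support] = rng.dirichlet(np.full(len(env_support), 0.5))
            src_name = "environment"
        mixed = inject_event(own, src, ev.allochthonous_fraction)
        next_switches = [d for d, _ in sched if d > ev.day]
        end = min(next_switches) if next_switches else days[-1] + 1
        overrides[ev.subject].append((ev.day, end, mixed, {
            "subject": ev.subject, "day": ev.day, "end_day": int(end),
            "allochthonous_fraction": ev.allochthonous_fraction,
            "source": src_name,
        }))
    # injected stretches get their own regime label (a genuinely new state)
    next_label = {s: max(r for _, r in schedule[s]) for s in subjects}

    rows = []
    meta_rows = []
    regime_labels: dict[str, int] = {}
    conc = spec.dirichlet_concentration
    lo, hi = spec.depth_range
    for si, subj in enumerate(subjects):
        for day in days:
            sample_id = f"{subj}.d{day:+04d}".replace("+", "p").replace("-", "m")
            label = _regime_at(schedule[subj], day)
            base = baselines[subj][label]
            for start, end, mixed, info in overrides[subj]:
                if start <= day < end:
                    base = mixed
                    key = (subj, start)
                    if "label" not in info:
                        next_label[subj] += 1
                        info["label"] = next_label[subj]
                    label = info["label"]
            # confinement-driven rare-taxon sharing, growing with day
            w = min(spec.rare_pool_cap, spec.convergence_rate * max(0, day))
            comp_base = (1.0 - w) * base + w * rare_profile
            alpha = conc * comp_base
            pos = alpha > 0
            comp = np.zeros(n)
            comp[pos] = rng.dirichlet(alpha[pos])
            depth = int(rng.integers(lo, hi + 1))
            counts = rng.multinomial(depth, comp)
            rows.append(counts)
            meta_rows.append((sample_id, subj, day, phase_for_day(day)))
            regime_labels[sample_id] = int(label)

    table = OtuTable(pd.DataFrame(
        np.array(rows), index=[m[0] for m in meta_rows], columns=otu_ids
    ))
    metadata = pd.DataFrame(meta_rows, columns=["sample_id", "subject_id", "day", "phase"])
    tree = _random_tree(otu_ids, rng)
    for subj in subjects:
        for _, _, _, info in overrides[subj]:
            event_truth.append(info)
    truth = CohortTruth(
        regime_labels=regime_labels,
        baselines=baselines,
        events=event_truth,
        schedule=schedule,
        otu_ids=otu_ids,
    )
    return Cohort(table, metadata, taxonomy, tree, truth)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, str]:
    """Write the cohort in the formats core reads; truth as a JSON sidecar."""
    from . import core

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": str(outdir / "otu_table.tsv"),
        "metadata": str(outdir / "metadata.tsv"),
        "taxonomy": str(outdir / "taxonomy.tsv"),
        "tree": str(outdir / "tree.nwk"),
        "truth": str(outdir / "truth.json"),
    }
    core.write_otu_table(cohort.table, paths["table"])
    core.write_metadata(cohort.metadata, paths["metadata"])
    core.write_taxonomy(cohort.taxonomy, paths["taxonomy"])
    core.write_tree(cohort.tree, paths["tree"])
    cohort.truth.to_json(paths["truth"])
    return paths
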