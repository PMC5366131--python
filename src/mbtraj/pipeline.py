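"""End-to-end pipeline: simulate/ingest -> normalize -> distances/trend ->
steady states -> source attribution -> CAO -> report.

Every run writes a manifest recording the full effective configuration, the
stage-local seeds (derived from the global seed by stable hashing of stage
names, so stochastic stages have independent reproducible streams) and a
SHA-256 hash of every output file. Rerunning with the same config and seed
reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cao as cao_mod
from . import core, distance, normalize, simulate, sources, states

log = logging.getLogger("mbtraj")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Pipeline configuration; all defaults are recorded in the manifest."""

    out_dir: str = "results/run"
    seed: int = 0
    # inputs: either paths...
    table_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    tree_path: str | None = None
    # ...or a synthetic cohort spec (dict of CohortSpec overrides)
    cohort: dict | None = field(default_factory=dict)
    # stage parameters
    height: float | str = "auto"
    n_perm: int = 999
    n_boot: int = 999
    trend_metric: str = "unifrac-u"
    day_tolerance: int = 3
    gibbs: dict = field(default_factory=dict)
    z_threshold: float = 1.5
    cao_threshold: float = cao_mod.MIN_MEAN_ABUNDANCE
    # certification at p < 0.001 needs > 999 permutations
    cao_n_perm: int = 1999

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise core.ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def validate(self) -> None:
        if self.table_path is not None:
            for p in (self.table_path, self.metadata_path):
                if p is None or not Path(p).exists():
                    raise core.ValidationError(f"input path missing: {p}")
            if self.trend_metric.startswith("unifrac") and (
                self.tree_path is None or not Path(self.tree_path).exists()
            ):
                raise core.ValidationError(
                    "UniFrac trend requested but no tree supplied"
                )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "stage_seeds": {},
        "outputs": {},
        "stages": {},
    }

    def record(stage: str, name: str, path: Path) -> None:
        manifest["outputs"][f"{stage}/{name}"] = {
            "path": str(path), "sha256": _sha256(path),
        }

    # --- stage: ingest / simulate -----------------------------------------
    if config.table_path is not None:
        table = core.read_otu_table(config.table_path)
        meta = core.read_metadata(config.metadata_path)
        taxonomy = (core.read_taxonomy(config.taxonomy_path)
                    if config.taxonomy_path else core.Taxonomy())
        tree = core.read_tree(config.tree_path) if config.tree_path else None
        truth = None
        log.info("ingested table %s: %d samples x %d OTUs",
                 config.table_path, *table.data.shape)
    else:
        seed = stage_seed(config.seed, "simulate")
        manifest["stage_seeds"]["simulate"] = seed
        spec = simulate.CohortSpec(**{**(config.cohort or {}), "seed": seed})
        cohort = simulate.generate_cohort(spec)
        paths = simulate.write_cohort(cohort, out / "cohort")
        for name, p in paths.items():
            record("simulate", name, Path(p))
        table, meta = cohort.table, cohort.metadata
        taxonomy, tree, truth = cohort.taxonomy, cohort.tree, cohort.truth
        log.info("simulated cohort: %d samples x %d OTUs", *table.data.shape)

    frac = core.to_fractional(table)
    subjects = sorted(meta["subject_id"].unique())

    # --- stage: normalize --------------------------------------------------
    norm_dir = out / "normalize"
    norm_dir.mkdir(exist_ok=True)
    hsets: dict[str, normalize.HighAbundanceSet] = {}
    series_by_subject: dict[str, normalize.SubjectSeries] = {}
    for subj in subjects:
        series = normalize.SubjectSeries.from_table(frac, meta, subj)
        series_by_subject[subj] = series
        hset = normalize.select_high_abundance(series)
        hsets[subj] = hset
        ref = normalize.reference_normalize(series, hset)
        hz = normalize.horizon_transform(ref.normalized)
        ref.normalized.to_csv(norm_dir / f"{subj}_normalized.tsv", sep="\t")
        ref.weights.to_csv(norm_dir / f"{subj}_weights.tsv", sep="\t")
        hz.bands.to_csv(norm_dir / f"{subj}_horizon_bands.tsv", sep="\t")
        for suffix in ("normalized", "weights", "horizon_bands"):
            record("normalize", f"{subj}_{suffix}", norm_dir / f"{subj}_{suffix}.tsv")
    shared = normalize.shared_otu_sets(hsets)
    shared_doc = {
        "core_otu_count": len(shared["core_otus"]),
        "core_otus": shared["core_otus"],
        "core_fraction_per_subject": shared["core_fraction_per_subject"],
        "pairwise_counts": {
            "|".join(sorted(k)): v
            for k, v in shared["subset_counts"].items() if len(k) == 2
        },
    }
    with open(norm_dir / "shared_otus.json", "w") as fh:
        json.dump(shared_doc, fh, indent=1)
    record("normalize", "shared_otus", norm_dir / "shared_otus.json")
    manifest["stages"]["normalize"] = {
        "subjects": subjects,
        "hset_sizes": {s: len(h.otu_ids) for s, h in hsets.items()},
        "core_otu_count": len(shared["core_otus"]),
    }

    # --- stage: distances + trend ------------------------------------------
    trend_doc = None
    if tree is not None or config.trend_metric == "jsd":
        seed = stage_seed(config.seed, "trend")
        manifest["stage_seeds"]["trend"] = seed
        series = distance.inter_subject_distance_series(
            frac, meta, metric=config.trend_metric, tree=tree,
            day_tolerance=config.day_tolerance,
        )
        trend = distance.median_regression_trend(series, n_boot=config.n_boot,
                                                 seed=seed)
        trend_doc = {
            "metric": config.trend_metric,
            "slope_per_day": trend.slope,
            "intercept": trend.intercept,
            "rc_range": trend.rc_range,
            "rc_sd": trend.rc_sd,
            "p_value": trend.p_value,
            "n_boot": trend.n_boot,
            "n_pairs": trend.n,
        }
        with open(out / "trend.json", "w") as fh:
            json.dump(trend_doc, fh, indent=1)
        record("trend", "trend", out / "trend.json")
        manifest["stages"]["trend"] = trend_doc

    # --- stage: steady states ----------------------------------------------
    seed = stage_seed(config.seed, "states")
    manifest["stage_seeds"]["states"] = seed
    states_dir = out / "states"
    states_dir.mkdir(exist_ok=True)
    maps: dict[str, states.SteadyStateMap] = {}
    profiles: dict[str, pd.DataFrame] = {}
    state_info: dict[str, dict] = {}
    for subj in subjects:
        series = series_by_subject[subj]
        dm = distance.jsd_matrix(series.data)
        tree_l = states.ward_linkage(dm)
        ids = list(series.data.index)
        if config.height == "auto":
            smap, val = states.auto_height(
                tree_l, ids, series.days, series.data, dm,
                n_perm=config.n_perm, seed=seed, subject_id=subj,
                otu_subset=hsets[subj].otu_ids,
            )
        else:
            smap = states.cut_states(tree_l, float(config.height), ids,
                                     series.days, subj)
            val = states.validate_states(
                smap, series.data, dm, n_perm=config.n_perm, seed=seed,
                otu_subset=hsets[subj].otu_ids,
            ) if smap.n_states >= 2 else None
        maps[subj] = smap
        prof = states.state_profiles(smap, series.data)
        profiles[subj] = prof
        smap.labels.rename("state").to_csv(states_dir / f"{subj}_labels.tsv", sep="\t")
        prof.to_csv(states_dir / f"{subj}_profiles.tsv", sep="\t")
        record("states", f"{subj}_labels", states_dir / f"{subj}_labels.tsv")
        record("states", f"{subj}_profiles", states_dir / f"{subj}_profiles.tsv")
        succ = states.succession_summary(smap)
        state_info[subj] = {
            "n_states": smap.n_states,
            "cut_height": smap.cut_height,
            "validated": bool(val.all_pass) if val is not None else False,
            "overall_p": val.overall_permanova["p_value"] if val else None,
            "succession": succ,
        }
    with open(states_dir / "succession.json", "w") as fh:
        json.dump(state_info, fh, indent=1, default=str)
    record("states", "succession", states_dir / "succession.json")
    manifest["stages"]["states"] = {
        s: {"n_states": v["n_states"], "validated": v["validated"]}
        for s, v in state_info.items()
    }

    # --- stage: source attribution -----------------------------------------
    seed = stage_seed(config.seed, "sources")
    manifest["stage_seeds"]["sources"] = seed
    universe = list(frac.data.columns)
    aligned = {s: p.reindex(columns=universe, fill_value=0.0)
               for s, p in profiles.items()}
    order = {s: [int(v) for v in pd.unique(maps[s].labels)] for s in subjects}
    gibbs_settings = sources.GibbsSettings(**(config.gibbs or {}))
    scores = sources.exogenous_scores(
        aligned, state_order=order, settings=gibbs_settings, seed=seed,
        z_threshold=config.z_threshold,
    )
    sc_table = sources.scores_table(scores)
    sc_table.to_csv(out / "transitions.tsv", sep="\t", index=False)
    record("sources", "transitions", out / "transitions.tsv")
    flagged = sc_table[sc_table["major_change"]]
    manifest["stages"]["sources"] = {
        "n_transitions": len(sc_table),
        "n_major_changes": int(flagged.shape[0]),
        "major_changes": flagged.to_dict("records"),
    }

    # --- stage: CAO ---------------------------------------------------------
    seed = stage_seed(config.seed, "cao")
    manifest["stage_seeds"]["cao"] = seed
    cao_dir = out / "cao"
    cao_dir.mkdir(exist_ok=True)
    cao_info: dict[str, dict] = {}
    for subj in subjects:
        prof = profiles[subj]
        try:
            model = cao_mod.assign_cao(prof, n_perm=config.cao_n_perm, seed=seed,
                                       threshold=config.cao_threshold)
        except core.ValidationError as exc:
            cao_info[subj] = {"skipped": str(exc)}
            continue
        edges = cao_mod.cao_edges(model)
        over = cao_mod.state_overabundance(model, prof)
        model.groups.rename("group").to_csv(cao_dir / f"{subj}_groups.tsv", sep="\t")
        edges.to_csv(cao_dir / f"{subj}_edges.tsv", sep="\t", index=False)
        over.to_csv(cao_dir / f"{subj}_overabundance.tsv", sep="\t")
        for suffix in ("groups", "edges", "overabundance"):
            record("cao", f"{subj}_{suffix}", cao_dir / f"{subj}_{suffix}.tsv")
        cao_info[subj] = {
            "k": model.k,
            "silhouette": model.silhouette,
            "certified": model.certified,
            "n_edges": len(edges),
            "n_otus": len(model.otu_ids),
        }
    manifest["stages"]["cao"] = cao_info

    # --- truth (synthetic runs only): recovery diagnostics -------------------
    if truth is not None:
        from sklearn.metrics import adjusted_rand_score

        aris = {}
        for subj in subjects:
            ids = list(maps[subj].labels.index)
            true = [truth.regime_labels[i] for i in ids]
            aris[subj] = float(adjusted_rand_score(true, list(maps[subj].labels)))
        manifest["stages"]["truth_recovery"] = {
            "state_ari": aris,
            "planted_events": truth.events,
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def render_report(manifest: dict) -> str:
    """Plain-text summary mirroring stage outputs (no recomputation)."""
    lines = ["mbtraj pipeline report", "=" * 40]
    cfg = manifest.get("config", {})
    lines.append(f"seed: {cfg.get('seed')}  out: {cfg.get('out_dir')}")
    stages = manifest.get("stages", {})

    lines.append("\n[normalize]")
    if "normalize" in stages:
        st = stages["normalize"]
        lines.append(f"subjects: {', '.join(st['subjects'])}")
        lines.append("high-abundance set sizes: " + ", ".join(
            f"{s}={n}" for s, n in st["hset_sizes"].items()))
        lines.append(f"OTUs shared by all subjects: {st['core_otu_count']}")
    else:
        lines.append("not run")

    lines.append("\n[beta-diversity trend]")
    if "trend" in stages:
        t = stages["trend"]
        lines.append(
            f"{t['metric']}: slope {t['slope_per_day']:.3e}/day, "
            f"RC_range {t['rc_range']:.3f}, RC_sd {t['rc_sd']:.3f}, "
            f"bootstrap p {t['p_value']:.4g} (n={t['n_pairs']})"
        )
    else:
        lines.append("not run")

    lines.append("\n[steady states]")
    if "states" in stages:
        for s, v in stages["states"].items():
            flag = "validated" if v["validated"] else "unvalidated"
            lines.append(f"subject {s}: {v['n_states']} states ({flag})")
    else:
        lines.append("not run")

    lines.append("\n[source attribution]")
    if "sources" in stages:
        st = stages["sources"]
        lines.append(f"transitions scored: {st['n_transitions']}; "
                     f"major change events: {st['n_major_changes']}")
        for ev in st["major_changes"]:
            lines.append(
                f"  {ev['subject_id']}: state {ev['from_state']} -> "
                f"{ev['to_state']}, e={ev['exogenous']:.2f}, z={ev['z']:.2f}"
            )
    else:
        lines.append("not run")

    lines.append("\n[co-abundance groups]")
    if "cao" in stages:
        for s, v in stages["cao"].items():
            if "skipped" in v:
                lines.append(f"subject {s}: skipped ({v['skipped']})")
            else:
                cert = "certified" if v["certified"] else "not certified"
                lines.append(
                    f"subject {s}: k={v['k']} groups over {v['n_otus']} OTUs, "
                    f"silhouette {v['silhouette']:.2f}, {v['n_edges']} edges, {cert}"
                )
    else:
        lines.append("not run")

    if "truth_recovery" in stages:
        lines.append("\n[planted-truth recovery]")
        aris = stages["truth_recovery"]["state_ari"]
        lines.append("state ARI vs planted regimes: " + ", ".join(
            f"{s}={v:.2f}" for s, v in aris.items()))
    return "\n".join(lines)
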