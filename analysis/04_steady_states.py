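#!/usr/bin/env python
"""Steady-state detection, validation and ecological succession.

Per subject: Ward linkage on the Jensen-Shannon distance matrix, automatic
cut-height choice (best silhouette among cuts whose states pass the
within-state correlation and pairwise PERMANOVA checks), median state
profiles, and the succession timeline (episodes, recurrences,
return-to-initial). When the planted truth is available the detected states
are scored against it with the adjusted Rand index.
"""

import argparse
import json
from pathlib import Path

from sklearn.metrics import adjusted_rand_score

from mbtraj.core import read_metadata, read_otu_table, to_fractional
from mbtraj.distance import jsd_matrix
from mbtraj.normalize import SubjectSeries, select_high_abundance
from mbtraj.states import (
    auto_height,
    state_profiles,
    succession_summary,
    ward_linkage,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--out", default="results/states")
    ap.add_argument("--nperm", type=int, default=999)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cohort = Path(args.cohort)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    frac = to_fractional(read_otu_table(cohort / "otu_table.tsv"))
    meta = read_metadata(cohort / "metadata.tsv")
    truth_path = cohort / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else None

    summaries = {}
    for subj in sorted(meta["subject_id"].unique()):
        series = SubjectSeries.from_table(frac, meta, subj)
        hset = select_high_abundance(series)
        dm = jsd_matrix(series.data)
        tree = ward_linkage(dm)
        smap, val = auto_height(tree, list(series.data.index), series.days,
                                series.data, dm, n_perm=args.nperm,
                                seed=args.seed, subject_id=subj,
                                otu_subset=hset.otu_ids)
        prof = state_profiles(smap, series.data)
        succ = succession_summary(smap)
        smap.labels.rename("state").to_csv(out / f"{subj}_labels.tsv", sep="\t")
        prof.to_csv(out / f"{subj}_profiles.tsv", sep="\t")
        summaries[subj] = succ
        msg = (f"subject {subj}: {smap.n_states} states at height "
               f"{smap.cut_height:.3f}, "
               f"{'validated' if val and val.all_pass else 'unvalidated'}, "
               f"returned_to_initial={succ['returned_to_initial']}")
        if truth is not None:
            labels = truth["regime_labels"]
            true = [labels[i] for i in smap.labels.index]
            ari = adjusted_rand_score(true, list(smap.labels))
            msg += f", ARI vs planted {ari:.2f}"
        print(msg)
        recurring = [s for s, v in succ["states"].items()
                     if v["recurrences"] > 1]
        if recurring:
            print(f"  recurring states: {recurring}")
    with open(out / "succession.json", "w") as fh:
        json.dump(summaries, fh, indent=1)


if __name__ == "__main__":
    main()
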