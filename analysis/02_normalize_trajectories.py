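#!/usr/bin/env python
"""Per-subject trajectory normalization and shared-OTU analysis.

For each subject: select the highly abundant OTUs (90% of summed per-OTU
median abundance), normalize every time point to its similarity-weighted
reference community, and compute horizon-graph bands (median-centered,
MAD-wide). Then intersect the per-subject high-abundance sets to report how
much of each subject's abundant microbiota is shared cohort-wide.
"""

import argparse
import json
from pathlib import Path

from mbtraj.core import (
    aggregate_by_rank,
    read_metadata,
    read_otu_table,
    read_taxonomy,
    to_fractional,
)
from mbtraj.normalize import (
    SubjectSeries,
    horizon_transform,
    reference_normalize,
    select_high_abundance,
    shared_otu_sets,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--out", default="results/normalize")
    args = ap.parse_args()

    cohort = Path(args.cohort)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    table = read_otu_table(cohort / "otu_table.tsv")
    meta = read_metadata(cohort / "metadata.tsv")
    frac = to_fractional(table)

    # phylum-level signatures: mean relative abundance per subject
    taxonomy = read_taxonomy(cohort / "taxonomy.tsv")
    phyla = aggregate_by_rank(frac, taxonomy, "phylum")
    by_subject = phyla.data.groupby(
        meta.set_index("sample_id")["subject_id"]).mean()
    by_subject.to_csv(out / "phylum_means.tsv", sep="\t")
    print("phylum-level mean relative abundance per subject:")
    print((100 * by_subject).round(1).to_string())
    print()

    hsets = {}
    for subj in sorted(meta["subject_id"].unique()):
        series = SubjectSeries.from_table(frac, meta, subj)
        hset = select_high_abundance(series)
        hsets[subj] = hset
        ref = reference_normalize(series, hset)
        hz = horizon_transform(ref.normalized)
        ref.normalized.to_csv(out / f"{subj}_normalized.tsv", sep="\t")
        hz.bands.to_csv(out / f"{subj}_horizon_bands.tsv", sep="\t")
        print(f"subject {subj}: {len(hset.otu_ids)} highly abundant OTUs "
              f"cover {hset.coverage:.1%} of summed medians; "
              f"scale factors {ref.scale_factors.min():.2f}-"
              f"{ref.scale_factors.max():.2f}")

    shared = shared_otu_sets(hsets)
    core = shared["core_otus"]
    print(f"\nOTUs highly abundant in every subject: {len(core)}")
    for subj, fr in shared["core_fraction_per_subject"].items():
        print(f"  {subj}: {fr:.0%} of its high-abundance set is cohort-core")
    with open(out / "shared_otus.json", "w") as fh:
        json.dump({
            "core_otus": core,
            "core_fraction_per_subject": shared["core_fraction_per_subject"],
        }, fh, indent=1)


if __name__ == "__main__":
    main()
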