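"""Domain types, file I/O and elementary transformations.

The pipeline's universal input is an OTU count table (samples x OTUs) with
per-sample metadata (subject, collection day relative to module entry, study
phase), a Greengenes-style taxonomy and, for phylogenetic metrics, a rooted
Newick tree whose leaves are OTU ids.

Tables are stored as pandas DataFrames in the canonical orientation
``samples x OTUs``; on disk the classic QIIME convention (OTUs as rows,
first header ``#OTU ID``) is used, and BIOM-JSON v1.0 is supported as an
alternative interchange format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import skbio

PHASES = ("pre", "confinement", "post")
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_GG_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

ENTRY_DAY = 0
EXIT_DAY = 520


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


# ---------------------------------------------------------------------------
# OTU tables


@dataclass
class OtuTable:
    """Integer count matrix, samples as rows, OTUs as columns.

    Invariants: counts >= 0, every sample total > 0, unique ids.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValidationError("sample and OTU identifiers must be unique")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("counts must be integers")
            df = df.astype(np.int64)
            self.data = df
            arr = df.to_numpy()
        if (arr < 0).any():
            bad = df.index[(arr < 0).any(axis=1)][0]
            raise ValidationError(f"negative count in sample {bad!r}")
        totals = arr.sum(axis=1)
        if (totals == 0).any():
            bad = df.index[totals == 0][0]
            raise ValidationError(f"sample {bad!r} has zero total count")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    def totals(self) -> pd.Series:
        return self.data.sum(axis=1)


@dataclass
class FractionalTable:
    """Relative-abundance matrix; each sample row sums to 1 (tol 1e-9)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.data.to_numpy(dtype=float)
        if (arr < -1e-12).any():
            raise ValidationError("fractional abundances must be non-negative")
        sums = arr.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = self.data.index[np.argmax(np.abs(sums - 1.0))]
            raise ValidationError(f"sample {bad!r} fractions sum to {sums.max()}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)


def to_fractional(table: OtuTable) -> FractionalTable:
    """Divide each sample's counts by its total so rows sum to 1."""
    totals = table.data.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValidationError(f"sample {bad!r} has zero total count")
    return FractionalTable(table.data.div(totals, axis=0))


# ---------------------------------------------------------------------------
# Sample metadata

METADATA_COLUMNS = ("sample_id", "subject_id", "day", "phase")


def validate_metadata(
    meta: pd.DataFrame, entry_day: int = ENTRY_DAY, exit_day: int = EXIT_DAY
) -> pd.DataFrame:
    """Check the metadata schema and phase/day consistency.

    ``day`` is relative to module entry (negative = pre-entry); ``phase`` must
    be ``pre`` for day < entry_day, ``confinement`` inside [entry, exit] and
    ``post`` after exit. (subject_id, day) pairs must be unique.
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    meta = meta.copy()
    meta["day"] = meta["day"].astype(int)
    bad_phase = set(meta["phase"]) - set(PHASES)
    if bad_phase:
        raise ValidationError(f"unknown phase values: {sorted(bad_phase)}")
    expected = np.where(
        meta["day"] < entry_day, "pre",
        np.where(meta["day"] <= exit_day, "confinement", "post"),
    )
    mismatch = meta.loc[meta["phase"].to_numpy() != expected, "sample_id"]
    if len(mismatch):
        raise ValidationError(
            f"phase inconsistent with day for samples: {list(mismatch[:5])}"
        )
    if meta.duplicated(["subject_id", "day"]).any():
        raise ValidationError("(subject_id, day) pairs must be unique")
    if meta["sample_id"].duplicated().any():
        raise ValidationError("sample_id must be unique")
    return meta


def phase_for_day(day: int, entry_day: int = ENTRY_DAY, exit_day: int = EXIT_DAY) -> str:
    if day < entry_day:
        return "pre"
    if day <= exit_day:
        return "confinement"
    return "post"


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Taxonomy


@dataclass
class Taxonomy:
    """otu_id -> lineage of up to 7 ranks (kingdom..species); '' = missing."""

    lineages: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def rank_of(self, otu_id: str, rank: str) -> str:
        idx = RANKS.index(rank)
        lineage = self.lineages.get(otu_id, ())
        if idx < len(lineage):
            return lineage[idx]
        return ""


def parse_lineage(s: str) -> tuple[str, ...]:
    """Parse a Greengenes-style 'k__Bacteria; p__Firmicutes; ...' string.

    Unparseable strings are stored verbatim as a species-level label.
    """
    parts = [p.strip() for p in s.split(";")]
    out = [""] * 7
    parsed_any = False
    for p in parts:
        for i, pref in enumerate(_GG_PREFIXES):
            if p.startswith(pref):
                out[i] = p[len(pref):].strip()
                parsed_any = True
                break
    if not parsed_any and s.strip():
        out[6] = s.strip()
    while out and out[-1] == "":
        out.pop()
    return tuple(out)


def format_lineage(lineage: tuple[str, ...]) -> str:
    padded = list(lineage) + [""] * (7 - len(lineage))
    return "; ".join(pref + name for pref, name in zip(_GG_PREFIXES, padded))


def read_taxonomy(path: str | Path) -> Taxonomy:
    df = pd.read_csv(path, sep="\t", header=None, names=["otu_id", "lineage"],
                     dtype=str, comment="#")
    lineages: dict[str, tuple[str, ...]] = {}
    for otu, lin in zip(df["otu_id"], df["lineage"].fillna("")):
        if otu in lineages:
            raise ValidationError(f"duplicate taxonomy entry for {otu!r}")
        lineages[otu] = parse_lineage(lin)
    return Taxonomy(lineages)


def write_taxonomy(tax: Taxonomy, path: str | Path) -> None:
    with open(path, "w") as fh:
        for otu, lin in tax.lineages.items():
            fh.write(f"{otu}\t{format_lineage(lin)}\n")


def aggregate_by_rank(
    table: FractionalTable, taxonomy: Taxonomy, rank: str
) -> FractionalTable:
    """Sum member-OTU abundances per taxon at ``rank``.

    OTUs lacking an assignment at that rank pool into ``unclassified``;
    per-sample mass is conserved.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = [taxonomy.rank_of(o, rank) or "unclassified" for o in table.otu_ids]
    agg = table.data.T.groupby(pd.Index(labels, name=rank)).sum().T
    return FractionalTable(agg)


# ---------------------------------------------------------------------------
# OTU table I/O: classic QIIME TSV and BIOM-JSON v1.0


def read_otu_table(path: str | Path, format: str = "tsv") -> OtuTable:
    """Read an OTU count table.

    TSV follows the classic QIIME convention (OTUs as rows, first header
    ``#OTU ID``); a transposed table with first header ``#SampleID`` /
    ``sample_id`` is detected and accepted. ``biom-json`` reads the BIOM
    v1.0 JSON schema (sparse or dense).
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom-json":
        return _read_biom_json(path)
    raise ValidationError(f"unknown format {format!r}")


def _read_tsv(path: str | Path) -> OtuTable:
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# Constructed"):  # QIIME comment line
            first = fh.readline()
        header = first.rstrip("\n").split("\t")
        if not header or len(header) < 2:
            raise ValidationError(f"{path}: malformed header line")
        key = header[0].lstrip("#").strip().lower().replace(" ", "").replace("_", "")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValidationError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            rows.append(parts)
    ids = [r[0] for r in rows]
    try:
        values = np.array([[float(v) for v in r[1:]] for r in rows])
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric count ({exc})") from None
    df = pd.DataFrame(values, index=ids, columns=header[1:])
    if key in ("sampleid", "sampleids", "sample"):
        pass  # samples already as rows
    else:
        # default: QIIME classic, OTUs as rows -> transpose to samples x OTUs
        df = df.T
    df.index.name = None
    if not np.allclose(df.to_numpy(), np.round(df.to_numpy())):
        raise ValidationError(f"{path}: non-integer count values")
    return OtuTable(df.astype(np.int64))


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write in the classic QIIME orientation (OTUs as rows, '#OTU ID')."""
    df = table.data.T
    with open(path, "w") as fh:
        fh.write("#OTU ID\t" + "\t".join(df.columns) + "\n")
        for otu, row in zip(df.index, df.to_numpy()):
            fh.write(otu + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def _read_biom_json(path: str | Path) -> OtuTable:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"{path}: invalid JSON ({exc})") from None
    for key in ("rows", "columns", "data", "shape", "matrix_type"):
        if key not in doc:
            raise ValidationError(f"{path}: BIOM document missing field {key!r}")
    n_obs, n_samp = doc["shape"]
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    if len(otu_ids) != n_obs or len(sample_ids) != n_samp:
        raise ValidationError(f"{path}: shape does not match rows/columns")
    mat = np.zeros((n_obs, n_samp))
    if doc["matrix_type"] == "sparse":
        for entry in doc["data"]:
            i, j, v = entry
            mat[int(i), int(j)] = v
    elif doc["matrix_type"] == "dense":
        mat = np.asarray(doc["data"], dtype=float)
    else:
        raise ValidationError(f"{path}: unknown matrix_type {doc['matrix_type']!r}")
    df = pd.DataFrame(mat.T, index=sample_ids, columns=otu_ids)
    if not np.allclose(df.to_numpy(), np.round(df.to_numpy())):
        raise ValidationError(f"{path}: non-integer count values")
    return OtuTable(df.astype(np.int64))


def write_biom_json(table: OtuTable, path: str | Path, table_id: str = "table") -> None:
    """Write BIOM v1.0 JSON (sparse)."""
    mat = table.data.T.to_numpy()  # obs x samples
    data = [
        [int(i), int(j), int(mat[i, j])]
        for i, j in zip(*np.nonzero(mat))
    ]
    doc = {
        "id": table_id,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "mbtraj",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [mat.shape[0], mat.shape[1]],
        "rows": [{"id": o, "metadata": None} for o in table.otu_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Phylogenetic tree


def read_tree(path: str | Path) -> skbio.TreeNode:
    tree = skbio.TreeNode.read(str(path), format="newick")
    validate_tree(tree)
    return tree


def write_tree(tree: skbio.TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def validate_tree(tree: skbio.TreeNode) -> None:
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise ValidationError("tree leaf labels are not unique")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValidationError(f"negative branch length at {node.name!r}")


def check_leaf_coverage(tree: skbio.TreeNode, otu_ids: Iterable[str]) -> list[str]:
    """Return the OTU ids absent from the tree's leaves."""
    leaves = {t.name for t in tree.tips()}
    return sorted(set(otu_ids) - leaves)
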