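"""Readers and writers for the on-disk artifacts of an epicarp study.

Conventions
-----------
* Feature tables are tab-delimited, phylotypes as rows, samples as columns
  (the usual orientation of amplicon count tables); the first column holds the
  phylotype id.
* Taxonomy is stored as QIIME-style lineage strings ``k__X; p__Y; ...; s__Z``.
  Unassigned ranks are serialized as empty ``r__`` tokens so rank position is
  never ambiguous; readers also tolerate truncated lineages.
* Distance matrices use the square labelled TSV understood by
  :class:`skbio.DistanceMatrix` (``lsmat``).

All readers validate their input and raise :class:`~epicarp.errors.FormatError`
or :class:`~epicarp.errors.ValidationError` naming the first offending record;
all writers emit files their readers accept.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix

from .errors import FormatError, ValidationError

#: The seven taxonomic ranks used throughout, highest first.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Single-letter lineage prefixes, aligned with :data:`RANKS`.
RANK_PREFIXES = ("k", "p", "c", "o", "f", "g", "s")

METADATA_COLUMNS = (
    "sample_id",
    "pair_id",
    "fruit_type",
    "ripening_stage",
    "replicate",
    "spiked",
    "site_x_km",
    "site_y_km",
    "mean_radius_mm",
    "fruits_per_sample",
)


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the structural invariants of a phylotype-by-sample count table.

    Returns the table with an integer dtype. Raises
    :class:`ValidationError` on duplicate ids, non-integral or negative
    counts; an all-zero sample column is legal but triggers a warning.
    """
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()][0]
        raise ValidationError(f"duplicate phylotype id {dup!r}")
    if table.columns.has_duplicates:
        dup = table.columns[table.columns.duplicated()][0]
        raise ValidationError(f"duplicate sample id {dup!r}")
    values = table.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.integer):
        frac, _ = np.modf(values.astype(float))
        if np.any(frac != 0):
            i, j = np.argwhere(frac != 0)[0]
            raise ValidationError(
                f"non-integer count {values[i, j]!r} at phylotype "
                f"{table.index[i]!r}, sample {table.columns[j]!r}"
            )
    if values.size and (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative count at phylotype {table.index[i]!r}, "
            f"sample {table.columns[j]!r}"
        )
    out = table.astype(np.int64)
    empty = out.columns[out.sum(axis=0) == 0]
    if len(empty):
        warnings.warn(
            f"sample(s) with all-zero counts retained: {list(empty)}",
            stacklevel=2,
        )
    return out


def read_feature_table(path) -> pd.DataFrame:
    """Read a TSV count table (phylotypes x samples) with strict validation."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    parsed = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        if numeric.isna().any():
            row = raw.index[numeric.isna()][0]
            raise FormatError(
                f"non-numeric count {raw.loc[row, col]!r} at phylotype "
                f"{row!r}, sample {col!r}"
            )
        parsed[col] = numeric
    try:
        return validate_feature_table(parsed)
    except ValidationError as exc:  # keep the file context in the message
        raise FormatError(f"{path}: {exc}") from exc


def write_feature_table(table: pd.DataFrame, path) -> None:
    validate_feature_table(table).to_csv(path, sep="\t", index_label="phylotype_id")


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def parse_lineage(lineage: str) -> dict:
    """Parse a ``k__X; p__Y`` lineage string into a rank -> name mapping.

    Empty or missing trailing tokens yield empty strings. Raises
    :class:`FormatError` on unknown prefixes, out-of-order ranks, or a rank
    gap (a rank assigned below an unassigned one), which would make
    taxonomic aggregation ambiguous.
    """
    fields = [f.strip() for f in lineage.split(";")] if lineage.strip() else []
    names = {rank: "" for rank in RANKS}
    position = -1
    for field in fields:
        if not field:
            continue
        if "__" not in field:
            raise FormatError(f"malformed lineage token {field!r} in {lineage!r}")
        prefix, name = field.split("__", 1)
        if prefix not in RANK_PREFIXES:
            raise FormatError(f"unknown rank prefix {prefix!r} in {lineage!r}")
        idx = RANK_PREFIXES.index(prefix)
        if idx <= position:
            raise FormatError(f"out-of-order rank {prefix!r} in {lineage!r}")
        position = idx
        names[RANKS[idx]] = name.strip()
    assigned = [bool(names[r]) for r in RANKS]
    if True in assigned:
        deepest = max(i for i, a in enumerate(assigned) if a)
        for i in range(deepest):
            if not assigned[i]:
                raise FormatError(
                    f"lineage {lineage!r} assigns {RANKS[deepest]} but leaves "
                    f"{RANKS[i]} unassigned (rank gap)"
                )
    return names


def format_lineage(names: Mapping[str, str]) -> str:
    """Serialize a rank mapping as a full 7-token lineage string."""
    return "; ".join(
        f"{p}__{names.get(r, '')}" for p, r in zip(RANK_PREFIXES, RANKS)
    )


def validate_taxonomy(taxonomy: pd.DataFrame, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check a parsed taxonomy frame; optionally check coverage of a table."""
    missing = [c for c in RANKS if c not in taxonomy.columns]
    if missing:
        raise ValidationError(f"taxonomy missing rank column(s) {missing}")
    if taxonomy.index.has_duplicates:
        dup = taxonomy.index[taxonomy.index.duplicated()][0]
        raise ValidationError(f"duplicate phylotype id {dup!r} in taxonomy")
    if table is not None:
        absent = table.index.difference(taxonomy.index)
        if len(absent):
            raise ValidationError(
                f"phylotype {absent[0]!r} in the feature table has no taxonomy row"
            )
    return taxonomy


def read_taxonomy(path) -> pd.DataFrame:
    """Read a TSV of ``phylotype_id<TAB>lineage[<TAB>species_hint]``.

    Returns a frame indexed by phylotype id with one column per rank plus
    ``species_hint`` (empty string when absent).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "phylotype_id" not in raw.columns or "lineage" not in raw.columns:
        raise FormatError(f"{path}: taxonomy must have 'phylotype_id' and 'lineage' columns")
    rows = {}
    for _, rec in raw.iterrows():
        pid = rec["phylotype_id"]
        if pid in rows:
            raise FormatError(f"{path}: duplicate phylotype id {pid!r}")
        try:
            names = parse_lineage(rec["lineage"])
        except FormatError as exc:
            raise FormatError(f"{path}: phylotype {pid!r}: {exc}") from exc
        names["species_hint"] = rec.get("species_hint", "")
        rows[pid] = names
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "phylotype_id"
    return validate_taxonomy(frame)


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    validate_taxonomy(taxonomy)
    out = pd.DataFrame(
        {
            "phylotype_id": taxonomy.index,
            "lineage": [format_lineage(row) for _, row in taxonomy.iterrows()],
            "species_hint": taxonomy.get(
                "species_hint", pd.Series("", index=taxonomy.index)
            ).to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the factorial-design invariants of a sample metadata frame.

    Expects the frame indexed by sample id. Stages must lie in 1..4, radii be
    positive, and every pair id map to exactly one spiked and one non-spiked
    sample.
    """
    required = [c for c in METADATA_COLUMNS if c != "sample_id"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing column(s) {missing}")
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise ValidationError(f"duplicate sample id {dup!r}")
    stages = meta["ripening_stage"].astype(int)
    bad = meta.index[~stages.isin([1, 2, 3, 4])]
    if len(bad):
        raise ValidationError(
            f"sample {bad[0]!r} has ripening_stage "
            f"{meta.loc[bad[0], 'ripening_stage']!r} outside 1-4"
        )
    radii = meta["mean_radius_mm"].astype(float)
    bad = meta.index[radii <= 0]
    if len(bad):
        raise ValidationError(f"sample {bad[0]!r} has non-positive mean_radius_mm")
    offenders = []
    for pair, sub in meta.groupby("pair_id", sort=True):
        spiked = sub["spiked"].astype(bool)
        if len(sub) != 2 or spiked.sum() != 1:
            offenders.append(str(pair))
    if offenders:
        raise ValidationError(
            "pair id(s) without exactly one spiked and one non-spiked sample: "
            + ", ".join(sorted(offenders))
        )
    out = meta.copy()
    out["ripening_stage"] = stages
    out["replicate"] = out["replicate"].astype(int)
    out["spiked"] = out["spiked"].astype(bool)
    for col in ("site_x_km", "site_y_km", "mean_radius_mm"):
        out[col] = out[col].astype(float)
    out["fruits_per_sample"] = out["fruits_per_sample"].astype(int)
    return out


def read_metadata(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    if "sample_id" not in raw.columns:
        raise FormatError(f"{path}: metadata must have a 'sample_id' column")
    raw = raw.set_index("sample_id")
    try:
        return validate_metadata(raw)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_metadata(meta: pd.DataFrame, path) -> None:
    validate_metadata(meta).to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# sequences and distance matrices
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    """Read a FASTA file into an id -> uppercase sequence mapping."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_distance_matrix(path) -> DistanceMatrix:
    return DistanceMatrix.read(str(path), format="lsmat")


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    dm.write(str(path), format="lsmat")
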