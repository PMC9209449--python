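"""Internal-standard (spike-in) detection, recovery assessment, and absolute
cell quantification.

A known number of live cells of a foreign fungus is added to one half of every
sample before DNA extraction. If the standard's phylotype is reliably
recovered in the spiked halves of a stratum (and rarely appears naturally in
the non-spiked halves), read counts in that stratum can be converted to
absolute cell numbers:

    cells_ij = reads_ij / standard_reads_j * cells_added

Because this is a read ratio, the estimate is invariant to sequencing depth.
Cell totals are additionally expressed per mm^2 of fruit surface, approximated
per sample as ``fruits_per_sample * 4 * pi * r^2`` from the mean fruit radius.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousStandardError,
    ParameterError,
    StandardNotFoundError,
    ValidationError,
)


@dataclass(frozen=True)
class SpikeConfig:
    """How to find the standard and when to trust a stratum.

    A stratum (fruit type) is *usable* when the standard is seen in at least
    ``min_spiked_recovery`` of its spiked samples and at most
    ``max_background_rate`` of its non-spiked ones. With the defaults a
    23/24-spiked, 1/24-non-spiked stratum qualifies and a 12/24 one does not.
    """

    standard_label: str = "Plectosphaerella cucumerina"
    standard_sequence: str | None = None
    cells_added: int = 265
    identity_threshold: float = 1.0
    min_spiked_recovery: float = 0.90
    max_background_rate: float = 0.10
    background_correction: bool = True

    def validate(self) -> "SpikeConfig":
        for name in ("identity_threshold", "min_spiked_recovery", "max_background_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.cells_added < 1:
            raise ParameterError("cells_added must be a positive count")
        return self


def detect_standard(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
    config: SpikeConfig | None = None,
    sequences: dict | None = None,
) -> tuple[str, pd.Series]:
    """Resolve the internal-standard phylotype and return its read vector.

    Matching is by exact sequence identity against ``sequences`` when a
    reference sequence is configured, otherwise by taxonomy: a phylotype whose
    species, species hint or genus equals ``standard_label``. Exactly one
    match is required.
    """
    config = (config or SpikeConfig()).validate()
    candidates: list[str] = []
    if config.standard_sequence is not None:
        if not sequences:
            raise ParameterError(
                "standard_sequence configured but no representative sequences given"
            )
        ref = config.standard_sequence.upper()
        for pid, seq in sequences.items():
            if pid in table.index and _identity(seq.upper(), ref) >= config.identity_threshold:
                candidates.append(pid)
    elif taxonomy is not None:
        label = config.standard_label
        tax = taxonomy.loc[taxonomy.index.intersection(table.index)]
        hint = tax.get("species_hint", pd.Series("", index=tax.index))
        mask = (
            (tax["species"] == label) | (hint == label) | (tax["genus"] == label)
        )
        candidates = list(tax.index[mask])
    else:
        if config.standard_label in table.index:
            candidates = [config.standard_label]
    if not candidates:
        raise StandardNotFoundError(
            f"internal standard {config.standard_label!r} not found in the table"
        )
    if len(candidates) > 1:
        raise AmbiguousStandardError(
            f"multiple phylotypes match the internal standard: {sorted(candidates)}"
        )
    pid = candidates[0]
    return pid, table.loc[pid].copy()


def _identity(a: str, b: str) -> float:
    """Fractional identity of two sequences (edit-distance based)."""
    if a == b:
        return 1.0
    try:
        import edlib

        d = edlib.align(a, b)["editDistance"]
        return 1.0 - d / max(len(a), len(b))
    except ImportError:  # exact matching only
        return 0.0


def assess_recovery(
    standard_reads: pd.Series,
    metadata: pd.DataFrame,
    config: SpikeConfig | None = None,
    stratify_by: str = "fruit_type",
) -> pd.DataFrame:
    """Per-stratum recovery of the standard in spiked vs non-spiked samples.

    Returns one row per stratum with positive-sample counts, the recovery and
    background rates, and the ``usable`` flag defined by the config
    thresholds.
    """
    config = (config or SpikeConfig()).validate()
    present = standard_reads.reindex(metadata.index) > 0
    if present.isna().any():
        missing = metadata.index[present.isna()][0]
        raise ValidationError(f"no standard reads recorded for sample {missing!r}")
    rows = []
    for stratum, sub in metadata.groupby(stratify_by, sort=True):
        spiked = sub.index[sub["spiked"]]
        nonspiked = sub.index[~sub["spiked"]]
        n_sp, n_ns = len(spiked), len(nonspiked)
        pos_sp = int(present[spiked].sum())
        pos_ns = int(present[nonspiked].sum())
        recovery = pos_sp / n_sp if n_sp else float("nan")
        background = pos_ns / n_ns if n_ns else float("nan")
        usable = (
            n_sp > 0
            and recovery >= config.min_spiked_recovery
            and (n_ns == 0 or background <= config.max_background_rate)
        )
        rows.append(
            {
                stratify_by: stratum,
                "n_spiked": n_sp,
                "n_spiked_positive": pos_sp,
                "n_nonspiked": n_ns,
                "n_nonspiked_positive": pos_ns,
                "spiked_recovery": recovery,
                "background_rate": background,
                "usable": usable,
            }
        )
    return pd.DataFrame(rows).set_index(stratify_by)


def estimate_surface_area(mean_radius_mm: float, fruits_per_sample: int = 1) -> float:
    """Pooled fruit surface area in mm^2: ``n * 4 * pi * r^2``."""
    if not mean_radius_mm > 0:
        raise ParameterError("mean_radius_mm must be positive")
    if fruits_per_sample < 1:
        raise ParameterError("fruits_per_sample must be at least 1")
    return fruits_per_sample * 4.0 * math.pi * mean_radius_mm**2


@dataclass
class AbsoluteAbundanceTable:
    """Estimated absolute abundances for the usable spiked samples.

    ``cells`` excludes the standard phylotype; ``excluded`` maps sample id to
    the reason it was dropped (zero or fully background-corrected standard
    reads, or an unusable stratum).
    """

    cells: pd.DataFrame  # phylotype x sample, estimated cells
    total_cells: pd.Series
    surface_area_mm2: pd.Series
    total_cells_per_mm2: pd.Series
    standard_id: str
    excluded: dict = field(default_factory=dict)

    def subset_cells_per_mm2(self, phylotype_ids) -> pd.Series:
        """Cell density of a taxon subset (e.g. one order) per sample."""
        ids = [p for p in phylotype_ids if p in self.cells.index]
        return self.cells.loc[ids].sum(axis=0) / self.surface_area_mm2


def absolute_abundance(
    table: pd.DataFrame,
    standard_id: str,
    metadata: pd.DataFrame,
    config: SpikeConfig | None = None,
    recovery: pd.DataFrame | None = None,
) -> AbsoluteAbundanceTable:
    """Convert reads to estimated cells for spiked samples in usable strata.

    With background correction on (default), each spiked sample's standard
    reads are first reduced by the standard reads of its paired non-spiked
    half — the natural occurrence of the standard taxon would otherwise
    inflate the denominator. Pairs whose corrected standard reads drop to
    zero or below are excluded, as are samples with no standard reads at all.
    """
    config = (config or SpikeConfig()).validate()
    if standard_id not in table.index:
        raise StandardNotFoundError(f"{standard_id!r} not present in the table")
    standard_reads = table.loc[standard_id]
    if recovery is None:
        recovery = assess_recovery(standard_reads, metadata, config)
    usable_strata = set(recovery.index[recovery["usable"]])

    pair_lookup = {}
    for pair, sub in metadata.groupby("pair_id"):
        spiked_ids = sub.index[sub["spiked"]]
        nonspiked_ids = sub.index[~sub["spiked"]]
        if len(spiked_ids) == 1 and len(nonspiked_ids) == 1:
            pair_lookup[spiked_ids[0]] = nonspiked_ids[0]

    excluded: dict[str, str] = {}
    kept: dict[str, float] = {}
    for sid in metadata.index[metadata["spiked"]]:
        stratum = metadata.loc[sid, "fruit_type"]
        if stratum not in usable_strata:
            excluded[sid] = f"stratum {stratum!r} not usable"
            continue
        reads = float(standard_reads.get(sid, 0))
        if reads <= 0:
            excluded[sid] = "no standard reads"
            continue
        if config.background_correction and sid in pair_lookup:
            reads -= float(standard_reads.get(pair_lookup[sid], 0))
            if reads <= 0:
                excluded[sid] = "standard reads fully explained by background"
                continue
            reads = max(reads, 1.0)
        kept[sid] = reads
    if not kept:
        raise ValidationError("no usable spiked samples for absolute quantification")

    sample_ids = [s for s in metadata.index if s in kept]
    denom = np.array([kept[s] for s in sample_ids])
    community = table.drop(index=standard_id)
    cells = community[sample_ids].astype(float) / denom * config.cells_added
    total = cells.sum(axis=0)
    area = pd.Series(
        [
            estimate_surface_area(
                float(metadata.loc[s, "mean_radius_mm"]),
                int(metadata.loc[s, "fruits_per_sample"]),
            )
            for s in sample_ids
        ],
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for sid, reason in excluded.items():
        warnings.warn(f"sample {sid!r} excluded from quantification: {reason}")
    return AbsoluteAbundanceTable(
        cells=cells,
        total_cells=total,
        surface_area_mm2=area,
        total_cells_per_mm2=total / area,
        standard_id=standard_id,
        excluded=excluded,
    )


def remove_standard(table: pd.DataFrame, standard_id: str) -> pd.DataFrame:
    """Drop the standard phylotype row before community analysis (idempotent)."""
    if standard_id not in table.index:
        warnings.warn(f"standard {standard_id!r} not in table; returning unchanged")
        return table.copy()
    return table.drop(index=standard_id)
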