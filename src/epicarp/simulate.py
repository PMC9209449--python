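"""Ground-truthed synthetic epicarp communities.

The generator emulates the study design the analysis pipeline expects: four
fruit types sampled at four ripening stages with six biological replicates,
every sample split into a spiked half (a fixed number of live internal-standard
cells added before DNA extraction) and a non-spiked half, sequenced to a depth
of tens of thousands of ITS reads.

Model
-----
* Base phylotype abundances are log-normal (a long-tailed community in which a
  few moulds dominate, as on real fruit surfaces).
* Each fruit type carries a disjoint set of indicator phylotypes whose
  abundance is multiplied by a fold change on that fruit; a second set of
  stage-responsive phylotypes trends monotonically across ripening stages.
* The realized community of each *pair* (the physical fruit wash, before it is
  split in two) is a Dirichlet draw around the expected composition, scaled to
  an absolute cell total; both halves share it, as the halves of a real wash
  share one community.
* Reads are multinomial draws at a log-normally varying depth, independently
  per half, so the spiked and non-spiked halves are technical replicates of
  one biological sample.
* The internal standard occurs as a sparse natural background (Poisson cells
  in a random subset of pairs) and as exactly ``spike_cells`` additional cells
  in every spiked half.

Everything is driven by one seed; identical parameters give bit-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .errors import ParameterError

DEFAULT_FRUITS = ("blueberry", "cherry", "raspberry", "strawberry")

#: Identifier given to the internal-standard phylotype in synthetic tables.
STANDARD_ID = "phylo_standard"

#: Lineage of the internal standard (a Plectosphaerella cucumerina isolate).
STANDARD_LINEAGE = {
    "kingdom": "Fungi",
    "phylum": "Ascomycota",
    "class": "Sordariomycetes",
    "order": "Glomerellales",
    "family": "Plectosphaerellaceae",
    "genus": "Plectosphaerella",
    "species": "Plectosphaerella cucumerina",
}

# Mean fruit radius (mm) per stage 1..4; fruits swell as they ripen.
DEFAULT_RADII = {
    "blueberry": (3.0, 4.0, 5.0, 6.0),
    "cherry": (6.0, 8.0, 10.0, 12.0),
    "raspberry": (7.0, 8.5, 10.0, 11.0),
    "strawberry": (8.0, 10.0, 13.0, 15.0),
}

# One fixed site per fruit type within a <19 km span; the stone- and
# cane-fruit sites sit close together, the others further out.
DEFAULT_SITES = {
    "blueberry": (0.0, 0.0),
    "cherry": (12.0, 3.0),
    "raspberry": (15.0, 5.0),
    "strawberry": (4.0, 16.0),
}

# Host-potential-index scores per fruit: synthetic stand-ins on the published
# scale, ordered so raspberry carries the maximum.
DEFAULT_HPI = {
    "raspberry": 2.1,
    "strawberry": 1.3,
    "cherry": 1.1,
    "blueberry": 0.6,
}


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic study.

    Defaults reproduce the real design: 4 fruits x 4 stages x 6 replicates,
    each sample split into spiked/non-spiked halves, 265 standard cells per
    spiked half at roughly 0.5% of a community of ~53,000 cells, mean depth
    50,000 reads, and a sparse natural background of the standard taxon.
    """

    fruit_types: tuple = DEFAULT_FRUITS
    n_stages: int = 4
    n_replicates: int = 6
    n_phylotypes: int = 300
    depth_mean: float = 50_000.0
    depth_cv: float = 0.3
    overdispersion: float = 200.0
    spike_cells: int = 265
    spike_target_fraction: float = 0.005
    #: Natural occurrence of the standard taxon among non-spiked samples:
    #: a single rate, or a fruit -> rate mapping (key "default" as fallback).
    #: The default keeps cherry nearly background-free while the overall rate
    #: sits near one-in-five, so exactly one stratum passes the usability gate.
    background_spike_prevalence: float | dict = field(
        default_factory=lambda: {"cherry": 1 / 24, "default": 0.28}
    )
    background_spike_reads_mean: float = 20.0
    n_indicator_taxa_per_fruit: int = 10
    indicator_fold_change: float = 8.0
    n_stage_taxa: int = 10
    stage_fold_change: float = 2.0
    radius_mm_by_fruit_stage: dict = field(default_factory=lambda: dict(DEFAULT_RADII))
    fruits_per_sample: dict = field(
        default_factory=lambda: {"blueberry": 20, "default": 10}
    )
    site_coords_km: dict = field(default_factory=lambda: dict(DEFAULT_SITES))
    seed: int = 0

    def validate(self) -> "SimulationParams":
        if len(self.fruit_types) < 1 or len(set(self.fruit_types)) != len(self.fruit_types):
            raise ParameterError("fruit_types must be non-empty and unique")
        for name in ("n_stages", "n_replicates", "n_phylotypes", "spike_cells"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be a positive count")
        if self.n_stages > 4:
            raise ParameterError("n_stages must be at most 4 (stages are coded 1-4)")
        for name in ("depth_mean", "overdispersion", "indicator_fold_change",
                     "stage_fold_change"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("spike_target_fraction",):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ParameterError(f"{name} must lie in (0, 1)")
        bg = self.background_spike_prevalence
        bg_values = bg.values() if isinstance(bg, dict) else [bg]
        if not all(0 <= v < 1 for v in bg_values):
            raise ParameterError("background_spike_prevalence must lie in [0, 1)")
        if self.depth_cv < 0 or self.background_spike_reads_mean < 0:
            raise ParameterError("depth_cv and background_spike_reads_mean must be >= 0")
        needed = self.n_indicator_taxa_per_fruit * len(self.fruit_types) + self.n_stage_taxa
        if needed > self.n_phylotypes:
            raise ParameterError(
                "n_phylotypes too small for the requested indicator and stage taxa"
            )
        for fruit in self.fruit_types:
            radii = self.radii_for(fruit)
            if any(r <= 0 for r in radii):
                raise ParameterError(f"radius_mm_by_fruit_stage[{fruit!r}] must be positive")
            if any(b < a for a, b in zip(radii, radii[1:])):
                raise ParameterError(
                    f"radius_mm_by_fruit_stage[{fruit!r}] must be non-decreasing with stage"
                )
            if self.fruit_count_for(fruit) < 1:
                raise ParameterError(f"fruits_per_sample[{fruit!r}] must be >= 1")
        return self

    # -- per-fruit lookups with sensible fallbacks ---------------------------
    def radii_for(self, fruit: str) -> tuple:
        radii = self.radius_mm_by_fruit_stage.get(fruit)
        if radii is None:
            radii = tuple(5.0 + 2.0 * s for s in range(self.n_stages))
        return tuple(radii)[: self.n_stages]

    def fruit_count_for(self, fruit: str) -> int:
        return int(
            self.fruits_per_sample.get(fruit, self.fruits_per_sample.get("default", 10))
        )

    def background_for(self, fruit: str) -> float:
        bg = self.background_spike_prevalence
        if isinstance(bg, dict):
            return float(bg.get(fruit, bg.get("default", 0.0)))
        return float(bg)

    def site_for(self, fruit: str, index: int) -> tuple:
        if fruit in self.site_coords_km:
            return tuple(self.site_coords_km[fruit])
        # spread unknown fruits on a coarse grid inside the 19 km span
        return (4.0 * (index % 5), 4.0 * (index // 5))

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["fruit_types"] = list(d["fruit_types"])
        d["radius_mm_by_fruit_stage"] = {
            k: list(v) for k, v in d["radius_mm_by_fruit_stage"].items()
        }
        d["site_coords_km"] = {k: list(v) for k, v in d["site_coords_km"].items()}
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class GroundTruth:
    """The cell-scale truth behind a simulated read table."""

    true_cells: pd.DataFrame  # phylotype x sample, absolute cells (incl. standard)
    true_indicator_sets: dict  # fruit -> list of phylotype ids
    true_stage_taxa: list  # phylotype ids with a ripening trend
    true_group_effects: dict  # factor -> effect description
    taxonomy: pd.DataFrame


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def generate_design(params: SimulationParams) -> pd.DataFrame:
    """Build the factorial sample sheet: one spiked and one non-spiked half per
    fruit x stage x replicate combination, sharing a pair id.

    Returns a metadata frame indexed by sample id that satisfies
    :func:`epicarp.io.validate_metadata`.
    """
    params.validate()
    rows = []
    for fi, fruit in enumerate(params.fruit_types):
        radii = params.radii_for(fruit)
        site = params.site_for(fruit, fi)
        for stage in range(1, params.n_stages + 1):
            for rep in range(1, params.n_replicates + 1):
                pair = f"{fruit}_s{stage}_r{rep}"
                for spiked, suffix in ((False, "N"), (True, "S")):
                    rows.append(
                        {
                            "sample_id": f"{pair}_{suffix}",
                            "pair_id": pair,
                            "fruit_type": fruit,
                            "ripening_stage": stage,
                            "replicate": rep,
                            "spiked": spiked,
                            "site_x_km": site[0],
                            "site_y_km": site[1],
                            "mean_radius_mm": radii[stage - 1],
                            "fruits_per_sample": params.fruit_count_for(fruit),
                        }
                    )
    meta = pd.DataFrame(rows).set_index("sample_id")
    return eio.validate_metadata(meta)


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

_SACCHAROMYCETALES = [
    # (family, genus, [species hints])
    ("Saccharomycodaceae", "Hanseniaspora", ["Hanseniaspora uvarum"] * 4 + ["Hanseniaspora opuntiae"]),
    ("Pichiaceae", "Pichia", ["Pichia terricola", "Pichia pijperi", ""]),
    ("Metschnikowiaceae", "Metschnikowia", ["Metschnikowia pulcherrima", "Metschnikowia gruessii", "Metschnikowia kunwiensis", ""]),
    ("Saccharomycetaceae", "Saccharomyces", ["Saccharomyces cerevisiae", ""]),
    ("Incertae sedis", "Candida", ["Candida zemplinina", "Candida californica", "", ""]),
    ("Debaryomycetaceae", "Debaryomyces", [""]),
    ("Metschnikowiaceae", "Kodamaea", [""]),
    ("Incertae sedis", "Starmerella", [""]),
    ("Phaffomycetaceae", "Barnettozyma", [""]),
    ("Dipodascaceae", "Geotrichum", [""]),
]

_FILAMENTOUS = [
    ("Ascomycota", "Dothideomycetes", "Capnodiales", "Cladosporiaceae", "Cladosporium", ""),
    ("Ascomycota", "Dothideomycetes", "Dothideales", "Dothioraceae", "Aureobasidium", "Aureobasidium pullulans"),
    ("Ascomycota", "Leotiomycetes", "Helotiales", "Sclerotiniaceae", "Botrytis", "Botrytis cinerea"),
    ("Ascomycota", "Eurotiomycetes", "Eurotiales", "Aspergillaceae", "Penicillium", ""),
    ("Ascomycota", "Dothideomycetes", "Pleosporales", "Pleosporaceae", "Alternaria", ""),
    ("Ascomycota", "Dothideomycetes", "Capnodiales", "Mycosphaerellaceae", "Ramularia", "Ramularia endophylla"),
    ("Ascomycota", "Leotiomycetes", "Erysiphales", "Erysiphaceae", "Podosphaera", "Podosphaera aphanis"),
    ("Basidiomycota", "Exobasidiomycetes", "Exobasidiales", "Exobasidiaceae", "Exobasidium", ""),
    ("Basidiomycota", "Microbotryomycetes", "Sporidiobolales", "Sporidiobolaceae", "Sporobolomyces", ""),
    ("Basidiomycota", "Tremellomycetes", "Tremellales", "Bulleribasidiaceae", "Vishniacozyma", ""),
    ("Basidiomycota", "Tremellomycetes", "Filobasidiales", "Filobasidiaceae", "Filobasidium", ""),
    ("Basidiomycota", "Ustilaginomycetes", "Ustilaginales", "Ustilaginaceae", "Kalmanozyma", "Kalmanozyma fusiformata"),
]


def generate_taxonomy(phylotype_ids, rng: np.random.Generator) -> pd.DataFrame:
    """Assign plausible fungal lineages to synthetic phylotypes.

    Roughly 12% of phylotypes are budding yeasts (order Saccharomycetales,
    including the genera attractive to *D. suzukii*); the rest are filamentous
    ascomycetes and basidiomycete yeasts common on fruit surfaces. A minority
    are left partially assigned to exercise unassigned-rank handling.
    """
    n = len(phylotype_ids)
    rows = {}
    yeast_templates = [t for t in _SACCHAROMYCETALES for _ in t[2]]
    yeast_hints = [h for t in _SACCHAROMYCETALES for h in t[2]]
    n_yeast = max(min(n, 4), int(round(0.12 * n)))
    for i, pid in enumerate(phylotype_ids):
        if i < n_yeast:
            k = i % len(yeast_templates)
            family, genus, _ = yeast_templates[k]
            hint = yeast_hints[k]
            rows[pid] = {
                "kingdom": "Fungi",
                "phylum": "Ascomycota",
                "class": "Saccharomycetes",
                "order": "Saccharomycetales",
                "family": family,
                "genus": genus,
                "species": hint,
                "species_hint": hint,
            }
        else:
            phylum, cls, order, family, genus, hint = _FILAMENTOUS[
                int(rng.integers(len(_FILAMENTOUS)))
            ]
            row = {
                "kingdom": "Fungi",
                "phylum": phylum,
                "class": cls,
                "order": order,
                "family": family,
                "genus": genus,
                "species": hint,
                "species_hint": hint,
            }
            # ~10% only coarsely assigned, as in real ITS classifications
            if rng.random() < 0.10:
                depth = int(rng.integers(1, 5))  # keep ranks up to `depth`
                for rank in eio.RANKS[depth:]:
                    row[rank] = ""
                row["species_hint"] = ""
            rows[pid] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "phylotype_id"
    return frame


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def generate_counts(
    design: pd.DataFrame, params: SimulationParams
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the read table (and its cell-scale ground truth) for a design.

    Returns ``(feature_table, ground_truth)`` where the feature table contains
    the internal-standard phylotype as an ordinary row (id
    :data:`STANDARD_ID`).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_taxa = params.n_phylotypes
    pids = [f"phylo_{i:04d}" for i in range(1, n_taxa + 1)]

    taxonomy = generate_taxonomy(pids, rng)

    # base community: long-tailed log-normal abundances
    base = rng.lognormal(mean=0.0, sigma=2.0, size=n_taxa)

    # planted effects: disjoint indicator sets per fruit, then stage taxa
    shuffled = rng.permutation(n_taxa)
    indicator_sets = {}
    cursor = 0
    for fruit in params.fruit_types:
        take = shuffled[cursor : cursor + params.n_indicator_taxa_per_fruit]
        indicator_sets[fruit] = [pids[i] for i in take]
        cursor += params.n_indicator_taxa_per_fruit
    stage_taxa_idx = shuffled[cursor : cursor + params.n_stage_taxa]
    stage_taxa = [pids[i] for i in stage_taxa_idx]
    stage_sign = rng.choice([-1.0, 1.0], size=params.n_stage_taxa)

    indicator_idx = {
        fruit: np.array([pids.index(p) for p in members])
        for fruit, members in indicator_sets.items()
    }

    pair_ids = design["pair_id"].drop_duplicates().tolist()
    pair_info = design[~design["spiked"]].set_index("pair_id")

    total_cells_mean = params.spike_cells / params.spike_target_fraction

    # realized community per pair (shared by both halves)
    community = {}
    background_cells = {}
    for pair in pair_ids:
        fruit = pair_info.loc[pair, "fruit_type"]
        stage = int(pair_info.loc[pair, "ripening_stage"])
        weights = base.copy()
        if fruit in indicator_idx and params.indicator_fold_change != 1.0:
            weights[indicator_idx[fruit]] *= params.indicator_fold_change
        if params.n_stage_taxa and params.stage_fold_change != 1.0 and params.n_stages > 1:
            frac = (stage - 1) / (params.n_stages - 1)
            weights[stage_taxa_idx] *= params.stage_fold_change ** (stage_sign * frac)
        p = weights / weights.sum()
        if np.isfinite(params.overdispersion):
            p = rng.dirichlet(params.overdispersion * p)
        total = total_cells_mean * _lognormal_factor(rng, 0.25)
        community[pair] = total * p
        bg_rate = params.background_for(fruit)
        if bg_rate and rng.random() < bg_rate:
            mean_bg_cells = (
                params.background_spike_reads_mean / params.depth_mean * total_cells_mean
            )
            background_cells[pair] = int(rng.poisson(mean_bg_cells))
        else:
            background_cells[pair] = 0

    all_pids = pids + [STANDARD_ID]
    counts = np.zeros((n_taxa + 1, len(design)), dtype=np.int64)
    true_cells = np.zeros_like(counts, dtype=float)

    for j, (sid, row) in enumerate(design.iterrows()):
        pair = row["pair_id"]
        cells = np.empty(n_taxa + 1)
        cells[:n_taxa] = community[pair]
        cells[n_taxa] = background_cells[pair] + (
            params.spike_cells if row["spiked"] else 0
        )
        true_cells[:, j] = cells
        depth = max(1, int(round(params.depth_mean * _lognormal_factor(rng, params.depth_cv))))
        counts[:, j] = rng.multinomial(depth, cells / cells.sum())

    table = pd.DataFrame(counts, index=all_pids, columns=design.index)
    taxonomy.loc[STANDARD_ID] = {**STANDARD_LINEAGE, "species_hint": STANDARD_LINEAGE["species"]}

    truth = GroundTruth(
        true_cells=pd.DataFrame(true_cells, index=all_pids, columns=design.index),
        true_indicator_sets=indicator_sets,
        true_stage_taxa=stage_taxa,
        true_group_effects={
            "fruit_type": {"fold_change": params.indicator_fold_change,
                           "taxa_per_fruit": params.n_indicator_taxa_per_fruit},
            "ripening_stage": {"fold_change": params.stage_fold_change,
                               "n_taxa": params.n_stage_taxa},
        },
        taxonomy=taxonomy,
    )
    return table, truth


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """A mean-one log-normal multiplier with the given coefficient of variation."""
    if cv <= 0:
        return 1.0
    sigma2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(mean=-0.5 * sigma2, sigma=math.sqrt(sigma2)))


# ---------------------------------------------------------------------------
# host-potential-index scores
# ---------------------------------------------------------------------------

def generate_hpi_table(fruit_names, scores: dict | None = None) -> pd.DataFrame:
    """One host-potential-index score per fruit.

    Default scores are synthetic stand-ins on the published scale, with
    raspberry carrying the maximum. Unknown fruit names receive deterministic
    descending filler scores (with a warning) so arbitrary synthetic designs
    still produce a usable table.
    """
    fruit_names = list(fruit_names)
    if len(fruit_names) != len(set(fruit_names)):
        raise ParameterError("duplicate fruit names in HPI table request")
    if len(fruit_names) < 2:
        raise ParameterError(
            "HPI table needs at least 2 fruits (correlation undefined otherwise)"
        )
    lookup = dict(DEFAULT_HPI)
    if scores:
        lookup.update(scores)
    values = []
    for i, fruit in enumerate(fruit_names):
        if fruit in lookup:
            values.append(float(lookup[fruit]))
        else:
            warnings.warn(f"no HPI score for {fruit!r}; using a filler value")
            values.append(0.5 - 0.01 * i)
    return pd.DataFrame({"fruit_type": fruit_names, "hpi": values}).set_index("fruit_type")


# ---------------------------------------------------------------------------
# convenience bundle + on-disk round trip
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    params: SimulationParams
    metadata: pd.DataFrame
    table: pd.DataFrame
    truth: GroundTruth
    hpi: pd.DataFrame


def simulate_dataset(params: SimulationParams | None = None) -> SyntheticDataset:
    """Generate design, counts, taxonomy and HPI scores in one call."""
    params = (params or SimulationParams()).validate()
    design = generate_design(params)
    table, truth = generate_counts(design, params)
    if len(params.fruit_types) >= 2:
        hpi = generate_hpi_table(params.fruit_types)
    else:
        hpi = pd.DataFrame(columns=["hpi"])
    return SyntheticDataset(params, design, table, truth, hpi)


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write a synthetic dataset in the formats the readers consume.

    Returns a mapping of artifact name to path. Includes the ground-truth cell
    table and a JSON echo of the parameters for provenance.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "metadata": outdir / "metadata.tsv",
        "hpi": outdir / "hpi.tsv",
        "true_cells": outdir / "true_cells.tsv",
        "params": outdir / "params.json",
    }
    eio.write_feature_table(ds.table, paths["counts"])
    eio.write_taxonomy(ds.truth.taxonomy, paths["taxonomy"])
    eio.write_metadata(ds.metadata, paths["metadata"])
    ds.hpi.to_csv(paths["hpi"], sep="\t")
    ds.truth.true_cells.to_csv(paths["true_cells"], sep="\t", index_label="phylotype_id")
    paths["params"].write_text(ds.params.to_json() + "\n")
    return paths
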