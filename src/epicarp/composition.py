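"""Indicator-phylotype analysis, shared/unique set summaries, and targeted
taxon aggregations.

The indicator value of a phylotype for a sample group combines specificity
(A: the group's share of the phylotype's mean abundance) and fidelity (B: the
fraction of the group's samples containing it): ``IndVal = sqrt(A * B)``,
maximal when a phylotype is exclusive to and ubiquitous in one group.
Significance comes from permuting group labels; the reported p is for the
best (argmax) group, corrected across phylotypes by Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations as iter_permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

from . import io as eio
from .errors import ParameterError, ValidationError
from .inference import bh_adjust, dunn_posthoc, kruskal_wallis

__all__ = [
    "IndicatorAnalysis",
    "IndicatorResults",
    "indval_components",
    "set_summary",
    "SetSummary",
    "filter_by_taxonomy",
    "aggregate_reads",
    "AggregateComparison",
    "hpi_correlation",
    "ATTRACTIVE_GENERA",
]

#: Budding-yeast genera empirically attractive to *Drosophila suzukii*.
ATTRACTIVE_GENERA = ("Hanseniaspora", "Pichia", "Saccharomyces", "Candida", "Metschnikowia")


# ---------------------------------------------------------------------------
# indicator analysis
# ---------------------------------------------------------------------------

def indval_components(x: np.ndarray, group_index: np.ndarray, n_groups: int):
    """Specificity A, fidelity B and the IndVal statistic per taxon and group.

    ``x`` is taxa x samples (counts or normalised abundances); ``group_index``
    maps each sample to 0..n_groups-1. Returns ``(A, B, stat)`` each of shape
    (taxa, groups).
    """
    counts = np.bincount(group_index, minlength=n_groups).astype(float)
    member = np.zeros((x.shape[1], n_groups))
    member[np.arange(x.shape[1]), group_index] = 1.0
    mean_abund = (x @ member) / counts  # taxa x groups
    denom = mean_abund.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(denom > 0, mean_abund / np.maximum(denom, 1e-300), 0.0)
    b = ((x > 0).astype(float) @ member) / counts
    return a, b, np.sqrt(a * b)


@dataclass
class IndicatorResults:
    """Per-phylotype indicator statistics with permutation p and BH q."""

    table: pd.DataFrame
    n_permutations: int
    seed: int | None
    method: str

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < alpha]

    def summary(self) -> str:
        sig = self.significant()
        lines = [
            f"Indicator analysis ({self.method}, permutations={self.n_permutations})",
            f"{len(sig)} of {len(self.table)} phylotypes significant at q < 0.05",
        ]
        if len(sig):
            counts = sig["group"].value_counts().sort_index()
            lines += [f"  {g}: {c} indicator phylotype(s)" for g, c in counts.items()]
        return "\n".join(lines)


class IndicatorAnalysis:
    """Indicator-value analysis of a feature table against a grouping factor."""

    def __init__(self, table: pd.DataFrame, groups):
        groups = pd.Series(np.asarray(groups), index=table.columns)
        levels = sorted(pd.unique(groups))
        if len(levels) < 2:
            raise ParameterError("indicator analysis needs at least 2 groups")
        sizes = groups.value_counts()
        empty = [g for g in levels if sizes.get(g, 0) == 0]
        if empty:
            raise ParameterError(f"group(s) with no samples: {empty}")
        self.table = table
        self.levels = levels
        self.group_index = np.array([levels.index(g) for g in groups])

    def fit(
        self,
        permutations: int = 999,
        seed: int | None = None,
        method: str = "sampled",
    ) -> IndicatorResults:
        """Compute IndVal per phylotype and its label-permutation p-value.

        ``method="exact"`` enumerates every distinct assignment of the
        observed labels to samples (guarded to small designs).
        """
        x = self.table.to_numpy(dtype=float)
        if np.any(x < 0):
            raise ValidationError("abundances must be non-negative")
        k = len(self.levels)
        a, b, stat = indval_components(x, self.group_index, k)
        best = stat.argmax(axis=1)
        rows_idx = np.arange(x.shape[0])
        obs = stat[rows_idx, best]

        if method == "exact":
            labels = self.group_index
            n = len(labels)
            total = factorial(n)
            if total > 50_000:
                raise ParameterError("exact enumeration is limited to very small n")
            seen = {}
            for perm in iter_permutations(range(n)):
                key = tuple(labels[list(perm)])
                if key not in seen:
                    seen[key] = None
            assignments = np.array(list(seen.keys()))
            ge = np.zeros(x.shape[0])
            for assign in assignments:
                _, _, s = indval_components(x, np.asarray(assign), k)
                ge += s.max(axis=1) >= obs - 1e-12
            p = ge / len(assignments)
            n_perm = len(assignments)
        elif method == "sampled":
            rng = np.random.default_rng(seed)
            ge = np.zeros(x.shape[0])
            labels = self.group_index
            for _ in range(permutations):
                perm = rng.permutation(len(labels))
                _, _, s = indval_components(x, labels[perm], k)
                ge += s.max(axis=1) >= obs - 1e-12
            p = (ge + 1.0) / (permutations + 1.0)
            n_perm = permutations
        else:
            raise ParameterError(f"unknown method {method!r}")

        out = pd.DataFrame(
            {
                "group": [self.levels[i] for i in best],
                "A": a[rows_idx, best],
                "B": b[rows_idx, best],
                "stat": obs,
                "p": p,
            },
            index=pd.Index(self.table.index, name="phylotype_id"),
        )
        out["q"] = bh_adjust(out["p"].to_numpy())
        return IndicatorResults(table=out, n_permutations=n_perm, seed=seed, method=method)


# ---------------------------------------------------------------------------
# shared / unique sets
# ---------------------------------------------------------------------------

@dataclass
class SetSummary:
    """Presence-based comparison of phylotype sets across groups.

    ``venn`` maps a ``"&"``-joined sorted group combination to the number of
    observed phylotypes present in exactly those groups; the cells partition
    the observed phylotypes, so their counts sum to ``n_observed``.
    """

    groups: list
    presence: pd.DataFrame  # taxa x groups, bool
    unique_counts: dict
    venn: dict
    core_ids: list
    core_read_share: float
    n_observed: int

    def summary(self) -> str:
        lines = [f"{self.n_observed} phylotypes observed across {len(self.groups)} groups"]
        lines.append(
            f"core (present in all groups): {len(self.core_ids)} phylotypes, "
            f"{100 * self.core_read_share:.1f}% of reads"
        )
        for g in self.groups:
            lines.append(f"unique to {g}: {self.unique_counts[g]}")
        return "\n".join(lines)


def set_summary(table: pd.DataFrame, groups) -> SetSummary:
    """Core, unique and full Venn-cell counts of phylotype presence by group."""
    groups = pd.Series(np.asarray(groups), index=table.columns)
    levels = sorted(pd.unique(groups))
    if len(levels) < 2:
        raise ParameterError("set summary needs at least 2 groups")
    presence = pd.DataFrame(
        {g: (table.loc[:, groups[groups == g].index].sum(axis=1) > 0) for g in levels}
    )
    observed = presence.any(axis=1)
    venn: dict[str, int] = {}
    masks = presence.to_numpy()
    for i in np.flatnonzero(observed.to_numpy()):
        key = "&".join(g for g, m in zip(levels, masks[i]) if m)
        venn[key] = venn.get(key, 0) + 1
    unique_counts = {g: venn.get(g, 0) for g in levels}
    core_mask = presence.all(axis=1)
    core_ids = list(table.index[core_mask])
    total_reads = float(table.to_numpy().sum())
    core_share = (
        float(table.loc[core_ids].to_numpy().sum()) / total_reads if total_reads else 0.0
    )
    return SetSummary(
        groups=levels,
        presence=presence,
        unique_counts=unique_counts,
        venn=venn,
        core_ids=core_ids,
        core_read_share=core_share,
        n_observed=int(observed.sum()),
    )


# ---------------------------------------------------------------------------
# taxonomy-targeted subsets
# ---------------------------------------------------------------------------

def filter_by_taxonomy(
    table: pd.DataFrame, taxonomy: pd.DataFrame, rank: str, names
) -> pd.DataFrame:
    """Rows of the table whose lineage matches any of ``names`` at ``rank``.

    ``rank`` may also be ``"species_hint"`` to select on the curated species
    labels. Returns an (possibly empty, with warning) row subset.
    """
    valid = eio.RANKS + ("species_hint",)
    if rank not in valid:
        raise ParameterError(f"unknown rank {rank!r}; choose from {valid}")
    if isinstance(names, str):
        names = [names]
    tax = taxonomy.loc[taxonomy.index.intersection(table.index)]
    hits = tax.index[tax[rank].isin(set(names))]
    if len(hits) == 0:
        warnings.warn(f"no phylotypes match {sorted(names)} at rank {rank!r}")
    return table.loc[table.index.intersection(hits)]


@dataclass
class AggregateComparison:
    """Per-sample summed abundance of a taxon subset plus its group test."""

    totals: pd.Series
    kw_statistic: float
    kw_df: int
    kw_p: float
    posthoc: pd.DataFrame


def aggregate_reads(subset: pd.DataFrame, groups) -> AggregateComparison:
    """Sum a taxon subset per sample and compare the totals between groups
    (Kruskal-Wallis with Dunn's BH-corrected post-hoc)."""
    if subset.shape[0] == 0:
        raise ParameterError("cannot aggregate an empty taxon subset")
    totals = subset.sum(axis=0).astype(float)
    groups = pd.Series(np.asarray(groups), index=subset.columns)
    levels = sorted(pd.unique(groups))
    samples = [totals[groups[groups == g].index].to_numpy() for g in levels]
    stat, df, p = kruskal_wallis(samples)
    posthoc = dunn_posthoc(samples, labels=levels)
    return AggregateComparison(totals=totals, kw_statistic=stat, kw_df=df, kw_p=p, posthoc=posthoc)


# ---------------------------------------------------------------------------
# host-potential-index correlation
# ---------------------------------------------------------------------------

def hpi_correlation(group_totals: pd.Series, hpi_scores: pd.Series):
    """Pearson correlation of per-fruit abundance totals with HPI scores.

    Returns ``(r, p)``; with only two fruits r degenerates to +/-1 and p is
    withheld (None) with a warning. With the study's four fruits the test has
    little power — interpret p accordingly.
    """
    common = group_totals.index.intersection(hpi_scores.index)
    if len(common) < 2:
        raise ParameterError("need at least 2 matching fruits for a correlation")
    x = group_totals[common].to_numpy(dtype=float)
    y = hpi_scores[common].to_numpy(dtype=float)
    if len(common) == 2:
        warnings.warn("only 2 fruits: r is degenerate (+/-1) and p is withheld")
        r = 1.0 if (x[1] - x[0]) * (y[1] - y[0]) > 0 else -1.0
        return r, None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
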