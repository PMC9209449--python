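"""End-to-end orchestration: simulate (or load) -> quantify -> normalise ->
diversity -> tests -> indicators -> sets -> targeted taxa -> report.

The pipeline mirrors the analysis order of an epicarp study: absolute
quantification with the internal standard first, then the standard phylotype
is removed and the community re-analysed on CSS-normalised relative
abundances. One global seed is fanned out to per-stage substreams so any stage
can be re-run in isolation; with a fixed seed the JSON outputs are
byte-identical across runs. Progress is logged to standard error; results are
only ever written to files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition, diversity, io as eio, normalize, simulate, spike
from .errors import EpicarpError, ParameterError, StageError
from .inference import (
    TwoWayAnova,
    bh_adjust,
    dunn_posthoc,
    kruskal_wallis,
    normality_gate,
    round_sig,
    tukey_hsd,
)
from .permanova import Permanova, mantel, pairwise_permanova

log = logging.getLogger("epicarp")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``input_dir`` (a directory holding counts.tsv,
    taxonomy.tsv, metadata.tsv and optionally hpi.tsv) or ``simulation``
    must be provided.
    """

    output_dir: str | Path = "epicarp_run"
    input_dir: str | Path | None = None
    simulation: simulate.SimulationParams | None = None
    spike_config: spike.SpikeConfig = field(default_factory=spike.SpikeConfig)
    css_params: normalize.CssParams = field(default_factory=normalize.CssParams)
    metrics: tuple = ("jaccard_binary", "jaccard_abundance")
    factors: tuple = ("fruit_type", "ripening_stage")
    permutations: int = 999
    pairwise: bool = True
    seed: int = 0

    def validate(self) -> "RunConfig":
        if (self.input_dir is None) == (self.simulation is None):
            raise ParameterError(
                "exactly one of input_dir or simulation must be supplied"
            )
        if self.permutations < 1:
            raise ParameterError("permutations must be >= 1")
        return self


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _write_json(payload, path: Path):
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")


def _univariate_block(values: pd.Series, meta: pd.DataFrame, factors, permutable_name: str):
    """The richness-style decision tree on one per-sample response."""
    fa, fb = factors
    gate = normality_gate(values.to_numpy())
    block = {
        "response": permutable_name,
        "branch": gate.branch,
        "shapiro_p_raw": gate.shapiro_p_raw,
        "shapiro_p_sqrt": gate.shapiro_p_sqrt,
    }
    levels_a = sorted(meta[fa].unique())
    groups_a = [values[meta.index[meta[fa] == g]].to_numpy() for g in levels_a]
    if gate.branch in ("anova", "sqrt_anova"):
        transformation = "sqrt" if gate.branch == "sqrt_anova" else "none"
        res = TwoWayAnova.from_frame(
            meta.assign(**{permutable_name: values}), permutable_name, fa, fb
        ).fit(transformation=transformation)
        block["anova"] = res.table.reset_index().to_dict(orient="records")
        block["omega_squared"] = res.omega_squared().to_dict()
        try:
            block["effect_ratio"] = res.effect_ratio(fa, fb)
        except (ParameterError, KeyError):
            block["effect_ratio"] = None
        block["tukey"] = tukey_hsd(
            groups_a,
            labels=levels_a,
            ms_error=res.ms_error,
            df_error=int(res.table.loc["Residual", "df"]),
        ).to_dict(orient="records")
    else:
        stat, df, p = kruskal_wallis(groups_a)
        block["kruskal_wallis"] = {"statistic": stat, "df": df, "p": p}
        block["dunn"] = dunn_posthoc(groups_a, labels=levels_a).to_dict(orient="records")
    return block


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a manifest of produced artifacts.

    Any stage failure aborts the run with :class:`StageError`; partial
    outputs are retained next to a ``FAILED`` marker naming the stage.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "decisions": {}}
    stage = "setup"
    try:
        root_seq = np.random.SeedSequence(config.seed)
        stage_seeds = {
            name: int(s.generate_state(1)[0] % (2**31 - 1))
            for name, s in zip(
                ["simulate", "permanova", "pairwise", "indicators", "mantel"],
                root_seq.spawn(5),
            )
        }
        manifest["stage_seeds"] = stage_seeds

        # -- load or simulate ------------------------------------------------
        stage = "data"
        log.info("[%s] preparing input data", stage)
        hpi = None
        if config.simulation is not None:
            params = dataclasses.replace(config.simulation, seed=stage_seeds["simulate"])
            ds = simulate.simulate_dataset(params)
            simulate.write_dataset(ds, outdir / "synthetic")
            table, taxonomy, meta, hpi = ds.table, ds.truth.taxonomy, ds.metadata, ds.hpi
        else:
            indir = Path(config.input_dir)
            table = eio.read_feature_table(indir / "counts.tsv")
            taxonomy = eio.read_taxonomy(indir / "taxonomy.tsv")
            meta = eio.read_metadata(indir / "metadata.tsv")
            hpi_path = indir / "hpi.tsv"
            if hpi_path.exists():
                hpi = pd.read_csv(hpi_path, sep="\t").set_index("fruit_type")
        eio.validate_taxonomy(taxonomy, table)
        meta = meta.loc[table.columns]
        manifest["stages"].append(stage)

        # -- spike quantification -------------------------------------------
        stage = "quantify"
        log.info("[%s] internal-standard quantification", stage)
        std_id, std_reads = spike.detect_standard(table, taxonomy, config.spike_config)
        recovery = spike.assess_recovery(std_reads, meta, config.spike_config)
        recovery.to_csv(outdir / "recovery_report.tsv", sep="\t")
        _write_json(
            {"standard_id": std_id, "recovery": recovery.reset_index().to_dict(orient="records")},
            outdir / "recovery_report.json",
        )
        quant = None
        if recovery["usable"].any():
            quant = spike.absolute_abundance(
                table, std_id, meta, config.spike_config, recovery
            )
            quant.cells.to_csv(outdir / "absolute_cells.tsv", sep="\t", index_label="phylotype_id")
            pd.DataFrame(
                {
                    "total_cells": quant.total_cells,
                    "surface_area_mm2": quant.surface_area_mm2,
                    "total_cells_per_mm2": quant.total_cells_per_mm2,
                }
            ).to_csv(outdir / "absolute_totals.tsv", sep="\t", index_label="sample_id")
            manifest["decisions"]["excluded_samples"] = quant.excluded
            # cell totals and area-normalised density across stages (usable strata)
            usable = recovery.index[recovery["usable"]].tolist()
            qmeta = meta.loc[quant.total_cells.index]
            quant_tests = {}
            for label, series in (
                ("total_cells", quant.total_cells),
                ("total_cells_per_mm2", quant.total_cells_per_mm2),
            ):
                stages_lv = sorted(qmeta["ripening_stage"].unique())
                groups = [
                    series[qmeta.index[qmeta["ripening_stage"] == s]].to_numpy()
                    for s in stages_lv
                ]
                if len(groups) >= 2 and all(len(g) for g in groups):
                    stat, df, p = kruskal_wallis(groups)
                    quant_tests[label] = {
                        "statistic": stat, "df": df, "p": p,
                        "dunn": dunn_posthoc(groups, labels=[str(s) for s in stages_lv])
                        .to_dict(orient="records"),
                    }
            _write_json(
                {"usable_strata": usable, "stage_effects": quant_tests},
                outdir / "absolute_stage_tests.json",
            )
        else:
            manifest["decisions"]["quantification"] = "no usable strata"
        manifest["decisions"]["usable_strata"] = recovery["usable"][recovery["usable"]].index.tolist()
        manifest["stages"].append(stage)

        # -- community table: remove standard, CSS-normalise ----------------
        stage = "normalize"
        log.info("[%s] removing standard and CSS-normalising", stage)
        community = spike.remove_standard(table, std_id)
        community = community.loc[:, community.sum(axis=0) > 0]
        cmeta = meta.loc[community.columns]
        css = normalize.css_normalize(community, config.css_params)
        css.to_csv(outdir / "css_normalized.tsv", sep="\t", index_label="phylotype_id")
        manifest["stages"].append(stage)

        # -- alpha diversity + univariate tests ------------------------------
        stage = "diversity"
        log.info("[%s] alpha diversity and univariate tests", stage)
        alpha = diversity.alpha_diversity(community)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
        alpha_tests = {
            name: _univariate_block(alpha[name], cmeta, config.factors, name)
            for name in ("richness", "shannon", "simpson")
        }
        _write_json(alpha_tests, outdir / "alpha_tests.json")
        manifest["decisions"]["alpha_branches"] = {
            k: v["branch"] for k, v in alpha_tests.items()
        }

        # within-fruit stage tests on richness (the interaction follow-up)
        fa, fb = config.factors
        within = {}
        for fruit, sub in cmeta.groupby(fa, sort=True):
            vals = alpha.loc[sub.index, "richness"]
            gate = normality_gate(vals.to_numpy())
            stages_lv = sorted(sub[fb].unique())
            groups = [vals[sub.index[sub[fb] == s]].to_numpy() for s in stages_lv]
            if len(groups) < 2 or any(len(g) < 2 for g in groups):
                continue
            if gate.branch in ("anova", "sqrt_anova"):
                y = np.sqrt(vals) if gate.branch == "sqrt_anova" else vals
                f_stat, p = _one_way_f(groups if gate.branch == "anova" else
                                       [np.sqrt(g) for g in groups])
                within[str(fruit)] = {"branch": gate.branch, "F": f_stat, "p": p}
            else:
                stat, df, p = kruskal_wallis(groups)
                within[str(fruit)] = {"branch": "kruskal_wallis", "statistic": stat, "df": df, "p": p}
        _write_json(within, outdir / "within_fruit_stage_tests.json")
        manifest["stages"].append(stage)

        # -- distance matrices + PERMANOVA -----------------------------------
        stage = "permanova"
        log.info("[%s] distance matrices and PERMANOVA", stage)
        perm_results = {}
        perm_rng = np.random.default_rng(stage_seeds["permanova"])
        pair_rng = np.random.default_rng(stage_seeds["pairwise"])
        for metric in config.metrics:
            source = community if metric == "jaccard_binary" else css
            dm = diversity.distance_matrix(source, metric)
            eio.write_distance_matrix(dm, outdir / f"distance_{metric}.tsv")
            res = Permanova(dm, cmeta, list(config.factors), interaction=True).fit(
                permutations=config.permutations,
                seed=int(perm_rng.integers(2**31 - 1)),
            )
            entry = {
                "table": res.table.reset_index().to_dict(orient="records"),
                "n_permutations": res.n_permutations,
            }
            try:
                entry["r2_ratio"] = res.r_squared_ratio(fa, fb)
            except ParameterError:
                entry["r2_ratio"] = None
            if config.pairwise:
                for factor in config.factors:
                    entry[f"pairwise_{factor}"] = pairwise_permanova(
                        dm, cmeta, factor,
                        permutations=config.permutations,
                        seed=int(pair_rng.integers(2**31 - 1)),
                    ).to_dict(orient="records")
            perm_results[metric] = entry
        _write_json(perm_results, outdir / "permanova.json")
        manifest["stages"].append(stage)

        # -- indicators ------------------------------------------------------
        stage = "indicators"
        log.info("[%s] indicator phylotypes", stage)
        ind = composition.IndicatorAnalysis(css, cmeta[fa]).fit(
            permutations=config.permutations, seed=stage_seeds["indicators"]
        )
        ind.table.to_csv(outdir / "indicators.tsv", sep="\t")
        manifest["stages"].append(stage)

        # -- set summary -----------------------------------------------------
        stage = "sets"
        log.info("[%s] core/unique phylotype sets", stage)
        sets = composition.set_summary(community, cmeta[fa])
        _write_json(
            {
                "groups": sets.groups,
                "venn": sets.venn,
                "unique_counts": sets.unique_counts,
                "core_count": len(sets.core_ids),
                "core_read_share": sets.core_read_share,
                "n_observed": sets.n_observed,
            },
            outdir / "set_summary.json",
        )
        manifest["stages"].append(stage)

        # -- targeted taxa ---------------------------------------------------
        stage = "target_taxa"
        log.info("[%s] targeted taxon aggregations", stage)
        targets = {}
        for name, rank, names_ in (
            ("saccharomycetales", "order", ["Saccharomycetales"]),
            ("attractive_genera", "genus", list(composition.ATTRACTIVE_GENERA)),
            ("h_uvarum", "species_hint", ["Hanseniaspora uvarum"]),
            ("b_cinerea", "species_hint", ["Botrytis cinerea"]),
        ):
            subset = composition.filter_by_taxonomy(css, taxonomy, rank, names_)
            if subset.shape[0] == 0:
                targets[name] = {"n_phylotypes": 0}
                continue
            agg = composition.aggregate_reads(subset, cmeta[fa])
            targets[name] = {
                "n_phylotypes": int(subset.shape[0]),
                "kruskal_wallis": {
                    "statistic": agg.kw_statistic, "df": agg.kw_df, "p": agg.kw_p,
                },
                "group_means": agg.totals.groupby(cmeta[fa]).mean().to_dict(),
                "dunn": agg.posthoc.to_dict(orient="records"),
            }
        _write_json(targets, outdir / "target_taxa.json")
        manifest["stages"].append(stage)

        # -- mantel + HPI ----------------------------------------------------
        stage = "correlations"
        log.info("[%s] geographic Mantel and HPI correlations", stage)
        correlations = {}
        geo = diversity.geographic_distance_matrix(cmeta)
        comm_dm = diversity.distance_matrix(community, "jaccard_binary")
        r, p = mantel(
            comm_dm, geo, permutations=min(config.permutations, 999),
            seed=stage_seeds["mantel"],
        )
        correlations["mantel_geography"] = {"r": r, "p": p}
        if hpi is not None and len(hpi) >= 2:
            attract = composition.filter_by_taxonomy(
                css, taxonomy, "genus", list(composition.ATTRACTIVE_GENERA)
            )
            if attract.shape[0]:
                last_stage = cmeta["ripening_stage"].max()
                ripe = cmeta.index[cmeta["ripening_stage"] == last_stage]
                totals = attract[ripe].sum(axis=0).groupby(cmeta.loc[ripe, fa]).sum()
                r_hpi, p_hpi = composition.hpi_correlation(totals, hpi["hpi"])
                correlations["hpi_attractive_yeasts"] = {"r": r_hpi, "p": p_hpi}
        _write_json(correlations, outdir / "correlations.json")
        manifest["stages"].append(stage)

        # -- report ----------------------------------------------------------
        stage = "report"
        results = {
            "alpha_tests": alpha_tests,
            "permanova": perm_results,
            "indicators": ind,
            "sets": sets,
            "targets": targets,
            "correlations": correlations,
        }
        (outdir / "report.md").write_text(report(results))
        manifest["stages"].append(stage)
        _write_json(manifest, outdir / "manifest.json")
        return manifest
    except EpicarpError:
        (outdir / "FAILED").write_text(f"stage: {stage}\n")
        raise
    except Exception as exc:  # wrap unexpected failures with stage context
        (outdir / "FAILED").write_text(f"stage: {stage}\n{exc}\n")
        raise StageError(stage, str(exc)) from exc


def _one_way_f(groups) -> tuple[float, float]:
    from scipy import stats as sstats

    f, p = sstats.f_oneway(*groups)
    return float(f), float(p)


def report(results: dict) -> str:
    """Render a human-readable markdown summary of a completed run.

    Missing sections are noted and skipped rather than raising.
    """
    lines = ["# Epicarp community analysis report", ""]

    alpha = results.get("alpha_tests")
    if alpha and "richness" in alpha:
        rich = alpha["richness"]
        lines.append("## Phylotype richness")
        lines.append(f"Decision branch: {rich['branch']}.")
        ratio = rich.get("effect_ratio")
        if ratio is not None and np.isfinite(ratio) and ratio > 0:
            a_name, b_name = ("fruit type", "ripening stage")
            if ratio >= 1:
                lines.append(
                    f"{a_name} had a {round_sig(ratio, 2):g} times greater effect "
                    f"(omega-squared) than {b_name} on richness."
                )
            else:
                lines.append(
                    f"{b_name} had a {round_sig(1 / ratio, 2):g} times greater effect "
                    f"(omega-squared) than {a_name} on richness."
                )
        if rich.get("kruskal_wallis"):
            kw = rich["kruskal_wallis"]
            verdict = "significant" if kw["p"] < 0.05 else "no significant"
            lines.append(
                f"Kruskal-Wallis: chi-squared = {kw['statistic']:.2f}, "
                f"P = {kw['p']:.3g} ({verdict} group effect at alpha = 0.05)."
            )
        lines.append("")
    else:
        lines.append("_Alpha-diversity section missing; skipped._\n")

    perm = results.get("permanova")
    if perm:
        lines.append("## Community structure (PERMANOVA)")
        for metric, entry in perm.items():
            ratio = entry.get("r2_ratio")
            terms = {row["term"]: row for row in entry["table"]}
            frags = []
            for term, row in terms.items():
                if term in ("Residual", "Total"):
                    continue
                sig = "significant" if (row["p"] is not None and row["p"] < 0.05) else "not significant"
                frags.append(f"{term}: R2 = {row['R2']:.3g}, P = {row['p']:.4g} ({sig})")
            lines.append(f"- **{metric}** — " + "; ".join(frags))
            if ratio:
                lines.append(
                    f"  The first factor's effect (R2) was {round_sig(ratio, 2):g} "
                    "times that of the second."
                )
        lines.append("")
    else:
        lines.append("_PERMANOVA section missing; skipped._\n")

    ind = results.get("indicators")
    if ind is not None:
        lines.append("## Indicator phylotypes")
        lines.append(ind.summary())
        lines.append("")

    sets = results.get("sets")
    if sets is not None:
        lines.append("## Shared and unique phylotypes")
        lines.append(sets.summary())
        lines.append("")

    targets = results.get("targets")
    if targets:
        lines.append("## Taxa relevant to D. suzukii")
        for name, entry in targets.items():
            if not entry.get("n_phylotypes"):
                lines.append(f"- {name}: no matching phylotypes; skipped.")
                continue
            kw = entry["kruskal_wallis"]
            verdict = "significant" if kw["p"] < 0.05 else "no significant"
            lines.append(
                f"- {name} ({entry['n_phylotypes']} phylotypes): Kruskal-Wallis "
                f"chi-squared = {kw['statistic']:.2f}, P = {kw['p']:.3g} "
                f"({verdict} fruit effect)."
            )
        lines.append("")

    corr = results.get("correlations")
    if corr:
        lines.append("## Correlations")
        if "mantel_geography" in corr:
            m = corr["mantel_geography"]
            lines.append(
                f"- Mantel (geographic vs community distance): r = {m['r']:.3f}, "
                f"P = {m['p']:.4g}."
            )
        if "hpi_attractive_yeasts" in corr:
            h = corr["hpi_attractive_yeasts"]
            ptxt = "withheld (n = 2)" if h["p"] is None else f"{h['p']:.3g}"
            lines.append(
                f"- Attractive-yeast abundance vs host potential index: "
                f"r = {h['r']:.3f}, P = {ptxt}."
            )
        lines.append("")
    return "\n".join(lines)
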