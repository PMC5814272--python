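"""Run orchestration: stages io -> phenotype -> burden -> neoantigen -> stats.

A run directory accumulates one subdirectory per stage; each stage's
tables are written before the next begins, so partial output survives a
failure.  All tables use a fixed float format and the manifest carries no
timestamps, making a rerun with the same config and seed byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DataError, ImmunoscopeError
from .io_formats import (read_clinical, read_expression, read_fasta, read_gmt,
                         read_hla, read_maf)
from .phenotype import (CallingConfig, InfiltrationMatrix, MetagenePanel,
                        call_infiltration, cooccurrence,
                        infiltration_prevalence)
from .neoantigen import NeoantigenThresholds, predict_cohort
from .repair import (RepairGeneSets, classify_repair, gene_panel_mutation_rates,
                     median_split, mutation_burden, oncogene_positive,
                     quartile_split, repair_status_frame, substitution_spectrum)
from .stats import (infiltration_fold_change, km_logrank, mean_test, pearson,
                    significance_stars, two_proportion_z)
from .synthetic import (COHORT_FILES, CohortConfig, default_predictor,
                        generate_cohort, synthetic_panel)

log = logging.getLogger("immunoscope")

STAGES = ("io", "phenotype", "burden", "neoantigen", "stats")

_FLOAT_FMT = "%.10g"


class StageError(ImmunoscopeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_config() -> dict[str, Any]:
    """Full default run configuration (synthetic demo cohort)."""
    return {
        "seed": 0,
        "synthetic": {
            "n_samples": 60,
            "frac_hr_mut": 0.15,
            "frac_mmr_mut": 0.10,
            "frac_pole_mut": 0.05,
            "lambda0": 5.0,
            "rho": 3.0,
            "n_proteins": 60,
            "frac_infiltrated": 0.30,
            "delta": 2.0,
            "sigma": 1.0,
            "beta": 1.0,
            "gamma": 0.7,
            "frac_oncogene": 0.25,
            "panel_cell_types": 10,
            "panel_genes_per_set": 20,
            "panel_n_tcell": 4,
        },
        "inputs": None,  # alternative to synthetic: paths to cohort files
        "calling": {
            "n_permutations": 499,
            "q_threshold": 0.10,
            "weight_exponent": 1.0,
        },
        "thresholds": {
            "k": 9,
            "mutant_ic50_max": 500.0,
            "wt_ic50_min": 500.0,
            "expression_min": 0.0,
        },
        "panels": {
            "correlation_genes": ["IFNG", "GZMB", "FASLG", "LAG3", "TAP2",
                                  "CCR1", "LTBR", "TNFRSF25", "IL12RB2",
                                  "IL17RA", "IL21", "TSLP", "IL33", "IL7",
                                  "EDA2R"],
            "m1_genes": ["NOS2", "IL23A"],
            "m2_genes": ["SOCS2", "CHIA", "CHI3L1", "CHI3L2", "KLF4"],
            "pd_l1_gene": "CD274",
            "pd_1_gene": "PDCD1",
            "ifn_genes": ["IFNG", "IL12RB2", "TAP2"],
            "oncogene_rules": [["KRAS", "p.G12*"]],
        },
        "cooccurrence_alpha": 0.05,
        "fold_change_min_samples": 10,
    }


def merge_config(overrides: Mapping[str, Any] | None) -> dict[str, Any]:
    cfg = default_config()
    if not overrides:
        return cfg
    for key, value in overrides.items():
        if key not in cfg:
            raise ConfigError(f"unknown configuration key {key!r}")
        if isinstance(cfg[key], dict) and isinstance(value, Mapping):
            for k2, v2 in value.items():
                if k2 not in cfg[key] and key != "inputs":
                    raise ConfigError(f"unknown configuration key {key}.{k2}")
                cfg[key][k2] = v2
        else:
            cfg[key] = value
    return cfg


def load_config(path) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return merge_config(doc)


def config_hash(cfg: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False,
           index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format=_FLOAT_FMT)


def _cohort_config_from(cfg: Mapping[str, Any]) -> CohortConfig:
    syn = dict(cfg["synthetic"])
    panel = synthetic_panel(
        n_cell_types=int(syn.pop("panel_cell_types", 10)),
        genes_per_set=int(syn.pop("panel_genes_per_set", 20)),
        n_tcell=int(syn.pop("panel_n_tcell", 4)))
    return CohortConfig(panel=panel, seed=int(cfg["seed"]), **syn)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_io(cfg: Mapping[str, Any], rundir: Path) -> None:
    """Materialise the cohort files under ``rundir/cohort``."""
    cohort_dir = rundir / "cohort"
    if cfg.get("inputs"):
        cohort_dir.mkdir(parents=True, exist_ok=True)
        inputs = cfg["inputs"]
        for key, fname in COHORT_FILES.items():
            src = inputs.get(key)
            if src is None:
                raise ConfigError(f"inputs.{key} missing from configuration")
            src = Path(src)
            if not src.exists():
                raise DataError(f"input file for {key!r} not found: {src}")
            (cohort_dir / fname).write_bytes(src.read_bytes())
    else:
        cohort_cfg = _cohort_config_from(cfg)
        cohort, truth = generate_cohort(cohort_cfg)
        cohort.write(cohort_dir)
        truth.write(rundir / "truth")
    # validate everything round-trips through the readers
    _load_cohort(rundir)


def _load_cohort(rundir: Path):
    cohort_dir = rundir / "cohort"
    paths = {k: cohort_dir / v for k, v in COHORT_FILES.items()}
    for key, path in paths.items():
        if not path.exists():
            raise DataError(f"cohort file for {key!r} not found: {path} "
                            "(run the io stage first)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        muts = read_maf(paths["maf"])
        expr = read_expression(paths["expression"])
        proteins = read_fasta(paths["fasta"])
        sets = read_gmt(paths["panel"])
        tcell_df = pd.read_csv(paths["tcell"], sep="\t")
        hla = read_hla(paths["hla"])
        clinical = read_clinical(paths["clinical"])
    tcells = tcell_df.loc[tcell_df["is_tcell_subtype"] == 1, "cell_type"]
    panel = MetagenePanel.from_gene_sets(sets, tcell_subtypes=tcells)
    return muts, expr, proteins, panel, hla, clinical


def stage_phenotype(cfg: Mapping[str, Any], rundir: Path) -> None:
    _, expr, _, panel, _, _ = _load_cohort(rundir)
    out = rundir / "phenotype"
    out.mkdir(parents=True, exist_ok=True)
    calling = CallingConfig(
        n_permutations=int(cfg["calling"]["n_permutations"]),
        q_threshold=float(cfg["calling"]["q_threshold"]),
        weight_exponent=float(cfg["calling"]["weight_exponent"]),
        seed=int(cfg["seed"]))
    mat = call_infiltration(expr, panel, calling)
    _write(mat.results, out / "enrichment.tsv")
    _write(mat.calls.astype(int), out / "calls.tsv", index=True,
           index_label="sample_id")
    prev = infiltration_prevalence(mat, panel)
    prev_df = prev.per_cell_type.rename("percent_positive").reset_index()
    prev_df.columns = ["cell_type", "percent_positive"]
    agg = pd.DataFrame({"cell_type": ["any_tcell", "any_immune"],
                        "percent_positive": [prev.any_tcell, prev.any_immune]})
    _write(pd.concat([prev_df, agg], ignore_index=True), out / "prevalence.tsv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _write(cooccurrence(mat, alpha=float(cfg["cooccurrence_alpha"])),
               out / "cooccurrence.tsv")


def stage_burden(cfg: Mapping[str, Any], rundir: Path) -> None:
    muts, expr, _, _, _, _ = _load_cohort(rundir)
    out = rundir / "burden"
    out.mkdir(parents=True, exist_ok=True)
    roster = list(expr.sample_ids)
    burden = mutation_burden(muts, roster=roster)
    _write(burden.counts.rename("mutation_count").reset_index(),
           out / "burden.tsv")
    statuses = classify_repair(muts, roster=roster)
    _write(repair_status_frame(statuses).astype(int), out / "repair_status.tsv",
           index=True, index_label="sample_id")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _write(substitution_spectrum(muts), out / "spectrum.tsv", index=True)
        groups = median_split(burden)
    _write(groups.reset_index(), out / "burden_groups.tsv")
    onco = oncogene_positive(
        muts, [tuple(r) for r in cfg["panels"]["oncogene_rules"]],
        roster=roster)
    _write(onco.astype(int).reset_index(), out / "oncogene.tsv")


def stage_neoantigen(cfg: Mapping[str, Any], rundir: Path) -> None:
    muts, expr, proteins, _, hla, _ = _load_cohort(rundir)
    out = rundir / "neoantigen"
    out.mkdir(parents=True, exist_ok=True)
    th = NeoantigenThresholds(
        k=int(cfg["thresholds"]["k"]),
        mutant_ic50_max=float(cfg["thresholds"]["mutant_ic50_max"]),
        wt_ic50_min=float(cfg["thresholds"]["wt_ic50_min"]),
        expression_min=float(cfg["thresholds"]["expression_min"]))
    hla_map = {g.sample_id: g for g in hla}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        calls, load = predict_cohort(muts, proteins, hla_map,
                                     default_predictor(), expr, th,
                                     roster=list(expr.sample_ids))
    rows = []
    for call in calls:
        v = call.variant
        rows.append({
            "sample_id": v.sample_id, "gene": v.gene,
            "transcript_id": v.transcript_id, "position": v.position,
            "ref_aa": v.ref_aa, "alt_aa": v.alt_aa,
            "n_passing_pairs": len(call.passing_pairs),
            "is_neoantigen": int(call.is_neoantigen),
        })
    _write(pd.DataFrame(rows, columns=["sample_id", "gene", "transcript_id",
                                       "position", "ref_aa", "alt_aa",
                                       "n_passing_pairs", "is_neoantigen"]),
           out / "variant_calls.tsv")
    _write(load.reset_index(), out / "neoantigen_load.tsv")


def stage_stats(cfg: Mapping[str, Any], rundir: Path) -> None:
    muts, expr, _, panel, _, clinical = _load_cohort(rundir)
    out = rundir / "stats"
    out.mkdir(parents=True, exist_ok=True)
    panels = cfg["panels"]

    calls = pd.read_csv(rundir / "phenotype" / "calls.tsv", sep="\t",
                        index_col="sample_id").astype(bool)
    burden = pd.read_csv(rundir / "burden" / "burden.tsv", sep="\t",
                         index_col="sample_id")["mutation_count"]
    burden_groups = pd.read_csv(rundir / "burden" / "burden_groups.tsv",
                                sep="\t", index_col="sample_id")["burden_group"]
    repair = pd.read_csv(rundir / "burden" / "repair_status.tsv", sep="\t",
                         index_col="sample_id").astype(bool)
    onco = pd.read_csv(rundir / "burden" / "oncogene.tsv", sep="\t",
                       index_col="sample_id")["oncogene_positive"].astype(bool)
    load = pd.read_csv(rundir / "neoantigen" / "neoantigen_load.tsv", sep="\t",
                       index_col="sample_id")["neoantigen_load"]
    clin = {r.sample_id: r for r in clinical}

    # Figure 2A analogue: infiltration fold change, burden high vs low
    _write(infiltration_fold_change(
        calls, burden_groups.to_dict(), "high", "low",
        min_samples=int(cfg["fold_change_min_samples"])),
        out / "burden_fold_change.tsv")

    # Figure 2B-D analogue: label proportions in high vs low burden groups
    hi = burden_groups[burden_groups == "high"].index
    lo = burden_groups[burden_groups == "low"].index
    label_rows = []
    label_sources = {"oncogene_positive": onco.map({True: "positive",
                                                    False: "negative"})}
    label_sources["cluster"] = pd.Series(
        {s: (clin[s].cluster_label or "NA") for s in burden_groups.index})
    label_sources["histology"] = pd.Series(
        {s: (clin[s].histology_label or "NA") for s in burden_groups.index})
    for family, series in label_sources.items():
        for value in sorted(series.dropna().unique()):
            x1 = int((series.loc[hi] == value).sum())
            x2 = int((series.loc[lo] == value).sum())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                z, p = two_proportion_z(x1, len(hi), x2, len(lo))
            label_rows.append({
                "family": family, "label": value,
                "percent_high": 100 * x1 / len(hi),
                "percent_low": 100 * x2 / len(lo),
                "n_high": len(hi), "n_low": len(lo), "z": z, "p": p,
                "stars": significance_stars(p)})
    _write(pd.DataFrame(label_rows), out / "burden_group_labels.tsv")

    # Figure 3 analogue: burden by repair status; repair vs infiltration
    pathway_rows = []
    infil_rows = []
    for pathway in ("hr_mut", "mmr_mut", "pole_mut"):
        flag = repair[pathway]
        mut_ids = flag[flag].index
        wt_ids = flag[~flag].index
        if len(mut_ids) >= 2 and len(wt_ids) >= 2:
            cmp_burden = mean_test(burden.loc[mut_ids], burden.loc[wt_ids],
                                   label_a="mut", label_b="wt")
            cmp_load = mean_test(load.loc[mut_ids], load.loc[wt_ids],
                                 label_a="mut", label_b="wt")
            for metric, cmp in (("mutation_count", cmp_burden),
                                ("neoantigen_load", cmp_load)):
                pathway_rows.append({
                    "pathway": pathway, "metric": metric,
                    "n_mut": cmp.n_a, "n_wt": cmp.n_b,
                    "mean_mut": cmp.mean_a, "mean_wt": cmp.mean_b,
                    "sem_mut": cmp.sem_a, "sem_wt": cmp.sem_b,
                    "t": cmp.statistic, "p": cmp.p, "test": cmp.test_name,
                    "stars": significance_stars(cmp.p)})
        for ct in calls.columns:
            x1 = int(calls.loc[calls.index.intersection(mut_ids), ct].sum())
            x2 = int(calls.loc[calls.index.intersection(wt_ids), ct].sum())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                z, p = two_proportion_z(x1, max(len(mut_ids), 1),
                                        x2, max(len(wt_ids), 1))
            infil_rows.append({
                "pathway": pathway, "cell_type": ct,
                "percent_mut": 100 * x1 / max(len(mut_ids), 1),
                "percent_wt": 100 * x2 / max(len(wt_ids), 1),
                "z": z, "p": p, "stars": significance_stars(p)})
    _write(pd.DataFrame(pathway_rows), out / "repair_burden.tsv")
    _write(pd.DataFrame(infil_rows), out / "repair_infiltration.tsv")

    # IFN pathway gene mutation rates per pathway (mut vs wt)
    ifn_rows = []
    for pathway in ("hr_mut", "mmr_mut", "pole_mut"):
        flag = repair[pathway]
        if flag.any() and (~flag).any():
            groups = flag.map({True: "mut", False: "wt"}).to_dict()
            tab = gene_panel_mutation_rates(muts, panels["ifn_genes"],
                                            groups, "mut", "wt")
            tab.insert(0, "pathway", pathway)
            ifn_rows.append(tab)
    if ifn_rows:
        _write(pd.concat(ifn_rows, ignore_index=True),
               out / "ifn_mutation_rates.tsv")

    # Figure 4D analogue: neoantigen top-quartile vs rest infiltration
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        neo_groups = quartile_split(load)
    _write(neo_groups.reset_index(), out / "neoantigen_groups.tsv")
    _write(infiltration_fold_change(
        calls, neo_groups.to_dict(), "top_quartile", "rest",
        min_samples=int(cfg["fold_change_min_samples"])),
        out / "neoantigen_fold_change.tsv")

    # Figure 5A analogue: load vs gene expression Pearson correlations
    corr_rows = []
    for gene in panels["correlation_genes"]:
        if gene not in expr.gene_ids:
            continue
        x = load.reindex(expr.sample_ids).to_numpy(dtype=float)
        y = expr.values.loc[gene].to_numpy(dtype=float)
        try:
            res = pearson(x, y, gene=gene)
        except DataError:
            continue
        corr_rows.append({"gene": gene, "r": res.r, "p": res.p, "n": res.n,
                          "stars": res.stars})
    _write(pd.DataFrame(corr_rows, columns=["gene", "r", "p", "n", "stars"]),
           out / "gene_correlations.tsv")

    # Figure 5B-D analogue: M1/M2 and checkpoint expression, top vs rest
    expr_rows = []
    top_ids = neo_groups[neo_groups == "top_quartile"].index
    rest_ids = neo_groups[neo_groups == "rest"].index
    gene_families = ([("M1", g) for g in panels["m1_genes"]]
                     + [("M2", g) for g in panels["m2_genes"]]
                     + [("checkpoint", panels["pd_l1_gene"]),
                        ("checkpoint", panels["pd_1_gene"])])
    for family, gene in gene_families:
        if gene not in expr.gene_ids or len(top_ids) < 2 or len(rest_ids) < 2:
            continue
        vals = expr.values.loc[gene]
        cmp = mean_test(vals.loc[vals.index.intersection(top_ids)],
                        vals.loc[vals.index.intersection(rest_ids)],
                        label_a="neoantigen_high", label_b="neoantigen_low")
        expr_rows.append({
            "family": family, "gene": gene,
            "mean_high": cmp.mean_a, "mean_low": cmp.mean_b,
            "sem_high": cmp.sem_a, "sem_low": cmp.sem_b,
            "t": cmp.statistic, "p": cmp.p, "test": cmp.test_name,
            "stars": significance_stars(cmp.p)})
    _write(pd.DataFrame(expr_rows), out / "expression_groups.tsv")

    # Figure 5E analogue: survival of neoantigen-high vs low
    groups_clin = {
        "neoantigen_high": [clin[s] for s in top_ids if s in clin],
        "neoantigen_low": [clin[s] for s in rest_ids if s in clin],
    }
    if all(len(v) > 0 for v in groups_clin.values()):
        try:
            curves, chi2, p = km_logrank(groups_clin)
        except DataError as exc:
            log.warning("survival comparison skipped: %s", exc)
        else:
            curve_rows = []
            for gname, curve in curves.items():
                for i in range(len(curve.times)):
                    curve_rows.append({
                        "group": gname, "time": curve.times[i],
                        "survival": curve.survival[i],
                        "at_risk": int(curve.at_risk[i]),
                        "events": int(curve.n_events[i]),
                        "censored": int(curve.n_censored[i])})
            _write(pd.DataFrame(curve_rows), out / "survival_curves.tsv")
            _write(pd.DataFrame([{"chi_square": chi2, "p": p,
                                  "stars": significance_stars(p),
                                  "test": "logrank"}]),
                   out / "survival_test.tsv")


_STAGE_FUNCS = {
    "io": stage_io,
    "phenotype": stage_phenotype,
    "burden": stage_burden,
    "neoantigen": stage_neoantigen,
    "stats": stage_stats,
}


def run_pipeline(cfg: Mapping[str, Any], outdir,
                 stages: Sequence[str] = STAGES) -> Path:
    """Execute the requested stages in order and write the run manifest."""
    unknown = [s for s in stages if s not in _STAGE_FUNCS]
    if unknown:
        raise ConfigError(f"unknown stage(s) {unknown}")
    stages = [s for s in STAGES if s in stages]
    rundir = Path(outdir)
    rundir.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    manifest_path = rundir / "manifest.json"

    def write_manifest(error: str | None = None) -> None:
        doc = {
            "package": "immunoscope",
            "version": __version__,
            "seed": int(cfg["seed"]),
            "config_hash": config_hash(cfg),
            "stages_completed": completed,
        }
        if error is not None:
            doc["error"] = error
        manifest_path.write_text(json.dumps(doc, indent=1, sort_keys=True),
                                 encoding="utf-8")

    for stage in stages:
        log.info("stage %s: starting", stage)
        try:
            _STAGE_FUNCS[stage](cfg, rundir)
        except Exception as exc:
            write_manifest(error=f"stage {stage}: {exc}")
            raise StageError(stage, exc) from exc
        completed.append(stage)
        log.info("stage %s: done", stage)
    write_manifest()
    return rundir
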