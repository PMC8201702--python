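"""End-to-end orchestration of the divergent-selection GWAS analysis.

Stages: simulate (or load) inputs -> genotype QC -> parental-average
genotypes for response animals -> fixed-effect pre-adjustment ->
per-analysis (global / HRFI / LRFI) LMM association with genomic
control -> effective-test thresholds -> QTL windows/regions/SNP-QTL ->
allele-frequency trajectories and evolution classification -> summary.

Every stage writes plain text artifacts (CSV/TSV/JSON) into the run
directory so any stage can be re-run or swapped against external
tools, and a machine-readable ``summary.json`` mirrors the human
report.  Runs are deterministic given the seed and inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import regions as regions_mod
from . import traits as trait_defaults
from .assoc import apply_genomic_control, fit_null_lambda, score_markers
from .genotypes import predict_average_genotypes, qc_filter, write_plink
from .pedigree import build_a_matrix, write_pedigree
from .phenotypes import adjust_phenotypes
from .simdesign import SimConfig, simulate_experiment
from .thresholds import compute_thresholds
from .trajectories import evolution_records, records_table, trait_evolution_summary

logger = logging.getLogger(__name__)

ANALYSES = ("global", "HRFI", "LRFI")


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    analyses: tuple[str, ...] = ANALYSES
    traits: tuple[str, ...] | None = None  # default: all simulated traits
    genomewide_mlog10: float | str = 4.5  # or "auto" (effective-test Bonferroni)
    suggestive_mlog10: float = 3.0
    variance_kept: float = 0.996
    gc_estimator: str = "regression"
    refit_lambda_per_marker: bool = False
    qc_cf_min: float = 0.95
    qc_maf_min: float = 0.01
    qc_cr_min: float = 0.90
    qc_hwe_p: float = 1e-10  # 0 disables the Hardy-Weinberg filter
    adjust_fixed: tuple[str, ...] = ("sex", "contemporary_group")
    adjust_covariates: tuple[str, ...] = ()
    line_differences_sigma_g: dict[str, float] = field(
        default_factory=lambda: dict(trait_defaults.G9_DIFF_SIGMA_G)
    )
    seed: int | None = None
    out_dir: str = "runs/run"

    def validate(self) -> None:
        if not self.analyses:
            raise ValueError("at least one analysis must be selected")
        bad = set(self.analyses) - set(ANALYSES)
        if bad:
            raise ValueError(f"unknown analyses: {sorted(bad)}")
        if self.genomewide_mlog10 != "auto" and float(self.genomewide_mlog10) <= 0:
            raise ValueError("thresholds must be positive")
        if self.suggestive_mlog10 <= 0:
            raise ValueError("thresholds must be positive")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"stage {name!r} failed: {e}") from e
        return wrapped
    return deco


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline; returns the summary dict (also written)."""
    config.validate()
    sim_cfg = config.sim
    if config.seed is not None:
        sim_cfg = replace(sim_cfg, seed=config.seed)
    out = Path(config.out_dir)
    (out / "sim").mkdir(parents=True, exist_ok=True)

    sim = _stage("simulate")(simulate_experiment)(sim_cfg)
    write_pedigree(sim.pedigree, out / "sim" / "pedigree.csv")
    write_plink(sim.breeder_genotypes, out / "sim" / "breeders.ped", out / "sim" / "breeders.map")
    sim.phenotypes.to_csv(out / "sim" / "phenotypes.tsv", sep="\t", index=False)
    sim.true_qtl.to_csv(out / "sim" / "true_qtl.tsv", sep="\t", index=False)

    filtered, qc_report = _stage("qc")(qc_filter)(
        sim.breeder_genotypes, config.qc_cf_min, config.qc_maf_min,
        config.qc_cr_min, config.qc_hwe_p,
    )
    qc_report.write_json(out / "qc_report.json")

    avg = _stage("predict_genotypes")(predict_average_genotypes)(filtered, sim.pedigree)
    avg.write_dosage_tsv(out / "average_genotypes.tsv")

    traits = list(config.traits) if config.traits is not None else list(sim_cfg.traits)
    model_spec = {
        t: {"fixed": list(config.adjust_fixed), "covariates": list(config.adjust_covariates)}
        for t in traits
    }
    adjusted = _stage("adjust")(adjust_phenotypes)(sim.phenotypes, model_spec)
    adjusted.to_csv(out / "adjusted_phenotypes.tsv", sep="\t")

    thr = _stage("thresholds")(compute_thresholds)(
        filtered, config.variance_kept, suggestive=config.suggestive_mlog10
    )
    thr.write_json(out / "thresholds.json")
    if config.genomewide_mlog10 == "auto":
        genomewide = thr.genomewide_mlog10
    else:
        genomewide = float(config.genomewide_mlog10)

    ped = sim.pedigree
    resp_lines = dict(zip(ped["id"].astype(str), ped["line"]))
    assoc_dir = out / "assoc"
    assoc_dir.mkdir(exist_ok=True)
    assoc_by_analysis: dict[str, dict[str, pd.DataFrame]] = {}
    regions_by_analysis: dict[str, list] = {}
    inflation: dict[str, dict[str, float]] = {}
    lambdas: dict[str, dict[str, float]] = {}

    for analysis in config.analyses:
        if analysis == "global":
            ids_all = list(avg.ids)
        else:
            ids_all = [i for i in avg.ids if resp_lines.get(i) == analysis]
        assoc_by_analysis[analysis] = {}
        inflation[analysis] = {}
        lambdas[analysis] = {}
        windows = []
        a_cache: dict[tuple, object] = {}
        for trait in traits:
            res_t = adjusted[trait].dropna()
            ids = [i for i in ids_all if i in res_t.index]
            y = res_t.loc[ids]
            key = tuple(ids)
            if key not in a_cache:
                a_cache[key] = build_a_matrix(ped, ids)
            amat = a_cache[key]
            fit = _stage("assoc")(fit_null_lambda)(y, amat)
            scan = _stage("assoc")(score_markers)(
                y, avg, fit, refit_lambda_per_marker=config.refit_lambda_per_marker
            )
            scan, factor = _stage("genomic_control")(apply_genomic_control)(
                scan, estimator=config.gc_estimator
            )
            inflation[analysis][trait] = factor
            lambdas[analysis][trait] = fit.lambda_
            scan.insert(0, "analysis", analysis)
            scan.insert(0, "trait", trait)
            scan.to_csv(assoc_dir / f"{analysis}_{trait}.tsv", sep="\t", index=False)
            assoc_by_analysis[analysis][trait] = scan
            windows += regions_mod.make_windows(scan, genomewide, trait=trait, analysis=analysis)
        regs = _stage("regions")(regions_mod.fuse_regions)(windows, analysis=analysis)
        regions_by_analysis[analysis] = regs
        regions_mod.regions_table(regs).to_csv(out / f"regions_{analysis}.tsv", sep="\t", index=False)
        regions_mod.snp_qtl_table(regs).to_csv(out / f"snp_qtl_{analysis}.tsv", sep="\t", index=False)

    overlap, lookup = _stage("cross_analysis")(regions_mod.cross_analysis_compare)(
        regions_by_analysis, assoc_by_analysis, genomewide, config.suggestive_mlog10
    )
    overlap.to_csv(out / "region_overlap.tsv", sep="\t", index=False)
    lookup.to_csv(out / "snp_qtl_lookup.tsv", sep="\t", index=False)

    # trajectories of all tagged markers
    snp_by_trait: dict[str, list[str]] = {}
    for regs in regions_by_analysis.values():
        for r in regs:
            for s in r.snp_qtls:
                snp_by_trait.setdefault(s.trait, [])
                if s.snp_id not in snp_by_trait[s.trait]:
                    snp_by_trait[s.trait].append(s.snp_id)
    records_by_trait = {}
    all_records = []
    union_snps = sorted({s for snps in snp_by_trait.values() for s in snps})
    if union_snps:
        rec_map = {
            r.snp_id: r
            for r in _stage("trajectories")(evolution_records)(
                avg, ped, union_snps, n_generations=sim_cfg.n_generations
            )
        }
        for trait, snps in snp_by_trait.items():
            records_by_trait[trait] = [rec_map[s] for s in snps]
        all_records = [rec_map[s] for s in union_snps]
        records_table(all_records).to_csv(out / "evolution_records.tsv", sep="\t", index=False)
    evo_summary, corr = trait_evolution_summary(
        records_by_trait, config.line_differences_sigma_g
    ) if records_by_trait else (pd.DataFrame(), float("nan"))
    if not evo_summary.empty:
        evo_summary.to_csv(out / "trait_evolution_summary.tsv", sep="\t", index=False)

    categories = [r.category for r in all_records]
    cat_pct = {
        c: round(100.0 * categories.count(c) / len(categories), 2) if categories else 0.0
        for c in ("no_change", "co_selected", "opposite", "one_line_only")
    }
    shared = 0
    if "global" in regions_by_analysis and not overlap.empty:
        gsub = overlap[overlap["analysis"] == "global"]
        for _, row in gsub.iterrows():
            if any(row.get(f"overlap_{a}") for a in config.analyses if a != "global"):
                shared += 1
    summary = {
        "seed": sim_cfg.seed,
        "n_response_with_genotypes": len(avg.ids),
        "n_snps_after_qc": len(filtered.snp_map),
        "genomewide_mlog10": round(float(genomewide), 4),
        "suggestive_mlog10": config.suggestive_mlog10,
        "total_effective_tests": thr.total_effective,
        "lambda_by_analysis": {a: {t: round(v, 4) for t, v in d.items()} for a, d in lambdas.items()},
        "inflation_by_analysis": {a: {t: round(v, 4) for t, v in d.items()} for a, d in inflation.items()},
        "regions_per_analysis": {a: len(r) for a, r in regions_by_analysis.items()},
        "global_regions_shared_with_a_line": shared,
        "n_snp_qtl": len(all_records),
        "category_percentages": cat_pct,
        "trait_evolution": evo_summary.to_dict("records") if not evo_summary.empty else [],
        "evolution_vs_line_difference_correlation": None if np.isnan(corr) else round(corr, 4),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    logger.info("run complete: %s", out / "summary.json")
    return summary


def config_from_dict(d: dict) -> RunConfig:
    """Build a RunConfig (with nested SimConfig) from a plain mapping."""
    d = dict(d)
    sim_d = d.pop("sim", {})
    sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
    bad = set(sim_d) - sim_fields
    if bad:
        raise ValueError(f"unknown sim config keys: {sorted(bad)}")
    for key in ("founder_maf_range", "response_counts", "qtl_effects", "traits"):
        if key in sim_d and isinstance(sim_d[key], list):
            sim_d[key] = tuple(sim_d[key])
    sim = SimConfig(**sim_d)
    run_fields = {f.name for f in dataclasses.fields(RunConfig)}
    bad = set(d) - run_fields
    if bad:
        raise ValueError(f"unknown run config keys: {sorted(bad)}")
    for key in ("analyses", "traits", "adjust_fixed", "adjust_covariates"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return RunConfig(sim=sim, **d)
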