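"""End-to-end orchestration: simulate -> SE calling -> QC -> LD -> association -> concordance.

``run_stages`` executes the whole analysis in memory and returns every
intermediate product; ``run_pipeline`` wraps it with artifact writing, a
run report (per-stage counts, parameters, seed, file checksums) and a
human-readable summary.  Stage order follows the variant-selection
flowchart: condition-specific SE restriction, then variant QC, then LD
clumping, then association with FDR, then eQTL/expression concordance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .association import (
    association_scan,
    bh_fdr,
    stratified_analysis,
)
from .concordance import concordance_filter, differential_expression, eqtl_scan
from .ld import clump, r2_matrix
from .se_caller import (
    DEFAULT_EXCLUDE_CHROMS,
    DEFAULT_STITCH_DISTANCE,
    DEFAULT_TSS_WINDOW,
    call_ses,
    specific_ses,
)
from .simulate import SimConfig, gen_annotation, gen_expression, gen_genotypes, gen_peaks, gen_phenotypes, ground_truth
from .variant_qc import filter_variants, intersect_with_ses, qc_stats

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "se_call", "qc", "ld", "association", "stratify", "concordance")


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    stages: tuple[str, ...] = ALL_STAGES
    stitch_distance: int = DEFAULT_STITCH_DISTANCE
    tss_window: int = DEFAULT_TSS_WINDOW
    exclude_chroms: tuple[str, ...] = tuple(sorted(DEFAULT_EXCLUDE_CHROMS))
    maf_min: float = 0.05
    hwe_min: float = 1e-6
    call_rate_min: float = 0.95
    r2_threshold: float = 0.8
    clump_before_assoc: bool = True
    model: str = "additive"
    covariates: tuple[str, ...] = ("age", "bmi", "smoking", "family_history")
    stratify_var: str = "age_group"
    stratify_model: str = "dominant"
    fdr_m: int | None = None
    alpha_eqtl: float = 0.05
    alpha_de: float = 0.05
    de_method: str = "mannwhitney"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {ALL_STAGES}")

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return PipelineConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim_raw = dict(raw.pop("sim", {}))
        cov = sim_raw.pop("covariate_effects", None)
        from .simulate import CovariateEffects

        sim_kwargs = dict(sim_raw)
        if "conditions" in sim_kwargs:
            sim_kwargs["conditions"] = tuple(sim_kwargs["conditions"])
        if cov is not None:
            sim_kwargs["covariate_effects"] = CovariateEffects(**cov)
        for key in ("stages", "exclude_chroms", "covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return PipelineConfig(sim=SimConfig(**sim_kwargs), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunReport:
    counts: dict
    parameters: dict
    seed: int
    checksums: dict = field(default_factory=dict)


def run_stages(config: PipelineConfig) -> dict:
    """Run the enabled stages in order, in memory.

    Returns a dict of intermediate products plus a ``counts`` dict mirroring
    the flowchart (SEs called, variants surviving each filter, clumps,
    significant hits pre/post FDR, concordant genes).
    """
    out: dict = {"counts": {}}
    counts = out["counts"]
    if "simulate" not in config.stages:
        return out
    sim = config.sim

    # --- simulate -----------------------------------------------------------
    tss = gen_annotation(sim)
    peaks = {cond: gen_peaks(sim, cond) for cond in sim.conditions}
    gm_pool = gen_genotypes(sim)
    phen = gen_phenotypes(gm_pool, sim)
    phen = phen.assign(age_group=np.where(phen["age"] >= 70, ">=70", "<70"))
    expr = gen_expression(gm_pool, sim)
    out.update(tss=tss, peaks=peaks, genotypes_pool=gm_pool, phenotypes=phen, expression=expr,
               truth=ground_truth(sim))
    counts["samples_phenotyped"] = len(phen)
    counts["variants_simulated"] = gm_pool.n_variants

    if "se_call" not in config.stages:
        return out

    # --- SE calling and condition-specific set ------------------------------
    se_results = {
        cond: call_ses(pk, tss, config.stitch_distance, config.tss_window)
        for cond, pk in peaks.items()
    }
    target = se_results[sim.target_condition]
    backgrounds = [se_results[c] for c in sim.conditions[1:]]
    spec, spec_counts = specific_ses(target, backgrounds, set(config.exclude_chroms))
    out.update(se_results=se_results, specific=spec)
    counts["ses_per_condition"] = {c: len(r.se_set) for c, r in se_results.items()}
    counts["specific_ses"] = spec_counts

    if "qc" not in config.stages:
        return out

    # --- variant QC on the phenotyped study samples -------------------------
    gm = gm_pool.subset_samples(list(phen["sample"]))
    controls = list(phen.loc[phen["status"] == "control", "sample"])
    stats = qc_stats(gm, hwe_samples=controls)
    kept_ids, qc_counts = filter_variants(
        stats,
        {"maf_min": config.maf_min, "hwe_min": config.hwe_min, "call_rate_min": config.call_rate_min},
    )
    assignment = intersect_with_ses(
        gm.variants[gm.variants["id"].isin(kept_ids)], spec
    )
    se_variant_ids = list(dict.fromkeys(assignment["id"]))
    out.update(genotypes=gm, qc=stats, qc_counts=qc_counts, se_assignment=assignment)
    counts["variants_qc_pass"] = len(kept_ids)
    counts["qc_removals"] = qc_counts
    counts["variants_in_specific_ses"] = len(se_variant_ids)

    if "ld" not in config.stages:
        out["tested_ids"] = se_variant_ids
        return out

    # --- LD and clumping within SE regions ----------------------------------
    ld_frames, clumps = [], []
    for se_index, sub in assignment.groupby("se_index"):
        ids = list(dict.fromkeys(sub["id"]))
        if len(ids) < 2:
            clumps.extend(clump(gm.variants[gm.variants["id"].isin(ids)], pd.DataFrame(
                columns=["idA", "idB", "r2", "d_prime", "n", "ok"]), r2_threshold=config.r2_threshold))
            continue
        ldt = r2_matrix(gm, ids)
        ldt.insert(0, "se_index", se_index)
        ld_frames.append(ldt)
        clumps.extend(
            clump(gm.variants[gm.variants["id"].isin(ids)], ldt, r2_threshold=config.r2_threshold)
        )
    ld_table = pd.concat(ld_frames, ignore_index=True) if ld_frames else pd.DataFrame(
        columns=["se_index", "idA", "idB", "r2", "d_prime", "n", "ok"]
    )
    out.update(ld=ld_table, clumps=clumps)
    counts["clumps"] = len(clumps)
    tested_ids = [c.tag for c in clumps] if config.clump_before_assoc else se_variant_ids
    out["tested_ids"] = tested_ids

    if "association" not in config.stages:
        return out

    # --- association with FDR ------------------------------------------------
    assoc = association_scan(gm, phen, model=config.model, covariates=(), variant_ids=tested_ids)
    assoc_adj = association_scan(
        gm, phen, model=config.model, covariates=config.covariates, variant_ids=tested_ids
    )
    m = config.fdr_m or int(assoc["p"].notna().sum())
    assoc["p_fdr"] = bh_fdr(assoc["p"], m=m)
    assoc_adj["p_fdr"] = bh_fdr(assoc_adj["p"], m=m)
    out.update(association=assoc, association_adjusted=assoc_adj)
    counts["tests"] = int(assoc["p"].notna().sum())
    counts["significant_raw"] = int((assoc["p"] < 0.05).sum())
    counts["significant_fdr"] = int((assoc["p_fdr"] < 0.05).sum())
    top = assoc.dropna(subset=["p_fdr"]).sort_values("p_fdr")
    out["top_hit"] = None if top.empty else str(top.iloc[0]["variant"])
    counts["top_hit"] = out["top_hit"]

    if "stratify" in config.stages and out["top_hit"] is not None:
        try:
            strat, het = stratified_analysis(
                gm, phen, out["top_hit"], config.stratify_var,
                model=config.stratify_model, covariates=(),
            )
            out["stratified"] = strat
            out["heterogeneity"] = het
            counts["strata"] = int(strat["stratum"].nunique())
        except ValueError as exc:
            logger.warning("stratified analysis skipped: %s", exc)

    if "concordance" not in config.stages:
        return out

    # --- eQTL / tumor-expression concordance --------------------------------
    causal_id = gm_pool.meta["causal_id"]
    dose_calls = gm_pool.variant_calls(causal_id).astype(float)
    dose_calls[dose_calls < 0] = np.nan
    dosage = pd.Series(dose_calls, index=gm_pool.samples)
    eqtl = eqtl_scan(dosage, expr, gm_pool.meta["causal_chrom"], gm_pool.meta["causal_pos"])
    de = differential_expression(expr, method=config.de_method)
    conc = concordance_filter(eqtl, de, config.alpha_eqtl, config.alpha_de)
    out.update(eqtl=eqtl, de=de, concordance=conc)
    counts["concordant_genes"] = conc.loc[conc["concordant"], "gene"].tolist()
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> RunReport:
    """Run the enabled stages, write artifacts under ``out_dir``, return the report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res = run_stages(config)
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        written.append(path)

    if "tss" in res:
        emit("tss.bed", lambda p: sio.write_tss_bed(res["tss"], p))
        for cond, pk in res["peaks"].items():
            emit(f"peaks_{cond}.bed", lambda p, pk=pk: sio.write_peaks_bed(pk, p))
        emit("genotypes.vcf", lambda p: sio.write_vcf(res["genotypes_pool"], p))
        emit("phenotypes.tsv", lambda p: sio.write_phenotypes(res["phenotypes"], p))
        emit("truth.json", lambda p: sio.write_json(res["truth"], p))
        expr = res["expression"]
        sio.write_expression(expr, out_dir / "expression_genes.tsv",
                             out_dir / "expression_values.tsv", out_dir / "expression_samples.tsv")
        written += [out_dir / "expression_genes.tsv", out_dir / "expression_values.tsv",
                    out_dir / "expression_samples.tsv"]
    if "se_results" in res:
        for cond, r in res["se_results"].items():
            emit(f"se_calls_{cond}.bed", lambda p, r=r: sio.write_se_calls_bed(r, p))
        target_cond = config.sim.target_condition
        emit("rank_curve.tsv", lambda p: res["se_results"][target_cond].rank_table().to_csv(
            p, sep="\t", index=False))
        emit("specific_ses.bed", lambda p: _write_enhancers_bed(res["specific"], p))
    if "qc" in res:
        emit("variant_qc.tsv", lambda p: res["qc"].to_csv(p, sep="\t", index=False))
        emit("qc_summary.json", lambda p: sio.write_json(res["qc_counts"], p))
        emit("se_assignment.tsv", lambda p: res["se_assignment"].to_csv(p, sep="\t", index=False))
    if "ld" in res:
        emit("ld_pairs.tsv", lambda p: res["ld"].to_csv(p, sep="\t", index=False))
        emit("clumps.tsv", lambda p: pd.DataFrame(
            [{"tag": c.tag, "members": ",".join(c.members)} for c in res["clumps"]]
        ).to_csv(p, sep="\t", index=False))
    if "association" in res:
        emit("association.tsv", lambda p: res["association"].to_csv(p, sep="\t", index=False))
        emit("association_adjusted.tsv",
             lambda p: res["association_adjusted"].to_csv(p, sep="\t", index=False))
    if "stratified" in res:
        emit("stratified.tsv", lambda p: res["stratified"].to_csv(p, sep="\t", index=False))
        het = res["heterogeneity"]
        emit("heterogeneity.json", lambda p: sio.write_json(
            {"q": het.q, "df": het.df, "i2": het.i2, "p_het": het.p_het}, p))
    if "concordance" in res:
        emit("concordance.tsv", lambda p: res["concordance"].to_csv(p, sep="\t", index=False))

    report = RunReport(
        counts=res["counts"],
        parameters=config.to_dict(),
        seed=config.sim.seed,
        checksums={p.name: _sha256(p) for p in written},
    )
    sio.write_json(
        {"counts": report.counts, "parameters": report.parameters, "seed": report.seed,
         "checksums": report.checksums},
        out_dir / "report.json",
    )
    (out_dir / "report.md").write_text(report_render(report))
    return report


def _write_enhancers_bed(enhancers, path) -> None:
    with open(path, "w") as fh:
        for e in enhancers:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\tse_r{e.rank}\t{e.total_signal:.6g}\n")


def report_render(report: RunReport) -> str:
    """Deterministic human-readable summary of a run report."""
    lines = ["# sevariant run report", "", f"seed: {report.seed}", ""]
    c = report.counts
    if not c:
        return "\n".join(lines + ["(no stages enabled — empty run)", ""])
    lines.append("## Stage counts")
    for key, val in c.items():
        lines.append(f"- {key}: {val}")
    if "ses_per_condition" not in c:
        lines += ["", "(SE calling disabled; rank-curve section omitted)"]
    lines.append("")
    if report.checksums:
        lines.append("## Artifact checksums (sha256)")
        for name in sorted(report.checksums):
            lines.append(f"- {name}: {report.checksums[name]}")
        lines.append("")
    return "\n".join(lines)
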