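"""Synthetic inputs with the statistical structure the pipeline assumes.

Every downstream stage is exercisable without any external download: the
generator emits (a) multi-condition H3K27ac-like peak tracks with planted
super-enhancer clusters, (b) case-control genotypes with haplotype-block LD
and one planted risk allele inside a planted SE, (c) a phenotype table drawn
from a logistic disease model with epidemiological covariates, and (d) a
log2 expression matrix with a genotype dose effect on one target gene plus a
tumor-vs-normal shift.

The genotype pool is larger than the study (``pool_factor``) so that
case/control status can be rejection-sampled to the requested counts, which
is the retrospective design the odds ratio estimates.  Within an LD block,
haplotype alleles follow a first-order copy-or-redraw chain with copy
probability sqrt(within_block_r2): allele frequencies are preserved exactly
and the haplotype r^2 between adjacent variants equals within_block_r2 (with
geometric decay at longer range).  All outputs are deterministic functions
of the config, including its seed; each component draws from its own fixed
substream so regenerating one output never perturbs another.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import expit

from .concordance import ExpressionMatrix
from .se_caller import DEFAULT_STITCH_DISTANCE, DEFAULT_TSS_WINDOW, Peak
from .variant_qc import GenotypeMatrix

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class CovariateEffects:
    """Log-odds-ratio per covariate in the disease model (0 = no confounding)."""

    age: float = 0.02  # per year, centered at the age mean
    bmi: float = 0.01  # per kg/m^2, centered at the BMI mean
    smoking_ever: float = 0.15
    smoking_current: float = 0.30
    family_history: float = 0.70


@dataclass(frozen=True)
class SimConfig:
    """All generator parameters.  Defaults are the package's study conditions."""

    # genome / annotation
    n_chromosomes: int = 4
    chrom_length: int = 5_000_000
    include_chrx: bool = True
    n_tss: int = 40  # per chromosome

    # peak tracks; the first condition is the cancer ("target") condition
    conditions: tuple[str, ...] = ("tumor", "normal", "benign")
    n_peaks_per_condition: int = 150
    n_planted_se_clusters: int = 3  # target-specific, autosomal
    n_shared_se_clusters: int = 2  # planted in every condition
    peaks_per_cluster: int = 10
    cluster_span: int = 40_000
    background_signal_shape: float = 8.0
    background_signal_scale: float = 0.25
    se_signal_multiplier: float = 20.0

    # genotypes
    n_cases: int = 1_500
    n_controls: int = 1_000
    pool_factor: float = 4.0
    n_variants: int = 50
    block_size: int = 5
    within_block_r2: float = 0.95
    missing_rate: float = 0.02
    causal_maf: float = 0.2
    causal_or: float = 1.5

    # disease model
    baseline_prevalence_logit: float = -0.2
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)

    # expression
    n_genes: int = 4
    n_expr_samples: int = 200
    eqtl_beta: float = 0.5  # log2 units per risk allele, target gene
    tumor_shift: float = 1.0  # log2 units, tumor vs normal, target gene
    noise_sd: float = 0.5

    seed: int = 1

    def __post_init__(self) -> None:
        positive = {
            "n_chromosomes": self.n_chromosomes, "chrom_length": self.chrom_length,
            "n_peaks_per_condition": self.n_peaks_per_condition,
            "peaks_per_cluster": self.peaks_per_cluster, "cluster_span": self.cluster_span,
            "n_cases": self.n_cases, "n_controls": self.n_controls,
            "n_variants": self.n_variants, "block_size": self.block_size,
            "n_genes": self.n_genes, "n_expr_samples": self.n_expr_samples,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for name, v in {"n_tss": self.n_tss, "n_planted_se_clusters": self.n_planted_se_clusters,
                        "n_shared_se_clusters": self.n_shared_se_clusters}.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if not 0 < self.causal_maf <= 0.5:
            raise ValueError(f"causal_maf must be in (0, 0.5], got {self.causal_maf}")
        if self.causal_or <= 0:
            raise ValueError(f"causal_or must be > 0, got {self.causal_or}")
        if not 0 <= self.within_block_r2 <= 1:
            raise ValueError(f"within_block_r2 must be in [0, 1], got {self.within_block_r2}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.pool_factor < 1:
            raise ValueError("pool_factor must be >= 1")
        if not self.conditions:
            raise ValueError("at least one condition required")
        if self.cluster_span >= DEFAULT_STITCH_DISTANCE * self.peaks_per_cluster:
            raise ValueError(
                "cluster_span must be < stitch distance x peaks_per_cluster so planted "
                "clusters stitch into one region"
            )
        if self.background_signal_shape <= 0 or self.background_signal_scale <= 0:
            raise ValueError("gamma signal parameters must be positive")
        if self.se_signal_multiplier <= 0:
            raise ValueError("se_signal_multiplier must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(f"chr{i}" for i in range(1, self.n_chromosomes + 1))

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return self.autosomes + (("chrX",) if self.include_chrx else ())

    @property
    def target_condition(self) -> str:
        return self.conditions[0]

    @property
    def n_pool(self) -> int:
        return int(math.ceil(self.pool_factor * (self.n_cases + self.n_controls)))


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def gen_annotation(config: SimConfig) -> pd.DataFrame:
    """TSS annotation: n_tss uniform sites per chromosome with strand and gene id."""
    rng = _rng(config, 1)
    rows = []
    for chrom in config.chromosomes:
        pos = np.sort(rng.integers(0, config.chrom_length, size=config.n_tss))
        strands = rng.choice(["+", "-"], size=config.n_tss)
        for i, (p, s) in enumerate(zip(pos, strands)):
            rows.append({"chrom": chrom, "pos": int(p), "strand": str(s),
                         "gene_id": f"{chrom}_g{i:03d}"})
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "gene_id"])


@lru_cache(maxsize=8)
def planted_layout(config: SimConfig) -> tuple[dict, ...]:
    """Deterministic coordinates of the planted SE clusters.

    Shared clusters appear in every condition's track; 'specific' clusters
    (autosomal) and the optional chrX cluster appear only in the target
    condition — the autosomal specific clusters are the expected
    cancer-specific SE set.  Clusters avoid TSS windows entirely (so planted
    peaks survive the TSS-proximity exclusion) and keep a safety gap of two
    stitch distances from one another.
    """
    rng = _rng(config, 0)
    tss = gen_annotation(config)
    tss_by_chrom = {c: sub["pos"].to_numpy() for c, sub in tss.groupby("chrom")}
    placed: list[dict] = []
    kinds = (
        ["shared"] * config.n_shared_se_clusters
        + ["specific"] * config.n_planted_se_clusters
        + (["chrx_specific"] if config.include_chrx and config.n_planted_se_clusters > 0 else [])
    )
    margin = DEFAULT_TSS_WINDOW
    sep = 2 * DEFAULT_STITCH_DISTANCE
    for k, kind in enumerate(kinds):
        chrom_pool = ("chrX",) if kind == "chrx_specific" else config.autosomes
        for _ in range(2000):
            chrom = str(rng.choice(chrom_pool))
            start = int(rng.integers(0, config.chrom_length - config.cluster_span))
            end = start + config.cluster_span
            sites = tss_by_chrom.get(chrom, np.empty(0))
            if np.any((sites + margin > start) & (sites - margin < end)):
                continue
            if any(
                p["chrom"] == chrom and p["start"] - sep < end and p["end"] + sep > start
                for p in placed
            ):
                continue
            placed.append({"name": f"cluster{k}", "kind": kind, "chrom": chrom,
                           "start": start, "end": end})
            break
        else:
            raise ValueError(
                f"could not place planted SE cluster {k} ({kind}) without overlap; "
                "increase chrom_length or reduce clusters/TSS density"
            )
    return tuple(placed)


def _avoids_tss(start: int, end: int, sites: np.ndarray, window: int) -> bool:
    return not np.any((sites + window > start) & (sites - window < end))


def gen_peaks(config: SimConfig, condition_id: str) -> list[Peak]:
    """One condition's peak track: gamma-signal background plus planted clusters.

    Planted peaks are evenly spaced inside their cluster (pairwise gaps well
    under the stitch distance) with signal multiplied by se_signal_multiplier.
    All peaks avoid TSS +/- 2.5 kb so the planted clusters survive the
    exclusion filter.
    """
    if condition_id not in config.conditions:
        raise ValueError(f"unknown condition {condition_id!r}; config has {config.conditions}")
    cond_idx = config.conditions.index(condition_id)
    rng = _rng(config, 10 + cond_idx)
    tss = gen_annotation(config)
    tss_by_chrom = {c: sub["pos"].to_numpy() for c, sub in tss.groupby("chrom")}
    layout = planted_layout(config)

    peaks: list[Peak] = []
    # planted clusters for this condition
    mine = [c for c in layout if c["kind"] == "shared" or cond_idx == 0]
    for cluster in mine:
        k = config.peaks_per_cluster
        slot = config.cluster_span / k
        for i in range(k):
            width = int(rng.integers(800, 1200))
            jitter = int(rng.integers(0, max(1, int(slot) - width)))
            start = cluster["start"] + int(i * slot) + jitter
            end = min(start + width, cluster["end"])
            signal = float(
                rng.gamma(config.background_signal_shape, config.background_signal_scale)
                * config.se_signal_multiplier
            )
            peaks.append(Peak(cluster["chrom"], start, end, signal,
                              name=f"{condition_id}_{cluster['name']}_p{i}"))

    # background peaks
    lengths = np.array([config.chrom_length] * len(config.chromosomes), dtype=float)
    probs = lengths / lengths.sum()
    for i in range(config.n_peaks_per_condition):
        for _ in range(50):
            chrom = str(rng.choice(config.chromosomes, p=probs))
            width = int(rng.integers(600, 1400))
            start = int(rng.integers(0, config.chrom_length - width))
            sites = tss_by_chrom.get(chrom, np.empty(0))
            if _avoids_tss(start, start + width, sites, DEFAULT_TSS_WINDOW):
                signal = float(
                    rng.gamma(config.background_signal_shape, config.background_signal_scale)
                )
                peaks.append(Peak(chrom, start, start + width, signal,
                                  name=f"{condition_id}_bg{i:04d}"))
                break
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return peaks


def gen_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Unphased 0/1/2 calls for the population pool, organised in LD blocks.

    The first block sits inside the first autosomal target-specific planted SE
    cluster and its leftmost variant is the designated causal variant at
    ``causal_maf``.  ``meta`` records the causal id and its pre-missingness
    dosage (used by the phenotype and expression generators).
    """
    rng = _rng(config, 3)
    layout = planted_layout(config)
    specific = [c for c in layout if c["kind"] == "specific"]
    if not specific:
        raise ValueError("causal variant needs at least one autosomal specific SE cluster")
    causal_cluster = specific[0]

    n_pool = config.n_pool
    n_blocks = math.ceil(config.n_variants / config.block_size)
    c = math.sqrt(config.within_block_r2)  # haplotype copy probability

    records: list[dict] = []
    hap_rows: list[np.ndarray] = []
    causal_key: tuple[str, int] | None = None
    causal_geno: np.ndarray | None = None
    remaining = config.n_variants
    for b in range(n_blocks):
        bsize = min(config.block_size, remaining)
        remaining -= bsize
        if b == 0:
            p = config.causal_maf
            chrom = causal_cluster["chrom"]
            # stay inside the central 3/4 of the cluster so every block variant
            # falls within the stitched SE footprint (whose edges depend on the
            # jittered first/last peak positions)
            span = config.cluster_span
            spacing = max(200, (3 * span // 4) // max(bsize, 1))
            start = causal_cluster["start"] + span // 8
            pos = [start + i * spacing for i in range(bsize)]
            if pos[-1] >= causal_cluster["end"]:
                raise ValueError(
                    "causal LD block does not fit inside the planted SE cluster; "
                    "reduce block_size or enlarge cluster_span"
                )
        else:
            p = float(rng.uniform(0.1, 0.45))
            chrom = str(rng.choice(config.autosomes))
            start = int(rng.integers(0, config.chrom_length - 1000 * (bsize + 1)))
            pos = [start + i * 1000 for i in range(bsize)]

        prev = None
        for k in range(bsize):
            if prev is None:
                h = (rng.random((n_pool, 2)) < p).astype(np.int8)
            else:
                copy = rng.random((n_pool, 2)) < c
                fresh = (rng.random((n_pool, 2)) < p).astype(np.int8)
                h = np.where(copy, prev, fresh)
            prev = h
            geno = h.sum(axis=1).astype(np.int8)
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            records.append({"chrom": chrom, "pos": int(pos[k]), "ref": str(ref),
                            "alt": str(alt), "block": b, "block_index": k})
            hap_rows.append(geno)
            if b == 0 and k == 0:
                causal_key = (chrom, int(pos[k]))
                causal_geno = geno.copy()

    variants = pd.DataFrame(records)
    calls = np.vstack(hap_rows)
    # sort variants genomically and assign ids
    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
    variants = variants.iloc[order].reset_index(drop=True)
    calls = calls[order]
    variants.insert(0, "id", [f"snp{i:05d}" for i in range(len(variants))])

    # missingness after the truth snapshot
    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls = np.where(miss, np.int8(-1), calls)

    causal_row = variants[(variants["chrom"] == causal_key[0]) & (variants["pos"] == causal_key[1])]
    causal_id = str(causal_row["id"].iloc[0])
    samples = [f"s{i:06d}" for i in range(n_pool)]
    meta = {
        "causal_id": causal_id,
        "causal_chrom": causal_key[0],
        "causal_pos": causal_key[1],
        "causal_dosage": causal_geno,
        "causal_cluster": dict(causal_cluster),
    }
    return GenotypeMatrix(samples, variants[["id", "chrom", "pos", "ref", "alt"]], calls, meta)


# case-only clinicopathologic levels and sampling probabilities
_GLEASON = (["<7", "7", ">7"], [0.35, 0.45, 0.20])
_PSA = (["<10", "10-20", ">20"], [0.55, 0.30, 0.15])
_STAGE = (["I/II", "III/IV"], [0.75, 0.25])


def gen_phenotypes(genotypes: GenotypeMatrix, config: SimConfig) -> pd.DataFrame:
    """Case/control status and covariates by rejection sampling over the pool.

    Each pool sample gets covariates and a Bernoulli status from
    logit P(case) = baseline + log(causal_or) * dosage + covariate terms
    (continuous covariates centered); samples are accepted in pool order until
    the requested n_cases and n_controls are both reached.  Raises when the
    pool cannot supply the requested counts.  Cases additionally receive
    clinicopathologic subgroup labels (gleason, psa_group, stage).
    """
    if "causal_dosage" not in genotypes.meta:
        raise ValueError("genotype matrix lacks a designated causal variant")
    rng = _rng(config, 4)
    n = genotypes.n_samples
    dose = np.asarray(genotypes.meta["causal_dosage"], dtype=float)
    eff = config.covariate_effects

    age = rng.normal(65.0, 7.0, size=n)
    bmi = rng.normal(27.5, 4.5, size=n)
    smoking = rng.choice(["never", "ever", "current"], size=n, p=[0.45, 0.43, 0.12])
    famhist = (rng.random(n) < 0.08).astype(int)

    eta = (
        config.baseline_prevalence_logit
        + math.log(config.causal_or) * dose
        + eff.age * (age - 65.0)
        + eff.bmi * (bmi - 27.5)
        + eff.smoking_ever * (smoking == "ever")
        + eff.smoking_current * (smoking == "current")
        + eff.family_history * famhist
    )
    status = rng.random(n) < expit(eta)

    case_idx = np.flatnonzero(status)[: config.n_cases]
    control_idx = np.flatnonzero(~status)[: config.n_controls]
    if len(case_idx) < config.n_cases or len(control_idx) < config.n_controls:
        raise ValueError(
            f"pool of {n} exhausted before reaching {config.n_cases} cases / "
            f"{config.n_controls} controls (got {len(case_idx)}/{len(control_idx)}); "
            "adjust baseline_prevalence_logit or pool_factor"
        )
    keep = np.sort(np.concatenate([case_idx, control_idx]))
    is_case = status[keep]

    n_kept = len(keep)
    gleason = np.where(is_case, rng.choice(_GLEASON[0], size=n_kept, p=_GLEASON[1]), None)
    psa = np.where(is_case, rng.choice(_PSA[0], size=n_kept, p=_PSA[1]), None)
    stage = np.where(is_case, rng.choice(_STAGE[0], size=n_kept, p=_STAGE[1]), None)

    return pd.DataFrame(
        {
            "sample": [genotypes.samples[i] for i in keep],
            "status": np.where(is_case, "case", "control"),
            "age": age[keep],
            "bmi": bmi[keep],
            "smoking": smoking[keep],
            "family_history": famhist[keep],
            "gleason": gleason,
            "psa_group": psa,
            "stage": stage,
        }
    )


def gen_expression(genotypes: GenotypeMatrix, config: SimConfig) -> ExpressionMatrix:
    """log2 expression for a genotype-linked cohort with tumor/normal labels.

    Mirrors the four-candidate situation at a risk locus: gene 0 carries both
    the eQTL dose effect and the tumor shift (the true target), gene 1 the
    eQTL only, gene 2 the tumor shift only, and any further genes are null.
    Gene TSSs lie within the cis window of the causal variant.
    """
    if "causal_dosage" not in genotypes.meta:
        raise ValueError("genotype matrix lacks a designated causal variant")
    rng = _rng(config, 5)
    n_expr = min(config.n_expr_samples, genotypes.n_samples)
    samples = genotypes.samples[:n_expr]
    dose = np.asarray(genotypes.meta["causal_dosage"], dtype=float)[:n_expr]
    condition = np.where(rng.random(n_expr) < 0.5, "tumor", "normal").astype(object)
    is_tumor = condition == "tumor"

    roles = ["target", "eqtl_only", "de_only"] + ["null"] * max(0, config.n_genes - 3)
    roles = roles[: config.n_genes]
    chrom = genotypes.meta["causal_chrom"]
    cpos = genotypes.meta["causal_pos"]
    offsets = rng.integers(-800_000, 800_000, size=config.n_genes)
    genes = pd.DataFrame(
        {
            "gene": [f"gene{i:02d}" for i in range(config.n_genes)],
            "chrom": chrom,
            "tss": np.maximum(0, cpos + offsets),
            "role": roles,
        }
    )
    baseline = rng.uniform(2.0, 8.0, size=config.n_genes)
    values = np.empty((config.n_genes, n_expr))
    for g, role in enumerate(roles):
        mu = np.full(n_expr, baseline[g])
        if role in ("target", "eqtl_only"):
            mu = mu + config.eqtl_beta * dose
        if role in ("target", "de_only"):
            mu = mu + config.tumor_shift * is_tumor
        values[g] = mu + rng.normal(0.0, config.noise_sd, size=n_expr) if config.noise_sd > 0 else mu
    return ExpressionMatrix(
        genes=genes, samples=list(samples), values=values, condition=condition,
        meta={"target_gene": "gene00" if roles and roles[0] == "target" else None},
    )


def ground_truth(config: SimConfig) -> dict:
    """Planted structure as a JSON-serialisable dict (no genotype data)."""
    layout = planted_layout(config)
    gm = gen_genotypes(config)
    return {
        "clusters": [dict(c) for c in layout],
        "expected_specific_ses": [dict(c) for c in layout if c["kind"] == "specific"],
        "causal": {
            "id": gm.meta["causal_id"],
            "chrom": gm.meta["causal_chrom"],
            "pos": gm.meta["causal_pos"],
            "maf": config.causal_maf,
            "or": config.causal_or,
        },
        "target_gene": "gene00",
        "parameters": {
            "eqtl_beta": config.eqtl_beta,
            "tumor_shift": config.tumor_shift,
            "within_block_r2": config.within_block_r2,
            "seed": config.seed,
        },
    }


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
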