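"""Target-gene nomination by eQTL / tumor-expression directional concordance.

A candidate gene near the focal risk variant is nominated when (a) its
expression associates with the risk-allele dosage (cis-eQTL, OLS on log2
expression), (b) it is differentially expressed between tumor and normal
samples, and (c) the two effects point the same way: the allele that raises
disease odds shifts expression in the same direction as the tumor-vs-normal
difference.  This mirrors the decision rule used to single out one target
gene among several eQTL candidates at a risk locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_EQTL_WINDOW = 1_000_000
EXACT_MW_MAX_GROUP = 8  # exact Mann-Whitney when min group size <= this and no ties


@dataclass
class ExpressionMatrix:
    """log2-scale expression values for genes x samples with tumor/normal labels.

    ``genes`` is a DataFrame with columns gene, chrom, tss (bp, 0-based);
    ``condition`` holds 'tumor'/'normal' per sample.
    """

    genes: pd.DataFrame
    samples: list[str]
    values: np.ndarray
    condition: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} != ({len(self.genes)}, {len(self.samples)})"
            )
        if len(self.condition) != len(self.samples):
            raise ValueError("condition labels must match samples")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")
        bad = set(self.condition) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"conditions must be tumor/normal, got {sorted(bad)}")

    def gene_values(self, gene: str) -> np.ndarray:
        idx = self.genes.index[self.genes["gene"] == gene]
        if len(idx) == 0:
            raise KeyError(f"unknown gene {gene!r}")
        return self.values[int(idx[0])]


def eqtl_scan(
    dosage: pd.Series,
    expression: ExpressionMatrix,
    focal_chrom: str,
    focal_pos: int,
    window: int = DEFAULT_EQTL_WINDOW,
) -> pd.DataFrame:
    """Cis-eQTL scan: OLS of log2 expression on risk-allele dosage per gene.

    ``dosage`` is indexed by sample name (missing calls NaN).  Only genes whose
    TSS lies within +/- ``window`` of the focal variant on its chromosome are
    tested; only samples with both genotype and expression enter.  Genes with
    zero expression variance among the used samples are skipped with a warning.
    """
    common = [s for s in expression.samples if s in dosage.index]
    if not common:
        raise ValueError("no samples shared between genotypes and expression")
    col = {s: i for i, s in enumerate(expression.samples)}
    cols = np.array([col[s] for s in common])
    d = dosage.loc[common].to_numpy(dtype=float)

    in_cis = expression.genes[
        (expression.genes["chrom"] == focal_chrom)
        & (np.abs(expression.genes["tss"] - focal_pos) <= window)
    ]
    rows = []
    for gi, gene in zip(in_cis.index, in_cis["gene"]):
        yv = expression.values[gi, cols]
        use = np.isfinite(d)
        x, yy = d[use], yv[use]
        if len(x) < 3 or np.ptp(x) == 0:
            logger.warning("eqtl_scan: %s skipped (insufficient dosage variation)", gene)
            continue
        if np.ptp(yy) == 0:
            logger.warning("eqtl_scan: %s skipped (zero expression variance)", gene)
            continue
        fit = stats.linregress(x, yy)
        rows.append(
            {"gene": gene, "beta": float(fit.slope), "se": float(fit.stderr),
             "p": float(fit.pvalue), "n": int(len(x))}
        )
    return pd.DataFrame(rows, columns=["gene", "beta", "se", "p", "n"])


def differential_expression(expression: ExpressionMatrix, method: str = "mannwhitney") -> pd.DataFrame:
    """Per-gene tumor-vs-normal test on the log2 scale.

    method 'mannwhitney' uses the exact two-sided Mann-Whitney U when the
    smaller group has at most 8 samples and the pooled values are tie-free,
    falling back to the tie-corrected normal approximation; 'ttest' is the
    two-sided two-sample t-test.  log2fc is mean(tumor) - mean(normal).
    """
    is_tumor = expression.condition == "tumor"
    n_t, n_n = int(is_tumor.sum()), int((~is_tumor).sum())
    if n_t < 2 or n_n < 2:
        raise ValueError(f"need >= 2 samples per condition, got tumor={n_t} normal={n_n}")
    rows = []
    for gi, gene in zip(expression.genes.index, expression.genes["gene"]):
        tum = expression.values[gi, is_tumor]
        nor = expression.values[gi, ~is_tumor]
        log2fc = float(tum.mean() - nor.mean())
        if method == "mannwhitney":
            pooled = np.concatenate([tum, nor])
            exact = min(n_t, n_n) <= EXACT_MW_MAX_GROUP and len(np.unique(pooled)) == len(pooled)
            res = stats.mannwhitneyu(
                tum, nor, alternative="two-sided",
                method="exact" if exact else "asymptotic",
            )
            stat, p = float(res.statistic), float(res.pvalue)
        elif method == "ttest":
            res = stats.ttest_ind(tum, nor)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            raise ValueError(f"unknown method {method!r}; choose 'mannwhitney' or 'ttest'")
        rows.append({"gene": gene, "stat": stat, "p": p, "log2fc": log2fc})
    return pd.DataFrame(rows, columns=["gene", "stat", "p", "log2fc"])


def concordance_filter(
    eqtl: pd.DataFrame,
    de: pd.DataFrame,
    alpha_eqtl: float = 0.05,
    alpha_de: float = 0.05,
) -> pd.DataFrame:
    """Directional-concordance verdict per gene, sorted by eQTL p-value.

    A gene is concordant iff its eQTL p < alpha_eqtl, its tumor/normal p <
    alpha_de, and sign(eqtl beta) == sign(log2fc), with the eQTL beta oriented
    to the risk allele.  All genes present in both inputs are reported.
    """
    merged = eqtl.merge(
        de.rename(columns={"stat": "de_stat", "p": "de_p"}), on="gene", how="inner"
    ).rename(columns={"beta": "eqtl_beta", "p": "eqtl_p", "se": "eqtl_se"})
    sig = (merged["eqtl_p"] < alpha_eqtl) & (merged["de_p"] < alpha_de)
    same_sign = np.sign(merged["eqtl_beta"]) == np.sign(merged["log2fc"])
    nonzero = (merged["eqtl_beta"] != 0) & (merged["log2fc"] != 0)
    merged["concordant"] = (sig & same_sign & nonzero).to_numpy()
    return merged.sort_values("eqtl_p", kind="stable").reset_index(drop=True)
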