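"""Per-variant QC: MAF, call rate, exact Hardy-Weinberg test, and SE intersection.

Filters follow standard case-control GWAS practice: MAF >= 0.05 (inclusive),
exact-HWE p >= 1e-6 (inclusive), call rate > 0.95 (strict).  The HWE test is
the exact conditional test on heterozygote counts given the allele counts
(tail sum of configuration probabilities <= the observed one, no mid-p), by
default computed in controls only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

MISSING = -1

DEFAULT_THRESHOLDS = {"maf_min": 0.05, "hwe_min": 1e-6, "call_rate_min": 0.95}


@dataclass
class GenotypeMatrix:
    """Unphased diploid hard calls: 0/1/2 alt-allele counts, -1 for missing.

    ``variants`` is a DataFrame with columns id, chrom, pos (0-based), ref, alt;
    ``calls`` has shape (n_variants, n_samples).  ``meta`` carries generator
    annotations (e.g. the planted causal variant) and is not interpreted here.
    """

    samples: list[str]
    variants: pd.DataFrame
    calls: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} != (n_variants={len(self.variants)}, "
                f"n_samples={len(self.samples)})"
            )
        if self.variants["id"].duplicated().any():
            dups = self.variants.loc[self.variants["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate variant ids: {dups[:5]}")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("calls must be in {0, 1, 2, -1}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, names: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[n] for n in names], dtype=int)

    def subset_samples(self, names: list[str]) -> "GenotypeMatrix":
        idx = self.sample_index(names)
        meta = dict(self.meta)
        if "causal_dosage" in meta:
            meta["causal_dosage"] = np.asarray(meta["causal_dosage"])[idx]
        return GenotypeMatrix(list(names), self.variants.copy(), self.calls[:, idx], meta)

    def subset_variants(self, ids: list[str]) -> "GenotypeMatrix":
        order = {v: i for i, v in enumerate(self.variants["id"])}
        idx = np.array([order[i] for i in ids], dtype=int)
        return GenotypeMatrix(
            list(self.samples),
            self.variants.iloc[idx].reset_index(drop=True),
            self.calls[idx, :],
            dict(self.meta),
        )

    def variant_calls(self, variant_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"unknown variant id {variant_id!r}")
        return self.calls[int(idx[0])]


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg p-value conditional on allele counts.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one (plain tail-sum, no mid-p).  Probabilities follow the
    conditional distribution P(het) proportional to
    2^het * N! / (n_hom_major! * het! * n_hom_minor!), computed by the stable
    ratio recurrence.
    """
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        raise ValueError("no genotypes")
    n_minor_alleles = 2 * min(n_hom1, n_hom2) + n_het
    if n_minor_alleles == 0:
        return 1.0

    # heterozygote count has the same parity as the minor allele count;
    # accumulate the P(het)/P(het-2) ratio recurrence in log space to avoid
    # overflow at large sample sizes
    het_values = np.arange(n_minor_alleles % 2, n_minor_alleles + 1, 2)
    logp = np.zeros(len(het_values), dtype=float)
    for k in range(1, len(het_values)):
        het = het_values[k]
        hom_min = (n_minor_alleles - het) // 2
        hom_maj = n - het - hom_min
        logp[k] = logp[k - 1] + np.log(4.0 * (hom_min + 1) * (hom_maj + 1)) - np.log(
            float(het) * (het - 1)
        )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[het_values == n_het]
    if len(p_obs) == 0:  # observed het count inconsistent with allele counts
        raise ValueError(
            f"heterozygote count {n_het} incompatible with {n_minor_alleles} minor alleles"
        )
    return float(min(1.0, probs[probs <= p_obs[0] * (1 + 1e-12)].sum()))


def qc_stats(genotypes: GenotypeMatrix, hwe_samples: list[str] | None = None) -> pd.DataFrame:
    """Per-variant MAF, call rate and exact-HWE p.

    MAF and call rate use all samples; the HWE test is restricted to
    ``hwe_samples`` when given (typically the controls).  A variant with no
    non-missing calls gets NaN stats and ``all_missing=True``.
    """
    calls = genotypes.calls
    called = calls != MISSING
    n_called = called.sum(axis=1)
    alt_counts = np.where(called, calls, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_called > 0, alt_counts / (2.0 * n_called), np.nan)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    call_rate = n_called / calls.shape[1]

    if hwe_samples is not None:
        hcalls = calls[:, genotypes.sample_index(hwe_samples)]
    else:
        hcalls = calls
    hwe_p = np.full(len(calls), np.nan)
    for i in range(len(calls)):
        g = hcalls[i][hcalls[i] != MISSING]
        if len(g) == 0:
            continue
        hwe_p[i] = hwe_exact_p(int((g == 1).sum()), int((g == 0).sum()), int((g == 2).sum()))

    out = genotypes.variants[["id", "chrom", "pos"]].copy()
    out["maf"] = maf
    out["call_rate"] = call_rate
    out["hwe_p"] = hwe_p
    out["n_called"] = n_called
    out["all_missing"] = n_called == 0
    return out


def filter_variants(stats: pd.DataFrame, thresholds: dict | None = None) -> tuple[list[str], dict[str, int]]:
    """Apply the MAF / HWE / call-rate filters.

    A variant is kept iff it passes all three; a removed variant is attributed
    to the first failing filter in the order (maf, hwe, call_rate) for the
    summary counts, with all-missing variants counted separately.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    kept: list[str] = []
    counts = {"input": len(stats), "all_missing": 0, "maf": 0, "hwe": 0, "call_rate": 0}
    for row in stats.itertuples():
        if row.all_missing:
            counts["all_missing"] += 1
        elif not row.maf >= th["maf_min"]:
            counts["maf"] += 1
        elif not row.hwe_p >= th["hwe_min"]:
            counts["hwe"] += 1
        elif not row.call_rate > th["call_rate_min"]:
            counts["call_rate"] += 1
        else:
            kept.append(row.id)
    counts["kept"] = len(kept)
    return kept, counts


def intersect_with_ses(variants: pd.DataFrame, ses) -> pd.DataFrame:
    """Assign variants (columns id, chrom, pos) to every SE containing them.

    SE intervals are half-open: a variant at SE.start is inside, at SE.end it
    is outside.  Variants contained in no SE are absent from the result (they
    are dropped from downstream association).
    """
    trees: dict[str, IntervalTree] = {}
    for k, e in enumerate(ses):
        if e.end > e.start:
            trees.setdefault(e.chrom, IntervalTree())[e.start:e.end] = k
    rows = []
    for row in variants.itertuples():
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for hit in sorted(tree[row.pos], key=lambda iv: iv.data):
            e = ses[hit.data]
            rows.append(
                {"id": row.id, "chrom": row.chrom, "pos": row.pos,
                 "se_index": hit.data, "se_start": e.start, "se_end": e.end}
            )
    return pd.DataFrame(rows, columns=["id", "chrom", "pos", "se_index", "se_start", "se_end"])
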