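"""Two-locus linkage disequilibrium from unphased genotypes, and tag-SNP clumping.

r-squared is computed from maximum-likelihood haplotype frequencies obtained by
EM over the double-heterozygote phase ambiguity (the PLINK-style estimator),
started at linkage equilibrium.  Clumping is the standard greedy procedure:
seed with the most significant unassigned variant (leftmost position when no
p-values are given), absorb every unassigned variant in LD at or above the
threshold with the seed, repeat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_qc import MISSING, GenotypeMatrix

EM_TOL = 1e-10
EM_MAX_ITER = 1000


@dataclass
class LDEstimate:
    """ML haplotype frequencies and derived LD statistics for one variant pair.

    ``hap_freqs`` is (f_rr, f_rA, f_Ar, f_AA) over (ref, alt) alleles at the
    two loci.  ``ok`` is False (and r2/d_prime NaN) when either locus is
    monomorphic among the complete pairs — r2 is undefined there, not zero.
    """

    r2: float
    d_prime: float
    hap_freqs: np.ndarray
    converged: bool
    n_used: int
    ok: bool = True
    loglik_trace: np.ndarray | None = None


def estimate_r2(gA: np.ndarray, gB: np.ndarray, keep_trace: bool = False) -> LDEstimate:
    """EM estimate of r^2 between two unphased genotype vectors.

    Samples with a missing call at either locus are dropped.  The EM iterates
    the cis fraction of double heterozygotes until the haplotype frequencies
    move by less than 1e-10 (max 1000 iterations).
    """
    gA = np.asarray(gA)
    gB = np.asarray(gB)
    if gA.shape != gB.shape:
        raise ValueError("genotype vectors must have equal length")
    use = (gA != MISSING) & (gB != MISSING)
    a, b = gA[use].astype(int), gB[use].astype(int)
    n = len(a)
    if n == 0:
        return LDEstimate(np.nan, np.nan, np.full(4, np.nan), False, 0, ok=False)

    # 3x3 genotype table
    tab = np.zeros((3, 3), dtype=float)
    np.add.at(tab, (a, b), 1.0)

    pA = a.sum() / (2.0 * n)  # alt frequency, locus A
    pB = b.sum() / (2.0 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return LDEstimate(np.nan, np.nan, np.full(4, np.nan), False, n, ok=False)

    # Known haplotype counts from unambiguous cells; the double-het cell
    # tab[1,1] splits between cis (rr + AA) and trans (rA + Ar) phases.
    # counts[j, k]: haplotype with allele j at A, allele k at B (0=ref, 1=alt)
    base = np.zeros((2, 2))
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            cnt = tab[i, j]
            if cnt == 0:
                continue
            # each diploid contributes two haplotypes with known phase
            ha = [0] * (2 - i) + [1] * i
            hb = [0] * (2 - j) + [1] * j
            for x, y in zip(ha, hb):
                base[x, y] += cnt
    ndh = tab[1, 1]

    # start at linkage equilibrium
    f = np.array([(1 - pA) * (1 - pB), (1 - pA) * pB, pA * (1 - pB), pA * pB])
    trace = []
    converged = False
    total = 2.0 * n
    for _ in range(EM_MAX_ITER):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        counts = base.copy().ravel()
        counts[0] += ndh * w
        counts[3] += ndh * w
        counts[1] += ndh * (1 - w)
        counts[2] += ndh * (1 - w)
        newf = counts / total
        if keep_trace:
            trace.append(_loglik(tab, newf))
        if np.max(np.abs(newf - f)) < EM_TOL:
            f = newf
            converged = True
            break
        f = newf

    pA_ml = f[2] + f[3]
    pB_ml = f[1] + f[3]
    d = f[3] - pA_ml * pB_ml
    denom = pA_ml * (1 - pA_ml) * pB_ml * (1 - pB_ml)
    r2 = float(d * d / denom) if denom > 0 else np.nan
    dmax = min(pA_ml * (1 - pB_ml), (1 - pA_ml) * pB_ml) if d > 0 else min(
        pA_ml * pB_ml, (1 - pA_ml) * (1 - pB_ml)
    )
    d_prime = float(abs(d) / dmax) if dmax > 0 else np.nan
    return LDEstimate(
        min(r2, 1.0),
        min(d_prime, 1.0) if np.isfinite(d_prime) else d_prime,
        f,
        converged,
        n,
        ok=True,
        loglik_trace=np.array(trace) if keep_trace else None,
    )


def _loglik(tab: np.ndarray, f: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3x3 genotype table under hap freqs f."""
    f = np.maximum(f, 1e-300)
    frr, frA, fAr, fAA = f
    # P(genotype pair) under random union of haplotypes
    probs = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            p = 0.0
            # sum over ordered haplotype pairs consistent with (i, j)
            for x1 in (0, 1):
                for y1 in (0, 1):
                    for x2 in (0, 1):
                        for y2 in (0, 1):
                            if x1 + x2 == i and y1 + y2 == j:
                                p += f[2 * x1 + y1] * f[2 * x2 + y2]
            probs[i, j] = p
    return float((tab * np.log(np.maximum(probs, 1e-300))).sum())


def r2_matrix(genotypes: GenotypeMatrix, ids: list[str] | None = None) -> pd.DataFrame:
    """Pairwise LD table (idA, idB, r2, d_prime, n) for the given variants."""
    if ids is None:
        ids = list(genotypes.variants["id"])
    rows = []
    calls = {v: genotypes.variant_calls(v) for v in ids}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            est = estimate_r2(calls[ids[i]], calls[ids[j]])
            rows.append(
                {"idA": ids[i], "idB": ids[j], "r2": est.r2, "d_prime": est.d_prime,
                 "n": est.n_used, "ok": est.ok}
            )
    return pd.DataFrame(rows, columns=["idA", "idB", "r2", "d_prime", "n", "ok"])


@dataclass
class Clump:
    tag: str
    members: list[str]  # includes the tag


def clump(
    variants: pd.DataFrame,
    ld: pd.DataFrame,
    pvalues: dict[str, float] | None = None,
    r2_threshold: float = 0.8,
) -> list[Clump]:
    """Greedy LD clumping.

    ``variants`` needs columns id and pos; ``ld`` is a pairwise table as from
    :func:`r2_matrix`.  Seeds are chosen by ascending p-value (ties and the
    no-p-value case fall back to ascending position); each seed absorbs every
    unassigned variant whose r2 with the seed is >= the threshold.  Membership
    is seed-relative, not transitive; every variant lands in exactly one clump.
    """
    lookup: dict[tuple[str, str], float] = {}
    for row in ld.itertuples():
        if row.ok and np.isfinite(row.r2):
            lookup[(row.idA, row.idB)] = row.r2
            lookup[(row.idB, row.idA)] = row.r2

    def seed_key(row):
        p = pvalues.get(row.id, np.inf) if pvalues else np.inf
        return (p, row.pos, row.id)

    order = sorted(variants.itertuples(), key=seed_key)
    unassigned = {row.id for row in order}
    clumps: list[Clump] = []
    for row in order:
        if row.id not in unassigned:
            continue
        unassigned.discard(row.id)
        members = [row.id]
        for other in sorted(unassigned):
            if lookup.get((row.id, other), -np.inf) >= r2_threshold:
                members.append(other)
        for m in members:
            unassigned.discard(m)
        clumps.append(Clump(tag=row.id, members=members))
    return clumps
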