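"""Independent brute-force oracles shared by the unit and acceptance tests.

Each oracle recomputes its quantity by direct enumeration or counting,
independently of the library's implementation path.
"""

import math
from itertools import combinations

import numpy as np
import pandas as pd


def hwe_enumeration_oracle(n_het, n_hom1, n_hom2):
    """Exact HWE tail by direct evaluation of every configuration's conditional
    probability from 2^het * N! / (n_AA! n_Aa! n_aa!)."""
    n = n_het + n_hom1 + n_hom2
    minor = 2 * min(n_hom1, n_hom2) + n_het
    if minor == 0:
        return 1.0
    weights = {}
    for het in range(minor % 2, minor + 1, 2):
        hom_min = (minor - het) // 2
        hom_maj = n - het - hom_min
        if hom_maj < 0:
            continue
        logw = (
            het * math.log(2)
            + math.lgamma(n + 1)
            - math.lgamma(hom_maj + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_min + 1)
        )
        weights[het] = math.exp(logw)
    total = sum(weights.values())
    p_obs = weights[n_het] / total
    return min(1.0, sum(w for w in weights.values() if w / total <= p_obs * (1 + 1e-12)) / total)


def counting_oracle_r2(gA, gB):
    """Haplotype r^2 by direct counting — valid only without double heterozygotes,
    where every diploid's phase is determined."""
    assert not np.any((gA == 1) & (gB == 1))
    counts = np.zeros(4)
    for a, b in zip(gA, gB):
        ha = [0] * (2 - a) + [1] * a
        hb = [0] * (2 - b) + [1] * b
        for x, y in zip(ha, hb):
            counts[2 * x + y] += 1
    f = counts / counts.sum()
    pA, pB = f[2] + f[3], f[1] + f[3]
    d = f[3] - pA * pB
    return d * d / (pA * (1 - pA) * pB * (1 - pB))


def mannwhitney_enumeration_p(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n1, m = len(x), len(x) * len(y)

    def u_stat(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_stat(range(n1))
    lo, hi = min(u_obs, m - u_obs), max(u_obs, m - u_obs)
    total = hits = 0
    for idx in combinations(range(len(pooled)), n1):
        u = u_stat(idx)
        total += 1
        if u <= lo + 1e-9 or u >= hi - 1e-9:
            hits += 1
    return hits / total


def expr_pair(values, n_tumor):
    """Single-gene ExpressionMatrix with the first n_tumor samples labelled tumor."""
    from sevariant.concordance import ExpressionMatrix

    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[1]
    return ExpressionMatrix(
        genes=pd.DataFrame({"gene": ["g0"], "chrom": "chr1", "tss": [1000]}),
        samples=[f"s{i}" for i in range(n)],
        values=values,
        condition=np.array(["tumor"] * n_tumor + ["normal"] * (n - n_tumor), dtype=object),
    )
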