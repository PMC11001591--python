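"""Variant QC (MAF / exact HWE / call rate) and LD tagging on synthetic genotypes.

QC follows the usual case-control inclusion rules: MAF >= 0.05, exact-HWE
p >= 1e-6 (computed in controls), call rate > 95%.  Surviving variants inside
the cancer-specific SEs are then clumped at r^2 >= 0.8, leaving one tag per
haplotype block.
"""

from sevariant import (
    SimConfig,
    clump,
    filter_variants,
    gen_genotypes,
    gen_phenotypes,
    qc_stats,
    r2_matrix,
)

cfg = SimConfig(seed=42)
gm_pool = gen_genotypes(cfg)
phen = gen_phenotypes(gm_pool, cfg)
gm = gm_pool.subset_samples(list(phen["sample"]))

controls = list(phen.loc[phen["status"] == "control", "sample"])
stats = qc_stats(gm, hwe_samples=controls)
kept, counts = filter_variants(stats)
print(f"QC: {counts['input']} variants -> {counts['kept']} pass "
      f"(removed: maf {counts['maf']}, hwe {counts['hwe']}, call rate {counts['call_rate']})")

# LD inside the causal variant's block: adjacent pairs sit near the configured
# within-block r^2, decaying with distance
block_ids = [v for v in kept
             if gm.variants.set_index("id").loc[v, "chrom"] == gm.meta["causal_chrom"]
             and abs(gm.variants.set_index("id").loc[v, "pos"] - gm.meta["causal_pos"]) < 50_000]
ld = r2_matrix(gm, block_ids)
print(f"\npairwise r^2 within the causal block ({len(block_ids)} variants):")
print(ld[["idA", "idB", "r2", "d_prime"]].round(3).to_string(index=False))

clumps = clump(gm.variants[gm.variants["id"].isin(block_ids)], ld, r2_threshold=0.8)
for c in clumps:
    print(f"clump tag {c.tag}: members {c.members}")
# One tag (the leftmost member, the planted causal variant) represents the
# whole block in the association scan.
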