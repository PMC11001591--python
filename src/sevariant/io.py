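"""Readers and writers for the plain-text formats the pipeline exchanges.

Peaks travel as 5-column BED (chrom, start, end, name, signal) or ENCODE
narrowPeak (signalValue column used); TSS as BED6; genotypes as minimal
VCF v4.2 with a GT-only FORMAT ("./." for missing); phenotypes and
expression as tab-separated tables.  BED/internal coordinates are 0-based
half-open; VCF POS is 1-based as the format requires.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .se_caller import Peak, SECallResult, StitchedEnhancer
from .variant_qc import MISSING, GenotypeMatrix


def write_peaks_bed(peaks: list[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name or '.'}\t{p.signal:.6g}\n")


def read_peaks(path) -> list[Peak]:
    """Read BED5 (signal in column 5) or narrowPeak (signalValue, column 7)."""
    peaks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) >= 10:  # narrowPeak
                signal = float(f[6])
            elif len(f) >= 5:
                signal = float(f[4])
            else:
                raise ValueError(f"{path}:{ln}: expected BED5 or narrowPeak, got {len(f)} columns")
            peaks.append(Peak(f[0], int(f[1]), int(f[2]), signal, name=f[3]))
    return peaks


def write_tss_bed(tss: pd.DataFrame, path) -> None:
    """TSS as BED6: the TSS point as a 1-bp interval, gene id as name."""
    with open(path, "w") as fh:
        for row in tss.itertuples():
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.gene_id}\t0\t{row.strand}\n")


def read_tss_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{ln}: expected >= 4 BED columns")
            rows.append({"chrom": f[0], "pos": int(f[1]),
                         "strand": f[5] if len(f) >= 6 else "+", "gene_id": f[3]})
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "gene_id"])


def write_se_calls_bed(result: SECallResult, path) -> None:
    """SE/TE calls as BED with signal, rank and class columns."""
    with open(path, "w") as fh:
        for e in result.ranked:
            cls = "SE" if e.total_signal > result.cutoff_signal else "TE"
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\tregion_r{e.rank}\t"
                     f"{e.total_signal:.6g}\t{e.rank}\t{cls}\n")


def read_se_bed(path) -> list[StitchedEnhancer]:
    """Read SE intervals written by :func:`write_se_calls_bed` (SE rows only)."""
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.strip().split("\t")
            if len(f) >= 7 and f[6] != "SE":
                continue
            if len(f) >= 5:
                out.append(StitchedEnhancer(f[0], int(f[1]), int(f[2]), [], float(f[4]),
                                            rank=int(f[5]) if len(f) >= 6 else 0))
    return out


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal VCF v4.2 with a GT-only FORMAT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = list(dict.fromkeys(genotypes.variants["chrom"]))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        for i, row in enumerate(genotypes.variants.itertuples()):
            gts = "\t".join(_GT_CODE[int(g)] for g in genotypes.calls[i])
            fh.write(f"{row.chrom}\t{row.pos + 1}\t{row.id}\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into hard calls; multiallelic records are rejected."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    rows = []
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    remap = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {v.CHROM}:{v.POS} ({v.ID}); split or filter it first"
            )
        records.append({"id": v.ID or f"{v.CHROM}:{v.POS}", "chrom": v.CHROM,
                        "pos": v.POS - 1, "ref": v.REF, "alt": v.ALT[0]})
        rows.append(remap[np.asarray(v.gt_types, dtype=int)])
    vcf.close()
    variants = pd.DataFrame(records, columns=["id", "chrom", "pos", "ref", "alt"])
    calls = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    return GenotypeMatrix(samples, variants, calls)


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str})


def write_expression(expression, gene_path, values_path, samples_path) -> None:
    """Expression as three TSVs: gene metadata, gene x sample values, sample labels."""
    expression.genes.to_csv(gene_path, sep="\t", index=False)
    df = pd.DataFrame(expression.values, index=expression.genes["gene"], columns=expression.samples)
    df.to_csv(values_path, sep="\t", index_label="gene")
    pd.DataFrame({"sample": expression.samples, "condition": expression.condition}).to_csv(
        samples_path, sep="\t", index=False
    )


def read_expression(gene_path, values_path, samples_path):
    from .concordance import ExpressionMatrix

    genes = pd.read_csv(gene_path, sep="\t")
    values = pd.read_csv(values_path, sep="\t", index_col="gene")
    labels = pd.read_csv(samples_path, sep="\t", dtype={"sample": str})
    values = values.loc[genes["gene"]]
    labels = labels.set_index("sample").loc[values.columns]
    return ExpressionMatrix(
        genes=genes, samples=list(values.columns), values=values.to_numpy(),
        condition=labels["condition"].to_numpy(dtype=object),
    )


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
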