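"""File I/O helpers: FASTA, TSV and minimal VCF.

All tabular interchange is tab-separated text.  Genotypes travel as a minimal
VCF (CHROM POS ID REF ALT QUAL FILTER INFO FORMAT + per-sample GT); reading
goes through :mod:`pysam`, writing is a small text emitter since the files
carry nothing beyond coordinates, alleles and diploid GT calls.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

WHEAT_CHROMS = tuple(f"{g}{s}" for g in range(1, 8) for s in "ABD")


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_vcf(variants: pd.DataFrame, genotypes: pd.DataFrame, path,
              contig_length: int = 900_000_000) -> None:
    """Write a minimal VCF.

    ``variants``: columns chrom, pos, snp_id, ref, alt (one row per site).
    ``genotypes``: germplasm x snp_id matrix of allele doses; 0 -> 0/0,
    1 -> 1/1, 0.5 -> 0/1, NaN -> ./. (inbred lines are homozygous, so the
    dose encodes the genotype completely).
    """
    path = Path(path)
    samples = list(genotypes.index)
    chroms = []
    for c in variants["chrom"]:
        if c not in chroms:
            chroms.append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=erfsalt\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c},length={contig_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        order = variants.sort_values(["chrom", "pos"], kind="stable")
        for _, row in order.iterrows():
            doses = genotypes[row["snp_id"]]
            calls = []
            for d in doses:
                if pd.isna(d):
                    calls.append("./.")
                elif d == 0:
                    calls.append("0/0")
                elif d == 1:
                    calls.append("1/1")
                else:
                    calls.append("0/1")
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{row['snp_id']}\t"
                     f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n")


def read_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a (plain-text) VCF into (variants, germplasm x snp dose matrix).

    Dose coding mirrors :func:`write_vcf`: hom-ref 0, hom-alt 1, het 0.5,
    missing NaN.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows, doses = [], []
    for rec in vf:
        rows.append({"chrom": rec.chrom, "pos": rec.pos, "snp_id": rec.id,
                     "ref": rec.ref, "alt": rec.alts[0] if rec.alts else "."})
        site = []
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                site.append(np.nan)
            else:
                site.append(sum(gt) / len(gt))
        doses.append(site)
    variants = pd.DataFrame(rows)
    matrix = pd.DataFrame(np.array(doses).T, index=samples,
                          columns=variants["snp_id"].tolist())
    return variants, matrix
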