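"""Candidate-gene SNP association and haplotype analysis.

SNPs within a gene's coding region plus 2000 bp upstream of the start codon
are extracted from a genotype VCF, annotated with gene-relative coordinates
(ATG adenine = +1, promoter positions negative, no position 0) and, for CDS
sites, a synonymous/missense call under the standard genetic code.

Association with the leaf salt injury index uses per-SNP ordinary least
squares of phenotype on allele dose with the top genotype principal
components as structure covariates; q-values are Benjamini-Hochberg across
all tested SNPs and a SNP is significant when -log10 q > 2 (q < 0.01).
Germplasms sharing the joint alleles at a gene's significant SNPs form a
haplotype; haplotypes are labelled Hap1, Hap2, ... by descending frequency
and compared phenotypically with Welch t tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from . import io as _io
from .expression import bh_fdr
from .family import GeneModel
from .phenostats import WelchResult, welch_t

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

REGIONS = ("promoter", "CDS", "UTR3", "intergenic")


@dataclass
class SnpRecord:
    """A SNP with gene-relative annotation.

    ``ref``/``alt`` are the VCF (forward genomic strand) alleles;
    ``ref_coding``/``alt_coding`` are strand-flipped onto the gene's coding
    strand.  ``gene_relative_pos`` is negative upstream of the ATG and +1 at
    its adenine.  ``coding_effect`` is synonymous/missense for CDS sites,
    otherwise NA.
    """

    snp_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str = ""
    region: str = "intergenic"
    gene_relative_pos: int = 0
    ref_coding: str = ""
    alt_coding: str = ""
    coding_effect: str = "NA"


@dataclass(frozen=True)
class AssociationResult:
    snp_id: str
    beta: float
    p: float
    q: float
    maf: float

    @property
    def neg_log10_q(self) -> float:
        return float(-np.log10(self.q)) if self.q > 0 else np.inf

    @property
    def significant(self) -> bool:
        return self.neg_log10_q > 2.0


@dataclass
class HaplotypeAssignment:
    """Germplasm -> haplotype labels at a gene's significant SNPs.

    ``table`` has one row per germplasm with its joint allele string and
    label; labels are ordered by descending frequency (ties broken by
    allele-string lexicographic order).  Germplasms with a missing allele
    land in the "NA" bucket.
    """

    gene_id: str
    snp_ids: list[str]
    table: pd.DataFrame
    labels: dict[str, str] = field(default_factory=dict)  # allele string -> HapN

    def frequency(self) -> pd.Series:
        counts = self.table.loc[self.table["haplotype"] != "NA", "haplotype"].value_counts()
        return counts / counts.sum()


def relative_position(gene: GeneModel, pos: int) -> int:
    """Gene-relative coordinate of a genomic position; +1 = A of ATG, no 0."""
    if gene.strand == "+":
        return pos - gene.start + 1 if pos >= gene.start else pos - gene.start
    return gene.end - pos + 1 if pos <= gene.end else gene.end - pos


def extract_gene_snps(vcf, gene: GeneModel, upstream_bp: int = 2000,
                      cds_len: int | None = None) -> list[SnpRecord]:
    """SNPs overlapping the gene body plus ``upstream_bp`` of promoter.

    ``vcf`` is a VCF path or a variants DataFrame (chrom, pos, snp_id, ref,
    alt).  The window is strand-oriented: upstream means 5' of the ATG on
    the coding strand.  ``cds_len`` bounds the CDS in gene-relative
    coordinates; without it the whole gene body counts as CDS (intronless,
    UTR-free model).
    """
    if not gene.strand:
        raise ValueError("gene strand required")
    if isinstance(vcf, (str, Path)):
        variants, _ = _io.read_vcf(vcf)
    else:
        variants = vcf
    if gene.strand == "+":
        lo, hi = gene.start - upstream_bp, gene.end
    else:
        lo, hi = gene.start, gene.end + upstream_bp
    gene_len = gene.end - gene.start + 1
    cds_end = gene_len if cds_len is None else cds_len
    out: list[SnpRecord] = []
    sel = variants[(variants["chrom"] == gene.chrom)
                   & (variants["pos"] >= lo) & (variants["pos"] <= hi)]
    for _, row in sel.iterrows():
        rel = relative_position(gene, int(row["pos"]))
        if rel < -upstream_bp:
            continue
        if -upstream_bp <= rel <= -1:
            region = "promoter"
        elif 1 <= rel <= cds_end:
            region = "CDS"
        elif cds_end < rel <= gene_len:
            region = "UTR3"
        else:
            region = "intergenic"
        ref, alt = str(row["ref"]), str(row["alt"])
        if gene.strand == "-":
            ref_c, alt_c = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
        else:
            ref_c, alt_c = ref, alt
        out.append(SnpRecord(snp_id=str(row["snp_id"]), chrom=gene.chrom,
                             pos=int(row["pos"]), ref=ref, alt=alt,
                             gene_id=gene.gene_id, region=region,
                             gene_relative_pos=rel,
                             ref_coding=ref_c, alt_coding=alt_c))
    out.sort(key=lambda s: s.gene_relative_pos)
    return out


def annotate_coding_effect(snp: SnpRecord, cds_sequence: str) -> str:
    """Synonymous or missense under the standard genetic code.

    The SNP must be a CDS site; its gene-relative position indexes into the
    coding-strand CDS, whose length must be a multiple of 3.
    """
    if snp.region != "CDS":
        raise ValueError(f"{snp.snp_id}: not a CDS SNP ({snp.region})")
    cds = cds_sequence.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    pos = snp.gene_relative_pos
    if not 1 <= pos <= len(cds):
        raise ValueError(f"{snp.snp_id}: position {pos} beyond CDS")
    codon_i = (pos - 1) // 3
    offset = (pos - 1) % 3
    codon = list(cds[codon_i * 3: codon_i * 3 + 3])
    ref_codon, alt_codon = codon.copy(), codon.copy()
    ref_codon[offset] = snp.ref_coding or snp.ref
    alt_codon[offset] = snp.alt_coding or snp.alt
    aa_ref = str(Seq("".join(ref_codon)).translate())
    aa_alt = str(Seq("".join(alt_codon)).translate())
    effect = "synonymous" if aa_ref == aa_alt else "missense"
    snp.coding_effect = effect
    return effect


def _ols_slope_test(y: np.ndarray, g: np.ndarray, covars: np.ndarray | None):
    """OLS of y on [1, g, covars]; returns (beta_g, two-sided p)."""
    n = y.size
    cols = [np.ones(n), g]
    if covars is not None and covars.size:
        cols.extend(covars.T)
    X = np.column_stack(cols)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - X.shape[1]
    if dof <= 0:
        raise ValueError("not enough observations for the model")
    sigma2 = resid @ resid / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    if se == 0:
        return float(beta[1]), 1.0
    t = beta[1] / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(beta[1]), float(p)


def genotype_pcs(genotypes: pd.DataFrame, n_pcs: int) -> np.ndarray:
    """Top principal components of the centered germplasm x SNP dose matrix."""
    if n_pcs <= 0:
        return np.zeros((len(genotypes), 0))
    G = genotypes.to_numpy(float)
    G = np.nan_to_num(G - np.nanmean(G, axis=0), nan=0.0)
    U, S, _ = np.linalg.svd(G, full_matrices=False)
    k = min(n_pcs, S.size)
    return U[:, :k] * S[:k]


def associate(genotypes: pd.DataFrame, phenotype: pd.Series, n_pcs: int = 3,
              maf_min: float = 0.05) -> list[AssociationResult]:
    """Per-SNP OLS association of phenotype on allele dose.

    ``genotypes``: germplasm x SNP dose matrix (0 hom-ref, 1 hom-alt, 0.5
    het).  SNPs with minor-allele frequency < ``maf_min`` are dropped (and
    logged); constant columns are skipped with a warning.  q is BH across
    all tested SNPs; significance is -log10 q > 2.
    """
    phenotype = phenotype.reindex(genotypes.index)
    if phenotype.isna().any():
        raise ValueError("missing phenotype values")
    y = phenotype.to_numpy(float)
    covars = genotype_pcs(genotypes, n_pcs)

    kept, mafs = [], {}
    for snp in genotypes.columns:
        freq = float(genotypes[snp].mean())
        maf = min(freq, 1.0 - freq)
        if maf < maf_min:
            logger.info("MAF filter: dropping %s (MAF=%.3f)", snp, maf)
            continue
        if genotypes[snp].nunique() < 2:
            warnings.warn(f"{snp}: constant genotype column, skipped", stacklevel=2)
            continue
        kept.append(snp)
        mafs[snp] = maf

    betas, pvals = [], []
    for snp in kept:
        beta, p = _ols_slope_test(y, genotypes[snp].to_numpy(float), covars)
        betas.append(beta)
        pvals.append(p)
    qvals = bh_fdr(pvals)
    return [AssociationResult(snp_id=s, beta=b, p=p, q=float(q), maf=mafs[s])
            for s, b, p, q in zip(kept, betas, pvals, qvals)]


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "snp_id": r.snp_id, "maf": r.maf, "beta": r.beta, "p": r.p, "q": r.q,
        "neg_log10_q": r.neg_log10_q, "significant": r.significant,
    } for r in results])


def build_haplotypes(genotypes: pd.DataFrame, snps: list[SnpRecord] | None = None,
                     gene_id: str = "") -> HaplotypeAssignment:
    """Haplotypes from joint alleles at a gene's significant SNPs.

    Columns of ``genotypes`` are the significant SNPs (ordered by position
    when ``snps`` metadata is given).  Allele strings use the actual bases
    when metadata is available, otherwise 0/1 characters; heterozygous dose
    0.5 becomes 'H'; any missing allele sends the germplasm to the "NA"
    bucket.
    """
    if genotypes.shape[1] == 0:
        raise ValueError("need >= 1 significant SNP")
    meta = {s.snp_id: s for s in snps or []}
    cols = list(genotypes.columns)
    if meta:
        cols.sort(key=lambda c: meta[c].pos if c in meta else 0)

    def allele_char(snp, dose):
        if pd.isna(dose):
            return None
        if dose == 0.5:
            return "H"
        if snp in meta:
            return meta[snp].ref if dose == 0 else meta[snp].alt
        return "0" if dose == 0 else "1"

    strings = {}
    for germ in genotypes.index:
        chars = [allele_char(c, genotypes.at[germ, c]) for c in cols]
        strings[germ] = None if any(ch is None for ch in chars) else "".join(chars)

    freq: dict[str, int] = {}
    for s in strings.values():
        if s is not None:
            freq[s] = freq.get(s, 0) + 1
    ranked = sorted(freq, key=lambda s: (-freq[s], s))
    labels = {s: f"Hap{i + 1}" for i, s in enumerate(ranked)}

    table = pd.DataFrame({
        "germplasm": list(strings),
        "allele_string": [s if s is not None else "" for s in strings.values()],
        "haplotype": [labels[s] if s is not None else "NA" for s in strings.values()],
    }).set_index("germplasm")
    return HaplotypeAssignment(gene_id=gene_id, snp_ids=cols, table=table,
                               labels=labels)


@dataclass(frozen=True)
class HaplotypePairTest:
    hap_a: str
    hap_b: str
    mean_a: float
    mean_b: float
    favorable: str
    welch: WelchResult


def haplotype_phenotype_test(assignment: HaplotypeAssignment,
                             phenotype: pd.Series,
                             min_size: int = 2) -> list[HaplotypePairTest]:
    """Welch t between every pair of haplotypes with >= ``min_size`` carriers.

    The lower-mean haplotype of each pair is flagged favorable (lower injury
    = better salt tolerance).  Singleton haplotypes are excluded with a
    warning.
    """
    hap = assignment.table["haplotype"]
    groups = {}
    for label in sorted(hap.unique()):
        if label == "NA":
            continue
        members = hap.index[hap == label]
        values = phenotype.reindex(members).dropna()
        if len(values) < min_size:
            warnings.warn(f"{label}: only {len(values)} carriers, excluded",
                          stacklevel=2)
            continue
        groups[label] = values.to_numpy(float)
    out = []
    labels = sorted(groups)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            res = welch_t(groups[a], groups[b])
            ma, mb = float(groups[a].mean()), float(groups[b].mean())
            out.append(HaplotypePairTest(hap_a=a, hap_b=b, mean_a=ma, mean_b=mb,
                                         favorable=a if ma < mb else b, welch=res))
    return out


def haplotype_frequency_by_group(assignment: HaplotypeAssignment,
                                 groups: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group haplotype frequencies (%) and pairwise group differences.

    Frequencies are 100*count/group_size rounded to 2 decimals; differences
    are percentage points, 2 decimals.  Empty groups are an error.
    """
    hap = assignment.table["haplotype"]
    groups = groups.reindex(hap.index)
    labels = [l for l in sorted(hap.unique()) if l != "NA"]
    freq_rows = []
    sizes = {}
    for gname, idx in groups.groupby(groups).groups.items():
        size = len(idx)
        if size == 0:
            raise ValueError(f"empty group {gname}")
        sizes[gname] = size
        row = {"group": gname, "n": size}
        for l in labels:
            row[l] = round(100.0 * (hap.loc[idx] == l).sum() / size, 2)
        freq_rows.append(row)
    if not freq_rows:
        raise ValueError("no groups")
    freq = pd.DataFrame(freq_rows).set_index("group")
    diff_rows = []
    gnames = list(freq.index)
    for i, a in enumerate(gnames):
        for b in gnames[i + 1:]:
            for l in labels:
                diff_rows.append({"group_a": a, "group_b": b, "haplotype": l,
                                  "difference_pp": round(freq.at[b, l] - freq.at[a, l], 2)})
    return freq, pd.DataFrame(diff_rows)
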