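# erfsalt

Candidate-gene genetics of salt tolerance in hexaploid wheat, built around
the AP2/ERF transcription-factor family: family mining from protein
sequences, salt-stress expression categorization, injury-index phenotype
scoring, SNP/haplotype association, KASP marker design, promoter
cis-element scanning and focal-gene co-expression — all exercised end to
end on synthetic panels with planted ground truth, so every stage of the
pipeline is testable without any external download.

It is written for breeders and quantitative geneticists who run
candidate-gene association studies on diversity panels (here, a
117-germplasm panel of 66 landraces and 51 modern cultivars), and for
anyone who wants a desk-scale, fully reproducible model of that workflow.

## The analysis

**Family mining.** ERF proteins are identified by their ~60-residue AP2
DNA-binding domain, detected with a bundled log-odds position profile.
Within the domain, residues at alignment columns 14 and 19 discriminate the
subfamilies: Ala14 + Asp19 → ERF (binds the GCC-box), Val14 + Glu19 → DREB
(binds the DRE element); the invariant Ala37 is recorded but never filters.
Genes on the same homoeologous group (1–7) are merged into one family
member across the A/B/D subgenomes by reciprocal-best-hit with ≥ 90 %
global identity; same-chromosome copies within 10 Mb are tandem
duplicates.  Members are numbered by chromosome group and physical
position (TaERF1, TaERF2, …), copies suffixed by subgenome (TaERF16-B) and
tandem index (TaERF5-B1, TaERF5-B2).

**Expression.**  FPKM = fragments / (mapped fragments in millions ×
transcript length in kb).  Each NaCl timepoint (1, 6, 24, 48 h; three
replicates) is contrasted against 0 h; a contrast is significant when
|log2FC| ≥ 1 and the Benjamini–Hochberg q ≤ 0.01.  Genes are classified as
not expressed (FPKM < 1 in all samples), unchanged, sustained up, sustained
down, or mixed.

**Phenotypes.**  Per-plant leaf damage levels 0–4 aggregate to the leaf
salt injury index

    LSI (%) = 100 × Σ k·n_k / (4N),   k = 0..4,

averaged over three scoring experiments.  Grain traits measured under
control (CK) and salt conditions give the relative salt injury rate
RSIR (%) = 100 × (X_CK − X_NaCl) / X_CK.  qPCR expression uses
ΔCT = CT(target) − CT(reference) and 2^−ΔCT.

**Association.**  SNPs in the coding region and 2000 bp upstream of the
ATG are annotated with gene-relative coordinates (+1 at the A of ATG, no
position 0) and synonymous/missense calls.  Each SNP's allele dose is
regressed on the phenotype by OLS with the top three genotype principal
components as structure covariates; q-values are BH across all SNPs and
significance means −log10 q > 2.  Germplasms sharing the joint alleles at
a gene's significant SNPs form haplotypes (Hap1, Hap2, … by descending
frequency), compared by Welch t tests; the lower-injury haplotype is
flagged favorable.

**Markers and targets.**  A KASP assay on a chosen SNP carries two
allele-specific primers (identical except the 3′ base, tailed with the
universal FAM/HEX sequences) plus a common reverse primer, bodies sized
18–25 nt into a 57–62 °C melting band.  Candidate targets of a focal
transcription factor are differentially expressed genes with a promoter
GCC-box (GCCGCC, either strand), expression above FPKM 1, and Pearson
r ≥ 0.9 with the focal profile, ranked by soft-threshold adjacency |r|^β.

## Worked example

```python
from erfsalt.simulate import SimConfig
from erfsalt.pipeline import run_pipeline

res = run_pipeline(SimConfig(seed=1))
print(res.mining.summary)
print(res.census.to_string(index=False))
```

```
{'n_members': 54, 'n_genes': 158, 'n_tandem_members': 15,
 'pct_tandem_members': 27.8, ...}
         class  count  pct
 not_expressed     10 18.5
     unchanged     19 35.2
  sustained_up     13 24.1
sustained_down      6 11.1
         mixed      6 11.1
```

The miner recovers the planted family exactly: 54 members over all 21
chromosomes, 15 of them (27.8 %) in tandem clusters of 2–4 copies.  The
expression census recovers 53/54 planted classes at the default noise
level (one mixed member read as sustained down here).

```python
print(res.association.set_index("snp_id").loc["Snp52"].round(4))
t = res.hap_lsi_tests[0]
print(t.hap_a, t.mean_a, t.hap_b, t.mean_b, t.favorable, t.welch.stars)
```

```
maf 0.4017  beta -14.2895  q 0.0  neg_log10_q 11.4615  significant True
Hap1 55.44  Hap2 41.35  favorable=Hap2  ****
```

All five SNPs of the focal gene (promoter −247; CDS 216 and 624, both
synonymous; 3′-UTR 1111 and 1254) pass −log10 q > 2 out of the 1763-SNP
panel; Hap2 carriers show a ~14-point lower injury index (Welch p < 1e−4)
and a lower thousand-grain-weight RSIR.  The KASP assay designed on the
promoter SNP

```
FAM:  GAAGGTGACCAAGTTCATGCTccaattacggtcaataccggaatcC
HEX:  GAAGGTCGGAGTCAACGGATTccaattacggtcaataccggaatcG
```

genotypes all 117 germplasms onto the correct channel, and the
co-expression step returns exactly the five planted tracker genes
(r ≥ 0.989), excluding the low-expression one (max FPKM < 1).

A command-line layer mirrors the library: `erfsalt simulate`, `mine`,
`express`, `pheno`, `assoc`, `kasp`, `motifs`, `coexpress`.

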