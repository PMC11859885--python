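# Methods

## Scope and design

The package models a candidate-gene association study of salt tolerance in
hexaploid wheat around the AP2/ERF family.  Because no proteome, genotype
panel or expression archive ships with the package, a first-class
synthetic-data generator (`erfsalt.simulate`) produces every input with the
statistical structure the analysis assumes, together with ground-truth
labels; the analysis modules are then validated by recovery of that truth.
What passing tests demonstrate is therefore internal correctness and
statistical behavior of the methods under the stated generating model —
not performance on any real proteome or panel.

## Domain detection

HMMER-style profile search is replaced by a 60-column log-odds PSSM over
the 20-letter amino-acid alphabet, built from a small synthetic seed
alignment (`_ap2_profile.py`) that encodes the canonical AP2 architecture
(YRG element, WLG motif, RAYD element).  Scores are log2 odds against a
uniform background with pseudocount 0.5; the detection threshold is 8 bits
(exposed as `score_threshold`).  A profile-sampled window scores roughly
+150 bits and unrelated sequence roughly −50 bits per window, so the
threshold sits in a wide margin and the screen's logic (not its exact
sensitivity on real proteomes) is what is reproduced.  Residues are read
at profile columns 14/19/37, the literature's numbering; classification
uses only 14 and 19 (Ala/Asp → ERF, Val/Glu → DREB, anything else OTHER),
and a non-Ala column 37 raises a flag without affecting the call.

## Family assembly

Pairwise protein identity is global unit-cost alignment (edlib's
Needleman–Wunsch edit distance), identity = 100·(1 − d/max(len)).  Members
merge by (i) cross-subgenome reciprocal best hit within a homoeologous
group at ≥ 90 % identity and (ii) same-chromosome copies within 10 Mb at
the same identity bar (tandem duplicates).  Tandem clusters chain
consecutive same-chromosome family genes whose start positions are within
10 Mb; single-linkage by default ("within 10 Mb" is pairwise-ambiguous; a
strict-pairwise mode is available).  Splice variants collapse to the
longest protein per gene before mining.  Naming: members numbered by
(group 1→7, minimum start), copies suffixed `-A/-B/-D`, tandem copies
`-B1, -B2, …`; ties on coordinates break by gene id.  A legacy dot style
(`TaERF15.3`) is emitted only in a compatibility mode.

## Expression analysis

FPKM follows the standard definition (fragments / (mapped millions × kb)).
Differential expression is a Welch t test on log2(FPKM+1) per contrast
(each later timepoint vs 0 h) with a pseudo-count of 1 in the fold change
and BH-FDR within each contrast; significance = |log2FC| ≥ 1 and q ≤ 0.01.
This deliberately replaces negative-binomial machinery: with three
replicates and the categorical census as the reproducible surface, a
simple, transparent test suffices, and the simulator's NB overdispersion
(size 20) checks that the census survives realistic counting noise.
"Sustained" classes are operationalized as: at least one significant
contrast, all significant contrasts sharing one sign; both signs → mixed;
no significant contrast → unchanged; FPKM < 1 everywhere → not expressed
(that rule precedes all others).  A member takes the class of its most
responsive copy (most significant contrasts), ties with conflicting
classes breaking toward mixed.

The census reports counts with one-decimal percentages.  The residual
"mixed" category is reported as the complement to 100 % of the other
rounded classes whenever it is populated, so a census sums to exactly
100.0 (e.g. 7 of 54 prints as 12.9, not 13.0); the other classes use
conventional rounding.

## Phenotype statistics

LSI aggregates per-plant damage levels 0–4 (0 = healthy, 4 = dead or
nearly) to 100·Σk·n_k/(4N), averaged over three scoring experiments.
RSIR is the percent trait loss under salt relative to control; negative
values (salt above control) are reported, never clipped.  ΔCT and 2^−ΔCT
follow the usual qPCR convention.  All group comparisons are two-sided
Welch t tests (sidedness is a package choice) with star codes at
0.05/0.01/0.001/0.0001.

## Association and haplotypes

Gene-relative SNP coordinates put +1 at the A of the ATG with no position
0; promoter positions are negative down to −2000; the CDS/3′-UTR boundary
comes from the annotated CDS length (genes are modeled intronless).  For
minus-strand genes alleles are complemented onto the coding strand before
codon effects are computed with the standard genetic code.

The association model is per-SNP OLS of phenotype on allele dose (inbred
coding 0/1; heterozygotes 0.5) with the top `n_pcs = 3` genotype principal
components as covariates — a desk-scale, fully specified structure
correction standing in for mixed-model machinery.  SNPs with MAF < 0.05
are dropped and logged.  q-values reuse the same BH implementation as the
expression module; significance is −log10 q > 2.  Haplotypes are the joint
allele strings over a gene's significant SNPs, labelled by descending
frequency (ties lexicographic), with any missing allele sending a
germplasm to an NA bucket.  The favorable haplotype of a pair is the one
with the lower phenotype mean (lower injury).

## KASP design and in-silico genotyping

Allele primers end exactly at the SNP base on the chosen strand and share
their body otherwise; the FAM tail `GAAGGTGACCAAGTTCATGCT` and HEX tail
`GAAGGTCGGAGTCAACGGATT` are literal constants defined once.  Body length
(18–25 nt) is chosen to put the estimated Tm inside [57, 62] °C — the
Wallace rule 2(A+T)+4(G+C) for ≤ 14 nt, otherwise 64.9 + 41·(GC−16.4)/len;
deterministic and dependency-free, adequate for ranking windows, not a
thermodynamic model.  The common primer sits on the opposite strand with
its binding site 50–120 bp from the SNP, same Tm band.  An infeasible
template raises an error carrying the best candidate.  In-silico
genotyping is exact-match logic: the common primer site must be present;
each channel lights when its allele body (3′ base included) matches the
template on either strand; both → BOTH, neither → FAIL.

## Promoter motifs

Promoters are given 5′→3′ on the coding strand, last base adjacent to the
ATG; a hit at 0-based index i in a length-L promoter is reported at
ATG-relative position i − L (so −L…−1).  GCC-box consensus is fixed to
GCCGCC and the ABRE core to ACGTG (both overridable); reverse complements
are scanned and reported as minus-strand hits.  N never matches.

## Co-expression

Profiles are log2(FPKM+1) then min-max scaled per gene.  The stated
min-max-then-log order is degenerate (log 0 at every row minimum), so the
package applies the transforms in the numerically sound order and
documents the deviation.  The soft power β is the smallest 1–20 whose
|r|^β connectivity distribution fits a power law (R² ≥ 0.8 over 10
occupancy bins) with a negative slope *and* mean connectivity ≥ 0.5 —
without the connectivity floor, high powers make independent-noise
profiles spuriously "scale-free" as k collapses toward zero; fallback is
the conventional β = 6 with a warning.  Candidate targets of the focal
factor must be DEGs, carry a promoter GCC-box, reach FPKM ≥ 1 in some
sample and correlate with the focal profile at signed r ≥ 0.9 (a
configurable stand-in for "consistent expression pattern"); full network
module detection (topological overlap, tree cutting) is out of scope since
the usable output is the focal neighbor list.  z-scores for heatmap export
use the population (1/n) standard deviation.

## The synthetic generator

Defaults are the emulated study conditions: 54 members over 7 homoeologous
groups × 3 subgenomes (triads with probability 0.6, duos 0.25, singletons
0.15), 15 members carrying one tandem cluster of 2–4 copies spanning
≤ 10 Mb, 25 DREB relatives and 40 domain-free decoys; a 0/1/6/24/48 h × 3
replicate expression design with member classes 10/19/13/5/7
(off/flat/up/down/mixed); and a 117-germplasm panel (66 landraces, 51
cultivars) with a 1763-SNP candidate-gene panel (5 focal + 1758
background).  Copies of a member share a base protein mutated at 2 % per
site outside the domain, keeping within-member identity ≈ 96 % against the
90 % merge bar.  Positional jitter moves a tandem cluster as a block so
planted spans stay within the window.

The focal gene sits on the minus strand of 2B with its ATG at 640,765,377,
so its five SNPs fall at gene-relative −247 (promoter), 216 and 624
(third-codon, synonymous by construction) and 1111/1254 (3′-UTR) — the
same geometry as the printed marker table, which also exercises the
strand-flip code path.  The five SNPs are in perfect linkage; Hap2
(alt alleles) is planted in exactly round(freq·n) germplasms per subgroup
(22/66 landraces = 33.33 %, 25/51 cultivars = 49.02 %), so realized
frequencies equal the configured ones; which germplasms carry it is
random.  Injury: germplasm mean LSI = 55 − 15·[Hap2] + N(0, noise_sd = 8),
discretized per plant as round(N(4·LSI/100, 0.8)) clipped to 0–4, 15
plants × 3 experiments.  Grain traits get control values around
TGW 45 g / GL 6.5 mm / GW 3.3 mm with Hap2 lowering RSIR by 6/3/0
percentage points respectively (the null GW trait checks that not
everything comes out significant).  Background SNP frequencies carry the
landrace/cultivar axis plus two hidden ancestry axes (frequency shifts
~N(0, 0.15)), giving the PC correction real structure to absorb; they are
independent of phenotype.  Fragment counts are negative binomial
(size 20) around class-specific FPKM mean profiles; `noise_sd = 0`
switches counts, library sizes and trait noise to their deterministic
means.  "Off" genes are count-capped so FPKM < 1 holds in every sample as
a hard invariant.  The co-expression pool plants five tracker genes
following the focal profile with promoter GCC-boxes (four using the
motif offsets of the real predicted targets), one low-expression tracker
(max FPKM < 1), GCC-box DEGs with non-tracking profiles, tracking DEGs
without the motif, and flat genes — one probe per filter.  Promoters are
scrubbed of unplanned motif occurrences so planted offsets round-trip
exactly, and the region flanking the focal promoter SNP is nudged
base-by-base until the default KASP design succeeds there (a random ~50 %
GC context misses the Tm band about half the time).

All randomness derives from `numpy.random.default_rng([seed, stage])`; a
fixed seed yields byte-identical outputs.

## Problem sizes and numerics

The shipped study conditions (158 family genes, 15 samples, 1763 SNPs ×
117 germplasms, ~70 co-expression targets) run end to end in a few seconds
per seed; recovery statistics in the test suite use 20 seeds.  Numerical
choices: BH with explicit monotonicity enforcement; zero-variance Welch
edge cases defined (identical constants → p 1, distinct constants → p 0 in
the DE test; both-constant groups are an error in the phenotype test);
OLS via least squares with pseudoinverse guard; tie-breaks are
deterministic everywhere (stable sorts, lexicographic gene ids).

## Known limitations

No read-level simulation, LD decay, recombination or field-environment
structure; genes are intronless; the Tm estimate is not nearest-neighbor
thermodynamics; the association model is OLS+PCs, not a kinship mixed
model; the DE test is not a dispersion-shrinking NB model; co-expression
stops at the focal neighbor list.  All thresholds above are package
defaults exposed through function arguments or `SimConfig`.
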