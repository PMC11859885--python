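"""Synthetic hexaploid-wheat data generator.

Generates every input the downstream analysis consumes, with the
statistical structure the analysis assumes, plus ground-truth labels that
score each stage:

* a 21-chromosome genome (homoeologous groups 1-7 x subgenomes A/B/D) with
  family members planted as homoeolog triads/duos/singletons, 2-4-copy
  tandem clusters spanning <= 10 Mb, DREB-type relatives and domain-free
  decoy proteins, and 2000-bp promoters with motifs planted at recorded
  ATG-relative offsets;
* a 5-timepoint (0/1/6/24/48 h NaCl) x 3-replicate expression experiment
  with members drawn from five response classes (negative-binomial
  fragment counts around class-specific FPKM means);
* a germplasm panel (default 117 = 66 landraces + 51 cultivars) carrying a
  two-haplotype focal gene: five fully linked SNPs whose minor haplotype
  (Hap2) lowers the leaf salt injury index by a configurable effect and
  reduces grain-trait RSIR, against a background of phenotype-independent
  SNPs with group-structured allele frequencies;
* a co-expression target set: tracker genes that follow the focal profile
  and carry promoter GCC-boxes, one low-expression tracker, and background
  genes that separate the GCC-box, DEG and expression-floor filters.

The focal gene is planted on the minus strand of chromosome 2B with its ATG
at 640,765,377 so that its five SNPs sit at gene-relative -247 (promoter),
216 and 624 (CDS, synonymous third-codon positions), and 1111 and 1254
(3'-UTR).  A fixed seed makes every output byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._ap2_profile import AA_ALPHABET, default_pssm, sample_domain
from . import expression as _expr
from . import markers as _markers
from .io import write_fasta, write_tsv, write_vcf

DNA = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

RESPONSE_CLASS_ORDER = ("not_expressed", "unchanged", "sustained_up",
                        "sustained_down", "mixed")

# FPKM means per class at timepoints 0/1/6/24/48 h
CLASS_FPKM_PROFILES = {
    "not_expressed": (0.2, 0.2, 0.2, 0.2, 0.2),
    "unchanged": (30.0, 30.0, 30.0, 30.0, 30.0),
    "sustained_up": (8.0, 40.0, 80.0, 120.0, 160.0),
    "sustained_down": (60.0, 25.0, 12.0, 8.0, 5.0),
    "mixed": (20.0, 160.0, 50.0, 4.0, 3.0),
}

# Focal gene geometry (minus strand of 2B; gene-relative +1 at the ATG).
FOCAL_CHROM = "2B"
FOCAL_ATG_POS = 640_765_377
FOCAL_PROTEIN_LEN = 260           # -> CDS of 783 bp incl. stop
FOCAL_UTR3_LEN = 577              # -> gene span 1360 bp, covers the UTR SNPs
# (snp_id, gene-relative pos, forward-strand ref, alt)
FOCAL_SNPS = (
    ("Snp35", 1254, "A", "T"),    # 3'-UTR
    ("Snp36", 1111, "C", "T"),    # 3'-UTR
    ("Snp40", 624, "T", "C"),     # CDS, third base of codon 208 (synonymous)
    ("Snp49", 216, "C", "A"),     # CDS, third base of codon 72 (synonymous)
    ("Snp52", -247, "C", "G"),    # promoter
)
FOCAL_ABRE_OFFSETS = (-494, -596, -1114, -1324, -1331, -1584)

# GCC-box plants for the five co-expression trackers + the low-expression one
TRACKER_GCC_OFFSETS = (
    ((-646, "-"), (-608, "+")),
    ((-1240, "+"),),
    ((-1685, "-"), (-804, "+")),
    ((-1671, "+"), (-1652, "+")),
    ((-500, "+"),),
)
LOW_TRACKER_GCC_OFFSETS = ((-900, "+"),)

_MOTIF_PATTERNS = {"GCCGCC": ("GCC-box", "+"), "GGCGGC": ("GCC-box", "-"),
                   "ACGTG": ("ABRE", "+"), "CACGT": ("ABRE", "-")}

_DEFAULT_TANDEM_SPEC = (
    (2, 3.0), (2, 4.0), (2, 5.0), (2, 6.0), (2, 7.0), (2, 8.0), (2, 3.5),
    (2, 5.5), (3, 6.0), (3, 8.0), (3, 9.0), (3, 7.0), (3, 5.0),
    (4, 8.0), (4, 9.5),
)

_DEFAULT_CLASS_COUNTS = {"not_expressed": 10, "unchanged": 19,
                         "sustained_up": 13, "sustained_down": 5, "mixed": 7}

# grain traits: (control mean, control sd, Hap1 RSIR mean %, RSIR sd,
#                haplotype effect on RSIR in percentage points)
GRAIN_TRAITS = {
    "TGW": (45.0, 2.0, 12.0, 3.0, 6.0),
    "GL": (6.5, 0.2, 8.0, 2.0, 3.0),
    "GW": (3.3, 0.1, 5.0, 2.0, 0.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic panel (defaults = the emulated design)."""

    seed: int = 0
    n_groups: int = 7
    subgenomes: tuple[str, ...] = ("A", "B", "D")
    n_members: int = 54
    tandem_cluster_spec: tuple[tuple[int, float], ...] = _DEFAULT_TANDEM_SPEC
    n_decoys: int = 40
    n_dreb: int = 25
    timepoints: tuple[float, ...] = (0, 1, 6, 24, 48)
    n_reps: int = 3
    n_germplasm: int = 117
    n_landrace: int = 66
    n_cultivar: int = 51
    focal_effect: float = 15.0          # mean LSI shift (pp) between haplotypes
    noise_sd: float = 8.0               # germplasm-level LSI sd; 0 = noiseless sim
    class_counts: tuple[tuple[str, int], ...] = tuple(_DEFAULT_CLASS_COUNTS.items())
    nb_size: float = 20.0               # NB dispersion of fragment counts
    library_millions: float = 20.0      # mapped fragments per sample (millions)
    plants_per_rep: int = 15            # plants scored per germplasm per experiment
    n_background_snps: int = 1758   # + 5 focal = the study's 1763 SNPs
    hap2_freq_landrace: float = 0.3333
    hap2_freq_cultivar: float = 0.4902
    base_lsi: float = 55.0
    chrom_length_bp: int = 780_000_000
    n_gcc_deg_background: int = 30
    n_nogcc_deg: int = 20
    n_flat_targets: int = 14

    def __post_init__(self):
        if self.n_landrace + self.n_cultivar != self.n_germplasm:
            raise ValueError("n_landrace + n_cultivar must equal n_germplasm")
        for size, span in self.tandem_cluster_spec:
            if not 2 <= size <= 4:
                raise ValueError(f"tandem cluster size {size} outside 2..4")
            if span > 10.0:
                raise ValueError(f"tandem cluster span {span} Mb exceeds 10 Mb")
        if len(self.tandem_cluster_spec) > self.n_members - 1:
            raise ValueError("more tandem clusters than available members")
        if not self.timepoints or 0 not in self.timepoints:
            raise ValueError("timepoints must include the 0 h baseline")
        if len(self.timepoints) > 5:
            raise ValueError("at most 5 timepoints supported by the class profiles")

    @property
    def class_count_map(self) -> dict[str, int]:
        return dict(self.class_counts)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_protein(rng, length: int) -> str:
    return "".join(np.array(list(AA_ALPHABET))[rng.integers(0, 20, size=length)])


def make_protein(rng, subfamilies=("ERF",), length: int = 280,
                 offsets=None) -> tuple[str, list[int]]:
    """Protein with one sampled AP2-type domain per entry of ``subfamilies``.

    Returns (sequence, 1-based domain starts).  Used internally and by tests
    that need multi-domain proteins.
    """
    L = default_pssm().length
    n = len(subfamilies)
    if offsets is None:
        gap = (length - n * L) // (n + 1)
        offsets = [gap * (i + 1) + L * i for i in range(n)]
    seq = list(_random_protein(rng, length))
    starts = []
    for off, sf in zip(offsets, subfamilies):
        seq[off:off + L] = sample_domain(rng, sf)
        starts.append(off + 1)
    return "".join(seq), starts


def _mutate_outside(rng, protein: str, domain_start: int, rate: float = 0.02) -> str:
    """Substitute residues outside the domain at the given per-site rate."""
    L = default_pssm().length
    seq = list(protein)
    lo, hi = domain_start - 1, domain_start - 1 + L
    for i in range(len(seq)):
        if lo <= i < hi:
            continue
        if rng.random() < rate:
            choices = [a for a in AA_ALPHABET if a != seq[i]]
            seq[i] = choices[rng.integers(0, len(choices))]
    return "".join(seq)


def _random_dna(rng, length: int) -> list[str]:
    return list(DNA[rng.integers(0, 4, size=length)])


def _scrub_motifs(seq: list[str], planted: set[tuple[int, str]],
                  protected: set[int], rng) -> list[str]:
    """Remove every motif occurrence that was not deliberately planted.

    ``planted`` holds (0-based index, pattern) pairs that must survive;
    ``protected`` holds positions that may never be mutated (e.g. a SNP
    site).  Mutations avoid creating new occurrences by re-scanning.
    """
    planted_ranges = set()
    for idx, pat in planted:
        planted_ranges.update(range(idx, idx + len(pat)))
    for _ in range(200):
        s = "".join(seq)
        dirty = []
        for pat in _MOTIF_PATTERNS:
            start = s.find(pat)
            while start != -1:
                if (start, pat) not in planted:
                    dirty.append((start, pat))
                start = s.find(pat, start + 1)
        if not dirty:
            return seq
        for start, pat in dirty:
            positions = [i for i in range(start, start + len(pat))
                         if i not in planted_ranges and i not in protected]
            if not positions:
                continue
            i = positions[rng.integers(0, len(positions))]
            choices = [b for b in "ACGT" if b != seq[i]]
            seq[i] = choices[rng.integers(0, len(choices))]
    raise RuntimeError("motif scrubbing did not converge")


def _make_promoter(rng, plants=(), snp_sites=(), length: int = 2000) -> tuple[str, list]:
    """Random promoter with motifs planted at ATG-relative offsets.

    ``plants``: (offset, strand, consensus) triples, offset of the 5'-most
    base, in [-length, -1].  ``snp_sites``: (offset, base) pairs forced after
    scrubbing.  Returns (sequence, motif ground truth as
    (motif_name, strand, offset) triples).
    """
    seq = _random_dna(rng, length)
    planted = set()
    truth = []
    for offset, strand, consensus in plants:
        pat = consensus if strand == "+" else consensus.translate(_COMPLEMENT)[::-1]
        idx = length + offset
        if idx < 0 or idx + len(pat) > length:
            raise ValueError(f"motif offset {offset} outside the promoter")
        seq[idx:idx + len(pat)] = list(pat)
        planted.add((idx, pat))
        name = _MOTIF_PATTERNS[pat][0] if pat in _MOTIF_PATTERNS else consensus
        truth.append((name, strand, offset))
    protected = set()
    for offset, base in snp_sites:
        idx = length + offset
        seq[idx] = base
        protected.add(idx)
    seq = _scrub_motifs(seq, planted, protected, rng)
    return "".join(seq), sorted(truth, key=lambda t: t[2])


def _creates_motif(seq: list[str], i: int) -> bool:
    """Would the base at position i complete a motif occurrence?"""
    lo = max(0, i - 5)
    window = "".join(seq[lo: i + 6])
    return any(pat in window for pat in _MOTIF_PATTERNS)


def _ensure_kasp_site(seq: list[str], idx: int, ref_fwd: str, alt_fwd: str,
                      protected: set[int], rng, flank: int = 100) -> list[str]:
    """Guarantee the promoter SNP at ``idx`` supports a KASP design.

    Primer bodies must reach the assay's Tm band, which a random ~50 % GC
    context misses roughly half the time; this nudges single bases in the
    primer-landing regions (never the SNP itself or a planted motif) until
    the default design succeeds, keeping the site motif-free.
    """
    lo = max(0, idx - flank - 45)
    candidates = [i for i in list(range(lo, idx - 45))
                  + list(range(idx + 1, idx + 26))
                  if 0 <= i < len(seq) and i not in protected]
    for _ in range(500):
        window = "".join(seq[idx - flank: idx + flank + 1])
        template = _markers.revcomp(window)   # forward strand of the minus-strand gene
        try:
            _markers.design_kasp(template, ref_fwd, alt_fwd, snp_index=flank)
            return seq
        except _markers.KaspDesignError:
            pass
        i = candidates[rng.integers(0, len(candidates))]
        old = seq[i]
        seq[i] = "ACGT"[rng.integers(0, 4)]
        if seq[i] == old or _creates_motif(seq, i):
            seq[i] = old
    raise RuntimeError("could not make the KASP site designable")


_CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"), "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"), "E": ("GAA", "GAG"), "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"), "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"), "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"), "M": ("ATG",),
    "N": ("AAT", "AAC"), "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"), "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"), "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",), "Y": ("TAT", "TAC"),
}


def _reverse_translate(rng, protein: str) -> str:
    codons = [_CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein]
    return "".join(codons) + "TAA"


# ---------------------------------------------------------------------------
# gen_genome
# ---------------------------------------------------------------------------

@dataclass
class GenomeSim:
    config: SimConfig
    annotation: pd.DataFrame
    proteins: dict[str, str]
    promoters: dict[str, str]
    members: list[dict]                   # member_idx, gene_ids, subgenomes, tandem
    gene_member: dict[str, int]
    gene_kind: dict[str, str]             # erf / dreb / decoy
    domain_truth: dict[str, tuple[int, str]]
    motif_truth: dict[str, list[tuple[str, str, int]]]
    focal_gene_id: str
    focal_member_idx: int
    focal_cds: str
    n_tandem_members: int


def gen_genome(config: SimConfig) -> GenomeSim:
    """Annotation + protein FASTA + promoter FASTA with ground truth."""
    rng = _rng(config, 1)
    n = config.n_members
    # contiguous split of members over homoeologous groups
    sizes = [n // config.n_groups + (1 if i < n % config.n_groups else 0)
             for i in range(config.n_groups)]
    member_group, slot_in_group = [], []
    for g, size in enumerate(sizes):
        for j in range(size):
            member_group.append(g + 1)
            slot_in_group.append(j)

    max_slots = max(sizes)
    spacing = (config.chrom_length_bp - 50e6) / max(max_slots, 1)

    place_focal_exact = (config.chrom_length_bp >= FOCAL_ATG_POS + 5_000_000
                         and "B" in config.subgenomes and n >= 2)
    focal_idx = 0
    if place_focal_exact:
        group2 = [i for i, g in enumerate(member_group) if g == 2]
        focal_idx = (min(group2, key=lambda i: abs(25e6 + slot_in_group[i] * spacing
                                                   - FOCAL_ATG_POS))
                     if group2 else 0)

    tandem_idx = [i for i in range(n) if i != focal_idx]
    tandem_members = list(rng.choice(tandem_idx, size=len(config.tandem_cluster_spec),
                                     replace=False)) if config.tandem_cluster_spec else []
    tandem_of = {int(m): spec for m, spec in zip(tandem_members, config.tandem_cluster_spec)}

    members, gene_member, gene_kind = [], {}, {}
    proteins, promoters = {}, {}
    domain_truth, motif_truth = {}, {}
    annotation_rows = []
    counter = 0
    focal_gene_id, focal_cds = "", ""

    for m in range(n):
        # which subgenomes carry a copy
        r = rng.random()
        k = 3 if r < 0.60 else (2 if r < 0.85 else 1)
        k = min(k, len(config.subgenomes))
        subs = sorted(rng.choice(list(config.subgenomes), size=k, replace=False))
        if m == focal_idx and place_focal_exact and "B" not in subs:
            subs = sorted(set(subs) | {"B"})

        length = (FOCAL_PROTEIN_LEN if m == focal_idx
                  else int(rng.integers(240, 320)))
        dom_off = 4 if m == focal_idx else int(rng.integers(20, length - 80))
        base_protein, (dstart,) = make_protein(rng, ("ERF",), length, offsets=[dom_off])
        if m == focal_idx:
            bp = list(base_protein)
            bp[71], bp[207] = "L", "P"  # codons 72/208 host the synonymous SNPs
            base_protein = "".join(bp)

        base_pos = 25e6 + slot_in_group[m] * spacing
        cluster_sub = None
        if m in tandem_of:
            cluster_sub = subs[int(rng.integers(0, len(subs)))]
        gene_ids = []
        for sub in subs:
            n_copies = tandem_of[m][0] if sub == cluster_sub else 1
            span_mb = tandem_of[m][1] if sub == cluster_sub else 0.0
            offsets_bp = [0.0]
            if n_copies > 1:
                gaps = rng.uniform(0.6e6, span_mb * 1e6 / (n_copies - 1),
                                   size=n_copies - 1)
                scale = min(1.0, span_mb * 1e6 / gaps.sum())
                offsets_bp += list(np.cumsum(gaps * scale))
            # one jitter per subgenome placement: tandem copies must move as a
            # block or their start-to-start span could breach the 10-Mb window
            sub_jitter = rng.uniform(-3e6, 3e6)
            for c in range(n_copies):
                counter += 1
                gid = f"SYNG{counter:04d}"
                protein = base_protein if c == 0 and sub == subs[0] else \
                    _mutate_outside(rng, base_protein, dstart)
                is_focal_copy = (m == focal_idx and sub == "B" and c == 0
                                 and place_focal_exact)
                if is_focal_copy:
                    cds = _reverse_translate(rng, protein)
                    cds = (cds[:213] + "CTG" + cds[216:621] + "CCA" + cds[624:])
                    focal_gene_id, focal_cds = gid, cds
                    strand = "-"
                    end = FOCAL_ATG_POS
                    start = end - (len(cds) + FOCAL_UTR3_LEN) + 1
                else:
                    strand = "+" if rng.random() < 0.5 else "-"
                    start = max(1, int(base_pos + sub_jitter + offsets_bp[c]))
                    end = start + len(protein) * 3 + 3 + 450 - 1
                chrom = f"{member_group[m] if not is_focal_copy else 2}{sub}"
                annotation_rows.append({
                    "gene_id": gid, "chrom": chrom, "start": int(start),
                    "end": int(end), "strand": strand, "subgenome": sub,
                    "cds_len": len(protein) * 3 + 3,
                })
                proteins[gid] = protein
                gene_member[gid] = m
                gene_kind[gid] = "erf"
                domain_truth[gid] = (dstart, "ERF")
                gene_ids.append(gid)
                if is_focal_copy:
                    snp_off, snp_ref, snp_alt = FOCAL_SNPS[-1][1:]
                    snp_sites = [(snp_off, snp_ref.translate(_COMPLEMENT))]
                    plants = [(off, "+", "ACGTG") for off in FOCAL_ABRE_OFFSETS]
                    prom, truth = _make_promoter(rng, plants, snp_sites)
                    snp_idx = len(prom) + snp_off
                    prom = "".join(_ensure_kasp_site(list(prom), snp_idx,
                                                     snp_ref, snp_alt,
                                                     {snp_idx}, rng))
                else:
                    prom, truth = _make_promoter(rng)
                promoters[gid] = prom
                motif_truth[gid] = truth
        members.append({"member_idx": m, "gene_ids": gene_ids, "subgenomes": subs,
                        "tandem": m in tandem_of})

    # DREB relatives and domain-free decoys
    for kind, count in (("dreb", config.n_dreb), ("decoy", config.n_decoys)):
        for _ in range(count):
            counter += 1
            gid = f"SYNG{counter:04d}"
            length = int(rng.integers(200, 320))
            if kind == "dreb":
                protein, (dstart,) = make_protein(
                    rng, ("DREB",), length, offsets=[int(rng.integers(20, length - 80))])
                domain_truth[gid] = (dstart, "DREB")
            else:
                protein = _random_protein(rng, length)
            chrom = (f"{rng.integers(1, config.n_groups + 1)}"
                     f"{config.subgenomes[rng.integers(0, len(config.subgenomes))]}")
            start = int(rng.uniform(1e6, config.chrom_length_bp - 1e6))
            annotation_rows.append({
                "gene_id": gid, "chrom": chrom, "start": start,
                "end": start + length * 3 + 3 + 450 - 1,
                "strand": "+" if rng.random() < 0.5 else "-",
                "subgenome": chrom[-1], "cds_len": length * 3 + 3,
            })
            proteins[gid] = protein
            gene_kind[gid] = kind

    annotation = pd.DataFrame(annotation_rows)
    if not focal_gene_id:  # tiny/degenerate configs: fall back to first ERF gene
        focal_gene_id = members[focal_idx]["gene_ids"][0]
        focal_cds = _reverse_translate(rng, proteins[focal_gene_id])
    return GenomeSim(config=config, annotation=annotation, proteins=proteins,
                     promoters=promoters, members=members, gene_member=gene_member,
                     gene_kind=gene_kind, domain_truth=domain_truth,
                     motif_truth=motif_truth, focal_gene_id=focal_gene_id,
                     focal_member_idx=focal_idx, focal_cds=focal_cds,
                     n_tandem_members=len(tandem_of))


# ---------------------------------------------------------------------------
# gen_expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSim:
    counts: pd.DataFrame
    fpkm: pd.DataFrame
    samples: pd.DataFrame
    mapped_millions: pd.Series
    lengths_kb: pd.Series
    member_class: dict[int, str]
    gene_class: dict[str, str]


def _nb_counts(rng, mean: np.ndarray, nb_size: float, deterministic: bool) -> np.ndarray:
    if deterministic:
        return np.round(mean)
    p = nb_size / (nb_size + np.maximum(mean, 1e-12))
    return rng.negative_binomial(nb_size, p).astype(float)


def gen_expression(genome: GenomeSim, config: SimConfig | None = None) -> ExpressionSim:
    """Fragment counts + FPKM for the planted family, with true classes."""
    config = config or genome.config
    if config.n_reps < 1:
        raise ValueError("timepoints without replicates: n_reps must be >= 1")
    counts_map = config.class_count_map
    if sum(counts_map.values()) != config.n_members:
        raise ValueError("class counts must sum to n_members")
    rng = _rng(config, 2)

    order = list(rng.permutation(config.n_members))
    classes = [cls for cls in RESPONSE_CLASS_ORDER for _ in range(counts_map.get(cls, 0))]
    member_class = {int(m): cls for m, cls in zip(order, classes)}
    # the focal member must be expressed and responsive: force sustained_up
    focal = genome.focal_member_idx
    if member_class.get(focal) != "sustained_up" and counts_map.get("sustained_up", 0):
        donor = next(m for m, c in member_class.items() if c == "sustained_up")
        member_class[donor], member_class[focal] = member_class[focal], "sustained_up"

    samples = pd.DataFrame([
        {"sample": f"T{t:g}h_R{r}", "timepoint_h": float(t), "rep": r}
        for t in config.timepoints for r in range(1, config.n_reps + 1)])
    deterministic = config.noise_sd == 0
    mm = pd.Series(
        config.library_millions if deterministic
        else np.maximum(1.0, config.library_millions
                        * (1 + 0.03 * rng.standard_normal(len(samples)))),
        index=samples["sample"], name="mapped_millions", dtype=float)

    erf_genes = [g for g, k in genome.gene_kind.items() if k == "erf"]
    ann = genome.annotation.set_index("gene_id")
    lengths_kb = pd.Series({g: (ann.at[g, "end"] - ann.at[g, "start"] + 1) / 1000.0
                            for g in erf_genes}, name="length_kb")

    nt = len(config.timepoints)
    scales = {m: (1.0 if member_class[m] == "not_expressed"
                  else float(rng.lognormal(0.0, 0.3))) for m in member_class}
    gene_class = {}
    rows = []
    for gid in erf_genes:
        m = genome.gene_member[gid]
        cls = member_class[m]
        gene_class[gid] = cls
        profile = np.array(CLASS_FPKM_PROFILES[cls][:nt]) * scales[m]
        mean_fpkm = np.repeat(profile, config.n_reps)
        mean_counts = mean_fpkm * mm.to_numpy() * lengths_kb[gid]
        c = _nb_counts(rng, mean_counts, config.nb_size, deterministic)
        if cls == "not_expressed":  # hard non-expression guarantee (FPKM < 1)
            c = np.minimum(c, np.floor(0.9 * mm.to_numpy() * lengths_kb[gid]))
        rows.append(c)
    counts = pd.DataFrame(np.array(rows), index=erf_genes, columns=samples["sample"])
    fpkm = _expr.fpkm_matrix(counts, mm, lengths_kb)
    return ExpressionSim(counts=counts, fpkm=fpkm, samples=samples,
                         mapped_millions=mm, lengths_kb=lengths_kb,
                         member_class=member_class, gene_class=gene_class)


# ---------------------------------------------------------------------------
# gen_population
# ---------------------------------------------------------------------------

@dataclass
class PopulationSim:
    germplasm: list[str]
    groups: pd.Series                   # landrace / cultivar
    haplotype: pd.Series                # 1 or 2 (Hap2 = alt alleles, salt-tolerant)
    variants: pd.DataFrame
    genotypes: pd.DataFrame
    injury: pd.DataFrame                # germplasm, rep, n0..n4
    grain: pd.DataFrame                 # germplasm, trait, x_ck, x_nacl
    focal_snp_ids: list[str]
    lsi_mu: pd.Series


def gen_population(genome: GenomeSim, config: SimConfig | None = None) -> PopulationSim:
    """Genotypes, per-plant injury levels and grain traits for the panel."""
    config = config or genome.config
    if config.focal_effect != 0 and config.plants_per_rep == 0:
        raise ValueError("focal_effect requires plants_per_rep > 0")
    rng = _rng(config, 3)
    ann = genome.annotation.set_index("gene_id")
    focal = genome.focal_gene_id
    f_end, f_strand = int(ann.at[focal, "end"]), ann.at[focal, "strand"]
    f_start, f_chrom = int(ann.at[focal, "start"]), ann.at[focal, "chrom"]

    germ = [f"G{i + 1:03d}" for i in range(config.n_germplasm)]
    group_labels = np.array(["landrace"] * config.n_landrace
                            + ["cultivar"] * config.n_cultivar)
    group_labels = group_labels[rng.permutation(config.n_germplasm)]
    groups = pd.Series(group_labels, index=germ, name="group")

    # Hap2 planted as exact per-group counts so realized frequencies equal the
    # configured ones (e.g. 22/66 = 33.33 %, 25/51 = 49.02 %).
    hap = pd.Series(1, index=germ, name="haplotype")
    for gname, freq in (("landrace", config.hap2_freq_landrace),
                        ("cultivar", config.hap2_freq_cultivar)):
        idx = groups.index[groups == gname]
        n_hap2 = int(round(freq * len(idx)))
        chosen = rng.choice(len(idx), size=n_hap2, replace=False)
        hap.loc[idx[chosen]] = 2

    # focal SNPs: perfect linkage; Hap2 carries the alt allele everywhere
    def genomic_pos(rel: int) -> int:
        if f_strand == "+":
            return f_start + rel - 1 if rel >= 1 else f_start + rel
        return f_end - rel + 1 if rel >= 1 else f_end - rel

    var_rows = []
    geno = {}
    focal_ids = []
    for snp_id, rel, ref, alt in FOCAL_SNPS:
        var_rows.append({"chrom": f_chrom, "pos": genomic_pos(rel),
                         "snp_id": snp_id, "ref": ref, "alt": alt})
        geno[snp_id] = (hap == 2).astype(float)
        focal_ids.append(snp_id)

    # Background SNPs: population-structured allele frequencies with no
    # phenotype link.  Besides the landrace/cultivar axis the panel carries
    # two hidden ancestry axes (as a real diversity panel would), so the top
    # genotype PCs track genuine structure rather than chance directions.
    erf_genes = [g for g, k in genome.gene_kind.items() if k == "erf" and g != focal]
    bases = list("ACGT")
    land_mask = (groups == "landrace").to_numpy()
    axes = rng.integers(0, 2, size=(config.n_germplasm, 2)) - 0.5
    for i in range(config.n_background_snps):
        gid = erf_genes[int(rng.integers(0, len(erf_genes)))]
        g_start, g_end = int(ann.at[gid, "start"]), int(ann.at[gid, "end"])
        g_strand, g_chrom = ann.at[gid, "strand"], ann.at[gid, "chrom"]
        rel = int(rng.integers(-2000, g_end - g_start + 2))
        rel = rel if rel != 0 else 1
        pos = (g_start + rel - 1 if rel >= 1 else g_start + rel) if g_strand == "+" \
            else (g_end - rel + 1 if rel >= 1 else g_end - rel)
        ref, alt = rng.choice(bases, size=2, replace=False)
        p_land = rng.uniform(0.10, 0.90)
        p_cult = float(np.clip(p_land + rng.normal(0, 0.15), 0.05, 0.95))
        p = np.where(land_mask, p_land, p_cult)
        p = np.clip(p + axes @ rng.normal(0, 0.15, size=2), 0.02, 0.98)
        snp_id = f"bSnp{i + 1:03d}"
        var_rows.append({"chrom": g_chrom, "pos": int(pos), "snp_id": snp_id,
                         "ref": ref, "alt": alt})
        geno[snp_id] = pd.Series((rng.random(config.n_germplasm) < p).astype(float),
                                 index=germ)
    variants = pd.DataFrame(var_rows)
    genotypes = pd.DataFrame(geno, index=germ)

    # injury levels: germplasm-level mean LSI, discretized per-plant normals
    mu = (config.base_lsi - config.focal_effect * (hap == 2).to_numpy()
          + (0 if config.noise_sd == 0
             else rng.normal(0, config.noise_sd, config.n_germplasm)))
    mu = np.clip(mu, 2.0, 98.0)
    lsi_mu = pd.Series(mu, index=germ, name="lsi_mu")
    injury_rows = []
    for gi, g in enumerate(germ):
        for rep in range(1, 4):
            levels = np.clip(np.round(rng.normal(mu[gi] * 0.04, 0.8,
                                                 config.plants_per_rep)), 0, 4)
            counts = [int((levels == k).sum()) for k in range(5)]
            injury_rows.append({"germplasm": g, "rep": rep,
                                **{f"n{k}": counts[k] for k in range(5)}})
    injury = pd.DataFrame(injury_rows)

    grain_rows = []
    is_hap2 = (hap == 2).to_numpy()
    for trait, (mean, sd, rsir1, rsir_sd, effect) in GRAIN_TRAITS.items():
        ck = rng.normal(mean, sd, config.n_germplasm)
        r = rng.normal(rsir1 - effect * is_hap2, rsir_sd)
        nacl = ck * (1 - r / 100.0)
        for g, c, s in zip(germ, ck, nacl):
            grain_rows.append({"germplasm": g, "trait": trait,
                               "x_ck": float(c), "x_nacl": float(s)})
    grain = pd.DataFrame(grain_rows)
    return PopulationSim(germplasm=germ, groups=groups, haplotype=hap,
                         variants=variants, genotypes=genotypes, injury=injury,
                         grain=grain, focal_snp_ids=focal_ids, lsi_mu=lsi_mu)


# ---------------------------------------------------------------------------
# gen_targets (co-expression candidate pool)
# ---------------------------------------------------------------------------

@dataclass
class TargetSim:
    fpkm: pd.DataFrame
    promoters: dict[str, str]
    gcc_truth: dict[str, list[tuple[str, str, int]]]
    tracker_ids: list[str]
    low_tracker_id: str
    target_class: dict[str, str]


def gen_targets(genome: GenomeSim, expr: ExpressionSim,
                config: SimConfig | None = None) -> TargetSim:
    """Transcriptome-side target pool for the focal co-expression network.

    Five tracker genes follow the focal profile and carry promoter
    GCC-boxes (four with the motif offsets of the real predicted targets,
    one extra); a sixth tracker stays below the expression floor.  The
    background separates the filters: GCC-box DEGs with non-tracking
    (down/mixed) profiles, tracking DEGs without a GCC-box, and flat
    non-DEGs with and without the motif.
    """
    config = config or genome.config
    rng = _rng(config, 4)
    deterministic = config.noise_sd == 0
    focal_row = expr.fpkm.loc[genome.focal_gene_id].to_numpy()
    mm = expr.mapped_millions.to_numpy()
    n_samples = focal_row.size
    nt = len(config.timepoints)

    specs = []  # (kind, gcc plants)
    for t in range(5):
        specs.append(("tracker", [(off, strand, "GCCGCC")
                                  for off, strand in TRACKER_GCC_OFFSETS[t]]))
    specs.append(("low_tracker", [(off, strand, "GCCGCC")
                                  for off, strand in LOW_TRACKER_GCC_OFFSETS]))
    for _ in range(config.n_gcc_deg_background):
        off = -int(rng.integers(100, 1900))
        strand = "+" if rng.random() < 0.5 else "-"
        specs.append(("gcc_deg", [(off, strand, "GCCGCC")]))
    for _ in range(config.n_nogcc_deg):
        specs.append(("nogcc_deg", []))
    for i in range(config.n_flat_targets):
        if i % 2 == 0:
            off = -int(rng.integers(100, 1900))
            specs.append(("flat", [(off, "+", "GCCGCC")]))
        else:
            specs.append(("flat", []))

    fpkm_rows, promoters, gcc_truth, target_class = {}, {}, {}, {}
    tracker_ids, low_tracker_id = [], ""
    for i, (kind, plants) in enumerate(specs):
        tid = f"TG{i + 1:03d}"
        if kind in ("tracker", "low_tracker"):
            scale = float(rng.uniform(0.5, 2.0)) if kind == "tracker" else \
                0.8 / max(focal_row.max(), 1e-9)
            noise = (np.ones(n_samples) if deterministic
                     else np.exp(rng.normal(0, 0.15, n_samples)))
            row = focal_row * scale * noise
            if kind == "tracker":
                tracker_ids.append(tid)
            else:
                row = np.minimum(row, 0.95)
                low_tracker_id = tid
        else:
            cls = {"gcc_deg": ("sustained_down", "mixed")[i % 2],
                   "nogcc_deg": "sustained_up", "flat": "unchanged"}[kind]
            profile = np.repeat(np.array(CLASS_FPKM_PROFILES[cls][:nt])
                                * float(rng.lognormal(0, 0.3)), config.n_reps)
            length_kb = 1.5
            mean_counts = profile * mm * length_kb
            c = _nb_counts(rng, mean_counts, config.nb_size, deterministic)
            row = c / (mm * length_kb)
        fpkm_rows[tid] = row
        target_class[tid] = kind
        prom, truth = _make_promoter(rng, plants)
        promoters[tid] = prom
        gcc_truth[tid] = truth
    fpkm = pd.DataFrame(fpkm_rows, index=expr.fpkm.columns).T
    return TargetSim(fpkm=fpkm, promoters=promoters, gcc_truth=gcc_truth,
                     tracker_ids=tracker_ids, low_tracker_id=low_tracker_id,
                     target_class=target_class)


# ---------------------------------------------------------------------------
# bundle + file export
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: GenomeSim
    expr: ExpressionSim
    population: PopulationSim
    targets: TargetSim


def simulate_dataset(config: SimConfig, with_targets: bool = True) -> SimulatedDataset:
    genome = gen_genome(config)
    expr = gen_expression(genome, config)
    population = gen_population(genome, config)
    targets = gen_targets(genome, expr, config) if with_targets else None
    return SimulatedDataset(config=config, genome=genome, expr=expr,
                            population=population, targets=targets)


def focal_snp_template(genome: GenomeSim, flank: int = 100) -> tuple[str, str, int]:
    """Forward-strand templates around the promoter SNP (ref, alt, snp index).

    Built from the focal promoter (coding strand), reverse-complemented to
    forward orientation for the minus-strand focal gene.
    """
    prom = genome.promoters[genome.focal_gene_id]
    snp_rel = FOCAL_SNPS[-1][1]               # -247
    idx = len(prom) + snp_rel
    window = prom[idx - flank: idx + flank + 1]
    ref_fwd, alt_fwd = FOCAL_SNPS[-1][2], FOCAL_SNPS[-1][3]
    strand = genome.annotation.set_index("gene_id").at[genome.focal_gene_id, "strand"]
    if strand == "-":
        ref_t = window.translate(_COMPLEMENT)[::-1]
    else:
        ref_t = window
    center = flank
    assert ref_t[center] == ref_fwd
    alt_t = ref_t[:center] + alt_fwd + ref_t[center + 1:]
    return ref_t, alt_t, center


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Export the dataset as TSV/FASTA/VCF text files."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_tsv(ds.genome.annotation, out / "annotation.tsv")
    write_fasta(ds.genome.proteins, out / "proteins.fa")
    write_fasta(ds.genome.promoters, out / "promoters.fa")
    write_tsv(ds.expr.counts.reset_index(names="gene"), out / "counts.tsv")
    write_tsv(ds.expr.fpkm.reset_index(names="gene"), out / "fpkm.tsv")
    write_tsv(ds.expr.samples, out / "samples.tsv")
    write_vcf(ds.population.variants, ds.population.genotypes,
              out / "genotypes.vcf", contig_length=ds.config.chrom_length_bp)
    write_tsv(ds.population.injury, out / "injury_levels.tsv")
    write_tsv(ds.population.grain, out / "grain_traits.tsv")
    write_tsv(ds.population.groups.rename_axis("germplasm").reset_index(),
              out / "groups.tsv")
    if ds.targets is not None:
        write_tsv(ds.targets.fpkm.reset_index(names="gene"), out / "targets_fpkm.tsv")
        write_fasta(ds.targets.promoters, out / "target_promoters.fa")
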