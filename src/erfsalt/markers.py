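"""KASP allele-specific marker design and promoter cis-element scanning.

A KASP assay genotypes one SNP with three primers: two allele-specific
primers that are identical except for their 3'-terminal base (one per
allele), each carrying a universal fluorophore tail (FAM or HEX), plus one
common primer on the opposite strand.  Design here picks primer bodies of
18-25 nt whose estimated melting temperature falls in a configurable band,
and in-silico genotyping reduces the fluorescence readout to exact-match
logic on the template.

Promoter motif scanning reports GCC-box (core GCCGCC, the ERF binding site)
and ABRE (core ACGTG) occurrences on both strands with ATG-relative
negative coordinates: the promoter is given 5'->3' on the coding strand
with its last base adjacent to the ATG, and a hit at 0-based index i in a
length-L promoter sits at position i - L (so -L..-1; there is no 0).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

FAM_TAIL = "GAAGGTGACCAAGTTCATGCT"
HEX_TAIL = "GAAGGTCGGAGTCAACGGATT"

DEFAULT_MOTIFS = {"GCC-box": "GCCGCC", "ABRE": "ACGTG"}

_DNA_RE = re.compile(r"^[ACGTN]+$")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def primer_tm(seq: str) -> float:
    """Quick melting-temperature estimate in deg C.

    Wallace rule 2(A+T) + 4(G+C) for bodies of <= 14 nt; otherwise the
    GC-fraction formula 64.9 + 41*(GC - 16.4)/length.  Deterministic and
    dependency-free; adequate for ranking candidate bodies.
    """
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if len(s) <= 14:
        return 2.0 * at + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / len(s)


class KaspDesignError(ValueError):
    """Raised when no primer window reaches the Tm band; carries the best try."""

    def __init__(self, message: str, best_candidate: str | None = None,
                 best_tm: float | None = None):
        if best_candidate is not None:
            message += f" (best candidate {best_candidate!r}, Tm {best_tm:.1f} C)"
        super().__init__(message)
        self.best_candidate = best_candidate
        self.best_tm = best_tm


@dataclass(frozen=True)
class KaspMarker:
    """A designed KASP assay for one SNP.

    The two allele-specific primers share a body and differ only at the
    3'-terminal base, which reads the assayed allele on the chosen strand;
    FAM/HEX universal tails are literal constants prepended to the bodies.
    """

    snp_id: str
    common_primer: str
    fam_primer: str
    hex_primer: str
    fam_allele: str
    hex_allele: str
    tm_common: float
    tm_allele: float
    assay_strand: str = "+"

    @property
    def fam_body(self) -> str:
        return self.fam_primer[len(FAM_TAIL):]

    @property
    def hex_body(self) -> str:
        return self.hex_primer[len(HEX_TAIL):]

    def __post_init__(self):
        if not self.fam_primer.startswith(FAM_TAIL):
            raise ValueError("FAM primer must start with the FAM tail")
        if not self.hex_primer.startswith(HEX_TAIL):
            raise ValueError("HEX primer must start with the HEX tail")
        if self.fam_body[:-1] != self.hex_body[:-1]:
            raise ValueError("allele-specific bodies must differ only at the 3' base")
        if self.fam_body[-1] == self.hex_body[-1]:
            raise ValueError("allele-specific 3' bases must differ")


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence in a promoter, ATG-relative.

    ``position`` is the offset of the motif's 5'-most base on the forward
    (coding) strand, always in [-L, -1].
    """

    promoter_id: str
    motif_name: str
    strand: str
    position: int
    sequence: str


def _pick_body(template: str, snp_i: int, allele_pair: tuple[str, str],
               body_len: tuple[int, int], tm_band: tuple[float, float]):
    """Best allele-primer body ending at the SNP; returns (stem, L, tm) or raises."""
    lo, hi = tm_band
    mid = (lo + hi) / 2.0
    best, best_dev = None, None
    fallback, fallback_dev = None, None
    for L in range(body_len[0], body_len[1] + 1):
        if snp_i - L + 1 < 0:
            continue
        stem = template[snp_i - L + 1: snp_i]
        tms = [primer_tm(stem + a) for a in allele_pair]
        dev = max(abs(t - mid) for t in tms)
        if fallback is None or dev < fallback_dev:
            fallback, fallback_dev = stem + allele_pair[0], dev
        if all(lo <= t <= hi for t in tms):
            if best is None or dev < best_dev:
                best, best_dev = (stem, L, sum(tms) / 2.0), dev
    if best is None:
        raise KaspDesignError("no allele-primer window reaches the Tm band",
                              fallback, primer_tm(fallback) if fallback else None)
    return best


def _pick_common(template: str, snp_i: int, body_len: tuple[int, int],
                 tm_band: tuple[float, float], distance: tuple[int, int]):
    """Common primer on the opposite strand, 3' end 50-120 bp past the SNP."""
    lo, hi = tm_band
    mid = (lo + hi) / 2.0
    best, best_dev = None, None
    fallback, fallback_dev = None, None
    for d in range(distance[0], distance[1] + 1):
        j = snp_i + d  # 5'-most template base of the primer's binding site
        for L in range(body_len[0], body_len[1] + 1):
            if j + L > len(template):
                continue
            primer = revcomp(template[j: j + L])
            tm = primer_tm(primer)
            dev = abs(tm - mid)
            if fallback is None or dev < fallback_dev:
                fallback, fallback_dev = primer, dev
            if lo <= tm <= hi and (best is None or dev < best_dev):
                best, best_dev = (primer, tm), dev
    if best is None:
        raise KaspDesignError("no common-primer window reaches the Tm band",
                              fallback, primer_tm(fallback) if fallback else None)
    return best


def design_kasp(template: str, ref_allele: str, alt_allele: str,
                snp_id: str = "snp", snp_index: int | None = None,
                assay_strand: str = "+", fam_allele: str = "ref",
                tm_band: tuple[float, float] = (57.0, 62.0),
                body_len: tuple[int, int] = (18, 25),
                common_distance: tuple[int, int] = (50, 120)) -> KaspMarker:
    """Design a KASP marker on a SNP at the center of ``template``.

    ``template`` is forward genomic strand spanning the SNP (roughly +/-100
    bp); ``snp_index`` defaults to the center.  With ``assay_strand='-'``
    the allele primers read the reverse strand, so their 3' bases are the
    complements of the VCF alleles.  ``fam_allele`` picks which allele the
    FAM tail pairs with ("ref" default, "alt" to swap).
    """
    t = template.upper()
    if not _DNA_RE.match(t):
        raise ValueError("template must be A/C/G/T/N")
    ref_allele, alt_allele = ref_allele.upper(), alt_allele.upper()
    if ref_allele == alt_allele:
        raise ValueError("ref and alt alleles must differ")
    if fam_allele not in ("ref", "alt"):
        raise ValueError("fam_allele must be 'ref' or 'alt'")
    i = len(t) // 2 if snp_index is None else snp_index
    if assay_strand == "-":
        t = revcomp(t)
        i = len(t) - 1 - i
        a_ref = ref_allele.translate(_COMPLEMENT)
        a_alt = alt_allele.translate(_COMPLEMENT)
    elif assay_strand == "+":
        a_ref, a_alt = ref_allele, alt_allele
    else:
        raise ValueError("assay_strand must be '+' or '-'")

    stem, _, tm_allele = _pick_body(t, i, (a_ref, a_alt), body_len, tm_band)
    common, tm_common = _pick_common(t, i, body_len, tm_band, common_distance)

    ref_primer, alt_primer = stem + a_ref, stem + a_alt
    if fam_allele == "ref":
        fam_p, hex_p = FAM_TAIL + ref_primer, HEX_TAIL + alt_primer
        fam_a, hex_a = ref_allele, alt_allele
    else:
        fam_p, hex_p = FAM_TAIL + alt_primer, HEX_TAIL + ref_primer
        fam_a, hex_a = alt_allele, ref_allele
    return KaspMarker(snp_id=snp_id, common_primer=common, fam_primer=fam_p,
                      hex_primer=hex_p, fam_allele=fam_a, hex_allele=hex_a,
                      tm_common=tm_common, tm_allele=tm_allele,
                      assay_strand=assay_strand)


def _binds(body: str, template: str) -> bool:
    """Exact-match annealing on either strand, 3' base included."""
    return body in template or revcomp(body) in template


def in_silico_genotype(marker: KaspMarker, sequence) -> str:
    """FAM / HEX / BOTH / FAIL call for a germplasm template.

    ``sequence`` is one template string or an iterable of templates (a
    heterozygous pool).  A call requires the common primer site; each
    channel lights when its allele body (3' base included) matches exactly.
    """
    templates = [sequence.upper()] if isinstance(sequence, str) else \
        [s.upper() for s in sequence]
    if not any(_binds(marker.common_primer, t) for t in templates):
        return "FAIL"
    fam = any(_binds(marker.fam_body, t) for t in templates)
    hexx = any(_binds(marker.hex_body, t) for t in templates)
    if fam and hexx:
        return "BOTH"
    if fam:
        return "FAM"
    if hexx:
        return "HEX"
    return "FAIL"


def scan_motifs(promoter: str, promoter_id: str = "",
                motifs: dict[str, str] | None = None) -> list[MotifHit]:
    """Exact-string scan of a promoter for motif consensi on both strands.

    The reverse-complement of each consensus is scanned too and reported as
    a minus-strand hit at the position of its 5'-most forward-strand base.
    N never matches.  Non-ACGTN characters are an error.
    """
    seq = promoter.upper()
    if seq and not _DNA_RE.match(seq):
        raise ValueError("promoter must be A/C/G/T/N")
    motifs = DEFAULT_MOTIFS if motifs is None else motifs
    L = len(seq)
    hits: list[MotifHit] = []
    for name, consensus in motifs.items():
        consensus = consensus.upper()
        rc = revcomp(consensus)
        patterns = [(consensus, "+")] + ([(rc, "-")] if rc != consensus else [])
        for pat, strand in patterns:
            start = seq.find(pat)
            while start != -1:
                hits.append(MotifHit(promoter_id=promoter_id, motif_name=name,
                                     strand=strand, position=start - L,
                                     sequence=pat))
                start = seq.find(pat, start + 1)
    hits.sort(key=lambda h: (h.position, h.motif_name, h.strand))
    return hits
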