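"""ERF gene-family mining from proteins and gene coordinates.

Pipeline: AP2-domain detection (bundled PSSM), ERF/DREB residue
classification (Ala14/Asp19 vs Val14/Glu19), homoeolog grouping across the
A/B/D subgenomes of hexaploid wheat (reciprocal-best-hit, >=90 % global
identity), tandem-duplicate detection (same-chromosome single-linkage
chaining within 10 Mb) and positional naming (TaERF1..TaERFn by homoeologous
group 1..7, then physical position).
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from ._ap2_profile import RES14, RES19, RES37, Ap2Pssm, default_pssm

_CHROM_RE = re.compile(r"^([1-7])([ABD])$")

AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence; alphabet restricted to the 20 amino acids + X."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        if not AA_RE.match(self.sequence.upper()):
            raise ValueError(f"{self.id}: sequence contains non-amino-acid letters")


@dataclass
class AP2DomainHit:
    """A detected AP2-domain segment on a protein.

    ``domain_start``/``domain_end`` are 1-based inclusive protein positions;
    residues 14/19/37 are read off the profile's alignment columns (the
    literature's numbering), not raw protein offsets. ``atypical_res37`` is a
    warning flag only — it never changes the subfamily call.
    """

    protein_id: str
    domain_start: int
    domain_end: int
    score: float
    residue14: str
    residue19: str
    residue37: str
    subfamily: str = field(default="OTHER")
    atypical_res37: bool = field(default=False)


@dataclass(frozen=True)
class GeneModel:
    """Gene coordinates on a wheat chromosome (1A..7D), 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    subgenome: str = ""
    group: int = 0

    def __post_init__(self):
        m = _CHROM_RE.match(self.chrom)
        if not m:
            raise ValueError(f"{self.gene_id}: unknown chromosome {self.chrom!r}")
        grp, sub = int(m.group(1)), m.group(2)
        object.__setattr__(self, "group", grp)
        if self.subgenome and self.subgenome != sub:
            raise ValueError(f"{self.gene_id}: subgenome {self.subgenome} "
                             f"inconsistent with chromosome {self.chrom}")
        object.__setattr__(self, "subgenome", sub)
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclass
class FamilyMember:
    """One family member: a set of homoeologous/tandem gene copies."""

    genes: list[GeneModel]
    member_number: int = 0
    name: str = ""
    copy_names: dict[str, str] = field(default_factory=dict)
    tandem_cluster_id: str | None = None

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def min_start(self) -> int:
        return min(g.start for g in self.genes)

    @property
    def group(self) -> int:
        return self.genes[0].group


@dataclass
class TandemCluster:
    """Consecutive same-chromosome genes chained within the tandem window."""

    cluster_id: str
    chrom: str
    gene_ids: list[str]
    span_bp: int


# ---------------------------------------------------------------------------
# domain detection and subfamily classification
# ---------------------------------------------------------------------------

def detect_ap2(protein: ProteinRecord, pssm: Ap2Pssm | None = None,
               score_threshold: float = 8.0) -> list[AP2DomainHit]:
    """Scan a protein for AP2-domain windows scoring >= threshold (bits).

    Among overlapping qualifying windows the best-scoring ones are kept
    greedily, so two genuinely distinct domains on one protein both survive.
    A sequence shorter than the profile yields an empty list.
    """
    pssm = pssm or default_pssm()
    scores = pssm.score_windows(protein.sequence)
    hits: list[AP2DomainHit] = []
    order = np.argsort(scores, kind="stable")[::-1]
    taken: list[tuple[int, int]] = []
    L = pssm.length
    for i in order:
        if scores[i] < score_threshold:
            break
        if any(i < e and i + L > s for s, e in taken):
            continue
        taken.append((i, i + L))
        seq = protein.sequence.upper()
        hit = AP2DomainHit(
            protein_id=protein.id,
            domain_start=int(i) + 1,
            domain_end=int(i) + L,
            score=float(scores[i]),
            residue14=seq[i + RES14 - 1],
            residue19=seq[i + RES19 - 1],
            residue37=seq[i + RES37 - 1],
        )
        hit.subfamily = classify_subfamily(hit)
        hits.append(hit)
    hits.sort(key=lambda h: h.domain_start)
    return hits


def classify_subfamily(hit: AP2DomainHit) -> str:
    """ERF (Ala14+Asp19), DREB (Val14+Glu19) or OTHER.

    The rule is conjunctive on residues 14 and 19 only; a non-Ala residue 37
    is recorded as a warning flag on the hit but never changes the call.
    """
    pair = (hit.residue14.upper(), hit.residue19.upper())
    hit.atypical_res37 = hit.residue37.upper() != "A"
    if pair == ("A", "D"):
        return "ERF"
    if pair == ("V", "E"):
        return "DREB"
    return "OTHER"


# ---------------------------------------------------------------------------
# identity and homoeolog grouping
# ---------------------------------------------------------------------------

def pairwise_identity(proteins: dict[str, str],
                      pairs: list[tuple[str, str]] | None = None) -> dict[tuple[str, str], float]:
    """Global (Needleman-Wunsch, unit-cost) % identity for the given pairs.

    identity = 100 * (1 - edit_distance / max(len_a, len_b)); symmetric keys
    are stored both ways. With ``pairs=None`` all pairs are computed.
    """
    if pairs is None:
        pairs = list(itertools.combinations(sorted(proteins), 2))
    out: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        dist = edlib.align(proteins[a], proteins[b], mode="NW", task="distance")["editDistance"]
        ident = 100.0 * (1.0 - dist / max(len(proteins[a]), len(proteins[b])))
        out[(a, b)] = out[(b, a)] = ident
    return out


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def group_homoeologs(genes: list[GeneModel], identity: dict[tuple[str, str], float],
                     identity_min: float = 90.0,
                     tandem_window_mb: float = 10.0) -> list[FamilyMember]:
    """Partition ERF genes into family members.

    Two merge rules, both within one homoeologous group (same chromosome
    number):

    1. cross-subgenome reciprocal best hit with identity >= ``identity_min``
       (classic homoeolog triads), and
    2. same-chromosome copies within the tandem window whose identity passes
       the same bar (tandem duplicates of one member).

    The output is a partition: every input gene lands in exactly one member.
    """
    by_id = {g.gene_id: g for g in genes}
    uf = _UnionFind(by_id)

    def ident(a: str, b: str) -> float:
        return identity.get((a, b), 0.0)

    for grp in sorted({g.group for g in genes}):
        grp_genes = [g for g in genes if g.group == grp]
        subs = sorted({g.subgenome for g in grp_genes})
        # rule 1: reciprocal best cross-subgenome
        for sa, sb in itertools.combinations(subs, 2):
            ga = [g for g in grp_genes if g.subgenome == sa]
            gb = [g for g in grp_genes if g.subgenome == sb]
            best_ab = {a.gene_id: max(gb, key=lambda b: (ident(a.gene_id, b.gene_id), b.gene_id)).gene_id
                       for a in ga if gb}
            best_ba = {b.gene_id: max(ga, key=lambda a: (ident(b.gene_id, a.gene_id), a.gene_id)).gene_id
                       for b in gb if ga}
            for a, b in best_ab.items():
                if best_ba.get(b) == a and ident(a, b) >= identity_min:
                    uf.union(a, b)
        # rule 2: tandem copies on one chromosome
        for chrom in sorted({g.chrom for g in grp_genes}):
            cg = sorted((g for g in grp_genes if g.chrom == chrom), key=lambda g: (g.start, g.gene_id))
            for a, b in itertools.combinations(cg, 2):
                if abs(b.start - a.start) <= tandem_window_mb * 1e6 and \
                        ident(a.gene_id, b.gene_id) >= identity_min:
                    uf.union(a.gene_id, b.gene_id)

    comps: dict[str, list[GeneModel]] = {}
    for gid in by_id:
        comps.setdefault(uf.find(gid), []).append(by_id[gid])
    members = [FamilyMember(genes=sorted(v, key=lambda g: (g.subgenome, g.start, g.gene_id)))
               for v in comps.values()]
    members.sort(key=lambda m: (m.group, m.min_start, min(m.gene_ids)))
    return members


# ---------------------------------------------------------------------------
# tandem clusters
# ---------------------------------------------------------------------------

def detect_tandem(genes: list[GeneModel], window_mb: float = 10.0,
                  mode: str = "single_linkage") -> list[TandemCluster]:
    """Chain same-chromosome genes whose start positions are within the window.

    ``single_linkage`` (default) chains consecutive genes transitively, so
    starts at 1, 8 and 16 Mb form one cluster of three; ``strict`` requires
    every pair within a cluster to be within the window. Clusters of size
    >= 2 are reported; order of the input is irrelevant. Sizes above 4 are
    legal but draw a warning (the expected biology is 2~4 copies).
    """
    if mode not in ("single_linkage", "strict"):
        raise ValueError(f"unknown mode {mode!r}")
    window = window_mb * 1e6
    clusters: list[TandemCluster] = []
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    for chrom, group in itertools.groupby(ordered, key=lambda g: g.chrom):
        chain: list[GeneModel] = []
        for g in group:
            if not chain:
                chain = [g]
                continue
            anchor = chain[-1].start if mode == "single_linkage" else chain[0].start
            if g.start - anchor <= window:
                chain.append(g)
            else:
                if len(chain) >= 2:
                    clusters.append(_make_cluster(chain))
                chain = [g]
        if len(chain) >= 2:
            clusters.append(_make_cluster(chain))
    for i, c in enumerate(clusters):
        c.cluster_id = f"TD{i + 1:02d}"
        if len(c.gene_ids) > 4:
            warnings.warn(f"{c.cluster_id}: tandem cluster of {len(c.gene_ids)} genes "
                          "(expected 2~4)", stacklevel=2)
    return clusters


def _make_cluster(chain: list[GeneModel]) -> TandemCluster:
    return TandemCluster(cluster_id="", chrom=chain[0].chrom,
                         gene_ids=[g.gene_id for g in chain],
                         span_bp=chain[-1].start - chain[0].start)


def flag_tandem_members(members: list[FamilyMember],
                        clusters: list[TandemCluster]) -> None:
    """Mark a member as tandem-duplicated when >= 2 of its own copies share a cluster."""
    for m in members:
        ids = set(m.gene_ids)
        for c in clusters:
            if len(ids & set(c.gene_ids)) >= 2:
                m.tandem_cluster_id = c.cluster_id
                break


# ---------------------------------------------------------------------------
# naming and summary
# ---------------------------------------------------------------------------

def assign_names(members: list[FamilyMember], prefix: str = "TaERF",
                 compat_dot_style: bool = False) -> list[FamilyMember]:
    """Number members by (group 1..7, then minimum start), then name copies.

    A copy is "{prefix}{n}-{subgenome}"; when a subgenome holds several
    (tandem) copies they gain an index by position: -B1, -B2, ...  Duplicate
    coordinates tie-break deterministically on gene_id. ``compat_dot_style``
    emits the alternative "{prefix}{n}.{i}" form instead of "-{sub}{i}".
    """
    ordered = sorted(members, key=lambda m: (m.group, m.min_start, min(m.gene_ids)))
    for number, m in enumerate(ordered, start=1):
        m.member_number = number
        m.name = f"{prefix}{number}"
        m.copy_names = {}
        by_sub: dict[str, list[GeneModel]] = {}
        for g in m.genes:
            by_sub.setdefault(g.subgenome, []).append(g)
        running = 0
        for sub in sorted(by_sub):
            copies = sorted(by_sub[sub], key=lambda g: (g.start, g.gene_id))
            for i, g in enumerate(copies, start=1):
                running += 1
                if compat_dot_style and len(copies) > 1:
                    m.copy_names[g.gene_id] = f"{prefix}{number}.{running}"
                elif len(copies) > 1:
                    m.copy_names[g.gene_id] = f"{prefix}{number}-{sub}{i}"
                else:
                    m.copy_names[g.gene_id] = f"{prefix}{number}-{sub}"
    return ordered


def family_summary(members: list[FamilyMember],
                   clusters: list[TandemCluster] | None = None) -> dict:
    """Census of the mined family: counts and 1-decimal percentages."""
    if clusters is not None:
        flag_tandem_members(members, clusters)
    n = len(members)
    n_tandem = sum(1 for m in members if m.tandem_cluster_id)
    per_chrom: dict[str, int] = {}
    for m in members:
        for g in m.genes:
            per_chrom[g.chrom] = per_chrom.get(g.chrom, 0) + 1
    return {
        "n_members": n,
        "n_genes": sum(len(m.genes) for m in members),
        "n_tandem_members": n_tandem,
        "pct_tandem_members": round(100.0 * n_tandem / n, 1) if n else 0.0,
        "genes_per_chromosome": dict(sorted(per_chrom.items())),
    }


# ---------------------------------------------------------------------------
# end-to-end mining
# ---------------------------------------------------------------------------

@dataclass
class MiningResult:
    members: list[FamilyMember]
    clusters: list[TandemCluster]
    hits: dict[str, AP2DomainHit]
    erf_genes: list[GeneModel]
    subfamilies: dict[str, str]
    summary: dict

    def members_table(self) -> pd.DataFrame:
        rows = []
        for m in self.members:
            for g in m.genes:
                h = self.hits.get(g.gene_id)
                rows.append({
                    "name": m.copy_names.get(g.gene_id, m.name),
                    "member_number": m.member_number,
                    "gene_id": g.gene_id, "chrom": g.chrom,
                    "start": g.start, "end": g.end, "subgenome": g.subgenome,
                    "cluster_id": m.tandem_cluster_id or "",
                    "subfamily": h.subfamily if h else "",
                    "residue14": h.residue14 if h else "",
                    "residue19": h.residue19 if h else "",
                    "residue37": h.residue37 if h else "",
                })
        return pd.DataFrame(rows)


def _collapse_isoforms(proteins: dict[str, str], annotation: pd.DataFrame) -> dict[str, str]:
    """Keep one representative (longest) protein per gene.

    Isoform ids of the form "<gene_id>.<n>" collapse onto the gene id.
    """
    gene_ids = set(annotation["gene_id"])
    best: dict[str, str] = {}
    for pid, seq in proteins.items():
        gid = pid if pid in gene_ids else pid.rsplit(".", 1)[0]
        if gid not in best or len(seq) > len(best[gid]):
            best[gid] = seq
    return best


def mine_family(proteins: dict[str, str], annotation: pd.DataFrame,
                pssm: Ap2Pssm | None = None, score_threshold: float = 8.0,
                identity_min: float = 90.0, window_mb: float = 10.0) -> MiningResult:
    """Run the full family-mining pipeline.

    ``annotation`` needs columns gene_id, chrom, start, end, strand.
    Returns members named TaERF1..TaERFn, tandem clusters, per-protein domain
    hits and the census summary.
    """
    proteins = _collapse_isoforms(proteins, annotation)
    hits: dict[str, AP2DomainHit] = {}
    subfam: dict[str, str] = {}
    for gid, seq in proteins.items():
        found = detect_ap2(ProteinRecord(id=gid, sequence=seq), pssm, score_threshold)
        if found:
            best = max(found, key=lambda h: h.score)
            hits[gid] = best
            subfam[gid] = best.subfamily

    ann = annotation.set_index("gene_id")
    erf_ids = [gid for gid, sf in subfam.items() if sf == "ERF" and gid in ann.index]
    genes = [GeneModel(gene_id=g, chrom=ann.at[g, "chrom"], start=int(ann.at[g, "start"]),
                       end=int(ann.at[g, "end"]), strand=ann.at[g, "strand"])
             for g in sorted(erf_ids)]

    pairs = [(a.gene_id, b.gene_id)
             for _, grp in itertools.groupby(sorted(genes, key=lambda g: g.group),
                                             key=lambda g: g.group)
             for a, b in itertools.combinations(list(grp), 2)]
    identity = pairwise_identity({g.gene_id: proteins[g.gene_id] for g in genes}, pairs)

    members = group_homoeologs(genes, identity, identity_min, window_mb)
    clusters = detect_tandem(genes, window_mb)
    flag_tandem_members(members, clusters)
    members = assign_names(members)
    return MiningResult(members=members, clusters=clusters, hits=hits,
                        erf_genes=genes, subfamilies=subfam,
                        summary=family_summary(members))
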