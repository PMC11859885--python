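import random

import numpy as np
import pytest

from erfsalt._ap2_profile import default_pssm
from erfsalt.family import (AP2DomainHit, GeneModel, ProteinRecord,
                            assign_names, classify_subfamily, detect_ap2,
                            detect_tandem, family_summary, group_homoeologs,
                            mine_family, pairwise_identity)
from erfsalt.simulate import SimConfig, gen_genome, make_protein


def _hit(r14, r19, r37="A"):
    return AP2DomainHit(protein_id="p", domain_start=1, domain_end=60,
                        score=50.0, residue14=r14, residue19=r19, residue37=r37)


class TestDomainDetection:
    def test_planted_domains_recovered_with_subfamily(self, dataset):
        genome = dataset.genome
        for gid, (start, subfam) in list(genome.domain_truth.items())[:40]:
            hits = detect_ap2(ProteinRecord(id=gid, sequence=genome.proteins[gid]))
            assert len(hits) == 1, gid
            assert hits[0].domain_start == start
            assert hits[0].subfamily == subfam

    def test_decoys_yield_no_hits(self, dataset):
        genome = dataset.genome
        decoys = [g for g, k in genome.gene_kind.items() if k == "decoy"]
        assert decoys
        for gid in decoys:
            assert detect_ap2(ProteinRecord(id=gid, sequence=genome.proteins[gid])) == []

    def test_two_planted_domains_give_two_nonoverlapping_hits(self):
        rng = np.random.default_rng(7)
        seq, starts = make_protein(rng, ("ERF", "DREB"), length=300)
        hits = detect_ap2(ProteinRecord(id="p", sequence=seq))
        assert [h.domain_start for h in hits] == starts
        assert hits[0].domain_end < hits[1].domain_start
        assert [h.subfamily for h in hits] == ["ERF", "DREB"]

    def test_sequence_shorter_than_profile_is_empty_not_error(self):
        assert detect_ap2(ProteinRecord(id="p", sequence="MKV")) == []

    def test_invalid_protein_alphabet_rejected(self):
        with pytest.raises(ValueError):
            ProteinRecord(id="p", sequence="MKV*")
        with pytest.raises(ValueError):
            ProteinRecord(id="p", sequence="")


class TestClassify:
    @pytest.mark.parametrize("r14,r19,expected", [
        ("A", "D", "ERF"),
        ("V", "E", "DREB"),
        ("A", "E", "OTHER"),   # the rule is conjunctive
        ("V", "D", "OTHER"),
        ("G", "G", "OTHER"),
    ])
    def test_residue_rule(self, r14, r19, expected):
        assert classify_subfamily(_hit(r14, r19)) == expected

    def test_atypical_residue37_flags_but_never_changes_call(self):
        h = _hit("A", "D", r37="S")
        assert classify_subfamily(h) == "ERF"
        assert h.atypical_res37 is True
        h2 = _hit("A", "D", r37="A")
        classify_subfamily(h2)
        assert h2.atypical_res37 is False


def _gene(gid, chrom, start, end=None, strand="+"):
    return GeneModel(gene_id=gid, chrom=chrom, start=start,
                     end=end or start + 999, strand=strand)


class TestHomoeologGrouping:
    def test_triad_merges_into_one_member(self):
        genes = [_gene("a", "2A", 100), _gene("b", "2B", 120), _gene("d", "2D", 90)]
        ident = {(x, y): 97.0 for x in "abd" for y in "abd" if x != y}
        members = group_homoeologs(genes, ident)
        assert len(members) == 1
        assert sorted(members[0].gene_ids) == ["a", "b", "d"]

    def test_different_groups_never_merge(self):
        genes = [_gene("a", "2A", 100), _gene("b", "5B", 100)]
        members = group_homoeologs(genes, {("a", "b"): 99.9, ("b", "a"): 99.9})
        assert len(members) == 2

    def test_low_identity_singletons_stay_alone(self):
        genes = [_gene("a", "2A", 100), _gene("b", "2B", 100)]
        members = group_homoeologs(genes, {("a", "b"): 70.0, ("b", "a"): 70.0})
        assert len(members) == 2

    def test_output_is_a_partition(self, dataset, mining):
        seen = [g for m in mining.members for g in m.gene_ids]
        assert len(seen) == len(set(seen))
        erf_truth = {g for g, k in dataset.genome.gene_kind.items() if k == "erf"}
        assert set(seen) == erf_truth

    def test_unknown_chromosome_is_error(self):
        with pytest.raises(ValueError):
            _gene("a", "8A", 1)
        with pytest.raises(ValueError):
            _gene("a", "2X", 1)

    def test_identity_of_identical_sequences_is_100(self):
        prot = {"a": "MKVAYDE", "b": "MKVAYDE", "c": "MKVAYDA"}
        ident = pairwise_identity(prot)
        assert ident[("a", "b")] == 100.0
        assert ident[("a", "c")] == pytest.approx(100 * 6 / 7)


class TestTandem:
    def test_pair_within_window_clusters(self):
        genes = [_gene("a", "2B", 1_000_000), _gene("b", "2B", 5_000_000)]
        clusters = detect_tandem(genes)
        assert len(clusters) == 1 and len(clusters[0].gene_ids) == 2

    def test_pair_outside_window_does_not(self):
        genes = [_gene("a", "2B", 1_000_000), _gene("b", "2B", 20_000_000)]
        assert detect_tandem(genes) == []

    def test_single_linkage_chains_transitively(self):
        genes = [_gene("a", "2B", 1_000_000), _gene("b", "2B", 8_000_000),
                 _gene("c", "2B", 16_000_000)]
        clusters = detect_tandem(genes)
        assert len(clusters) == 1 and len(clusters[0].gene_ids) == 3
        # strict mode anchors on the first gene instead
        strict = detect_tandem(genes, mode="strict")
        assert [len(c.gene_ids) for c in strict] == [2]

    def test_invariant_to_input_order(self):
        rng = random.Random(0)
        genes = [_gene(f"g{i}", "3A", rng.randrange(1, 60_000_000)) for i in range(12)]
        ref = [(c.chrom, tuple(c.gene_ids)) for c in detect_tandem(genes)]
        for _ in range(5):
            rng.shuffle(genes)
            got = [(c.chrom, tuple(c.gene_ids)) for c in detect_tandem(genes)]
            assert got == ref

    def test_matches_all_pairs_single_linkage_oracle(self):
        rng = random.Random(42)
        for trial in range(30):
            n = rng.randrange(2, 21)
            genes = [_gene(f"g{i}", rng.choice(["1A", "1B"]),
                           rng.randrange(1, 40_000_000)) for i in range(n)]
            got = {frozenset(c.gene_ids) for c in detect_tandem(genes)}
            # oracle: union-find over all pairs within the window
            parent = {g.gene_id: g.gene_id for g in genes}

            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x

            for i in range(n):
                for j in range(i + 1, n):
                    a, b = genes[i], genes[j]
                    if a.chrom == b.chrom and abs(a.start - b.start) <= 10_000_000:
                        parent[find(a.gene_id)] = find(b.gene_id)
            comps = {}
            for g in genes:
                comps.setdefault(find(g.gene_id), set()).add(g.gene_id)
            want = {frozenset(c) for c in comps.values() if len(c) >= 2}
            assert got == want, f"trial {trial}"

    def test_oversized_cluster_warns_but_reports(self):
        genes = [_gene(f"g{i}", "2B", 1_000_000 + i * 2_000_000) for i in range(5)]
        with pytest.warns(UserWarning):
            clusters = detect_tandem(genes)
        assert len(clusters[0].gene_ids) == 5


class TestNaming:
    def test_sequential_numbering_by_group_then_position(self):
        members = group_homoeologs(
            [_gene("x", "3A", 500), _gene("y", "1A", 900), _gene("z", "1B", 100)],
            {})
        named = assign_names(members)
        assert [m.name for m in named] == ["TaERF1", "TaERF2", "TaERF3"]
        assert named[0].copy_names == {"z": "TaERF1-B"}   # 1B before 1A? no: by start
        assert named[1].copy_names == {"y": "TaERF2-A"}

    def test_single_copy_suffix_and_tandem_indices(self):
        members = group_homoeologs(
            [_gene("b1", "2B", 100), _gene("b2", "2B", 900_000)],
            {("b1", "b2"): 99.0, ("b2", "b1"): 99.0})
        named = assign_names(members)
        assert len(named) == 1
        assert named[0].copy_names == {"b1": "TaERF1-B1", "b2": "TaERF1-B2"}

    def test_compat_dot_style(self):
        members = group_homoeologs(
            [_gene("b1", "2B", 100), _gene("b2", "2B", 900_000)],
            {("b1", "b2"): 99.0, ("b2", "b1"): 99.0})
        named = assign_names(members, compat_dot_style=True)
        assert set(named[0].copy_names.values()) == {"TaERF1.1", "TaERF1.2"}


class TestSummary:
    @pytest.mark.parametrize("n_tandem,n,expected", [
        (15, 54, 27.8), (0, 54, 0.0), (54, 54, 100.0),
    ])
    def test_tandem_percentage(self, n_tandem, n, expected):
        members = []
        for i in range(n):
            m = group_homoeologs([_gene(f"g{i}", "1A", 1 + i * 20_000_000)], {})[0]
            m.tandem_cluster_id = "TD01" if i < n_tandem else None
            members.append(m)
        assert family_summary(members)["pct_tandem_members"] == expected


class TestEndToEndMining:
    def test_planted_family_recovered_exactly(self, dataset, mining):
        cfg, genome = dataset.config, dataset.genome
        assert mining.summary["n_members"] == cfg.n_members
        assert mining.summary["n_tandem_members"] == genome.n_tandem_members
        assert mining.summary["pct_tandem_members"] == pytest.approx(
            round(100 * genome.n_tandem_members / cfg.n_members, 1))
        # every mined member is exactly one planted member
        truth = {frozenset(m["gene_ids"]) for m in genome.members}
        mined = {frozenset(m.gene_ids) for m in mining.members}
        assert mined == truth

    def test_subfamily_calls_match_planted_kinds(self, dataset, mining):
        genome = dataset.genome
        for gid, kind in genome.gene_kind.items():
            if kind == "erf":
                assert mining.subfamilies.get(gid) == "ERF"
            elif kind == "dreb":
                assert mining.subfamilies.get(gid) == "DREB"
            else:
                assert gid not in mining.subfamilies

    def test_without_decoys_every_protein_classifies_erf(self):
        cfg = SimConfig(seed=11, n_members=8, n_decoys=0, n_dreb=0,
                        tandem_cluster_spec=((2, 3.0),))
        genome = gen_genome(cfg)
        res = mine_family(genome.proteins, genome.annotation)
        assert set(res.subfamilies.values()) == {"ERF"}
        assert len(res.subfamilies) == len(genome.proteins)


def test_pssm_profile_shape_and_scores():
    pssm = default_pssm()
    assert pssm.length == 60
    assert pssm.matrix.shape == (60, 20)
    # a consensus-sampled window scores far above threshold, noise far below
    rng = np.random.default_rng(1)
    seq, _ = make_protein(rng, ("ERF",), 200)
    assert pssm.score_windows(seq).max() > 40
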