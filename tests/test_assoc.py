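import numpy as np
import pandas as pd
import pytest
from scipy import stats

from erfsalt.assoc import (annotate_coding_effect, associate,
                           association_table, build_haplotypes,
                           extract_gene_snps, haplotype_frequency_by_group,
                           haplotype_phenotype_test, relative_position)
from erfsalt.family import GeneModel
from erfsalt.pipeline import focal_gene_model


def _variants(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "snp_id", "ref", "alt"])


PLUS_GENE = GeneModel(gene_id="g+", chrom="2B", start=10_000, end=11_359,
                      strand="+")
MINUS_GENE = GeneModel(gene_id="g-", chrom="2B", start=10_000, end=11_359,
                       strand="-")


class TestSnpExtraction:
    def test_promoter_snp_at_minus_247(self):
        v = _variants([("2B", 10_000 - 247, "s1", "C", "G")])
        recs = extract_gene_snps(v, PLUS_GENE)
        assert len(recs) == 1
        assert recs[0].gene_relative_pos == -247
        assert recs[0].region == "promoter"

    def test_window_edge_at_2000_bp(self):
        v = _variants([("2B", 10_000 - 2000, "in", "A", "T"),
                       ("2B", 10_000 - 2001, "out", "A", "T")])
        recs = extract_gene_snps(v, PLUS_GENE)
        assert [r.snp_id for r in recs] == ["in"]
        assert recs[0].gene_relative_pos == -2000

    def test_minus_strand_flips_frame_and_alleles(self):
        v = _variants([("2B", 11_359 + 10, "up", "C", "G"),
                       ("2B", 11_359, "atg", "T", "G")])
        recs = {r.snp_id: r for r in extract_gene_snps(v, MINUS_GENE)}
        assert recs["up"].gene_relative_pos == -10
        assert recs["up"].region == "promoter"
        assert recs["atg"].gene_relative_pos == 1
        assert (recs["atg"].ref_coding, recs["atg"].alt_coding) == ("A", "C")

    def test_regions_partition_with_cds_length(self):
        v = _variants([("2B", 10_000 + 215, "cds", "A", "G"),
                       ("2B", 10_000 + 900, "utr", "A", "G")])
        recs = {r.snp_id: r for r in extract_gene_snps(v, PLUS_GENE, cds_len=783)}
        assert recs["cds"].region == "CDS"
        assert recs["utr"].region == "UTR3"

    def test_relative_position_has_no_zero(self):
        assert relative_position(PLUS_GENE, 10_000) == 1
        assert relative_position(PLUS_GENE, 9_999) == -1
        assert relative_position(MINUS_GENE, 11_359) == 1
        assert relative_position(MINUS_GENE, 11_360) == -1

    def test_simulated_focal_gene_annotations(self, dataset):
        gene = focal_gene_model(dataset)
        ann = dataset.genome.annotation.set_index("gene_id")
        cds_len = int(ann.at[gene.gene_id, "cds_len"])
        recs = {r.snp_id: r for r in extract_gene_snps(
            dataset.population.variants, gene, cds_len=cds_len)}
        assert recs["Snp52"].region == "promoter"
        assert recs["Snp52"].gene_relative_pos == -247
        assert recs["Snp49"].gene_relative_pos == 216
        assert recs["Snp40"].gene_relative_pos == 624
        assert {recs["Snp36"].region, recs["Snp35"].region} == {"UTR3"}
        for sid in ("Snp49", "Snp40"):
            assert annotate_coding_effect(recs[sid],
                                          dataset.genome.focal_cds) == "synonymous"


class TestCodingEffect:
    def _snp(self, pos, ref, alt):
        from erfsalt.assoc import SnpRecord
        return SnpRecord(snp_id="s", chrom="2B", pos=0, ref=ref, alt=alt,
                         region="CDS", gene_relative_pos=pos,
                         ref_coding=ref, alt_coding=alt)

    def test_third_position_ala_swap_is_synonymous(self):
        cds = "ATG" + "GCT" * 100 + "TAA"   # pos 216 = codon 72 third base
        assert annotate_coding_effect(self._snp(216, "T", "C"), cds) == "synonymous"

    def test_start_codon_swap_is_missense(self):
        cds = "ATGGCTGCTTAA"
        assert annotate_coding_effect(self._snp(1, "A", "G"), cds) == "missense"

    def test_identical_alleles_trivially_synonymous(self):
        cds = "ATGGCTGCTTAA"
        assert annotate_coding_effect(self._snp(4, "G", "G"), cds) == "synonymous"

    def test_frame_and_bounds_errors(self):
        with pytest.raises(ValueError):
            annotate_coding_effect(self._snp(1, "A", "G"), "ATGGC")
        with pytest.raises(ValueError):
            annotate_coding_effect(self._snp(99, "A", "G"), "ATGTAA")
        bad = self._snp(1, "A", "G")
        bad.region = "promoter"
        with pytest.raises(ValueError):
            annotate_coding_effect(bad, "ATGTAA")


class TestAssociate:
    @staticmethod
    def _panel(seed=0, n=40, m=25):
        rng = np.random.default_rng(seed)
        geno = pd.DataFrame(rng.integers(0, 2, size=(n, m)).astype(float),
                            index=[f"G{i}" for i in range(n)],
                            columns=[f"s{j}" for j in range(m)])
        y = pd.Series(rng.normal(50, 8, n), index=geno.index)
        return geno, y

    def test_simple_regression_matches_closed_form(self):
        geno, y = self._panel()
        res = {r.snp_id: r for r in associate(geno, y, n_pcs=0, maf_min=0.0)}
        for snp in geno.columns:
            g = geno[snp].to_numpy()
            beta_hat = np.cov(g, y, bias=True)[0, 1] / np.var(g)
            assert res[snp].beta == pytest.approx(beta_hat, abs=1e-10)

    def test_matches_normal_equation_oracle_with_pcs(self):
        geno, y = self._panel(seed=1)
        n_pcs = 3
        results = {r.snp_id: r for r in associate(geno, y, n_pcs=n_pcs, maf_min=0.0)}
        G = geno.to_numpy() - geno.to_numpy().mean(axis=0)
        U, S, _ = np.linalg.svd(G, full_matrices=False)
        pcs = U[:, :n_pcs] * S[:n_pcs]
        for snp in geno.columns:
            X = np.column_stack([np.ones(len(y)), geno[snp], pcs])
            beta = np.linalg.solve(X.T @ X, X.T @ y.to_numpy())
            resid = y.to_numpy() - X @ beta
            dof = len(y) - X.shape[1]
            se = np.sqrt(resid @ resid / dof * np.linalg.inv(X.T @ X)[1, 1])
            p = 2 * stats.t.sf(abs(beta[1] / se), dof)
            assert results[snp].beta == pytest.approx(beta[1], abs=1e-10)
            assert results[snp].p == pytest.approx(p, abs=1e-10)

    def test_maf_filter_drops_rare_variants(self):
        geno, y = self._panel(seed=2)
        geno["rare"] = 0.0
        geno.loc[geno.index[0], "rare"] = 1.0   # MAF 1/40
        res = associate(geno, y, n_pcs=0, maf_min=0.05)
        assert "rare" not in {r.snp_id for r in res}

    def test_constant_column_skipped_with_warning(self):
        geno, y = self._panel(seed=3)
        geno["const"] = 0.5
        with pytest.warns(UserWarning):
            res = associate(geno, y, n_pcs=0, maf_min=0.0)
        assert "const" not in {r.snp_id for r in res}

    def test_missing_phenotype_is_error(self):
        geno, y = self._panel()
        with pytest.raises(ValueError):
            associate(geno, y.iloc[:-1], n_pcs=0)

    def test_significance_threshold_is_q_below_001(self):
        geno, y = self._panel(seed=4)
        y = y + 30 * geno["s0"]   # one strong true signal
        table = association_table(associate(geno, y, n_pcs=0, maf_min=0.0))
        row = table.set_index("snp_id").loc["s0"]
        assert row["significant"] and row["neg_log10_q"] > 2
        assert ((table["q"] < 0.01) == table["significant"]).all()


class TestHaplotypes:
    def test_identical_alleles_share_a_label(self):
        geno = pd.DataFrame({"s1": [0.0, 0.0, 1.0], "s2": [1.0, 1.0, 0.0]},
                            index=["a", "b", "c"])
        hap = build_haplotypes(geno)
        t = hap.table
        assert t.at["a", "haplotype"] == t.at["b", "haplotype"] == "Hap1"
        assert t.at["c", "haplotype"] == "Hap2"

    def test_majority_string_is_hap1(self, dataset):
        pop = dataset.population
        hap = build_haplotypes(pop.genotypes[pop.focal_snp_ids])
        carriers = hap.table["haplotype"] == "Hap1"
        assert carriers.sum() == 70          # 117 - (22 + 25) planted Hap2
        assert (pop.haplotype[carriers.index[carriers]] == 1).all()

    def test_all_unique_strings_yield_n_haplotypes(self):
        geno = pd.DataFrame(np.eye(4), index=list("abcd"),
                            columns=[f"s{i}" for i in range(4)])
        hap = build_haplotypes(geno)
        assert hap.table["haplotype"].nunique() == 4
        assert hap.frequency().eq(0.25).all()

    def test_missing_allele_goes_to_na_bucket(self):
        geno = pd.DataFrame({"s1": [0.0, np.nan], "s2": [1.0, 1.0]},
                            index=["a", "b"])
        hap = build_haplotypes(geno)
        assert hap.table.at["b", "haplotype"] == "NA"

    def test_invariant_to_germplasm_order(self):
        rng = np.random.default_rng(0)
        geno = pd.DataFrame(rng.integers(0, 2, size=(30, 3)).astype(float),
                            index=[f"G{i}" for i in range(30)],
                            columns=["s1", "s2", "s3"])
        ref = build_haplotypes(geno).table["haplotype"]
        shuffled = geno.sample(frac=1.0, random_state=1)
        got = build_haplotypes(shuffled).table["haplotype"]
        assert got.reindex(ref.index).equals(ref)

    def test_no_snps_is_error(self):
        with pytest.raises(ValueError):
            build_haplotypes(pd.DataFrame(index=["a"]))


class TestHaplotypePhenotype:
    def test_lower_mean_haplotype_flagged_favorable(self):
        geno = pd.DataFrame({"s1": [0.0] * 6 + [1.0] * 5},
                            index=[f"G{i}" for i in range(11)])
        hap = build_haplotypes(geno)
        pheno = pd.Series([60, 58, 62, 61, 59, 60, 40, 42, 38, 41, 39],
                          index=geno.index, dtype=float)
        tests = haplotype_phenotype_test(hap, pheno)
        assert len(tests) == 1
        assert tests[0].favorable == "Hap2"
        assert tests[0].welch.p < 1e-4

    def test_singleton_haplotype_excluded_with_warning(self):
        geno = pd.DataFrame({"s1": [0.0, 0.0, 0.0, 1.0]},
                            index=list("abcd"))
        hap = build_haplotypes(geno)
        pheno = pd.Series([1.0, 2.0, 3.0, 9.0], index=geno.index)
        with pytest.warns(UserWarning):
            assert haplotype_phenotype_test(hap, pheno) == []


class TestGroupFrequencies:
    def test_published_gap_is_15_69_points(self):
        idx = [f"G{i}" for i in range(117)]
        # 66 landraces (22 Hap2) + 51 cultivars (25 Hap2)
        hap_string = (["0"] * 44 + ["1"] * 22) + (["0"] * 26 + ["1"] * 25)
        geno = pd.DataFrame({"s1": [float(h) for h in hap_string]}, index=idx)
        hap = build_haplotypes(geno)
        groups = pd.Series(["landrace"] * 66 + ["cultivar"] * 51, index=idx)
        freq, diff = haplotype_frequency_by_group(hap, groups)
        assert freq.at["landrace", "Hap2"] == 33.33
        assert freq.at["cultivar", "Hap2"] == 49.02
        gap = diff.set_index("haplotype").at["Hap2", "difference_pp"]
        assert abs(gap) == 15.69

    def test_frequencies_sum_to_100_per_group(self, dataset):
        pop = dataset.population
        hap = build_haplotypes(pop.genotypes[pop.focal_snp_ids])
        freq, _ = haplotype_frequency_by_group(hap, pop.groups)
        hap_cols = [c for c in freq.columns if c.startswith("Hap")]
        assert np.allclose(freq[hap_cols].sum(axis=1), 100.0, atol=0.02)

    def test_single_group_emits_no_differences(self):
        geno = pd.DataFrame({"s1": [0.0, 1.0, 0.0]}, index=list("abc"))
        hap = build_haplotypes(geno)
        groups = pd.Series(["landrace"] * 3, index=list("abc"))
        _, diff = haplotype_frequency_by_group(hap, groups)
        assert diff.empty
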