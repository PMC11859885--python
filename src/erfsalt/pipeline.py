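"""End-to-end orchestration on a synthetic panel.

Chains the whole analysis — simulate, mine the family, call differential
expression and response classes, score injury phenotypes, run SNP
association, build haplotypes, design/genotype the KASP marker and pick
co-expression neighbors — and scores every stage against the simulator's
ground truth.  Tests and the acceptance script drive this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import assoc, coexpress, expression, markers, phenostats
from .family import GeneModel, MiningResult, mine_family
from .simulate import (FOCAL_SNPS, SimConfig, SimulatedDataset, focal_snp_template,
                       simulate_dataset)


@dataclass
class PipelineResult:
    dataset: SimulatedDataset
    mining: MiningResult
    de: pd.DataFrame
    gene_classes: pd.Series
    member_classes: pd.Series            # indexed by true member idx
    census: pd.DataFrame
    lsi: pd.Series
    association: pd.DataFrame
    focal_snp_records: list
    haplotypes: assoc.HaplotypeAssignment | None
    hap_lsi_tests: list
    hap_rsir_tests: dict
    hap_freq: pd.DataFrame | None
    hap_freq_diff: pd.DataFrame | None
    kasp_marker: markers.KaspMarker | None
    kasp_concordance: float
    neighbors: pd.DataFrame
    metrics: dict


def germplasm_lsi(injury: pd.DataFrame) -> pd.Series:
    """Mean leaf salt injury index per germplasm over repeated experiments."""
    out = {}
    for germ, grp in injury.groupby("germplasm"):
        counts = [phenostats.InjuryCounts(int(r.n0), int(r.n1), int(r.n2),
                                          int(r.n3), int(r.n4))
                  for r in grp.itertuples()]
        out[germ] = phenostats.lsi_mean(counts)
    return pd.Series(out, name="lsi")


def grain_rsir(grain: pd.DataFrame) -> pd.DataFrame:
    """Germplasm x trait table of relative salt injury rates (%)."""
    rows = {}
    for (germ, trait), grp in grain.groupby(["germplasm", "trait"]):
        row = grp.iloc[0]
        rows.setdefault(germ, {})[trait] = phenostats.rsir(row["x_ck"], row["x_nacl"])
    return pd.DataFrame(rows).T.sort_index()


def focal_gene_model(ds: SimulatedDataset) -> GeneModel:
    ann = ds.genome.annotation.set_index("gene_id")
    gid = ds.genome.focal_gene_id
    return GeneModel(gene_id=gid, chrom=ann.at[gid, "chrom"],
                     start=int(ann.at[gid, "start"]), end=int(ann.at[gid, "end"]),
                     strand=ann.at[gid, "strand"])


def run_pipeline(config: SimConfig, n_pcs: int = 3,
                 with_mining: bool = True) -> PipelineResult:
    ds = simulate_dataset(config)
    genome, expr, pop, targets = ds.genome, ds.expr, ds.population, ds.targets

    # --- family mining against planted ground truth -----------------------
    if with_mining:
        mining = mine_family(genome.proteins, genome.annotation)
    else:
        mining = None

    # --- expression: DE calls, response classes, member census ------------
    de = expression.de_table(expr.fpkm, expr.samples)
    gene_classes = expression.classify_all(expr.fpkm, de)
    member_genes = {m["member_idx"]: m["gene_ids"] for m in genome.members}
    member_classes = expression.member_classes(gene_classes, de, member_genes)
    census = expression.response_census(member_classes)
    truth = pd.Series(expr.member_class)
    class_recovery = float((member_classes.reindex(truth.index) == truth).mean())

    # --- phenotypes and association ---------------------------------------
    lsi = germplasm_lsi(pop.injury)
    results = assoc.associate(pop.genotypes, lsi, n_pcs=n_pcs)
    association = assoc.association_table(results)
    sig = set(association.loc[association["significant"], "snp_id"])
    focal_sig = [s for s in pop.focal_snp_ids if s in sig]

    focal_gene = focal_gene_model(ds)
    ann = genome.annotation.set_index("gene_id")
    cds_len = int(ann.at[genome.focal_gene_id, "cds_len"])
    focal_records = assoc.extract_gene_snps(pop.variants, focal_gene,
                                            cds_len=cds_len)
    for rec in focal_records:
        if rec.region == "CDS":
            assoc.annotate_coding_effect(rec, genome.focal_cds)

    haplotypes = hap_freq = hap_freq_diff = None
    hap_lsi_tests: list = []
    hap_rsir_tests: dict = {}
    if focal_sig:
        meta = [r for r in focal_records if r.snp_id in focal_sig]
        haplotypes = assoc.build_haplotypes(pop.genotypes[focal_sig], meta,
                                            gene_id=genome.focal_gene_id)
        hap_lsi_tests = assoc.haplotype_phenotype_test(haplotypes, lsi)
        rsir_df = grain_rsir(pop.grain)
        for trait in rsir_df.columns:
            hap_rsir_tests[trait] = assoc.haplotype_phenotype_test(
                haplotypes, rsir_df[trait])
        hap_freq, hap_freq_diff = assoc.haplotype_frequency_by_group(
            haplotypes, pop.groups)

    # --- KASP marker on the promoter SNP ----------------------------------
    ref_t, alt_t, center = focal_snp_template(genome)
    snp_id, _, ref, alt = FOCAL_SNPS[-1]
    marker = markers.design_kasp(ref_t, ref, alt, snp_id=snp_id,
                                 snp_index=center)
    calls = {}
    for germ in pop.germplasm:
        template = alt_t if pop.haplotype[germ] == 2 else ref_t
        calls[germ] = markers.in_silico_genotype(marker, template)
    expected = {g: ("HEX" if pop.haplotype[g] == 2 else "FAM")
                for g in pop.germplasm}
    kasp_concordance = float(np.mean([calls[g] == expected[g]
                                      for g in pop.germplasm]))

    # --- co-expression neighbors ------------------------------------------
    combined = pd.concat([expr.fpkm.loc[[genome.focal_gene_id]], targets.fpkm])
    de_targets = expression.de_table(targets.fpkm, expr.samples)
    deg_flags = de_targets.groupby("gene")["significant"].any()
    gcc_flags = pd.Series({tid: any(h.motif_name == "GCC-box"
                                    for h in markers.scan_motifs(seq, tid))
                           for tid, seq in targets.promoters.items()})
    norm = coexpress.normalize_profiles(combined)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta = coexpress.pick_soft_power(np.corrcoef(norm.to_numpy()))
    neighbors = coexpress.focal_neighbors(genome.focal_gene_id, combined,
                                          deg_flags, gcc_flags, beta=beta)
    found = set(neighbors["gene"])
    truth_set = set(targets.tracker_ids)
    precision = len(found & truth_set) / len(found) if found else 0.0
    recall = len(found & truth_set) / len(truth_set) if truth_set else 0.0

    metrics = {
        "n_members_found": mining.summary["n_members"] if mining else None,
        "n_tandem_members_found": mining.summary["n_tandem_members"] if mining else None,
        "pct_tandem_members": mining.summary["pct_tandem_members"] if mining else None,
        "class_recovery": class_recovery,
        "n_focal_snps_significant": len(focal_sig),
        "frac_snps_significant": float(association["significant"].mean())
        if len(association) else 0.0,
        "hap2_favorable_lsi": bool(hap_lsi_tests
                                   and all(_is_hap2(t.favorable, haplotypes, pop)
                                           for t in hap_lsi_tests)),
        "kasp_concordance": kasp_concordance,
        "neighbor_precision": precision,
        "neighbor_recall": recall,
        "soft_power": beta,
    }
    return PipelineResult(dataset=ds, mining=mining, de=de,
                          gene_classes=gene_classes, member_classes=member_classes,
                          census=census, lsi=lsi, association=association,
                          focal_snp_records=focal_records, haplotypes=haplotypes,
                          hap_lsi_tests=hap_lsi_tests, hap_rsir_tests=hap_rsir_tests,
                          hap_freq=hap_freq, hap_freq_diff=hap_freq_diff,
                          kasp_marker=marker, kasp_concordance=kasp_concordance,
                          neighbors=neighbors, metrics=metrics)


def _is_hap2(label: str, haplotypes: assoc.HaplotypeAssignment,
             pop) -> bool:
    """True when the named haplotype label is the planted Hap2 (alt) group."""
    carriers = haplotypes.table.index[haplotypes.table["haplotype"] == label]
    if len(carriers) == 0:
        return False
    return bool((pop.haplotype.reindex(carriers) == 2).all())
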