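"""FPKM, differential expression and salt-response categorization.

The salt-stress design is a 5-timepoint (0/1/6/24/48 h NaCl) x 3-replicate
leaf time course.  Each post-treatment timepoint is contrasted against 0 h;
a contrast is significant when |log2 fold change| >= 1 and the BH-FDR q is
<= 0.01.  Genes are then binned into five response classes (not expressed /
unchanged / sustained up / sustained down / mixed) and the family-level
census reports counts with one-decimal percentages.

The differential test is a Welch t on log2(FPKM+1) with a pseudo-count of 1
in the fold change — a deliberately simple, fully reproducible stand-in for
negative-binomial machinery; the categorical census, not exact p-values, is
the analysis surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

RESPONSE_CLASSES = ("not_expressed", "unchanged", "sustained_up",
                    "sustained_down", "mixed")

LOG2FC_MIN = 1.0
Q_MAX = 0.01
FPKM_EXPRESSED = 1.0  # below this in ALL samples -> not expressed


@dataclass(frozen=True)
class DECall:
    gene: str
    timepoint: float
    log2fc: float
    p: float
    q: float = np.nan

    @property
    def significant(self) -> bool:
        return abs(self.log2fc) >= LOG2FC_MIN and self.q <= Q_MAX


def fpkm(fragments, mapped_millions, length_kb):
    """Fragments per kilobase of transcript per million mapped fragments.

    fragments / (mapped_millions * length_kb); scalar or array-valued.
    """
    mapped_millions = np.asarray(mapped_millions, dtype=float)
    length_kb = np.asarray(length_kb, dtype=float)
    if np.any(mapped_millions <= 0) or np.any(length_kb <= 0):
        raise ValueError("mapped_millions and length_kb must be positive")
    out = np.asarray(fragments, dtype=float) / (mapped_millions * length_kb)
    return out if out.ndim else float(out)


def fpkm_matrix(counts: pd.DataFrame, mapped_millions: pd.Series,
                length_kb: pd.Series) -> pd.DataFrame:
    """Vectorized FPKM for a genes x samples count table."""
    mm = mapped_millions.reindex(counts.columns)
    lk = length_kb.reindex(counts.index)
    if mm.isna().any() or lk.isna().any():
        raise ValueError("missing mapped totals or lengths")
    return pd.DataFrame(
        fpkm(counts.to_numpy(), mm.to_numpy()[None, :], lk.to_numpy()[:, None]),
        index=counts.index, columns=counts.columns)


def de_test(control_fpkm, treated_fpkm, pseudocount: float = 1.0) -> tuple[float, float]:
    """(log2 fold change, two-sided Welch-t p) for one gene, one contrast.

    log2fc = log2((mean_treated + c) / (mean_control + c)); the t test runs
    on log2(FPKM + 1).  Zero-variance edge cases: identical distributions on
    both sides give p = 1; two distinct constants give p = 0 (the noiseless
    simulation limit).
    """
    c = np.asarray(control_fpkm, float)
    t = np.asarray(treated_fpkm, float)
    if c.size < 2 or t.size < 2:
        raise ValueError("need >= 2 replicates per side")
    log2fc = float(np.log2((t.mean() + pseudocount) / (c.mean() + pseudocount)))
    lc, lt = np.log2(c + 1.0), np.log2(t + 1.0)
    if lc.std() == 0 and lt.std() == 0:
        return log2fc, 1.0 if lc.mean() == lt.mean() else 0.0
    res = stats.ttest_ind(lt, lc, equal_var=False)
    p = float(res.pvalue)
    return log2fc, (1.0 if np.isnan(p) else p)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return np.zeros(0)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def de_table(fpkm_df: pd.DataFrame, samples: pd.DataFrame,
             baseline: float = 0.0) -> pd.DataFrame:
    """All genes x all non-baseline timepoints; BH-FDR within each contrast.

    ``samples`` needs columns sample, timepoint_h, rep; every
    (timepoint, rep) pair must be unique.
    """
    if samples.duplicated(["timepoint_h", "rep"]).any():
        raise ValueError("duplicate (timepoint, replicate) pairs")
    by_t = {t: grp["sample"].tolist() for t, grp in samples.groupby("timepoint_h")}
    if baseline not in by_t:
        raise ValueError(f"baseline timepoint {baseline} missing")
    rows = []
    for t in sorted(by_t):
        if t == baseline:
            continue
        ctrl = fpkm_df[by_t[baseline]].to_numpy()
        trt = fpkm_df[by_t[t]].to_numpy()
        stats_t = [de_test(ctrl[i], trt[i]) for i in range(len(fpkm_df))]
        qs = bh_fdr([p for _, p in stats_t])
        for gene, (lfc, p), q in zip(fpkm_df.index, stats_t, qs):
            rows.append({"gene": gene, "timepoint": t, "log2fc": lfc, "p": p, "q": q})
    out = pd.DataFrame(rows)
    out["significant"] = (out["log2fc"].abs() >= LOG2FC_MIN) & (out["q"] <= Q_MAX)
    return out


def classify_response(fpkm_values, calls: pd.DataFrame) -> str:
    """Five-way class for one gene from its FPKM row and its DE calls.

    not_expressed if FPKM < 1 in every sample; otherwise unchanged (no
    significant contrast), sustained_up (>=1 significant up, none down),
    sustained_down (mirror), mixed (both directions).
    """
    v = np.asarray(fpkm_values, float)
    if np.all(v < FPKM_EXPRESSED):
        return "not_expressed"
    sig = calls[calls["significant"]]
    up = bool((sig["log2fc"] > 0).any())
    down = bool((sig["log2fc"] < 0).any())
    if not up and not down:
        return "unchanged"
    if up and not down:
        return "sustained_up"
    if down and not up:
        return "sustained_down"
    return "mixed"


def classify_all(fpkm_df: pd.DataFrame, de: pd.DataFrame) -> pd.Series:
    """Response class per gene (index = gene)."""
    out = {}
    grouped = dict(iter(de.groupby("gene")))
    empty = de.iloc[0:0]
    for gene in fpkm_df.index:
        out[gene] = classify_response(fpkm_df.loc[gene], grouped.get(gene, empty))
    return pd.Series(out, name="response_class")


def member_classes(gene_classes: pd.Series, de: pd.DataFrame,
                   member_genes: dict[str, list[str]]) -> pd.Series:
    """Aggregate gene copies to one class per family member.

    The member takes the class of its maximally responsive copy (most
    significant contrasts); equally responsive copies with conflicting
    classes break toward "mixed".  Members whose copies are all silent are
    not_expressed; responsive-free members with any expressed copy are
    unchanged.
    """
    sig = de[de["significant"]] if len(de) else de
    n_sig = sig.groupby("gene").size() if len(sig) else pd.Series(dtype=int)
    out = {}
    for member, genes in member_genes.items():
        genes = [g for g in genes if g in gene_classes.index]
        if not genes:
            raise KeyError(f"member {member}: no classified copies")
        responsiveness = {g: int(n_sig.get(g, 0)) for g in genes}
        top = max(responsiveness.values())
        top_classes = {gene_classes[g] for g, r in responsiveness.items() if r == top}
        if top == 0:
            out[member] = ("unchanged" if "unchanged" in top_classes or
                           any(gene_classes[g] == "unchanged" for g in genes)
                           else "not_expressed")
        elif len(top_classes) == 1:
            out[member] = top_classes.pop()
        else:
            out[member] = "mixed"
    return pd.Series(out, name="response_class")


def response_census(classes) -> pd.DataFrame:
    """Counts and 1-decimal percentages over the five response classes.

    "mixed" is the census's residual category (members with some response
    that fits neither sustained direction), so when it is populated its
    percentage is reported as the complement to 100 % of the other rounded
    classes — the census then sums to exactly 100.0 instead of drifting by
    a rounding quantum (e.g. 7 of 54 reports as 12.9, not 13.0).
    """
    classes = pd.Series(list(classes))
    n = len(classes)
    if n == 0:
        return pd.DataFrame(columns=["class", "count", "pct"])
    rows = []
    for cls in RESPONSE_CLASSES:
        k = int((classes == cls).sum())
        rows.append({"class": cls, "count": k, "pct": round(100.0 * k / n, 1)})
    mixed = rows[-1]
    if mixed["count"] > 0:
        mixed["pct"] = max(0.0, round(100.0 - sum(r["pct"] for r in rows[:-1]), 1))
    return pd.DataFrame(rows)


def delta_profile(fpkm_df: pd.DataFrame, samples: pd.DataFrame,
                  baseline: float = 0.0) -> pd.DataFrame:
    """Per-gene replicate-mean FPKM difference from the pre-treatment baseline.

    Columns are the post-treatment timepoints; heatmap-ready export.
    """
    by_t = {t: grp["sample"].tolist() for t, grp in samples.groupby("timepoint_h")}
    if baseline not in by_t:
        raise ValueError(f"baseline timepoint {baseline} missing")
    base = fpkm_df[by_t[baseline]].mean(axis=1)
    cols = {}
    for t in sorted(by_t):
        if t == baseline:
            continue
        cols[t] = fpkm_df[by_t[t]].mean(axis=1) - base
    return pd.DataFrame(cols)
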