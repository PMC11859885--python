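"""Focal-gene co-expression: normalization, soft threshold, neighbor picks.

Candidate target genes of a focal transcription factor are differentially
expressed genes that (i) carry the factor's binding element (GCC-box) in
their promoter, (ii) are expressed above an FPKM floor, and (iii) track the
focal gene's profile with a signed Pearson correlation at or above a high
threshold (default 0.9).  Candidates are ranked by the soft-thresholded
adjacency |r|^beta, with beta chosen by the usual scale-free topology
criterion.

Profiles are log2(FPKM+1)-transformed and then min-max scaled per gene
(this order keeps zeros finite; a min-max-first ordering would be
degenerate under a subsequent log).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

FALLBACK_BETA = 6


def normalize_profiles(fpkm_df: pd.DataFrame) -> pd.DataFrame:
    """Per gene: v = log2(FPKM+1), then (v - min)/(max - min), so each
    non-constant gene spans exactly [0, 1]; constant genes map to all-zeros
    (with a warning)."""
    v = np.log2(fpkm_df.to_numpy(float) + 1.0)
    lo = v.min(axis=1, keepdims=True)
    hi = v.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant gene(s) normalized to zeros",
                      stacklevel=2)
    span[flat] = 1.0
    out = (v - lo) / span
    out[flat] = 0.0
    return pd.DataFrame(out, index=fpkm_df.index, columns=fpkm_df.columns)


def zscore_matrix(fpkm_df: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score across samples using the population (1/n) sd.

    Heatmap export convention: row means 0, row sds 1; constant rows map to
    zeros with a warning.
    """
    v = fpkm_df.to_numpy(float)
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)  # population sd
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant gene(s) z-scored to zeros",
                      stacklevel=2)
    sd[flat] = 1.0
    out = (v - mean) / sd
    out[flat] = 0.0
    return pd.DataFrame(out, index=fpkm_df.index, columns=fpkm_df.columns)


def pick_soft_power(corr: pd.DataFrame | np.ndarray, powers=range(1, 21),
                    r2_min: float = 0.8, n_bins: int = 10,
                    mean_k_min: float = 0.5) -> int:
    """Smallest soft-threshold power giving an approximately scale-free network.

    For each beta the adjacency |r|^beta (diagonal excluded) yields node
    connectivities k; their distribution is binned (``n_bins`` equal-width
    bins) and log10 p(k) is regressed on log10 mean-k.  The power qualifies
    when the fit R^2 >= ``r2_min`` with a negative slope and the mean
    connectivity still reaches ``mean_k_min`` — without the connectivity
    floor, high powers make even independent-noise profiles look
    heavy-tailed as k collapses toward zero.  If no power qualifies the
    conventional fallback beta=6 is returned with a warning.
    """
    C = np.asarray(corr, float)
    if C.shape[0] < 20:
        raise ValueError("need >= 20 genes to assess scale-free fit")
    A0 = np.abs(C).copy()
    np.fill_diagonal(A0, 0.0)
    for beta in powers:
        k = (A0 ** beta).sum(axis=1)
        if k.mean() < mean_k_min:
            continue
        fit = _scale_free_r2(k, n_bins)
        if fit is not None:
            r2, slope = fit
            if r2 >= r2_min and slope < 0:
                return int(beta)
    warnings.warn(f"no power reaches scale-free R^2 >= {r2_min}; "
                  f"falling back to beta={FALLBACK_BETA}", stacklevel=2)
    return FALLBACK_BETA


def _scale_free_r2(k: np.ndarray, n_bins: int):
    """(R^2, slope) of log10 p(k) on log10 mean-k over occupancy bins, or None."""
    k = k[k > 0]
    if k.size == 0 or k.max() == k.min():
        return None
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 2:
        return None
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * np.asarray(xs) + intercept
    ss_res = float(((np.asarray(ys) - pred) ** 2).sum())
    ss_tot = float(((np.asarray(ys) - np.mean(ys)) ** 2).sum())
    if ss_tot == 0:
        return None
    return 1.0 - ss_res / ss_tot, slope


def focal_neighbors(focal_gene: str, fpkm_df: pd.DataFrame,
                    deg_flags: pd.Series, gcc_flags: pd.Series,
                    beta: int = FALLBACK_BETA, r_min: float = 0.9,
                    fpkm_floor: float = 1.0) -> pd.DataFrame:
    """Candidate targets of the focal gene, ranked by adjacency |r|^beta.

    Candidates must be differentially expressed, carry a promoter GCC-box,
    reach ``fpkm_floor`` in at least one sample, and correlate with the
    focal profile at signed Pearson r >= ``r_min`` (an anti-correlated gene
    never qualifies at positive r_min).  The focal gene itself must pass
    the expression floor.
    """
    if focal_gene not in fpkm_df.index:
        raise KeyError(focal_gene)
    if float(fpkm_df.loc[focal_gene].max()) < fpkm_floor:
        raise ValueError(f"focal gene {focal_gene} below the FPKM floor")
    norm = normalize_profiles(fpkm_df)
    focal = norm.loc[focal_gene].to_numpy()
    rows = []
    for gene in fpkm_df.index:
        if gene == focal_gene:
            continue
        if not bool(deg_flags.get(gene, False)) or not bool(gcc_flags.get(gene, False)):
            continue
        max_fpkm = float(fpkm_df.loc[gene].max())
        if max_fpkm < fpkm_floor:
            continue
        x = norm.loc[gene].to_numpy()
        if x.std() == 0 or focal.std() == 0:
            continue
        r = float(np.corrcoef(focal, x)[0, 1])
        if r < r_min:
            continue
        rows.append({"gene": gene, "r": r, "adjacency": abs(r) ** beta,
                     "max_fpkm": max_fpkm})
    out = pd.DataFrame(rows, columns=["gene", "r", "adjacency", "max_fpkm"])
    return out.sort_values("adjacency", ascending=False, kind="stable").reset_index(drop=True)
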