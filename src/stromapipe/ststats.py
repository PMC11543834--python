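"""Spot-level filtering, cell-count normalization and correlation analyses.

Counts are normalized to a per-spot cell basis: each spot's counts are
divided by its nuclei count and rescaled to the cohort median nuclei count
(21 in the reference dataset), then rounded half-away-from-zero back to
integers.  Genes must reach 10 total reads and be detected in 10 spots;
normalized spots must retain 40 detected genes and 100 total counts.

Correlations are Spearman throughout (average ranks for ties, t
approximation with n-2 df for the p-value), computed on log2(count + 1)
expression where expression is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import PipelineConfig


@dataclass
class NormalizedCounts:
    """Cell-count-normalized integer counts plus the scale target used."""

    counts: pd.DataFrame  # genes x spots, integers
    cell_counts: pd.Series  # per retained spot
    median_cell_count: int


def filter_genes(counts: pd.DataFrame, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Keep genes with >= min_gene_reads total reads AND nonzero counts in
    >= min_gene_spots spots."""
    cfg = cfg or PipelineConfig()
    arr = counts.to_numpy()
    keep = (arr.sum(axis=1) >= cfg.min_gene_reads) & (
        (arr > 0).sum(axis=1) >= cfg.min_gene_spots
    )
    return counts.loc[keep]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def normalize_cell_count(
    counts: pd.DataFrame,
    cell_counts: pd.Series,
    target: int | None = None,
) -> NormalizedCounts:
    """Rescale each spot's counts to a common cell-count basis.

    out_gs = round(counts_gs / n_s * target); target defaults to the median
    cell count over the supplied spots.  Spots with cell count 0 are dropped
    (their counts cannot be put on a per-cell basis).
    """
    cc = cell_counts.reindex(counts.columns)
    if cc.isna().any():
        missing = list(counts.columns[cc.isna()])[:5]
        raise ValueError(f"spots without cell counts: {missing}")
    keep = cc > 0
    if (~keep).any():
        import warnings

        warnings.warn(
            f"dropping {int((~keep).sum())} spot(s) with cell count 0", stacklevel=2
        )
    counts = counts.loc[:, keep]
    cc = cc[keep].astype(int)
    if target is None:
        target = int(np.median(cc.to_numpy()))
    scaled = counts.to_numpy(float) / cc.to_numpy(float)[None, :] * target
    out = pd.DataFrame(
        _round_half_away(scaled).astype(np.int64),
        index=counts.index,
        columns=counts.columns,
    )
    return NormalizedCounts(counts=out, cell_counts=cc, median_cell_count=int(target))


def filter_spots(norm: NormalizedCounts, cfg: PipelineConfig | None = None) -> NormalizedCounts:
    """Keep spots with >= min_spot_genes detected genes AND a normalized
    total of >= min_spot_total."""
    cfg = cfg or PipelineConfig()
    arr = norm.counts.to_numpy()
    keep = ((arr > 0).sum(axis=0) >= cfg.min_spot_genes) & (
        arr.sum(axis=0) >= cfg.min_spot_total
    )
    return NormalizedCounts(
        counts=norm.counts.loc[:, keep],
        cell_counts=norm.cell_counts[keep],
        median_cell_count=norm.median_cell_count,
    )


def log2p1(counts) -> np.ndarray:
    return np.log2(np.asarray(counts, float) + 1.0)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with average-rank ties; p from the t approximation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs for a p-value")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def rank_coexpression(norm: NormalizedCounts, target_gene: str) -> pd.DataFrame:
    """Spearman correlation of the target gene with every other gene across
    retained spots, on log2(count+1), ranked by descending rho."""
    if target_gene not in norm.counts.index:
        raise KeyError(f"gene {target_gene!r} not in matrix")
    L = log2p1(norm.counts.to_numpy())
    genes = list(norm.counts.index)
    ti = genes.index(target_gene)
    target = L[ti]
    rows = []
    for gi, g in enumerate(genes):
        if gi == ti:
            continue
        if np.ptp(L[gi]) == 0 or np.ptp(target) == 0:
            rows.append((g, np.nan, np.nan, L.shape[1]))
            continue
        rho, p = sps.spearmanr(target, L[gi])
        rows.append((g, float(rho), float(p), L.shape[1]))
    out = pd.DataFrame(rows, columns=["gene", "rho", "p", "n"])
    out = out.sort_values("rho", ascending=False, na_position="last").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def cross_compartment_correlation(
    norm: NormalizedCounts,
    calls: pd.Series,
    samples: pd.Series,
    gene_a: str,
    classes_a: list[str],
    gene_b: str,
    classes_b: list[str],
) -> dict:
    """Correlate per-sample mean expression of gene A in one histology
    compartment with gene B in another.

    For each sample, mean log2(count+1) of gene A over spots called in
    classes_a and of gene B over spots in classes_b; Spearman across samples.
    """
    calls = calls.reindex(norm.counts.columns)
    samples = samples.reindex(norm.counts.columns)
    la = pd.Series(log2p1(norm.counts.loc[gene_a]), index=norm.counts.columns)
    lb = pd.Series(log2p1(norm.counts.loc[gene_b]), index=norm.counts.columns)
    pairs = []
    for s in samples.dropna().unique():
        in_s = samples == s
        sel_a = in_s & calls.isin(classes_a)
        sel_b = in_s & calls.isin(classes_b)
        if sel_a.any() and sel_b.any():
            pairs.append((float(la[sel_a].mean()), float(lb[sel_b].mean())))
    if len(pairs) < 3:
        raise ValueError(
            f"only {len(pairs)} samples have spots in both compartments (need >= 3)"
        )
    a, b = zip(*pairs)
    rho, p = sps.spearmanr(a, b)
    return {
        "pair": f"{gene_a}[{'+'.join(classes_a)}] vs {gene_b}[{'+'.join(classes_b)}]",
        "rho": float(rho),
        "p": float(p),
        "n": len(pairs),
    }


def celltype_fraction_correlation(
    norm: NormalizedCounts, fractions: pd.DataFrame, target_gene: str
) -> pd.DataFrame:
    """Spearman correlation of the target gene's expression with each supplied
    per-spot cell-type fraction.

    ``fractions`` is spots x cell types, rows aligned to norm's spots; types
    with a constant fraction yield an undefined rho, reported as missing.
    """
    common = norm.counts.columns.intersection(fractions.index)
    if len(common) < 3:
        raise ValueError("need >= 3 spots shared between counts and fractions")
    expr = log2p1(norm.counts.loc[target_gene, common])
    rows = []
    for ct in fractions.columns:
        f = fractions.loc[common, ct].to_numpy(float)
        if np.ptp(f) == 0 or np.ptp(expr) == 0:
            rows.append((ct, np.nan, np.nan, len(common)))
            continue
        rho, p = sps.spearmanr(expr, f)
        rows.append((ct, float(rho), float(p), len(common)))
    out = pd.DataFrame(rows, columns=["cell_type", "rho", "p", "n"])
    return out.sort_values("rho", ascending=False, na_position="last").reset_index(drop=True)
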