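"""Positional specificity statistics for the germinal-center niche.

Per-gene positive-predictive value (PPV) of GC positioning among Tfh,
its rank/percentile convention, Wilcoxon rank-sum contrasts with multiple
testing control, the three-way contamination-aware specificity
integration, nearest-cell distances, and kernel-smoothed distance-decay
curves.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ValidationError
from .io import CellTable, CountMatrix
from .util import library_size_normalize


def call_positivity(counts: CountMatrix, threshold: int = 1) -> sparse.csr_matrix:
    """Boolean gene×cell matrix: positive iff raw count >= threshold."""
    if threshold < 1:
        raise ParameterError("positivity threshold must be >= 1")
    X = counts.X.tocsr()
    out = X.copy()
    out.data = (out.data >= threshold)
    out.eliminate_zeros()
    return out.astype(bool)


def gc_ppv(
    positivity: sparse.spmatrix,
    genes,
    tfh_mask: np.ndarray,
    in_gc: np.ndarray,
    min_pos: int = 20,
) -> pd.DataFrame:
    """Per-gene GC positive-predictive value among positive Tfh.

    PPV = (positive Tfh inside the GC mask) / (positive Tfh).  Genes with
    fewer than ``min_pos`` positive Tfh are reported but flagged as not
    included, so they stay out of the ranking.
    """
    tfh_mask = np.asarray(tfh_mask, dtype=bool)
    in_gc = np.asarray(in_gc, dtype=bool)
    if tfh_mask.sum() == 0:
        raise ValidationError("no Tfh cells in the dataset; PPV is undefined")
    P = sparse.csr_matrix(positivity)
    n_pos = np.asarray(P[:, tfh_mask].sum(axis=1)).ravel().astype(int)
    n_pos_gc = np.asarray(P[:, tfh_mask & in_gc].sum(axis=1)).ravel().astype(int)
    with np.errstate(invalid="ignore"):
        ppv = np.where(n_pos > 0, n_pos_gc / np.maximum(n_pos, 1), np.nan)
    return pd.DataFrame({
        "gene": np.asarray(genes, dtype=object),
        "n_pos_tfh": n_pos,
        "n_pos_tfh_in_gc": n_pos_gc,
        "ppv": ppv,
        "included": n_pos >= min_pos,
    })


def rank_percentile(rows: pd.DataFrame) -> pd.DataFrame:
    """Rank included genes by PPV and attach percentiles.

    Included genes are sorted by PPV descending (ties: more positive Tfh
    first, then gene name); rank 1 is the highest PPV and
    percentile = 100·(1 − (rank − 1)/n), reported to one decimal, so rank 1
    maps to 100.0 and rank 25 of 5,101 to 99.5.
    """
    if not rows["included"].any():
        raise ValidationError("no included genes to rank")
    out = rows.copy()
    out["rank"] = pd.array([pd.NA] * len(out), dtype="Int64")
    out["percentile"] = np.nan
    inc = out[out["included"]].sort_values(
        by=["ppv", "n_pos_tfh", "gene"], ascending=[False, False, True], kind="mergesort"
    )
    n = len(inc)
    ranks = np.arange(1, n + 1)
    out.loc[inc.index, "rank"] = ranks
    out.loc[inc.index, "percentile"] = np.round(100.0 * (1.0 - (ranks - 1) / n), 1)
    return out.sort_values(
        by=["included", "ppv", "n_pos_tfh", "gene"],
        ascending=[False, False, False, True], kind="mergesort",
    ).reset_index(drop=True)


@dataclass
class ContrastResult:
    """Per-gene log2FC / p / adjusted p for one named two-group comparison."""

    name: str
    table: pd.DataFrame  # gene, log2fc, p_value, p_adj, n_group1, n_group2


def _dense(X, cols):
    if sparse.issparse(X):
        return X[:, cols].toarray()
    return np.asarray(X, dtype=float)[:, cols]


def wilcoxon_contrast(
    X,
    genes,
    group1: np.ndarray,
    group2: np.ndarray,
    *,
    pseudocount: float = 1e-9,
    mt_method: str = "bonferroni",
    normalize: bool = True,
    name: str = "",
) -> ContrastResult:
    """Two-sided Wilcoxon rank-sum test per gene between two cell groups.

    ``group1``/``group2`` are disjoint boolean masks or index arrays over
    the cell axis of ``X`` (genes × cells).  For count data, values are
    library-size normalized before the fold-change; the test itself is rank
    based, so normalization affects only log2FC.  Small tie-free groups
    (both sizes ≤ 8) use the exact null distribution; otherwise the normal
    approximation with tie and continuity corrections.  log2FC =
    log2((mean1 + ε)/(mean2 + ε)); multiplicity control is Bonferroni by
    default, Benjamini–Hochberg by request.
    """
    n_cells = X.shape[1]
    g1 = _as_index(group1, n_cells)
    g2 = _as_index(group2, n_cells)
    if np.intersect1d(g1, g2).size:
        raise ValidationError("contrast groups overlap")
    if len(g1) < 3 or len(g2) < 3:
        raise ParameterError("each contrast group needs at least 3 cells")
    if mt_method not in ("bonferroni", "fdr_bh"):
        raise ParameterError(f"unknown mt_method {mt_method!r}")

    Xn = library_size_normalize(X) if normalize else X
    x1 = _dense(Xn, g1)
    x2 = _dense(Xn, g2)

    small = max(len(g1), len(g2)) <= 8
    if small:
        p = np.empty(x1.shape[0])
        for i in range(x1.shape[0]):
            if np.ptp(np.concatenate([x1[i], x2[i]])) == 0:
                p[i] = 1.0
            else:
                p[i] = mannwhitneyu(x1[i], x2[i], alternative="two-sided", method="auto").pvalue
    else:
        const = np.array([
            np.ptp(np.concatenate([x1[i], x2[i]])) == 0 for i in range(x1.shape[0])
        ])
        p = np.ones(x1.shape[0])
        if (~const).any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = mannwhitneyu(
                    x1[~const], x2[~const], alternative="two-sided",
                    method="asymptotic", use_continuity=True, axis=1,
                )
            p[~const] = np.nan_to_num(res.pvalue, nan=1.0)
    p = np.clip(p, 0.0, 1.0)

    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2((m1 + pseudocount) / (m2 + pseudocount))
    p_adj = multipletests(p, method=mt_method)[1]
    table = pd.DataFrame({
        "gene": np.asarray(genes, dtype=object),
        "log2fc": log2fc,
        "p_value": p,
        "p_adj": p_adj,
        "n_group1": len(g1),
        "n_group2": len(g2),
    })
    return ContrastResult(name=name, table=table)


def _as_index(group, n):
    group = np.asarray(group)
    if group.dtype == bool:
        if len(group) != n:
            raise ValidationError("boolean group mask length does not match cell axis")
        return np.flatnonzero(group)
    return group.astype(int)


def three_way_specificity(
    spatial_counts: CountMatrix,
    tfh_mask: np.ndarray,
    in_gc: np.ndarray,
    reference_counts: CountMatrix,
    reference_labels,
    *,
    tfh_label: str = "Tfh",
    alpha: float = 0.05,
    pseudocount: float = 1e-9,
) -> pd.DataFrame:
    """Three-contrast specificity integration over mutually covered genes.

    Per gene: (1) spatial Tfh inside vs outside the GC mask, (2) Tfh vs all
    other cells within the GC, (3) dissociated-reference Tfh vs all other
    lineages.  ``passes_filter`` requires Bonferroni-adjusted p < alpha in
    all three contrasts.  A gene expressed by GC B cells shows up here with
    a positive in-GC fold change but a negative reference fold change — the
    signature of spillover contamination rather than genuine Tfh
    expression.
    """
    shared = [g for g in spatial_counts.genes if g in set(reference_counts.genes)]
    if not shared:
        raise ValidationError("spatial and reference panels share no genes")
    sp = spatial_counts.subset_genes(shared)
    ref = reference_counts.subset_genes(shared)
    tfh_mask = np.asarray(tfh_mask, dtype=bool)
    in_gc = np.asarray(in_gc, dtype=bool)
    ref_labels = np.asarray(
        reference_labels.labels.values if hasattr(reference_labels, "labels") else reference_labels,
        dtype=object,
    )
    ref_tfh = ref_labels == tfh_label

    c1 = wilcoxon_contrast(
        sp.X, shared, tfh_mask & in_gc, tfh_mask & ~in_gc,
        pseudocount=pseudocount, name="tfh_gc_vs_out",
    )
    c2 = wilcoxon_contrast(
        sp.X, shared, tfh_mask & in_gc, ~tfh_mask & in_gc,
        pseudocount=pseudocount, name="tfh_vs_other_in_gc",
    )
    c3 = wilcoxon_contrast(
        ref.X, shared, ref_tfh, ~ref_tfh,
        pseudocount=pseudocount, name="reference_tfh_vs_other",
    )
    out = pd.DataFrame({
        "gene": shared,
        "lfc_gc_vs_out": c1.table["log2fc"].values,
        "p_adj_gc_vs_out": c1.table["p_adj"].values,
        "lfc_tfh_vs_other_in_gc": c2.table["log2fc"].values,
        "p_adj_tfh_vs_other_in_gc": c2.table["p_adj"].values,
        "lfc_reference": c3.table["log2fc"].values,
        "p_adj_reference": c3.table["p_adj"].values,
    })
    out["passes_filter"] = (
        (out["p_adj_gc_vs_out"] < alpha)
        & (out["p_adj_tfh_vs_other_in_gc"] < alpha)
        & (out["p_adj_reference"] < alpha)
    )
    return out


def distance_to_nearest(cells: CellTable, target_mask: np.ndarray) -> pd.Series:
    """Distance from each cell to the nearest target cell in its sample.

    Target cells get distance 0.  Samples without any target cell get NaN
    for all their cells, with a warning.
    """
    target_mask = np.asarray(target_mask, dtype=bool)
    if len(target_mask) != len(cells):
        raise ValidationError("target mask length does not match the cell table")
    xy = cells.xy
    sample = cells.sample_ids
    dist = np.full(len(cells), np.nan)
    for sid in pd.unique(sample):
        idx = np.flatnonzero(sample == sid)
        targets = idx[target_mask[idx]]
        if len(targets) == 0:
            warnings.warn(f"sample '{sid}' has no target cells; distances are NaN", stacklevel=2)
            continue
        tree = cKDTree(xy[targets])
        dist[idx], _ = tree.query(xy[idx], k=1)
    return pd.Series(dist, index=cells.cell_ids, name="distance_um")


@dataclass
class DecayCurve:
    """Kernel-smoothed mean expression as a function of distance."""

    gene: str
    grid: np.ndarray
    values: np.ndarray   # NaN where no cell lies within 3 bandwidths
    bandwidth: float


def smoothed_decay(
    expr: np.ndarray,
    distances: np.ndarray,
    bandwidth: float = 25.0,
    grid: np.ndarray | None = None,
    gene: str = "",
) -> DecayCurve:
    """Nadaraya–Watson Gaussian-kernel regression of expression on distance."""
    if bandwidth <= 0:
        raise ParameterError("bandwidth must be positive")
    expr = np.asarray(expr, dtype=float)
    distances = np.asarray(distances, dtype=float)
    ok = np.isfinite(distances) & np.isfinite(expr)
    expr, distances = expr[ok], distances[ok]
    if len(expr) == 0:
        raise ValidationError("no cells with finite expression and distance")
    if grid is None:
        grid = np.arange(0.0, 300.0 + 1e-9, 5.0)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ParameterError("grid must be strictly increasing")
    d = distances[None, :] - grid[:, None]
    w = np.exp(-0.5 * (d / bandwidth) ** 2)
    has_support = (np.abs(d) <= 3 * bandwidth).any(axis=1)
    denom = w.sum(axis=1)
    values = np.full(len(grid), np.nan)
    values[has_support] = (w @ expr)[has_support] / denom[has_support]
    return DecayCurve(gene=gene, grid=grid, values=values, bandwidth=float(bandwidth))
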