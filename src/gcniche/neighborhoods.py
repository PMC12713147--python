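"""Cellular neighborhoods and the merged, hole-filled GC mask.

A cell's neighborhood is the cell-type composition of its k nearest
neighbors (self included).  K-means over these composition vectors across
all samples jointly yields cellular neighborhoods (CNs); declarative rules
annotate CNs from their type composition; and the union of GC-annotated
CNs, rasterized, morphologically closed, and flood-filled from the border,
defines the merged germinal-center mask that anchors every positional
statistic.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import disk
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .errors import AmbiguityError, ParameterError, ValidationError
from .io import CellTable, DEFAULT_TYPE_VOCAB


def knn_composition(cells: CellTable, k: int = 20, categories=None):
    """Type-composition vector of each cell's k-nearest-neighbor window.

    The window contains the cell itself plus its k−1 nearest neighbors
    within the same sample (Euclidean distance on centroids).  Returns
    ``(composition, categories)`` where composition is (cells × categories)
    and every row sums to 1.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if categories is None:
        categories = [t for t in DEFAULT_TYPE_VOCAB if t in set(cells.type_l1)]
        extra = sorted(set(cells.type_l1) - set(categories))
        categories = list(categories) + extra
    cat_ix = {c: i for i, c in enumerate(categories)}
    try:
        type_idx = np.array([cat_ix[t] for t in cells.type_l1])
    except KeyError as exc:
        raise ValidationError(f"type label {exc} missing from categories") from exc
    xy = cells.xy
    sample = cells.sample_ids
    comp = np.zeros((len(cells), len(categories)))
    for sid in pd.unique(sample):
        idx = np.flatnonzero(sample == sid)
        if len(idx) <= k:
            raise ParameterError(
                f"sample '{sid}' has only {len(idx)} cells; need more than k={k}"
            )
        tree = cKDTree(xy[idx])
        _, nn = tree.query(xy[idx], k=k)  # self is its own nearest neighbor
        window_types = type_idx[idx][nn]
        for j in range(len(categories)):
            comp[idx, j] = (window_types == j).sum(axis=1)
    comp /= k
    return comp, list(categories)


class NeighborhoodClusterer(BaseEstimator, ClusterMixin):
    """K-means cellular neighborhoods over k-NN composition vectors.

    Parameters
    ----------
    k : int
        Neighborhood window size (self included).
    n_neighborhoods : int
        Number of CNs to resolve.
    n_init : int
        K-means restarts (k-means++ initialization).
    random_state : int or None
        Seed for k-means.

    Attributes (after ``fit``)
    --------------------------
    categories_ : list of type labels defining composition columns
    composition_ : (cells × categories) window compositions
    labels_ : per-cell CN id in ``[0, n_neighborhoods)``
    cluster_centers_ : per-CN composition centroid
    enrichment_ : DataFrame, per-CN type fraction ÷ global type fraction
    fractions_ : DataFrame, per-CN member-cell type fractions
    annotations_ : dict cn_id → label (after :func:`annotate_neighborhoods`)
    """

    def __init__(self, k: int = 20, n_neighborhoods: int = 10, n_init: int = 10,
                 random_state: int | None = None):
        self.k = k
        self.n_neighborhoods = n_neighborhoods
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, cells: CellTable, y=None):
        if self.n_neighborhoods < 2:
            raise ParameterError("n_neighborhoods must be >= 2")
        comp, categories = knn_composition(cells, k=self.k)
        n_distinct = len(np.unique(comp, axis=0))
        if self.n_neighborhoods > n_distinct:
            raise ParameterError(
                f"n_neighborhoods={self.n_neighborhoods} exceeds the "
                f"{n_distinct} distinct composition vectors"
            )
        km = KMeans(
            n_clusters=self.n_neighborhoods, n_init=self.n_init,
            random_state=self.random_state,
        ).fit(comp)
        self.categories_ = categories
        self.composition_ = comp
        self.labels_ = km.labels_.astype(int)
        self.cluster_centers_ = km.cluster_centers_
        self._kmeans = km
        self.fractions_, self.enrichment_ = _cn_type_tables(
            cells.type_l1, self.labels_, categories
        )
        self.annotations_ = None
        return self

    def predict(self, cells: CellTable) -> np.ndarray:
        comp, _ = knn_composition(cells, k=self.k, categories=self.categories_)
        return self._kmeans.predict(comp)

    def fit_predict(self, cells: CellTable, y=None) -> np.ndarray:
        return self.fit(cells).labels_


def _cn_type_tables(type_l1, labels, categories):
    n_cn = int(labels.max()) + 1
    frac = pd.DataFrame(0.0, index=range(n_cn), columns=categories)
    for cn in range(n_cn):
        member = type_l1[labels == cn]
        if len(member):
            counts = pd.Series(member).value_counts()
            for t in categories:
                frac.loc[cn, t] = counts.get(t, 0) / len(member)
    global_frac = pd.Series(type_l1).value_counts(normalize=True)
    enrich = frac.copy()
    for t in categories:
        g = global_frac.get(t, 0.0)
        enrich[t] = frac[t] / g if g > 0 else np.nan
    return frac, enrich


@dataclass(frozen=True)
class Condition:
    """One clause of an annotation rule: ``metric(type) op value``."""

    type_name: str
    metric: str   # 'fraction' or 'enrichment'
    op: str       # '>', '>=', '<', '<='
    value: float

    def holds(self, fractions: pd.Series, enrichment: pd.Series) -> bool:
        table = fractions if self.metric == "fraction" else enrichment
        x = float(table.get(self.type_name, 0.0))
        if np.isnan(x):
            x = 0.0
        return {
            ">": x > self.value, ">=": x >= self.value,
            "<": x < self.value, "<=": x <= self.value,
        }[self.op]


@dataclass(frozen=True)
class Rule:
    label: str
    conditions: tuple


# Default rules, written on member-cell type fractions and kept mutually
# exclusive so no CN can fire two of them.  Unmatched CNs become "Other";
# GC-interior CNs left unmatched are recovered later by hole-filling.
DEFAULT_RULES = (
    Rule("GC_LZ", (
        Condition("LZ_GCB", "fraction", ">", 0.2),
        Condition("DZ_GCB", "fraction", "<=", 0.2),
        Condition("NaiveB", "fraction", "<=", 0.5),
    )),
    Rule("GC_DZ", (
        Condition("DZ_GCB", "fraction", ">", 0.2),
        Condition("LZ_GCB", "fraction", "<=", 0.2),
        Condition("NaiveB", "fraction", "<=", 0.5),
    )),
    Rule("Mantle", (
        Condition("NaiveB", "fraction", ">", 0.5),
    )),
    Rule("TZone", (
        Condition("nnCD4", "fraction", ">", 0.35),
        Condition("NaiveB", "fraction", "<=", 0.5),
        Condition("LZ_GCB", "fraction", "<=", 0.2),
        Condition("DZ_GCB", "fraction", "<=", 0.2),
        Condition("Epithelium", "fraction", "<=", 0.4),
    )),
    Rule("Epithelium", (
        Condition("Epithelium", "fraction", ">", 0.4),
        Condition("nnCD4", "fraction", "<=", 0.35),
        Condition("NaiveB", "fraction", "<=", 0.5),
        Condition("LZ_GCB", "fraction", "<=", 0.2),
        Condition("DZ_GCB", "fraction", "<=", 0.2),
    )),
)


def annotate_neighborhoods(model: NeighborhoodClusterer, rules=DEFAULT_RULES) -> dict:
    """Label each CN by its uniquely matching rule.

    Raises :class:`AmbiguityError` if two rules fire for one CN; CNs with
    no matching rule are labeled ``"Other"``.
    """
    annotations = {}
    for cn in model.fractions_.index:
        frac = model.fractions_.loc[cn]
        enr = model.enrichment_.loc[cn]
        matched = [r.label for r in rules if all(c.holds(frac, enr) for c in r.conditions)]
        if len(matched) > 1:
            raise AmbiguityError(
                f"CN {cn} matches multiple annotation rules: {', '.join(matched)}"
            )
        annotations[int(cn)] = matched[0] if matched else "Other"
    model.annotations_ = annotations
    return annotations


@dataclass
class MaskGrid:
    origin: tuple     # (x0, y0) of the raster's top-left bin corner, µm
    bin_um: float
    raster: np.ndarray  # bool, indexed [row=y, col=x]


@dataclass
class RegionMask:
    """Raster + per-cell boolean encoding of the merged GC compartment."""

    grids: dict                 # sample_id -> MaskGrid
    in_gc: pd.Series            # index: cell_id
    provenance: dict = field(default_factory=dict)


def close_and_fill(raster: np.ndarray, closing_radius: int) -> np.ndarray:
    """Binary closing followed by border flood-fill hole removal.

    The raster is padded before closing so border bins are not eroded; the
    result is always a superset of the input and the operation is
    idempotent.
    """
    raster = np.asarray(raster, dtype=bool)
    if closing_radius > 0:
        pad = closing_radius + 1
        padded = np.pad(raster, pad, constant_values=False)
        closed = ndimage.binary_closing(padded, structure=disk(closing_radius))
        closed = closed[pad:-pad, pad:-pad]
        closed |= raster  # guard against any erosion of single-pixel detail
    else:
        closed = raster.copy()
    return ndimage.binary_fill_holes(closed)


def merge_gc_mask(
    cells: CellTable,
    cn_labels: np.ndarray,
    gc_cn_ids,
    bin_um: float = 20.0,
    closing_radius: int = 2,
) -> RegionMask:
    """Merge GC-annotated CNs into one hole-filled spatial mask.

    Cells assigned to any CN in ``gc_cn_ids`` are rasterized per sample at
    ``bin_um`` resolution; the raster is closed with a disk of
    ``closing_radius`` bins and every enclosed background component is
    filled.  A cell is inside the GC iff its containing bin is true.
    """
    gc_cn_ids = list(gc_cn_ids)
    if len(gc_cn_ids) == 0:
        raise ParameterError("gc_cn_ids must be a non-empty set of CN ids")
    if bin_um <= 0:
        raise ParameterError("bin_um must be positive")
    cn_labels = np.asarray(cn_labels)
    if len(cn_labels) != len(cells):
        raise ValidationError("cn_labels length does not match the cell table")
    is_gc_cell = np.isin(cn_labels, gc_cn_ids)
    if not is_gc_cell.any():
        warnings.warn("no cell is assigned to any GC CN; mask is empty", stacklevel=2)

    xy = cells.xy
    sample = cells.sample_ids
    in_gc = np.zeros(len(cells), dtype=bool)
    grids = {}
    for sid in pd.unique(sample):
        idx = np.flatnonzero(sample == sid)
        x0, y0 = xy[idx, 0].min() - bin_um, xy[idx, 1].min() - bin_um
        nx = int(np.floor((xy[idx, 0].max() - x0) / bin_um)) + 2
        ny = int(np.floor((xy[idx, 1].max() - y0) / bin_um)) + 2
        cols = np.floor((xy[idx, 0] - x0) / bin_um).astype(int)
        rows = np.floor((xy[idx, 1] - y0) / bin_um).astype(int)
        raster = np.zeros((ny, nx), dtype=bool)
        gc_here = is_gc_cell[idx]
        raster[rows[gc_here], cols[gc_here]] = True
        filled = close_and_fill(raster, closing_radius)
        in_gc[idx] = filled[rows, cols]
        grids[sid] = MaskGrid((x0, y0), bin_um, filled)

    return RegionMask(
        grids=grids,
        in_gc=pd.Series(in_gc, index=cells.cell_ids),
        provenance={"gc_cn_ids": gc_cn_ids, "bin_um": bin_um, "closing_radius": closing_radius},
    )
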