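"""Synthetic tonsil tissue with known ground truth.

The generator lays out secondary lymphoid follicles — germinal centers
split into a light zone (LZ) and dark zone (DZ), wrapped in a naive-B
mantle — inside a T-cell zone with an epithelial band, places cells by
region-wise homogeneous Poisson point processes, samples cell types from
region-conditioned compositions, and draws probe counts from a
negative-binomial model whose means are set by a gene-program table.
Cell-to-cell contamination, the dominant artifact of imaging-based spatial
assays, is applied after clean sampling through three channels: transcript
diffusion to nearby cells, segmentation swaps with the nearest neighbor,
and additive vertical overlap with a phantom co-located cell.

Ground truth (each cell's region and type before contamination, each
gene's program class and its in-GC positivity fraction among Tfh) is
recorded so every downstream statistic can be checked against what was
planted.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .errors import GCNicheError, ParameterError
from .io import CellTable, CountMatrix, LabelMap
from .util import substream

REGIONS = ("GC_LZ", "GC_DZ", "Mantle", "TZone", "Epithelium")
TYPES = ("Tfh", "nnCD4", "LZ_GCB", "DZ_GCB", "NaiveB", "FDC", "Epithelium", "Other")
GENE_CLASSES = (
    "gc_tfh_restricted",
    "pan_tfh",
    "gc_associated_unrestricted",
    "gcb_restricted",
    "fdc_restricted",
    "non_gc_tfh",
    "housekeeping",
)

#: cells per µm² by region
DEFAULT_DENSITIES = {
    "GC_LZ": 0.013,
    "GC_DZ": 0.013,
    "Mantle": 0.013,
    "TZone": 0.0062,
    "Epithelium": 0.009,
}

#: P(type | region); each row sums to 1
DEFAULT_COMPOSITION = {
    "GC_LZ": {"Tfh": 0.17, "nnCD4": 0.06, "LZ_GCB": 0.52, "NaiveB": 0.05, "FDC": 0.12, "Other": 0.08},
    "GC_DZ": {"Tfh": 0.08, "nnCD4": 0.06, "DZ_GCB": 0.68, "NaiveB": 0.05, "FDC": 0.03, "Other": 0.10},
    "Mantle": {"Tfh": 0.09, "nnCD4": 0.12, "NaiveB": 0.66, "Other": 0.13},
    "TZone": {"Tfh": 0.10, "nnCD4": 0.52, "NaiveB": 0.16, "Other": 0.22},
    "Epithelium": {"Epithelium": 0.82, "nnCD4": 0.06, "NaiveB": 0.04, "Other": 0.08},
}

_CLASS_PANEL = {
    # class: (n genes, baseline mean, restricted fold)
    "gc_tfh_restricted": (4, 0.08, 60.0),
    "pan_tfh": (16, 0.05, 30.0),
    "gc_associated_unrestricted": (16, 0.05, 45.0),
    "gcb_restricted": (20, 0.08, 50.0),
    "fdc_restricted": (10, 0.08, 50.0),
    "non_gc_tfh": (14, 0.05, 30.0),
    "housekeeping": (120, None, 1.0),
}

_CLASS_PREFIX = {
    "gc_tfh_restricted": "GCTFH",
    "pan_tfh": "PANTFH",
    "gc_associated_unrestricted": "GCASSOC",
    "gcb_restricted": "GCB",
    "fdc_restricted": "FDC",
    "non_gc_tfh": "NGTFH",
    "housekeeping": "HK",
}


def default_gene_programs(class_counts: dict | None = None, seed: int = 7654321) -> pd.DataFrame:
    """Build the default 200-gene program table.

    The panel covers all seven program classes with mild per-gene jitter on
    baseline and fold strength.  The table is a pure function of its own
    seed, so the panel is identical across tissue realizations.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cls_name in GENE_CLASSES:
        n, base, strength = _CLASS_PANEL[cls_name]
        if class_counts and cls_name in class_counts:
            n = class_counts[cls_name]
        for i in range(n):
            if cls_name == "housekeeping":
                b = float(np.exp(rng.uniform(np.log(0.2), np.log(2.0))))
                s = 1.0
            else:
                b = float(base * np.exp(rng.normal(0.0, 0.1)))
                s = float(strength * np.exp(rng.normal(0.0, 0.15)))
            rows.append(
                {"gene": f"{_CLASS_PREFIX[cls_name]}{i + 1:03d}", "gene_class": cls_name,
                 "baseline": b, "strength": s}
            )
    return pd.DataFrame(rows)


@dataclass
class ContaminationParams:
    """Cell-to-cell contamination model settings.

    ``diffusion_lambda`` is the per-transcript probability of leaving its
    cell for a neighbor within ``diffusion_radius_um`` (Gaussian kernel,
    scale = radius/2, truncated at the radius).  Segmentation swaps
    exchange a fixed count fraction with the nearest neighbor; vertical
    overlap additively copies a fraction of a phantom co-located cell.
    Diffusion and swap conserve per-gene totals; overlap adds counts and is
    logged.
    """

    diffusion_lambda: float = 0.1
    diffusion_radius_um: float = 15.0
    swap_prob: float = 0.03
    swap_fraction: float = 0.3
    overlap_prob: float = 0.03
    overlap_fraction: float = 0.5

    def validate(self) -> "ContaminationParams":
        if not 0.0 <= self.diffusion_lambda <= 1.0:
            raise ParameterError("diffusion_lambda must lie in [0, 1]")
        if self.diffusion_lambda > 0 and self.diffusion_radius_um <= 0:
            raise ParameterError("diffusion_radius_um must be positive when diffusion_lambda > 0")
        for name in ("swap_prob", "swap_fraction", "overlap_prob", "overlap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        return self

    @classmethod
    def none(cls) -> "ContaminationParams":
        return cls(diffusion_lambda=0.0, swap_prob=0.0, overlap_prob=0.0)


@dataclass
class TissueConfig:
    """Geometry, composition, expression, and contamination settings."""

    field_um: tuple = (2000.0, 2000.0)
    n_follicles: int = 8
    follicle_radius_um: float = 140.0
    follicle_radius_sd_um: float = 12.0
    mantle_um: float = 40.0
    lz_fraction: float = 0.5
    epithelium_band_um: float = 80.0
    densities: dict = field(default_factory=lambda: dict(DEFAULT_DENSITIES))
    composition: dict = field(default_factory=lambda: {r: dict(v) for r, v in DEFAULT_COMPOSITION.items()})
    ambient_rate: float = 0.02
    dispersion: float = 2.0
    contamination: ContaminationParams = field(default_factory=ContaminationParams)
    programs: pd.DataFrame | None = None
    n_samples: int = 1
    positivity_threshold: int = 1  # used only to record planted positivity fractions
    seed: int = 0

    def validate(self) -> "TissueConfig":
        if self.n_follicles < 1:
            raise ParameterError("n_follicles must be >= 1")
        if self.follicle_radius_um <= 0 or self.mantle_um < 0:
            raise ParameterError("follicle radius must be positive and mantle nonnegative")
        if not 0 < self.lz_fraction < 1:
            raise ParameterError("lz_fraction must lie strictly between 0 and 1")
        for region, comp in self.composition.items():
            s = sum(comp.values())
            if abs(s - 1.0) > 1e-9:
                raise ParameterError(f"composition for region {region} sums to {s}, not 1")
            unknown = set(comp) - set(TYPES)
            if unknown:
                raise ParameterError(f"unknown cell type(s) in composition: {sorted(unknown)}")
        if any(d <= 0 for d in self.densities.values()):
            raise ParameterError("all region densities must be positive")
        if self.ambient_rate < 0:
            raise ParameterError("ambient_rate must be >= 0")
        if self.dispersion <= 0:
            raise ParameterError("dispersion must be positive")
        self.contamination.validate()
        return self

    @classmethod
    def small(cls, seed: int = 0, **kw) -> "TissueConfig":
        """A reduced tissue (~4k cells, 2 follicles) for fast desk checks."""
        defaults = dict(
            field_um=(900.0, 800.0),
            n_follicles=2,
            follicle_radius_um=120.0,
            follicle_radius_sd_um=8.0,
            seed=seed,
        )
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class TruthTable:
    """Per-cell and per-gene ground truth recorded before contamination."""

    cells: pd.DataFrame   # cell_id, sample_id, true_region, true_type
    genes: pd.DataFrame   # gene, gene_class, planted_gc_fraction


@dataclass
class PhantomModel:
    """Samples expression profiles for phantom overlapping cells."""

    mean_tensor: np.ndarray        # (genes, regions, types)
    region_idx: np.ndarray         # per cell
    composition_probs: np.ndarray  # (regions, types)
    dispersion: float

    def sample(self, cell_indices: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        r = self.region_idx[cell_indices]
        t = np.empty(len(cell_indices), dtype=int)
        for ri in np.unique(r):
            m = r == ri
            t[m] = rng.choice(len(TYPES), size=m.sum(), p=self.composition_probs[ri])
        mu = self.mean_tensor[:, r, t]
        lam = rng.gamma(self.dispersion, mu / self.dispersion)
        return rng.poisson(lam)


@dataclass
class SyntheticTissue:
    """Bundle returned by :func:`generate_tissue`."""

    cells: CellTable
    counts: CountMatrix
    truth: TruthTable
    follicles: pd.DataFrame
    clean_counts: CountMatrix
    contamination_log: dict
    config: TissueConfig


def _mean_tensor(programs: pd.DataFrame, ambient: float) -> np.ndarray:
    """Expected clean counts per (gene, region, type)."""
    G = len(programs)
    M = np.zeros((G, len(REGIONS), len(TYPES)))
    r_ix = {r: i for i, r in enumerate(REGIONS)}
    t_ix = {t: i for i, t in enumerate(TYPES)}
    gc = [r_ix["GC_LZ"], r_ix["GC_DZ"]]
    non_gc = [r_ix[r] for r in ("Mantle", "TZone", "Epithelium")]
    tfh = t_ix["Tfh"]
    for g, row in enumerate(programs.itertuples(index=False)):
        peak = row.baseline * row.strength
        cls_name = row.gene_class
        if cls_name == "gc_tfh_restricted":
            M[g, gc, tfh] = peak
        elif cls_name == "pan_tfh":
            M[g, :, tfh] = peak
        elif cls_name == "gc_associated_unrestricted":
            M[g, gc, tfh] = peak
            M[g, non_gc, tfh] = peak / 10.0
        elif cls_name == "gcb_restricted":
            M[g, :, t_ix["LZ_GCB"]] = peak
            M[g, :, t_ix["DZ_GCB"]] = peak
        elif cls_name == "fdc_restricted":
            M[g, :, t_ix["FDC"]] = peak
        elif cls_name == "non_gc_tfh":
            M[g, non_gc, tfh] = peak
        elif cls_name == "housekeeping":
            M[g, :, :] = row.baseline
        else:
            raise ParameterError(f"unknown gene class {cls_name!r}")
    return M + ambient


def _lz_plane_offset(radius: float, lz_fraction: float) -> float:
    """Signed offset of the LZ/DZ chord so the LZ side has the target area share."""
    if abs(lz_fraction - 0.5) < 1e-12:
        return 0.0

    def frac(t):  # area fraction of disk on the side (x - t*r) >= 0 ... t in (-1, 1)
        return (math.acos(t) - t * math.sqrt(1 - t * t)) / math.pi

    t = brentq(lambda u: frac(u) - lz_fraction, -1 + 1e-9, 1 - 1e-9)
    return t * radius


def _place_follicles(cfg: TissueConfig, rng: np.random.Generator, max_retries: int = 2000) -> pd.DataFrame:
    W, H = cfg.field_um
    rows = []
    for i in range(cfg.n_follicles):
        r = float(np.clip(
            rng.normal(cfg.follicle_radius_um, cfg.follicle_radius_sd_um),
            0.6 * cfg.follicle_radius_um, 1.45 * cfg.follicle_radius_um,
        ))
        outer = r + cfg.mantle_um
        lo_x, hi_x = outer + 5, W - outer - 5
        lo_y, hi_y = cfg.epithelium_band_um + outer + 5, H - outer - 5
        if lo_x >= hi_x or lo_y >= hi_y:
            raise GCNicheError("field too small for the requested follicle size")
        for attempt in range(max_retries):
            cx = rng.uniform(lo_x, hi_x)
            cy = rng.uniform(lo_y, hi_y)
            ok = all(
                math.hypot(cx - p["cx"], cy - p["cy"]) >= outer + p["radius"] + cfg.mantle_um + 20
                for p in rows
            )
            if ok:
                break
        else:
            raise GCNicheError(
                f"could not place follicle {i + 1}/{cfg.n_follicles} without overlap after "
                f"{max_retries} retries; use fewer or smaller follicles"
            )
        rows.append({
            "follicle": i, "cx": cx, "cy": cy, "radius": r,
            "split_angle": float(rng.uniform(0, 2 * math.pi)),
        })
    return pd.DataFrame(rows)


def _sample_cells_one_sample(cfg: TissueConfig, sample_id: str, rng: np.random.Generator):
    W, H = cfg.field_um
    follicles = _place_follicles(cfg, rng)
    xs, ys, regions = [], [], []

    for f in follicles.itertuples(index=False):
        # GC disk, split into LZ/DZ by a chord through (near) the center
        n_gc = rng.poisson(cfg.densities["GC_LZ"] * math.pi * f.radius ** 2)
        rad = f.radius * np.sqrt(rng.random(n_gc))
        ang = rng.uniform(0, 2 * math.pi, n_gc)
        px = f.cx + rad * np.cos(ang)
        py = f.cy + rad * np.sin(ang)
        u = np.array([math.cos(f.split_angle), math.sin(f.split_angle)])
        off = _lz_plane_offset(f.radius, cfg.lz_fraction)
        side = (px - f.cx) * u[0] + (py - f.cy) * u[1] - off
        xs.append(px); ys.append(py)
        regions.append(np.where(side >= 0, "GC_LZ", "GC_DZ"))

        # mantle annulus
        outer = f.radius + cfg.mantle_um
        area = math.pi * (outer ** 2 - f.radius ** 2)
        n_m = rng.poisson(cfg.densities["Mantle"] * area)
        rad = np.sqrt(f.radius ** 2 + rng.random(n_m) * (outer ** 2 - f.radius ** 2))
        ang = rng.uniform(0, 2 * math.pi, n_m)
        xs.append(f.cx + rad * np.cos(ang)); ys.append(f.cy + rad * np.sin(ang))
        regions.append(np.full(n_m, "Mantle"))

    # T zone: homogeneous process over the sub-band field, thinned outside follicles
    band = cfg.epithelium_band_um
    n_t = rng.poisson(cfg.densities["TZone"] * W * (H - band))
    px = rng.uniform(0, W, n_t)
    py = rng.uniform(band, H, n_t)
    keep = np.ones(n_t, dtype=bool)
    for f in follicles.itertuples(index=False):
        outer = f.radius + cfg.mantle_um
        keep &= (px - f.cx) ** 2 + (py - f.cy) ** 2 > outer ** 2
    xs.append(px[keep]); ys.append(py[keep])
    regions.append(np.full(int(keep.sum()), "TZone"))

    # epithelial band along the top edge
    n_e = rng.poisson(cfg.densities["Epithelium"] * W * band)
    xs.append(rng.uniform(0, W, n_e)); ys.append(rng.uniform(0, band, n_e))
    regions.append(np.full(n_e, "Epithelium"))

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    region = np.concatenate(regions)
    follicles = follicles.assign(sample_id=sample_id)
    return x, y, region, follicles


def expected_cell_count(cfg: TissueConfig) -> float:
    """Closed-form Poisson expectation of the generated cell count."""
    W, H = cfg.field_um
    r, m = cfg.follicle_radius_um, cfg.mantle_um
    gc_area = cfg.n_follicles * math.pi * r ** 2
    mantle_area = cfg.n_follicles * math.pi * ((r + m) ** 2 - r ** 2)
    band_area = W * cfg.epithelium_band_um
    tz_area = W * (H - cfg.epithelium_band_um) - cfg.n_follicles * math.pi * (r + m) ** 2
    per_sample = (
        cfg.densities["GC_LZ"] * gc_area
        + cfg.densities["Mantle"] * mantle_area
        + cfg.densities["TZone"] * tz_area
        + cfg.densities["Epithelium"] * band_area
    )
    return cfg.n_samples * per_sample


def _sample_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> sparse.csr_matrix:
    lam = rng.gamma(dispersion, mu / dispersion)
    return sparse.csr_matrix(rng.poisson(lam).astype(np.int64))


def generate_tissue(config: TissueConfig) -> SyntheticTissue:
    """Generate one synthetic tissue dataset with ground truth.

    Returns the observed (contaminated) counts together with the clean
    counts, the truth table, and the follicle geometry needed to recompute
    every cell's true region.
    """
    cfg = config.validate()
    programs = cfg.programs if cfg.programs is not None else default_gene_programs()

    geom_rng = substream(cfg.seed, "geometry")
    type_rng = substream(cfg.seed, "types")
    count_rng = substream(cfg.seed, "counts")

    xs, ys, regs, samples, fol_frames = [], [], [], [], []
    for s in range(cfg.n_samples):
        sid = f"S{s + 1}"
        x, y, region, follicles = _sample_cells_one_sample(cfg, sid, geom_rng)
        xs.append(x); ys.append(y); regs.append(region)
        samples.append(np.full(len(x), sid))
        fol_frames.append(follicles)
    x = np.concatenate(xs); y = np.concatenate(ys)
    region = np.concatenate(regs); sample = np.concatenate(samples)
    n = len(x)
    follicles = pd.concat(fol_frames, ignore_index=True)

    # region-conditioned cell types
    t_ix = {t: i for i, t in enumerate(TYPES)}
    r_ix = {r: i for i, r in enumerate(REGIONS)}
    comp_probs = np.zeros((len(REGIONS), len(TYPES)))
    for r_name, comp in cfg.composition.items():
        for t_name, p in comp.items():
            comp_probs[r_ix[r_name], t_ix[t_name]] = p
    region_idx = np.array([r_ix[r] for r in region])
    type_idx = np.empty(n, dtype=int)
    for ri in range(len(REGIONS)):
        m = region_idx == ri
        if m.any():
            type_idx[m] = type_rng.choice(len(TYPES), size=int(m.sum()), p=comp_probs[ri])
    types = np.asarray(TYPES, dtype=object)[type_idx]

    cell_ids = np.array([f"{s}_c{i:06d}" for i, s in enumerate(sample)], dtype=object)
    cells = CellTable.from_frame(pd.DataFrame({
        "cell_id": cell_ids, "x": x, "y": y, "sample_id": sample, "type_l1": types,
    }))

    tensor = _mean_tensor(programs, cfg.ambient_rate)
    mu = tensor[:, region_idx, type_idx]
    clean_X = _sample_counts(mu, cfg.dispersion, count_rng)
    genes = programs["gene"].to_numpy(object)
    clean = CountMatrix.from_parts(genes, cell_ids, clean_X)

    phantom = PhantomModel(tensor, region_idx, comp_probs, cfg.dispersion)
    observed, log = apply_contamination(
        clean, cells, cfg.contamination, seed=cfg.seed, phantom_model=phantom
    )

    in_gc_true = np.isin(region, ("GC_LZ", "GC_DZ"))
    tfh = types == "Tfh"
    pos = (clean_X[:, tfh] >= cfg.positivity_threshold).toarray()
    n_pos = pos.sum(axis=1)
    n_pos_gc = (pos & in_gc_true[tfh][None, :]).sum(axis=1)
    with np.errstate(invalid="ignore"):
        planted_frac = np.where(n_pos > 0, n_pos_gc / np.maximum(n_pos, 1), np.nan)

    truth = TruthTable(
        cells=pd.DataFrame({
            "cell_id": cell_ids, "sample_id": sample,
            "true_region": region, "true_type": types,
        }),
        genes=programs.assign(planted_gc_fraction=planted_frac)[
            ["gene", "gene_class", "planted_gc_fraction"]
        ],
    )
    return SyntheticTissue(cells, observed, truth, follicles, clean, log, cfg)


def _neighbor_structure(xy: np.ndarray, sample: np.ndarray, radius: float, kernel_scale: float):
    """Per-cell truncated-Gaussian neighbor weights as CSR-like arrays."""
    n = len(xy)
    donors, recips, dists = [], [], []
    for sid in pd.unique(sample):
        idx = np.flatnonzero(sample == sid)
        if len(idx) < 2:
            continue
        tree = cKDTree(xy[idx])
        pairs = tree.query_pairs(radius, output_type="ndarray")
        if len(pairs) == 0:
            continue
        a, b = idx[pairs[:, 0]], idx[pairs[:, 1]]
        d = np.hypot(*(xy[a] - xy[b]).T)
        donors.append(np.concatenate([a, b]))
        recips.append(np.concatenate([b, a]))
        dists.append(np.concatenate([d, d]))
    if not donors:
        indptr = np.zeros(n + 1, dtype=np.int64)
        return indptr, np.empty(0, dtype=np.int64), np.empty(0)
    donor = np.concatenate(donors)
    recip = np.concatenate(recips)
    dist = np.concatenate(dists)
    order = np.lexsort((recip, donor))
    donor, recip, dist = donor[order], recip[order], dist[order]
    w = np.exp(-dist ** 2 / (2 * kernel_scale ** 2))
    counts = np.bincount(donor, minlength=n)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    # normalized within-row cumulative weights; pin each row end to exactly 1
    cum = np.cumsum(w)
    row_start_cum = np.concatenate([[0.0], cum])[indptr[:-1]]
    row_tot = np.add.reduceat(w, indptr[:-1][counts > 0]) if counts.any() else np.empty(0)
    totals = np.zeros(n)
    totals[counts > 0] = row_tot
    cumw = (cum - np.repeat(row_start_cum, counts)) / np.repeat(
        np.where(totals == 0, 1.0, totals), counts
    )
    ends = indptr[1:][counts > 0] - 1
    cumw[ends] = 1.0
    return indptr, recip, cumw


def _column_delta(block: np.ndarray, cols: np.ndarray, shape) -> sparse.coo_matrix:
    """Sparse matrix equal to ``block`` placed at the given columns."""
    g, c = np.nonzero(block)
    return sparse.coo_matrix((block[g, c], (g, cols[c])), shape=shape, dtype=np.int64)


def apply_contamination(
    counts: CountMatrix,
    cells: CellTable,
    params: ContaminationParams,
    *,
    seed: int = 0,
    phantom_model: PhantomModel | None = None,
) -> tuple[CountMatrix, dict]:
    """Apply diffusion, segmentation-swap, and vertical-overlap contamination.

    Diffusion and swap conserve per-gene total counts exactly; overlap adds
    counts, and the per-gene additions are returned in the log.
    """
    params.validate()
    if params.overlap_prob > 0 and phantom_model is None:
        raise ParameterError("overlap_prob > 0 requires a phantom_model")
    X = counts.X.tocsr().copy()
    n_genes, n_cells = X.shape
    xy = cells.xy
    sample = cells.sample_ids
    log: dict = {"n_diffused": 0, "n_swap_pairs": 0, "overlap_added_per_gene": np.zeros(n_genes, dtype=np.int64)}

    # --- transcript diffusion -------------------------------------------------
    if params.diffusion_lambda > 0:
        rng = substream(seed, "diffusion")
        indptr, nbr, cumw = _neighbor_structure(
            xy, sample, params.diffusion_radius_um, params.diffusion_radius_um / 2.0
        )
        has_nbr = (indptr[1:] > indptr[:-1])
        coo = X.tocoo()
        g_idx, c_idx, vals = coo.row, coo.col, coo.data
        can_move = has_nbr[c_idx]
        moved = np.zeros_like(vals)
        moved[can_move] = rng.binomial(vals[can_move], params.diffusion_lambda)
        keep = vals - moved
        rep_c = np.repeat(c_idx, moved)
        rep_g = np.repeat(g_idx, moved)
        if len(rep_c):
            # categorical draw of a recipient per moved transcript via one
            # global searchsorted over per-row cumulative weights
            aug = cumw + np.repeat(np.arange(n_cells), np.diff(indptr))
            key = rep_c + rng.random(len(rep_c)) * (1 - 1e-12)
            pos = np.searchsorted(aug, key, side="left")
            dest = nbr[pos]
            rows = np.concatenate([g_idx, rep_g])
            cols = np.concatenate([c_idx, dest])
            data = np.concatenate([keep, np.ones(len(rep_c), dtype=keep.dtype)])
        else:
            rows, cols, data = g_idx, c_idx, keep
        X = sparse.coo_matrix((data, (rows, cols)), shape=X.shape).tocsr()
        X.sum_duplicates()
        X.eliminate_zeros()
        log["n_diffused"] = int(moved.sum())

    # --- segmentation swap ----------------------------------------------------
    if params.swap_prob > 0:
        rng = substream(seed, "swap")
        sel = np.flatnonzero(rng.random(n_cells) < params.swap_prob)
        used: set[int] = set()
        pairs = []
        for sid in pd.unique(sample):
            idx = np.flatnonzero(sample == sid)
            if len(idx) < 2:
                continue
            tree = cKDTree(xy[idx])
            sel_here = [i for i in sel if sample[i] == sid]
            if not sel_here:
                continue
            _, nn = tree.query(xy[sel_here], k=2)
            for i, row in zip(sel_here, nn):
                j = int(idx[row[1]])
                if i in used or j in used:
                    continue
                used.add(i); used.add(j)
                pairs.append((i, j))
        if pairs:
            ai = np.array([p[0] for p in pairs])
            bi = np.array([p[1] for p in pairs])
            A = X[:, ai].toarray()
            B = X[:, bi].toarray()
            give_a = rng.binomial(A, params.swap_fraction)
            give_b = rng.binomial(B, params.swap_fraction)
            X = (X + _column_delta(give_b - give_a, ai, X.shape)
                 + _column_delta(give_a - give_b, bi, X.shape)).tocsr()
            X.eliminate_zeros()
        log["n_swap_pairs"] = len(pairs)

    # --- vertical overlap (additive) -------------------------------------------
    if params.overlap_prob > 0:
        rng = substream(seed, "overlap")
        sel = np.flatnonzero(rng.random(n_cells) < params.overlap_prob)
        if len(sel):
            phantom = phantom_model.sample(sel, rng)
            added = rng.binomial(phantom, params.overlap_fraction)
            X = (X + _column_delta(added, sel, X.shape)).tocsr()
            X.eliminate_zeros()
            log["overlap_added_per_gene"] = added.sum(axis=1).astype(np.int64)

    return CountMatrix.from_parts(counts.genes, counts.cells, X), log


@dataclass
class DissociatedReference:
    """Contamination-free reference modality with lineage labels.

    Stands in for a dissociated single-cell RNA layer: the same gene
    programs, sampled per lineage with a latent region context (dissociation
    destroys position, so each cell's context is drawn from a tissue-wide
    mixture).
    """

    counts: CountMatrix
    labels: LabelMap
    means: np.ndarray            # (genes, cells) planted expectations
    region_context: np.ndarray   # latent region per cell
    programs: pd.DataFrame


DEFAULT_REFERENCE_COMPOSITION = {
    "Tfh": 0.15, "nnCD4": 0.30, "NaiveB": 0.28, "LZ_GCB": 0.10,
    "DZ_GCB": 0.08, "FDC": 0.02, "Epithelium": 0.02, "Other": 0.05,
}
DEFAULT_REGION_MIX = {"GC_LZ": 0.18, "GC_DZ": 0.10, "Mantle": 0.22, "TZone": 0.50}


def generate_dissociated_reference(
    programs: pd.DataFrame | None = None,
    n_cells: int = 2000,
    composition: dict | None = None,
    region_mix: dict | None = None,
    dispersion: float = 2.0,
    ambient: float = 0.02,
    seed: int = 0,
) -> DissociatedReference:
    """Generate a labeled dissociated single-cell reference dataset."""
    programs = programs if programs is not None else default_gene_programs()
    composition = composition or dict(DEFAULT_REFERENCE_COMPOSITION)
    region_mix = region_mix or dict(DEFAULT_REGION_MIX)
    lineages = [t for t, p in composition.items() if p > 0]
    if len(lineages) < 2:
        raise ParameterError("reference needs at least 2 lineages with positive proportion")
    if abs(sum(composition.values()) - 1.0) > 1e-9:
        raise ParameterError("reference composition must sum to 1")
    rng = substream(seed, "reference")
    t_ix = {t: i for i, t in enumerate(TYPES)}
    r_ix = {r: i for i, r in enumerate(REGIONS)}
    type_idx = rng.choice(
        [t_ix[t] for t in composition], size=n_cells, p=list(composition.values())
    )
    region_idx = rng.choice(
        [r_ix[r] for r in region_mix], size=n_cells, p=list(region_mix.values())
    )
    tensor = _mean_tensor(programs, ambient)
    mu = tensor[:, region_idx, type_idx]
    X = _sample_counts(mu, dispersion, rng)
    cell_ids = np.array([f"ref_c{i:06d}" for i in range(n_cells)], dtype=object)
    types = np.asarray(TYPES, dtype=object)[type_idx]
    counts = CountMatrix.from_parts(programs["gene"].to_numpy(object), cell_ids, X)
    labels = LabelMap.from_mapping("reference_lineage", dict(zip(cell_ids, types)))
    regions = np.asarray(REGIONS, dtype=object)[region_idx]
    return DissociatedReference(counts, labels, mu, regions, programs)


def generate_gene_activity(
    reference: DissociatedReference, noise_sd: float = 0.4, seed: int = 0
) -> np.ndarray:
    """Per-gene accessibility-activity matrix for the reference cells.

    A monotone noisy transform of the planted expression expectations:
    log1p of the planted mean plus Gaussian noise, clipped at zero so the
    score behaves like a nonnegative accessibility signal.  At
    ``noise_sd = 0`` the activity rank-matches the planted means exactly;
    large noise washes the correlation out.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = substream(seed, "activity")
    base = np.log1p(reference.means)
    if noise_sd > 0:
        base = np.maximum(base + rng.normal(0.0, noise_sd, size=base.shape), 0.0)
    return base
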