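"""Domain data model and on-disk interchange.

Cell tables travel as tab-delimited text with a header row; count matrices
as Matrix Market coordinate files with plain-text gene and cell sidecars —
the prevailing single-cell interchange conventions.  Coordinates are
continuous micrometres in a sample-local frame with the image convention
(origin top-left, y increasing downward).
"""
from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .errors import FormatError, ParameterError, ValidationError

#: Level-1 cell-type vocabulary used throughout the package.
DEFAULT_TYPE_VOCAB = (
    "Tfh",
    "nnCD4",
    "LZ_GCB",
    "DZ_GCB",
    "NaiveB",
    "FDC",
    "Epithelium",
    "Other",
)

REQUIRED_CELL_COLUMNS = ("cell_id", "x", "y", "sample_id", "type_l1")


@dataclass
class CellTable:
    """One row per segmented cell: position, sample, and type labels.

    ``df`` always contains the required columns ``cell_id, x, y, sample_id,
    type_l1``; optional ``type_l2`` and ``cn_id`` plus any extra metadata
    columns are preserved.
    """

    df: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame, vocabulary=None) -> "CellTable":
        missing = [c for c in REQUIRED_CELL_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"cell table missing required column(s): {', '.join(missing)}")
        df = df.copy()
        dup = df["cell_id"][df["cell_id"].duplicated()].unique()
        if len(dup):
            shown = ", ".join(map(str, dup[:10]))
            raise ValidationError(f"duplicate cell_id value(s): {shown}")
        for c in ("x", "y"):
            vals = pd.to_numeric(df[c], errors="coerce")
            if not np.isfinite(vals).all():
                raise ValidationError(f"column '{c}' contains non-finite values")
            df[c] = vals.astype(float)
        df["cell_id"] = df["cell_id"].astype(str)
        df["sample_id"] = df["sample_id"].astype(str)
        df["type_l1"] = df["type_l1"].astype(str)
        if vocabulary is not None:
            bad = sorted(set(df["type_l1"]) - set(vocabulary))
            if bad:
                raise ValidationError(f"type_l1 label(s) outside vocabulary: {', '.join(bad)}")
        return cls(df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.df["cell_id"].to_numpy()

    @property
    def xy(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(float)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.df["sample_id"].to_numpy()

    @property
    def type_l1(self) -> np.ndarray:
        return self.df["type_l1"].to_numpy()

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cell_table(path, vocabulary=None) -> CellTable:
    """Read a delimited cell table (tab or comma separated, header row)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    return CellTable.from_frame(df, vocabulary=vocabulary)


@dataclass
class CountMatrix:
    """Sparse gene×cell matrix of nonnegative integer counts."""

    genes: np.ndarray
    cells: np.ndarray
    X: sparse.csr_matrix

    @classmethod
    def from_parts(cls, genes, cells, X) -> "CountMatrix":
        genes = np.asarray(genes, dtype=object)
        cells = np.asarray(cells, dtype=object)
        X = sparse.csr_matrix(X)
        if X.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix shape {X.shape} does not match sidecars "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
        if len(set(genes)) != len(genes):
            raise ValidationError("gene identifiers are not unique")
        if len(set(cells)) != len(cells):
            raise ValidationError("cell identifiers are not unique")
        if X.nnz and X.data.min() < 0:
            raise ValidationError("count matrix contains negative entries")
        return cls(genes, cells, X)

    @property
    def shape(self):
        return self.X.shape

    def subset_genes(self, genes) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.genes)}
        rows = [idx[g] for g in genes]
        return CountMatrix(np.asarray(genes, dtype=object), self.cells, self.X[rows, :].tocsr())

    def write(self, matrix_path, genes_path, cells_path) -> None:
        spio.mmwrite(str(matrix_path), self.X.tocoo(), field="integer")
        Path(genes_path).write_text("\n".join(map(str, self.genes)) + "\n")
        Path(cells_path).write_text("\n".join(map(str, self.cells)) + "\n")


def read_count_matrix(matrix_path, genes_path, cells_path) -> CountMatrix:
    """Read a Matrix Market coordinate matrix with gene/cell sidecar files."""
    try:
        M = spio.mmread(str(matrix_path))
    except Exception as exc:  # malformed mtx header/body
        raise FormatError(f"cannot parse Matrix Market file {matrix_path}: {exc}") from exc
    genes = [line for line in Path(genes_path).read_text().splitlines() if line.strip()]
    cells = [line for line in Path(cells_path).read_text().splitlines() if line.strip()]
    if M.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix header declares shape {M.shape} but sidecars list "
            f"{len(genes)} genes and {len(cells)} cells"
        )
    return CountMatrix.from_parts(genes, cells, M)


def validate_pairing(cells: CellTable, counts: CountMatrix) -> None:
    """Require a paired cell table and count matrix to cover the same cells."""
    a = set(cells.cell_ids)
    b = set(map(str, counts.cells))
    if a != b:
        only_table = sorted(a - b)[:5]
        only_matrix = sorted(b - a)[:5]
        raise ValidationError(
            "cell table and count matrix cover different cells; "
            f"{len(a - b)} only in table (e.g. {only_table}), "
            f"{len(b - a)} only in matrix (e.g. {only_matrix})"
        )
    if not np.array_equal(cells.cell_ids.astype(str), np.asarray(counts.cells, dtype=str)):
        raise ValidationError("cell table and count matrix list cells in different orders")


@dataclass
class LabelMap:
    """Per-cell cluster labels under one named labeling scheme."""

    name: str
    labels: pd.Series  # index: cell_id, values: label strings

    @classmethod
    def from_mapping(cls, name, mapping) -> "LabelMap":
        s = pd.Series(mapping, dtype=object)
        if s.index.duplicated().any():
            raise ValidationError(f"labeling '{name}' assigns some cells more than once")
        return cls(name, s.astype(str))

    def write(self, path) -> None:
        df = pd.DataFrame({"cell_id": self.labels.index, "label": self.labels.values})
        df.to_csv(path, sep="\t", index=False)


def read_label_map(path, name=None) -> LabelMap:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if not {"cell_id", "label"}.issubset(df.columns):
        raise FormatError("label file must have columns 'cell_id' and 'label'")
    return LabelMap.from_mapping(
        name or Path(path).stem, dict(zip(df["cell_id"].astype(str), df["label"].astype(str)))
    )


@dataclass
class AnalysisConfig:
    """All numeric knobs of the analysis pipeline, in one place.

    Every output artifact echoes ``config_hash`` and ``seed`` so that any
    table can be traced back to the exact settings that produced it.
    """

    knn_k: int = 20                 # neighborhood window size (self included)
    n_neighborhoods: int = 10       # number of cellular neighborhoods (CNs)
    bin_um: float = 20.0            # raster bin size for the GC mask
    closing_radius_bins: int = 2    # binary-closing radius, in bins
    positivity_threshold: int = 1   # raw counts needed to call a cell positive
    min_pos_tfh: int = 20           # positive Tfh needed for ranking inclusion
    pseudocount: float = 1e-9       # epsilon in the log2 fold-change
    mt_method: str = "bonferroni"   # 'bonferroni' or 'fdr_bh'
    bandwidth_um: float = 25.0      # Gaussian bandwidth of the decay smoother
    grid_max_um: float = 300.0      # decay-curve grid upper end
    grid_step_um: float = 5.0       # decay-curve grid step
    seed: int = 0

    def validate(self) -> "AnalysisConfig":
        positive = {
            "knn_k": self.knn_k,
            "n_neighborhoods": self.n_neighborhoods,
            "bin_um": self.bin_um,
            "positivity_threshold": self.positivity_threshold,
            "min_pos_tfh": self.min_pos_tfh,
            "pseudocount": self.pseudocount,
            "bandwidth_um": self.bandwidth_um,
            "grid_max_um": self.grid_max_um,
            "grid_step_um": self.grid_step_um,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ParameterError(f"config field '{name}' must be positive, got {value!r}")
        if self.closing_radius_bins < 0:
            raise ParameterError("closing_radius_bins must be >= 0")
        if self.mt_method not in ("bonferroni", "fdr_bh"):
            raise ParameterError(f"unknown mt_method {self.mt_method!r}")
        if int(self.seed) < 0:
            raise ParameterError("seed must be a nonnegative integer")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(data) - known)
        if bad:
            raise FormatError(f"unknown config field(s): {', '.join(bad)}")
        return cls(**data).validate()


def write_table(df: pd.DataFrame, path, *, config: AnalysisConfig | None = None) -> None:
    """Write a result table with a provenance header (config hash + seed)."""
    buf = _io.StringIO()
    if config is not None:
        buf.write(f"# config_hash={config.config_hash}\n# seed={config.seed}\n")
    df.to_csv(buf, sep="\t", index=False, float_format="%.10g")
    Path(path).write_text(buf.getvalue())
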