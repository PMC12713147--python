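"""Seeding and small shared helpers."""
from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a named, independent random stream derived from one base seed.

    Every source of randomness in the package draws from a stream obtained
    here, so individual stages can be re-run in isolation and still
    reproduce exactly what a full run would have produced.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def library_size_normalize(X, target: float | None = None):
    """Scale each cell (column) to a common total count.

    Zero-total cells are left at zero.  Returns a dense float array when the
    input is dense, sparse CSR when sparse.
    """
    from scipy import sparse

    if sparse.issparse(X):
        totals = np.asarray(X.sum(axis=0)).ravel().astype(float)
    else:
        X = np.asarray(X, dtype=float)
        totals = X.sum(axis=0)
    pos = totals > 0
    if target is None:
        target = float(np.median(totals[pos])) if pos.any() else 1.0
    scale = np.zeros_like(totals)
    scale[pos] = target / totals[pos]
    if sparse.issparse(X):
        return (X @ sparse.diags(scale)).tocsr()
    return X * scale[None, :]
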