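"""Cross-modality feature meta-ranking and clustering concordance.

Fisher's method combines per-gene p-values from an RNA contrast and a
chromatin gene-activity contrast into one meta p-value; the lowest-meta-p
genes are then ranked by the mean of the two log2 fold-changes.  Adjusted
mutual information (AMI) quantifies agreement between two clusterings of
the same cells, corrected for chance under the permutation model and
invariant to cluster naming.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .errors import ParameterError, ValidationError
from .io import LabelMap
from .specificity import ContrastResult


def fisher_meta_p(p1, p2):
    """Fisher combination of two p-values: X² = −2(ln p1 + ln p2), 4 df."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    tiny = np.nextafter(0.0, 1.0)
    if np.any(p1 <= 0) or np.any(p2 <= 0):
        warnings.warn("p-value of 0 clamped to the smallest positive float", stacklevel=2)
    p1 = np.clip(p1, tiny, 1.0)
    p2 = np.clip(p2, tiny, 1.0)
    x2 = -2.0 * (np.log(p1) + np.log(p2))
    return chi2.sf(x2, df=4)


def combine_meta(
    contrast_rna: ContrastResult,
    contrast_activity: ContrastResult,
    min_top: int = 10,
) -> pd.DataFrame:
    """Meta-rank genes tested in both modalities.

    Per shared gene: ``meta_p`` from Fisher's method on the two raw
    p-values and ``meta_lfc`` as the mean of the two log2 fold-changes.
    The top set is the ``min_top`` lowest-meta-p genes (the minimum
    threshold retaining at least that many), ranked by meta log2FC
    descending.
    """
    rna = contrast_rna.table.set_index("gene")
    act = contrast_activity.table.set_index("gene")
    shared = [g for g in rna.index if g in act.index]
    if not shared:
        raise ValidationError("RNA and activity contrasts share no genes")
    out = pd.DataFrame({
        "gene": shared,
        "lfc_rna": rna.loc[shared, "log2fc"].values,
        "p_rna": rna.loc[shared, "p_value"].values,
        "lfc_activity": act.loc[shared, "log2fc"].values,
        "p_activity": act.loc[shared, "p_value"].values,
    })
    out["meta_p"] = fisher_meta_p(out["p_rna"], out["p_activity"])
    out["meta_lfc"] = (out["lfc_rna"] + out["lfc_activity"]) / 2.0
    k = min(min_top, len(out))
    ceiling = np.sort(out["meta_p"].values)[k - 1]
    out["in_top"] = out["meta_p"] <= ceiling
    out["rank"] = pd.array([pd.NA] * len(out), dtype="Int64")
    top = out[out["in_top"]].sort_values(
        by=["meta_lfc", "gene"], ascending=[False, True], kind="mergesort"
    )
    out.loc[top.index, "rank"] = np.arange(1, len(top) + 1)
    return out.sort_values(
        by=["in_top", "meta_lfc"], ascending=[False, False], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class ConcordanceResult:
    """Contingency table and information-theoretic agreement of two labelings."""

    name_a: str
    name_b: str
    contingency: pd.DataFrame
    mi: float
    emi: float
    h_a: float
    h_b: float
    ami: float
    n_cells: int


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def _expected_mi(a_counts: np.ndarray, b_counts: np.ndarray, n: int) -> float:
    """E[MI] under the permutation (hypergeometric) null of fixed marginals."""
    emi = 0.0
    log_n = np.log(n)
    for ai in a_counts:
        for bj in b_counts:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1)
            term_log = (
                gammaln(ai + 1) + gammaln(bj + 1)
                + gammaln(n - ai + 1) + gammaln(n - bj + 1)
                - gammaln(n + 1) - gammaln(nij + 1)
                - gammaln(ai - nij + 1) - gammaln(bj - nij + 1)
                - gammaln(n - ai - bj + nij + 1)
            )
            emi += float(np.sum(
                (nij / n) * (np.log(nij) + log_n - np.log(ai) - np.log(bj)) * np.exp(term_log)
            ))
    return emi


def ami(a: LabelMap, b: LabelMap) -> ConcordanceResult:
    """Adjusted mutual information between two labelings of the same cells.

    AMI = (MI − E[MI]) / (mean(H(a), H(b)) − E[MI]) with the expectation
    taken under the permutation model.  Equals 1 iff the labelings are
    identical up to renaming; a degenerate zero denominator returns 0 by
    convention.  Labelings over unequal cell universes are intersected with
    a warning.
    """
    sa, sb = a.labels, b.labels
    common = sa.index.intersection(sb.index)
    if len(common) < len(sa) or len(common) < len(sb):
        warnings.warn(
            f"labelings cover different cells; intersecting to {len(common)}", stacklevel=2
        )
    if len(common) < 2:
        raise ValidationError("need at least 2 common cells to compare labelings")
    la = sa.loc[common].values
    lb = sb.loc[common].values
    cont = pd.crosstab(pd.Series(la, name=a.name), pd.Series(lb, name=b.name))
    C = cont.to_numpy()
    n = int(C.sum())
    a_counts = C.sum(axis=1)
    b_counts = C.sum(axis=0)

    nz = C > 0
    pij = C[nz] / n
    pa = (a_counts / n)[np.nonzero(nz)[0]]
    pb = (b_counts / n)[np.nonzero(nz)[1]]
    mi = float(np.sum(pij * np.log(pij / (pa * pb))))
    h_a = _entropy(a_counts, n)
    h_b = _entropy(b_counts, n)
    emi = _expected_mi(a_counts, b_counts, n)
    denom = 0.5 * (h_a + h_b) - emi
    value = 0.0 if abs(denom) < 1e-15 else (mi - emi) / denom
    return ConcordanceResult(
        name_a=a.name, name_b=b.name, contingency=cont,
        mi=mi, emi=emi, h_a=h_a, h_b=h_b, ami=float(value), n_cells=n,
    )


def pairwise_ami(labelmaps) -> pd.DataFrame:
    """Symmetric matrix of AMI values over a collection of labelings."""
    labelmaps = list(labelmaps)
    if len(labelmaps) < 2:
        raise ParameterError("need at least two labelings")
    names = [lm.name for lm in labelmaps]
    M = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i in range(len(labelmaps)):
        for j in range(i + 1, len(labelmaps)):
            v = ami(labelmaps[i], labelmaps[j]).ami
            M.iat[i, j] = M.iat[j, i] = v
    return M
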