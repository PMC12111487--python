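"""Correspondence analysis of the gene x codon RSCU matrix and Axis-1
correlation follow-up.

CA is the chi-square-metric ordination: with P the matrix scaled to sum 1,
row and column margins r and c, the standardised residual matrix is
S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}.  Its singular value decomposition
S = U diag(sigma) V^T gives principal row coordinates
F = D_r^{-1/2} U diag(sigma) and column coordinates
G = D_c^{-1/2} V diag(sigma); sigma_k^2 is the inertia of axis k and the
total inertia equals the matrix chi-square statistic divided by the grand
total.  Axes are sign-indeterminate: a deterministic default orientation is
applied and :func:`orient_axes` can pin Axis signs to an external variable
(here, so that Axis 1 correlates non-negatively with GC3s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError, InsufficientDataError

_RELATIVE_RANK_TOL = 1e-10


@dataclass
class CAResult:
    """Correspondence-analysis decomposition of a genes x codons matrix."""

    row_scores: pd.DataFrame  # genes x retained axes (principal coordinates)
    col_scores: pd.DataFrame  # codons x retained axes
    inertia: np.ndarray  # absolute inertia per retained axis (sigma^2)
    inertia_pct: np.ndarray  # percentage of total inertia per axis
    n_axes: int
    total_inertia: float
    dropped_columns: list[str] = field(default_factory=list)

    def axis(self, k: int = 1) -> pd.Series:
        """Row scores on axis ``k`` (1-based)."""
        return self.row_scores[f"Axis{k}"]


def correspondence_analysis(matrix: pd.DataFrame) -> CAResult:
    """Standard correspondence analysis of a non-negative matrix.

    Rows are genes, columns codons (RSCU values by default in this package,
    raw counts if the caller prefers).  All-zero columns are dropped and
    reported on the result; all-zero rows are an error.  A matrix whose rows
    are all proportional yields a degenerate result with zero informative
    axes.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise InputError("CA input must be non-negative")
    col_mask = X.sum(axis=0) > 0
    dropped = [str(c) for c, keep in zip(matrix.columns, col_mask) if not keep]
    X = X[:, col_mask]
    cols = [c for c, keep in zip(matrix.columns, col_mask) if keep]
    if X.shape[1] == 0 or X.sum() <= 0:
        raise InputError("CA input has no positive column")
    if (X.sum(axis=1) == 0).any():
        raise InputError("CA input contains an all-zero row")

    grand = X.sum()
    P = X / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sigma, Vt = np.linalg.svd(S, full_matrices=False)

    total_inertia = float(np.sum(sigma**2))
    if total_inertia <= 0 or sigma[0] ** 2 <= 1e-15:
        empty = pd.DataFrame(index=matrix.index)
        return CAResult(
            row_scores=empty,
            col_scores=pd.DataFrame(index=cols),
            inertia=np.empty(0),
            inertia_pct=np.empty(0),
            n_axes=0,
            total_inertia=max(total_inertia, 0.0),
            dropped_columns=dropped,
        )

    keep = sigma**2 > sigma[0] ** 2 * _RELATIVE_RANK_TOL
    U, sigma, Vt = U[:, keep], sigma[keep], Vt[keep, :]

    F = (U * sigma) / np.sqrt(r)[:, None]
    G = (Vt.T * sigma) / np.sqrt(c)[:, None]

    # Deterministic default orientation: largest-|loading| column positive.
    for j in range(F.shape[1]):
        pivot = np.argmax(np.abs(G[:, j]))
        if G[pivot, j] < 0:
            G[:, j] *= -1
            F[:, j] *= -1

    axes = [f"Axis{k + 1}" for k in range(F.shape[1])]
    inertia = sigma**2
    return CAResult(
        row_scores=pd.DataFrame(F, index=matrix.index, columns=axes),
        col_scores=pd.DataFrame(G, index=cols, columns=axes),
        inertia=inertia,
        inertia_pct=100.0 * inertia / total_inertia,
        n_axes=len(axes),
        total_inertia=total_inertia,
        dropped_columns=dropped,
    )


def orient_axes(ca: CAResult, reference: Sequence[float], axes: Sequence[int] = (1,)) -> CAResult:
    """Reflect the given axes (1-based) so their row scores correlate
    non-negatively with ``reference`` (e.g. per-gene GC3s).  Reflection
    leaves inertia untouched; it only pins the arbitrary sign."""
    ref = np.asarray(list(reference), dtype=float)
    for k in axes:
        name = f"Axis{k}"
        if name not in ca.row_scores.columns:
            continue
        scores = ca.row_scores[name].to_numpy()
        if np.std(scores) == 0 or np.std(ref) == 0:
            continue
        if np.corrcoef(scores, ref)[0, 1] < 0:
            ca.row_scores[name] = -scores
            ca.col_scores[name] = -ca.col_scores[name].to_numpy()
    return ca


#: Inter-variable pairs reported alongside the Axis-1 correlations.
COMPOSITION_PAIRS = (("GC3", "GC1"), ("GC3", "GC2"), ("GC1", "GC2"))


def axis1_correlations(
    ca: CAResult,
    per_gene: pd.DataFrame,
    method: str = "spearman",
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Correlate Axis-1 row scores with per-gene composition and indices.

    ``per_gene`` is indexed by gene id with columns drawn from
    {GC1, GC2, GC3, GC3s, GC_all, CAI, CBI, ENC, L_aa}.  Returns one row per
    pair with coefficient, two-sided p, method and Benjamini-Hochberg
    adjusted p.  Constant variables are flagged undefined, not errored.
    """
    if ca.n_axes == 0:
        raise InsufficientDataError("degenerate CA: no axes to correlate")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    axis1 = ca.axis(1).reindex(per_gene.index)
    if axis1.isna().any():
        raise InputError("per-gene table does not match CA rows")
    if len(per_gene) < 3:
        raise InsufficientDataError("need >= 3 genes for correlations")

    if variables is None:
        preferred = ["GC1", "GC2", "GC3", "GC3s", "GC_all", "CAI", "CBI", "ENC", "L_aa"]
        variables = [v for v in preferred if v in per_gene.columns]

    corr_fn = stats.spearmanr if method == "spearman" else stats.pearsonr

    def one(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
        mask = np.isfinite(a) & np.isfinite(b)
        if mask.sum() < 3 or np.std(a[mask]) == 0 or np.std(b[mask]) == 0:
            return float("nan"), float("nan")
        res = corr_fn(a[mask], b[mask])
        return float(res.statistic), float(res.pvalue)

    rows = []
    ax = axis1.to_numpy(dtype=float)
    for v in variables:
        coef, p = one(ax, per_gene[v].to_numpy(dtype=float))
        rows.append({"variable_a": "Axis1", "variable_b": v, "coefficient": coef, "p_value": p})
    for a, b in COMPOSITION_PAIRS:
        if a in per_gene.columns and b in per_gene.columns:
            coef, p = one(
                per_gene[a].to_numpy(dtype=float), per_gene[b].to_numpy(dtype=float)
            )
            rows.append({"variable_a": a, "variable_b": b, "coefficient": coef, "p_value": p})

    out = pd.DataFrame(rows)
    out["method"] = method
    out["undefined"] = ~np.isfinite(out["p_value"])
    out["p_adj_bh"] = np.nan
    ok = out["undefined"] == False  # noqa: E712
    if ok.any():
        out.loc[ok, "p_adj_bh"] = multipletests(
            out.loc[ok, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    return out
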