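"""Correspondence-analysis family with externally imposed row weights.

All analyses here are expressed as one weighted "duality-diagram" style
decomposition of a centered table Z with row weights w and column weights
(metric) m: the generalized SVD of ``diag(sqrt(w)) Z diag(sqrt(m))``.
Total inertia is ``sum_i w_i sum_j m_j Z_ij^2`` and equals the sum of the
eigenvalues. Specializations:

* ``coa``  — correspondence analysis of a non-negative contingency-like
  table (chi-square metric); total inertia equals chi^2 / N.
* ``mca``  — multiple correspondence analysis of categorical descriptors
  (quantitative columns pre-discretized into quantile classes), i.e. a
  CA of the indicator super-table with possibly imposed row weights.
* ``fca``  — fuzzy correspondence analysis: the CA of the fuzzy profile
  super-table (each trait block a frequency profile).
* ``pca``  — weighted, column-standardized principal component analysis,
  the fallback for quantitative trait tables.

Imposed row weights are how the separate R- and Q-analyses inherit the
site and species weights of the abundance-table CA before the three-table
co-inertia step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import EnvironmentTable, FuzzyTraitTable

logger = logging.getLogger(__name__)

RANK_EPS = 1e-12  # eigenvalue cutoff for rank detection


@dataclass
class OrdinationResult:
    """Eigendecomposition of a weighted, centered table.

    ``tab`` is the centered/standardized table Z; ``row_weights`` and
    ``col_weights`` are the weights/metric under which Z was decomposed
    (needed downstream by the three-table co-inertia analysis).
    """

    kind: str
    eigenvalues: np.ndarray
    row_scores: pd.DataFrame       # principal coordinates
    col_scores: pd.DataFrame       # principal coordinates
    row_weights: pd.Series
    col_weights: pd.Series
    total_inertia: float
    tab: pd.DataFrame              # centered table Z
    col_coefs: pd.DataFrame        # normed column coefficients (for projection)
    meta: dict = field(default_factory=dict)

    @property
    def rank(self) -> int:
        return len(self.eigenvalues)

    @property
    def percent_inertia(self) -> np.ndarray:
        if self.total_inertia == 0:
            return np.zeros_like(self.eigenvalues)
        return 100.0 * self.eigenvalues / self.total_inertia


def _canonical_signs(V: np.ndarray) -> np.ndarray:
    """Per axis, make the coefficient of largest |value| positive."""
    flips = np.ones(V.shape[1])
    for k in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            flips[k] = -1.0
    return flips


def _decompose(Z: pd.DataFrame, row_w: pd.Series, col_w: pd.Series,
               kind: str, meta: dict | None = None) -> OrdinationResult:
    Zm = Z.to_numpy(dtype=float)
    w = row_w.to_numpy(dtype=float)
    m = col_w.to_numpy(dtype=float)
    A = np.sqrt(w)[:, None] * Zm * np.sqrt(m)[None, :]
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    eig = s**2
    keep = eig > RANK_EPS
    U, s, Vt, eig = U[:, keep], s[keep], Vt[keep], eig[keep]
    flips = _canonical_signs((Vt.T / np.where(np.sqrt(m)[:, None] > 0, np.sqrt(m)[:, None], 1.0)))
    U = U * flips
    Vt = Vt * flips[:, None]

    with np.errstate(divide="ignore", invalid="ignore"):
        sw = np.where(w > 0, np.sqrt(w), np.inf)
        sm = np.where(m > 0, np.sqrt(m), np.inf)
    row_sc = (U * s) / sw[:, None]
    col_co = Vt.T / sm[:, None]          # normed: c' D_m c = 1
    col_sc = col_co * s

    axes = [f"Axis{k+1}" for k in range(len(eig))]
    total = float(np.sum(w[:, None] * m[None, :] * Zm**2))
    return OrdinationResult(
        kind=kind,
        eigenvalues=eig,
        row_scores=pd.DataFrame(row_sc, index=Z.index, columns=axes),
        col_scores=pd.DataFrame(col_sc, index=Z.columns, columns=axes),
        row_weights=row_w,
        col_weights=col_w,
        total_inertia=total,
        tab=Z,
        col_coefs=pd.DataFrame(col_co, index=Z.columns, columns=axes),
        meta=meta or {},
    )


# ---------------------------------------------------------------------------
# CoA
# ---------------------------------------------------------------------------

def coa(table: pd.DataFrame) -> OrdinationResult:
    """Correspondence analysis of a non-negative table (chi-square metric).

    Zero rows/columns are dropped with a warning; the trivial axis is
    removed by the double centering. Total inertia equals chi^2/N.
    """
    N = table.to_numpy(dtype=float)
    if (N < 0).any():
        raise ValueError("CA requires a non-negative table")
    if N.sum() <= 0:
        raise ValueError("CA requires a positive grand total")
    zr = table.index[N.sum(axis=1) == 0]
    zc = table.columns[N.sum(axis=0) == 0]
    if len(zr) or len(zc):
        logger.warning("dropping zero rows %s / columns %s", list(zr), list(zc))
        table = table.drop(index=zr, columns=zc)
        N = table.to_numpy(dtype=float)
    P = N / N.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    Z = P / np.outer(r, c) - 1.0
    return _decompose(pd.DataFrame(Z, index=table.index, columns=table.columns),
                      pd.Series(r, index=table.index),
                      pd.Series(c, index=table.columns), kind="coa")


# ---------------------------------------------------------------------------
# Profile-table CA core (MCA / FCA)
# ---------------------------------------------------------------------------

def _profile_ca(X: pd.DataFrame, row_w: pd.Series | None, kind: str,
                meta: dict | None = None) -> OrdinationResult:
    """CA of a row-profile table (rows sum to 1) under imposed row weights."""
    if row_w is None:
        row_w = pd.Series(np.full(len(X), 1.0 / len(X)), index=X.index)
    else:
        row_w = pd.Series(row_w, index=X.index).astype(float)
        if (row_w < 0).any():
            raise ValueError("row weights must be non-negative")
        row_w = row_w / row_w.sum()
    Xm = X.to_numpy(dtype=float)
    cw = row_w.to_numpy() @ Xm
    keep = cw > 0
    if not keep.all():
        logger.warning("dropping %d unoccupied columns", int((~keep).sum()))
        X = X.loc[:, keep]
        Xm = Xm[:, keep]
        cw = cw[keep]
    Z = Xm / cw[None, :] - 1.0
    return _decompose(pd.DataFrame(Z, index=X.index, columns=X.columns),
                      row_w, pd.Series(cw, index=X.columns), kind=kind, meta=meta)


def discretize_quantiles(values: pd.Series, n_classes: int = 3) -> pd.Series:
    """Discretize a quantitative descriptor into quantile classes."""
    ranks = values.rank(method="average", pct=True)
    edges = np.linspace(0, 1, n_classes + 1)[1:-1]
    cls = np.searchsorted(edges, ranks.to_numpy(), side="left")
    return pd.Series([f"{values.name or 'var'}.Q{k+1}" for k in cls], index=values.index)


def mca(R: EnvironmentTable | pd.DataFrame, row_weights: pd.Series | None = None,
        n_classes: int = 3) -> OrdinationResult:
    """Multiple correspondence analysis of the environment table.

    Quantitative descriptors are discretized into ``n_classes`` quantile
    classes; single-level factors are dropped with a warning. With uniform
    row weights the total inertia obeys the classical identity
    ``(n_levels / n_factors) - 1``.
    """
    df = R.data if isinstance(R, EnvironmentTable) else R
    factors = {}
    for col in df.columns:
        if pd.api.types.is_numeric_dtype(df[col]):
            factors[col] = discretize_quantiles(df[col], n_classes)
        else:
            factors[col] = df[col].astype(str)
    fdf = pd.DataFrame(factors, index=df.index)
    keep = [c for c in fdf.columns if fdf[c].nunique() > 1]
    dropped = [c for c in fdf.columns if c not in keep]
    if dropped:
        logger.warning("dropping single-level factor(s) %s", dropped)
    if not keep:
        raise ValueError("MCA needs at least one factor with >= 2 levels")
    fdf = fdf[keep]
    G = pd.get_dummies(fdf, prefix=keep, prefix_sep="=").astype(float)
    X = G / len(keep)  # each row sums to 1
    return _profile_ca(X, row_weights, kind="mca",
                       meta={"n_factors": len(keep), "n_levels": G.shape[1]})


def fca(Q: FuzzyTraitTable, row_weights: pd.Series | None = None) -> OrdinationResult:
    """Fuzzy correspondence analysis: CA of the fuzzy profile super-table.

    Taxa with a missing block for any trait must be excluded beforehand
    (see ``FuzzyTraitTable.complete_taxa``). A zero-inertia result (all
    profiles identical) is flagged in ``meta['zero_inertia']``.
    """
    prof = Q.to_profile()
    mask = prof.missing_mask()
    if mask.any().any():
        bad = list(mask.index[mask.any(axis=1)])
        raise ValueError(f"taxa with missing trait blocks in FCA: {bad}")
    X = prof.data / len(prof.traits)
    flat = X.copy()
    flat.columns = [f"{t}__{m}" for t, m in X.columns]
    res = _profile_ca(flat, row_weights, kind="fca", meta={"n_traits": len(prof.traits)})
    res.meta["zero_inertia"] = bool(res.total_inertia < RANK_EPS)
    return res


# ---------------------------------------------------------------------------
# PCA (quantitative traits / descriptors)
# ---------------------------------------------------------------------------

def pca(X: pd.DataFrame, row_weights: pd.Series | None = None,
        scale: bool = True) -> OrdinationResult:
    """Weighted, column-standardized PCA (identity column metric)."""
    if row_weights is None:
        row_w = pd.Series(np.full(len(X), 1.0 / len(X)), index=X.index)
    else:
        row_w = pd.Series(row_weights, index=X.index).astype(float)
        row_w = row_w / row_w.sum()
    Xm = X.to_numpy(dtype=float)
    w = row_w.to_numpy()
    mean = w @ Xm
    Z = Xm - mean
    if scale:
        sd = np.sqrt(w @ (Z**2))
        const = sd <= 0
        if const.any():
            logger.warning("dropping constant column(s) %s", list(X.columns[const]))
            X = X.loc[:, ~const]
            Z = Z[:, ~const]
            sd = sd[~const]
        Z = Z / sd[None, :]
    cw = pd.Series(np.ones(Z.shape[1]), index=X.columns)
    return _decompose(pd.DataFrame(Z, index=X.index, columns=X.columns), row_w, cw, kind="pca")


def weighted_reanalysis(result: OrdinationResult, row_weights: pd.Series,
                        source) -> OrdinationResult:
    """Re-run an ordination with externally imposed row weights.

    ``source`` is the original input object (table or FuzzyTraitTable).
    Uniform weights reproduce the unweighted analysis; a zero-weight row
    has no influence on the axes.
    """
    row_weights = pd.Series(row_weights).astype(float)
    if not result.row_scores.index.equals(row_weights.index):
        raise ValueError("row weights are misaligned with the ordination rows")
    if result.kind == "mca":
        return mca(source, row_weights=row_weights)
    if result.kind == "fca":
        return fca(source, row_weights=row_weights)
    if result.kind == "pca":
        return pca(source, row_weights=row_weights)
    raise ValueError(f"cannot impose row weights on analysis kind {result.kind!r}")
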