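"""Cross-disorder co-alteration matrix, hit map, thresholding, hubs, map correlation.

The co-alteration (structural covariance of disease effects) matrix correlates
each pair of parcels' effect-size profiles across disorders: entry (i, j) is the
Pearson correlation between parcel i's and parcel j's vectors of Cohen's d
values. Degree-centrality hubs are parcels with a high sum of supra-threshold
connections after keeping the strongest 20% of edges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .atlas import DisorderEffectSet, ParcelMap, SquareMatrix
from .spins import SpinEnsemble, spin_map, spin_pvalue

MIN_COMPLETE_PAIRS = 10


@dataclass
class HubMap:
    """Degree-centrality map with the thresholding provenance that produced it."""

    map: ParcelMap
    sparsity: float
    mode: str  # weighted_sum | binary_count
    threshold_scope: str  # global | row


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    xm = x - np.sum(w * x)
    ym = y - np.sum(w * y)
    denom = math.sqrt(np.sum(w * xm**2) * np.sum(w * ym**2))
    return float(np.sum(w * xm * ym) / denom) if denom > 0 else np.nan


def coalteration_matrix(effects: DisorderEffectSet, weights: np.ndarray | None = None,
                        labels=None) -> SquareMatrix:
    """Inter-regional Pearson correlation of effect profiles across disorders.

    Parameters
    ----------
    effects : DisorderEffectSet
        Parcels x disorders Cohen's d table; at least 3 disorders.
    weights : array, optional
        Per-disorder weights (e.g. proportional to total sample size) for a
        weighted Pearson correlation. Default: unweighted.
    labels : sequence, optional
        Parcel labels for the result; defaults to positional indices.
    """
    X = effects.effects
    n_parcels, n_dis = X.shape
    if n_dis < 3:
        raise ValueError("need at least 3 disorders to correlate across disorders")
    constant = np.nanstd(X, axis=1) == 0
    if weights is None and not np.isnan(X).any():
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(X)
    else:
        w = np.ones(n_dis) if weights is None else np.asarray(weights, float)
        r = np.empty((n_parcels, n_parcels))
        for i in range(n_parcels):
            r[i, i] = 1.0
            for j in range(i + 1, n_parcels):
                ok = np.isfinite(X[i]) & np.isfinite(X[j])
                if ok.sum() < 3:
                    r[i, j] = r[j, i] = np.nan
                    continue
                r[i, j] = r[j, i] = _weighted_pearson(X[i, ok], X[j, ok], w[ok])
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} parcel(s) have constant effect profiles; "
            "their correlations are undefined (NA)",
            stacklevel=2,
        )
        r[constant, :] = np.nan
        r[:, constant] = np.nan
    np.fill_diagonal(r, 1.0)
    return SquareMatrix(r, list(labels) if labels is not None else list(range(n_parcels)),
                        kind="coalteration")


def hit_map(effects: DisorderEffectSet, part: str = "all") -> ParcelMap:
    """Sum of per-disorder z-scored effect maps ('hit map').

    ``part='reductions'`` zeroes positive Cohen's d entries before z-scoring
    (shared thickness reductions only); ``'increases'`` analogously keeps the
    positive part. Zero-variance maps are skipped with a warning.
    """
    if part not in ("all", "reductions", "increases"):
        raise ValueError("part must be 'all', 'reductions' or 'increases'")
    X = effects.effects.copy()
    if part == "reductions":
        X = np.where(X < 0, X, 0.0)
    elif part == "increases":
        X = np.where(X > 0, X, 0.0)
    total = np.zeros(X.shape[0])
    for j, name in enumerate(effects.disorder_id):
        col = X[:, j]
        sd = np.nanstd(col, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"disorder {name!r} has zero-variance map for part={part!r}; skipped",
                          stacklevel=2)
            continue
        total = total + (col - np.nanmean(col)) / sd
    return ParcelMap(total, name=f"hit_map_{part}", units="summed z")


def threshold_matrix(m: SquareMatrix, sparsity: float = 0.8, scope: str = "global") -> SquareMatrix:
    """Zero all but the strongest (1 - sparsity) fraction of connections.

    ``scope='global'`` ranks the upper-triangle entries by signed value and
    keeps the top ceil((1-sparsity) * n_edges), zeroing symmetrically;
    ``scope='row'`` keeps the top ceil((1-sparsity) * (n-1)) entries of each
    row independently (the result is generally not symmetric and is returned
    as a raw array — see :func:`threshold_rows`). Ties are broken by value,
    then lower label index. The diagonal is always zeroed.
    """
    if not (0 <= sparsity < 1):
        raise ValueError("sparsity must be in [0, 1)")
    if scope == "row":
        return RowThresholdedMatrix(threshold_rows(m.entries, sparsity), m.labels, m.kind)
    if scope != "global":
        raise ValueError("scope must be 'global' or 'row'")
    A = m.entries.copy()
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = A[iu, ju]
    n_keep = math.ceil((1.0 - sparsity) * vals.size)
    # deterministic: sort by (-value, i, j)
    order = np.lexsort((ju, iu, -vals))
    keep = order[:n_keep]
    out = np.zeros_like(A)
    out[iu[keep], ju[keep]] = vals[keep]
    out = out + out.T
    return SquareMatrix(out, m.labels, m.kind)


class RowThresholdedMatrix:
    """Row-wise thresholded matrix; not necessarily symmetric."""

    def __init__(self, entries: np.ndarray, labels, kind: str):
        self.entries = np.asarray(entries, float)
        self.labels = list(labels)
        self.kind = kind

    @property
    def n(self) -> int:
        return len(self.labels)


def threshold_rows(entries: np.ndarray, sparsity: float = 0.8) -> np.ndarray:
    """Keep the top (1-sparsity) fraction of each row's off-diagonal entries."""
    if not (0 <= sparsity < 1):
        raise ValueError("sparsity must be in [0, 1)")
    A = np.asarray(entries, float).copy()
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    n_keep = math.ceil((1.0 - sparsity) * (n - 1))
    out = np.zeros_like(A)
    cols = np.arange(n)
    for i in range(n):
        row = A[i].copy()
        row[i] = -np.inf
        off = cols != i
        order = np.lexsort((cols[off], -row[off]))
        keep = cols[off][order[:n_keep]]
        out[i, keep] = A[i, keep]
    return out


def degree_hubs(m: SquareMatrix, sparsity: float = 0.8, mode: str = "weighted_sum",
                scope: str = "global") -> HubMap:
    """Degree centrality on the thresholded matrix.

    ``weighted_sum`` sums the retained edge weights at each parcel (default,
    the covariance-network convention for 'sum of strong connections');
    ``binary_count`` counts retained edges.
    """
    if mode not in ("weighted_sum", "binary_count"):
        raise ValueError("mode must be 'weighted_sum' or 'binary_count'")
    thr = threshold_matrix(m, sparsity=sparsity, scope=scope)
    A = thr.entries
    if scope == "row":
        # an edge counts as retained if kept in either endpoint's row
        A = np.where(A != 0, A, A.T)
    deg = A.sum(axis=1) if mode == "weighted_sum" else (A != 0).sum(axis=1).astype(float)
    return HubMap(ParcelMap(deg, name="degree", units="degree"), sparsity, mode, scope)


def pearson_pairwise(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r over pairwise-complete entries."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < MIN_COMPLETE_PAIRS:
        raise ValueError(f"fewer than {MIN_COMPLETE_PAIRS} complete pairs")
    aa, bb = a[ok], b[ok]
    with np.errstate(invalid="ignore"):
        return float(np.corrcoef(aa, bb)[0, 1])


def correlate_maps(a: ParcelMap, b: ParcelMap, spins: SpinEnsemble,
                   sided: str = "two") -> tuple[float, float]:
    """Pearson correlation of two parcel maps with spin-test significance.

    Map ``a`` is spun; the null distribution is the correlation of each
    rotated surrogate of ``a`` with ``b``. Returns ``(r, p_spin)``.
    """
    r_obs = pearson_pairwise(a.values, b.values)
    surrogates = spin_map(a, spins)
    nulls = _corr_rows_with(surrogates, b.values)
    return r_obs, spin_pvalue(r_obs, nulls, sided=sided)


def _corr_rows_with(rows: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``rows`` with vector ``y`` (pairwise-complete per row)."""
    y = np.asarray(y, float)
    ok_y = np.isfinite(y)
    if np.isfinite(rows).all() and ok_y.all():
        X = rows - rows.mean(axis=1, keepdims=True)
        yy = y - y.mean()
        denom = np.sqrt((X**2).sum(axis=1) * (yy**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            return (X @ yy) / denom
    return np.array([pearson_pairwise(row, y) for row in rows])
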