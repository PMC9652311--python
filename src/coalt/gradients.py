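"""Diffusion-map gradients of the co-alteration matrix.

The matrix is row-thresholded (top 20% of each parcel's connections kept),
converted to a normalized-angle affinity, and decomposed with diffusion map
embedding (anisotropy alpha = 0.5, diffusion-time-zero scaling), yielding
unitless components G1, G2, ... that order parcels by the similarity of their
covariance profiles. Variance explained is reported as each nontrivial
eigenvalue over the sum of the retained nontrivial eigenvalues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.stats import rankdata

from .atlas import DisorderEffectSet, SquareMatrix
from .coalteration import coalteration_matrix, threshold_rows

_DEGENERACY_TOL = 1e-10


@dataclass
class GradientSet:
    """Diffusion embedding components with their spectrum and provenance."""

    components: np.ndarray          # (n_parcels, k); G1 = column 0
    eigenvalues: np.ndarray         # k nontrivial Markov eigenvalues, descending
    alpha: float
    sparsity: float
    diffusion_time: str = "t=0 (lambda/(1-lambda) scaling)"
    sign_anchor: str = "largest-|loading| positive"
    degenerate_pairs: list = field(default_factory=list)

    @property
    def g1(self) -> np.ndarray:
        return self.components[:, 0]

    @property
    def g2(self) -> np.ndarray:
        return self.components[:, 1]

    def variance_fraction(self) -> np.ndarray:
        return variance_explained(self)


def build_affinity(m: SquareMatrix, sparsity: float = 0.8) -> SquareMatrix:
    """Row-threshold a matrix and apply the normalized-angle similarity kernel.

    Each row keeps its top (1 - sparsity) fraction of connections; affinity is
    ``1 - arccos(cosine(row_i, row_j)) / pi`` on the thresholded rows, a
    nonnegative symmetric similarity in [0, 1] with unit diagonal.
    """
    thr = threshold_rows(m.entries, sparsity)
    norms = np.linalg.norm(thr, axis=1)
    if np.any(norms == 0):
        bad = m.labels[int(np.argmax(norms == 0))]
        raise ValueError(f"parcel {bad!r} has an all-zero row after thresholding")
    cos = (thr @ thr.T) / np.outer(norms, norms)
    np.clip(cos, -1.0, 1.0, out=cos)
    aff = 1.0 - np.arccos(cos) / np.pi
    aff = (aff + aff.T) / 2.0
    np.fill_diagonal(aff, 1.0)
    return SquareMatrix(aff, m.labels, kind="affinity")


def diffusion_embedding(aff: SquareMatrix, alpha: float = 0.5, n_components: int = 10,
                        sign_anchor: np.ndarray | None = None,
                        scale_by_lambda: bool = True) -> GradientSet:
    """Diffusion map embedding of a nonnegative symmetric affinity matrix.

    The affinity is density-normalized (``W' = D^-alpha W D^-alpha``), turned
    into a Markov transition operator, and eigendecomposed via the conjugate
    symmetric form. The trivial stationary component is dropped; with the
    diffusion-time-zero rule each component i is scaled by
    ``lambda_i / (1 - lambda_i)``. Signs are fixed deterministically: each
    component is flipped so its correlation with ``sign_anchor`` is
    nonnegative (fallback: its largest-magnitude loading is positive).
    """
    W = np.asarray(aff.entries, float)
    if np.any(W < -1e-12):
        raise ValueError("affinity must be nonnegative")
    n = W.shape[0]
    if not 1 <= n_components <= n - 1:
        raise ValueError("n_components must be in [1, n-1]")

    d = W.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("affinity has an all-zero row")
    W_alpha = W / np.outer(d**alpha, d**alpha)
    d_alpha = W_alpha.sum(axis=1)
    # symmetric conjugate of the Markov operator P = D^-1 W_alpha
    inv_sqrt = 1.0 / np.sqrt(d_alpha)
    S = W_alpha * np.outer(inv_sqrt, inv_sqrt)
    S = (S + S.T) / 2.0
    lam, vec = eigh(S)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]

    # right eigenvectors of P; normalize against the stationary component
    phi = vec * inv_sqrt[:, None]
    psi = phi / phi[:, [0]]
    lam_nt = lam[1 : n_components + 1]
    comps = psi[:, 1 : n_components + 1].copy()
    if scale_by_lambda:
        lam_safe = np.minimum(lam_nt, 1.0 - 1e-12)
        comps = comps * (lam_safe / (1.0 - lam_safe))

    degenerate = [
        (i, i + 1) for i in range(len(lam_nt) - 1) if lam_nt[i] - lam_nt[i + 1] < _DEGENERACY_TOL
    ]
    if degenerate:
        warnings.warn(f"near-degenerate eigenvalue pairs: {degenerate}", stacklevel=2)

    anchor_desc = "largest-|loading| positive"
    for i in range(comps.shape[1]):
        c = comps[:, i]
        if sign_anchor is not None and np.std(sign_anchor) > 0 and np.std(c) > 0:
            s = np.corrcoef(c, sign_anchor)[0, 1]
            anchor_desc = "anchor map"
        else:
            s = c[int(np.argmax(np.abs(c)))]
        if s < 0:
            comps[:, i] = -c
    return GradientSet(comps, lam_nt, alpha=alpha, sparsity=np.nan,
                       sign_anchor=anchor_desc, degenerate_pairs=degenerate)


def variance_explained(g: GradientSet) -> np.ndarray:
    """Fraction lambda_i / sum(lambda_j) over the retained nontrivial spectrum."""
    lam = np.clip(np.asarray(g.eigenvalues, float), 0.0, None)
    total = lam.sum()
    if total == 0:
        raise ValueError("all-zero spectrum")
    return lam / total


def compute_gradients(m: SquareMatrix, sparsity: float = 0.8, alpha: float = 0.5,
                      n_components: int = 10, sign_anchor: np.ndarray | None = None) -> GradientSet:
    """Convenience: affinity construction + diffusion embedding in one call."""
    g = diffusion_embedding(build_affinity(m, sparsity=sparsity), alpha=alpha,
                            n_components=n_components, sign_anchor=sign_anchor)
    g.sparsity = sparsity
    return g


def bin_gradient(component: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Quantile bins along a gradient (5-percentile bins for the default 20).

    Returns integer bin labels 1..n_bins per parcel. Rank-based, hence
    invariant to monotone transforms; tied values share the lower bin.
    """
    x = np.asarray(component, float)
    if not np.isfinite(x).all():
        raise ValueError("component values must be finite")
    n = x.size
    if n_bins > n:
        raise ValueError("n_bins exceeds number of parcels")
    ranks = rankdata(x, method="min")  # ties -> lowest shared rank -> lower bin
    bins = np.floor((ranks - 1) * n_bins / n).astype(int) + 1
    return np.minimum(bins, n_bins)


def gradient_stability(effects: DisorderEffectSet, sparsity: float = 0.8, alpha: float = 0.5,
                       n_components: int = 10, weights: np.ndarray | None = None) -> pd.DataFrame:
    """Leave-one-disorder-out stability of G1 and G2.

    For each excluded disorder, the co-alteration matrix and gradients are
    recomputed and compared (absolute Pearson r after sign alignment) with the
    full-sample gradients. Needs at least 4 disorders so every reduced matrix
    still correlates across >= 3 disorders.
    """
    if effects.n_disorders < 4:
        raise ValueError("leave-one-out stability needs at least 4 disorders")
    full = compute_gradients(coalteration_matrix(effects, weights=weights),
                             sparsity=sparsity, alpha=alpha, n_components=n_components)
    rows = []
    for disorder in effects.disorder_id:
        reduced_effects = effects.drop(disorder)
        w = None
        if weights is not None:
            keep = [d != disorder for d in effects.disorder_id]
            w = np.asarray(weights)[keep]
        red = compute_gradients(coalteration_matrix(reduced_effects, weights=w),
                                sparsity=sparsity, alpha=alpha, n_components=n_components)
        rows.append({
            "excluded": disorder,
            "abs_r_G1": abs(float(np.corrcoef(full.g1, red.g1)[0, 1])),
            "abs_r_G2": abs(float(np.corrcoef(full.g2, red.g2)[0, 1])),
        })
    return pd.DataFrame(rows)
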