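"""Positioning individual disorders within the transdiagnostic framework.

Within-disorder covariance is defined from inverted absolute differences of a
disorder's Cohen's d values between regions; coupling maps correlate each
parcel's disorder-specific covariance profile with its transdiagnostic one.
Disorders are compared by map-wise correlation, clustered hierarchically, and
embedded by their relation to transdiagnostic hubs, epicenters and gradients.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .atlas import ConnectivityBundle, DisorderEffectSet, ParcelMap, SquareMatrix
from .coalteration import HubMap, correlate_maps
from .epicenters import map_epicenters
from .gradients import GradientSet
from .spins import SpinEnsemble


def disorder_covariance(d_map: ParcelMap, labels=None) -> SquareMatrix:
    """Within-disorder co-alteration: S(i, j) = -|d_i - d_j| (inverted differences).

    Larger (less negative) entries mean more similar illness effects; the
    diagonal is 0, the maximum.
    """
    d = d_map.values
    S = -np.abs(d[:, None] - d[None, :])
    return SquareMatrix(S, list(labels) if labels is not None else list(range(d.size)),
                        kind="similarity")


def coupling_map(disorder_m: SquareMatrix, trans_m: SquareMatrix) -> ParcelMap:
    """Per-parcel correlation between disorder-specific and transdiagnostic profiles.

    For each parcel i, Pearson r between row i of the disorder covariance and
    row i of the transdiagnostic co-alteration matrix, excluding entry i.
    """
    if disorder_m.n != trans_m.n:
        raise ValueError("matrices are on different atlases")
    n = disorder_m.n
    out = np.empty(n)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        a = disorder_m.entries[i, mask]
        b = trans_m.entries[i, mask]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
            out[i] = np.nan
        else:
            out[i] = np.corrcoef(a[ok], b[ok])[0, 1]
    return ParcelMap(out, name="coupling", units="Pearson r")


def cross_disorder_similarity(effects: DisorderEffectSet, k: int = 2,
                              method: str = "average") -> tuple[SquareMatrix, np.ndarray]:
    """Pairwise disorder-map correlations and their hierarchical clustering.

    Agglomerative clustering (default average linkage) on distance 1 - r,
    cut at ``k`` clusters. Cluster labels are renumbered deterministically so
    that cluster 1 contains the first disorder (by column order), etc.
    """
    if effects.n_disorders < 3:
        raise ValueError("need at least 3 disorders")
    X = effects.effects
    if np.any(np.nanstd(X, axis=0) == 0):
        raise ValueError("constant disorder map; correlation undefined")
    R = np.corrcoef(X.T)
    sim = SquareMatrix(R, effects.disorder_id, kind="similarity")
    dist = 1.0 - R
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    # deterministic labels: order clusters by their smallest member index
    order = {}
    for member in range(len(raw)):
        order.setdefault(raw[member], len(order) + 1)
    labels = np.array([order[c] for c in raw], dtype=int)
    return sim, labels


def embed_disorders(effects: DisorderEffectSet, hubs: HubMap, trans_epicenters: pd.DataFrame,
                    gradients: GradientSet, conn: ConnectivityBundle, spins: SpinEnsemble,
                    alpha: float = 0.05, overlap_denominator: str = "transdiagnostic") -> pd.DataFrame:
    """Per-disorder coordinates in the transdiagnostic co-alteration space.

    For each disorder: correlation (+ spin p) of its Cohen's d map with the
    transdiagnostic hub map and with G1/G2; and the percent overlap between
    its disorder-specific significant epicenters (epicenter mapping run on
    the d map) and the transdiagnostic significant epicenters. Overlap is 0
    with a flag when either set is empty.
    """
    if overlap_denominator not in ("transdiagnostic", "jaccard"):
        raise ValueError("overlap_denominator must be 'transdiagnostic' or 'jaccard'")
    trans_sig = set(trans_epicenters.loc[trans_epicenters["significant"].fillna(False), "seed"])
    g1 = ParcelMap(gradients.g1, name="G1")
    g2 = ParcelMap(gradients.g2, name="G2")
    rows = []
    for disorder in effects.disorder_id:
        d_map = effects.column(disorder)
        r_hub, p_hub = correlate_maps(d_map, hubs.map, spins)
        r_g1, p_g1 = correlate_maps(d_map, g1, spins)
        r_g2, p_g2 = correlate_maps(d_map, g2, spins)
        res = map_epicenters(d_map, conn, spins, alpha=alpha)
        dis_sig = set(res.loc[res["significant"].fillna(False), "seed"])
        flag = ""
        if not dis_sig:
            flag = "no disorder-specific epicenters"
            overlap = 0.0
        elif not trans_sig:
            flag = "no transdiagnostic epicenters"
            overlap = 0.0
        elif overlap_denominator == "jaccard":
            overlap = 100.0 * len(dis_sig & trans_sig) / len(dis_sig | trans_sig)
        else:
            overlap = 100.0 * len(dis_sig & trans_sig) / len(trans_sig)
        rows.append({
            "disorder_id": disorder,
            "r_hub": r_hub, "p_spin_hub": p_hub,
            "epicenter_overlap_pct": overlap,
            "n_disorder_epicenters": len(dis_sig),
            "r_G1": r_g1, "p_spin_G1": p_g1,
            "r_G2": r_g2, "p_spin_G2": p_g2,
            "flag": flag,
        })
    return pd.DataFrame(rows)
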