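"""Disease-epicenter mapping.

A seed region is a candidate epicenter when its normative connectivity profile
spatially resembles the co-alteration hub map: for each of the 68 cortical and
14 subcortical seeds, the seed's connectivity profile is correlated with the
hub map (Pearson r), significance is assessed by spinning the hub map
(two-sided), and significant seeds are ranked by descending r. For cortical
seeds the seed's own parcel is excluded from both vectors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atlas import ConnectivityBundle, ParcelMap
from .coalteration import HubMap
from .spins import SpinEnsemble, spin_map, spin_pvalue


def _corr_excluding(profile: np.ndarray, target: np.ndarray, exclude: int | None) -> float:
    if exclude is not None:
        mask = np.ones(profile.size, bool)
        mask[exclude] = False
        profile, target = profile[mask], target[mask]
    ok = np.isfinite(profile) & np.isfinite(target)
    if ok.sum() < 3 or np.std(profile[ok]) == 0 or np.std(target[ok]) == 0:
        return np.nan
    return float(np.corrcoef(profile[ok], target[ok])[0, 1])


def _null_corrs(profile: np.ndarray, surrogates: np.ndarray, exclude: int | None) -> np.ndarray:
    """Correlation of one seed profile with every surrogate map (vectorized)."""
    if exclude is not None:
        mask = np.ones(profile.size, bool)
        mask[exclude] = False
        profile, surrogates = profile[mask], surrogates[:, mask]
    if not (np.isfinite(profile).all() and np.isfinite(surrogates).all()):
        return np.array([_corr_excluding(profile, s, None) for s in surrogates])
    p = profile - profile.mean()
    S = surrogates - surrogates.mean(axis=1, keepdims=True)
    denom = np.sqrt((p**2).sum() * (S**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (S @ p) / denom


def map_epicenters(hubs: HubMap | ParcelMap, conn: ConnectivityBundle,
                   spins: SpinEnsemble, alpha: float = 0.05) -> pd.DataFrame:
    """Correlate every seed's connectivity profile with the hub (or any target) map.

    Returns one row per seed (cortical parcels first, then subcortical seeds)
    with columns ``seed``, ``seed_type``, ``r``, ``p_spin``, ``significant``
    and ``rank`` (descending r among significant seeds; NA otherwise). The hub
    map is the spun object, giving one common spatial null for all 82 seeds.
    """
    target = hubs.map if isinstance(hubs, HubMap) else hubs
    values = target.values
    n = values.size
    if conn.cortical.n != n:
        raise ValueError("hub map and cortical connectivity are on different atlases")
    surrogates = spin_map(values, spins)  # (n_spins, n)

    rows = []
    seeds = [(conn.cortical.labels[s], "cortical", conn.cortical.entries[s], s) for s in range(n)]
    seeds += [(lab, "subcortical", conn.subcortical_seeds[s], None)
              for s, lab in enumerate(conn.subcortical_labels)]
    for label, seed_type, profile, exclude in seeds:
        r = _corr_excluding(profile, values, exclude)
        if np.isnan(r):
            p = np.nan
        else:
            p = spin_pvalue(r, _null_corrs(profile, surrogates, exclude), sided="two")
        rows.append({"seed": label, "seed_type": seed_type, "r": r, "p_spin": p})

    res = pd.DataFrame(rows)
    res["significant"] = res["p_spin"] < alpha
    res["rank"] = pd.NA
    sig = res.index[res["significant"].fillna(False)]
    # descending r; ties broken by seed label for determinism
    order = sorted(sig, key=lambda i: (-res.at[i, "r"], str(res.at[i, "seed"])))
    for k, i in enumerate(order, start=1):
        res.at[i, "rank"] = k
    res.attrs["alpha"] = alpha
    res.attrs["modality"] = conn.modality
    return res


def top_epicenters(result: pd.DataFrame, k: int = 5) -> list[str]:
    """The k significant seeds with highest r (fewer if fewer are significant)."""
    sig = result[result["significant"].fillna(False)].copy()
    sig = sig.sort_values("rank")
    return [str(s) for s in sig["seed"].head(k)]
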