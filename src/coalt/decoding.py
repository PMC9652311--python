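"""Multi-level contextualization of gradients.

Three decoders: stratification of gradient values by von Economo-Koskinas
cytoarchitectonic class; meta-analytic term decoding along five-percentile
gradient bins with center-of-gravity ordering; and gene-expression decoding
with a spatial (spin-surrogate) null per gene plus two set-level gene-
specificity nulls (coexpression-matched random sets and brain-expressed
random sets).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import AtlasMetadata
from .gradients import bin_gradient
from .spins import SpinEnsemble, spin_map, spin_pvalue


def stratify_by_class(component: np.ndarray, atlas: AtlasMetadata) -> pd.DataFrame:
    """Group gradient values by cytoarchitectonic class; descriptive only.

    Returns one row per class with n, mean, sd, median, min, max. No
    inferential statistic is computed.
    """
    if atlas.cyto_class is None:
        raise ValueError("atlas has no cytoarchitectonic class labels")
    x = np.asarray(component, float)
    df = pd.DataFrame({"cyto_class": atlas.cyto_class, "value": x})
    out = (
        df.groupby("cyto_class", sort=True)["value"]
        .agg(n="count", mean="mean", sd="std", median="median", min="min", max="max")
        .reset_index()
    )
    return out


@dataclass
class TermDecodingResult:
    """Bin-wise term associations and their centers of gravity along a gradient."""

    z_by_bin: pd.DataFrame       # n_bins x n_terms mean z
    cog: pd.Series               # per-term center of gravity, in bin units 1..n_bins
    ordering: list[str]          # terms sorted by center of gravity


def term_decoding(terms: pd.DataFrame, component: np.ndarray, n_bins: int = 20) -> TermDecodingResult:
    """Decode term maps along a gradient's quantile bins.

    Each bin's association with a term is the mean parcel z within the bin;
    the center of gravity weights bin positions by the positive part of the
    bin profile: ``cog(t) = sum_b b * max(z(b,t), 0) / sum_b max(z(b,t), 0)``.
    Terms with no positive association in any bin get ``cog = NA``.
    """
    z = terms.to_numpy(dtype=float)
    if z.shape[0] != np.asarray(component).size:
        raise ValueError("term table and gradient have different numbers of parcels")
    bins = bin_gradient(component, n_bins=n_bins)
    z_by_bin = np.full((n_bins, z.shape[1]), np.nan)
    for b in range(1, n_bins + 1):
        members = bins == b
        if members.any():
            z_by_bin[b - 1] = z[members].mean(axis=0)
    zb = pd.DataFrame(z_by_bin, index=np.arange(1, n_bins + 1), columns=terms.columns)

    pos = np.clip(z_by_bin, 0.0, None)
    weight_sum = np.nansum(pos, axis=0)
    b_idx = np.arange(1, n_bins + 1, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        cog_vals = np.nansum(pos * b_idx[:, None], axis=0) / weight_sum
    cog_vals = np.where(weight_sum > 0, cog_vals, np.nan)
    cog = pd.Series(cog_vals, index=terms.columns, name="cog")
    ordering = list(cog.sort_values(kind="stable").dropna().index) + list(cog.index[cog.isna()])
    return TermDecodingResult(zb, cog, ordering)


def term_positions_2d(terms: pd.DataFrame, g1: np.ndarray, g2: np.ndarray,
                      n_bins: int = 20) -> pd.DataFrame:
    """Per-term weighted mean position in the (G1, G2) bin plane."""
    cog1 = term_decoding(terms, g1, n_bins=n_bins).cog
    cog2 = term_decoding(terms, g2, n_bins=n_bins).cog
    return pd.DataFrame({"cog_G1": cog1, "cog_G2": cog2})


@dataclass
class GeneDecodingResult:
    """Per-gene gradient correlations with spatial and gene-specificity nulls."""

    table: pd.DataFrame          # gene, r, p_spatial, candidate, brain_expressed
    candidate_set: list[str]
    set_statistic: float         # mean |r| over the candidate set
    p_coexp_null: float | None
    p_brain_null: float | None
    n_positive: int
    n_negative: int


def _corr_with_columns(x: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Pearson r of vector x with each column of M."""
    xz = (x - x.mean()) / x.std(ddof=0)
    Mz = (M - M.mean(axis=0)) / M.std(axis=0, ddof=0)
    return (Mz.T @ xz) / x.size


def gene_decoding(expression: pd.DataFrame, component: np.ndarray, spins: SpinEnsemble,
                  brain_expressed: pd.Series | np.ndarray | None = None,
                  p_cut: float = 0.01, n_null_sets: int = 1000,
                  seed: int = 0, coexp_tolerance: float = 1.0) -> GeneDecodingResult:
    """Correlate gene expression maps with a gradient, with three nulls.

    Spatial specificity: each gene's observed r is compared against its
    correlations with spin surrogates of the gradient (two-sided, add-one
    rule); genes at ``p_spatial < p_cut`` form the candidate set. Gene
    specificity of the set statistic (mean |r|) is then tested against (i)
    random gene sets matched to the candidate set's coexpression-level decile
    profile and (ii) random sets drawn from brain-expressed genes only.
    """
    g = np.asarray(component, float)
    X = expression.to_numpy(dtype=float)
    genes = list(expression.columns)
    if X.shape[0] != g.size:
        raise ValueError("expression table and gradient have different numbers of parcels")

    r_obs = _corr_with_columns(g, X)
    surrogates = spin_map(g, spins)                       # (S, n_parcels)
    Gz = (surrogates - surrogates.mean(axis=1, keepdims=True))
    Gz /= Gz.std(axis=1, keepdims=True, ddof=0)
    Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    nulls = (Gz @ Xz) / g.size                            # (S, n_genes)
    exceed = (np.abs(nulls) >= np.abs(r_obs)[None, :]).sum(axis=0)
    p_spatial = (1 + exceed) / (1 + spins.n_spins)

    candidate = p_spatial < p_cut
    table = pd.DataFrame({
        "gene": genes,
        "r": r_obs,
        "p_spatial": p_spatial,
        "candidate": candidate,
    })
    if brain_expressed is not None:
        table["brain_expressed"] = np.asarray(brain_expressed, bool)

    candidate_set = [genes[j] for j in np.flatnonzero(candidate)]
    n_pos = int(np.sum(r_obs[candidate] > 0))
    n_neg = int(np.sum(r_obs[candidate] < 0))
    if not candidate_set:
        warnings.warn("candidate gene set is empty; specificity tests skipped", stacklevel=2)
        return GeneDecodingResult(table, [], np.nan, None, None, 0, 0)

    rng = np.random.default_rng(seed)
    set_idx = np.flatnonzero(candidate)
    obs_stat = float(np.mean(np.abs(r_obs[set_idx])))
    k = set_idx.size

    # coexpression level per gene: mean |r| with all other genes
    C = np.corrcoef(Xz.T)
    np.fill_diagonal(C, np.nan)
    coexp = np.nanmean(np.abs(C), axis=1)
    deciles = np.clip(np.searchsorted(np.quantile(coexp, np.linspace(0.1, 0.9, 9)), coexp), 0, 9)
    target_hist = np.bincount(deciles[set_idx], minlength=10)

    null_coexp = np.empty(n_null_sets)
    null_mean_coexp = np.empty(n_null_sets)
    pool_by_decile = [np.flatnonzero(deciles == d) for d in range(10)]
    for b in range(n_null_sets):
        chosen = []
        for d in range(10):
            need = target_hist[d]
            if need == 0:
                continue
            pool = pool_by_decile[d]
            chosen.append(rng.choice(pool, size=min(need, pool.size), replace=False))
        idx = np.concatenate(chosen)
        null_coexp[b] = np.mean(np.abs(r_obs[idx]))
        null_mean_coexp[b] = np.mean(coexp[idx])
    # decile matching must keep null sets at the candidate set's coexpression level
    cand_coexp = float(np.mean(coexp[set_idx]))
    coexp_band = coexp_tolerance * float(np.std(coexp, ddof=0))
    dev = abs(float(np.mean(null_mean_coexp)) - cand_coexp)
    if dev > coexp_band:
        warnings.warn(
            "null-coexpressed sets sit below the candidate set's coexpression level "
            f"(mean dev {dev:.3g} > band {coexp_band:.3g}); decile matching cannot track "
            "a candidate set in the extreme tail of the coexpression distribution",
            stacklevel=2,
        )
    p_coexp = spin_pvalue(obs_stat, null_coexp, sided="greater")

    if brain_expressed is not None:
        brain_idx = np.flatnonzero(np.asarray(brain_expressed, bool))
        if brain_idx.size < k:
            warnings.warn("fewer brain-expressed genes than the candidate set; brain null skipped",
                          stacklevel=2)
            p_brain = None
        else:
            null_brain = np.empty(n_null_sets)
            for b in range(n_null_sets):
                idx = rng.choice(brain_idx, size=k, replace=False)
                null_brain[b] = np.mean(np.abs(r_obs[idx]))
            p_brain = spin_pvalue(obs_stat, null_brain, sided="greater")
    else:
        p_brain = None

    return GeneDecodingResult(table, candidate_set, obs_stat, p_coexp, p_brain, n_pos, n_neg)
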