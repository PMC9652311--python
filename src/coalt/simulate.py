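"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the shape of the real study inputs — six parcel-wise
Cohen's d maps on a 68-parcel bilateral atlas, normative cortico-cortical and
subcortico-cortical connectivity, and annotation tables — with planted,
recoverable structure:

* a shared latent spatial pattern loaded by a block of disorders (emulating
  the SCZ/BD/OCD cluster), so co-alteration and clustering have signal;
* spatial autocorrelation, by smoothing white noise with a von-Mises-like
  kernel on great-circle distance, so spin nulls are tested honestly;
* planted connectome epicenters whose seed profiles resemble the hub map;
* term maps whose peaks march along a target gradient, and expression tables
  with a known subset of signal genes.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import CYTO_CLASSES, AtlasMetadata, ConnectivityBundle, DisorderEffectSet, ParcelMap, SquareMatrix

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0

# ENIGMA-style disorder labels and sample sizes used as simulation defaults;
# the first three form the shared-pattern block.
DEFAULT_DISORDERS = ("SCZ", "BD", "OCD", "MDD", "ASD", "ADHD")
DEFAULT_N_CASES = (4474, 1837, 1498, 1911, 1571, 733)
DEFAULT_N_CONTROLS = (5098, 2582, 1436, 7663, 1651, 539)

SUBCORTICAL_LABELS = tuple(
    f"{h}_{s}" for h in ("L", "R")
    for s in ("accumbens", "amygdala", "caudate", "hippocampus", "pallidum", "putamen", "thalamus")
)


def _default_loadings() -> np.ndarray:
    # rows = disorders (DEFAULT_DISORDERS order), cols = latent patterns 1, 2.
    # Block disorders load the shared latent; the rest load the second axis.
    return np.array(
        [
            [1.00, 0.10],
            [0.90, 0.15],
            [0.80, 0.05],
            [0.10, 0.80],
            [0.05, 0.70],
            [0.00, 0.60],
        ]
    )


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the conditions every test runs at."""

    n_parcels_per_hemi: int = 34
    n_disorders: int = 6
    shared_block: tuple = (0, 1, 2)
    latent_loadings: np.ndarray = field(default_factory=_default_loadings)
    latent_patterns: str = "harmonics"  # or "two_block"
    autocorr_length: float = 0.3        # radians, angular scale of smoothing
    noise_sd: float = 0.5               # residual Cohen's d s.d.
    epicenter_parcels: tuple = (5, 40)  # planted cortical epicenter indices
    subcortical_epicenters: tuple = (3, 10)
    conn_noise_sd: float = 0.1          # noise on planted epicenter profiles
    hub_coupling: float = 1.5           # degree scaling toward the hub target
    n_terms: int = 24
    term_noise_sd: float = 0.1
    n_genes: int = 500
    n_signal_genes: int = 20
    signal_r: float = 0.8
    brain_expressed_frac: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.latent_loadings = np.asarray(self.latent_loadings, dtype=float)
        for name in ("autocorr_length", "noise_sd", "conn_noise_sd", "term_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.autocorr_length == 0:
            raise ValueError("autocorr_length must be positive")


def two_block_config(**overrides) -> SimulationConfig:
    """Preset planting a clean two-block co-alteration structure.

    All disorders load a single binary latent (parcels split by the
    anterior-posterior coordinate), so the co-alteration matrix has two
    blocks and the principal gradient should separate them. Loadings
    alternate in sign across disorders: inter-regional correlations are taken
    across disorders, so only disorder-to-disorder loading variation creates
    covariance structure.
    """
    loadings = np.array(
        [[1.00, 0.0], [-0.90, 0.0], [1.10, 0.0], [-0.95, 0.0], [1.05, 0.0], [-0.85, 0.0]]
    )
    cfg = SimulationConfig(latent_loadings=loadings, latent_patterns="two_block", noise_sd=0.5)
    return replace(cfg, **overrides) if overrides else cfg


def make_atlas(config: SimulationConfig) -> AtlasMetadata:
    """Quasi-uniform bilateral atlas on per-hemisphere spheres.

    Each hemisphere's centroids are a Fibonacci lattice covering a full unit
    sphere — the registration-sphere geometry spin tests are defined on, under
    which a rotation is a closed isometry of the hemisphere's domain. The
    right hemisphere mirrors the left (x -> -x). Cytoarchitectonic classes
    are assigned by latitude (z) bands, five per hemisphere.
    """
    n = config.n_parcels_per_hemi
    if n < 4:
        raise ValueError("n_parcels_per_hemi must be >= 4")
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    sin_theta = np.sqrt(1.0 - z**2)
    phi = 2.0 * np.pi * ((k * _GOLDEN) % 1.0)
    left = np.column_stack([sin_theta * np.cos(phi), sin_theta * np.sin(phi), z])
    left /= np.linalg.norm(left, axis=1, keepdims=True)
    right = left * np.array([-1.0, 1.0, 1.0])

    band = np.minimum((np.argsort(np.argsort(-z)) * 5) // n, 4)
    cyto = np.array([CYTO_CLASSES[b] for b in band], dtype=object)

    return AtlasMetadata(
        parcel_id=np.array([f"lh_p{i+1:02d}" for i in range(n)]
                           + [f"rh_p{i+1:02d}" for i in range(n)], dtype=object),
        hemisphere=np.array(["L"] * n + ["R"] * n, dtype=object),
        centroid=np.vstack([left, right]),
        cyto_class=np.concatenate([cyto, cyto]),
    )


def smoothing_kernel(centroids: np.ndarray, length: float) -> np.ndarray:
    """Row-normalized von-Mises-like kernel on great-circle distance."""
    cos_d = np.clip(centroids @ centroids.T, -1.0, 1.0)
    K = np.exp((cos_d - 1.0) / length**2)
    return K / K.sum(axis=1, keepdims=True)


def smooth_noise(atlas: AtlasMetadata, rng: np.random.Generator, length: float,
                 size: int = 1) -> np.ndarray:
    """(n_parcels, size) spatially autocorrelated standard-normalized noise fields.

    White noise is kernel-smoothed within each hemisphere's sphere; the two
    hemispheres' fields are independent and each is standardized within its
    hemisphere. This matches the per-hemisphere geometry the spin null
    rotates on: a hemisphere-mean offset is invariant under within-hemisphere
    rotation, so leaving one in the noise would hand the maps a component the
    spin null can never explore.
    """
    raw = rng.standard_normal((atlas.n_parcels, size))
    sm = np.empty_like(raw)
    for h in ("L", "R"):
        idx = np.flatnonzero(atlas.hemisphere == h)
        K = smoothing_kernel(atlas.centroid[idx], length)
        v = K @ raw[idx]
        sm[idx] = (v - v.mean(axis=0)) / v.std(axis=0, ddof=0)
    return sm


def latent_patterns(atlas: AtlasMetadata, kind: str = "harmonics") -> np.ndarray:
    """(n_parcels, 2) latent spatial patterns, z-scored across parcels.

    ``harmonics``: anterior-posterior (y) and inferior-superior (z) axes —
    fixed low-order spherical harmonics, mirror-symmetric across hemispheres.
    ``two_block``: a binary anterior/posterior split plus the z axis.
    """
    y, z = atlas.centroid[:, 1], atlas.centroid[:, 2]
    if kind == "harmonics":
        pats = np.column_stack([y, z])
    elif kind == "two_block":
        pats = np.column_stack([np.where(y >= np.median(y), 1.0, -1.0), z])
    else:
        raise ValueError("latent kind must be 'harmonics' or 'two_block'")
    return (pats - pats.mean(axis=0)) / pats.std(axis=0, ddof=0)


def two_block_labels(atlas: AtlasMetadata) -> np.ndarray:
    """Ground-truth block membership used by the two-block preset."""
    y = atlas.centroid[:, 1]
    return y >= np.median(y)


def make_effects(atlas: AtlasMetadata, config: SimulationConfig) -> DisorderEffectSet:
    """Disorder effect maps: latent patterns x loadings + smooth residual noise."""
    rng = np.random.default_rng(config.seed)
    lat = latent_patterns(atlas, config.latent_patterns)
    loadings = config.latent_loadings[: config.n_disorders]
    effects = lat @ loadings.T
    if config.noise_sd > 0:
        effects = effects + config.noise_sd * smooth_noise(
            atlas, rng, config.autocorr_length, size=config.n_disorders
        )
    names = list(DEFAULT_DISORDERS[: config.n_disorders])
    if config.n_disorders > len(DEFAULT_DISORDERS):
        names += [f"D{j+1}" for j in range(len(DEFAULT_DISORDERS), config.n_disorders)]
    n_cases = list(DEFAULT_N_CASES[: config.n_disorders]) or None
    n_controls = list(DEFAULT_N_CONTROLS[: config.n_disorders]) or None
    if config.n_disorders > len(DEFAULT_DISORDERS):
        n_cases = n_controls = None
    return DisorderEffectSet(effects, names, n_cases, n_controls)


def _planted_profile(hub_values: np.ndarray) -> np.ndarray:
    h = np.asarray(hub_values, float)
    rng_v = h.max() - h.min()
    p = (h - h.min()) / rng_v if rng_v > 0 else np.full_like(h, 0.5)
    return p + 0.1


def make_connectome(atlas: AtlasMetadata, hub_target: ParcelMap,
                    config: SimulationConfig) -> ConnectivityBundle:
    """Symmetric nonnegative connectome with planted epicenters.

    Baseline connectivity is a smooth distance kernel scaled so that row sums
    increase with ``hub_target`` (hubby parcels are better connected). Each
    planted epicenter seed's profile is replaced by a positively rescaled copy
    of the hub target plus noise, so that seed's connectivity resembles the
    hub map. Subcortical seeds are built the same way: planted epicenters get
    hub-like profiles, the rest smooth random ones.
    """
    hub_target.check_atlas(atlas)
    rng = np.random.default_rng(config.seed + 1)
    n = atlas.n_parcels
    p = _planted_profile(hub_target.values)
    scale = 1.0 + config.hub_coupling * (p - p.min()) / (p.max() - p.min() if p.max() > p.min() else 1.0)
    cos_d = np.clip(atlas.centroid @ atlas.centroid.T, -1.0, 1.0)
    K = np.exp((cos_d - 1.0) / config.autocorr_length**2)
    W = np.outer(scale, scale) * K
    for s in config.epicenter_parcels:
        profile = p.copy()
        if config.conn_noise_sd > 0:
            profile = profile + config.conn_noise_sd * smooth_noise(atlas, rng, config.autocorr_length)[:, 0]
        profile = np.clip(profile, 0.0, None)
        W[s, :] = profile
        W[:, s] = profile
    np.fill_diagonal(W, 0.0)
    cortical = SquareMatrix(W, list(atlas.parcel_id), kind="connectivity")

    seeds = np.empty((len(SUBCORTICAL_LABELS), n))
    for i in range(len(SUBCORTICAL_LABELS)):
        if i in config.subcortical_epicenters:
            profile = p.copy()
            if config.conn_noise_sd > 0:
                profile = profile + config.conn_noise_sd * smooth_noise(atlas, rng, config.autocorr_length)[:, 0]
        else:
            v = smooth_noise(atlas, rng, config.autocorr_length)[:, 0]
            profile = v - v.min() + 0.1
        seeds[i] = np.clip(profile, 0.0, None)
    return ConnectivityBundle(cortical, seeds, list(SUBCORTICAL_LABELS), modality="rs-fMRI")


def make_annotations(atlas: AtlasMetadata, gradient_target: ParcelMap,
                     config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Term z maps and gene expression with planted gradient alignment.

    Returns ``(terms, expression, genes)``: 24 term maps whose response peaks
    move monotonically along the target gradient; an expression table whose
    first ``n_signal_genes`` genes correlate with the gradient at roughly
    ``signal_r`` (the rest are spatially autocorrelated noise); and gene
    metadata with ``brain_expressed`` flags and the planted ground truth.
    """
    gradient_target.check_atlas(atlas)
    rng = np.random.default_rng(config.seed + 2)
    g = gradient_target.values
    q = (np.argsort(np.argsort(g)) + 0.5) / g.size  # gradient rank position in (0, 1)

    centers = (np.arange(config.n_terms) + 0.5) / config.n_terms
    width = 0.12
    terms = np.exp(-((q[:, None] - centers[None, :]) ** 2) / (2 * width**2))
    if config.term_noise_sd > 0:
        terms = terms + config.term_noise_sd * rng.standard_normal(terms.shape)
    terms_df = pd.DataFrame(
        terms, index=list(atlas.parcel_id),
        columns=[f"term_{t+1:02d}" for t in range(config.n_terms)],
    )

    gz = (g - g.mean()) / g.std(ddof=0)
    noise = smooth_noise(atlas, rng, config.autocorr_length, size=config.n_genes)
    rho = float(np.clip(config.signal_r, 0.0, 1.0))
    expr = noise.copy()
    k = config.n_signal_genes
    expr[:, :k] = rho * gz[:, None] + np.sqrt(1.0 - rho**2) * noise[:, :k]
    gene_names = [f"gene_{j+1:04d}" for j in range(config.n_genes)]
    expr_df = pd.DataFrame(expr, index=list(atlas.parcel_id), columns=gene_names)

    brain = rng.random(config.n_genes) < config.brain_expressed_frac
    brain[:k] = True
    genes_df = pd.DataFrame(
        {"gene": gene_names, "brain_expressed": brain,
         "planted_signal": np.arange(config.n_genes) < k}
    )
    return terms_df, expr_df, genes_df
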