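"""End-to-end orchestration of the co-alteration analysis on synthetic inputs.

`run_synthetic_study` generates a full synthetic dataset (effect maps,
connectome, annotations) and pushes it through every analysis stage. It is
the programmatic equivalent of running the CLI stages in sequence and is what
the worked example in the README executes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .atlas import AtlasMetadata, ConnectivityBundle, DisorderEffectSet, ParcelMap
from .coalteration import HubMap, coalteration_matrix, correlate_maps, degree_hubs, hit_map
from .decoding import GeneDecodingResult, TermDecodingResult, gene_decoding, term_decoding
from .disorders import cross_disorder_similarity, embed_disorders
from .epicenters import map_epicenters, top_epicenters
from .gradients import GradientSet, compute_gradients, variance_explained
from .simulate import SimulationConfig, make_annotations, make_atlas, make_connectome, make_effects
from .spins import SpinEnsemble, build_spins


@dataclass
class StudyResult:
    """All artifacts of one end-to-end run."""

    atlas: AtlasMetadata
    effects: DisorderEffectSet
    spins: SpinEnsemble
    matrix: object                  # co-alteration SquareMatrix
    hubs: HubMap
    hit: ParcelMap
    hub_hit_r: float
    hub_hit_p: float
    conn: ConnectivityBundle
    epicenters: pd.DataFrame
    top_epicenters: list
    gradients: GradientSet
    variance_fractions: object
    term_result: TermDecodingResult
    gene_result: GeneDecodingResult
    similarity: object
    cluster_labels: object
    positions: pd.DataFrame


def run_synthetic_study(config: SimulationConfig | None = None, n_spins: int = 1000,
                        sparsity: float = 0.8, alpha: float = 0.5,
                        n_components: int = 10, epicenter_alpha: float = 0.05,
                        gene_p_cut: float = 0.01, n_null_sets: int = 1000) -> StudyResult:
    """Generate a synthetic dataset and run the full analysis pipeline on it."""
    config = config or SimulationConfig()
    atlas = make_atlas(config)
    effects = make_effects(atlas, config)
    spins = build_spins(atlas, n_spins=n_spins, seed=config.seed + 101)

    matrix = coalteration_matrix(effects, labels=list(atlas.parcel_id))
    hubs = degree_hubs(matrix, sparsity=sparsity)
    hit = hit_map(effects)
    hub_hit_r, hub_hit_p = correlate_maps(hubs.map, hit, spins)

    conn = make_connectome(atlas, hubs.map, config)
    epi = map_epicenters(hubs, conn, spins, alpha=epicenter_alpha)
    top = top_epicenters(epi, k=5)

    grads = compute_gradients(matrix, sparsity=sparsity, alpha=alpha,
                              n_components=n_components,
                              sign_anchor=atlas.centroid[:, 1])
    var_frac = variance_explained(grads)

    g1_map = ParcelMap(grads.g1, name="G1")
    terms, expr, genes = make_annotations(atlas, g1_map, config)
    term_res = term_decoding(terms, grads.g1)
    gene_res = gene_decoding(expr, grads.g1, spins,
                             brain_expressed=genes["brain_expressed"],
                             p_cut=gene_p_cut, n_null_sets=n_null_sets,
                             seed=config.seed + 7)

    sim, labels = cross_disorder_similarity(effects, k=2)
    positions = embed_disorders(effects, hubs, epi, grads, conn, spins, alpha=epicenter_alpha)

    return StudyResult(
        atlas=atlas, effects=effects, spins=spins, matrix=matrix, hubs=hubs,
        hit=hit, hub_hit_r=hub_hit_r, hub_hit_p=hub_hit_p, conn=conn,
        epicenters=epi, top_epicenters=top, gradients=grads,
        variance_fractions=var_frac, term_result=term_res, gene_result=gene_res,
        similarity=sim, cluster_labels=labels, positions=positions,
    )
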