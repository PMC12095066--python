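"""Trait-panel reduction: Mantel correlations, modularity clustering,
heritability-based representatives, and min-max normalization.

Image-derived phenomics panels contain hundreds of highly redundant traits.
The reduction works on the traits' pairwise *distance structure* over the
lines: for each trait a k x k Euclidean distance matrix over its full time
profiles is computed, and the Mantel correlation between two traits is the
Pearson correlation of the strict lower triangles of their distance
matrices. Traits connected above a Mantel threshold form a graph whose
modularity communities define clusters; each cluster is represented by its
member with the highest mean SNP-based heritability over the timepoints.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist

from .containers import TraitTensor
from .markers import GRM, GRMEigen, grm_eigendecomposition, reml_single_component

__all__ = [
    "TraitClustering",
    "mantel_correlation_matrix",
    "build_trait_graph",
    "detect_modularity_clusters",
    "select_representative_traits",
    "minmax_normalize_tensor",
    "mean_heritability_over_time",
    "select_traits",
]

logger = logging.getLogger("dmdgp")


@dataclass
class TraitClustering:
    trait_ids: list[str]
    mantel: np.ndarray
    edge_threshold: float
    memberships: dict[str, int]
    representatives: list[str]
    mean_h2: dict[str, float]


def mantel_correlation_matrix(t: TraitTensor, method: str = "distance") -> np.ndarray:
    """p x p Mantel correlation matrix over all genotypes and timepoints.

    ``method='distance'`` (default) correlates the lower triangles of the
    per-trait line x line Euclidean distance matrices; ``method='flat'``
    is the plain Pearson correlation of the flattened line x time profiles.
    Traits whose distance entries have zero variance get NaN correlations
    (flagged), with a unit diagonal.
    """
    k, p = t.n_lines, t.n_traits
    if method == "distance":
        if k < 4:
            raise ValueError("need at least 4 lines for a meaningful Mantel statistic")
        rows = np.stack([pdist(t.values[:, j, :]) for j in range(p)])
    elif method == "flat":
        rows = t.values.transpose(1, 0, 2).reshape(p, -1)
    else:
        raise ValueError(f"unknown Mantel method {method!r}")
    sd = rows.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        for j in np.flatnonzero(degenerate):
            logger.warning("trait %r has zero distance variance; Mantel undefined",
                           t.trait_ids[j])
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.corrcoef(rows)
    M[degenerate, :] = np.nan
    M[:, degenerate] = np.nan
    np.fill_diagonal(M, 1.0)
    return M


def build_trait_graph(mantel: np.ndarray, threshold: float = 0.96,
                      absolute: bool = False) -> nx.Graph:
    """Unweighted trait graph with an edge where Mantel r exceeds the threshold.

    The default compares the signed correlation (r > threshold); with
    ``absolute=True`` the comparison uses |r|. Isolated nodes are retained.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    p = mantel.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(p))
    vals = np.abs(mantel) if absolute else mantel
    iu, ju = np.triu_indices(p, k=1)
    with np.errstate(invalid="ignore"):
        mask = vals[iu, ju] > threshold
    g.add_edges_from(zip(iu[mask], ju[mask]))
    return g


def detect_modularity_clusters(graph: nx.Graph) -> dict[int, int]:
    """Deterministic greedy (CNM-style) modularity communities.

    Returns node -> cluster label; labels are assigned in order of each
    community's smallest node index. An edgeless graph yields singletons.
    """
    if graph.number_of_edges() == 0:
        return {node: i for i, node in enumerate(sorted(graph.nodes))}
    communities = nx.community.greedy_modularity_communities(graph)
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    return {node: label for label, members in enumerate(communities) for node in members}


def select_representative_traits(memberships: dict[str, int],
                                 mean_h2: dict[str, float]) -> list[str]:
    """Per cluster, the trait with maximal mean heritability (ties: lexicographic)."""
    missing = [trait for trait in memberships if trait not in mean_h2]
    if missing:
        raise ValueError(f"no heritability for clustered trait(s): {missing[:5]}")
    clusters: dict[int, list[str]] = {}
    for trait, label in memberships.items():
        clusters.setdefault(label, []).append(trait)
    reps = []
    for label in sorted(clusters):
        members = sorted(clusters[label])
        best = max(members, key=lambda tr: (mean_h2[tr], ))
        ties = [m for m in members if mean_h2[m] == mean_h2[best]]
        if len(ties) > 1:
            best = min(ties)
            logger.info("cluster %d: heritability tie broken lexicographically (%r)",
                        label, best)
        reps.append(best)
    return reps


def minmax_normalize_tensor(t: TraitTensor) -> TraitTensor:
    """Map each trait to [0, 1] using its min/max over all lines and timepoints.

    A constant trait maps to all zeros (warning). Idempotent.
    """
    values = t.values.copy()
    lo = values.min(axis=(0, 2), keepdims=True)
    hi = values.max(axis=(0, 2), keepdims=True)
    span = hi - lo
    flat = span[0, :, 0] == 0
    for j in np.flatnonzero(flat):
        warnings.warn(f"trait {t.trait_ids[j]!r} is constant; normalized to zeros",
                      stacklevel=2)
    span = np.where(span == 0, 1.0, span)
    return TraitTensor(
        list(t.line_ids), list(t.trait_ids), t.time_axis.copy(),
        (values - lo) / span, [b.copy() for b in t.blocks],
    )


def mean_heritability_over_time(t: TraitTensor, K: GRM | GRMEigen) -> dict[str, float]:
    """Per-trait mean GREML h² over the timepoints (constant slices -> NaN)."""
    eig = K if isinstance(K, GRMEigen) else grm_eigendecomposition(K)
    out = {}
    for j, trait in enumerate(t.trait_ids):
        h2s = []
        for ti in range(t.n_timepoints):
            y = t.values[:, j, ti]
            if np.ptp(y) == 0:
                continue
            h2s.append(reml_single_component(y, eig).h2)
        out[trait] = float(np.mean(h2s)) if h2s else float("nan")
    return out


def select_traits(t: TraitTensor, K: GRM, threshold: float = 0.96,
                  absolute: bool = False,
                  mantel_method: str = "distance") -> TraitClustering:
    """Full reduction: Mantel matrix -> graph -> clusters -> representatives."""
    mantel = mantel_correlation_matrix(t, method=mantel_method)
    graph = build_trait_graph(np.nan_to_num(mantel, nan=0.0), threshold,
                              absolute=absolute)
    labels = detect_modularity_clusters(graph)
    memberships = {t.trait_ids[node]: label for node, label in labels.items()}
    mean_h2 = mean_heritability_over_time(t, K)
    reps = select_representative_traits(memberships, mean_h2)
    return TraitClustering(
        trait_ids=list(t.trait_ids), mantel=mantel, edge_threshold=threshold,
        memberships=memberships, representatives=reps, mean_h2=mean_h2,
    )
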