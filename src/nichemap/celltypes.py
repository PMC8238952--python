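"""Clustering, marker-based cell typing, expression enrichment, HSC calling.

Cells are clustered on normalized expression with the Louvain-Jaccard
algorithm (k-nearest-neighbor graph, edges weighted by the Jaccard overlap
of neighbor sets, Louvain community detection), clusters are assigned a
type by their mean marker expression, and HSCs are called with a
percentile rule on raw Mecom counts plus a Kit floor.
"""

from __future__ import annotations

import random
from typing import Mapping, Sequence

import igraph
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "louvain_jaccard_cluster",
    "assign_cluster_types",
    "enrichment_profile",
    "call_hscs",
]


def louvain_jaccard_cluster(
    norm: pd.DataFrame | np.ndarray,
    k_neighbors: int = 15,
    seed: int = 0,
    resolution: float = 1.0,
) -> np.ndarray:
    """Louvain-Jaccard clustering of cells on normalized expression.

    Builds the k-nearest-neighbor graph (Euclidean), weights each edge by
    the Jaccard overlap of the two endpoints' neighbor sets (including the
    point itself), and runs Louvain (multilevel modularity) community
    detection with a fixed RNG seed.  Returns an integer cluster id per
    cell.
    """
    X = np.asarray(norm, dtype=float)
    n = X.shape[0]
    if n <= k_neighbors:
        raise ValueError(f"need more than k_neighbors={k_neighbors} cells, got {n}")
    if np.all(X == X[0]):
        # degenerate input: every cell identical -> one community
        return np.zeros(n, dtype=int)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neigh_sets = [set(row) for row in idx]  # row includes the point itself
    edges: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in idx[i][1:]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            if (a, b) not in edges:
                inter = len(neigh_sets[a] & neigh_sets[b])
                union = len(neigh_sets[a] | neigh_sets[b])
                edges[(a, b)] = inter / union
    g = igraph.Graph(n=n, edges=list(edges), edge_attrs={"weight": list(edges.values())})
    igraph.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(weights="weight", resolution=resolution)
    return np.asarray(part.membership, dtype=int)


def assign_cluster_types(
    clusters: np.ndarray,
    norm: pd.DataFrame,
    panel: Mapping[str, Sequence[str]],
    min_margin: float = 0.0,
    mode: str = "cluster",
) -> pd.DataFrame:
    """Assign a cell type to every cluster from marker expression.

    For each cluster the score of a type is the mean (over cells, then over
    that type's markers) normalized expression; the argmax type is assigned
    unless it fails to exceed the runner-up by the relative ``min_margin``,
    in which case the cluster is labeled "Unknown".

    ``mode="cell"`` scores every cell individually instead (each cell its
    own cluster), for marker typing without a clustering step.

    Returns a per-cell frame with ``cluster_id`` and ``type_label``.
    """
    if not panel:
        raise ValueError("marker panel is empty")
    missing = [g for gs in panel.values() for g in gs if g not in norm.columns]
    if missing:
        raise ValueError(f"markers missing from expression matrix: {missing[:5]}")
    if mode not in ("cluster", "cell"):
        raise ValueError(f"unknown mode {mode!r}")
    clusters = (
        np.arange(len(norm)) if mode == "cell" else np.asarray(clusters)
    )
    types = list(panel)
    labels = {}
    for c in np.unique(clusters):
        sub = norm.iloc[clusters == c]
        scores = np.array([sub[list(panel[t])].to_numpy().mean() for t in types])
        order = np.argsort(scores)[::-1]
        top, runner = scores[order[0]], scores[order[1]] if len(scores) > 1 else 0.0
        if top > runner * (1.0 + min_margin) and top > 0:
            labels[c] = types[order[0]]
        else:
            labels[c] = "Unknown"
    return pd.DataFrame(
        {"cluster_id": clusters, "type_label": [labels[c] for c in clusters]},
        index=norm.index,
    )


def enrichment_profile(
    norm: pd.DataFrame,
    types: Sequence[str] | np.ndarray,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Per-type log2 expression enrichment over the whole population.

    ``E[t, g] = log2((mean over type-t cells of norm[, g] + eps) /
    (mean over all cells + eps))``; a small pseudocount avoids log of zero.
    """
    types = np.asarray(types)
    if len(types) != len(norm):
        raise ValueError("types must align with the rows of norm")
    pop_mean = norm.to_numpy(dtype=float).mean(axis=0)
    rows = {}
    for t in pd.unique(types):
        tm = norm.iloc[types == t].to_numpy(dtype=float).mean(axis=0)
        with np.errstate(divide="ignore"):
            rows[t] = np.log2((tm + eps) / (pop_mean + eps))
    return pd.DataFrame.from_dict(rows, orient="index", columns=norm.columns)


def call_hscs(
    counts: pd.DataFrame,
    mecom_gene: str = "Mecom",
    kit_gene: str = "Kit",
    percentile: float = 99.95,
) -> pd.Series:
    """Call HSCs by the Mecom-percentile plus Kit rule on raw counts.

    The Mecom threshold is the ``percentile``-th percentile (linear
    interpolation) of raw Mecom counts over all retained cells of the
    dataset; a cell is an HSC when its Mecom count is strictly above the
    threshold and its Kit count is >= 1.  Apply per genotype dataset.
    """
    for g in (mecom_gene, kit_gene):
        if g not in counts.columns:
            raise KeyError(f"gene {g!r} not in the count matrix")
    mecom = counts[mecom_gene].to_numpy(dtype=float)
    kit = counts[kit_gene].to_numpy(dtype=float)
    threshold = float(np.percentile(mecom, percentile))
    flags = (mecom > threshold) & (kit >= 1)
    out = pd.Series(flags, index=counts.index, name="is_hsc")
    out.attrs["mecom_threshold"] = threshold
    return out
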