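"""Spatial statistics: neighborhood graph, pair enrichment, niches, contacts.

Two cells are "in a neighborhood" when their centroids are strictly less
than 20 um apart.  Pair-proximity enrichment compares the observed
frequency of each cell-type pair among neighbor edges with the frequency
expected from randomly pairing cells given type abundances; an HSC niche
is the set of cells within 20 um of an HSC.
"""

from __future__ import annotations

from itertools import combinations_with_replacement
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from nichemap.stats import bh_fdr, chi2_2x2_yates

__all__ = [
    "build_neighbor_graph",
    "pair_enrichment",
    "reproducible_enrichments",
    "define_niches",
    "niche_composition",
    "contact_fraction",
]


def build_neighbor_graph(centroids_um: np.ndarray, radius_um: float = 20.0) -> pd.DataFrame:
    """Neighbor edges between all cell pairs strictly closer than
    ``radius_um``.

    Returns a frame with columns ``i, j, distance`` (i < j, cell indices
    into ``centroids_um``).  Uses a k-d tree, not an all-pairs scan.
    """
    pts = np.asarray(centroids_um, dtype=float)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=radius_um, output_type="ndarray")
    if len(pairs) == 0:
        return pd.DataFrame(columns=["i", "j", "distance"]).astype(
            {"i": int, "j": int, "distance": float}
        )
    d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    keep = d < radius_um  # strict inequality; query_pairs includes == r
    pairs, d = pairs[keep], d[keep]
    lo = np.minimum(pairs[:, 0], pairs[:, 1])
    hi = np.maximum(pairs[:, 0], pairs[:, 1])
    return pd.DataFrame({"i": lo, "j": hi, "distance": d})


def pair_enrichment(
    graph: pd.DataFrame,
    types: Sequence[str] | np.ndarray,
    include_self_pairs: bool = True,
    type_names: Sequence[str] | None = None,
    yates: bool = True,
) -> pd.DataFrame:
    """Cell-type pair-proximity enrichment against a random-pairing null.

    The observed probability of the unordered pair (a, b) is its share of
    neighbor edges; the expected probability under random pairing is
    ``2 f_a f_b`` for a != b and ``f_a**2`` for a == b, with ``f_t`` the
    abundance fraction of type t among all cells.  The log2 of the ratio is
    the enrichment fold.  Per pair, a 1-df chi-square (optionally Yates-
    corrected) compares observed vs expected edge counts, and p-values are
    Benjamini-Hochberg adjusted across pairs.

    With ``include_self_pairs=False``, same-type edges are removed first and
    the expectation renormalized over non-self pairs:
    ``P_exp(a, b) = 2 f_a f_b / (1 - sum_t f_t**2)``.

    Pairs involving a type with zero cells are reported with NaN statistics
    rather than dropped.
    """
    types = np.asarray(types)
    n_cells = len(types)
    if type_names is None:
        type_names = sorted(pd.unique(types))
    fracs = {
        t: (float((types == t).sum()) / n_cells if n_cells else 0.0) for t in type_names
    }

    ti = types[graph["i"].to_numpy()] if len(graph) else np.empty(0, dtype=types.dtype)
    tj = types[graph["j"].to_numpy()] if len(graph) else np.empty(0, dtype=types.dtype)
    if not include_self_pairs:
        keep = ti != tj
        ti, tj = ti[keep], tj[keep]
    total_edges = len(ti)

    self_mass = sum(f * f for f in fracs.values())
    rows = []
    for a, b in combinations_with_replacement(type_names, 2):
        if not include_self_pairs and a == b:
            continue
        obs = int(np.sum(((ti == a) & (tj == b)) | ((ti == b) & (tj == a))))
        p_exp = fracs[a] ** 2 if a == b else 2.0 * fracs[a] * fracs[b]
        if not include_self_pairs:
            p_exp = p_exp / (1.0 - self_mass) if self_mass < 1.0 else np.nan
        if total_edges == 0 or not np.isfinite(p_exp) or p_exp == 0:
            rows.append((a, b, obs, p_exp, np.nan, np.nan))
            continue
        p_obs = obs / total_edges
        with np.errstate(divide="ignore"):
            log2_enr = np.log2(p_obs / p_exp) if p_obs > 0 else -np.inf
        expected = p_exp * total_edges
        try:
            if yates:
                _, chi_p = chi2_2x2_yates(
                    obs, total_edges - obs, expected, total_edges - expected
                )
            else:
                table = np.array(
                    [[obs, total_edges - obs], [expected, total_edges - expected]]
                )
                n = table.sum()
                num = abs(table[0, 0] * table[1, 1] - table[0, 1] * table[1, 0])
                stat = n * num**2 / (
                    table[0].sum() * table[1].sum() * table[:, 0].sum() * table[:, 1].sum()
                )
                from scipy import stats as sps

                chi_p = float(sps.chi2.sf(stat, df=1))
        except ValueError:
            chi_p = np.nan
        rows.append((a, b, obs, p_exp, log2_enr, chi_p))

    out = pd.DataFrame(
        rows,
        columns=[
            "type_a",
            "type_b",
            "observed_pairs",
            "expected_probability",
            "log2_enrichment",
            "chi2_p",
        ],
    )
    out["fdr_q"] = bh_fdr(out["chi2_p"].to_numpy())
    return out.set_index(["type_a", "type_b"])


def reproducible_enrichments(
    per_replicate_tables: Sequence[pd.DataFrame],
    p_cut: float = 0.01,
    min_replicates: int = 3,
    p_field: str = "fdr_q",
) -> pd.Series:
    """Flag type pairs that are positively enriched and significant
    (``p_field < p_cut``) in at least ``min_replicates`` replicates.
    """
    if len(per_replicate_tables) < min_replicates:
        raise ValueError(
            f"need at least {min_replicates} replicate tables, got {len(per_replicate_tables)}"
        )
    index = per_replicate_tables[0].index
    hits = pd.Series(0, index=index)
    for tab in per_replicate_tables:
        tab = tab.reindex(index)
        sig = (tab["log2_enrichment"] > 0) & (tab[p_field] < p_cut)
        hits += sig.fillna(False).astype(int)
    return (hits >= min_replicates).rename("reproducible")


def define_niches(
    hsc_flags: pd.Series | np.ndarray,
    centroids_um: np.ndarray,
    radius_um: float = 20.0,
    strict: bool = True,
) -> dict:
    """Per-HSC niche membership within ``radius_um`` of each HSC.

    Members are the cells surrounding the HSC (the central HSC is excluded
    from its own member list; other HSCs can be members).  Returns a dict
    with ``members`` (hsc id -> list of member ids), ``niche_cells`` (union
    of all members), and ``non_niche_cells`` (retained cells in neither any
    niche nor the HSC set).

    ``strict`` uses distance < radius (matching the neighborhood
    definition); set False for <=.
    """
    flags = pd.Series(hsc_flags)
    ids = np.asarray(flags.index)
    pts = np.asarray(centroids_um, dtype=float)
    if len(flags) != len(pts):
        raise ValueError("hsc_flags must align with centroids")
    tree = cKDTree(pts)
    hsc_pos = np.flatnonzero(flags.to_numpy())
    members: dict = {}
    for h in hsc_pos:
        near = tree.query_ball_point(pts[h], radius_um)
        dist = np.linalg.norm(pts[near] - pts[h], axis=1)
        ok = (dist < radius_um) if strict else (dist <= radius_um)
        members[ids[h]] = sorted(ids[k] for k, good in zip(near, ok) if good and k != h)
    niche_cells = sorted(set().union(*members.values())) if members else []
    hsc_ids = set(ids[hsc_pos])
    non_niche = sorted(set(ids) - set(niche_cells) - hsc_ids)
    return {"members": members, "niche_cells": niche_cells, "non_niche_cells": non_niche}


def niche_composition(
    niche_cells: Sequence,
    types: pd.Series,
    type_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cell-type composition of the niche vs the overall population.

    For each type t, tests the proportion of t among niche cells against
    its proportion among all retained cells with a continuity-corrected
    2x2 chi-square.  Returns per-type counts, fractions and p-values.
    """
    niche_cells = list(niche_cells)
    if not niche_cells:
        raise ValueError("niche cell set is empty")
    types = pd.Series(types)
    niche_types = types.loc[niche_cells]
    n_niche, n_all = len(niche_types), len(types)
    if type_names is None:
        type_names = sorted(types.unique())
    rows = []
    for t in type_names:
        a = int((niche_types == t).sum())
        c = int((types == t).sum())
        try:
            _, p = chi2_2x2_yates(a, n_niche - a, c, n_all - c)
        except ValueError:
            p = np.nan
        rows.append((t, a, n_niche, c, n_all, a / n_niche, c / n_all, p))
    return pd.DataFrame(
        rows,
        columns=[
            "type",
            "niche_count",
            "niche_total",
            "overall_count",
            "overall_total",
            "niche_fraction",
            "overall_fraction",
            "chi2_p",
        ],
    ).set_index("type")


def contact_fraction(
    mask: np.ndarray,
    group_a_labels: Sequence[int],
    group_b_labels: Sequence[int],
) -> float:
    """Fraction of group-a cells in direct contact with any group-b cell.

    Two labels touch when one label's pixels, dilated by one pixel
    (8-connectivity), overlap the other's pixels.
    """
    group_a = [int(a) for a in group_a_labels]
    group_b = set(int(b) for b in group_b_labels)
    if not group_a:
        raise ValueError("group_a is empty")
    mask = np.asarray(mask)
    struct = np.ones((3, 3), dtype=bool)
    objects = ndimage.find_objects(mask)
    touching = 0
    for a in group_a:
        sl = objects[a - 1] if a - 1 < len(objects) else None
        if sl is None:
            continue
        sl = tuple(
            slice(max(s.start - 2, 0), min(s.stop + 2, dim))
            for s, dim in zip(sl, mask.shape)
        )
        sub = mask[sl]
        dil = ndimage.binary_dilation(sub == a, structure=struct)
        neighbors = set(np.unique(sub[dil])) - {0, a}
        if neighbors & group_b:
            touching += 1
    return touching / len(group_a)
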