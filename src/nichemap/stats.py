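"""Statistical primitives and composite testing procedures.

Contains the low-level tests used throughout the pipeline (continuity-
corrected 2x2 chi-square, Welch's t from summary statistics, Wilcoxon
rank-sum, Benjamini-Hochberg FDR) and the two composite procedures:
replicate-reproducible differential expression and the niche gene-marker
co-expression screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "chi2_2x2_yates",
    "welch_t_from_summary",
    "bh_fdr",
    "wilcoxon_rank_sum",
    "deg_analysis",
    "niche_correlation_screen",
    "DEGRecord",
    "CorrelationRecord",
]


def chi2_2x2_yates(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Continuity-corrected (Yates) chi-square test on a 2x2 table.

    Table layout::

        [[a, b],
         [c, d]]

    Returns ``(statistic, p)`` with the 1-df upper-tail p-value.  The
    correction term ``|ad - bc| - N/2`` is floored at zero.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("all table margins must be positive")
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    stat = n * num**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(sps.chi2.sf(stat, df=1))
    return float(stat), p


def welch_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float, float]:
    """Two-sided Welch's t-test from group means, SDs and sizes.

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom.
    ``s1`` and ``s2`` are standard deviations.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    v1, v2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return float(t), float(df), p


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    NaN inputs (untestable hypotheses) are passed through as NaN and do not
    count toward the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj, 1.0)
        q[ok] = out
    return q


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses exact enumeration when the pooled sample is small (n1 + n2 <= 20,
    no ties); otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


@dataclass
class DEGRecord:
    """Per-gene differential-expression result with reproducibility flags."""

    gene: str
    log2_fold_change: float
    p_total: float
    q_total: float
    p_group1: float
    p_group2: float
    direction_consistent: bool
    significant: bool


def _log2fc(a: np.ndarray, b: np.ndarray, eps: float) -> float:
    return float(np.log2((a.mean() + eps) / (b.mean() + eps)))


def deg_analysis(
    norm: pd.DataFrame,
    group_a_cells: Sequence,
    group_b_cells: Sequence,
    replicate_ids: Mapping | pd.Series,
    replicate_split: tuple[Sequence, Sequence],
    fc_cut: float = 2.0,
    q_total_cut: float = 0.05,
    p_group_cut: float = 0.1,
    eps: float = 0.1,
) -> pd.DataFrame:
    """Differential expression between two cell groups with a replicate-
    reproducibility requirement.

    A gene is reported significant only when, on the pooled data, its fold
    change is >= ``fc_cut`` one way or the other and its FDR-adjusted
    Wilcoxon rank-sum p is < ``q_total_cut``, AND in each of the two
    replicate groups the raw p is < ``p_group_cut`` with a fold-change
    direction consistent with the pooled data.  Genes failing the replicate
    check are disregarded as unreproducible.

    Parameters
    ----------
    norm
        cells x genes normalized expression (rows indexed by cell id).
    group_a_cells, group_b_cells
        Disjoint cell-id collections defining the contrast (A vs B).
    replicate_ids
        Mapping / Series cell id -> biological replicate id.
    replicate_split
        Two collections of replicate ids partitioning the replicates.
    eps
        Pseudocount (normalized units) added to group means for the fold
        change.
    """
    a_idx = list(group_a_cells)
    b_idx = list(group_b_cells)
    if not a_idx or not b_idx:
        raise ValueError("both cell groups must be non-empty")
    if set(a_idx) & set(b_idx):
        raise ValueError("cell groups must be disjoint")
    rep = pd.Series(replicate_ids)
    g1_reps, g2_reps = set(replicate_split[0]), set(replicate_split[1])
    if not g1_reps or not g2_reps:
        raise ValueError("both replicate groups must be non-empty")

    def subset(cells: list, reps: set | None) -> pd.DataFrame:
        if reps is None:
            return norm.loc[cells]
        keep = [c for c in cells if rep.loc[c] in reps]
        return norm.loc[keep]

    lfc_cut = np.log2(fc_cut)
    frames = {}
    for label, reps in (("total", None), ("group1", g1_reps), ("group2", g2_reps)):
        A = subset(a_idx, reps)
        B = subset(b_idx, reps)
        if A.empty or B.empty:
            raise ValueError(f"replicate split leaves an empty cell group in {label}")
        lfc = np.array([_log2fc(A[g].to_numpy(), B[g].to_numpy(), eps) for g in norm.columns])
        pvals = np.array(
            [wilcoxon_rank_sum(A[g].to_numpy(), B[g].to_numpy()) for g in norm.columns]
        )
        frames[label] = (lfc, pvals)

    lfc_t, p_t = frames["total"]
    q_t = bh_fdr(p_t)
    lfc_1, p_1 = frames["group1"]
    lfc_2, p_2 = frames["group2"]
    consistent = (np.sign(lfc_1) == np.sign(lfc_t)) & (np.sign(lfc_2) == np.sign(lfc_t))
    significant = (
        (np.abs(lfc_t) >= lfc_cut)
        & (q_t < q_total_cut)
        & (p_1 < p_group_cut)
        & (p_2 < p_group_cut)
        & consistent
    )
    return pd.DataFrame(
        {
            "gene": list(norm.columns),
            "log2_fold_change": lfc_t,
            "p_total": p_t,
            "q_total": q_t,
            "p_group1": p_1,
            "p_group2": p_2,
            "direction_consistent": consistent,
            "significant": significant,
        }
    ).set_index("gene")


@dataclass
class CorrelationRecord:
    """Best marker correlation of a niche gene with one cell type."""

    niche_gene: str
    cell_type: str
    best_marker: str
    r: float
    q: float


def niche_correlation_screen(
    niche_norm: pd.DataFrame,
    marker_panel: Mapping[str, Sequence[str]],
    niche_gene_list: Sequence[str],
    r_cut: float = 0.1,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Screen niche genes for co-expression with cell-type markers.

    Pearson correlation between each niche gene and each marker gene across
    individual niche cells; p-values are BH-adjusted over all tested pairs;
    for each (niche gene, cell type) the marker with the highest r is kept,
    and records with ``r > r_cut`` and ``q < q_cut`` are reported.

    Pairs where either vector is constant (undefined correlation) are
    skipped.  Requires at least 3 niche cells.
    """
    if len(niche_norm) < 3:
        raise ValueError("need at least 3 niche cells for the correlation screen")
    rows = []  # (gene, type, marker, r, p)
    for gene in niche_gene_list:
        gvec = niche_norm[gene].to_numpy(dtype=float)
        for ctype, markers in marker_panel.items():
            for marker in markers:
                if marker == gene:
                    continue
                mvec = niche_norm[marker].to_numpy(dtype=float)
                if np.std(gvec) == 0 or np.std(mvec) == 0:
                    continue
                r, p = sps.pearsonr(gvec, mvec)
                rows.append((gene, ctype, marker, float(r), float(p)))
    if not rows:
        return pd.DataFrame(columns=["niche_gene", "cell_type", "best_marker", "r", "q"])
    tab = pd.DataFrame(rows, columns=["niche_gene", "cell_type", "best_marker", "r", "p"])
    tab["q"] = bh_fdr(tab["p"].to_numpy())
    best = (
        tab.sort_values("r", ascending=False)
        .groupby(["niche_gene", "cell_type"], sort=False)
        .head(1)
    )
    out = best[(best["r"] > r_cut) & (best["q"] < q_cut)]
    return out[["niche_gene", "cell_type", "best_marker", "r", "q"]].reset_index(drop=True)
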