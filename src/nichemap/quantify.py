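"""Gene- and cell-level quality control and per-cell normalization."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "gene_qc",
    "detect_outlier_genes",
    "filter_low_count_cells",
    "normalize_cells",
]


def gene_qc(
    total_counts_per_gene: pd.Series | Mapping[str, float],
    bulk_fpkm: pd.Series | Mapping[str, float],
    min_r: float = 0.7,
    exclusion_list: Sequence[str] = (),
    log_transform: bool = True,
) -> tuple[float, bool, pd.Series]:
    """Dataset-level QC against a bulk expression reference.

    Pearson correlation between per-gene total imaging counts and bulk FPKM
    (both log10(x+1)-transformed by default); the dataset is usable only
    when the correlation exceeds ``min_r``.  Genes on ``exclusion_list``
    (species whose imaging counts are inconsistent with bulk) are flagged
    ``qc_pass = False`` regardless.

    Returns ``(r, dataset_usable, qc_pass)`` with ``qc_pass`` indexed by
    gene.
    """
    counts = pd.Series(total_counts_per_gene, dtype=float)
    fpkm = pd.Series(bulk_fpkm, dtype=float)
    genes = counts.index.intersection(fpkm.index)
    if len(genes) < 3:
        raise ValueError("need at least 3 shared genes for the QC correlation")
    x = counts.loc[genes].to_numpy()
    y = fpkm.loc[genes].to_numpy()
    if log_transform:
        x = np.log10(x + 1.0)
        y = np.log10(y + 1.0)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("QC correlation undefined: a vector is constant")
    r = float(sps.pearsonr(x, y)[0])
    qc_pass = pd.Series(True, index=counts.index)
    qc_pass[qc_pass.index.isin(exclusion_list)] = False
    return r, r > min_r, qc_pass


def detect_outlier_genes(
    total_counts_per_gene: pd.Series | Mapping[str, float],
    bulk_fpkm: pd.Series | Mapping[str, float],
    n_outliers: int = 8,
    log_transform: bool = True,
) -> list[str]:
    """Greedy leave-one-out outlier detection for the bulk-QC correlation.

    Repeatedly removes the gene whose exclusion most improves the Pearson
    correlation with the bulk reference, ``n_outliers`` times.  An automatic
    alternative to supplying an explicit exclusion list; off by default in
    the pipeline.
    """
    counts = pd.Series(total_counts_per_gene, dtype=float)
    fpkm = pd.Series(bulk_fpkm, dtype=float)
    genes = list(counts.index.intersection(fpkm.index))
    x = counts.loc[genes].to_numpy()
    y = fpkm.loc[genes].to_numpy()
    if log_transform:
        x = np.log10(x + 1.0)
        y = np.log10(y + 1.0)
    keep = np.ones(len(genes), dtype=bool)
    outliers: list[str] = []
    for _ in range(n_outliers):
        best_gain, best_idx = -np.inf, None
        for i in np.flatnonzero(keep):
            trial = keep.copy()
            trial[i] = False
            r = sps.pearsonr(x[trial], y[trial])[0]
            if r > best_gain:
                best_gain, best_idx = r, i
        keep[best_idx] = False
        outliers.append(genes[best_idx])
    return outliers


def filter_low_count_cells(
    counts: pd.DataFrame, min_total: int = 10
) -> pd.DataFrame:
    """Drop cells with fewer than ``min_total`` detected molecules.

    A cell with exactly ``min_total`` molecules is retained (strict-
    inequality reading of the "< 10 detected RNA molecules" rule).
    """
    if counts.empty:
        return counts.copy()
    totals = counts.sum(axis=1)
    return counts.loc[totals >= min_total].copy()


def normalize_cells(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-cell normalization: each gene's count divided by the cell's total
    and multiplied by 1,000, so row sums are 1,000.
    """
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    if np.any(totals <= 0):
        raise ValueError("cells with zero total counts must be filtered before normalization")
    return counts.div(totals, axis=0) * 1000.0
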