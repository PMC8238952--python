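"""From image stacks to decoded molecules and segmented cells.

Pixel-based decoding: every bit image is binarized at a high intensity
quantile, each pixel's 16-bit on/off vector is matched to the codebook with
single-error correction, and adjacent same-gene pixels are merged into one
molecule.  Cells are segmented by watershed on the membrane-stain image
(ridges become boundaries), then pruned by area and field-of-view edge
rules before molecules are assigned to cell territories.

Conventions: 0-based pixel indices, ``(x, y) = (column, row)``, and
``um = pixel * pixel_size_nm / 1000``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology, segmentation
from skimage.registration import phase_cross_correlation

from nichemap.codebook import Codebook, N_BITS

__all__ = [
    "correct_drift",
    "decode_image_stack",
    "segment_cells",
    "filter_cells",
    "remove_edge_cells",
    "assign_spots",
    "mask_properties",
]


def correct_drift(bead_images: Sequence[np.ndarray]) -> np.ndarray:
    """Per-round integer (dx, dy) offsets from fiducial-bead images.

    Round 0 is the reference; ``offsets[r]`` is the translation of round r
    relative to round 0, i.e. a bead at (x, y) in round 0 appears at
    ``(x + dx, y + dy)`` in round r.  Estimated by image cross-correlation
    (phase correlation) to integer-pixel precision.
    """
    if len(bead_images) < 1:
        raise ValueError("need at least one bead image")
    ref = np.asarray(bead_images[0], dtype=float)
    if np.ptp(ref) == 0:
        raise ValueError("reference bead image is blank")
    offsets = np.zeros((len(bead_images), 2), dtype=int)
    for r in range(1, len(bead_images)):
        img = np.asarray(bead_images[r], dtype=float)
        if np.ptp(img) == 0:
            raise ValueError(f"bead image for round {r} is blank")
        shift, _, _ = phase_cross_correlation(ref, img, upsample_factor=1)
        # shift registers img onto ref: img displaced by -shift (row, col)
        offsets[r] = (-int(round(shift[1])), -int(round(shift[0])))
    return offsets


def _undrift(image: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Translate an image by (-dx, -dy) to align round r back onto round 0."""
    if dx == 0 and dy == 0:
        return image
    return ndimage.shift(image, (-dy, -dx), order=0, mode="constant", cval=0.0)


def decode_image_stack(
    bit_stack: np.ndarray,
    codebook: Codebook,
    threshold_quantile: float = 0.999,
    offsets: np.ndarray | None = None,
    pixel_size_nm: float = 107.9,
    fov_id: int = 0,
) -> pd.DataFrame:
    """Decode a 16-round bit-image stack into a molecule table.

    Each bit image is first translated back by its round's drift offset,
    then binarized at its own ``threshold_quantile`` intensity quantile
    (pixels strictly above the quantile are "on"; when the quantile value is
    zero, any positive pixel is on, which makes noiseless images decode
    exactly).  Each pixel's 16-bit vector is matched to the codebook with
    at most one bit error; adjacent same-gene pixels (4-connectivity) merge
    into a single molecule at the component centroid.

    Returns a SpotTable: ``gene, x_um, y_um, n_pixels, fov_id``.
    """
    bit_stack = np.asarray(bit_stack, dtype=float)
    if bit_stack.ndim != 3 or bit_stack.shape[0] != N_BITS:
        raise ValueError(f"bit_stack must have shape (16, H, W), got {bit_stack.shape}")
    H, W = bit_stack.shape[1:]
    px_um = pixel_size_nm / 1000.0

    binary = np.zeros((N_BITS, H, W), dtype=bool)
    for b in range(N_BITS):
        img = bit_stack[b]
        if offsets is not None:
            img = _undrift(img, int(offsets[b][0]), int(offsets[b][1]))
        thr = np.quantile(img, threshold_quantile)
        binary[b] = img > thr

    weights = (1 << np.arange(N_BITS - 1, -1, -1, dtype=np.int64))
    packed = np.tensordot(weights, binary.astype(np.int64), axes=(0, 0))
    gene_img = codebook.decode_lut()[packed]
    n_genes = len(codebook.entries)
    gene_img[gene_img >= n_genes] = -1  # blanks are not reported as molecules

    names = codebook.gene_names
    # one labeling pass: 4-connected components of equal gene value
    comp = measure.label(gene_img, background=-1, connectivity=1)
    n_comp = int(comp.max())
    if n_comp == 0:
        return pd.DataFrame(columns=["gene", "x_um", "y_um", "n_pixels", "fov_id"])
    flat_comp = comp.ravel()
    first = np.zeros(n_comp + 1, dtype=np.int64)
    first[flat_comp[::-1]] = np.arange(flat_comp.size - 1, -1, -1)
    gene_of = gene_img.ravel()[first[1:]]
    areas = np.bincount(flat_comp)[1:]
    rows_sum = np.bincount(flat_comp, weights=np.repeat(np.arange(H), W))[1:]
    cols_sum = np.bincount(flat_comp, weights=np.tile(np.arange(W), H))[1:]
    return pd.DataFrame(
        {
            "gene": [names[g] for g in gene_of],
            "x_um": cols_sum / areas * px_um,
            "y_um": rows_sum / areas * px_um,
            "n_pixels": areas.astype(int),
            "fov_id": fov_id,
        }
    )


def segment_cells(
    membrane_image: np.ndarray,
    smooth_sigma: float = 2.0,
    min_depth: float = 0.2,
) -> np.ndarray:
    """Watershed segmentation of the membrane-stain image.

    The smoothed membrane intensity is treated as topography: basins are
    cell interiors, ridges are boundaries.  Seeds are the local minima
    deeper than ``min_depth`` (h-minima transform), which suppresses the
    shallow minima produced by interior noise; watershed lines are assigned
    to background (label 0).  A constant image has no minima deeper than
    ``min_depth`` and yields zero labels.

    Returns an int32 label mask with contiguous positive labels.
    """
    img = np.asarray(membrane_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("membrane image must be 2D")
    sm = ndimage.gaussian_filter(img, smooth_sigma) if smooth_sigma > 0 else img
    minima = morphology.extrema.h_minima(sm, min_depth)
    markers, n_markers = ndimage.label(minima)
    if n_markers == 0:
        return np.zeros_like(img, dtype=np.int32)
    labels = segmentation.watershed(sm, markers, watershed_line=True)
    out, _, _ = segmentation.relabel_sequential(labels.astype(np.int32))
    return out.astype(np.int32)


def filter_cells(mask: np.ndarray, min_area: int = 2500, max_area: int = 20000) -> np.ndarray:
    """Remove labels with area strictly below ``min_area`` or strictly above
    ``max_area`` pixels (boundary areas are retained); relabels sequentially.
    """
    mask = np.asarray(mask)
    areas = np.bincount(mask.ravel())
    bad = np.zeros(areas.size, dtype=bool)
    bad[1:] = (areas[1:] < min_area) | (areas[1:] > max_area)
    out = np.where(bad[mask], 0, mask)
    out, _, _ = segmentation.relabel_sequential(out)
    return out.astype(np.int32)


def remove_edge_cells(mask: np.ndarray) -> np.ndarray:
    """Remove labels touching any border of the field of view."""
    mask = np.asarray(mask)
    edge_labels = np.unique(
        np.concatenate([mask[0, :], mask[-1, :], mask[:, 0], mask[:, -1]])
    )
    bad = np.zeros(int(mask.max()) + 1, dtype=bool)
    bad[edge_labels[edge_labels > 0]] = True
    out = np.where(bad[mask], 0, mask)
    out, _, _ = segmentation.relabel_sequential(out)
    return out.astype(np.int32)


def mask_properties(mask: np.ndarray, pixel_size_nm: float = 107.9) -> pd.DataFrame:
    """Per-label area (pixels) and centroid (um), indexed by label."""
    px_um = pixel_size_nm / 1000.0
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        return pd.DataFrame(columns=["area_px", "x_um", "y_um"])
    props = measure.regionprops_table(mask, properties=("label", "area", "centroid"))
    return pd.DataFrame(
        {
            "area_px": props["area"].astype(int),
            "x_um": props["centroid-1"] * px_um,
            "y_um": props["centroid-0"] * px_um,
        },
        index=pd.Index(props["label"], name="cell"),
    )


def assign_spots(
    spots: pd.DataFrame,
    mask: np.ndarray,
    gene_names: Sequence[str],
    pixel_size_nm: float = 107.9,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign decoded molecules to segmented cells.

    Each molecule is added to the count of the label under its centroid
    pixel; molecules over background (label 0) are discarded.  Returns
    ``(counts, meta)``: a cells x genes integer matrix indexed by mask
    label, and per-cell centroid/area metadata.
    """
    px_um = pixel_size_nm / 1000.0
    H, W = mask.shape
    meta = mask_properties(mask, pixel_size_nm)
    counts = pd.DataFrame(
        0, index=meta.index, columns=list(gene_names), dtype=int
    )
    if len(spots):
        rows = np.clip(np.round(spots["y_um"].to_numpy() / px_um).astype(int), 0, H - 1)
        cols = np.clip(np.round(spots["x_um"].to_numpy() / px_um).astype(int), 0, W - 1)
        labels = mask[rows, cols]
        tab = pd.DataFrame({"cell": labels, "gene": spots["gene"].to_numpy()})
        tab = tab[tab["cell"] > 0]
        agg = tab.groupby(["cell", "gene"]).size()
        for (cell, gene), n in agg.items():
            if cell in counts.index and gene in counts.columns:
                counts.at[cell, gene] += n
    return counts, meta
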