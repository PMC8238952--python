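"""Synthetic tissue-scene generator with ground truth.

Emulates the data the imaging pipeline consumes: a dense 2D tissue of
contiguous cells (Voronoi territories of packed cell centers), cell types
with configurable abundances and pairwise spatial affinities (a Potts-like
Gibbs model), per-cell gene counts from a type-specific mean matrix with
negative-binomial noise, a rare HSC-like type marked by two genes, and
rendered membrane / per-bit spot / fiducial-bead images with configurable
spot dropout, false positives and per-round stage drift.

The generator does not attempt optics realism (no PSF fitting,
photobleaching or chromatic aberration): spots are isotropic Gaussians on
an otherwise clean background, and drift is a pure per-round translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from nichemap.codebook import Codebook, build_mhd4_codebook

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "sample_cell_positions",
    "assign_types_with_affinity",
    "sample_expression",
    "render_scene",
    "simulate_scene",
    "default_config",
    "default_marker_panel",
]

N_ROUNDS = 16


@dataclass
class SceneConfig:
    """Parameters of a synthetic tissue scene.

    Distances are in micrometres unless noted; ``pixel_size_nm`` converts to
    the image grid (107.9 nm per pixel, matching the imaging system the
    pipeline is designed for).
    """

    n_cells: int = 150
    field_size_um: tuple[float, float] = (150.0, 150.0)
    pixel_size_nm: float = 107.9
    min_separation_um: float = 8.0
    type_names: tuple[str, ...] = ()
    type_fractions: tuple[float, ...] = ()
    affinity: np.ndarray | None = None  # symmetric log-attraction, 0 = neutral
    gene_names: tuple[str, ...] = ()
    mean_expression: np.ndarray | None = None  # types x genes expected counts
    dispersion: float = 10.0  # NB size parameter; np.inf = Poisson
    hsc_type_name: str | None = None
    spot_dropout_rate: float = 0.0
    spot_false_positive_rate: float = 0.0
    drift_per_round_px: tuple[int, int] = (0, 0)
    seed: int = 0
    # Gibbs sampler for type assignment
    affinity_radius_um: float = 20.0
    gibbs_sweeps: int = 20
    # rendering
    membrane_ridge_amplitude: float = 1.0
    membrane_noise_sigma: float = 0.05
    spot_sigma_px: float = 0.8
    spot_amplitude: float = 1.0
    image_noise_sigma: float = 0.0
    n_beads: int = 60

    def __post_init__(self) -> None:
        if self.type_names:
            fr = np.asarray(self.type_fractions, dtype=float)
            if fr.size != len(self.type_names):
                raise ValueError("type_fractions must match type_names")
            if not np.isclose(fr.sum(), 1.0):
                raise ValueError("type_fractions must sum to 1")
        if self.mean_expression is not None and np.any(np.asarray(self.mean_expression) < 0):
            raise ValueError("mean_expression must be non-negative")
        for r in (self.spot_dropout_rate, self.spot_false_positive_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def shape_px(self) -> tuple[int, int]:
        w, h = self.field_size_um
        return (int(round(h / self.pixel_size_um)), int(round(w / self.pixel_size_um)))


@dataclass
class GroundTruth:
    """Everything the generator knows about a scene."""

    config: SceneConfig
    codebook: Codebook
    positions_um: np.ndarray  # (n_cells, 2) as (x, y)
    types: np.ndarray  # (n_cells,) type-name strings
    counts: pd.DataFrame  # cells x genes integers
    molecules: pd.DataFrame  # gene, x_um, y_um, cell
    territory: np.ndarray  # (H, W) int, pixel -> cell index
    membrane_image: np.ndarray
    bit_stack: np.ndarray  # (16, H, W)
    bead_stack: np.ndarray  # (16, H, W)


def sample_cell_positions(config: SceneConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Dart-throwing sampler of cell centers with a hard minimum separation.

    Returns an (n_cells, 2) array of (x, y) positions in micrometres.
    Raises when the requested packing is infeasible (area bound) or after
    bounded rejection retries.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    w, h = config.field_size_um
    n = config.n_cells
    d = config.min_separation_um
    # disks of radius d/2 must fit; allow generous packing slack (hex ~0.9)
    if n * np.pi * (d / 2.0) ** 2 > 0.7 * w * h:
        raise ValueError(
            f"cannot place {n} cells at separation {d} um in a {w} x {h} um field"
        )
    # occupancy grid with cell size d: only the 5x5 neighborhood can conflict
    nx = max(int(np.ceil(w / d)), 1)
    ny = max(int(np.ceil(h / d)), 1)
    grid: dict[tuple[int, int], list[np.ndarray]] = {}
    pts: list[np.ndarray] = []
    attempts = 0
    max_attempts = 200 * n
    while len(pts) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"failed to place {n} cells at separation {d} um after {max_attempts} tries"
            )
        cand = rng.uniform((0.0, 0.0), (w, h))
        attempts += 1
        gx, gy = min(int(cand[0] / d), nx - 1), min(int(cand[1] / d), ny - 1)
        ok = True
        for ix in range(gx - 1, gx + 2):
            for iy in range(gy - 1, gy + 2):
                for p in grid.get((ix, iy), ()):
                    if np.hypot(cand[0] - p[0], cand[1] - p[1]) < d:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts.append(cand)
            grid.setdefault((gx, gy), []).append(cand)
    return np.asarray(pts)


def assign_types_with_affinity(
    positions_um: np.ndarray,
    config: SceneConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Assign per-cell type labels with pairwise spatial affinity.

    Potts-like Gibbs sampler: starting from independent draws from the
    abundance fractions, each cell is relabeled in turn with
    ``P(t) ∝ fraction_t * exp(sum_j affinity[t, type_j])`` over its spatial
    neighbors (within ``affinity_radius_um``), for a fixed number of sweeps.
    With a zero affinity matrix this reduces to independent multinomial
    sampling.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = len(positions_um)
    k = len(config.type_names)
    fractions = np.asarray(config.type_fractions, dtype=float)
    labels = rng.choice(k, size=n, p=fractions)
    aff = config.affinity
    if aff is None or not np.any(np.asarray(aff)):
        return np.asarray(config.type_names)[labels]
    aff = np.asarray(aff, dtype=float)
    if aff.shape != (k, k) or not np.allclose(aff, aff.T):
        raise ValueError("affinity must be a symmetric types x types matrix")
    tree = cKDTree(positions_um)
    neighbors = [
        [j for j in tree.query_ball_point(positions_um[i], config.affinity_radius_um) if j != i]
        for i in range(n)
    ]
    logf = np.log(np.where(fractions > 0, fractions, 1e-300))
    for _ in range(config.gibbs_sweeps):
        for i in range(n):
            logp = logf.copy()
            for j in neighbors[i]:
                logp += aff[:, labels[j]]
            logp -= logp.max()
            p = np.exp(logp)
            zero = fractions == 0
            p[zero] = 0.0
            p /= p.sum()
            labels[i] = rng.choice(k, p=p)
    return np.asarray(config.type_names)[labels]


def sample_expression(
    types: np.ndarray,
    config: SceneConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample per-cell gene counts from the type-specific mean matrix.

    Counts are negative binomial with mean ``mean_expression[type, gene]``
    and size (dispersion) parameter ``config.dispersion`` so that
    ``var = mean + mean**2 / dispersion``; ``dispersion = inf`` gives the
    Poisson limit.  Sampled as a gamma-Poisson mixture.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    mean = np.asarray(config.mean_expression, dtype=float)
    type_index = {t: i for i, t in enumerate(config.type_names)}
    mu = mean[[type_index[t] for t in types], :]
    r = config.dispersion
    if np.isinf(r):
        lam = mu
    else:
        if r <= 0:
            raise ValueError("dispersion must be positive (or inf for Poisson)")
        lam = np.where(mu > 0, rng.gamma(shape=r, scale=np.maximum(mu, 1e-300) / r), 0.0)
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, columns=list(config.gene_names))


def _render_impulses(
    shape: tuple[int, int],
    rows: np.ndarray,
    cols: np.ndarray,
    sigma: float,
    amplitude: float,
) -> np.ndarray:
    """Sum of Gaussian spots (peak ~ ``amplitude``) at integer pixel centers."""
    img = np.zeros(shape, dtype=np.float64)
    ok = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    np.add.at(img, (rows[ok], cols[ok]), 1.0)
    if sigma > 0:
        img = ndimage.gaussian_filter(img, sigma)
        img *= amplitude * 2.0 * np.pi * sigma**2
    else:
        img *= amplitude
    return img


def render_scene(
    positions_um: np.ndarray,
    types: np.ndarray,
    counts: pd.DataFrame,
    codebook: Codebook,
    config: SceneConfig,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Render membrane, 16 bit images and 16 bead images for a scene.

    Cell territories are the Voronoi cells of the sampled centers; the
    membrane image carries bright ridges (width ~2 px) along territory
    boundaries.  Each molecule is placed uniformly inside its cell's
    territory and produces a Gaussian spot in the four bit images where its
    gene's barcode is 1, each spot independently omitted with
    ``spot_dropout_rate``; per-pixel false-positive spots are added at
    ``spot_false_positive_rate``.  Round ``r`` images (bits and beads) are
    translated by the cumulative drift ``r * drift_per_round_px``.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    H, W = config.shape_px
    px = config.pixel_size_um

    centers_px = positions_um[:, ::-1] / px  # (row, col)
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    tree = cKDTree(centers_px)
    territory = tree.query(grid, workers=-1)[1].reshape(H, W).astype(np.int32)

    # membrane ridges along territory boundaries, ~2 px wide
    boundary = np.zeros((H, W), dtype=bool)
    boundary[:, :-1] |= territory[:, :-1] != territory[:, 1:]
    boundary[:-1, :] |= territory[:-1, :] != territory[1:, :]
    boundary = ndimage.binary_dilation(boundary)
    membrane = config.membrane_ridge_amplitude * ndimage.gaussian_filter(
        boundary.astype(float), 1.0
    )
    if config.membrane_noise_sigma > 0:
        membrane = membrane + rng.normal(0.0, config.membrane_noise_sigma, size=(H, W))

    # molecules: uniform over each cell's territory pixels
    cell_pixels: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    order = np.argsort(territory.ravel(), kind="stable")
    flat = territory.ravel()[order]
    bounds = np.searchsorted(flat, np.arange(len(positions_um) + 1))
    rows_all = order // W
    cols_all = order % W
    for i in range(len(positions_um)):
        sl = slice(bounds[i], bounds[i + 1])
        cell_pixels[i] = (rows_all[sl], cols_all[sl])

    mol_gene, mol_row, mol_col, mol_cell = [], [], [], []
    gene_list = list(counts.columns)
    cmat = counts.to_numpy()
    for i in range(len(positions_um)):
        prow, pcol = cell_pixels[i]
        total = int(cmat[i].sum())
        if total == 0 or prow.size == 0:
            continue
        pick = rng.integers(0, prow.size, size=total)
        genes = np.repeat(np.arange(cmat.shape[1]), cmat[i])
        mol_gene.append(genes)
        mol_row.append(prow[pick])
        mol_col.append(pcol[pick])
        mol_cell.append(np.full(total, i))
    if mol_gene:
        mol_gene = np.concatenate(mol_gene)
        mol_row = np.concatenate(mol_row)
        mol_col = np.concatenate(mol_col)
        mol_cell = np.concatenate(mol_cell)
    else:
        mol_gene = np.empty(0, dtype=int)
        mol_row = mol_col = mol_cell = np.empty(0, dtype=int)

    molecules = pd.DataFrame(
        {
            "gene": [gene_list[g] for g in mol_gene],
            "x_um": mol_col * px,
            "y_um": mol_row * px,
            "cell": mol_cell,
        }
    )

    barcode_bits = np.array(
        [codebook.encode(g).bits for g in gene_list], dtype=np.uint8
    )  # genes x 16
    dx, dy = config.drift_per_round_px
    bit_stack = np.zeros((N_ROUNDS, H, W), dtype=np.float64)
    for b in range(N_ROUNDS):
        on = barcode_bits[mol_gene, b] == 1
        keep = on & (rng.random(mol_gene.size) >= config.spot_dropout_rate)
        r_shift = mol_row[keep] + b * dy
        c_shift = mol_col[keep] + b * dx
        img = _render_impulses((H, W), r_shift, c_shift, config.spot_sigma_px, config.spot_amplitude)
        if config.spot_false_positive_rate > 0:
            n_fp = rng.binomial(H * W, config.spot_false_positive_rate)
            img += _render_impulses(
                (H, W),
                rng.integers(0, H, n_fp),
                rng.integers(0, W, n_fp),
                config.spot_sigma_px,
                config.spot_amplitude,
            )
        if config.image_noise_sigma > 0:
            img += rng.normal(0.0, config.image_noise_sigma, size=(H, W))
        bit_stack[b] = img

    bead_r = rng.integers(0, H, config.n_beads)
    bead_c = rng.integers(0, W, config.n_beads)
    bead_stack = np.zeros((N_ROUNDS, H, W), dtype=np.float64)
    for b in range(N_ROUNDS):
        bead_stack[b] = _render_impulses(
            (H, W), bead_r + b * dy, bead_c + b * dx, 1.0, 2.0
        )

    return GroundTruth(
        config=config,
        codebook=codebook,
        positions_um=positions_um,
        types=types,
        counts=counts,
        molecules=molecules,
        territory=territory,
        membrane_image=membrane,
        bit_stack=bit_stack,
        bead_stack=bead_stack,
    )


def simulate_scene(config: SceneConfig, codebook: Codebook | None = None) -> GroundTruth:
    """Full scene simulation: positions -> types -> counts -> images.

    All randomness flows from ``config.seed``; the returned GroundTruth is
    bit-for-bit reproducible for a fixed config.
    """
    if codebook is None:
        codebook = build_mhd4_codebook(list(config.gene_names), seed=config.seed)
    missing = [g for g in config.gene_names if g not in codebook.entries]
    if missing:
        raise ValueError(f"genes missing from codebook: {missing[:5]}")
    rng = np.random.default_rng(config.seed)
    positions = sample_cell_positions(config, rng)
    types = assign_types_with_affinity(positions, config, rng)
    counts = sample_expression(types, config, rng)
    return render_scene(positions, types, counts, codebook, config, rng)


# ---------------------------------------------------------------------------
# Default study-like conditions


def default_marker_panel() -> dict[str, list[str]]:
    """Marker genes per cell type for the default fetal-liver-like scene."""
    return {
        "AEC": ["Fstl1", "Cxcl12"],
        "SEC": ["Stab2", "Lyve1"],
        "hepatocyte": ["Alb", "Afp"],
        "macrophage": ["Csf1r", "Adgre1"],
        "MK": ["Pf4", "Vwf"],
        "myeloid": ["S100a8", "Mpo"],
        "erythroid progenitor": ["Gata1", "Klf1"],
        "erythroid": ["Hba-a1", "Hbb-bs"],
    }


def default_config(
    n_cells: int = 150,
    field_size_um: tuple[float, float] = (150.0, 150.0),
    seed: int = 0,
    n_filler_genes: int = 122,
    spot_dropout_rate: float = 0.0,
    spot_false_positive_rate: float = 0.0,
    drift_per_round_px: tuple[int, int] = (0, 0),
) -> SceneConfig:
    """Canonical synthetic fetal-liver-like scene.

    Eight major cell types with markers plus a rare HSC type marked by
    Mecom and Kit; erythroid-dominated abundances; positive self-affinity
    (cells aggregate with their own type) plus planted HSC-endothelium and
    macrophage-erythroid attractions, mirroring the spatial structure the
    pipeline is meant to detect.  The 140-gene panel is the marker set plus
    Mecom/Kit plus filler niche genes at low uniform expression.
    """
    panel = default_marker_panel()
    type_names = list(panel) + ["HSC"]
    fractions = {
        "AEC": 0.05,
        "SEC": 0.05,
        "hepatocyte": 0.13,
        "macrophage": 0.08,
        "MK": 0.04,
        "myeloid": 0.10,
        "erythroid progenitor": 0.12,
        "erythroid": 0.42,
        "HSC": 0.01,
    }
    markers = [g for gs in panel.values() for g in gs]
    genes = markers + ["Mecom", "Kit"] + [f"Niche{i + 1:03d}" for i in range(n_filler_genes)]
    k, G = len(type_names), len(genes)
    mean = np.full((k, G), 0.05)
    gidx = {g: i for i, g in enumerate(genes)}
    for t, gs in panel.items():
        ti = type_names.index(t)
        for g in gs:
            mean[ti, gidx[g]] = 9.0
    hsc = type_names.index("HSC")
    mean[hsc, gidx["Mecom"]] = 8.0
    mean[hsc, gidx["Kit"]] = 8.0
    mean[type_names.index("erythroid progenitor"), gidx["Kit"]] = 2.0
    # a couple of filler genes expressed broadly so cells have body
    mean[:, gidx["Niche001"]] = 2.0
    mean[:, gidx["Niche002"]] = 1.0

    # kept weak so the Potts clumping does not distort marginal abundances
    aff = np.zeros((k, k))
    np.fill_diagonal(aff, 0.12)
    for a, b, w in [
        ("HSC", "AEC", 0.30),
        ("HSC", "SEC", 0.20),
        ("macrophage", "erythroid", 0.18),
    ]:
        ia, ib = type_names.index(a), type_names.index(b)
        aff[ia, ib] = aff[ib, ia] = w
    aff[hsc, hsc] = 0.0  # HSCs are solitary

    return SceneConfig(
        n_cells=n_cells,
        field_size_um=field_size_um,
        min_separation_um=8.0,
        type_names=tuple(type_names),
        type_fractions=tuple(fractions[t] for t in type_names),
        affinity=aff,
        gene_names=tuple(genes),
        mean_expression=mean,
        dispersion=10.0,
        hsc_type_name="HSC",
        spot_dropout_rate=spot_dropout_rate,
        spot_false_positive_rate=spot_false_positive_rate,
        drift_per_round_px=drift_per_round_px,
        affinity_radius_um=12.0,
        seed=seed,
    )
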