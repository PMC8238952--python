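"""End-to-end orchestration of the synthetic-scene analysis workflow.

Runs simulate -> drift-correct -> decode -> segment -> filter -> quantify ->
QC -> normalize -> cluster/type -> HSC call -> neighbor graph -> pair
enrichment -> niches -> composition/contact -> DEG -> correlation screen,
writing every intermediate table plus a machine-readable run manifest.
Each simulated scene plays the role of one biological replicate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from nichemap import celltypes, imaging, quantify, spatial, stats
from nichemap.codebook import Codebook, build_mhd4_codebook
from nichemap.synthetic import (
    SceneConfig,
    default_config,
    default_marker_panel,
    simulate_scene,
)

logger = logging.getLogger("nichemap")

__all__ = ["RunConfig", "run_end_to_end"]


@dataclass
class RunConfig:
    """Parameters of an end-to-end synthetic run.

    ``n_replicates`` scenes are simulated with consecutive seeds and
    analyzed as biological replicates of one genotype dataset.
    """

    scene: SceneConfig = field(default_factory=default_config)
    n_replicates: int = 2
    genotype: str = "WT"
    # imaging
    threshold_quantile: float = 0.999
    smooth_sigma: float = 2.0
    min_depth: float = 0.2
    min_area_px: int = 2500
    max_area_px: int = 20000
    # quantify
    min_cell_total: int = 10
    qc_min_r: float = 0.7
    exclusion_list: tuple[str, ...] = ()
    # typing
    k_neighbors: int = 15
    louvain_seed: int = 0
    min_margin: float = 0.0
    hsc_percentile: float = 99.0
    # spatial
    neighbor_radius_um: float = 20.0
    # stats
    deg_eps: float = 0.1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scene"]["affinity"] = np.asarray(self.scene.affinity).tolist() if self.scene.affinity is not None else None
        d["scene"]["mean_expression"] = (
            np.asarray(self.scene.mean_expression).tolist()
            if self.scene.mean_expression is not None
            else None
        )
        return d


def _analyze_replicate(
    scene, config: RunConfig, codebook: Codebook, replicate_id: int
) -> dict:
    """Image-level analysis of one replicate scene."""
    t0 = time.time()
    offsets = imaging.correct_drift(list(scene.bead_stack))
    spots = imaging.decode_image_stack(
        scene.bit_stack,
        codebook,
        threshold_quantile=config.threshold_quantile,
        offsets=offsets,
        pixel_size_nm=scene.config.pixel_size_nm,
        fov_id=replicate_id,
    )
    mask = imaging.segment_cells(
        scene.membrane_image, smooth_sigma=config.smooth_sigma, min_depth=config.min_depth
    )
    mask = imaging.filter_cells(mask, config.min_area_px, config.max_area_px)
    mask = imaging.remove_edge_cells(mask)
    counts, meta = imaging.assign_spots(
        spots, mask, list(scene.config.gene_names), scene.config.pixel_size_nm
    )
    logger.info(
        "replicate %d: %d molecules, %d segmented cells (%.1f s)",
        replicate_id,
        len(spots),
        len(meta),
        time.time() - t0,
    )
    return {
        "scene": scene,
        "offsets": offsets,
        "spots": spots,
        "mask": mask,
        "counts": counts,
        "meta": meta,
    }


def run_end_to_end(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full workflow on simulated replicates.

    Returns a dict of result tables; when ``outdir`` is given, every table
    is also written as TSV along with a JSON run manifest (parameters,
    seeds, row counts).
    """
    genes = list(config.scene.gene_names)
    codebook = build_mhd4_codebook(genes, seed=config.scene.seed)
    panel = {
        t: m for t, m in default_marker_panel().items() if all(g in genes for g in m)
    }

    reps = []
    for r in range(config.n_replicates):
        scene_cfg = dataclasses.replace(config.scene, seed=config.scene.seed + 1000 * r)
        scene = simulate_scene(scene_cfg, codebook)
        reps.append(_analyze_replicate(scene, config, codebook, r))

    # pooled cell matrix across replicates
    counts = pd.concat(
        [rep["counts"].set_index(pd.Index(
            [f"r{r}c{lbl}" for lbl in rep["counts"].index], name="cell"))
         for r, rep in enumerate(reps)]
    )
    meta = pd.concat(
        [rep["meta"].set_index(pd.Index(
            [f"r{r}c{lbl}" for lbl in rep["meta"].index], name="cell"))
         for r, rep in enumerate(reps)]
    )
    meta["replicate_id"] = [int(c.split("c")[0][1:]) for c in meta.index]
    meta["genotype"] = config.genotype
    # replicate-local segmentation label, for mask-level analyses
    meta["mask_label"] = [int(c.split("c")[1]) for c in meta.index]

    # gene QC against the scene's own bulk-like reference
    fractions = np.asarray(config.scene.type_fractions)
    bulk = pd.Series(
        fractions @ np.asarray(config.scene.mean_expression), index=genes, name="FPKM"
    )
    qc_r, usable, qc_pass = quantify.gene_qc(
        counts.sum(axis=0), bulk, min_r=config.qc_min_r,
        exclusion_list=config.exclusion_list,
    )
    kept_genes = [g for g in genes if qc_pass[g]]
    counts = counts[kept_genes]

    counts = quantify.filter_low_count_cells(counts, config.min_cell_total)
    meta = meta.loc[counts.index]
    norm = quantify.normalize_cells(counts)

    clusters = celltypes.louvain_jaccard_cluster(
        norm, k_neighbors=config.k_neighbors, seed=config.louvain_seed
    )
    typing = celltypes.assign_cluster_types(clusters, norm, panel, config.min_margin)
    profile = celltypes.enrichment_profile(norm, typing["type_label"].to_numpy())
    hsc = celltypes.call_hscs(counts, percentile=config.hsc_percentile)

    centroids = meta[["x_um", "y_um"]].to_numpy()
    # spatial analyses are per replicate (separate coordinate frames)
    enrich_tables = []
    for r in range(config.n_replicates):
        sel = meta["replicate_id"] == r
        graph = spatial.build_neighbor_graph(
            centroids[sel.to_numpy()], config.neighbor_radius_um
        )
        enrich_tables.append(
            pair_tab := spatial.pair_enrichment(
                graph, typing.loc[sel, "type_label"].to_numpy(), include_self_pairs=False
            )
        )
    if config.n_replicates >= 3:
        reproducible = spatial.reproducible_enrichments(enrich_tables, min_replicates=3)
    else:
        reproducible = None

    # niches pooled across replicates; distances only within a replicate are
    # meaningful, so build niches per replicate and take the union
    members: dict = {}
    for r in range(config.n_replicates):
        sel = (meta["replicate_id"] == r).to_numpy()
        sub_ids = meta.index[sel]
        niches_r = spatial.define_niches(
            hsc.loc[sub_ids], centroids[sel], config.neighbor_radius_um
        )
        members.update(niches_r["members"])
    niche_cells = sorted(set().union(*members.values())) if members else []
    hsc_ids = set(hsc.index[hsc])
    non_niche = sorted(set(meta.index) - set(niche_cells) - hsc_ids)

    composition = (
        spatial.niche_composition(niche_cells, typing["type_label"])
        if niche_cells
        else None
    )

    # direct contact of HSCs with endothelial cells, per replicate masks
    ec_types = {"AEC", "SEC"}
    contact = np.nan
    hsc_meta = meta.loc[sorted(hsc_ids)] if hsc_ids else meta.iloc[:0]
    fractions_by_rep = []
    for r in range(config.n_replicates):
        rep_hscs = hsc_meta[hsc_meta["replicate_id"] == r]["mask_label"].tolist()
        sel = meta["replicate_id"] == r
        ec_labels = meta.loc[
            sel & typing["type_label"].isin(ec_types), "mask_label"
        ].tolist()
        if rep_hscs:
            fractions_by_rep.append(
                (
                    len(rep_hscs),
                    spatial.contact_fraction(reps[r]["mask"], rep_hscs, ec_labels),
                )
            )
    if fractions_by_rep:
        n_tot = sum(n for n, _ in fractions_by_rep)
        contact = sum(n * f for n, f in fractions_by_rep) / n_tot

    deg = None
    if niche_cells and len(non_niche) > 0 and config.n_replicates >= 2:
        half = config.n_replicates // 2
        split = (list(range(half)), list(range(half, config.n_replicates)))
        rep_of = meta["replicate_id"]
        covered = all(
            any(rep_of[c] in grp for c in niche_cells)
            and any(rep_of[c] in grp for c in non_niche)
            for grp in split
        )
        if covered:
            deg = stats.deg_analysis(
                norm,
                niche_cells,
                non_niche,
                rep_of,
                split,
                eps=config.deg_eps,
            )
        else:
            logger.info("skipping DEG: a replicate group has no niche cells")

    screen = None
    if len(niche_cells) >= 3:
        niche_gene_list = [g for g in kept_genes if g.startswith("Niche")] or kept_genes
        screen = stats.niche_correlation_screen(
            norm.loc[niche_cells], panel, niche_gene_list
        )

    results = {
        "codebook": codebook,
        "replicates": reps,
        "qc_r": qc_r,
        "qc_usable": usable,
        "counts": counts,
        "norm": norm,
        "meta": meta,
        "clusters": clusters,
        "typing": typing,
        "enrichment_profile": profile,
        "hsc": hsc,
        "pair_enrichment": enrich_tables,
        "reproducible": reproducible,
        "niche_members": members,
        "niche_cells": niche_cells,
        "non_niche_cells": non_niche,
        "niche_composition": composition,
        "contact_fraction": contact,
        "deg": deg,
        "correlation_screen": screen,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        codebook.to_json(outdir / "codebook.json")
        counts.to_csv(outdir / "counts.tsv", sep="\t")
        norm.round(6).to_csv(outdir / "norm.tsv", sep="\t")
        meta.join(typing).join(hsc).to_csv(outdir / "cells.tsv", sep="\t")
        profile.round(6).to_csv(outdir / "enrichment_profile.tsv", sep="\t")
        for r, tab in enumerate(enrich_tables):
            tab.round(6).to_csv(outdir / f"pair_enrichment_rep{r}.tsv", sep="\t")
        if composition is not None:
            composition.round(6).to_csv(outdir / "niche_composition.tsv", sep="\t")
        if deg is not None:
            deg.round(6).to_csv(outdir / "deg_niche_vs_nonniche.tsv", sep="\t")
        if screen is not None:
            screen.round(6).to_csv(outdir / "niche_correlation_screen.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(h, m) for h, ms in members.items() for m in ms],
            columns=["hsc_id", "member_id"],
        ).to_csv(outdir / "niche_members.tsv", sep="\t", index=False)
        manifest = {
            "config": config.to_dict(),
            "qc_r": qc_r,
            "qc_usable": bool(usable),
            "n_cells": int(len(counts)),
            "n_genes": int(counts.shape[1]),
            "n_hscs": int(hsc.sum()),
            "n_niche_cells": len(niche_cells),
            "contact_fraction": None if np.isnan(contact) else float(contact),
            "n_molecules": int(sum(len(rep["spots"]) for rep in reps)),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return results
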