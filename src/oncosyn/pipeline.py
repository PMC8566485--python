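"""End-to-end orchestration: simulate/ingest -> qc -> atlas -> project ->
degs -> trajectory -> interaction -> coexpress -> screen.

Each stage reads only its declared inputs and writes TSV outputs under
the run directory; a manifest records the config hash, the seed
registry, and a checksum for every stage file, so an unchanged rerun
reproduces identical checksums for all deterministic stages and a
partially complete run resumes after the last stage whose outputs
verify.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import annotate, fit_reference, merge_clusters, normalize_log
from .coexpress import coexpression_fraction
from .degs import within_between_analysis
from .interaction import (
    call_interactions,
    call_summary,
    expression_changes,
    permutation_null,
)
from .iodata import CellMatrix, RunConfig, read_dir, write_markers, write_table
from .licscreen import hscmpp_specificity, nominate_candidates, train_rf
from .project import embed_cells, project_cells, state_frequencies
from .qc import mito_filter, score_doublets
from .simdata import SimConfig, default_hematopoiesis_config, marker_table, simulate
from .trajectory import density_compare, diffusion_pseudotime

log = logging.getLogger("oncosyn")

STAGES = ("simulate", "qc", "atlas", "project", "degs", "trajectory",
          "interaction", "coexpress", "screen")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    # named substream: stable per-stage seed below 2**31
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(
    config: RunConfig,
    out_dir,
    input_dir=None,
    resume: bool = True,
    coexpress_pair: tuple[str, str] = ("Gcnt2", "Mpo"),
) -> dict:
    """Execute all stages in dependency order and return the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = config.to_yaml()
    manifest_path = out / "manifest.json"
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": config.seed,
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in STAGES},
        "stages": {},
    }
    prior = (
        json.loads(manifest_path.read_text())
        if resume and manifest_path.exists()
        else {"stages": {}, "config_sha256": None}
    )
    reusable = prior.get("config_sha256") == manifest["config_sha256"]

    def finish(stage: str, inputs: list[Path], outputs: list[Path]):
        manifest["stages"][stage] = {
            "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
            "outputs": {p.name: _sha256(p) for p in outputs},
            "finished_at": time.time(),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))

    def done(stage: str, outputs: list[Path]) -> bool:
        if not (reusable and stage in prior["stages"]):
            return False
        rec = prior["stages"][stage]
        ok = all(
            p.exists() and rec["outputs"].get(p.name) == _sha256(p)
            for p in outputs
        )
        if ok:
            manifest["stages"][stage] = rec
        return ok

    # ---- stage: simulate / ingest -----------------------------------
    sim_out = out / "sim"
    truth_cells_p = out / "truth_cells.tsv"
    truth_genes_p = out / "truth_genes.tsv"
    markers_p = out / "markers.tsv"
    if input_dir is None:
        sim_cfg = default_hematopoiesis_config(
            n_genes=config.sim.get("n_genes", 2000),
            n_cells=config.sim.get("n_cells", 2000),
            seed=_stage_seed(config.seed, "simulate"),
        )
        for k, v in config.sim.items():
            if not hasattr(sim_cfg, k):
                raise ValueError(f"unknown sim config field {k!r}")
            setattr(sim_cfg, k, v)
        cm, truth = simulate(sim_cfg)
        if not done("simulate", [truth_cells_p, truth_genes_p, markers_p]):
            write_table(truth.cells, truth_cells_p)
            write_table(truth.genes, truth_genes_p)
            write_markers(marker_table(truth), markers_p)
            finish("simulate", [], [truth_cells_p, truth_genes_p, markers_p])
        markers = marker_table(truth)
    else:
        cm = read_dir(input_dir)
        markers_file = Path(input_dir) / "markers.tsv"
        if not markers_file.exists():
            raise FileNotFoundError(
                f"atlas stage needs a marker file: {markers_file} not found"
            )
        from .iodata import read_markers

        markers = read_markers(markers_file)
        write_markers(markers, markers_p)
        finish("simulate", [markers_file], [markers_p])

    # ---- stage: qc ---------------------------------------------------
    qc_p = out / "qc_report.tsv"
    qp = config.qc
    cm0, mito_rep = mito_filter(cm, qp.mito_threshold, qp.mito_prefix)
    qc_seed = _stage_seed(config.seed, "qc")
    frames = []
    keep_ids = []
    for key in cm0.sample_key().unique():
        sub = cm0.subset_cells((cm0.sample_key() == key).to_numpy())
        rep = score_doublets(
            sub, n_sim_frac=qp.n_sim_frac, k=qp.doublet_k,
            n_pcs=qp.doublet_n_pcs, seed=qc_seed,
            fallback_threshold=qp.doublet_fallback_threshold,
        )
        frames.append(rep.per_cell.assign(sample=key))
        keep_ids.extend(rep.per_cell.index[rep.per_cell["pass_doublet"]])
    doublet_rep = pd.concat(frames)
    qc_table = mito_rep.per_cell.join(doublet_rep.drop(columns="sample"),
                                      how="left")
    write_table(qc_table.reset_index(names="cell_id"), qc_p)
    finish("qc", [], [qc_p])
    cells = cm0.subset_cells(np.isin(cm0.cell_ids, np.asarray(keep_ids, dtype=object)))

    # ---- stage: atlas ------------------------------------------------
    ap = config.atlas
    ref_dir = out / "reference"
    wt = cells.subset_cells((cells.cell_meta["genotype"] == "WT").to_numpy())
    model = fit_reference(
        wt, n_pcs=ap.n_pcs, resolution=ap.resolution, k=ap.knn_k,
        n_hvg=ap.n_hvg, scale=ap.scale, seed=_stage_seed(config.seed, "atlas"),
    )
    model = merge_clusters(model, ap.corr_threshold, ap.min_edge_frac)
    model = annotate(model, markers, normalize_log(wt, ap.scale))
    model.save(ref_dir)
    finish("atlas", [markers_p], [ref_dir / "arrays.npz", ref_dir / "meta.json"])

    # ---- stage: project ----------------------------------------------
    proj_p = out / "projection.tsv"
    freq_p = out / "state_frequencies.tsv"
    mut = cells.subset_cells((cells.cell_meta["genotype"] != "WT").to_numpy())
    proj = project_cells(mut, model)
    labels_all = pd.concat(
        [
            pd.Series(model.state_label, index=pd.Index(model.cell_ids)),
            proj.labels(),
        ]
    ).reindex(pd.Index(cells.cell_ids))
    write_table(proj.assignments.reset_index(names="cell_id"), proj_p)
    freqs = state_frequencies(labels_all, cells.cell_meta)
    write_table(freqs, freq_p)
    finish("project", [], [proj_p, freq_p])

    # ---- stage: degs -------------------------------------------------
    degs_p, degsum_p = out / "degs.tsv", out / "degs_summary.tsv"
    dp = config.degs
    norm_all = normalize_log(cells, ap.scale)
    deg_table, deg_summary = within_between_analysis(
        norm_all, cells.cell_meta, labels_all, gene_ids=cells.gene_ids,
        pool_timepoints=dp.pool_timepoints, min_cells=dp.min_cells,
        alpha=dp.alpha,
    )
    write_table(deg_table, degs_p)
    write_table(deg_summary, degsum_p)
    finish("degs", [proj_p], [degs_p, degsum_p])

    # ---- stage: trajectory -------------------------------------------
    tp = config.trajectory
    pt_p, dens_p, comp_p = out / "pseudotime.tsv", out / "density.tsv", out / "composition.tsv"
    emb_all = np.vstack([model.embeddings, proj.embeddings])
    order = pd.Index(np.concatenate([model.cell_ids, mut.cell_ids]))
    emb_all = emb_all[order.get_indexer(pd.Index(cells.cell_ids))]
    pt = diffusion_pseudotime(
        emb_all, labels_all.to_numpy(), cell_ids=cells.cell_ids,
        root_state=tp.root_state, n_dcs=tp.n_dcs, k=tp.knn_k,
        lineage_states=list(tp.lineage_states),
    )
    write_table(pt.frame().reset_index(names="cell_id"), pt_p)
    dc = density_compare(
        pt, cells.cell_meta, labels_all.to_numpy(),
        bandwidth=tp.bandwidth, delta=tp.delta,
    )
    write_table(dc.densities.reset_index(names="rank"), dens_p)
    comp_rows = [
        {"genotype": g, "state": s, "fraction": f}
        for g, comp in dc.composition.items()
        for s, f in comp.items()
    ]
    write_table(pd.DataFrame(comp_rows, columns=["genotype", "state", "fraction"]),
                comp_p)
    finish("trajectory", [proj_p], [pt_p, dens_p, comp_p])

    # ---- stage: interaction ------------------------------------------
    ip = config.interaction
    int_p, intsum_p = out / "interaction.tsv", out / "interaction_summary.tsv"
    subset = None if ip.subset == "all" else [ip.subset]
    int_frames, sum_rows = [], []
    for t_ in sorted(cells.cell_meta["timepoint"].unique()):
        tab = expression_changes(
            cells, timepoint=t_, subset_states=subset,
            state_labels=labels_all.to_numpy(), scale=ap.scale,
        )
        null = permutation_null(
            tab, n_perm=ip.n_perm,
            seed=_stage_seed(config.seed, "interaction"), scheme=ip.scheme,
        )
        called = call_interactions(tab, null)
        int_frames.append(called.assign(timepoint=t_))
        s = call_summary(called).assign(timepoint=t_)
        sum_rows.append(s)
    write_table(pd.concat(int_frames, ignore_index=True), int_p)
    write_table(pd.concat(sum_rows, ignore_index=True), intsum_p)
    finish("interaction", [proj_p], [int_p, intsum_p])

    # ---- stage: coexpress --------------------------------------------
    cp = config.coexpress
    co_p = out / "coexpression.tsv"
    g1, g2 = coexpress_pair
    if g1 in cells.gene_ids and g2 in cells.gene_ids:
        res = coexpression_fraction(
            cells, g1, g2, expr_threshold=cp.expr_threshold,
            n_cells=cp.n_cells, n_iter=cp.n_iter,
            seed=_stage_seed(config.seed, "coexpress"),
        )
        write_table(res.per_group, co_p)
    else:
        write_table(pd.DataFrame(columns=["group", "fraction_full"]), co_p)
    finish("coexpress", [], [co_p])

    # ---- stage: screen -----------------------------------------------
    sp = config.screen
    screen_p = out / "screen.tsv"
    norm_wt = normalize_log(wt, ap.scale)
    rf = train_rf(
        norm_wt, wt.gene_ids, model.state_label, n_trees=sp.n_trees,
        n_top_genes=sp.n_top_genes, n_folds=sp.n_folds,
        seed=_stage_seed(config.seed, "screen"),
    )
    ab_mask = (cells.cell_meta["genotype"] == "AB").to_numpy()
    ab = cells.subset_cells(ab_mask)
    spec_r = hscmpp_specificity(rf, normalize_log(ab, ap.scale), ab.gene_ids)
    hsc_tab = expression_changes(
        cells, subset_states=["HSC/MPP"], state_labels=labels_all.to_numpy(),
        scale=ap.scale,
    )
    null = permutation_null(
        hsc_tab, n_perm=ip.n_perm,
        seed=_stage_seed(config.seed, "screen"), scheme=ip.scheme,
    )
    called = call_interactions(hsc_tab, null)
    lfc = called.set_index("gene")["delta_obs"]
    screen = nominate_candidates(spec_r, called, lfc, r_min=sp.r_min)
    write_table(screen.reset_index(names="gene"), screen_p)
    finish("screen", [int_p], [screen_p])

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
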