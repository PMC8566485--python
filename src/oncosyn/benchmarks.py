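"""Synthetic-truth validation scenarios.

Each function builds a simulated study with known ground truth, runs the
relevant pipeline components, and measures how well the truth is
recovered.  The scenarios double as the package's acceptance checks and
as worked examples of the intended problem sizes: interaction-score
recovery and null calibration, estimator bias, label-transfer accuracy,
differential-expression behavior, pseudotime ordering, QC operating
characteristics, and the random-forest screen.

Planted expression effects are placed on well-detected genes (baseline
12 counts/cell for up-effects, 12e for down-effects) with the up/down
baselines balanced so the double mutant's expected library size matches
wild type; this isolates the per-gene log effect from compositional
library shifts under counts-per-10k normalization.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import spearmanr

from .atlas import annotate, fit_reference, merge_clusters, normalize_log
from .degs import within_between_analysis
from .interaction import (
    call_interactions,
    decompose_change,
    exhaustive_null_pool,
    expression_changes,
    permutation_null,
)
from .iodata import CellMatrix
from .licscreen import hscmpp_specificity, nominate_candidates, train_rf
from .project import project_cells, embed_cells
from .qc import mito_filter, score_doublets
from .simdata import (
    SimConfig,
    SimTruth,
    default_hematopoiesis_config,
    marker_table,
    simulate,
)
from .trajectory import density_compare, diffusion_pseudotime

PLANT_BASE_UP = 12.0
PLANT_BASE_DOWN = 12.0 * np.e


def _flat_interaction_config(
    seed: int,
    n_genes: int = 2000,
    n_cells: int = 2000,
    n_up: int = 50,
    n_down: int = 50,
    effect: float = 1.0,
) -> SimConfig:
    """Single-state four-genotype design with balanced planted interactions."""
    base = np.random.default_rng(np.random.SeedSequence([seed, 23])).lognormal(
        -0.7, 1.0, n_genes
    )
    eff = np.zeros(n_genes)
    eff[:n_up] = effect
    eff[n_up:n_up + n_down] = -effect
    base[:n_up] = PLANT_BASE_UP
    base[n_up:n_up + n_down] = PLANT_BASE_DOWN
    return SimConfig(
        n_genes=n_genes,
        n_cells=n_cells,
        hierarchy={},
        root="S0",
        timepoints=("T3",),
        baseline_mean=base,
        effect_interaction=eff,
        markers_per_state=0,
        doublet_rate=0.0,
        mito_outlier_rate=0.0,
        seed=seed,
    )


def interaction_recovery(seed: int = 0, n_genes: int = 2000,
                         n_cells: int = 2000, n_perm: int = 1000) -> dict:
    """Recovery of 50 planted synergistic and 50 antagonistic genes."""
    cfg = _flat_interaction_config(seed, n_genes, n_cells)
    cm, truth = simulate(cfg)
    tab = expression_changes(cm, timepoint="T3")
    null = permutation_null(tab, n_perm=n_perm, seed=seed)
    called = call_interactions(tab, null).set_index("gene")
    up = [f"g{i:05d}" for i in range(50)]
    down = [f"g{i:05d}" for i in range(50, 100)]
    ok_up = (called.reindex(up)["call"] == "synergistic").fillna(False)
    ok_down = (called.reindex(down)["call"] == "antagonistic").fillna(False)
    sens = float(np.concatenate([ok_up, ok_down]).mean())
    return {"sensitivity": sens, "n_planted": 100, "n_cells": n_cells,
            "n_genes": n_genes}


def interaction_null_calibration(seed: int = 0, n_seeds: int = 10,
                                 n_genes: int = 2000, n_cells: int = 2000,
                                 n_perm: int = 1000) -> dict:
    """Called fraction on pure-noise simulations (expected 10% two-sided)."""
    fracs = []
    for i in range(n_seeds):
        cfg = _flat_interaction_config(seed + 1000 + i, n_genes, n_cells,
                                       n_up=0, n_down=0)
        cm, _ = simulate(cfg)
        tab = expression_changes(cm, timepoint="T3")
        null = permutation_null(tab, n_perm=n_perm, seed=seed + i)
        called = call_interactions(tab, null)
        fracs.append(float((called["call"] != "none").mean()))
    return {"called_fraction": float(np.mean(fracs)), "per_seed": fracs,
            "n_seeds": n_seeds}


def interaction_bias(seed: int = 0, n_cells: int = 5000,
                     n_genes: int = 2000) -> dict:
    """Bias of the measured score for a planted log effect of +1."""
    cfg = _flat_interaction_config(seed, n_genes, n_cells)
    cm, _ = simulate(cfg)
    tab = expression_changes(cm, timepoint="T3").set_index("gene")
    up = [f"g{i:05d}" for i in range(50)]
    down = [f"g{i:05d}" for i in range(50, 100)]
    bias_up = float(tab.loc[up, "score"].mean() - 1.0)
    bias_down = float(tab.loc[down, "score"].mean() + 1.0)
    return {"bias": max(abs(bias_up), abs(bias_down)), "bias_up": bias_up,
            "bias_down": bias_down, "n_cells": n_cells}


def null_quantile_oracle(seed: int = 0, n_perm: int = 10_000) -> dict:
    """Sampled gene-pairing null versus exhaustive enumeration, 5 genes.

    Pooling the independent permutations of 5 genes over all 120
    orderings weights every pairing (i, j) equally, so the exhaustive
    pool is the 25 pairwise differences.
    """
    rng = np.random.default_rng(seed)
    dobs = rng.uniform(0, 0.1, 5)
    dexp = rng.uniform(0, 0.1, 5)
    table = pd.DataFrame(
        {"delta_obs": dobs, "delta_exp": dexp, "score": dobs - dexp}
    )
    null = permutation_null(table, n_perm=n_perm, seed=seed,
                            scheme="independent")
    exact = exhaustive_null_pool(dobs, dexp)
    q05e, q95e = np.percentile(exact, [5, 95])
    return {
        "q05_error": abs(null.q05 - q05e),
        "q95_error": abs(null.q95 - q95e),
        "max_error": float(max(abs(null.q05 - q05e), abs(null.q95 - q95e))),
        "n_perm": n_perm,
    }


def decompose_identity(seed: int = 0, n_instances: int = 5) -> dict:
    """Exactness of composition + expression = total on random instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_instances):
        n_genes, n_cells = 12, 120
        counts = rng.poisson(rng.lognormal(0.0, 1.0, (n_genes, n_cells)) + 0.5)
        counts[:, counts.sum(axis=0) == 0] += 1
        geno = rng.choice(["WT", "AB"], n_cells)
        labels = rng.choice(["s1", "s2", "s3"], n_cells)
        cm = CellMatrix(
            counts, [f"g{j}" for j in range(n_genes)],
            [f"c{j}" for j in range(n_cells)],
            pd.DataFrame({"genotype": geno, "timepoint": "T1"},
                         index=[f"c{j}" for j in range(n_cells)]),
        )
        dec = decompose_change(cm, [f"g{j}" for j in range(3)], "AB", labels)
        err = (dec["composition"] + dec["expression"] - dec["total"]).abs().max()
        worst = max(worst, float(err))
    return {"max_identity_error": worst, "n_instances": n_instances}


# ----------------------------------------------------------------------

def projection_benchmark(seed: int = 0, n_genes: int = 2000,
                         n_cells: int = 2000, holdout: float = 0.2) -> dict:
    """Held-out wild-type label-transfer accuracy through the full atlas path."""
    cfg = default_hematopoiesis_config(n_genes=n_genes, n_cells=n_cells,
                                       seed=seed)
    cfg.genotypes = ("WT",)
    cfg.doublet_rate = 0.0
    cfg.mito_outlier_rate = 0.0
    cm, truth = simulate(cfg)
    tc = truth.cells.set_index("cell_id")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(cm.n_cells)
    n_test = int(holdout * cm.n_cells)
    test = cm.subset_cells(perm[:n_test])
    train = cm.subset_cells(perm[n_test:])
    model = fit_reference(train, seed=seed)
    model = merge_clusters(model)
    model = annotate(model, marker_table(truth), normalize_log(train))
    res = project_cells(test, model)
    acc = float(
        (res.labels().to_numpy() == tc.loc[test.cell_ids, "state"].to_numpy()).mean()
    )
    # reference self-projection: identical input must land on itself
    self_emb = embed_cells(train, model)
    self_dist = float(np.abs(self_emb - model.embeddings).max())
    ref_truth = tc.loc[train.cell_ids, "state"].to_numpy()
    ann_acc = float((model.state_label == ref_truth).mean())
    return {
        "holdout_accuracy": acc,
        "n_test": n_test,
        "self_embedding_error": self_dist,
        "reference_annotation_accuracy": ann_acc,
        "n_populations": len(np.unique(model.population)),
    }


def deg_benchmark(seed: int = 0, n_genes: int = 1000,
                  n_cells: int = 600) -> dict:
    """Type-I control and within/between separation of the DEG framework."""
    # null: hierarchy and composition effects but zero expression effects
    cfg = default_hematopoiesis_config(n_genes=n_genes, n_cells=n_cells,
                                       seed=seed)
    cfg.effect_A = cfg.effect_B = cfg.effect_interaction = None
    cfg.doublet_rate = 0.0
    cfg.mito_outlier_rate = 0.0
    cm, truth = simulate(cfg)
    labels = truth.cells.set_index("cell_id").loc[cm.cell_ids, "state"]
    norm = normalize_log(cm)
    _, summary = within_between_analysis(
        norm, cm.cell_meta, labels, gene_ids=cm.gene_ids,
        timepoints=["T3"],
    )
    ok = summary[~summary["skipped"]]
    within = ok[ok["comparison"] == "within"]
    between = ok[ok["comparison"] == "between"]
    n_tested = (np.asarray((norm > 0).sum(axis=1)).ravel() > 3).sum()
    max_within_frac = float((within["n_deg"] / n_tested).max())

    # separation: for each state the smallest between-state count must
    # exceed the largest within-state count
    states = sorted(set(labels))
    n_sep = 0
    for s in states:
        w = within[within["state"] == s]["n_deg"]
        b = between[between["state"].str.split("|").apply(lambda p: s in p)][
            "n_deg"
        ]
        if len(w) and len(b) and b.min() > w.max():
            n_sep += 1
    return {
        "max_within_fraction": max_within_frac,
        "states_separated": n_sep,
        "n_states": len(states),
        "n_within": len(within),
        "n_between": len(between),
    }


def trajectory_benchmark(seed: int = 0, n_cells: int = 2000,
                         n_genes: int = 800) -> dict:
    """Pseudotime ordering on a 5-state linear chain + density null check."""
    chain = {"S1": "S0", "S2": "S1", "S3": "S2", "S4": "S3"}
    cfg = SimConfig(
        n_genes=n_genes, n_cells=n_cells, hierarchy=chain, root="S0",
        genotypes=("WT",), timepoints=("T1",), doublet_rate=0.0,
        mito_outlier_rate=0.0, seed=seed,
    )
    cm, truth = simulate(cfg)
    model = fit_reference(cm, seed=seed)
    tc = truth.cells.set_index("cell_id").loc[cm.cell_ids]
    pt = diffusion_pseudotime(model.embeddings, tc["state"].to_numpy(),
                              cell_ids=cm.cell_ids, root_state="S0")
    rho = float(spearmanr(pt.tau, tc["pseudotime"].to_numpy()).statistic)

    # a genotype identical to the reference must show no enrichment:
    # duplicate the pool, once labeled WT and once labeled B
    dup = pd.DataFrame({
        "genotype": np.r_[np.repeat("WT", cm.n_cells), np.repeat("B", cm.n_cells)],
        "timepoint": "T1",
    })
    from .trajectory import PseudotimeResult

    pt2 = PseudotimeResult(
        tau=np.r_[pt.tau, pt.tau],
        rank=np.r_[pt.rank, pt.rank],
        in_lineage=np.r_[pt.in_lineage, pt.in_lineage],
        root_cell=pt.root_cell,
        cell_ids=np.r_[pt.cell_ids, pt.cell_ids],
    )
    dc = density_compare(pt2, dup, np.r_[tc["state"], tc["state"]])
    n_enriched = sum(len(v) for v in dc.enriched_intervals.values())
    integrals = {
        g: float(np.trapezoid(dc.densities[g], dc.grid))
        for g in dc.densities.columns
    }
    return {
        "spearman": rho,
        "n_enriched_identical": n_enriched,
        "density_integrals": integrals,
        "n_cells": cm.n_cells,
    }


def qc_benchmark(seed: int = 0) -> dict:
    """Exact mito-filter retention plus doublet-score AUROC."""
    rng = np.random.default_rng(seed)
    # 100-cell fixture: 7 constructed above the 10% mito threshold
    n_genes, n_cells = 50, 100
    counts = rng.poisson(2.0, (n_genes, n_cells))
    counts[:, counts.sum(axis=0) == 0] += 1
    genes = [f"g{i}" for i in range(n_genes - 2)] + ["mt-1", "mt-2"]
    counts[-2:] = 0
    hot = rng.choice(n_cells, 7, replace=False)
    for c in range(n_cells):
        tot = counts[:-2, c].sum()
        # 5% mito for ordinary cells, >12% for the constructed outliers
        target = int(np.ceil((0.13 if c in hot else 0.05) * tot / 0.87))
        counts[-2, c] = target
    meta = pd.DataFrame({"genotype": "WT", "timepoint": "T1"},
                        index=[f"c{i}" for i in range(n_cells)])
    cm = CellMatrix(counts, genes, list(meta.index), meta)
    kept, _ = mito_filter(cm)

    # two far-separated states + constructed cross-state doublets
    half = 300
    progs = []
    for s, lo, hi in (("X", 0, 40), ("Y", 40, 80)):
        base = np.full(200, 0.3)
        base[lo:hi] = 5.0
        c = rng.poisson(np.tile(base, (half, 1))).T
        progs.append(c)
    singles = np.hstack(progs)
    n_dbl = 60
    ia = rng.integers(0, half, n_dbl)
    ib = rng.integers(half, 2 * half, n_dbl)
    doublets = singles[:, ia] + singles[:, ib]
    allc = np.hstack([singles, doublets])
    allc[:, allc.sum(axis=0) == 0] += 1
    ids = [f"c{i}" for i in range(allc.shape[1])]
    meta2 = pd.DataFrame({"genotype": "WT", "timepoint": "T1"}, index=ids)
    cm2 = CellMatrix(allc, [f"g{i}" for i in range(200)], ids, meta2)
    rep = score_doublets(cm2, seed=seed)
    is_dbl = np.r_[np.zeros(2 * half, bool), np.ones(n_dbl, bool)]
    auroc = _auroc(rep.per_cell["doublet_score"].to_numpy(), is_dbl)
    return {"mito_retained": kept.n_cells, "mito_expected": 93,
            "doublet_auroc": float(auroc), "n_doublets": n_dbl}


def _auroc(score: np.ndarray, truth: np.ndarray) -> float:
    from scipy.stats import rankdata

    r = rankdata(score)
    n1 = truth.sum()
    n0 = len(truth) - n1
    return (r[truth].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def rf_benchmark(seed: int = 0, n_genes: int = 2000, n_cells: int = 600,
                 n_trees: int = 500) -> dict:
    """Random-forest classifier accuracy and the candidate screen."""
    cfg = default_hematopoiesis_config(n_genes=n_genes, n_cells=n_cells,
                                       seed=seed)
    cfg.doublet_rate = 0.0
    cfg.mito_outlier_rate = 0.0
    cm, truth = simulate(cfg)
    tc = truth.cells.set_index("cell_id")
    wt = cm.subset_cells((cm.cell_meta["genotype"] == "WT").to_numpy())
    wt_labels = tc.loc[wt.cell_ids, "state"].to_numpy()
    norm_wt = normalize_log(wt)
    rf = train_rf(norm_wt, wt.gene_ids, wt_labels, n_trees=n_trees, seed=seed)

    # chance-level baseline: shuffled labels on a class-balanced subsample
    # (with unequal state frequencies a label-shuffled classifier learns
    # the majority class, so chance is 1/n_states only when balanced)
    rng = np.random.default_rng(seed)
    per_state = pd.Series(wt_labels).groupby(wt_labels).indices
    n_min = min(len(v) for v in per_state.values())
    bal = np.sort(np.concatenate([
        rng.choice(v, n_min, replace=False) for v in per_state.values()
    ]))
    rf_shuf = train_rf(
        sp.csr_matrix(norm_wt)[:, bal], wt.gene_ids,
        rng.permutation(wt_labels[bal]),
        n_trees=max(100, n_trees // 5), seed=seed,
    )

    # two perfectly separable states
    two = _separable_two_state(seed)
    rf_two = train_rf(normalize_log(two[0]), two[0].gene_ids, two[1],
                      n_trees=200, seed=seed)

    # candidate screen on the double mutant
    labels_all = tc.loc[cm.cell_ids, "state"].to_numpy()
    ab = cm.subset_cells((cm.cell_meta["genotype"] == "AB").to_numpy())
    spec = hscmpp_specificity(rf, normalize_log(ab), ab.gene_ids)
    hsc_tab = expression_changes(cm, timepoint="T3",
                                 subset_states=["HSC/MPP"],
                                 state_labels=labels_all)
    null = permutation_null(hsc_tab, n_perm=1000, seed=seed)
    called = call_interactions(hsc_tab, null)
    lfc = called.set_index("gene")["delta_obs"]
    screen = nominate_candidates(spec, called, lfc)
    planted = truth.genes.loc[truth.genes["effect_interaction"] > 0, "gene_id"]
    flagged = set(screen.index[screen["candidate"].fillna(False)])
    tp = len(flagged & set(planted))
    others = screen.index.difference(planted)
    fp = len(flagged & set(others))
    return {
        "cv_accuracy": rf.mean_accuracy,
        "cv_accuracy_shuffled": rf_shuf.mean_accuracy,
        "cv_accuracy_two_state": rf_two.mean_accuracy,
        "screen_recovered": tp,
        "screen_planted": int(len(planted)),
        "screen_false_positives": fp,
        "screen_n_other": int(len(others)),
        "n_wt_cells": wt.n_cells,
    }


def _separable_two_state(seed: int):
    rng = np.random.default_rng(seed)
    n = 150
    prog = np.full((2, 100), 0.2)
    prog[0, :30] = 6.0
    prog[1, 30:60] = 6.0
    counts = np.hstack([
        rng.poisson(np.tile(prog[0], (n, 1))).T,
        rng.poisson(np.tile(prog[1], (n, 1))).T,
    ])
    counts[:, counts.sum(axis=0) == 0] += 1
    ids = [f"c{i}" for i in range(2 * n)]
    meta = pd.DataFrame({"genotype": "WT", "timepoint": "T1"}, index=ids)
    cm = CellMatrix(counts, [f"g{i}" for i in range(100)], ids, meta)
    labels = np.array(["X"] * n + ["Y"] * n, dtype=object)
    return cm, labels
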