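import numpy as np
import pytest

from oncosyn.atlas import normalize_log
from oncosyn.degs import wilcoxon_de, within_between_analysis
from oncosyn.simdata import default_hematopoiesis_config, simulate


def test_exact_mann_whitney_small_groups():
    """[1,2,3] vs [4,5,6]: all 20 rank assignments give two-sided p = 0.1."""
    t = wilcoxon_de(np.array([[1.0, 2, 3]]), np.array([[4.0, 5, 6]]),
                    ["g"], min_cells=1)
    assert t["pvalue"].iloc[0] == pytest.approx(0.1)


def test_identical_groups_no_degs():
    rng = np.random.default_rng(0)
    x = rng.poisson(2.0, (20, 30)).astype(float)
    t = wilcoxon_de(x, x.copy(), [f"g{i}" for i in range(20)])
    assert (t["pvalue"] == 1.0).all()
    assert t["significant"].sum() == 0


def test_symmetry_under_group_swap():
    rng = np.random.default_rng(1)
    a = rng.normal(1.0, 1.0, (15, 40))
    b = rng.normal(1.5, 1.0, (15, 40))
    a[a < 0] = 0
    b[b < 0] = 0
    genes = [f"g{i}" for i in range(15)]
    t1 = wilcoxon_de(a, b, genes)
    t2 = wilcoxon_de(b, a, genes)
    assert np.allclose(t1["pvalue"], t2["pvalue"])
    assert np.allclose(t1["log_fc"], -t2["log_fc"])


def test_adjusted_p_geq_raw_and_bh_oracle():
    """BH step-up on the per-gene p values: adjusted >= raw, and the
    textbook instance p=[.01,.02,.03] adjusts to [.03,.03,.03]."""
    rng = np.random.default_rng(2)
    a = rng.normal(0, 1, (30, 50))
    b = rng.normal(0.3, 1, (30, 50))
    t = wilcoxon_de(np.abs(a), np.abs(b), [f"g{i}" for i in range(30)])
    assert (t["adj_pvalue"] >= t["pvalue"] - 1e-15).all()
    from statsmodels.stats.multitest import multipletests

    _, adj, _, _ = multipletests([0.01, 0.02, 0.03], method="fdr_bh")
    assert np.allclose(adj, [0.03, 0.03, 0.03])


def test_min_cells_skip():
    t = wilcoxon_de(np.ones((5, 10)), np.ones((5, 50)), list("abcde"),
                    min_cells=20)
    assert t is None


@pytest.fixture(scope="module")
def null_within():
    """Hierarchy with composition effects but zero expression effects."""
    cfg = default_hematopoiesis_config(n_genes=600, n_cells=300, seed=13)
    cfg.effect_A = cfg.effect_B = cfg.effect_interaction = None
    cfg.doublet_rate = 0.0
    cfg.mito_outlier_rate = 0.0
    cm, truth = simulate(cfg)
    labels = truth.cells.set_index("cell_id").loc[cm.cell_ids, "state"]
    return cm, labels


def test_within_state_null_controlled(null_within):
    """With no genotype expression effects, within-state DEG fractions
    stay at or below the nominal 1% FDR level."""
    cm, labels = null_within
    norm = normalize_log(cm)
    _, summary = within_between_analysis(
        norm, cm.cell_meta, labels, gene_ids=cm.gene_ids, timepoints=["T2"],
    )
    ok = summary[(~summary["skipped"]) & (summary["comparison"] == "within")]
    n_tested = (np.asarray((norm > 0).sum(axis=1)).ravel() > 3).sum()
    assert len(ok) > 10
    assert (ok["n_deg"] / n_tested).max() <= 0.01


def test_between_exceeds_within(null_within):
    """Distinct state programs: between-state comparisons dwarf
    within-state ones for every assessable state."""
    cm, labels = null_within
    norm = normalize_log(cm)
    _, summary = within_between_analysis(
        norm, cm.cell_meta, labels, gene_ids=cm.gene_ids, timepoints=["T3"],
    )
    ok = summary[~summary["skipped"]]
    within = ok[ok["comparison"] == "within"]
    between = ok[ok["comparison"] == "between"]
    for s in sorted(set(within["state"])):
        w = within[within["state"] == s]["n_deg"].max()
        b = between[between["state"].str.split("|").apply(lambda p: s in p)]
        if len(b):
            assert b["n_deg"].min() > w, s


def test_injected_within_effects_detected():
    """~60 planted within-state effect genes in genotype B raise B's
    within-state DEG counts into the right range."""
    cfg = default_hematopoiesis_config(n_genes=600, n_cells=300, seed=14)
    n_eff = 60
    eff = np.zeros(600)
    eff[np.arange(300, 300 + n_eff)] = 1.2
    cfg.effect_A = np.zeros(600)
    cfg.effect_B = eff
    cfg.effect_interaction = np.zeros(600)
    cfg.doublet_rate = 0.0
    cfg.mito_outlier_rate = 0.0
    cm, truth = simulate(cfg)
    labels = truth.cells.set_index("cell_id").loc[cm.cell_ids, "state"]
    norm = normalize_log(cm)
    _, summary = within_between_analysis(
        norm, cm.cell_meta, labels, gene_ids=cm.gene_ids, timepoints=["T3"],
        genotypes=["WT", "A", "B"],
    )
    ok = summary[(~summary["skipped"]) & (summary["comparison"] == "within")]
    b_counts = ok[ok["genotype"] == "B"]["n_deg"]
    a_counts = ok[ok["genotype"] == "A"]["n_deg"]
    # the big states detect most planted genes; genotype A stays null
    assert b_counts.max() >= 0.5 * n_eff
    assert a_counts.max() <= 5
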