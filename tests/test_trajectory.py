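import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, spearmanr

from oncosyn.atlas import fit_reference, normalize_log
from oncosyn.simdata import SimConfig, simulate
from oncosyn.trajectory import (
    PseudotimeResult,
    coexpression_segregation,
    density_compare,
    diffusion_pseudotime,
)

from conftest import make_cell_matrix


@pytest.fixture(scope="module")
def chain():
    """5-state linear chain with its reference embedding."""
    hier = {"S1": "S0", "S2": "S1", "S3": "S2", "S4": "S3"}
    cfg = SimConfig(n_genes=600, n_cells=900, hierarchy=hier, root="S0",
                    genotypes=("WT",), timepoints=("T1",), doublet_rate=0.0,
                    mito_outlier_rate=0.0, seed=2)
    cm, truth = simulate(cfg)
    model = fit_reference(cm, seed=2)
    tc = truth.cells.set_index("cell_id").loc[cm.cell_ids]
    return cm, model, tc


def test_root_cell_has_zero_tau(chain):
    cm, model, tc = chain
    pt = diffusion_pseudotime(model.embeddings, tc["state"].to_numpy(),
                              root_state="S0")
    assert pt.tau[pt.root_cell] == 0.0
    assert tc["state"].iloc[pt.root_cell] == "S0"


def test_chain_ordering_recovered(chain):
    cm, model, tc = chain
    pt = diffusion_pseudotime(model.embeddings, tc["state"].to_numpy(),
                              root_state="S0")
    rho = spearmanr(pt.tau, tc["pseudotime"].to_numpy()).statistic
    assert rho >= 0.9


def test_tau_invariant_to_cell_order_and_scaling(chain):
    cm, model, tc = chain
    pt = diffusion_pseudotime(model.embeddings, tc["state"].to_numpy(),
                              root_state="S0")
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(pt.tau))
    pt_perm = diffusion_pseudotime(model.embeddings[perm],
                                   tc["state"].to_numpy()[perm],
                                   root_state="S0")
    assert np.allclose(pt_perm.tau, pt.tau[perm], atol=1e-6)
    pt_scaled = diffusion_pseudotime(3.0 * model.embeddings,
                                     tc["state"].to_numpy(), root_state="S0")
    assert np.allclose(pt_scaled.tau, pt.tau, rtol=1e-6, atol=1e-8)


def test_ranks_uniform(chain):
    cm, model, tc = chain
    pt = diffusion_pseudotime(model.embeddings, tc["state"].to_numpy(),
                              root_state="S0")
    assert kstest(pt.rank / 100.0, "uniform").pvalue > 0.01
    assert pt.rank.min() == 0.0 and pt.rank.max() == 100.0


def test_missing_root_state_errors(chain):
    cm, model, tc = chain
    with pytest.raises(ValueError, match="absent"):
        diffusion_pseudotime(model.embeddings, tc["state"].to_numpy(),
                             root_state="nope")


def _dup_pt(pt):
    return PseudotimeResult(
        tau=np.r_[pt.tau, pt.tau], rank=np.r_[pt.rank, pt.rank],
        in_lineage=np.r_[pt.in_lineage, pt.in_lineage],
        root_cell=pt.root_cell, cell_ids=np.r_[pt.cell_ids, pt.cell_ids],
    )


def test_density_identical_genotypes_no_enrichment(chain):
    """A mutant identical to WT shows no enriched interval at any delta>0,
    and each reflected KDE integrates to one over [0, 100]."""
    cm, model, tc = chain
    pt = diffusion_pseudotime(model.embeddings, tc["state"].to_numpy(),
                              root_state="S0", cell_ids=cm.cell_ids)
    pt2 = _dup_pt(pt)
    n = cm.n_cells
    meta = pd.DataFrame({"genotype": ["WT"] * n + ["B"] * n,
                         "timepoint": "T1"})
    states = np.r_[tc["state"].to_numpy(), tc["state"].to_numpy()]
    dc = density_compare(pt2, meta, states, delta=0.2)
    assert dc.enriched_intervals["B"] == []
    for g in dc.densities.columns:
        integral = np.trapezoid(dc.densities[g].to_numpy(), dc.grid)
        assert integral == pytest.approx(1.0, abs=1e-3)


def test_density_shift_detected_with_composition(chain):
    """Shifting a pseudo-genotype's cells toward late ranks produces
    enrichment intervals populated by the late states."""
    cm, model, tc = chain
    pt = diffusion_pseudotime(model.embeddings, tc["state"].to_numpy(),
                              root_state="S0", cell_ids=cm.cell_ids)
    # mutant = biased resample of late-rank cells
    rng = np.random.default_rng(1)
    w = (pt.rank / 100.0) ** 2 + 1e-6
    pick = rng.choice(len(w), size=len(w), p=w / w.sum())
    pt2 = PseudotimeResult(
        tau=np.r_[pt.tau, pt.tau[pick]], rank=np.r_[pt.rank, pt.rank[pick]],
        in_lineage=np.r_[pt.in_lineage, pt.in_lineage[pick]],
        root_cell=pt.root_cell,
        cell_ids=np.r_[pt.cell_ids, pt.cell_ids[pick]],
    )
    n = cm.n_cells
    meta = pd.DataFrame({"genotype": ["WT"] * n + ["B"] * n,
                         "timepoint": "T1"})
    states = np.r_[tc["state"].to_numpy(), tc["state"].to_numpy()[pick]]
    dc = density_compare(pt2, meta, states, delta=0.2)
    assert len(dc.enriched_intervals["B"]) >= 1
    comp = dc.composition["B"]
    late_share = comp.get("S3", 0) + comp.get("S4", 0)
    assert late_share > 0.5


def test_coexpression_segregation_scores():
    counts = np.zeros((6, 30), int)
    counts[0:2, :10] = 8   # HSC markers in the first 10 cells
    counts[2:4, 10:20] = 8  # GMP markers next
    counts[4:6, 20:] = 8   # GN markers last
    counts[5, :] += 1      # keep libraries nonzero
    cm = make_cell_matrix(counts)
    sets = {"HSC/MPP": ["g0", "g1"], "GMP": ["g2", "g3"], "GN": ["g4", "g5"]}
    pt = PseudotimeResult(tau=np.arange(30.0), rank=np.linspace(0, 100, 30),
                          in_lineage=np.ones(30, bool), root_cell=0,
                          cell_ids=np.asarray(cm.cell_ids, dtype=object))
    table, dual = coexpression_segregation(
        normalize_log(cm), cm.gene_ids, sets, pt, meta=cm.cell_meta
    )
    first = table.iloc[0]
    assert first["HSC/MPP"] > 0 > first["GMP"]
    assert table.iloc[-1]["GN"] > 0
    with pytest.raises(ValueError, match="empty"):
        coexpression_segregation(normalize_log(cm), cm.gene_ids,
                                 {"HSC/MPP": []}, pt)
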