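import numpy as np
import pandas as pd
import pytest

from oncosyn.atlas import annotate, fit_reference, merge_clusters, normalize_log
from oncosyn.iodata import CellMatrix
from oncosyn.simdata import default_hematopoiesis_config, marker_table, simulate


def make_cell_matrix(counts, genotype="WT", timepoint="T1", gene_ids=None):
    """Small CellMatrix helper for hand-built fixtures."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    cell_ids = [f"c{i}" for i in range(n_cells)]
    genotype = [genotype] * n_cells if isinstance(genotype, str) else genotype
    timepoint = [timepoint] * n_cells if isinstance(timepoint, str) else timepoint
    meta = pd.DataFrame(
        {"genotype": genotype, "timepoint": timepoint}, index=cell_ids
    )
    return CellMatrix(counts, gene_ids, cell_ids, meta)


@pytest.fixture(scope="session")
def hemato_sim():
    """Shared default-design simulation at reduced size (1000 genes, 400/sample)."""
    cfg = default_hematopoiesis_config(n_genes=1000, n_cells=400, seed=7)
    cm, truth = simulate(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def wt_reference(hemato_sim):
    """Fitted, merged, annotated reference on the shared simulation's WT cells."""
    _, cm, truth = hemato_sim
    wt = cm.subset_cells((cm.cell_meta["genotype"] == "WT").to_numpy())
    model = fit_reference(wt, seed=0)
    model = merge_clusters(model)
    model = annotate(model, marker_table(truth), normalize_log(wt))
    return wt, model


@pytest.fixture(scope="session")
def truth_by_cell(hemato_sim):
    _, _, truth = hemato_sim
    return truth.cells.set_index("cell_id")
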