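import numpy as np
import pandas as pd
import pytest

from oncosyn.iodata import (
    CellMatrix,
    RunConfig,
    read_counts,
    read_dir,
    read_markers,
    read_table,
    write_counts,
    write_markers,
    write_table,
)

from conftest import make_cell_matrix


def write_triplet(tmp_path, entries, genes, barcodes, sheet_rows,
                  shape=None, transpose=False):
    shape = shape or (len(genes), len(barcodes))
    if transpose:
        shape = shape[::-1]
        entries = [(c, g, v) for g, c, v in entries]
    lines = ["%%MatrixMarket matrix coordinate integer general",
             f"{shape[0]} {shape[1]} {len(entries)}"]
    lines += [f"{r + 1} {c + 1} {v}" for r, c, v in entries]
    (tmp_path / "matrix.mtx").write_text("\n".join(lines) + "\n")
    (tmp_path / "genes.tsv").write_text("\n".join(genes) + "\n")
    (tmp_path / "barcodes.tsv").write_text("\n".join(barcodes) + "\n")
    sheet = "barcode\tgenotype\ttimepoint\n" + "\n".join(
        "\t".join(r) for r in sheet_rows
    )
    (tmp_path / "samples.tsv").write_text(sheet + "\n")
    return (tmp_path / "matrix.mtx", tmp_path / "genes.tsv",
            tmp_path / "barcodes.tsv", tmp_path / "samples.tsv")


@pytest.mark.parametrize("transpose", [False, True])
def test_read_counts_toy_triplet(tmp_path, transpose):
    """3-gene x 2-cell toy with entries (g1,c1)=5, (g3,c2)=2 reads back
    with column sums [5, 2], in file order, in either MM orientation."""
    paths = write_triplet(
        tmp_path, [(0, 0, 5), (2, 1, 2)], ["g1", "g2", "g3"], ["c1", "c2"],
        [("c1", "WT", "T1"), ("c2", "AB", "T3")], transpose=transpose,
    )
    cm = read_counts(*paths)
    assert cm.counts.shape == (3, 2)
    assert np.array_equal(cm.totals(), [5, 2])
    assert list(cm.gene_ids) == ["g1", "g2", "g3"]
    assert list(cm.cell_ids) == ["c1", "c2"]
    assert cm.cell_meta.loc["c2", "genotype"] == "AB"


def test_read_counts_empty_matrix_errors(tmp_path):
    paths = write_triplet(tmp_path, [], ["g1"], ["c1"], [("c1", "WT", "T1")])
    with pytest.raises(ValueError, match="no entries"):
        read_counts(*paths)


def test_read_counts_missing_barcode_dropped(tmp_path):
    """A barcode absent from the sample sheet is rejected, not invented."""
    paths = write_triplet(
        tmp_path, [(0, 0, 1), (0, 1, 3)], ["g1"], ["c1", "c2"],
        [("c1", "WT", "T1")],
    )
    cm = read_counts(*paths)
    assert cm.n_cells == 1
    assert list(cm.cell_ids) == ["c1"]


def test_read_counts_duplicate_genes_suffixed(tmp_path):
    paths = write_triplet(
        tmp_path, [(0, 0, 1), (1, 0, 2), (2, 0, 3)], ["Actb", "Actb", "Actb"],
        ["c1"], [("c1", "WT", "T1")],
    )
    cm = read_counts(*paths)
    assert list(cm.gene_ids) == ["Actb", "Actb.1", "Actb.2"]


def test_read_counts_dimension_mismatch(tmp_path):
    paths = write_triplet(
        tmp_path, [(0, 0, 1)], ["g1", "g2", "g3"], ["c1", "c2"],
        [("c1", "WT", "T1")], shape=(5, 4),
    )
    with pytest.raises(ValueError, match="matches neither"):
        read_counts(*paths)


def test_cell_matrix_invariants():
    with pytest.raises(ValueError, match="negative"):
        make_cell_matrix([[-1, 2]])
    with pytest.raises(ValueError, match="non-integer"):
        make_cell_matrix([[1.5, 2]])
    with pytest.raises(ValueError, match="duplicate gene"):
        make_cell_matrix([[1], [2]], gene_ids=["g", "g"])
    with pytest.raises(ValueError, match="gene ids"):
        CellMatrix(np.ones((2, 2), int), ["g1"], ["c1", "c2"],
                   pd.DataFrame({"genotype": ["WT"] * 2, "timepoint": ["T1"] * 2},
                                index=["c1", "c2"]))


def test_write_table_round_trip(tmp_path):
    df = pd.DataFrame({
        "gene": ["a", "b", "c"],
        "score": [0.1234567890123, -1e-9, 3.0],
        "n": [1, 2, 3],
    })
    p = tmp_path / "t.tsv"
    write_table(df, p)
    back = read_table(p)
    pd.testing.assert_frame_equal(df, back)
    write_table(df.iloc[:0], p)
    assert read_table(p).empty


def test_counts_round_trip(tmp_path, hemato_sim):
    """write_counts -> read_dir preserves counts, ids, order, and metadata."""
    _, cm, _ = hemato_sim
    sub = cm.subset_cells(np.arange(50))
    write_counts(sub, tmp_path / "trip")
    back = read_dir(tmp_path / "trip")
    assert (back.counts != sub.counts).nnz == 0
    assert np.array_equal(back.gene_ids, sub.gene_ids)
    assert np.array_equal(back.cell_ids, sub.cell_ids)
    assert back.cell_meta["genotype"].tolist() == sub.cell_meta["genotype"].tolist()


def test_markers_round_trip(tmp_path):
    markers = {"HSC/MPP": ["Msi2", "Flt3"], "GMP": ["Mpo"]}
    p = tmp_path / "markers.tsv"
    write_markers(markers, p)
    assert read_markers(p) == markers


def test_run_config_yaml_round_trip(tmp_path):
    cfg = RunConfig(seed=3)
    cfg.atlas.resolution = 1.5
    cfg.interaction.n_perm = 77
    p = tmp_path / "cfg.yaml"
    cfg.to_yaml(p)
    assert RunConfig.from_yaml(p) == cfg
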