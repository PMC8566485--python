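"""Input/output and run configuration.

The pipeline's universal carrier is :class:`CellMatrix`: a sparse
genes x cells UMI count matrix plus per-cell metadata (genotype, time
point, optional QC fields and state label).  On disk the package speaks
the 10x-style triplet dialect -- a Matrix Market coordinate file with a
gene list and a barcode list, one id per line -- together with a sample
sheet assigning each barcode to a genotype in ``{WT, A, B, AB}`` and a
time point in ``{T1, T2, T3}``.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from scipy.io import mmread, mmwrite

log = logging.getLogger("oncosyn")

GENOTYPES = ("WT", "A", "B", "AB")
TIMEPOINTS = ("T1", "T2", "T3")

REQUIRED_META = ("genotype", "timepoint")


def _dedupe(ids) -> np.ndarray:
    """Disambiguate duplicate identifiers by suffixing ".1", ".2", ...

    Deterministic and reversible: the first occurrence keeps the bare name.
    """
    seen: dict[str, int] = {}
    out = []
    for x in map(str, ids):
        n = seen.get(x, 0)
        out.append(x if n == 0 else f"{x}.{n}")
        seen[x] = n + 1
    return np.asarray(out, dtype=object)


@dataclass
class CellMatrix:
    """Sparse genes x cells counts with aligned per-cell metadata.

    Invariants (checked on construction): matrix dimensions match the id
    list lengths, ids are unique, counts are integral and non-negative,
    and ``cell_meta`` is indexed by ``cell_ids`` with at least the
    ``genotype`` and ``timepoint`` columns.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        g, c = self.counts.shape
        if g != len(self.gene_ids):
            raise ValueError(f"{g} matrix rows but {len(self.gene_ids)} gene ids")
        if c != len(self.cell_ids):
            raise ValueError(f"{c} matrix columns but {len(self.cell_ids)} cell ids")
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if pd.Index(ids).has_duplicates:
                raise ValueError(f"duplicate {name} ids")
        if self.counts.nnz:
            d = self.counts.data
            if d.min() < 0:
                raise ValueError("negative counts")
            if not np.allclose(d, np.round(d)):
                raise ValueError("non-integer counts")
        if not self.cell_meta.index.equals(pd.Index(self.cell_ids)):
            # allow construction from unordered metadata
            self.cell_meta = self.cell_meta.reindex(pd.Index(self.cell_ids))
        missing = [c_ for c_ in REQUIRED_META if c_ not in self.cell_meta.columns]
        if missing:
            raise ValueError(f"cell_meta lacks required columns {missing}")
        if self.cell_meta[list(REQUIRED_META)].isna().any().any():
            raise ValueError("cells with missing genotype/timepoint")

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        idx = pd.Index(self.gene_ids).get_indexer(np.atleast_1d(genes))
        if (idx < 0).any():
            missing = np.atleast_1d(genes)[idx < 0]
            raise KeyError(f"genes not in matrix: {list(missing)[:5]}")
        return idx

    def totals(self) -> np.ndarray:
        """Per-cell total UMI counts."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def mito_genes(self, prefix: str = "mt-") -> np.ndarray:
        """Boolean mask of mitochondrial genes by (case-insensitive) prefix."""
        p = prefix.lower()
        return np.array([str(g).lower().startswith(p) for g in self.gene_ids])

    def subset_cells(self, sel) -> "CellMatrix":
        sel = np.asarray(sel)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
        return CellMatrix(
            self.counts[:, sel],
            self.gene_ids,
            self.cell_ids[sel],
            self.cell_meta.iloc[sel],
        )

    def subset_genes(self, sel) -> "CellMatrix":
        sel = np.asarray(sel)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
        return CellMatrix(
            self.counts[sel], self.gene_ids[sel], self.cell_ids, self.cell_meta
        )

    def sample_key(self) -> pd.Series:
        """Per-cell "genotype:timepoint" sample identifier."""
        return (
            self.cell_meta["genotype"].astype(str)
            + ":"
            + self.cell_meta["timepoint"].astype(str)
        )

    @classmethod
    def concat(cls, parts: list["CellMatrix"]) -> "CellMatrix":
        """Column-wise concatenation of matrices sharing one gene namespace."""
        first = parts[0]
        for p in parts[1:]:
            if not np.array_equal(p.gene_ids, first.gene_ids):
                raise ValueError("gene namespaces differ")
        return cls(
            sp.hstack([p.counts for p in parts], format="csr"),
            first.gene_ids,
            np.concatenate([p.cell_ids for p in parts]),
            pd.concat([p.cell_meta for p in parts]),
        )

    def to_anndata(self):
        """Export as an AnnData (cells x genes), if anndata is installed."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene")),
        )


# ----------------------------------------------------------------------
# Readers / writers
# ----------------------------------------------------------------------

def read_counts(
    matrix_path,
    genes_path,
    barcodes_path,
    sample_sheet_path,
) -> CellMatrix:
    """Read a 10x-style triplet plus sample sheet into a :class:`CellMatrix`.

    Both genes x cells and cells x genes Matrix Market orientations are
    accepted and disambiguated against the id-file lengths; the internal
    canonical orientation is genes x cells.  Cells absent from the sample
    sheet are dropped (logged), and duplicate gene symbols are suffixed
    ".1", ".2", ...
    """
    m = mmread(str(matrix_path))
    if m.nnz == 0 and 0 in m.shape:
        raise ValueError("no entries")
    genes = _read_ids(genes_path)
    barcodes = _read_ids(barcodes_path)
    if m.shape == (len(genes), len(barcodes)):
        pass
    elif m.shape == (len(barcodes), len(genes)):
        m = m.T
    else:
        raise ValueError(
            f"matrix shape {m.shape} matches neither {len(genes)} genes x "
            f"{len(barcodes)} cells nor its transpose"
        )
    if m.nnz == 0:
        raise ValueError("no entries")
    m = sp.csr_matrix(m)
    if not np.allclose(m.data, np.round(m.data)):
        raise ValueError("non-integer entries in count matrix")

    genes = _dedupe(genes)
    if pd.Index(barcodes).has_duplicates:
        raise ValueError("duplicate cell barcodes")

    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    required = {"barcode", "genotype", "timepoint"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    sheet = sheet.set_index("barcode")
    keep = np.array([b in sheet.index for b in barcodes])
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("dropping %d cells absent from sample sheet", n_drop)
    barcodes = np.asarray(barcodes, dtype=object)[keep]
    meta = sheet.loc[barcodes, ["genotype", "timepoint"]].copy()
    meta.index.name = None
    return CellMatrix(m[:, np.flatnonzero(keep)], genes, barcodes, meta)


def _read_ids(path) -> list[str]:
    with open(path) as fh:
        # 10x genes.tsv may carry a second (symbol) column; the symbol keys
        ids = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            ids.append(parts[-1])
    return ids


def write_counts(cm: CellMatrix, out_dir) -> None:
    """Write a CellMatrix as matrix.mtx + genes.tsv + barcodes.tsv + samples.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(self_int(cm.counts)))
    (out / "genes.tsv").write_text("\n".join(map(str, cm.gene_ids)) + "\n")
    (out / "barcodes.tsv").write_text("\n".join(map(str, cm.cell_ids)) + "\n")
    sheet = cm.cell_meta.reset_index().rename(columns={"index": "barcode"})
    write_table(sheet, out / "samples.tsv")


def self_int(m: sp.spmatrix) -> sp.spmatrix:
    return m.astype(np.int64) if not np.issubdtype(m.dtype, np.integer) else m


def read_dir(in_dir) -> CellMatrix:
    """Read back a directory produced by :func:`write_counts`."""
    d = Path(in_dir)
    return read_counts(
        d / "matrix.mtx", d / "genes.tsv", d / "barcodes.tsv", d / "samples.tsv"
    )


def write_table(table: pd.DataFrame, path) -> None:
    """TSV with header; round-trips string/float/int columns losslessly."""
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_markers(path) -> dict[str, list[str]]:
    """Marker-gene TSV with columns (population, gene) -> {population: genes}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"population", "gene"}.issubset(df.columns):
        raise ValueError("marker file needs columns 'population' and 'gene'")
    return {p: list(g["gene"]) for p, g in df.groupby("population", sort=False)}


def write_markers(markers: dict[str, list[str]], path) -> None:
    rows = [(p, g) for p, genes in markers.items() for g in genes]
    write_table(pd.DataFrame(rows, columns=["population", "gene"]), path)


# ----------------------------------------------------------------------
# Run configuration
# ----------------------------------------------------------------------

@dataclass
class QCParams:
    mito_threshold: float = 0.10
    mito_prefix: str = "mt-"
    n_sim_frac: float = 1.0
    doublet_k: int = 30
    doublet_n_pcs: int = 30
    doublet_fallback_threshold: float = 0.25


@dataclass
class AtlasParams:
    scale: float = 10_000.0
    n_hvg: int = 2000
    n_pcs: int = 50
    knn_k: int = 15
    resolution: float = 1.0
    corr_threshold: float = 0.6
    min_edge_frac: float = 0.01


@dataclass
class DEGParams:
    min_cells: int = 20
    alpha: float = 0.01
    detect_cells: int = 3
    pool_timepoints: bool = False


@dataclass
class TrajectoryParams:
    root_state: str = "HSC/MPP"
    n_dcs: int = 10
    knn_k: int = 15
    bandwidth: float = 3.0
    delta: float = 0.2
    lineage_states: tuple = ("HSC/MPP", "GMP", "ProMo", "GN-early", "GN-late")


@dataclass
class InteractionParams:
    n_perm: int = 1000
    subset: str = "all"  # "all" or a state label, e.g. "HSC/MPP"
    scheme: str = "independent"  # or "paired"


@dataclass
class CoexpressParams:
    expr_threshold: int = 0
    n_cells: int = 1000
    n_iter: int = 10


@dataclass
class ScreenParams:
    n_trees: int = 500
    n_top_genes: int = 1000
    n_folds: int = 5
    r_min: float = 0.3


@dataclass
class RunConfig:
    """All tunable parameters of every stage, with serializable defaults."""

    seed: int = 0
    sim: dict = field(default_factory=dict)  # overrides for SimConfig fields
    qc: QCParams = field(default_factory=QCParams)
    atlas: AtlasParams = field(default_factory=AtlasParams)
    degs: DEGParams = field(default_factory=DEGParams)
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)
    interaction: InteractionParams = field(default_factory=InteractionParams)
    coexpress: CoexpressParams = field(default_factory=CoexpressParams)
    screen: ScreenParams = field(default_factory=ScreenParams)

    def to_yaml(self, path=None) -> str:
        doc = dataclasses.asdict(self)
        doc["trajectory"]["lineage_states"] = list(
            doc["trajectory"]["lineage_states"]
        )
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, src) -> "RunConfig":
        text = Path(src).read_text() if Path(str(src)).exists() else str(src)
        doc = yaml.safe_load(text) or {}
        kw = {}
        sections = {
            "qc": QCParams,
            "atlas": AtlasParams,
            "degs": DEGParams,
            "trajectory": TrajectoryParams,
            "interaction": InteractionParams,
            "coexpress": CoexpressParams,
            "screen": ScreenParams,
        }
        for key, val in doc.items():
            if key in sections:
                if "lineage_states" in val:
                    val["lineage_states"] = tuple(val["lineage_states"])
                kw[key] = sections[key](**val)
            else:
                kw[key] = val
        return cls(**kw)
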