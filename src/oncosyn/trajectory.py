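"""Diffusion pseudotime and cell-density shifts along differentiation.

All cells (reference and projected mutants) share one embedding; a
symmetric kNN graph with an adaptive Gaussian kernel yields a diffusion
operator whose leading non-stationary eigenvectors span a diffusion
space.  Pseudotime is the Euclidean distance from a root cell in that
space (components scaled by ``lambda / (1 - lambda)``), and cells of a
selected lineage are ranked 0-100% from least to most differentiated.
Genotype effects on differentiation appear as density shifts of those
ranks; enriched rank intervals and their cell-state composition
summarize where a mutant accumulates cells.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from scipy.stats import gaussian_kde, rankdata
from sklearn.neighbors import NearestNeighbors

log = logging.getLogger("oncosyn")


@dataclass
class PseudotimeResult:
    """Per-cell diffusion pseudotime and lineage percentile rank."""

    tau: np.ndarray  # diffusion pseudotime, root = 0; inf if unreachable
    rank: np.ndarray  # 0-100 percentile within the lineage pool (NaN outside)
    in_lineage: np.ndarray  # bool
    root_cell: int  # index into the pooled cell set
    cell_ids: np.ndarray
    diffusion_components: np.ndarray = field(repr=False, default=None)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tau": self.tau, "rank": self.rank, "in_lineage": self.in_lineage},
            index=pd.Index(self.cell_ids),
        )


def diffusion_pseudotime(
    embeddings: np.ndarray,
    state_labels,
    cell_ids=None,
    root_state: str = "HSC/MPP",
    n_dcs: int = 10,
    k: int = 15,
    lineage_states: list[str] | None = None,
) -> PseudotimeResult:
    """Diffusion pseudotime from an automatically chosen root cell.

    The root is the ``root_state`` cell closest to its state centroid
    (deterministic).  Cells in graph components not containing the root
    get ``tau = inf`` and are excluded from ranking; ranks are computed
    on the lineage-restricted, all-genotype pool (all cells when
    ``lineage_states`` is None).
    """
    emb = np.asarray(embeddings, float)
    labels = np.asarray(state_labels, dtype=object)
    n = len(emb)
    if cell_ids is None:
        cell_ids = np.arange(n).astype(str)
    root_mask = labels == root_state
    if not root_mask.any():
        raise ValueError(f"root state {root_state!r} absent")
    centroid = emb[root_mask].mean(axis=0)
    root = int(np.flatnonzero(root_mask)[
        np.argmin(np.linalg.norm(emb[root_mask] - centroid, axis=1))
    ])

    W = _adaptive_gaussian_graph(emb, k)
    ncomp, comp = connected_components(W, directed=False)
    reachable = comp == comp[root]
    if ncomp > 1:
        log.warning("kNN graph has %d components; %d cells unreachable from root",
                    ncomp, int((~reachable).sum()))

    tau = np.full(n, np.inf)
    dcs = np.zeros((n, n_dcs))
    idx = np.flatnonzero(reachable)
    Wr = W[idx][:, idx]
    evecs, evals = _diffusion_components(Wr, n_dcs)
    scale = evals / (1.0 - evals)
    phi = evecs * scale
    r_local = int(np.flatnonzero(idx == root)[0])
    tau[idx] = np.linalg.norm(phi - phi[r_local], axis=1)
    dcs[idx] = phi

    in_lineage = (
        np.isin(labels, list(lineage_states))
        if lineage_states is not None
        else np.ones(n, bool)
    ) & reachable
    rank = np.full(n, np.nan)
    pool = np.flatnonzero(in_lineage)
    if len(pool):
        rank[pool] = (rankdata(tau[pool]) - 1) / max(len(pool) - 1, 1) * 100.0
    return PseudotimeResult(
        tau=tau, rank=rank, in_lineage=in_lineage, root_cell=root,
        cell_ids=np.asarray(cell_ids, dtype=object), diffusion_components=dcs,
    )


def _adaptive_gaussian_graph(emb: np.ndarray, k: int) -> sp.csr_matrix:
    """Symmetric kNN graph with adaptive Gaussian kernel weights.

    Bandwidth sigma_i is the distance to the ``ceil(k/2)``-th neighbor;
    the edge weight is ``exp(-d_ij^2 / (sigma_i * sigma_j))``, making the
    kernel (and hence pseudotime) invariant to uniform rescaling of the
    embedding.
    """
    n = len(emb)
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    dist, idx = nn.kneighbors(emb)
    dist, idx = dist[:, 1:], idx[:, 1:]
    sigma = np.maximum(dist[:, max(int(np.ceil(k / 2)) - 1, 0)], 1e-12)
    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    w = np.exp(-(dist.ravel() ** 2) / (sigma[rows] * sigma[cols]))
    W = sp.csr_matrix((w, (rows, cols)), shape=(n, n))
    return W.maximum(W.T)


def _diffusion_components(W: sp.csr_matrix, n_dcs: int):
    """Leading non-stationary eigenpairs of the diffusion operator.

    The kernel is first density-normalized (anisotropic, alpha = 1) so
    that sampling density does not distort the geometry -- without it a
    low-density bottleneck dominates the relaxation spectrum and the
    scaled diffusion distance collapses to a step function.
    """
    q = np.asarray(W.sum(axis=1)).ravel()
    Qinv = sp.diags(1.0 / np.maximum(q, 1e-300))
    W = Qinv @ W @ Qinv
    d = np.asarray(W.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(d, 1e-300))
    D = sp.diags(d_inv_sqrt)
    M = D @ W @ D  # symmetric conjugate of the transition matrix
    n_ev = min(n_dcs + 1, W.shape[0] - 1)
    v0 = np.full(W.shape[0], 1.0 / np.sqrt(W.shape[0]))  # deterministic start
    evals, evecs = eigsh(M, k=n_ev, which="LA", v0=v0)
    order = np.argsort(-evals)
    evals, evecs = evals[order], evecs[:, order]
    # drop the stationary component (eigenvalue 1)
    evals, evecs = evals[1:], evecs[:, 1:]
    evals = np.clip(evals, -1.0 + 1e-12, 1.0 - 1e-9)
    psi = evecs * d_inv_sqrt[:, None]  # right eigenvectors of P
    # normalize and fix sign for determinism
    psi /= np.linalg.norm(psi, axis=0)
    sign = np.sign(psi[np.argmax(np.abs(psi), axis=0), np.arange(psi.shape[1])])
    psi *= sign
    return psi, evals


# ----------------------------------------------------------------------

@dataclass
class DensityComparison:
    """KDE over differentiation ranks per group, enrichment, composition."""

    grid: np.ndarray
    densities: pd.DataFrame  # columns = genotype, rows = grid
    enriched_intervals: dict  # genotype -> list[(lo, hi)]
    composition: dict  # genotype -> {state: fraction of mutant cells}


def density_compare(
    pt: PseudotimeResult,
    meta: pd.DataFrame,
    state_labels,
    reference_genotype: str = "WT",
    timepoint: str | None = None,
    bandwidth: float = 3.0,
    delta: float = 0.2,
    grid_step: float = 0.5,
) -> DensityComparison:
    """Compare per-genotype cell densities along the 0-100% rank axis.

    Densities use a reflected Gaussian KDE with a common bandwidth (rank
    units), so each integrates to one over [0, 100].  Enriched intervals
    are the maximal rank intervals where a mutant's density exceeds
    ``(1 + delta)`` times the reference density; the composition table
    gives the state-label fractions of that mutant's cells inside them.
    """
    labels = np.asarray(state_labels, dtype=object)
    sel = pt.in_lineage & np.isfinite(pt.rank)
    if timepoint is not None:
        sel &= (meta["timepoint"].to_numpy() == timepoint)
    geno = meta["genotype"].to_numpy()
    grid = np.arange(0.0, 100.0 + grid_step / 2, grid_step)
    dens = {}
    for g in pd.unique(geno):
        m = sel & (geno == g)
        if not m.any():
            raise ValueError(f"lineage pool empty for genotype {g!r}")
        dens[g] = _reflected_kde(pt.rank[m], grid, bandwidth)
    densities = pd.DataFrame(dens, index=grid)

    ref = densities[reference_genotype].to_numpy()
    intervals, composition = {}, {}
    for g in densities.columns:
        if g == reference_genotype:
            continue
        excess = densities[g].to_numpy() >= (1.0 + delta) * ref
        ivals = _maximal_intervals(grid, excess)
        intervals[g] = ivals
        m = sel & (geno == g)
        in_any = np.zeros(m.sum(), bool)
        r = pt.rank[m]
        for lo, hi in ivals:
            in_any |= (r >= lo) & (r <= hi)
        if in_any.any():
            comp = pd.Series(labels[m][in_any]).value_counts(normalize=True)
            composition[g] = comp.to_dict()
        else:
            composition[g] = {}
    return DensityComparison(
        grid=grid, densities=densities, enriched_intervals=intervals,
        composition=composition,
    )


def _reflected_kde(x: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    x = np.asarray(x, float)
    if x.std() < 1e-9:
        # degenerate: all mass at one rank; spread over one grid cell
        d = np.zeros_like(grid)
        d[np.argmin(np.abs(grid - x.mean()))] = 1.0 / (grid[1] - grid[0])
        return d
    kde = gaussian_kde(x, bw_method=bandwidth / x.std(ddof=1))
    # reflect at 0 and 100 so the density integrates to 1 on [0, 100]
    return kde(grid) + kde(-grid) + kde(200.0 - grid)


def _maximal_intervals(grid, mask) -> list[tuple[float, float]]:
    out = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = grid[i]
        elif not flag and start is not None:
            out.append((float(start), float(grid[i - 1])))
            start = None
    if start is not None:
        out.append((float(start), float(grid[-1])))
    return [iv for iv in out if iv[1] > iv[0]]


# ----------------------------------------------------------------------

def coexpression_segregation(
    norm: sp.spmatrix,
    gene_ids,
    marker_sets: dict[str, list[str]],
    pt: PseudotimeResult,
    meta: pd.DataFrame | None = None,
    dual_sets: tuple[str, str] = ("HSC/MPP", "GMP"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean z-scored marker-set scores per cell, ordered by pseudotime.

    Returns the per-cell score table (one column per marker set, rows
    sorted by tau) and, when metadata is given, the per-genotype
    fraction of cells scoring positive on both ``dual_sets`` -- the
    readout for aberrant co-expression of stemness and priming programs.
    """
    if not marker_sets or any(len(v) == 0 for v in marker_sets.values()):
        raise ValueError("empty marker set")
    gene_pos = pd.Index(np.asarray(gene_ids, dtype=object))
    X = np.asarray(sp.csr_matrix(norm).todense())
    mu = X.mean(axis=1)
    sd = X.std(axis=1)
    scores = {}
    for name, genes in marker_sets.items():
        idx = gene_pos.get_indexer(genes)
        idx = idx[idx >= 0]
        idx = idx[sd[idx] > 0]
        if len(idx) == 0:
            raise ValueError(f"no usable marker genes for set {name!r}")
        z = (X[idx] - mu[idx, None]) / sd[idx, None]
        scores[name] = z.mean(axis=0)
    table = pd.DataFrame(scores, index=pd.Index(pt.cell_ids))
    table["tau"] = pt.tau
    table = table.sort_values("tau")

    dual = pd.DataFrame()
    if meta is not None:
        a, b = dual_sets
        pos = (pd.DataFrame(scores)[a] > 0) & (pd.DataFrame(scores)[b] > 0)
        dual = (
            pd.DataFrame({"genotype": meta["genotype"].to_numpy(),
                          "dual_positive": pos.to_numpy()})
            .groupby("genotype", observed=True)["dual_positive"]
            .mean()
            .rename("dual_positive_fraction")
            .reset_index()
        )
    return table, dual
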