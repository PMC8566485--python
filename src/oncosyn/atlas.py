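"""Wild-type reference atlas: normalize, embed, cluster, merge, annotate.

The reference is learned from wild-type cells only, pooled across time
points: log-normalized expression, highly variable gene selection by
binned mean-standardized dispersion, per-gene z-scoring (the scaler is
frozen for later projection of mutant cells), PCA to the top 50
components, a k-nearest-neighbor graph in PC space, and Louvain
community detection.  Fine-grained clusters are merged into populations
by average-linkage agglomeration on (1 - Pearson correlation) of the
cluster mean profiles, restricted to cluster pairs adjacent in the
cluster-level kNN graph, and populations are annotated by marker-set
z-scores.
"""
from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .iodata import CellMatrix

log = logging.getLogger("oncosyn")


# ----------------------------------------------------------------------
# Normalization and gene selection
# ----------------------------------------------------------------------

def normalize_log(cells, scale: float = 10_000.0) -> sp.csr_matrix:
    """Depth-normalized, log1p-transformed expression (natural log).

    ``x[g, c] = log(1 + scale * count[g, c] / total[c])``.  Accepts a
    :class:`CellMatrix` or a raw sparse genes x cells matrix; returns a
    sparse genes x cells matrix.  Cells with zero total counts must have
    been removed beforehand.
    """
    counts = cells.counts if isinstance(cells, CellMatrix) else sp.csr_matrix(cells)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        raise ValueError("zero-total cell in normalize_log; run QC first")
    norm = counts.astype(np.float64).tocsc(copy=True)
    norm.data *= np.repeat(scale / totals, np.diff(norm.indptr))
    norm.data = np.log1p(norm.data)
    return norm.tocsr()


def _row_mean_var(m: sp.spmatrix) -> tuple[np.ndarray, np.ndarray]:
    m = sp.csr_matrix(m)
    n = m.shape[1]
    mean = np.asarray(m.mean(axis=1)).ravel()
    sq = m.copy()
    sq.data **= 2
    var = np.asarray(sq.mean(axis=1)).ravel() - mean**2
    return mean, np.maximum(var, 0.0) * n / max(n - 1, 1)


def select_hvg(
    norm: sp.spmatrix, gene_ids, n_hvg: int = 2000, n_bins: int = 20
) -> np.ndarray:
    """Top highly variable genes by binned, mean-standardized dispersion.

    Genes are ranked by the z-score of their dispersion (variance/mean of
    log-normalized expression) within 20 equal-count bins of the mean,
    which removes the mean-dispersion trend; the top ``n_hvg`` gene ids
    are returned.  All-constant input is an error; if fewer than
    ``n_hvg`` genes have nonzero variance, all of those are returned.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    mean, var = _row_mean_var(norm)
    nonconst = var > 1e-12 * np.maximum(mean**2, 1.0)
    if not nonconst.any():
        raise ValueError("all genes constant; cannot select HVGs")
    if nonconst.sum() < n_hvg:
        log.warning("only %d non-constant genes (< n_hvg=%d); returning all",
                    nonconst.sum(), n_hvg)
    disp = np.zeros_like(var)
    disp[nonconst] = var[nonconst] / np.maximum(mean[nonconst], 1e-12)
    idx = np.flatnonzero(nonconst)
    order = np.argsort(mean[idx], kind="stable")
    z = np.full(len(gene_ids), -np.inf)
    bins = np.array_split(idx[order], min(n_bins, len(idx)))
    for b in bins:
        d = disp[b]
        sd = d.std()
        z[b] = (d - d.mean()) / sd if sd > 0 else 0.0
    top = np.argsort(-z, kind="stable")[: min(n_hvg, int(nonconst.sum()))]
    return gene_ids[np.sort(top)]


# ----------------------------------------------------------------------
# Reference model
# ----------------------------------------------------------------------

@dataclass
class ReferenceModel:
    """Frozen wild-type reference for projection and annotation.

    Stores everything needed to place a new cell in the reference space
    without refitting: the HVG list, the per-gene z-score means/SDs on
    HVGs, the PC loading matrix, the reference embeddings, and per-cell
    cluster / population / state labels.
    """

    hvg: np.ndarray
    zscore_mean: np.ndarray
    zscore_sd: np.ndarray
    pc_loadings: np.ndarray  # (n_pcs, n_hvg)
    embeddings: np.ndarray  # (n_cells, n_pcs)
    cell_ids: np.ndarray
    cluster: np.ndarray  # per-cell fine cluster id
    population: np.ndarray  # per-cell merged population id
    state_label: np.ndarray  # per-cell annotation (after annotate())
    cluster_means: pd.DataFrame  # clusters x genes mean log-normalized profile
    cluster_corr: np.ndarray
    knn_edges: np.ndarray  # (n_edges, 2) cell-level kNN graph
    gene_ids: np.ndarray
    scale: float = 10_000.0
    population_labels: dict = field(default_factory=dict)

    def validate(self) -> None:
        gram = self.pc_loadings @ self.pc_loadings.T
        if not np.allclose(gram, np.eye(len(gram)), atol=1e-6):
            raise ValueError("PC basis not orthonormal")
        if len(np.unique(self.population)) > len(np.unique(self.cluster)):
            raise ValueError("more populations than clusters")

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            path / "arrays.npz",
            hvg=self.hvg.astype(str),
            zscore_mean=self.zscore_mean,
            zscore_sd=self.zscore_sd,
            pc_loadings=self.pc_loadings,
            embeddings=self.embeddings,
            cell_ids=self.cell_ids.astype(str),
            cluster=self.cluster,
            population=self.population,
            state_label=self.state_label.astype(str),
            cluster_corr=self.cluster_corr,
            knn_edges=self.knn_edges,
            gene_ids=self.gene_ids.astype(str),
        )
        self.cluster_means.to_csv(path / "cluster_means.tsv", sep="\t")
        (path / "meta.json").write_text(
            json.dumps({"scale": self.scale,
                        "population_labels": {str(k): v for k, v in
                                              self.population_labels.items()}})
        )

    @classmethod
    def load(cls, path) -> "ReferenceModel":
        path = Path(path)
        z = np.load(path / "arrays.npz", allow_pickle=False)
        meta = json.loads((path / "meta.json").read_text())
        return cls(
            hvg=z["hvg"].astype(object),
            zscore_mean=z["zscore_mean"],
            zscore_sd=z["zscore_sd"],
            pc_loadings=z["pc_loadings"],
            embeddings=z["embeddings"],
            cell_ids=z["cell_ids"].astype(object),
            cluster=z["cluster"],
            population=z["population"],
            state_label=z["state_label"].astype(object),
            cluster_means=pd.read_csv(path / "cluster_means.tsv", sep="\t",
                                      index_col=0),
            cluster_corr=z["cluster_corr"],
            knn_edges=z["knn_edges"],
            gene_ids=z["gene_ids"].astype(object),
            scale=meta["scale"],
            population_labels={int(k): v for k, v in
                               meta["population_labels"].items()},
        )


def fit_reference(
    wt_cells: CellMatrix,
    n_pcs: int = 50,
    resolution: float = 1.0,
    k: int = 15,
    n_hvg: int = 2000,
    scale: float = 10_000.0,
    seed: int = 0,
) -> ReferenceModel:
    """Build the wild-type reference embedding and Louvain clustering."""
    norm = normalize_log(wt_cells, scale)
    hvg = select_hvg(norm, wt_cells.gene_ids, n_hvg=n_hvg)
    hidx = wt_cells.gene_index(hvg)
    X = np.asarray(norm[hidx].T.todense())  # cells x hvg
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        log.info("dropping %d zero-variance HVGs from z-scoring", (~keep).sum())
        hvg, hidx, X, mu, sd = hvg[keep], hidx[keep], X[:, keep], mu[keep], sd[keep]
    Xz = (X - mu) / sd

    n_pcs_eff = min(n_pcs, Xz.shape[0] - 1, Xz.shape[1])
    if n_pcs_eff < n_pcs:
        log.warning("reducing n_pcs from %d to %d", n_pcs, n_pcs_eff)
    pca = PCA(n_components=n_pcs_eff, svd_solver="full")
    emb = pca.fit_transform(Xz)

    edges = _knn_edges(emb, k)
    graph = ig.Graph(n=len(emb), edges=[tuple(e) for e in edges], directed=False)
    random.seed(seed)  # igraph's Louvain draws node orders from python's RNG
    part = graph.community_multilevel(resolution=resolution)
    cluster = np.asarray(part.membership)

    cluster_means, corr = _cluster_profiles(norm, wt_cells.gene_ids, cluster)
    model = ReferenceModel(
        hvg=hvg,
        zscore_mean=mu,
        zscore_sd=sd,
        pc_loadings=pca.components_,
        embeddings=emb,
        cell_ids=wt_cells.cell_ids,
        cluster=cluster,
        population=cluster.copy(),
        state_label=np.array([str(c) for c in cluster], dtype=object),
        cluster_means=cluster_means,
        cluster_corr=corr,
        knn_edges=edges,
        gene_ids=wt_cells.gene_ids,
        scale=scale,
    )
    model.validate()
    return model


def _knn_edges(emb: np.ndarray, k: int) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(emb))).fit(emb)
    _, idx = nn.kneighbors(emb)
    src = np.repeat(np.arange(len(emb)), idx.shape[1] - 1)
    dst = idx[:, 1:].ravel()
    pairs = np.sort(np.stack([src, dst], axis=1), axis=1)
    return np.unique(pairs, axis=0)


def _cluster_profiles(norm, gene_ids, cluster):
    """Cluster-mean log-normalized profiles and their Pearson correlations.

    Correlations are computed on gene-standardized profiles (each gene
    centered/scaled across clusters) so that ubiquitously expressed
    genes do not dominate the similarity structure.
    """
    ids = np.unique(cluster)
    means = np.zeros((len(ids), norm.shape[0]))
    for i, c in enumerate(ids):
        means[i] = np.asarray(norm[:, cluster == c].mean(axis=1)).ravel()
    df = pd.DataFrame(means, index=[str(c) for c in ids], columns=list(gene_ids))
    corr = (
        np.corrcoef(_standardize_profiles(means)) if len(ids) > 1 else np.ones((1, 1))
    )
    return df, corr


def _standardize_profiles(means: np.ndarray, basis: np.ndarray | None = None):
    """Standardize profile genes using the (fixed) basis profiles' moments."""
    b = means if basis is None else basis
    mu, sd = b.mean(axis=0), b.std(axis=0)
    keep = sd > 0
    return (np.atleast_2d(means)[:, keep] - mu[keep]) / sd[keep]


# ----------------------------------------------------------------------
# Cluster merging and annotation
# ----------------------------------------------------------------------

def merge_clusters(
    model: ReferenceModel,
    corr_threshold: float = 0.6,
    min_edge_frac: float = 0.01,
) -> ReferenceModel:
    """Merge fine clusters into populations.

    Average-linkage agglomeration with distance (1 - Pearson correlation
    of cluster mean profiles); a merge is admissible only for cluster
    pairs adjacent in the cluster-level graph (at least ``min_edge_frac``
    of the possible inter-cluster kNN edges present), and proceeds while
    the closest admissible pair correlates above ``corr_threshold``.
    """
    if not (-1.0 < corr_threshold < 1.0):
        raise ValueError("corr_threshold must lie in (-1, 1)")
    ids = list(np.unique(model.cluster))
    sizes = {c: int((model.cluster == c).sum()) for c in ids}
    # inter-cluster kNN edge counts
    e_counts: dict[tuple, int] = {}
    cl = model.cluster
    for a, b in model.knn_edges:
        ca, cb = cl[a], cl[b]
        if ca != cb:
            key = tuple(sorted((ca, cb)))
            e_counts[key] = e_counts.get(key, 0) + 1

    profiles = {c: model.cluster_means.loc[str(c)].to_numpy() for c in ids}
    basis = np.vstack([profiles[c] for c in ids])
    groups = {c: {c} for c in ids}

    def corr_of(a, b):
        pa = np.average([profiles[x] for x in groups[a]], axis=0,
                        weights=[sizes[x] for x in groups[a]])
        pb = np.average([profiles[x] for x in groups[b]], axis=0,
                        weights=[sizes[x] for x in groups[b]])
        za, zb = _standardize_profiles(np.vstack([pa, pb]), basis=basis)
        return float(np.corrcoef(za, zb)[0, 1])

    # "possible" inter-cluster edges: the smaller side's kNN slots
    mean_degree = 2.0 * len(model.knn_edges) / max(len(model.cluster), 1)

    def adjacent(a, b):
        edges = sum(
            e_counts.get(tuple(sorted((x, y))), 0)
            for x in groups[a]
            for y in groups[b]
        )
        na = sum(sizes[x] for x in groups[a])
        nb = sum(sizes[y] for y in groups[b])
        possible = mean_degree * min(na, nb)
        return edges > 0 and edges >= min_edge_frac * possible

    while len(groups) > 1:
        best, best_corr = None, corr_threshold
        keys = sorted(groups)
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                if not adjacent(a, b):
                    continue
                r = corr_of(a, b)
                if r > best_corr:
                    best, best_corr = (a, b), r
        if best is None:
            break
        a, b = best
        groups[a] |= groups.pop(b)

    pop_of_cluster = {}
    for pid, (_, members) in enumerate(sorted(groups.items())):
        for c in members:
            pop_of_cluster[c] = pid
    population = np.array([pop_of_cluster[c] for c in model.cluster])
    model.population = population
    model.state_label = np.array([str(p) for p in population], dtype=object)
    model.population_labels = {}
    return model


def annotate(
    model: ReferenceModel,
    markers: dict[str, list[str]],
    norm: sp.spmatrix,
) -> ReferenceModel:
    """Assign marker-based labels to merged populations.

    Each candidate label is scored per population by the mean z-scored
    expression of its marker genes over the population's cells; the
    argmax label wins.  Marker genes absent from the matrix are logged
    and ignored (a label with no present markers scores -inf and is
    never assigned).  When one label wins several populations they are
    distinguished by "-early"/"-late" suffixes ordered by distance from
    the root-most population.
    """
    if not markers:
        raise ValueError("empty marker set")
    gene_pos = pd.Index(model.gene_ids)
    mean, var = _row_mean_var(norm)
    sd = np.sqrt(var)

    pops = np.unique(model.population)
    scores = pd.DataFrame(index=pops, columns=list(markers), dtype=float)
    for label, genes in markers.items():
        idx = gene_pos.get_indexer(genes)
        missing = [g for g, i in zip(genes, idx) if i < 0]
        if missing:
            log.info("label %r: %d marker genes absent, ignored", label, len(missing))
        idx = idx[idx >= 0]
        idx = idx[sd[idx] > 0]
        if len(idx) == 0:
            scores[label] = -np.inf
            continue
        sub = np.asarray(norm[idx].todense())
        z = (sub - mean[idx, None]) / sd[idx, None]
        for p in pops:
            scores.loc[p, label] = z[:, model.population == p].mean()

    assigned = {int(p): str(scores.loc[p].idxmax()) for p in pops}
    # disambiguate duplicated labels by distance from the root-most population
    by_label: dict[str, list[int]] = {}
    for p, lab in assigned.items():
        by_label.setdefault(lab, []).append(p)
    centroids = {
        int(p): model.embeddings[model.population == p].mean(axis=0) for p in pops
    }
    root_pop = min(assigned, key=lambda p: _maturation_rank(assigned[p]))
    for lab, ps in by_label.items():
        if len(ps) == 1:
            continue
        ps = sorted(
            ps, key=lambda p: np.linalg.norm(centroids[p] - centroids[root_pop])
        )
        suffixes = (
            ["-early", "-late"] if len(ps) == 2 else [f"-{i+1}" for i in range(len(ps))]
        )
        for p, suf in zip(ps, suffixes):
            assigned[p] = lab + suf
    model.population_labels = assigned
    model.state_label = np.array(
        [assigned[int(p)] for p in model.population], dtype=object
    )
    return model


def _maturation_rank(label: str) -> int:
    # HSC/MPP-like labels sort first so duplicates order away from the root
    return 0 if "HSC" in label or "MPP" in label else 1
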