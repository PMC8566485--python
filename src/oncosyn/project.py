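"""Label transfer of mutant cells into the frozen wild-type PC space.

Mutant cells never refit anything: they are log-normalized, restricted
to the reference highly variable genes, z-scored with the *reference*
means and SDs, rotated by the reference PC loadings, and each cell
copies the state label of its single nearest reference cell (Euclidean
distance).  Distance ties break to the lowest reference-cell index.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import pairwise_distances_argmin_min

from .atlas import ReferenceModel, normalize_log
from .iodata import CellMatrix

log = logging.getLogger("oncosyn")


@dataclass
class ProjectionResult:
    """Per-cell embedding, nearest reference neighbor, and transferred label."""

    embeddings: np.ndarray  # (n_cells, n_pcs)
    assignments: pd.DataFrame  # index cell_id: nearest_ref, distance, state_label

    def labels(self) -> pd.Series:
        return self.assignments["state_label"]


def embed_cells(cells: CellMatrix, model: ReferenceModel) -> np.ndarray:
    """Place cells into the reference PC space without label transfer."""
    present = pd.Index(cells.gene_ids).get_indexer(model.hvg)
    frac = (present >= 0).mean()
    if frac < 0.5:
        raise ValueError(
            f"only {frac:.0%} of reference HVGs present; gene namespace mismatch"
        )
    if frac < 1.0:
        log.info("%d reference HVGs absent; treated as zero after z-scoring",
                 int((present < 0).sum()))
    norm = normalize_log(cells, model.scale)
    n_hvg = len(model.hvg)
    X = np.zeros((cells.n_cells, n_hvg))
    have = present >= 0
    X[:, have] = np.asarray(norm[present[have]].T.todense())
    Xz = np.zeros_like(X)
    Xz[:, have] = (X[:, have] - model.zscore_mean[have]) / model.zscore_sd[have]
    # absent genes contribute their standardized zero:
    Xz[:, ~have] = (0.0 - model.zscore_mean[~have]) / model.zscore_sd[~have]
    return Xz @ model.pc_loadings.T


def project_cells(mutant: CellMatrix, model: ReferenceModel, k: int = 1) -> ProjectionResult:
    """Transfer reference state labels to mutant cells by nearest neighbor.

    ``k=1`` (the default) copies the closest reference cell's label;
    ``k>1`` takes a majority vote among the k closest (ties to the
    closest member).
    """
    emb = embed_cells(mutant, model)
    if k == 1:
        nearest, dist = pairwise_distances_argmin_min(emb, model.embeddings)
        labels = model.state_label[nearest]
    else:
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=k).fit(model.embeddings)
        dists, idx = nn.kneighbors(emb)
        nearest, dist = idx[:, 0], dists[:, 0]
        labels = np.array(
            [pd.Series(model.state_label[row]).mode().iloc[0] for row in idx],
            dtype=object,
        )
    assignments = pd.DataFrame(
        {
            "nearest_ref": model.cell_ids[nearest],
            "distance": dist,
            "state_label": labels,
        },
        index=pd.Index(mutant.cell_ids),
    )
    return ProjectionResult(embeddings=emb, assignments=assignments)


def state_frequencies(
    labels: pd.Series,
    meta: pd.DataFrame,
    groupings: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per (genotype, timepoint) state-frequency table with derived ratios.

    ``labels`` is a per-cell state series aligned with ``meta`` (which
    carries ``genotype`` and ``timepoint``).  ``groupings`` names state
    groups used for ratio columns; the defaults give the
    myeloid/erythroid and megakaryocyte/erythroid ratios.
    """
    if groupings is None:
        groupings = {
            "myeloid": ["GMP", "ProMo", "GN-early", "GN-late"],
            "erythroid": ["EryP", "Ery-early", "Ery-late"],
            "meg": ["Meg"],
        }
    df = meta[["genotype", "timepoint"]].copy()
    df["state"] = pd.Series(labels).to_numpy()
    rows = []
    for (g, t), grp in df.groupby(["genotype", "timepoint"], observed=True):
        if len(grp) == 0:
            raise ValueError(f"empty group {g}:{t}")
        freq = grp["state"].value_counts(normalize=True)
        rec = {"genotype": g, "timepoint": t, "n_cells": len(grp)}
        rec.update({f"freq:{s}": f for s, f in freq.items()})
        my = freq.reindex(groupings["myeloid"]).fillna(0).sum()
        er = freq.reindex(groupings["erythroid"]).fillna(0).sum()
        mg = freq.reindex(groupings["meg"]).fillna(0).sum()
        rec["myeloid_erythroid_ratio"] = my / er if er > 0 else np.inf
        rec["meg_ery_ratio"] = mg / er if er > 0 else np.inf
        rows.append(rec)
    out = pd.DataFrame(rows).fillna(0.0)
    return out
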