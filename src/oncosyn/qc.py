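"""Cell-level quality control: mitochondrial filtering and doublet scoring.

Stressed or dying cells are removed when more than a configurable share
(default 10%) of their transcripts come from mitochondrial genes; the
boundary is strict, so a cell at exactly the threshold is retained.
Putative doublets are flagged by the simulated-doublet strategy: sum the
counts of random cell pairs, co-embed observed and artificial doublets,
and score each observed cell by the doublet composition of its
neighborhood.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .atlas import normalize_log
from .iodata import CellMatrix

log = logging.getLogger("oncosyn")


@dataclass
class QCReport:
    """Per-cell QC metrics and pass/fail flags plus per-sample summaries."""

    per_cell: pd.DataFrame  # index cell_id: mito_fraction / doublet_score / flags
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)
    threshold: float | None = None


def mito_filter(
    cells: CellMatrix, threshold: float = 0.10, mito_prefix: str = "mt-"
) -> tuple[CellMatrix, QCReport]:
    """Drop cells whose mitochondrial transcript share exceeds ``threshold``.

    The fraction is mito counts / total counts per cell; cells with zero
    total counts are undefined and removed (reported separately).  With
    no mitochondrial genes in the matrix the filter is a no-op.
    """
    mito = cells.mito_genes(mito_prefix)
    totals = cells.totals()
    zero = totals == 0
    if mito.any():
        mito_counts = np.asarray(cells.counts[mito].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(zero, np.nan, mito_counts / np.where(zero, 1, totals))
        pass_mito = ~zero & ~(frac > threshold)
    else:
        log.warning("no mitochondrial genes matched prefix %r; mito filter is a no-op",
                    mito_prefix)
        frac = np.where(zero, np.nan, 0.0)
        pass_mito = ~zero
    per_cell = pd.DataFrame(
        {
            "mito_fraction": frac,
            "pass_mito": pass_mito,
            "zero_count": zero,
        },
        index=pd.Index(cells.cell_ids),
    )
    kept = cells.subset_cells(pass_mito)
    summary = (
        per_cell.join(cells.cell_meta[["genotype", "timepoint"]])
        .groupby(["genotype", "timepoint"], observed=True)
        .agg(n_before=("pass_mito", "size"), n_after=("pass_mito", "sum"),
             n_zero=("zero_count", "sum"))
        .reset_index()
    )
    return kept, QCReport(per_cell=per_cell, summary=summary, threshold=threshold)


def score_doublets(
    cells: CellMatrix,
    n_sim_frac: float = 1.0,
    k: int = 30,
    n_pcs: int = 30,
    seed: int = 0,
    fallback_threshold: float = 0.25,
) -> QCReport:
    """Score each cell's likelihood of being a doublet.

    ``ceil(n_sim_frac * n_cells)`` artificial doublets are synthesized by
    summing the counts of uniformly sampled cell pairs; observed and
    simulated cells are co-embedded (log-normalization, PCA fitted on the
    observed cells); each cell's score is ``rho / (1 + rho)`` where
    ``rho`` is the odds of simulated-doublet membership among its ``k``
    nearest co-embedded neighbors, rescaled by the simulation ratio.
    Cells above a threshold chosen at the minimum-density valley of the
    simulated-score histogram (fallback: ``fallback_threshold``) are
    flagged.  Intended to run per sample.
    """
    n = cells.n_cells
    n_sim = int(np.ceil(n_sim_frac * n))
    if n_sim < 1:
        raise ValueError("no simulated doublets (n_sim_frac too small)")
    if n < 100:
        log.warning("doublet scoring on %d cells (< 100); scores may be unstable", n)
    if k >= n:
        log.warning("k=%d >= n_cells=%d; reducing", k, n)
        k = n - 1
    rng = np.random.default_rng(seed)
    pairs = rng.integers(0, n, size=(n_sim, 2))
    sim_counts = cells.counts[:, pairs[:, 0]] + cells.counts[:, pairs[:, 1]]

    X_obs = _embed_counts(cells.counts)
    X_sim = _embed_counts(sim_counts)
    n_pcs = min(n_pcs, X_obs.shape[1], n - 1)
    pca = PCA(n_components=n_pcs, svd_solver="randomized", random_state=seed)
    E_obs = pca.fit_transform(X_obs)
    E_sim = pca.transform(X_sim)
    E = np.vstack([E_obs, E_sim])
    is_sim = np.zeros(len(E), bool)
    is_sim[n:] = True

    nn = NearestNeighbors(n_neighbors=k + 1).fit(E)
    _, idx = nn.kneighbors(E)
    idx = idx[:, 1:]  # drop self
    f = is_sim[idx].mean(axis=1)
    ratio = n / n_sim  # rescale neighbor odds by the simulation ratio
    with np.errstate(divide="ignore"):
        rho = np.where(f < 1.0, f / (1.0 - f), np.inf) * ratio
    score = np.ones_like(rho)
    finite = np.isfinite(rho)
    score[finite] = rho[finite] / (1.0 + rho[finite])
    obs_score, sim_score = score[:n], score[n:]

    threshold = _valley_threshold(sim_score)
    if threshold is None:
        threshold = fallback_threshold
    per_cell = pd.DataFrame(
        {
            "doublet_score": obs_score,
            "pass_doublet": obs_score <= threshold,
        },
        index=pd.Index(cells.cell_ids),
    )
    summary = pd.DataFrame(
        {
            "n_cells": [n],
            "n_sim": [n_sim],
            "n_flagged": [int((obs_score > threshold).sum())],
            "threshold": [threshold],
        }
    )
    return QCReport(per_cell=per_cell, summary=summary, threshold=threshold)


def _embed_counts(counts) -> np.ndarray:
    norm = normalize_log(_as_cm_counts(counts))
    return np.asarray(norm.T.todense())


def _as_cm_counts(counts):
    # normalize_log operates on a raw sparse matrix when given one
    return counts


def _valley_threshold(sim_scores: np.ndarray, bins: int = 50) -> float | None:
    """Minimum-density valley between the two main modes of the simulated scores.

    Returns None when the histogram has no interior valley (degenerate
    geometry, e.g. all cells identical).
    """
    if np.ptp(sim_scores) < 1e-12:
        return None
    hist, edges = np.histogram(sim_scores, bins=bins)
    peak_hi = int(np.argmax(hist))
    # main low-score peak left of the global one, if any
    left = hist[:peak_hi]
    if len(left) == 0 or left.max() == 0:
        return None
    peak_lo = int(np.argmax(left))
    if peak_hi - peak_lo < 2:
        return None
    valley = peak_lo + 1 + int(np.argmin(hist[peak_lo + 1:peak_hi]))
    return float(0.5 * (edges[valley] + edges[valley + 1]))
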