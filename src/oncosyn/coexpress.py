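"""Depth-matched co-expression fractions for gene pairs.

The fraction of cells expressing both genes of a pair is compared
across genotypes after downsampling each group to a common number of
cells, which removes cell-number artifacts; iteration means +- SD and
two-sided t-tests across iterations reproduce the figure-legend
statistic (a permutation alternative is provided, and preferred, since
downsampling iterations overlap and the t-test is anti-conservative).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .iodata import CellMatrix

log = logging.getLogger("oncosyn")


@dataclass
class CoexpressionResult:
    gene1: str
    gene2: str
    per_group: pd.DataFrame  # group, n_cells, fraction_full, mean, sd
    iterations: pd.DataFrame  # group x iteration fractions (long)
    tests: pd.DataFrame  # pairwise group comparisons
    expression: pd.DataFrame  # per-gene expression among expressing cells


def coexpression_fraction(
    cells: CellMatrix,
    gene1: str,
    gene2: str,
    expr_threshold: float = 0,
    n_cells: int = 1000,
    n_iter: int = 10,
    seed: int = 0,
    group_by: str = "genotype",
    timepoint: str | None = None,
    test: str = "ttest",
) -> CoexpressionResult:
    """Fraction of cells with both genes above ``expr_threshold`` counts.

    Per group (default: genotype, optionally restricted to one time
    point): the full-sample fraction, plus the mean +- SD over
    ``n_iter`` downsampling iterations of ``n_cells`` cells drawn
    without replacement.  Groups smaller than ``n_cells`` use all cells
    (warned; their SD is undefined).  ``test="permutation"`` replaces
    the cross-iteration t-test with a label-permutation test on the
    full-sample fractions.
    """
    gidx = cells.gene_index([gene1, gene2])
    x1 = np.asarray(cells.counts[gidx[0]].todense()).ravel()
    x2 = np.asarray(cells.counts[gidx[1]].todense()).ravel()
    e1, e2 = x1 > expr_threshold, x2 > expr_threshold
    co = e1 & e2

    meta = cells.cell_meta
    mask = np.ones(cells.n_cells, bool)
    if timepoint is not None:
        mask &= (meta["timepoint"].to_numpy() == timepoint)
    groups = meta[group_by].to_numpy()
    rng = np.random.default_rng(seed)

    rows, iters, expr_rows = [], [], []
    for g in pd.unique(groups[mask]):
        m = np.flatnonzero(mask & (groups == g))
        full = co[m].mean()
        fracs = []
        if len(m) >= n_cells:
            for it in range(n_iter):
                samp = rng.choice(m, size=n_cells, replace=False)
                fracs.append(co[samp].mean())
        else:
            log.warning("group %s has %d cells (< %d); downsampling skipped",
                        g, len(m), n_cells)
            fracs = [full]
        for it, f in enumerate(fracs):
            iters.append({"group": g, "iteration": it, "fraction": f})
        rows.append(
            {
                "group": g,
                "n_cells": len(m),
                "fraction_full": full,
                "mean": float(np.mean(fracs)),
                "sd": float(np.std(fracs, ddof=1)) if len(fracs) > 1 else np.nan,
            }
        )
        for gene, e, x in ((gene1, e1, x1), (gene2, e2, x2)):
            vals = x[m][e[m]]
            expr_rows.append(
                {
                    "group": g,
                    "gene": gene,
                    "n_expressing": int(e[m].sum()),
                    "mean_expr": float(vals.mean()) if len(vals) else np.nan,
                    "median_expr": float(np.median(vals)) if len(vals) else np.nan,
                }
            )

    it_df = pd.DataFrame(iters)
    tests = []
    for ga, gb in combinations([r["group"] for r in rows], 2):
        fa = it_df.loc[it_df["group"] == ga, "fraction"].to_numpy()
        fb = it_df.loc[it_df["group"] == gb, "fraction"].to_numpy()
        if test == "permutation":
            p = _permutation_pvalue(
                co[mask & (groups == ga)], co[mask & (groups == gb)], rng
            )
        else:
            p = float(ttest_ind(fa, fb).pvalue) if min(len(fa), len(fb)) > 1 else np.nan
        tests.append({"group1": ga, "group2": gb, "pvalue": p})

    return CoexpressionResult(
        gene1=gene1,
        gene2=gene2,
        per_group=pd.DataFrame(rows),
        iterations=it_df,
        tests=pd.DataFrame(tests),
        expression=pd.DataFrame(expr_rows),
    )


def _permutation_pvalue(a: np.ndarray, b: np.ndarray, rng, n_perm: int = 2000):
    """Two-sided permutation test for a difference of two proportions."""
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    na = len(a)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if abs(pooled[:na].mean() - pooled[na:].mean()) >= obs - 1e-15:
            hits += 1
    return (hits + 1) / (n_perm + 1)
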