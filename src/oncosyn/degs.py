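"""Within-state versus between-state differential expression.

The presence of a *new* cellular state in a mutant genotype would make
mutant cells differ from their matched wild-type state about as much as
distinct wild-type states differ from each other.  The test therefore
contrasts two classes of comparisons: "within state" (same transferred
state label, wild type versus a mutant genotype) and "between states"
(two state labels within one genotype).  Differential genes come from a
two-sided Wilcoxon rank-sum (Mann-Whitney U) test per gene with
Benjamini-Hochberg correction; a gene is significant below an adjusted
p of 0.01.
"""
from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("oncosyn")


def wilcoxon_de(
    group1: sp.spmatrix | np.ndarray,
    group2: sp.spmatrix | np.ndarray,
    gene_ids,
    min_cells: int = 20,
    detect_cells: int = 3,
    alpha: float = 0.01,
) -> pd.DataFrame | None:
    """Per-gene two-sided Mann-Whitney U on log-normalized expression.

    Inputs are genes x cells matrices of the two groups.  Genes are
    restricted to those detected in more than ``detect_cells`` cells of
    the pooled groups.  For group sizes both <= 8 the exact null
    distribution is used; otherwise the normal approximation with tie
    correction and continuity correction.  Returns None (and logs) when
    either group is smaller than ``min_cells``.  Log fold change is the
    difference of group means of log-normalized expression.
    """
    X1 = _dense(group1)
    X2 = _dense(group2)
    n1, n2 = X1.shape[1], X2.shape[1]
    if n1 < min_cells or n2 < min_cells:
        log.info("comparison skipped: group sizes %d/%d below min_cells=%d",
                 n1, n2, min_cells)
        return None
    gene_ids = np.asarray(gene_ids, dtype=object)
    detected = ((X1 > 0).sum(axis=1) + (X2 > 0).sum(axis=1)) > detect_cells
    if not detected.any():
        return _empty_table()
    x1, x2 = X1[detected], X2[detected]
    method = "exact" if (n1 <= 8 and n2 <= 8) else "asymptotic"
    if method == "exact":
        stats = np.empty(x1.shape[0])
        ps = np.empty(x1.shape[0])
        for i in range(x1.shape[0]):
            ties = len(np.unique(np.concatenate([x1[i], x2[i]]))) < n1 + n2
            r = mannwhitneyu(
                x1[i], x2[i], alternative="two-sided",
                method="asymptotic" if ties else "exact",
            )
            stats[i], ps[i] = r.statistic, r.pvalue
    else:
        r = mannwhitneyu(x1, x2, alternative="two-sided", axis=1,
                         method="asymptotic")
        stats, ps = r.statistic, r.pvalue
    ps = np.clip(ps, 0.0, 1.0)
    _, adj, _, _ = multipletests(ps, method="fdr_bh")
    lfc = x1.mean(axis=1) - x2.mean(axis=1)
    return pd.DataFrame(
        {
            "gene": gene_ids[detected],
            "log_fc": lfc,
            "statistic": stats,
            "pvalue": ps,
            "adj_pvalue": adj,
            "significant": adj < alpha,
        }
    )


def _dense(x):
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x, float)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["gene", "log_fc", "statistic", "pvalue", "adj_pvalue",
                 "significant"]
    )


def within_between_analysis(
    norm: sp.spmatrix,
    meta: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    gene_ids=None,
    timepoints: list[str] | None = None,
    genotypes: list[str] | None = None,
    reference_genotype: str = "WT",
    pool_timepoints: bool = False,
    min_cells: int = 20,
    alpha: float = 0.01,
    between_mode: str = "pairwise",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All within-state and between-state comparisons plus a count summary.

    Within state: per state, the reference genotype versus each mutant
    genotype at a matched time point.  Between states: all unordered
    state pairs within each genotype ("pairwise"; ``between_mode="rest"``
    compares each state against all remaining cells instead).  Returns
    the long table of DEG rows and a per-comparison summary of counts;
    skipped comparisons (too few cells) appear in the summary with
    ``n_deg = -1``.
    """
    labels = np.asarray(pd.Series(labels))
    if gene_ids is None:
        gene_ids = np.arange(norm.shape[0]).astype(str).astype(object)
    gene_ids = np.asarray(gene_ids, dtype=object)
    meta = meta.reset_index(drop=True)
    geno = meta["genotype"].to_numpy()
    tp = meta["timepoint"].to_numpy()
    if timepoints is None:
        timepoints = ["all"] if pool_timepoints else sorted(set(tp))
    if genotypes is None:
        genotypes = sorted(set(geno))
    states = sorted(set(labels))

    deg_rows, summary = [], []

    def run(mask1, mask2, **tags):
        t = wilcoxon_de(norm[:, np.flatnonzero(mask1)],
                        norm[:, np.flatnonzero(mask2)],
                        gene_ids, min_cells=min_cells, alpha=alpha)
        if t is None:
            summary.append({**tags, "n_deg": -1, "skipped": True})
            return
        n = int(t["significant"].sum())
        summary.append({**tags, "n_deg": n, "skipped": False})
        t = t.assign(**tags)
        deg_rows.append(t[t["significant"]])

    for t_ in timepoints:
        tmask = np.ones(len(meta), bool) if t_ == "all" else (tp == t_)
        for s in states:
            smask = labels == s
            ref = tmask & smask & (geno == reference_genotype)
            for g in genotypes:
                if g == reference_genotype:
                    continue
                run(tmask & smask & (geno == g), ref,
                    comparison="within", timepoint=t_, state=s, genotype=g)
        for g in genotypes:
            gmask = tmask & (geno == g)
            if between_mode == "pairwise":
                for s1, s2 in combinations(states, 2):
                    run(gmask & (labels == s1), gmask & (labels == s2),
                        comparison="between", timepoint=t_,
                        state=f"{s1}|{s2}", genotype=g)
            else:
                for s in states:
                    run(gmask & (labels == s), gmask & (labels != s),
                        comparison="between", timepoint=t_,
                        state=f"{s}|rest", genotype=g)

    degs = (
        pd.concat(deg_rows, ignore_index=True) if deg_rows else _empty_table()
    )
    return degs, pd.DataFrame(summary)
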