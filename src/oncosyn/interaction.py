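"""Per-gene interaction score between two cooperating lesions.

For each gene the observed expression change in the double mutant is
compared with the additive expectation from the two single mutants, all
on the scale of mean log-normalized expression (log1p of
counts-per-10k, the UMI analogue of log-transformed TPM):

    dA    = E[g | A]  - E[g | WT]
    dB    = E[g | B]  - E[g | WT]
    d_obs = E[g | AB] - E[g | WT]
    d_exp = dA + dB
    I     = d_obs - d_exp

``I > 0`` marks synergy, ``I < 0`` antagonism, relative to additivity on
the log scale.  Significance comes from a permutation null: the observed
and expected change vectors are independently shuffled across genes and
their differences pooled; genes with scores beyond the pooled 5th/95th
percentiles are called.  The per-genotype change of a gene set can
further be decomposed exactly into a cell-composition term and a
within-state expression term.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .atlas import normalize_log
from .iodata import CellMatrix

log = logging.getLogger("oncosyn")


@dataclass
class NullModel:
    """Pooled permutation null of interaction scores."""

    n_perm: int
    q05: float
    q95: float
    seed: int
    scheme: str
    pool: np.ndarray  # (n_perm * n_genes,) permuted scores

    def __post_init__(self):
        if self.q05 > self.q95:
            raise ValueError("q05 > q95")


def expression_changes(
    cells: CellMatrix,
    timepoint: str | None = None,
    subset_states: list[str] | None = None,
    state_labels=None,
    detect_cells: int = 3,
    scale: float = 10_000.0,
    norm: sp.spmatrix | None = None,
) -> pd.DataFrame:
    """Per-gene genotype means and observed/expected changes at one time point.

    All four genotypes must be present.  Genes are restricted to those
    detected in more than ``detect_cells`` cells of the pooled subset.
    ``subset_states`` (with per-cell ``state_labels``) restricts the
    computation to labeled states, e.g. the stem-cell compartment.
    """
    mask = np.ones(cells.n_cells, bool)
    if timepoint is not None:
        mask &= (cells.cell_meta["timepoint"].to_numpy() == timepoint)
    if subset_states is not None:
        if state_labels is None:
            raise ValueError("subset_states requires state_labels")
        mask &= np.isin(np.asarray(state_labels, dtype=object), subset_states)
    sub = cells.subset_cells(mask)
    geno = sub.cell_meta["genotype"].to_numpy()
    for g in ("WT", "A", "B", "AB"):
        if not (geno == g).any():
            raise ValueError(f"genotype {g!r} missing"
                             + (f" at {timepoint}" if timepoint else ""))
    x = normalize_log(sub, scale) if norm is None else norm[:, np.flatnonzero(mask)]
    detected = np.asarray((x > 0).sum(axis=1)).ravel() > detect_cells
    x = sp.csr_matrix(x)[detected]
    means = {
        g: np.asarray(x[:, np.flatnonzero(geno == g)].mean(axis=1)).ravel()
        for g in ("WT", "A", "B", "AB")
    }
    tab = pd.DataFrame(
        {
            "gene": np.asarray(cells.gene_ids, dtype=object)[detected],
            "mean_WT": means["WT"],
            "mean_A": means["A"],
            "mean_B": means["B"],
            "mean_AB": means["AB"],
        }
    )
    tab["delta_A"] = tab["mean_A"] - tab["mean_WT"]
    tab["delta_B"] = tab["mean_B"] - tab["mean_WT"]
    tab["delta_obs"] = tab["mean_AB"] - tab["mean_WT"]
    tab["delta_exp"] = tab["delta_A"] + tab["delta_B"]
    tab["score"] = tab["delta_obs"] - tab["delta_exp"]
    return tab


def permutation_null(
    table: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "swap",
) -> NullModel:
    """Permutation null of the interaction score.

    Three shuffling schemes of the observed/expected change vectors are
    supported; all pool the permuted scores and record the 5th/95th
    percentiles.

    ``swap`` (default): per gene, randomly exchange which value is
    "observed" and which "expected", i.e. the null scores are random
    sign flips of the per-gene scores.  Because each gene keeps its own
    pair of values, observed scores and null scores are exchangeable
    under the global null, so the two-sided 5% cut calls 10% of genes
    by construction.

    ``independent``: per permutation, shuffle the gene order of the
    observed vector and of the expected vector independently.
    ``paired``: shuffle only the observed vector against the fixed
    expected vector.  Both gene-pairing schemes break the within-gene
    covariance induced by the shared wild-type and single-mutant means,
    which widens the null; they are retained for sensitivity analyses.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scheme not in ("swap", "independent", "paired"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if len(table) < 100:
        log.warning("permutation null on only %d genes", len(table))
    dobs = table["delta_obs"].to_numpy()
    dexp = table["delta_exp"].to_numpy()
    rng = np.random.default_rng(seed)
    n = len(dobs)
    pool = np.empty(n_perm * n)
    score = dobs - dexp
    for p in range(n_perm):
        if scheme == "swap":
            signs = rng.choice([-1.0, 1.0], size=n)
            pool[p * n:(p + 1) * n] = signs * score
        else:
            po = rng.permutation(n)
            pe = rng.permutation(n) if scheme == "independent" else np.arange(n)
            pool[p * n:(p + 1) * n] = dobs[po] - dexp[pe]
    q05, q95 = np.percentile(pool, [5.0, 95.0])
    return NullModel(n_perm=n_perm, q05=float(q05), q95=float(q95),
                     seed=seed, scheme=scheme, pool=pool)


def exhaustive_null_pool(dobs: np.ndarray, dexp: np.ndarray) -> np.ndarray:
    """Exact pooled null over all gene pairings (enumeration oracle).

    Pooling the score vectors over every permutation weights each
    ordered pairing (i, j) equally, so the exhaustive pool is simply all
    pairwise differences ``dobs[i] - dexp[j]``.
    """
    return np.subtract.outer(np.asarray(dobs), np.asarray(dexp)).ravel()


def call_interactions(table: pd.DataFrame, null: NullModel) -> pd.DataFrame:
    """Attach significance calls and directions to an interaction table.

    synergistic iff score > q95, antagonistic iff score < q05, else
    none; direction is the sign of the observed change.
    """
    out = table.copy()
    out["q05"], out["q95"] = null.q05, null.q95
    out["call"] = np.where(
        out["score"] > null.q95,
        "synergistic",
        np.where(out["score"] < null.q05, "antagonistic", "none"),
    )
    out["direction"] = np.where(out["delta_obs"] >= 0, "up", "down")
    return out


def call_summary(called: pd.DataFrame) -> pd.DataFrame:
    """Fraction of genes per call class (the per-time-point readout)."""
    frac = (
        called["call"].value_counts(normalize=True)
        .reindex(["synergistic", "antagonistic", "none"])
        .fillna(0.0)
    )
    return pd.DataFrame({"call": frac.index, "fraction": frac.to_numpy()})


def geneset_interaction_trajectory(
    cells: CellMatrix,
    gene_set: list[str],
    timepoints=("T1", "T2", "T3"),
    subset_states=None,
    state_labels=None,
    detect_cells: int = 3,
) -> pd.DataFrame:
    """Interaction-score distribution of a gene set at each time point."""
    rows = []
    for t in timepoints:
        tab = expression_changes(
            cells, timepoint=t, subset_states=subset_states,
            state_labels=state_labels, detect_cells=detect_cells,
        )
        sub = tab[tab["gene"].isin(gene_set)]
        if sub.empty:
            raise ValueError(f"gene set empty after detection filter at {t}")
        for _, r in sub.iterrows():
            rows.append({"timepoint": t, "gene": r["gene"], "score": r["score"]})
    out = pd.DataFrame(rows)
    out["median_score"] = out.groupby("timepoint")["score"].transform("median")
    return out


def decompose_change(
    cells: CellMatrix,
    genes: list[str],
    genotype: str,
    state_labels,
    reference_genotype: str = "WT",
    timepoint: str | None = None,
    scale: float = 10_000.0,
) -> pd.DataFrame:
    """Split a genotype's expression change into composition and expression terms.

    With state frequencies ``f_s`` and state-wise mean log-normalized
    expression ``mu_{g,s}``::

        total       = sum_s f_s^m mu_{g,s}^m - sum_s f_s^WT mu_{g,s}^WT
        composition = sum_s (f_s^m - f_s^WT) mu_{g,s}^WT
        expression  = sum_s f_s^m (mu_{g,s}^m - mu_{g,s}^WT)

    and ``composition + expression = total`` exactly.  A state present
    in only one genotype contributes with the other genotype's mean set
    to zero (flagged in the output).
    """
    labels = np.asarray(state_labels, dtype=object)
    mask = np.ones(cells.n_cells, bool)
    if timepoint is not None:
        mask &= (cells.cell_meta["timepoint"].to_numpy() == timepoint)
    geno = cells.cell_meta["genotype"].to_numpy()
    gidx = cells.gene_index(genes)
    norm = normalize_log(cells, scale)[gidx]

    def stats(g):
        m = mask & (geno == g)
        if not m.any():
            raise ValueError(f"no cells for genotype {g!r}")
        lab = labels[m]
        states, counts = np.unique(lab, return_counts=True)
        f = dict(zip(states, counts / counts.sum()))
        mu = {
            s: np.asarray(norm[:, np.flatnonzero(m)[lab == s]].mean(axis=1)).ravel()
            for s in states
        }
        return f, mu

    f_m, mu_m = stats(genotype)
    f_w, mu_w = stats(reference_genotype)
    all_states = sorted(set(f_m) | set(f_w))
    zeros = np.zeros(len(gidx))
    rows = []
    for gi, gname in enumerate(genes):
        comp = expr = total = 0.0
        flagged = []
        for s in all_states:
            fm, fw = f_m.get(s, 0.0), f_w.get(s, 0.0)
            mm = mu_m.get(s, zeros)[gi]
            mw = mu_w.get(s, zeros)[gi]
            if s not in f_m or s not in f_w:
                flagged.append(s)
            comp += (fm - fw) * mw
            expr += fm * (mm - mw)
            total += fm * mm - fw * mw
        rows.append(
            {
                "gene": gname,
                "composition": comp,
                "expression": expr,
                "total": total,
                "one_sided_states": ",".join(flagged),
            }
        )
    return pd.DataFrame(rows)
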