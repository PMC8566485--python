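"""Random-forest screen for stem-cell-restricted, synergistically activated genes.

Cells are samples, genes features, states classes.  A preliminary
forest on all expressed genes ranks genes by impurity importance; the
top 1000 are kept and the classifier refit, with stratified 5-fold
cross-validation reporting accuracy.  The trained forest's class
probability for the stem compartment (HSC/MPP) is then correlated with
each gene's expression across double-mutant cells: genes with high
correlation are stem-restricted, and those that are additionally called
synergistic (interaction module, stem-cell subset) with a positive fold
change are nominated as candidate regulators of leukemia-initiating
cells.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger("oncosyn")


@dataclass
class RFModel:
    forest: RandomForestClassifier
    genes: np.ndarray  # selected feature genes
    classes: np.ndarray
    fold_accuracy: np.ndarray
    mean_accuracy: float
    fold_assignment: np.ndarray = field(repr=False, default=None)

    def predict_proba_frame(self, X: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(self.forest.predict_proba(X), columns=self.classes)


def _dense_cells_by_genes(norm) -> np.ndarray:
    return np.asarray(sp.csr_matrix(norm).T.todense())


def train_rf(
    norm: sp.spmatrix,
    gene_ids,
    labels,
    n_trees: int = 500,
    n_top_genes: int = 1000,
    n_folds: int = 5,
    detect_cells: int = 3,
    min_state_cells: int = 5,
    seed: int = 0,
) -> RFModel:
    """Two-stage random-forest state classifier with cross-validated accuracy.

    ``norm`` is genes x cells log-normalized expression of the labeled
    (reference) cells.  Stage 1 fits on all expressed genes (detected in
    more than ``detect_cells`` cells) and keeps the ``n_top_genes`` most
    important; stage 2 refits on those with stratified k-fold CV, then a
    final refit on all cells.  States with fewer than ``min_state_cells``
    cells are excluded (warned).
    """
    labels = np.asarray(pd.Series(labels), dtype=object)
    counts = pd.Series(labels).value_counts()
    bad = counts[counts < min_state_cells].index
    if len(bad):
        log.warning("excluding states with < %d cells: %s", min_state_cells,
                    list(bad))
    keep_cells = ~np.isin(labels, list(bad))
    norm = sp.csr_matrix(norm)[:, np.flatnonzero(keep_cells)]
    labels = labels[keep_cells]
    if len(pd.unique(labels)) < 2:
        raise ValueError("need at least two states to train")

    gene_ids = np.asarray(gene_ids, dtype=object)
    expressed = np.asarray((norm > 0).sum(axis=1)).ravel() > detect_cells
    X_all = _dense_cells_by_genes(norm[expressed])
    genes_all = gene_ids[expressed]

    stage1 = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    ).fit(X_all, labels)
    order = np.argsort(-stage1.feature_importances_, kind="stable")
    top = np.sort(order[: min(n_top_genes, X_all.shape[1])])
    X = X_all[:, top]
    genes = genes_all[top]

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_acc = []
    fold_assignment = np.full(len(labels), -1)
    for fold, (tr, te) in enumerate(skf.split(X, labels)):
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1
        ).fit(X[tr], labels[tr])
        fold_acc.append(float((clf.predict(X[te]) == labels[te]).mean()))
        fold_assignment[te] = fold
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    ).fit(X, labels)
    return RFModel(
        forest=forest,
        genes=genes,
        classes=forest.classes_,
        fold_accuracy=np.asarray(fold_acc),
        mean_accuracy=float(np.mean(fold_acc)),
        fold_assignment=fold_assignment,
    )


def hscmpp_specificity(
    rf: RFModel,
    norm_target: sp.spmatrix,
    gene_ids,
    hsc_label: str = "HSC/MPP",
) -> pd.Series:
    """Per-gene Pearson correlation with the HSC/MPP class probability.

    Computed across the target cells (typically the double mutant).
    Genes with zero variance get a missing correlation.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    gpos = pd.Index(gene_ids).get_indexer(rf.genes)
    if (gpos < 0).any():
        raise ValueError("target matrix lacks classifier feature genes")
    X_feat = _dense_cells_by_genes(sp.csr_matrix(norm_target)[gpos])
    if hsc_label not in rf.classes:
        raise ValueError(f"{hsc_label!r} not among classifier classes")
    prob = rf.forest.predict_proba(X_feat)[:, list(rf.classes).index(hsc_label)]

    X = _dense_cells_by_genes(norm_target)
    pc = prob - prob.mean()
    denom_p = np.sqrt((pc**2).sum())
    Xc = X - X.mean(axis=0)
    denom_g = np.sqrt((Xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ pc) / (denom_g * denom_p)
    r[denom_g == 0] = np.nan
    if denom_p == 0:
        r[:] = np.nan
    return pd.Series(r, index=pd.Index(gene_ids, name="gene"), name="r_hsc")


def nominate_candidates(
    specificity: pd.Series,
    interaction_called: pd.DataFrame,
    lfc_hsc: pd.Series,
    r_min: float = 0.3,
) -> pd.DataFrame:
    """Flag stem-restricted, synergistically activated genes.

    candidate iff correlation >= ``r_min`` AND interaction call is
    synergistic AND the AB-vs-WT fold change within HSC/MPP is positive;
    output ranked by correlation x interaction score.
    """
    tab = interaction_called.set_index("gene")
    df = pd.DataFrame(
        {
            "r_hsc": specificity,
            "call": tab["call"].reindex(specificity.index),
            "score": tab["score"].reindex(specificity.index),
            "log_fc_hsc": pd.Series(lfc_hsc).reindex(specificity.index),
        }
    )
    df["candidate"] = (
        (df["r_hsc"] >= r_min)
        & (df["call"] == "synergistic")
        & (df["log_fc_hsc"] > 0)
    )
    df["rank_score"] = df["r_hsc"] * df["score"]
    return df.sort_values("rank_score", ascending=False)
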