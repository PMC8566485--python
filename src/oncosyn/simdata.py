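"""Hierarchical multi-genotype single-cell count simulator with known truth.

The generator emulates a 12-sample study design -- four genotypes
(``WT``, ``A``, ``B``, ``AB``; wild type, each single lesion, and the
double mutant) at three time points (``T1``-``T3``) -- over a branching
hierarchy of hematopoietic cell states rooted at HSC/MPP.  Each cell
draws a state from its sample's state-frequency vector and a continuous
position ``u in [0, 1]`` on the edge leading into that state; its
expected expression interpolates log-linearly between the parent and
state programs, producing the continuum of intermediate cells seen in
real differentiation landscapes.  Genotype acts twice:

* on state frequencies (composition effects), and
* on per-gene expression through additive log-effects for ``A`` and
  ``B`` plus an interaction log-effect applied only in ``AB``.

Counts are negative binomial (gamma-Poisson) with a log-normal library
size; doublets sum the counts of two independently drawn cells of the
same sample; mitochondrial outliers have their ``mt-`` gene counts
inflated above a 10% transcript share.  Everything derives from a single
seed through per-sample substreams, so output is bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .iodata import GENOTYPES, TIMEPOINTS, CellMatrix

# 11-state hematopoietic hierarchy: child -> parent
HEMATO_HIERARCHY = {
    "MEP": "HSC/MPP",
    "GMP": "HSC/MPP",
    "Lym": "HSC/MPP",
    "Meg": "MEP",
    "EryP": "MEP",
    "Ery-early": "EryP",
    "Ery-late": "Ery-early",
    "ProMo": "GMP",
    "GN-early": "GMP",
    "GN-late": "GN-early",
}
HEMATO_ROOT = "HSC/MPP"

# A few canonical mouse marker symbols per population, used as the first
# marker gene names so that worked examples read naturally; remaining
# markers get synthetic names.
CANONICAL_MARKERS = {
    "HSC/MPP": ["Msi2", "Flt3", "Hoxa9", "Gcnt2", "Hlf"],
    "MEP": ["Pf4", "Vwf", "Itga2b", "Gata2", "Apoe"],
    "GMP": ["Mpo", "Elane", "Ctsg", "Prtn3"],
    "ProMo": ["Csf1r", "Irf8", "Ly86"],
    "Lym": ["Cd79a", "Vpreb1", "Igll1"],
    "Meg": ["Itga2b.meg", "Gp1bb", "Rab27b"],
    "EryP": ["Klf1", "Epor"],
    "Ery-early": ["Hba-a1", "Alas2"],
    "Ery-late": ["Hbb-bs", "Bpgm"],
    "GN-early": ["Camp", "Ngp"],
    "GN-late": ["S100a8", "S100a9"],
}


@dataclass
class SimConfig:
    """Parameters of the simulator; defaults define the study conditions."""

    n_genes: int = 2000
    n_cells: int = 2000  # per sample
    hierarchy: dict = field(default_factory=lambda: dict(HEMATO_HIERARCHY))
    root: str = HEMATO_ROOT
    markers_per_state: int = 25
    marker_boost: float = 8.0  # fold increase of marker genes in their state
    # state frequencies: {(genotype, timepoint): vector over states}
    state_frequencies: dict = field(default_factory=dict)
    genotypes: tuple = GENOTYPES
    timepoints: tuple = TIMEPOINTS
    # per-gene log-scale effects (length n_genes, default all zero)
    effect_A: np.ndarray | None = None
    effect_B: np.ndarray | None = None
    effect_interaction: np.ndarray | None = None
    interaction_time_ramp: dict = field(
        default_factory=lambda: {"T1": 1.0, "T2": 1.0, "T3": 1.0}
    )
    baseline_mean: np.ndarray | None = None  # per-gene base mean counts/cell
    baseline_overrides: dict = field(default_factory=dict)  # gene index -> mean
    # Beta(a, b) law of the edge position u: the default (2, 1) puts more
    # mass near the attractor state while keeping a continuum of
    # intermediates between parent and child programs.
    edge_beta_a: float = 2.0
    edge_beta_b: float = 1.0
    dispersion: float = 10.0  # NB size; np.inf -> Poisson
    libsize_mu: float = 0.0  # log-normal library factor, natural-log scale
    libsize_sigma: float = 0.35
    doublet_rate: float = 0.05
    mito_outlier_rate: float = 0.02
    n_mito_genes: int = 10
    mito_base_share: float = 0.04  # expected mito transcript share in inliers
    seed: int = 0

    @property
    def states(self) -> list[str]:
        return [self.root] + list(self.hierarchy.keys())

    @property
    def n_states(self) -> int:
        return len(self.states)

    def validate(self) -> None:
        states = self.states
        # tree check: every non-root has a parent path reaching the root
        for s in self.hierarchy:
            seen, node = set(), s
            while node != self.root:
                if node in seen or node not in self.hierarchy:
                    raise ValueError(f"hierarchy is not a tree rooted at {self.root!r}")
                seen.add(node)
                node = self.hierarchy[node]
        for key, f in self.state_frequencies.items():
            f = np.asarray(f, float)
            if len(f) != len(states):
                raise ValueError(f"frequency vector for {key} has wrong length")
            if abs(f.sum() - 1.0) > 1e-8:
                raise ValueError(f"frequencies for {key} sum to {f.sum()}, not 1")
            if (f < 0).any():
                raise ValueError(f"negative frequency in {key}")
        for eff in (self.effect_A, self.effect_B, self.effect_interaction):
            if eff is not None and not np.all(np.isfinite(eff)):
                raise ValueError("effects must be finite")

    def depth(self, state: str) -> int:
        d, node = 0, state
        while node != self.root:
            node = self.hierarchy[node]
            d += 1
        return d


@dataclass
class SimTruth:
    """Ground truth of a simulated data set.

    ``cells``: one row per cell with its true state, genotype, time
    point, doublet flag (and partner state), continuous edge position
    ``u`` and normalized pseudotime along its lineage path.
    ``genes``: one row per gene with its marker state (empty string for
    non-markers) and additive/interaction log-effect sizes.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame

    def validate(self) -> None:
        if self.cells["state"].isna().any():
            raise ValueError("cell without a true state")
        flagged = self.genes["effect_interaction"] != 0.0
        if not np.all(self.genes.loc[flagged, "effect_interaction"] != 0):
            raise ValueError("flagged interaction gene with zero effect")


# ----------------------------------------------------------------------

def default_hematopoiesis_config(
    n_genes: int = 2000,
    n_cells: int = 2000,
    seed: int = 0,
    n_planted_hsc_synergy: int = 10,
    planted_effect: float = 1.0,
) -> SimConfig:
    """The default 11-state hematopoietic study design.

    Composition effects encode the qualitative biology of the two
    lesions: ``A`` (RAS-pathway activation) expands the myeloid branch,
    ``B`` (loss of the repressive epigenetic regulator) expands HSC/MPP,
    and the double mutant ``AB`` additionally and progressively expands
    MEP and Meg.  Ten HSC/MPP marker genes carry a synergistic
    (``AB``-only) expression effect of ``planted_effect`` on the natural
    log scale, and a sprinkling of genes carry purely additive single
    mutant effects.
    """
    cfg = SimConfig(n_genes=n_genes, n_cells=n_cells, seed=seed)
    states = cfg.states
    base = {
        "HSC/MPP": 0.20, "MEP": 0.06, "GMP": 0.12, "Lym": 0.08,
        "Meg": 0.04, "EryP": 0.10, "Ery-early": 0.10, "Ery-late": 0.08,
        "ProMo": 0.08, "GN-early": 0.08, "GN-late": 0.06,
    }
    myeloid = {"GMP", "ProMo", "GN-early", "GN-late"}
    tw = {"T1": 0.4, "T2": 0.7, "T3": 1.0}
    freqs = {}
    for g in cfg.genotypes:
        for t in cfg.timepoints:
            f = np.array([base[s] for s in states], float)
            w = tw[t]
            if g in ("A", "AB"):
                f *= np.array([1 + 1.0 * w if s in myeloid else 1 for s in states])
            if g in ("B", "AB"):
                f *= np.array([1 + 1.2 * w if s == "HSC/MPP" else 1 for s in states])
            if g == "AB":
                f *= np.array(
                    [1 + 1.5 * w if s in ("MEP", "Meg") else 1 for s in states]
                )
            freqs[(g, t)] = f / f.sum()
    cfg.state_frequencies = freqs

    rng = np.random.default_rng(np.random.SeedSequence([seed, 1_000_003]))
    eff_a = np.zeros(n_genes)
    eff_b = np.zeros(n_genes)
    eff_i = np.zeros(n_genes)
    # additive single-lesion effects on non-marker genes for realism
    n_marked = cfg.n_states * cfg.markers_per_state
    free = np.arange(n_marked, n_genes)
    pick = rng.choice(free, size=min(60, len(free)), replace=False)
    eff_a[pick[:30]] = rng.choice([-0.5, 0.5], size=len(pick[:30]))
    eff_b[pick[30:]] = rng.choice([-0.5, 0.5], size=len(pick[30:]))
    # HSC/MPP-restricted synergy genes: the first markers of the root state,
    # modeled as well-expressed in their compartment
    eff_i[:n_planted_hsc_synergy] = planted_effect
    cfg.baseline_overrides = {i: 2.0 for i in range(n_planted_hsc_synergy)}
    cfg.effect_A, cfg.effect_B, cfg.effect_interaction = eff_a, eff_b, eff_i
    cfg.interaction_time_ramp = {"T1": 0.4, "T2": 0.7, "T3": 1.0}
    return cfg


def _gene_names(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Gene names and per-gene marker-state assignment.

    Gene layout: the first ``n_states * markers_per_state`` genes are the
    state markers (root state first), the last ``n_mito_genes`` genes are
    mitochondrial ("mt-1", ...), everything between is background.
    """
    states = cfg.states
    marker_state = np.array([""] * cfg.n_genes, dtype=object)
    names = np.array([f"g{i:05d}" for i in range(cfg.n_genes)], dtype=object)
    i = 0
    for s in states:
        canon = CANONICAL_MARKERS.get(s, [])
        for j in range(cfg.markers_per_state):
            if i >= cfg.n_genes:
                raise ValueError("n_genes too small for marker layout")
            marker_state[i] = s
            if j < len(canon):
                names[i] = canon[j]
            i += 1
    for j in range(cfg.n_mito_genes):
        names[cfg.n_genes - cfg.n_mito_genes + j] = f"mt-{j + 1}"
    return names, marker_state


def _state_programs(cfg: SimConfig, marker_state: np.ndarray, rng) -> dict:
    """Per-state mean expression vectors (counts per cell, before effects)."""
    if cfg.baseline_mean is not None:
        base = np.asarray(cfg.baseline_mean, float).copy()
    else:
        base = rng.lognormal(mean=-0.7, sigma=1.0, size=cfg.n_genes)
    for gi, val in cfg.baseline_overrides.items():
        base[gi] = val
    mito = np.zeros(cfg.n_genes, bool)
    mito[cfg.n_genes - cfg.n_mito_genes:] = True
    if cfg.n_mito_genes:
        nonmito_total = base[~mito].sum()
        share = cfg.mito_base_share
        base[mito] = share / (1 - share) * nonmito_total / cfg.n_mito_genes
    programs = {}
    for s in cfg.states:
        m = base.copy()
        m[(marker_state == s) & ~mito] *= cfg.marker_boost
        # markers of other states are damped so programs separate cleanly
        m[(marker_state != s) & (marker_state != "") & ~mito] /= cfg.marker_boost
        programs[s] = m
    return programs


def simulate(cfg: SimConfig) -> tuple[CellMatrix, SimTruth]:
    """Draw the full 12-sample data set; returns counts plus ground truth."""
    cfg.validate()
    names, marker_state = _gene_names(cfg)
    root_ss = np.random.SeedSequence([cfg.seed, 7])
    prog_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    programs = _state_programs(cfg, marker_state, prog_rng)
    log_programs = {s: np.log(np.maximum(p, 1e-12)) for s, p in programs.items()}
    states = cfg.states
    depth = {s: cfg.depth(s) for s in states}
    max_depth = max(1, max(depth.values()))

    eff_a = np.zeros(cfg.n_genes) if cfg.effect_A is None else np.asarray(cfg.effect_A, float)
    eff_b = np.zeros(cfg.n_genes) if cfg.effect_B is None else np.asarray(cfg.effect_B, float)
    eff_i = (
        np.zeros(cfg.n_genes)
        if cfg.effect_interaction is None
        else np.asarray(cfg.effect_interaction, float)
    )

    blocks, metas, truths = [], [], []
    sample_idx = 0
    substreams = root_ss.spawn(len(cfg.genotypes) * len(cfg.timepoints))
    for g in cfg.genotypes:
        for t in cfg.timepoints:
            rng = np.random.default_rng(substreams[sample_idx])
            sample_idx += 1
            freq = np.asarray(
                cfg.state_frequencies.get(
                    (g, t), np.full(len(states), 1.0 / len(states))
                ),
                float,
            )
            ramp = cfg.interaction_time_ramp.get(t, 1.0)
            log_effect = (
                eff_a * (g in ("A", "AB"))
                + eff_b * (g in ("B", "AB"))
                + eff_i * ramp * (g == "AB")
            )
            n = cfg.n_cells
            n_dbl = int(round(cfg.doublet_rate * n))
            n_single = n - n_dbl

            children = {s: [c for c, p in cfg.hierarchy.items() if p == s]
                        for s in states}

            def draw_cells(m, rng=rng, freq=freq, log_effect=log_effect):
                # Each state occupies a "star" in program space: the
                # committed half of the edge from its parent (position
                # w in [0.5, 1] toward its own program) plus, for half
                # of its cells, the first half of an outgoing edge
                # toward a uniformly chosen child (w_out in [0, 0.5]).
                # Every cell therefore lies closest to its own state
                # program, while adjacent states connect through a
                # continuum of intermediates with no density gap.
                sidx = rng.choice(len(states), size=m, p=freq)
                u = rng.beta(cfg.edge_beta_a, cfg.edge_beta_b, size=m)
                side_draw = rng.uniform(size=m)
                child_draw = rng.uniform(size=m)
                lam = np.empty((m, cfg.n_genes))
                pt = np.empty(m)
                for k, s in enumerate(states):
                    rows = np.flatnonzero(sidx == k)
                    if len(rows) == 0:
                        continue
                    kids = children[s]
                    is_root = s == cfg.root
                    if is_root:
                        outgoing = np.ones(len(rows), bool) if kids else \
                            np.zeros(len(rows), bool)
                    elif kids:
                        outgoing = side_draw[rows] < 0.5
                    else:
                        outgoing = np.zeros(len(rows), bool)
                    lp = np.empty((len(rows), cfg.n_genes))
                    # incoming side: committed toward the own program
                    inc = ~outgoing
                    if inc.any():
                        if is_root:
                            lp[inc] = log_programs[s]
                            pt[rows[inc]] = 0.0
                        else:
                            w = 0.5 + 0.5 * u[rows[inc]]
                            parent = cfg.hierarchy[s]
                            lp[inc] = (
                                np.outer(1 - w, log_programs[parent])
                                + np.outer(w, log_programs[s])
                            )
                            pt[rows[inc]] = depth[s] - 1 + w
                    # outgoing side: drifting toward a child, still own state
                    if outgoing.any():
                        ci = (child_draw[rows[outgoing]] * len(kids)).astype(int)
                        w_out = 0.5 * (1.0 - u[rows[outgoing]])
                        for j, c in enumerate(kids):
                            sel = ci == j
                            if not sel.any():
                                continue
                            rr = np.flatnonzero(outgoing)[sel]
                            lp[rr] = (
                                np.outer(1 - w_out[sel], log_programs[s])
                                + np.outer(w_out[sel], log_programs[c])
                            )
                        pt[rows[outgoing]] = depth[s] + w_out
                    lam[rows] = np.exp(lp + log_effect)
                lib = np.exp(rng.normal(cfg.libsize_mu, cfg.libsize_sigma, size=m))
                lam *= lib[:, None]
                if np.isfinite(cfg.dispersion):
                    lam = rng.gamma(cfg.dispersion, lam / cfg.dispersion)
                counts = rng.poisson(lam).astype(np.int32)
                pt = pt / (max_depth + 0.5)
                return counts, np.array(states, dtype=object)[sidx], u, pt

            counts_s, state_s, u_s, pt_s = draw_cells(n_single)
            c1, st1, u1, pt1 = draw_cells(n_dbl)
            c2, st2, _, _ = draw_cells(n_dbl)
            counts = np.vstack([counts_s, c1 + c2]) if n_dbl else counts_s
            state = np.concatenate([state_s, st1]) if n_dbl else state_s
            partner = np.concatenate(
                [np.array([""] * n_single, dtype=object), st2]
            ) if n_dbl else np.array([""] * n_single, dtype=object)
            u_all = np.concatenate([u_s, u1]) if n_dbl else u_s
            pt_all = np.concatenate([pt_s, pt1]) if n_dbl else pt_s
            is_dbl = np.zeros(n, bool)
            is_dbl[n_single:] = True

            # mitochondrial outliers among singlets
            is_mito_out = np.zeros(n, bool)
            n_out = int(round(cfg.mito_outlier_rate * n))
            if n_out and cfg.n_mito_genes:
                out_idx = rng.choice(n_single, size=min(n_out, n_single), replace=False)
                is_mito_out[out_idx] = True
                mcols = np.arange(cfg.n_genes - cfg.n_mito_genes, cfg.n_genes)
                for ci in out_idx:
                    nonmito = counts[ci].sum() - counts[ci, mcols].sum()
                    frac = rng.uniform(0.12, 0.30)
                    target = int(np.ceil(frac / (1 - frac) * max(nonmito, 1)))
                    cur = max(counts[ci, mcols].sum(), 1)
                    counts[ci, mcols] = np.ceil(
                        counts[ci, mcols] * target / cur
                    ).astype(np.int32)

            ids = np.array(
                [f"{g}_{t}_c{i:05d}" for i in range(n)], dtype=object
            )
            blocks.append(sp.csr_matrix(counts.T))
            metas.append(
                pd.DataFrame(
                    {"genotype": g, "timepoint": t}, index=pd.Index(ids)
                )
            )
            truths.append(
                pd.DataFrame(
                    {
                        "cell_id": ids,
                        "genotype": g,
                        "timepoint": t,
                        "state": state,
                        "u": u_all,
                        "pseudotime": pt_all,
                        "is_doublet": is_dbl,
                        "partner_state": partner,
                        "is_mito_outlier": is_mito_out,
                    }
                )
            )

    counts_all = sp.hstack(blocks, format="csr")
    meta = pd.concat(metas)
    cm = CellMatrix(counts_all, names, np.asarray(meta.index, dtype=object), meta)
    genes = pd.DataFrame(
        {
            "gene_id": names,
            "marker_state": marker_state,
            "effect_A": eff_a,
            "effect_B": eff_b,
            "effect_interaction": eff_i,
        }
    )
    truth = SimTruth(cells=pd.concat(truths, ignore_index=True), genes=genes)
    truth.validate()
    return cm, truth


def marker_table(truth: SimTruth, markers_per_state: int | None = None) -> dict:
    """Ground-truth marker sets, in the format :func:`oncosyn.iodata.read_markers` yields."""
    out: dict[str, list[str]] = {}
    for _, row in truth.genes.iterrows():
        if row["marker_state"]:
            out.setdefault(row["marker_state"], []).append(row["gene_id"])
    if markers_per_state is not None:
        out = {k: v[:markers_per_state] for k, v in out.items()}
    return out
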