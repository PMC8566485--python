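import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from oncosyn.atlas import (
    ReferenceModel,
    annotate,
    fit_reference,
    merge_clusters,
    normalize_log,
    select_hvg,
)
from oncosyn.simdata import SimConfig, marker_table, simulate

from conftest import make_cell_matrix


class TestNormalizeLog:
    def test_closed_form(self):
        cm = make_cell_matrix([[100], [9900]])
        norm = normalize_log(cm, scale=10_000.0)
        assert norm[0, 0] == pytest.approx(np.log(101.0))

    def test_zero_counts_stay_zero_and_depth_invariance(self):
        cm = make_cell_matrix([[0, 0], [5, 10], [15, 30]])
        norm = normalize_log(cm)
        assert norm[0, 0] == 0.0
        # cell 2 is cell 1 with every count doubled
        assert np.allclose(norm[:, 0].todense(), norm[:, 1].todense())

    def test_zero_total_cell_errors(self):
        cm = make_cell_matrix([[0, 1]])
        with pytest.raises(ValueError, match="zero-total"):
            normalize_log(cm)

    def test_matches_scanpy_oracle(self):
        """Independent cross-check against scanpy's normalize_total+log1p."""
        sc = pytest.importorskip("scanpy")
        rng = np.random.default_rng(0)
        counts = rng.poisson(1.0, (50, 30)) + (rng.uniform(size=(50, 30)) < 0.1)
        counts[:, counts.sum(axis=0) == 0] += 1
        cm = make_cell_matrix(counts)
        ours = np.asarray(normalize_log(cm, 10_000.0).todense())
        ad = cm.to_anndata()
        sc.pp.normalize_total(ad, target_sum=10_000.0)
        sc.pp.log1p(ad)
        theirs = np.asarray(ad.X.todense()).T
        assert np.allclose(ours, theirs, atol=1e-10)


class TestSelectHVG:
    def test_state_restricted_gene_outranks_housekeeping(self):
        """Equal-mean genes: concentrated expression beats uniform."""
        n = 200
        rng = np.random.default_rng(1)
        housekeeping = rng.poisson(2.0, n)
        restricted = np.zeros(n, int)
        restricted[:20] = rng.poisson(20.0, 20)
        filler = rng.poisson(1.0, (30, n))
        counts = np.vstack([housekeeping, restricted, filler])
        counts[:, counts.sum(axis=0) == 0] += 1
        cm = make_cell_matrix(counts)
        hvg = select_hvg(normalize_log(cm), cm.gene_ids, n_hvg=5)
        assert "g1" in hvg  # the restricted gene

    def test_all_nonconstant_returned_when_n_hvg_large(self):
        cm = make_cell_matrix(np.random.default_rng(0).poisson(2, (10, 50)) + 1)
        hvg = select_hvg(normalize_log(cm), cm.gene_ids, n_hvg=100)
        assert len(hvg) == 10

    def test_all_constant_errors(self):
        cm = make_cell_matrix(np.full((5, 20), 2))
        with pytest.raises(ValueError, match="constant"):
            select_hvg(normalize_log(cm), cm.gene_ids)

    def test_marker_genes_enriched(self):
        """Simulated markers are strongly over-represented among HVGs."""
        from oncosyn.simdata import default_hematopoiesis_config

        cfg = default_hematopoiesis_config(n_genes=2000, n_cells=300, seed=5)
        cfg.genotypes = ("WT",)
        cm, truth = simulate(cfg)
        markers = set(g for gs in marker_table(truth).values() for g in gs)
        hvg = set(select_hvg(normalize_log(cm), cm.gene_ids, n_hvg=200))
        frac_in_hvg = len(hvg & markers) / len(hvg)
        frac_overall = len(markers) / cm.n_genes
        assert frac_in_hvg >= 4 * frac_overall


class TestFitReference:
    def test_two_separated_states_perfectly_clustered(self):
        cfg = SimConfig(n_genes=300, n_cells=400, hierarchy={"S1": "S0"},
                        root="S0", genotypes=("WT",), timepoints=("T1",),
                        markers_per_state=30, marker_boost=12.0,
                        edge_beta_a=20.0, doublet_rate=0.0,
                        mito_outlier_rate=0.0, seed=8)
        cm, truth = simulate(cfg)
        model = fit_reference(cm, n_pcs=20, resolution=1.0, seed=0)
        truth_states = truth.cells.set_index("cell_id").loc[cm.cell_ids, "state"]
        assert adjusted_rand_score(truth_states, model.cluster) == 1.0

    def test_basis_orthonormal_and_cluster_range(self, wt_reference):
        wt, model = wt_reference
        gram = model.pc_loadings @ model.pc_loadings.T
        assert np.allclose(gram, np.eye(len(gram)), atol=1e-6)
        assert 11 <= len(np.unique(model.cluster)) <= 40

    def test_save_load_round_trip(self, wt_reference, tmp_path):
        _, model = wt_reference
        model.save(tmp_path / "ref")
        back = ReferenceModel.load(tmp_path / "ref")
        assert np.allclose(back.embeddings, model.embeddings)
        assert np.array_equal(back.state_label, model.state_label)
        assert back.population_labels == model.population_labels


class TestMergeAndAnnotate:
    def test_threshold_near_one_is_identity(self, wt_reference):
        import copy

        _, model = wt_reference
        m = copy.deepcopy(model)
        m = merge_clusters(m, corr_threshold=0.9999)
        assert len(np.unique(m.population)) == len(np.unique(m.cluster))

    def test_threshold_out_of_range(self, wt_reference):
        _, model = wt_reference
        with pytest.raises(ValueError):
            merge_clusters(model, corr_threshold=1.5)

    def test_overclustered_states_remerge(self, hemato_sim):
        """Sub-clusters of one simulated state merge; distinct branches do not."""
        _, cm, truth = hemato_sim
        wt = cm.subset_cells((cm.cell_meta["genotype"] == "WT").to_numpy())
        model = fit_reference(wt, resolution=3.0, seed=0)
        n_clusters = len(np.unique(model.cluster))
        model = merge_clusters(model)
        n_pops = len(np.unique(model.population))
        assert n_pops <= n_clusters
        assert 8 <= n_pops <= 14  # close to the 11 true states

    def test_annotation_recovers_true_labels(self, hemato_sim, wt_reference,
                                             truth_by_cell):
        _, cm, truth = hemato_sim
        wt, model = wt_reference
        labels = set(model.population_labels.values())
        true_states = set(truth.cells["state"])
        assert len(labels & true_states) >= 9
        wt_truth = truth_by_cell.loc[wt.cell_ids]
        mask = ~wt_truth["is_doublet"].to_numpy()
        acc = (model.state_label[mask] == wt_truth["state"].to_numpy()[mask]).mean()
        assert acc >= 0.9

    def test_annotate_empty_markers_errors(self, wt_reference):
        wt, model = wt_reference
        with pytest.raises(ValueError, match="empty"):
            annotate(model, {}, normalize_log(wt))

    def test_absent_marker_label_never_assigned(self, wt_reference):
        wt, model = wt_reference
        import copy

        m = copy.deepcopy(model)
        markers = {"Ghost": ["not_a_gene_1", "not_a_gene_2"],
                   "Everything": list(wt.gene_ids[:50])}
        m = annotate(m, markers, normalize_log(wt))
        assert "Ghost" not in set(m.population_labels.values())
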