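import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncosyn.interaction import (
    call_interactions,
    call_summary,
    decompose_change,
    exhaustive_null_pool,
    expression_changes,
    geneset_interaction_trajectory,
    permutation_null,
)
from oncosyn.simdata import SimConfig, simulate

from conftest import make_cell_matrix


def _table(dobs, dexp):
    dobs, dexp = np.asarray(dobs, float), np.asarray(dexp, float)
    return pd.DataFrame({"delta_obs": dobs, "delta_exp": dexp,
                         "score": dobs - dexp})


class TestScoreArithmetic:
    def test_worked_example(self):
        """Means 1.0/1.5/1.3/2.2 -> dA=.5, dB=.3, d_exp=.8, d_obs=1.2, I=.4."""
        tab = pd.DataFrame({"mean_WT": [1.0], "mean_A": [1.5],
                            "mean_B": [1.3], "mean_AB": [2.2]})
        tab["delta_A"] = tab["mean_A"] - tab["mean_WT"]
        tab["delta_B"] = tab["mean_B"] - tab["mean_WT"]
        tab["delta_obs"] = tab["mean_AB"] - tab["mean_WT"]
        tab["delta_exp"] = tab["delta_A"] + tab["delta_B"]
        score = (tab["delta_obs"] - tab["delta_exp"]).iloc[0]
        assert score == pytest.approx(0.4)

    def test_expression_changes_invariants(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3.0, (40, 200))
        counts[:, counts.sum(axis=0) == 0] += 1
        geno = np.repeat(["WT", "A", "B", "AB"], 50)
        cm = make_cell_matrix(counts, genotype=list(geno))
        tab = expression_changes(cm)
        assert np.allclose(tab["score"],
                           tab["delta_obs"] - tab["delta_exp"])
        assert np.allclose(tab["delta_exp"],
                           tab["delta_A"] + tab["delta_B"])

    def test_missing_genotype_errors(self):
        cm = make_cell_matrix(np.ones((5, 30), int),
                              genotype=["WT"] * 15 + ["A"] * 15)
        with pytest.raises(ValueError, match="missing"):
            expression_changes(cm)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-2, 2), min_size=4, max_size=4),
           st.floats(-5, 5))
    def test_antisymmetry_and_location_invariance(self, deltas, c):
        """I(d_obs, d_exp) = -I(d_exp, d_obs); adding a constant to all
        four genotype means leaves I unchanged."""
        wt, a, b, ab = deltas
        d_obs, d_exp = ab - wt, (a - wt) + (b - wt)
        i1 = d_obs - d_exp
        i2 = d_exp - d_obs
        assert i1 == pytest.approx(-i2)
        wt2, a2, b2, ab2 = wt + c, a + c, b + c, ab + c
        i3 = (ab2 - wt2) - ((a2 - wt2) + (b2 - wt2))
        assert i3 == pytest.approx(i1, abs=1e-9)


class TestPermutationNull:
    def test_degenerate_equal_vectors(self):
        null = permutation_null(_table([0.7] * 120, [0.7] * 120), n_perm=10,
                                seed=0)
        assert null.q05 == null.q95 == 0.0

    def test_enumeration_oracle_five_genes(self):
        """Sampled independent-pairing null matches the exhaustive pool of
        all gene pairings (all 120 orderings weight each pair equally)."""
        rng = np.random.default_rng(3)
        dobs, dexp = rng.uniform(0, 0.1, 5), rng.uniform(0, 0.1, 5)
        null = permutation_null(_table(dobs, dexp), n_perm=10_000, seed=1,
                                scheme="independent")
        exact = exhaustive_null_pool(dobs, dexp)
        assert abs(null.q05 - np.percentile(exact, 5)) < 0.01
        assert abs(null.q95 - np.percentile(exact, 95)) < 0.01

    def test_fixed_seed_reproducible(self):
        t = _table(np.arange(150) * 0.01, np.arange(150)[::-1] * 0.01)
        n1 = permutation_null(t, n_perm=50, seed=9)
        n2 = permutation_null(t, n_perm=50, seed=9)
        assert n1.q05 == n2.q05 and n1.q95 == n2.q95
        assert np.array_equal(n1.pool, n2.pool)

    def test_swap_null_calibration_by_construction(self):
        """With per-gene-independent observed/expected values, the default
        swap null calls ~10% of genes on pure noise."""
        rng = np.random.default_rng(4)
        fracs = []
        for _ in range(10):
            t = _table(rng.normal(0, 1, 2000), rng.normal(0, 1, 2000))
            null = permutation_null(t, n_perm=200, seed=0)
            called = call_interactions(t, null)
            fracs.append((called["call"] != "none").mean())
        assert np.mean(fracs) == pytest.approx(0.10, abs=0.02)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            permutation_null(_table([1] * 100, [1] * 100), n_perm=0)
        with pytest.raises(ValueError):
            permutation_null(_table([1] * 100, [1] * 100), scheme="bogus")


class TestCalls:
    def test_call_definitions(self):
        t = _table([1.0, 0.0, -1.0], [0.0, 0.0, 0.0])
        null = permutation_null(t, n_perm=1, seed=0)
        called = call_interactions(t, null)
        null.q05, null.q95 = -0.5, 0.5
        called = call_interactions(t, null)
        assert list(called["call"]) == ["synergistic", "none", "antagonistic"]
        assert list(called["direction"]) == ["up", "up", "down"]
        s = call_summary(called)
        assert s.set_index("call")["fraction"].sum() == pytest.approx(1.0)


@pytest.fixture(scope="module")
def ramped():
    # up/down planted baselines balanced (12 vs 12e) so the double
    # mutant's library matches wild type at full ramp
    n_genes = 300
    base = np.random.default_rng(5).lognormal(-0.5, 0.8, n_genes)
    eff = np.zeros(n_genes)
    eff[:10] = 1.0
    eff[10:20] = -1.0
    base[:10] = 12.0
    base[10:20] = 12.0 * np.e
    base[20:30] = 8.0  # exactly additive reporter genes
    cfg = SimConfig(n_genes=n_genes, n_cells=500, hierarchy={}, root="S0",
                    baseline_mean=base, effect_interaction=eff,
                    interaction_time_ramp={"T1": 0.0, "T2": 0.5, "T3": 1.0},
                    markers_per_state=0, doublet_rate=0.0,
                    mito_outlier_rate=0.0, seed=6)
    cm, _ = simulate(cfg)
    return cm


class TestGenesetTrajectory:
    def test_ramped_set_is_monotone(self, ramped):
        genes = [f"g{i:05d}" for i in range(10)]
        out = geneset_interaction_trajectory(ramped, genes)
        med = out.groupby("timepoint")["score"].median()
        assert med["T1"] < med["T2"] < med["T3"]
        assert med["T3"] == pytest.approx(1.0, abs=0.25)

    def test_additive_set_medians_near_zero(self, ramped):
        genes = [f"g{i:05d}" for i in range(20, 30)]
        out = geneset_interaction_trajectory(ramped, genes)
        assert out.groupby("timepoint")["score"].median().abs().max() < 0.15

    def test_singleton_and_empty_sets(self, ramped):
        one = geneset_interaction_trajectory(ramped, ["g00000"])
        assert (one.groupby("timepoint").size() == 1).all()
        with pytest.raises(ValueError, match="empty"):
            geneset_interaction_trajectory(ramped, ["nope"])


class TestDecompose:
    def _cm(self, counts, geno):
        return make_cell_matrix(counts, genotype=list(geno))

    def test_identity_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            counts = rng.poisson(2.0, (8, 90)) + 1
            geno = rng.choice(["WT", "AB"], 90)
            labels = rng.choice(["x", "y", "z"], 90)
            cm = self._cm(counts, geno)
            d = decompose_change(cm, [f"g{i}" for i in range(8)], "AB", labels)
            assert np.allclose(d["composition"] + d["expression"], d["total"],
                               atol=1e-12)

    def test_pure_expression_shift_has_zero_composition(self):
        # same label layout in both genotypes; one gene's share shifts
        wt_block = np.full((3, 20), 2)
        ab_block = np.full((3, 20), 2)
        ab_block[0] = 6
        counts = np.hstack([wt_block, ab_block])
        geno = ["WT"] * 20 + ["AB"] * 20
        labels = (["x"] * 10 + ["y"] * 10) * 2
        d = decompose_change(self._cm(counts, geno), ["g0"], "AB", labels)
        assert d["composition"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert d["total"].iloc[0] != 0.0

    def test_pure_composition_shift_has_zero_expression(self):
        # identical per-state expression, shifted frequencies
        x_cell = [5, 0, 1]
        y_cell = [0, 5, 1]
        wt = np.array([x_cell] * 10 + [y_cell] * 10).T
        ab = np.array([x_cell] * 16 + [y_cell] * 4).T
        counts = np.hstack([wt, ab])
        geno = ["WT"] * 20 + ["AB"] * 20
        labels = ["x"] * 10 + ["y"] * 10 + ["x"] * 16 + ["y"] * 4
        d = decompose_change(self._cm(counts, geno), ["g0"], "AB", labels)
        assert d["expression"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert d["composition"].iloc[0] != 0.0

    def test_one_sided_state_flagged(self):
        counts = np.hstack([np.full((2, 20), 2), np.full((2, 20), 3)])
        geno = ["WT"] * 20 + ["AB"] * 20
        labels = ["x"] * 20 + ["x"] * 10 + ["only_ab"] * 10
        d = decompose_change(self._cm(counts, geno), ["g0"], "AB", labels)
        assert "only_ab" in d["one_sided_states"].iloc[0]
        assert np.allclose(d["composition"] + d["expression"], d["total"],
                           atol=1e-12)
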