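"""Sensitivity analysis: LHS, PRCC, GSA, local SA, identifiability screens."""

import numpy as np
import pandas as pd
import pytest

from tipstalk import fixtures, sens
from tipstalk.network import ModelDefinition, Parameter, Reaction, Species


def prcc_precision_matrix_oracle(X, y):
    """Independent PRCC route: partial correlations from the inverse of the
    rank correlation matrix (off-diagonal of the scaled precision matrix)."""
    from scipy.stats import rankdata
    rX = np.column_stack([rankdata(X[:, j]) for j in range(X.shape[1])])
    ry = rankdata(y)
    M = np.column_stack([rX, ry])
    C = np.corrcoef(M, rowvar=False)
    P = np.linalg.inv(C)
    k = X.shape[1]
    return np.array([-P[j, k] / np.sqrt(P[j, j] * P[k, k]) for j in range(k)])


class TestLhs:
    def test_one_point_per_decile(self):
        X = sens.lhs_sample([(0.0, 1.0)], 10, seed=0).ravel()
        assert sorted(np.floor(X * 10).astype(int).tolist()) == list(range(10))

    def test_seed_reproducibility(self):
        a = sens.lhs_sample([(0, 1), (2, 5)], 20, seed=3)
        b = sens.lhs_sample([(0, 1), (2, 5)], 20, seed=3)
        assert np.array_equal(a, b)

    def test_uniform_marginal_mean(self):
        X = sens.lhs_sample([(2.0, 6.0)], 1000, seed=1).ravel()
        se = (6 - 2) / np.sqrt(12) / np.sqrt(1000)
        assert abs(X.mean() - 4.0) < 3 * se

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(sens.DegenerateSamplingError):
            sens.lhs_sample([(1.0, 1.0)], 10)
        with pytest.raises(sens.DegenerateSamplingError):
            sens.lhs_sample([(0.0, 1.0)], 1)


class TestPrcc:
    def test_monotone_single_input(self):
        rng = np.random.default_rng(0)
        X = rng.random((200, 4))
        y = np.expm1(3 * X[:, 0]) + 1e-3 * rng.random(200)
        co, pv = sens.prcc(X, y)
        assert co[0] > 0.95
        assert np.all(np.abs(co[1:]) < 0.2)
        assert pv[0] < 1e-10

    def test_exact_negative_monotone(self):
        rng = np.random.default_rng(1)
        X = rng.random((50, 3))
        co, pv = sens.prcc(X, -X[:, 1])
        assert co[1] == pytest.approx(-1.0, abs=1e-12)
        assert pv[1] == 0.0

    def test_pure_noise_null(self):
        """With y independent of all inputs, ≥90% of coefficients across
        seeds stay below the 0.2 influence cutoff with p above 0.05."""
        hits = total = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.random((200, 5))
            y = rng.random(200)
            co, pv = sens.prcc(X, y)
            hits += int(np.sum((np.abs(co) < 0.2) & (pv > 0.05)))
            total += 5
        assert hits / total >= 0.9

    def test_agreement_with_precision_matrix_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.random((120, 5))
        y = 2 * X[:, 0] - 3 * X[:, 3] + 0.3 * rng.random(120)
        co, _ = sens.prcc(X, y)
        ref = prcc_precision_matrix_oracle(X, y)
        assert np.max(np.abs(co - ref)) < 1e-10

    def test_duplicated_column_flagged_not_computed(self):
        rng = np.random.default_rng(2)
        x = rng.random(60)
        X = np.column_stack([x, x, rng.random(60)])
        co, pv = sens.prcc(X, rng.random(60))
        assert np.isnan(co[0]) and np.isnan(co[1])
        assert not np.isnan(co[2])

    def test_constant_output_undefined(self):
        rng = np.random.default_rng(3)
        co, pv = sens.prcc(rng.random((30, 2)), np.ones(30))
        assert np.all(np.isnan(co)) and np.all(np.isnan(pv))

    def test_invariance_under_monotone_input_transform(self):
        rng = np.random.default_rng(4)
        X = rng.random((80, 3)) + 0.1
        y = X[:, 0] - X[:, 2] + 0.05 * rng.random(80)
        co1, pv1 = sens.prcc(X, y)
        X2 = X.copy()
        X2[:, 0] = np.log(X2[:, 0])          # strictly increasing
        X2[:, 2] = X2[:, 2] ** 3             # strictly increasing
        co2, pv2 = sens.prcc(X2, y)
        assert np.array_equal(co1, co2)
        assert np.array_equal(pv1, pv2)


@pytest.fixture(scope="module")
def gsa_result(two_cell_model):
    params = ["kdeg_He", "kp_Dll", "kNotchR1", "kform_Notch", "kform_Gs",
              "teta_ERKDll4", "kdeg_mDll4", "ktransl_Dll4", "khesr2"]
    return sens.gsa_ecpi(two_cell_model,
                         conditions=("normoxia-differential",),
                         parameters=params, n=48, seed=7,
                         solver_options={"method": "BDF", "rtol": 1e-6,
                                         "atol": 1e-10})


class TestGsaEcpi:

    def test_bounds_respect_factor(self, two_cell_model):
        v = two_cell_model.parameters["kdeg_He"].value
        X = sens.lhs_sample([(v / 1.5, v * 1.5)], 100, seed=0).ravel()
        assert X.min() >= v / 1.5 and X.max() <= v * 1.5

    def test_table_shape_and_ranges(self, gsa_result):
        t = gsa_result.table
        assert set(t["output"]) == {"ECPI_c1", "ECPI_c2"}
        assert set(t["timepoint"]) == {1.0, 12.0}
        ok = ~t["prcc"].isna()
        assert np.all(np.abs(t.loc[ok, "prcc"]) <= 1.0)
        assert np.all((t.loc[ok, "p"] >= 0) & (t.loc[ok, "p"] <= 1))

    def test_hes1_degradation_drives_second_cell_index(self, gsa_result):
        """kdeg_He sits among the high-|PRCC| Notch parameters for the
        stalk (second) cell's ECPI."""
        sub = gsa_result.table[(gsa_result.table.output == "ECPI_c2")
                               & (gsa_result.table.timepoint == 12.0)]
        ranked = sub.reindex(sub["prcc"].abs().sort_values(ascending=False).index)
        top = list(ranked["parameter"][:3])
        assert "kdeg_He" in top
        assert abs(float(sub[sub.parameter == "kdeg_He"]["prcc"].iloc[0])) > 0.2

    def test_dll4_production_constant_drives_first_cell_index(self, gsa_result):
        sub = gsa_result.table[gsa_result.table.output == "ECPI_c1"]
        best = float(np.nanmax(np.abs(
            sub[sub.parameter == "kp_Dll"]["prcc"].to_numpy(float))))
        assert best > 0.2

    def test_unknown_condition_rejected(self, two_cell_model):
        with pytest.raises(ValueError):
            sens.gsa_ecpi(two_cell_model, conditions=("anoxia",), n=4)


class TestLocalSensitivity:
    def test_receptor2_dominates_receptor1(self, two_cell_model):
        df = sens.local_sensitivity(
            two_cell_model, targets=("Hes1_c1", "Hes1_c2"),
            inputs=("R2", "R1"), horizons=(2.0, 12.0),
            conditions=("normoxia-differential",),
            solver_options={"method": "BDF", "rtol": 1e-8, "atol": 1e-12})
        for (tgt, h), g in df.groupby(["target", "horizon_h"]):
            s_r2 = np.nanmax(np.abs(g[g["input"].str.startswith("R2")]["sensitivity"]))
            s_r1 = np.nanmax(np.abs(g[g["input"].str.startswith("R1")]["sensitivity"]))
            assert s_r2 > s_r1

    def test_zero_perturbation_rejected(self, two_cell_model):
        with pytest.raises(ValueError):
            sens.local_sensitivity(two_cell_model, fraction=0.0)

    def test_horizon_beyond_duration_rejected(self, two_cell_model):
        with pytest.raises(ValueError):
            sens.local_sensitivity(two_cell_model, horizons=(-1.0,))


class TestScreens:
    def _result(self, rows):
        return sens.SensitivityResult(
            table=pd.DataFrame(rows, columns=["parameter", "output", "timepoint",
                                              "condition", "prcc", "p"]),
            n=10, seed=0)

    def test_influence_screen_enumeration(self):
        res = self._result([
            ("a", "y", 1.0, "c", 0.9, 1e-6),    # kept: both criteria
            ("b", "y", 1.0, "c", 0.05, 0.5),    # dropped
            ("c", "y", 1.0, "c", 0.25, 0.2),    # kept: |PRCC| > 0.2
            ("d", "y", 1.0, "c", 0.1, 0.01),    # kept: p < 0.05
            ("e", "y", 1.0, "c", np.nan, np.nan),  # dropped: undefined
        ])
        assert sens.influence_screen(res) == ["a", "c", "d"]

    def test_influence_screen_empty(self):
        assert sens.influence_screen(self._result([])) == []

    def test_collinearity_removes_reverse_of_binding(self, binding_toy):
        kept, removed = sens.collinearity_screen(binding_toy, ["kon", "koff"])
        assert kept == ["kon"]
        assert removed == [("kon", "koff")]

    def test_collinearity_no_reversible_pairs(self, mini_notch_toy):
        params = ["KI", "kD", "kI", "kdeg"]
        kept, removed = sens.collinearity_screen(mini_notch_toy, params)
        assert kept == params and removed == []

    def test_collinearity_three_pair_network(self):
        m = ModelDefinition(name="three-pairs")
        m.species = [Species(n, initial_value=1.0) for n in
                     ["A", "B", "C", "X", "pX", "Y", "pY"]]
        m.parameters = {n: Parameter(n, 1e-3) for n in
                        ["kon", "koff", "kp1", "kdp1", "kp2", "kdp2"]}
        m.reactions = [
            Reaction("bind", [("A", 1), ("B", 1)], [("C", 1)], law_params={"k": "kon"}),
            Reaction("unbind", [("C", 1)], [("A", 1), ("B", 1)], law_params={"k": "koff"}),
            Reaction("phos1", [("X", 1)], [("pX", 1)], law_params={"k": "kp1"}),
            Reaction("dephos1", [("pX", 1)], [("X", 1)], law_params={"k": "kdp1"}),
            Reaction("phos2", [("Y", 1)], [("pY", 1)], law_params={"k": "kp2"}),
            Reaction("dephos2", [("pY", 1)], [("Y", 1)], law_params={"k": "kdp2"}),
        ]
        m.observables = {}
        kept, removed = sens.collinearity_screen(m, list(m.parameters))
        assert len(removed) == 3
        assert kept == ["kon", "kp1", "kp2"]

    def test_group_classification_exact_partition(self, two_cell_model):
        rows_v = [("a", "y", 1.0, "n", 0.8, 0.01), ("b", "y", 1.0, "n", 0.1, 0.5),
                  ("c", "y", 1.0, "n", 0.3, 0.1)]
        rows_h = [("a", "y", 1.0, "h", 0.2, 0.1), ("b", "y", 1.0, "h", 0.7, 0.01),
                  ("c", "y", 1.0, "h", 0.3, 0.1)]
        groups = sens.classify_parameter_groups(
            two_cell_model, self._result(rows_v), self._result(rows_h),
            parameters=["a", "b", "c"])
        # ties (c) go to the vegf group, fitted first
        assert groups == {"vegf": ["a", "c"], "hypoxia": ["b"]}

    def test_group_classification_missing_parameter(self, two_cell_model):
        with pytest.raises(KeyError):
            sens.classify_parameter_groups(
                two_cell_model, self._result([]), self._result([]),
                parameters=["ghost"])
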