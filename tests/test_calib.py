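"""Calibration: weighted SSR, PSO, staged fitting, runs test, bootstrap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tipstalk import calib, fixtures
from tipstalk.calib import (
    DatasetError,
    DegenerateResidualError,
    ExperimentalDataset,
    bootstrap_uq,
    coverage_fraction,
    make_model_predictor,
    pso,
    runs_test,
    staged_fit,
    weighted_ssr,
)
from tipstalk.protocols import StimulusProtocol


def analytic_predictor(params, obs, cond, times):
    """Saturating response y = 1 - exp(-k t); cheap and exactly known."""
    return 1.0 - np.exp(-params["k"] * np.asarray(times, float))


class TestDataset:
    def test_validation_catches_bad_values(self):
        df = pd.DataFrame({"time_h": [0.0], "observable": ["y"], "value": [1.5],
                           "condition": ["c"], "source": ["s"], "weight": [1.0]})
        with pytest.raises(DatasetError):
            ExperimentalDataset(df)

    def test_equal_group_weights(self):
        rows = [(t, "y", 0.5, "c", "s1") for t in (0, 1, 2, 3)] + \
               [(t, "y", 0.5, "c", "s2") for t in (0, 1)]
        ds = ExperimentalDataset.from_records(rows)
        w = ds.records.groupby("source")["weight"].sum()
        assert w["s1"] == pytest.approx(1.0) and w["s2"] == pytest.approx(1.0)


class TestWeightedSsr:
    def test_perfect_fit_is_zero(self):
        times = np.linspace(0.5, 10, 8)
        ds = fixtures.generate_synthetic_timecourses(
            analytic_predictor, {"c": StimulusProtocol(duration=10, pre_equilibrate_h=0)},
            {"k": 0.4}, ["y"], sample_times=times)
        assert weighted_ssr(analytic_predictor, {"k": 0.4}, ds) < 1e-10

    def test_all_zero_weights_give_zero(self):
        rows = [(t, "y", 0.3, "c", "s") for t in (0.0, 1.0, 2.0)]
        ds = ExperimentalDataset.from_records(rows)
        ds.records["weight"] = 0.0
        assert weighted_ssr(analytic_predictor, {"k": 1.0}, ds) == 0.0

    def test_hand_computed_three_points(self):
        # predictor returns the series itself; normalized sim = [0.5, 1, 0.25]
        def pred(params, obs, cond, times):
            return np.array([2.0, 4.0, 1.0])
        rows = [(0.0, "y", 0.4, "c", "s"), (1.0, "y", 0.9, "c", "s"),
                (2.0, "y", 0.35, "c", "s")]
        ds = ExperimentalDataset.from_records(rows, equal_group_weights=False)
        expected = (0.5 - 0.4) ** 2 + (1.0 - 0.9) ** 2 + (0.25 - 0.35) ** 2
        assert weighted_ssr(pred, {}, ds) == pytest.approx(expected, rel=1e-12)

    def test_simulation_failure_penalised_finite(self):
        def broken(params, obs, cond, times):
            raise RuntimeError("diverged")
        rows = [(0.0, "y", 0.4, "c", "s")]
        ds = ExperimentalDataset.from_records(rows)
        v = weighted_ssr(broken, {}, ds)
        assert np.isfinite(v) and v >= calib.PENALTY


class TestPso:
    def test_sphere_minimum_recovered(self):
        res = pso(lambda x: float(np.sum((x - 0.3) ** 2)), [(-2, 2)] * 3,
                  iterations=200, seed=1)
        assert np.max(np.abs(res.x - 0.3)) < 1e-3

    def test_rosenbrock_benchmark(self):
        res = pso(lambda x: float((1 - x[0]) ** 2 + 100 * (x[1] - x[0] ** 2) ** 2),
                  [(-2, 2)] * 2, iterations=300, seed=2)
        assert res.fun < 1e-3

    def test_trace_monotone_and_bounds_respected(self):
        seen = []
        def obj(x):
            seen.append(x.copy())
            return float(np.sum(x ** 2))
        res = pso(obj, [(0.5, 2.0)] * 2, swarm_size=10, iterations=50, seed=3)
        assert np.all(np.diff(res.trace) <= 0)
        pts = np.array(seen)
        assert pts.min() >= 0.5 - 1e-12 and pts.max() <= 2.0 + 1e-12
        assert res.fun == pytest.approx(2 * 0.25)  # boundary optimum

    def test_seed_determinism(self):
        f = lambda x: float(np.sum(np.sin(x) + x ** 2))
        a = pso(f, [(-3, 3)] * 4, iterations=40, seed=9)
        b = pso(f, [(-3, 3)] * 4, iterations=40, seed=9)
        assert np.array_equal(a.x, b.x) and a.fun == b.fun

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pso(lambda x: 0.0, [(0, np.inf)])
        with pytest.raises(ValueError):
            pso(lambda x: 0.0, [(0, 1)], swarm_size=1)


class TestRunsTest:
    def test_alternating_signs_reject_randomness(self):
        h, p = runs_test([1, -1, 1, -1, 1, -1, 1, -1, 1, -1])
        assert h == 1
        # exact two-sided tail for n1 = n2 = 5, runs = 10
        assert p == pytest.approx(2 * 2 / 252, rel=1e-12)

    def test_two_runs_reject_randomness(self):
        h, p = runs_test([2, 2, 2, 2, 2, -2, -2, -2, -2, -2])
        assert h == 1 and p < 0.05

    def test_degenerate_one_sided_input(self):
        with pytest.raises(DegenerateResidualError):
            runs_test([1.0, 1.0, 1.0])

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (6, 6), (5, 7)])
    def test_exact_p_matches_exhaustive_enumeration(self, n1, n2):
        """For n ≤ 12 the combinatorial null must agree exactly with brute
        enumeration over all sign arrangements."""
        n = n1 + n2
        mu = 1 + 2 * n1 * n2 / n
        counts = {}
        for pos in itertools.combinations(range(n), n1):
            signs = np.full(n, -1)
            signs[list(pos)] = 1
            r = 1 + int(np.sum(signs[1:] != signs[:-1]))
            counts[r] = counts.get(r, 0) + 1
        total = sum(counts.values())
        for r_obs in sorted(counts):
            p_enum = sum(c for r, c in counts.items()
                         if abs(r - mu) >= abs(r_obs - mu) - 1e-12) / total
            x = [1.0 if s > 0 else -1.0 for s in
                 next(self._arrangement(n, n1, r_obs))]
            h, p = runs_test(x)
            assert p == pytest.approx(p_enum, abs=1e-12)
            assert h == (1 if p < 0.05 else 0)

    @staticmethod
    def _arrangement(n, n1, runs):
        for pos in itertools.combinations(range(n), n1):
            signs = np.full(n, -1)
            signs[list(pos)] = 1
            if 1 + int(np.sum(signs[1:] != signs[:-1])) == runs:
                yield signs
                return

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.sampled_from([-2.0, -1.0, 1.0, 2.0]), min_size=4, max_size=40))
    def test_contract_h_binary_p_in_unit_interval(self, xs):
        x = np.asarray(xs)
        if np.all(x - x.mean() >= 0) or np.all(x - x.mean() <= 0):
            with pytest.raises(DegenerateResidualError):
                runs_test(x)
        else:
            h, p = runs_test(x)
            assert h in (0, 1) and 0.0 <= p <= 1.0


@pytest.fixture(scope="module")
def cascade_setup():
    return TestStagedFit.make_setup()


class TestStagedFit:
    @staticmethod
    def make_setup():
        mc = fixtures.toy_network("mm-cascade")
        proto = StimulusProtocol(duration=24.0, pre_equilibrate_h=0.0)
        protos = {"normoxia+vegf50": proto, "normoxia+vegf10": proto, "hypoxia": proto}
        pred = make_model_predictor(mc, protos,
                                    condition_overrides={"normoxia+vegf10": {"E0": 0.2}})
        true = {"kcat1": 6e-3, "Km1": 0.25, "krev1": 1.2e-3,
                "kcat2": 1e-3, "Km2": 2.0, "krev2": 1.5e-4}
        base = {k: mc.parameters[k].value for k in true}
        groups = {"vegf": ["kcat1", "Km1", "krev1"],
                  "hypoxia": ["kcat2", "Km2", "krev2"]}
        times = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0)
        return mc, proto, pred, true, base, groups, times

    def _datasets(self, setup, sigma, seeds=(3, 4)):
        mc, proto, pred, true, base, groups, times = setup
        nm = (lambda s: fixtures.NoiseModel(sigma=sigma, seed=s)) if sigma else \
             (lambda s: fixtures.NoiseModel(kind="none"))
        ds_v = fixtures.generate_synthetic_timecourses(
            pred, {"normoxia+vegf50": proto, "normoxia+vegf10": proto},
            true, ["P", "S"], sample_times=times, noise=nm(seeds[0]))
        ds_h = fixtures.generate_synthetic_timecourses(
            pred, {"hypoxia": proto}, true, ["Y", "X"],
            sample_times=times, noise=nm(seeds[1]))
        return [ds_v, ds_h]

    def test_zero_noise_objective_near_zero(self, cascade_setup):
        mc, proto, pred, true, base, groups, times = cascade_setup
        fit = staged_fit(pred, self._datasets(cascade_setup, 0.0), groups, base,
                         seed=12, swarm_size=15, iterations=40)
        assert fit.objective < 1e-6

    def test_fit_never_worsens_baseline_objective(self, cascade_setup):
        mc, proto, pred, true, base, groups, times = cascade_setup
        data = self._datasets(cascade_setup, 0.05)
        fit = staged_fit(pred, data, groups, base, seed=5, swarm_size=10,
                         iterations=25)
        assert fit.objective <= weighted_ssr(pred, base, data) + 1e-12
        assert np.all(np.diff(fit.objective_trace[:25]) <= 0)
        for p, v in fit.values.items():
            lo, hi = fit.bounds[p]
            assert lo <= v <= hi

    def test_seed_determinism(self, cascade_setup):
        mc, proto, pred, true, base, groups, times = cascade_setup
        data = self._datasets(cascade_setup, 0.05)
        f1 = staged_fit(pred, data, groups, base, seed=21, swarm_size=8,
                        iterations=15, polish=False)
        f2 = staged_fit(pred, data, groups, base, seed=21, swarm_size=8,
                        iterations=15, polish=False)
        assert f1.values == f2.values

    def test_empty_group_skipped_with_warning(self, caplog):
        times = np.linspace(0.5, 10, 8)
        ds = fixtures.generate_synthetic_timecourses(
            analytic_predictor, {"c": StimulusProtocol(duration=10, pre_equilibrate_h=0)},
            {"k": 0.4}, ["y"], sample_times=times)
        with caplog.at_level("WARNING"):
            fit = staged_fit(analytic_predictor, ds, {"vegf": ["k"], "hypoxia": []},
                             {"k": 0.2}, seed=0, swarm_size=8, iterations=20)
        assert "skipped" in caplog.text
        assert fit.values["k"] == pytest.approx(0.4, rel=0.05)


class TestBootstrap:
    def _dataset(self, seed):
        times = np.linspace(0.5, 12, 10)
        frames = []
        for s in range(3):
            d = fixtures.generate_synthetic_timecourses(
                analytic_predictor,
                {"c": StimulusProtocol(duration=12, pre_equilibrate_h=0)},
                {"k": 0.4}, ["y"], sample_times=times,
                noise=fixtures.NoiseModel(sigma=0.05, seed=seed * 31 + s))
            d.records["source"] = f"study{s}"
            frames.append(d.records)
        ds = ExperimentalDataset(pd.concat(frames, ignore_index=True))
        ds.reweight_equal_groups()
        return ds

    def test_single_resample_reduces_to_one_refit(self):
        ds = self._dataset(0)
        fit = staged_fit(analytic_predictor, ds, {"vegf": ["k"]}, {"k": 0.1},
                         seed=0, swarm_size=8, iterations=20)
        band = bootstrap_uq(analytic_predictor, ds, fit, groups={"vegf": ["k"]},
                            n_boot=1, seed=0, swarm_size=6, iterations=10)
        t, lo, hi = band.interval("y", "c")
        assert np.array_equal(lo, hi)  # degenerate band from a single refit

    def test_band_contains_point_prediction(self):
        ds = self._dataset(1)
        fit = staged_fit(analytic_predictor, ds, {"vegf": ["k"]}, {"k": 0.1},
                         seed=1, swarm_size=8, iterations=20)
        band = bootstrap_uq(analytic_predictor, ds, fit, groups={"vegf": ["k"]},
                            n_boot=30, seed=1, swarm_size=6, iterations=12)
        t, lo, hi = band.interval("y", "c")
        yhat = band.point[band.point.observable == "y"]["value"].to_numpy()
        # percentile band brackets the point estimate up to refit scatter
        assert np.all(lo <= yhat + 1e-3) and np.all(yhat - 1e-3 <= hi)

    def test_invalid_arguments_rejected(self):
        ds = self._dataset(2)
        fit = staged_fit(analytic_predictor, ds, {"vegf": ["k"]}, {"k": 0.1},
                         seed=2, swarm_size=6, iterations=10)
        with pytest.raises(ValueError):
            bootstrap_uq(analytic_predictor, ds, fit, n_boot=0)
        with pytest.raises(ValueError):
            bootstrap_uq(analytic_predictor, ds, fit, level=1.5)


class TestCoverageFraction:
    def _band(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        table = pd.DataFrame({"observable": "y", "condition": "c", "time_h": t,
                              "lower": [0.1, 0.2, 0.3, 0.4],
                              "upper": [0.3, 0.4, 0.5, 0.6]})
        return calib.PredictionBand(table=table, level=0.95, n_boot=10, seed=0)

    def test_midpoints_fully_covered(self):
        band = self._band()
        rows = [(t, "y", v, "c", "s") for t, v in
                zip([0, 1, 2, 3], [0.2, 0.3, 0.4, 0.5])]
        ds = ExperimentalDataset.from_records(rows)
        assert coverage_fraction(band, ds) == 1.0

    def test_outside_data_not_covered(self):
        band = self._band()
        rows = [(t, "y", 0.95, "c", "s") for t in [0, 1, 2, 3]]
        ds = ExperimentalDataset.from_records(rows)
        assert coverage_fraction(band, ds) == 0.0

    def test_three_of_four_inside(self):
        band = self._band()
        rows = [(0.0, "y", 0.2, "c", "s"), (1.0, "y", 0.3, "c", "s"),
                (2.0, "y", 0.45, "c", "s"), (3.0, "y", 0.9, "c", "s")]
        ds = ExperimentalDataset.from_records(rows)
        assert coverage_fraction(band, ds) == pytest.approx(0.75)

    def test_no_matching_points_raises(self):
        band = self._band()
        rows = [(0.0, "other", 0.2, "c", "s")]
        ds = ExperimentalDataset.from_records(rows)
        with pytest.raises(DatasetError):
            coverage_fraction(band, ds)
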