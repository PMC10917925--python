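"""Simulation layer: integration, normalization, ECPI calls, experiments."""

import numpy as np
import pytest

import tipstalk as ts
from tipstalk.sim import (
    DegenerateNormalizationError,
    dll4_titration_experiment,
    default_time_grid,
    ecpi_timecourse,
    normalize_to_max,
    simulate,
)
from tipstalk.protocols import StimulusProtocol
from conftest import FAST_SOLVER, rel_diff


class TestNormalization:
    def test_example(self):
        assert normalize_to_max([2, 4, 1]).tolist() == [0.5, 1.0, 0.25]

    def test_constant_positive_series(self):
        assert normalize_to_max([3.0, 3.0, 3.0]).tolist() == [1.0, 1.0, 1.0]

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateNormalizationError):
            normalize_to_max([0.0, 0.0])
        with pytest.raises(DegenerateNormalizationError):
            normalize_to_max([])

    def test_idempotence_and_argmax_preservation(self, traj_differential):
        s = traj_differential.series("pVEGFR2_c1")
        n1 = normalize_to_max(s)
        assert np.array_equal(normalize_to_max(n1), n1)
        assert np.argmax(n1) == np.argmax(s)
        assert n1.max() == 1.0


class TestSimulate:
    def test_equal_stimulation_gives_identical_cells(self, traj_equal):
        for base in ("Hes1", "Dll4", "NICD", "pERK", "NO", "Ca"):
            assert rel_diff(traj_equal.series(f"{base}_c1"),
                            traj_equal.series(f"{base}_c2")) < 1e-8

    def test_relabeling_symmetry(self, two_cell_model, rhs, traj_differential):
        """Swapping the protocol's cells swaps the trajectories (up to solver
        roundoff: the two cell blocks are summed in different orders)."""
        proto = StimulusProtocol(vegf_cell1=0.0012, vegf_cell2=0.0006, duration=12.0)
        swapped = simulate(two_cell_model, proto.swapped(), rhs=rhs,
                           solver_options=dict(FAST_SOLVER))
        for base in ("Hes1", "Dll4", "NICD", "pERK", "NO"):
            assert rel_diff(traj_differential.series(f"{base}_c1"),
                            swapped.series(f"{base}_c2")) < 1e-7
            assert rel_diff(traj_differential.series(f"{base}_c2"),
                            swapped.series(f"{base}_c1")) < 1e-7

    def test_differential_vegf_marker_ordering(self, traj_differential):
        """The more stimulated cell keeps higher surface VEGFR2, pVEGFR2 and
        Dll4; the neighbour accumulates NICD and Hes1 (late window)."""
        late = traj_differential.time_h >= 9.0
        higher_in_c1 = ("VEGFR2", "pVEGFR2", "Dll4")
        higher_in_c2 = ("NICD", "Hes1")
        for base in higher_in_c1:
            assert traj_differential.series(f"{base}_c1")[late].mean() > \
                   traj_differential.series(f"{base}_c2")[late].mean()
        for base in higher_in_c2:
            assert traj_differential.series(f"{base}_c2")[late].mean() > \
                   traj_differential.series(f"{base}_c1")[late].mean()

    def test_events_apply_at_event_time(self, two_cell_model, rhs):
        proto = StimulusProtocol(vegf_cell1=0.0, vegf_cell2=0.0, duration=1.0,
                                 pre_equilibrate_h=0.0,
                                 events=[(0.5, "Dll4_c2", 5.0)])
        traj = simulate(two_cell_model, proto, rhs=rhs,
                        solver_options=dict(FAST_SOLVER))
        d = traj.series("Dll4_c2")
        before = d[traj.time_h < 0.5]
        at = d[np.argmin(np.abs(traj.time_h - 0.5))]
        assert before.max() < 1.0
        assert at == pytest.approx(5.0, rel=1e-6)

    def test_bad_time_grid_rejected(self, two_cell_model, rhs):
        proto = StimulusProtocol(duration=1.0)
        with pytest.raises(ValueError):
            simulate(two_cell_model, proto, t_grid=np.array([0.0, 2.0]), rhs=rhs)
        with pytest.raises(ValueError):
            simulate(two_cell_model, proto, t_grid=np.array([0.5, 0.25]), rhs=rhs)

    def test_default_grid_resolution_rule(self):
        assert np.diff(default_time_grid(2.0))[0] == pytest.approx(1 / 60)
        assert np.diff(default_time_grid(12.0))[0] == pytest.approx(5 / 60)

    def test_solver_tolerance_robustness(self, two_cell_model, rhs, traj_differential):
        """Halving tolerances moves the 12 h ECPI by far less than 0.5%."""
        tight = simulate(two_cell_model,
                         StimulusProtocol(vegf_cell1=0.0012, vegf_cell2=0.0006,
                                          duration=12.0),
                         rhs=rhs,
                         solver_options={"method": "BDF", "rtol": 5e-9, "atol": 5e-13})
        r0 = ecpi_timecourse(traj_differential)
        r1 = ecpi_timecourse(tight)
        assert abs(r0.ecpi_c1[-1] - r1.ecpi_c1[-1]) / r0.ecpi_c1[-1] < 0.005
        assert abs(r0.ecpi_c2[-1] - r1.ecpi_c2[-1]) / r0.ecpi_c2[-1] < 0.005


class TestEcpiTimecourse:
    def test_differential_calls_tip_and_stalk(self, traj_differential):
        rep = ecpi_timecourse(traj_differential)
        assert rep.calls == {"c1": "tip", "c2": "stalk"}
        assert rep.mean_c1 < rep.mean_c2

    def test_equal_stimulation_is_undifferentiated(self, traj_equal):
        rep = ecpi_timecourse(traj_equal)
        assert rep.calls["c1"] == rep.calls["c2"] == "undifferentiated"
        assert rep.separation < 0.05

    def test_dapt_abolishes_patterning(self, traj_dapt):
        rep = ecpi_timecourse(traj_dapt)
        assert rep.calls["c1"] == rep.calls["c2"] == "undifferentiated"

    def test_dapt_suppresses_nicd_and_hes1(self, traj_differential, traj_dapt):
        for base in ("NICD", "Hes1"):
            for cell in ("c1", "c2"):
                assert traj_dapt.series(f"{base}_{cell}").max() < \
                       0.2 * traj_differential.series(f"{base}_{cell}").max()

    def test_undefined_index_when_dll4_absent(self, two_cell_model, rhs):
        # without VEGF, Dll4 stays at zero and the index is undefined
        proto = StimulusProtocol(vegf_cell1=0.0, vegf_cell2=0.0, duration=1.0,
                                 pre_equilibrate_h=0.0)
        traj = simulate(two_cell_model, proto, rhs=rhs,
                        solver_options=dict(FAST_SOLVER))
        with pytest.raises(ts.UndefinedIndexError):
            ecpi_timecourse(traj)


class TestHypoxia:
    def test_hif_arm_upregulated_without_patterning(self, traj_normoxia_basal,
                                                    traj_hypoxia_basal):
        for base in ("HIF1a", "HIF2a", "mVEGFA"):
            fold = traj_hypoxia_basal.series(f"{base}_c1")[-1] / \
                traj_normoxia_basal.series(f"{base}_c1")[-1]
            assert fold > 2.0
        rep = ecpi_timecourse(traj_hypoxia_basal)
        assert rep.calls["c1"] == rep.calls["c2"] == "undifferentiated"

    def test_hypoxia_with_differential_vegf_still_patterns(self, two_cell_model, rhs):
        proto = StimulusProtocol(vegf_cell1=0.00012, vegf_cell2=0.00006,
                                 o2=9.95, duration=12.0)
        rep = ecpi_timecourse(simulate(two_cell_model, proto, rhs=rhs,
                                       solver_options=dict(FAST_SOLVER)))
        assert rep.calls == {"c1": "tip", "c2": "stalk"}

    def test_hypoxia_reduces_free_enos(self, traj_normoxia_basal, traj_hypoxia_basal):
        assert traj_hypoxia_basal.series("eNOS_c1")[-1] < \
            traj_normoxia_basal.series("eNOS_c1")[-1]


@pytest.fixture(scope="module")
def titration(two_cell_model, rhs):
    return dll4_titration_experiment(two_cell_model, (0.0, 2.0, 20.0),
                                     solver_options=dict(FAST_SOLVER), rhs=rhs)


class TestDll4Titration:

    def test_symmetric_at_zero_dll4(self, titration):
        tr = titration[0.0]
        assert rel_diff(tr.series("NO_c1"), tr.series("NO_c2")) < 1e-8

    def test_dll4_activates_notch_in_neighbour(self, titration):
        early = titration[2.0].time_h <= 0.5
        assert titration[2.0].series("NICD_c1")[early].max() > \
            10 * titration[0.0].series("NICD_c1")[early].max()

    def test_cell1_no_release_monotone_nonincreasing(self, titration):
        late_means = []
        for level in (0.0, 2.0, 20.0):
            tr = titration[level]
            late = tr.time_h >= 1.5
            late_means.append(tr.series("NO_c1")[late].mean())
        assert late_means[0] >= late_means[1] * (1 - 1e-9)
        assert late_means[1] >= late_means[2] * (1 - 1e-9)
        assert late_means[2] < late_means[0]

    def test_negative_level_rejected(self, two_cell_model, rhs):
        with pytest.raises(ValueError):
            dll4_titration_experiment(two_cell_model, (-1.0,), rhs=rhs)
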