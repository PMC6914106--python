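"""Category classification, TAU/DTx transitions, attrition, and the cohort
trajectories."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dtxecon as dx
from dtxecon.cohort import attrition_masses, tau_transition_matrix
from dtxecon.parameters import ParameterError

from conftest import make_null_effect


class TestClassifyBiomarker:
    @pytest.mark.parametrize("disease, value, category", [
        ("t2dm", 5.0, 1), ("t2dm", 6.4, 1), ("t2dm", 6.5, 2), ("t2dm", 7.49, 2),
        ("t2dm", 7.5, 3), ("t2dm", 9.0, 3),   # printed "7.5% to 9.0%" is inclusive
        ("t2dm", 9.01, 4), ("t2dm", 13.0, 4),
        ("htn", 119.9, 1), ("htn", 120.0, 2), ("htn", 129.9, 2),
        ("htn", 130.0, 3), ("htn", 139.9, 3), ("htn", 140.0, 4),
    ])
    def test_boundary_convention(self, disease, value, category):
        assert dx.classify_biomarker(disease, value) == category

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -1.0, 0.0])
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ValueError):
            dx.classify_biomarker("t2dm", bad)


class TestTauTransition:
    def test_full_persistence_is_identity(self):
        np.testing.assert_allclose(
            dx.tau_transition([0.1, 0.2, 0.3, 0.4], persistence=1.0),
            [0.1, 0.2, 0.3, 0.4])

    def test_symmetric_adjacent_spill(self):
        np.testing.assert_allclose(
            dx.tau_transition([0, 1, 0, 0], persistence=0.8),
            [0.1, 0.8, 0.1, 0.0])

    def test_end_categories_reflect_inward(self):
        np.testing.assert_allclose(
            dx.tau_transition([0, 0, 0, 1], persistence=0.8), [0, 0, 0.2, 0.8])

    @given(raw=st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
           persistence=st.floats(0.0, 1.0))
    @settings(max_examples=50, derandomize=True)
    def test_conserves_mass(self, raw, persistence):
        dist = np.array(raw) / np.sum(raw)
        out = dx.tau_transition(dist, persistence)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        assert (out >= -1e-12).all()

    def test_diagonal_mass_at_least_persistence(self):
        M = tau_transition_matrix(0.8)
        assert (np.diag(M) >= 0.8 - 1e-12).all()


class TestDtxTransition:
    def test_identity_table(self, t2dm):
        t2dm.synthesis.responder_fraction_y1 = 0.0
        t2dm.synthesis.mean_change_y1 = 0.0
        table = dx.synthesize_transition_tables(t2dm)
        dist = np.array([0.0, 0.47, 0.34, 0.19])
        np.testing.assert_allclose(dx.dtx_transition(dist, 1, table), dist)

    def test_year1_responder_mass_reaches_improved_categories(self, params):
        table = dx.synthesize_transition_tables(params)
        e = params.enrollment_distribution
        out = dx.dtx_transition(e, 1, table)
        # everyone improving >= 1 category leaves their enrollment category
        moved = sum(e[c] * table.year1[c, :c].sum() for c in range(4))
        assert moved == pytest.approx(params.synthesis.responder_fraction_y1, abs=1e-9)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_missing_year_rejected(self, t2dm):
        table = dx.synthesize_transition_tables(t2dm)
        with pytest.raises(ParameterError, match="no year"):
            table.matrix_for_year(4)


class TestAttrition:
    def test_retention_path_from_printed_rates(self):
        np.testing.assert_allclose(
            dx.AttritionSchedule().retained_by_year(), [0.64, 0.576, 0.5184])

    def test_cumulative_year1_withdrawal_is_36_percent(self):
        retained, withdrawn, month = attrition_masses(dx.AttritionSchedule())[0]
        assert withdrawn == pytest.approx(0.36)
        assert month == 3.0

    def test_zero_attrition_leaves_masses_unchanged(self, disease):
        p = dx.default_parameters(disease)
        p.attrition = dx.AttritionSchedule(y1_early=0.0, y1_late=0.0, y2=0.0, y3=0.0)
        traj = dx.simulate_cohort(p, "DTX_TAU")
        np.testing.assert_allclose(traj.retained(), [1.0, 1.0, 1.0])
        for st_ in traj.years.values():
            assert st_.new_withdrawn_mass == 0.0

    @pytest.mark.parametrize("bump", [0.1, 0.3, 0.5])
    def test_more_early_attrition_weakly_lowers_every_year(self, bump):
        base = dx.AttritionSchedule().retained_by_year()
        bumped = dx.AttritionSchedule(y1_early=0.20 + bump).retained_by_year()
        assert (bumped <= base + 1e-12).all()

    def test_apply_attrition_sets_return_distribution(self, t2dm):
        traj = dx.simulate_cohort(t2dm, "DTX_TAU")
        tau = dx.tau_transition(t2dm.enrollment_distribution, 0.8)
        traj = dx.apply_attrition(traj, t2dm.attrition, 1, tau)
        np.testing.assert_allclose(traj.years[1].withdrawn_distribution,
                                   t2dm.enrollment_distribution)
        traj = dx.apply_attrition(traj, t2dm.attrition, 2, tau)
        np.testing.assert_allclose(traj.years[2].withdrawn_distribution, tau)


class TestSimulateCohort:
    def test_tau_arm_is_stationary_persistence_of_enrollment(self, params):
        traj = dx.simulate_cohort(params, "TAU")
        expected = dx.tau_transition(params.enrollment_distribution,
                                     params.tau_persistence)
        for y in (1, 2, 3):
            np.testing.assert_allclose(traj.years[y].active_distribution, expected)
            assert traj.years[y].retained_fraction == 1.0

    def test_dtx_retention_matches_schedule(self, params):
        traj = dx.simulate_cohort(params, "DTX_TAU")
        np.testing.assert_allclose(traj.retained(), [0.64, 0.576, 0.5184])

    def test_mass_conservation_every_year(self, params):
        for arm in ("TAU", "DTX_TAU"):
            traj = dx.simulate_cohort(params, arm)
            for y, state in traj.years.items():
                total = sum(s.mass * s.year_fraction for s in state.segments)
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_mass_conservation_on_random_parameter_sets(self, disease):
        for seed in range(5):
            p = dx.random_parameter_set(disease, seed=seed)
            traj = dx.simulate_cohort(p, "DTX_TAU")
            for state in traj.years.values():
                total = sum(s.mass * s.year_fraction for s in state.segments)
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_null_effect_trajectories_identical(self, disease):
        p = make_null_effect(disease)
        tau = dx.simulate_cohort(p, "TAU")
        dtx = dx.simulate_cohort(p, "DTX_TAU")
        for y in (1, 2, 3):
            np.testing.assert_allclose(dtx.years[y].active_distribution,
                                       tau.years[y].active_distribution)
            for seg in dtx.years[y].segments:
                np.testing.assert_allclose(seg.distribution,
                                           p.enrollment_distribution)

    def test_synthesis_disabled_raises_clear_error(self, t2dm):
        t2dm.allow_synthesis = False
        with pytest.raises(ParameterError, match="transition_tables"):
            dx.simulate_cohort(t2dm, "DTX_TAU")

    def test_unknown_arm_rejected(self, t2dm):
        with pytest.raises(ParameterError, match="arm"):
            dx.simulate_cohort(t2dm, "placebo")
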