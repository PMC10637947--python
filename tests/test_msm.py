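"""Multistate-model core: generators, probabilities, likelihood, fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from sarcomsm.msm import (DEFAULT_STRUCTURE, PanelDataset, TransitionStructure,
                          build_intensity_matrix, crude_rates, fit_msm,
                          goodness_of_fit, hazard_ratios,
                          observed_transition_table, panel_log_likelihood,
                          predict_probability_ci, sojourn_times,
                          transition_probability, validate_intensity_matrix)
from sarcomsm.reference import REFERENCE_INTENSITIES, reference_intensity_matrix

from conftest import (brute_force_log_likelihood, random_generator_matrix,
                      uniformization_probability)


class TestIntensityMatrix:
    def test_diagonal_is_negative_row_sum(self):
        Q = build_intensity_matrix(DEFAULT_STRUCTURE,
                                   {(1, 2): 0.176, (1, 3): 0.043, (1, 4): 0.013})
        assert Q[0, 0] == pytest.approx(-0.232)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_all_zero_values(self):
        Q = build_intensity_matrix(DEFAULT_STRUCTURE, {})
        assert np.all(Q == 0)

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            build_intensity_matrix(DEFAULT_STRUCTURE, {(1, 2): -0.1})

    def test_disallowed_transition_rejected(self):
        with pytest.raises(ValueError):
            build_intensity_matrix(DEFAULT_STRUCTURE, {(4, 1): 0.1})

    def test_structure_rejects_absorbing_exit(self):
        with pytest.raises(ValueError):
            TransitionStructure(n_states=3, transitions=((3, 1),),
                                absorbing=frozenset({3}))

    def test_validate_flags_structural_zero_violation(self):
        Q = reference_intensity_matrix()
        Q[3, 0] = 0.1
        Q[3, 3] = -0.1
        with pytest.raises(ValueError):
            validate_intensity_matrix(Q, DEFAULT_STRUCTURE)


class TestTransitionProbability:
    def test_zero_time_is_identity(self, reference_Q):
        assert np.allclose(transition_probability(reference_Q, 0.0), np.eye(4))

    def test_negative_time_rejected(self, reference_Q):
        with pytest.raises(ValueError):
            transition_probability(reference_Q, -0.5)

    def test_two_state_closed_form(self):
        S = TransitionStructure(2, ((1, 2),), frozenset({2}))
        Q = build_intensity_matrix(S, {(1, 2): 0.5})
        P = transition_probability(Q, 2.0)
        assert P[0, 0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_published_one_year_probability(self, reference_Q):
        P = transition_probability(reference_Q, 1.0)
        assert P[0, 1] == pytest.approx(0.127, abs=0.005)

    def test_rows_sum_to_one_and_entries_in_range(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            Q = random_generator_matrix(rng)
            P = transition_probability(Q, rng.uniform(0, 5))
            assert np.abs(P.sum(axis=1) - 1).max() < 1e-8
            assert P.min() >= -1e-12

    def test_chapman_kolmogorov(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            Q = random_generator_matrix(rng)
            t, s = rng.uniform(0.1, 3, size=2)
            lhs = transition_probability(Q, t + s)
            rhs = transition_probability(Q, t) @ transition_probability(Q, s)
            assert np.abs(lhs - rhs).max() < 1e-8

    def test_agrees_with_uniformization_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            Q = random_generator_matrix(rng)
            t = rng.uniform(0.1, 4)
            assert np.abs(transition_probability(Q, t)
                          - uniformization_probability(Q, t)).max() < 1e-8

    def test_absorbing_row_is_unit_vector(self, reference_Q):
        P = transition_probability(reference_Q, 3.0)
        assert np.allclose(P[3], [0, 0, 0, 1], atol=1e-12)


class TestSojournTimes:
    def test_published_possible_sarcopenia_sojourn(self, reference_Q):
        soj = sojourn_times(reference_Q)
        assert soj[2] == pytest.approx(1 / 0.461, abs=1e-12)
        assert soj[2] == pytest.approx(2.17, abs=0.02)

    def test_reciprocal_of_exit_rate(self):
        Q = build_intensity_matrix(DEFAULT_STRUCTURE, {(1, 2): 0.25})
        assert sojourn_times(Q)[1] == 4.0

    def test_zero_exit_rate_is_infinite(self):
        Q = build_intensity_matrix(DEFAULT_STRUCTURE, {(2, 1): 0.5})
        soj = sojourn_times(Q)
        assert np.isinf(soj[1]) and 4 not in soj


class TestPanelLogLikelihood:
    def test_single_interval_closed_form(self, two_state_structure):
        df = pd.DataFrame({"subject_id": ["a", "a"], "time": [0.0, 1.0],
                           "state": [1, 1], "death_exact": [False, False]})
        ds = PanelDataset.from_frame(df, structure=two_state_structure)
        ll = panel_log_likelihood(np.log([0.7]), ds, two_state_structure,
                                  exact_death=False)
        assert ll == pytest.approx(-0.7, abs=1e-12)

    def test_empty_dataset_is_zero(self):
        df = pd.DataFrame({"subject_id": [], "time": [], "state": []})
        ds = PanelDataset.from_frame(df)
        assert panel_log_likelihood(np.log(np.full(9, 0.1)), ds) == 0.0

    @pytest.mark.parametrize("exact_death", [False, True])
    def test_matches_brute_force_oracle(self, exact_death):
        """100 random toy trajectories, likelihood vs per-interval expm loop."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            Q = random_generator_matrix(rng, scale=0.4)
            logq = np.log([Q[r - 1, s - 1] for r, s in DEFAULT_STRUCTURE.transitions])
            n_obs = rng.integers(2, 5)
            times = np.cumsum(rng.uniform(0.3, 2.0, size=n_obs))
            states = [int(rng.integers(1, 4))]
            for _ in range(n_obs - 1):
                if states[-1] == 4:
                    break
                states.append(int(rng.integers(1, 5)))
            times = times[: len(states)]
            if len(states) < 2:
                continue
            df = pd.DataFrame({"subject_id": "a", "time": times, "state": states})
            ds = PanelDataset.from_frame(df)
            ll = panel_log_likelihood(logq, ds, exact_death=exact_death)
            oracle = brute_force_log_likelihood(Q, ds.intervals(), exact_death)
            assert ll == pytest.approx(oracle, rel=1e-10, abs=1e-10)

    def test_three_interval_trajectory_oracle(self, toy_panel, reference_Q):
        logq = np.log([reference_Q[r - 1, s - 1]
                       for r, s in DEFAULT_STRUCTURE.transitions])
        ll = panel_log_likelihood(logq, toy_panel, exact_death=True)
        oracle = brute_force_log_likelihood(reference_Q, toy_panel.intervals(),
                                            exact_death=True)
        assert ll == pytest.approx(oracle, rel=1e-12)

    def test_zero_length_interval_rejected(self):
        df = pd.DataFrame({"subject_id": ["a", "a"], "time": [1.0, 1.0],
                           "state": [1, 2]})
        with pytest.raises(ValueError):
            PanelDataset.from_frame(df)


def _two_state_panel(n, k, structure):
    """n subjects observed over a unit interval; k end absorbed."""
    rows = []
    for i in range(n):
        rows.append({"subject_id": f"s{i}", "time": 0.0, "state": 1,
                     "death_exact": False})
        rows.append({"subject_id": f"s{i}", "time": 1.0,
                     "state": 2 if i < k else 1, "death_exact": False})
    return PanelDataset.from_frame(pd.DataFrame(rows), structure=structure)


class TestFitMsm:
    def test_closed_form_mle_two_state(self, two_state_structure):
        ds = _two_state_panel(100, 50, two_state_structure)
        model = fit_msm(ds, structure=two_state_structure, exact_death=False)
        lam = model.intensity_matrix()[0, 1]
        assert model.converged
        assert lam == pytest.approx(-np.log(0.5), abs=1e-4)

    def test_deterministic_given_data(self, two_state_structure):
        ds = _two_state_panel(60, 20, two_state_structure)
        m1 = fit_msm(ds, structure=two_state_structure, exact_death=False)
        m2 = fit_msm(ds, structure=two_state_structure, exact_death=False)
        assert np.array_equal(m1.params, m2.params)

    def test_boundary_flagged_when_no_transitions(self, two_state_structure):
        ds = _two_state_panel(40, 0, two_state_structure)
        with pytest.warns(UserWarning):
            model = fit_msm(ds, structure=two_state_structure, exact_death=False)
        assert model.intensity_matrix()[0, 1] < 1e-5
        assert not model.converged

    def test_init_matrix_accepted(self, two_state_structure):
        ds = _two_state_panel(100, 50, two_state_structure)
        Q0 = build_intensity_matrix(two_state_structure, {(1, 2): 0.3})
        model = fit_msm(ds, structure=two_state_structure, init=Q0,
                        exact_death=False)
        assert model.intensity_matrix()[0, 1] == pytest.approx(-np.log(0.5), abs=1e-4)


class TestHazardRatios:
    @staticmethod
    def _model_with(beta, se):
        from sarcomsm.msm import FittedModel
        effects = (("x", ((1, 2),)),)
        params = np.concatenate([np.log(np.full(9, 0.1)), [beta]])
        cov = np.zeros((10, 10))
        cov[9, 9] = se**2
        return FittedModel(structure=DEFAULT_STRUCTURE, params=params,
                           covariance=cov, log_likelihood=0.0, converged=True,
                           n_iter=1, n_subjects=1, n_intervals=1,
                           covariate_effects=effects)

    def test_null_beta_with_se(self):
        hr = hazard_ratios(self._model_with(0.0, 0.1)).iloc[0]
        assert hr["hr"] == 1.0
        assert hr["lower"] == pytest.approx(np.exp(-1.96 * 0.1), abs=2e-4)
        assert hr["upper"] == pytest.approx(np.exp(1.96 * 0.1), abs=2e-4)

    def test_degenerate_zero_se(self):
        hr = hazard_ratios(self._model_with(0.0, 0.0)).iloc[0]
        assert (hr["hr"], hr["lower"], hr["upper"]) == (1.0, 1.0, 1.0)

    def test_monotone_in_beta(self):
        hrs = [hazard_ratios(self._model_with(b, 0.1))["hr"].iloc[0]
               for b in (-0.5, 0.0, 0.4, 1.0)]
        assert all(a < b for a, b in zip(hrs, hrs[1:]))

    def test_no_covariance_flagged(self):
        m = self._model_with(0.3, 0.1)
        m.covariance = None
        hr = hazard_ratios(m)
        assert not hr.attrs["has_ci"] and np.isnan(hr["se"].iloc[0])


class TestPredictProbabilityCI:
    def test_zero_variance_collapses_to_point(self, two_state_structure):
        ds = _two_state_panel(100, 50, two_state_structure)
        model = fit_msm(ds, structure=two_state_structure, exact_death=False)
        model.covariance = np.zeros_like(model.covariance)
        point, lo, hi = predict_probability_ci(model, 1.0, n_draws=200, seed=1)
        assert np.allclose(point, lo) and np.allclose(point, hi)

    def test_reproducible_given_seed(self, two_state_structure):
        ds = _two_state_panel(100, 50, two_state_structure)
        model = fit_msm(ds, structure=two_state_structure, exact_death=False)
        a = predict_probability_ci(model, 1.0, n_draws=300, seed=7)
        b = predict_probability_ci(model, 1.0, n_draws=300, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_small_draws_warns(self, two_state_structure):
        ds = _two_state_panel(100, 50, two_state_structure)
        model = fit_msm(ds, structure=two_state_structure, exact_death=False)
        with pytest.warns(UserWarning, match="n_draws"):
            predict_probability_ci(model, 1.0, n_draws=50, seed=1)


class TestCrudeRates:
    def test_hand_counted_toy_panel(self, toy_panel):
        rates = crude_rates(toy_panel.data[["subject_id", "time", "state"]])
        # origin 1: intervals a(0-2), a? no: a 0->2y from 1, a 2->4 from 2,
        # b 0->2 from 1; person-years in 1 = 2+2 = 4; events 1->2: 1
        r12 = rates[(rates["from"] == 1) & (rates["to"] == 2)].iloc[0]
        assert r12["person_years"] == 4.0
        assert r12["events"] == 1
        assert r12["rate_per_100py"] == pytest.approx(100 * 1 / 4.0)
        # origin 2: a 2->4y, c 0->2y: 4 PY; events 2->1: 1, 2->3: 1
        r21 = rates[(rates["from"] == 2) & (rates["to"] == 1)].iloc[0]
        assert r21["person_years"] == 4.0 and r21["events"] == 1
        r34 = rates[(rates["from"] == 3) & (rates["to"] == 4)].iloc[0]
        assert r34["person_years"] == 1.0
        assert r34["rate_per_100py"] == pytest.approx(100.0)

    def test_no_events_zero_rate(self):
        df = pd.DataFrame({"subject_id": ["a", "a"], "time": [0, 2], "state": [1, 1]})
        rates = crude_rates(df)
        assert (rates["rate_per_100py"] == 0).all()


class TestObservedTransitionTable:
    def test_published_column_percentages(self):
        """Counts with the published no-sarcopenia column reproduce 71.9 etc."""
        from sarcomsm.reference import REFERENCE_TRANSITION_COUNTS
        rows = []
        i = 0
        for (r, s), n in REFERENCE_TRANSITION_COUNTS.items():
            for _ in range(n):
                rows.append({"subject_id": f"p{i}", "time": 0.0, "state": r})
                rows.append({"subject_id": f"p{i}", "time": 2.0, "state": s})
                i += 1
        table = observed_transition_table(pd.DataFrame(rows))
        col = table.percentages[1].round(1)
        assert list(col.loc[[1, 2, 3, 4]]) == [71.9, 19.1, 5.6, 3.4]
        assert table.counts[1].sum() == 3062
        assert table.total_pairs == sum(REFERENCE_TRANSITION_COUNTS.values())

    def test_single_pair_is_100_percent(self):
        df = pd.DataFrame({"subject_id": ["a", "a"], "time": [0, 2], "state": [1, 3]})
        table = observed_transition_table(df)
        assert table.percentages.loc[3, 1] == 100.0

    def test_column_totals_conserve_pairs(self, toy_panel):
        table = observed_transition_table(toy_panel.data[["subject_id", "time", "state"]])
        assert table.total_pairs == len(toy_panel.intervals())


class TestGoodnessOfFit:
    def test_baseline_expected_equals_observed(self, toy_panel, reference_Q):
        logq = np.log([reference_Q[r - 1, s - 1]
                       for r, s in DEFAULT_STRUCTURE.transitions])
        from sarcomsm.msm import FittedModel
        model = FittedModel(structure=DEFAULT_STRUCTURE, params=logq,
                            covariance=None, log_likelihood=0.0, converged=True,
                            n_iter=0, n_subjects=3, n_intervals=5)
        gof = goodness_of_fit(model, toy_panel, [0.0])
        at0 = gof[gof["time"] == 0]
        assert np.allclose(at0["observed"], at0["expected"])

    def test_absorbing_expected_monotone_in_time(self, toy_panel, reference_Q):
        logq = np.log([reference_Q[r - 1, s - 1]
                       for r, s in DEFAULT_STRUCTURE.transitions])
        from sarcomsm.msm import FittedModel
        model = FittedModel(structure=DEFAULT_STRUCTURE, params=logq,
                            covariance=None, log_likelihood=0.0, converged=True,
                            n_iter=0, n_subjects=3, n_intervals=5)
        gof = goodness_of_fit(model, toy_panel, [0.0, 2.0, 3.0])
        dead = gof[gof["state"] == 4].sort_values("time")
        frac = dead["expected"].to_numpy() / np.maximum(
            gof.groupby("time")["observed"].sum().to_numpy(), 1)
        assert np.all(np.diff(frac) >= -1e-12)

    def test_late_eval_time_warns(self, toy_panel, reference_Q):
        logq = np.log([reference_Q[r - 1, s - 1]
                       for r, s in DEFAULT_STRUCTURE.transitions])
        from sarcomsm.msm import FittedModel
        model = FittedModel(structure=DEFAULT_STRUCTURE, params=logq,
                            covariance=None, log_likelihood=0.0, converged=True,
                            n_iter=0, n_subjects=3, n_intervals=5)
        with pytest.warns(UserWarning, match="beyond follow-up"):
            goodness_of_fit(model, toy_panel, [10.0])
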