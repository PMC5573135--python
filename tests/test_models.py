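"""Observer-model formulas, trial selection, and fitting procedures."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import catrep
from catrep.models import (
    ALPHA_BOUNDS,
    NonIdentifiableBoundError,
    PredictionSeries,
    SIGMA_FLOOR,
    UnderdeterminedCategoryError,
    VARIANCE_FLOOR,
    test_region_probs as transfer_region_probs,
    training_region_probs,
)
from catrep.protocol import Session, Trial, record_response


def _series(p_region, observed):
    p = np.asarray(p_region, dtype=float)
    y = np.asarray(observed, dtype=int)
    return PredictionSeries(
        trial_index=np.arange(1, len(p) + 1),
        label=np.array(["B"] * len(p), dtype=object),
        p_region=p,
        p_response=None,
        observed=y,
    )


def _generative_density_params(kind="RB"):
    s = catrep.make_structure(kind)
    if kind == "RB":
        return catrep.DensityModelParams(
            mode="univariate",
            means={lab: s.means[lab][1:] for lab in "ABCD"},
            covs={lab: s.covs[lab][1:, 1:] for lab in "ABCD"},
        )
    return catrep.DensityModelParams(
        mode="bivariate",
        means=dict(s.means),
        covs=dict(s.covs),
    )


class TestDensityRegionProb:
    def test_generative_rb_value(self):
        # f_B(0.67) / (f_B(0.67) + f_A(0.67)) with A, B normal(0.30, 0.01),
        # normal(0.67, 0.01): the A density is down by exp(-(0.37)^2 / 0.02).
        params = _generative_density_params("RB")
        p = catrep.density_region_prob(params, np.array([1.9, 0.67]), ("B", "A"))
        expected = 1.0 / (1.0 + np.exp(-(0.37**2) / (2 * 0.01)))
        assert p == pytest.approx(expected, abs=1e-6)
        assert p == pytest.approx(0.9989, abs=2e-4)

    def test_equidistant_stimulus_is_half(self):
        params = _generative_density_params("RB")
        mid = np.array([1.9, (0.30 + 0.67) / 2])
        assert catrep.density_region_prob(params, mid, ("A", "B")) == pytest.approx(0.5)

    def test_vanishing_alternative_density_forces_one(self):
        params = _generative_density_params("RB")
        far = np.array([1.9, 0.30])  # 3.7 SDs below the B mean, 37 below D
        assert catrep.density_region_prob(params, far, ("A", "D")) == pytest.approx(1.0)

    def test_complements_sum_to_one(self):
        params = _generative_density_params("II")
        rng = np.random.default_rng(3)
        pts = rng.normal([1.7, 1.7], 0.5, size=(50, 2))
        p_b = catrep.density_region_prob(params, pts, ("B", "C"))
        p_c = catrep.density_region_prob(params, pts, ("C", "B"))
        np.testing.assert_allclose(p_b + p_c, 1.0, atol=1e-12)

    def test_midpoint_switch_matches_optimal_bound(self):
        # With equal variances and alpha -> inf the implied A/B decision flips
        # exactly at the midpoint of the means (the optimal linear bound).
        params = _generative_density_params("RB")
        mid = (0.30 + 0.67) / 2
        below = catrep.density_region_prob(params, np.array([0.0, mid - 1e-6]), ("A", "B"))
        above = catrep.density_region_prob(params, np.array([0.0, mid + 1e-6]), ("A", "B"))
        assert below > 0.5 > above


class TestBoundaryRegionProbs:
    @pytest.fixture
    def params(self):
        return catrep.BoundaryModelParams(
            projection_axis=np.array([0.0, 1.0]),
            c_ab=0.485,
            sigma_ab=0.1,
            c_cd=1.215,
            sigma_cd=0.1,
        )

    def test_stimulus_at_bound_is_half(self, params):
        p = catrep.boundary_region_prob_train(params, np.array([0.0, 0.485]), ("A", "B"))
        assert p == pytest.approx(0.5)

    def test_far_side_limits(self, params):
        ds = np.column_stack([np.zeros(5), np.linspace(0.485, -0.5, 5)])
        p = catrep.boundary_region_prob_train(params, ds, ("A", "B"))
        assert np.all(np.diff(p) > 0) and p[-1] > 0.999

    def test_train_complement_identity(self, params):
        ds = np.column_stack([np.zeros(9), np.linspace(-1, 2.5, 9)])
        p_a = catrep.boundary_region_prob_train(params, ds, ("A", "B"))
        np.testing.assert_allclose(p_a + (1 - p_a), 1.0, atol=1e-15)

    def test_test_symmetric_point_is_half(self, params):
        # F_AB(d) = 1 - F_CD(d) at the midpoint of two equal-noise bounds.
        mid = np.array([0.0, (0.485 + 1.215) / 2])
        assert catrep.boundary_region_prob_test(params, mid) == pytest.approx(0.5)

    def test_test_forced_value(self):
        # When F_CD = 1 (nothing left on the C side) and F_AB = 0.5, the B
        # probability is forced to 0.5 / (0.5 + 0) = 1.
        params = catrep.BoundaryModelParams(
            projection_axis=np.array([0.0, 1.0]),
            c_ab=0.485,
            sigma_ab=0.1,
            c_cd=-5.0,
            sigma_cd=0.001,
        )
        at_ab = np.array([0.0, 0.485])
        assert catrep.boundary_region_prob_test(params, at_ab) == pytest.approx(1.0, abs=1e-8)

    def test_test_complement_identity(self, params):
        ds = np.column_stack([np.zeros(9), np.linspace(-0.5, 2.2, 9)])
        p_b = catrep.boundary_region_prob_test(params, ds)
        assert np.all((p_b >= 0) & (p_b <= 1))

    def test_degenerate_zero_over_zero_is_half(self):
        # Bounds oriented so that below AB and above CD overlap nowhere:
        # F_AB = 0 and 1 - F_CD = 0 far below both bounds is impossible for
        # ordered bounds, so swap them to force the 0/0 region.
        params = catrep.BoundaryModelParams(
            projection_axis=np.array([0.0, 1.0]),
            c_ab=10.0,
            sigma_ab=0.001,
            c_cd=-10.0,
            sigma_cd=0.001,
        )
        p = catrep.boundary_region_prob_test(params, np.array([0.0, 0.0]))
        assert p == pytest.approx(0.5)


class TestDecisionProb:
    def test_alpha_zero_is_guessing(self):
        assert catrep.decision_prob(0.9, 0.1, 0.0) == pytest.approx(0.5)
        assert catrep.decision_prob(1.0, 0.0, 0.0) == pytest.approx(0.5)

    def test_equal_region_probs_are_guessing(self):
        for alpha in (0.5, 5.0, 50.0):
            assert catrep.decision_prob(0.4, 0.4, alpha) == pytest.approx(0.5)

    def test_hand_value(self):
        # alpha=2, p_CX=1, p_CY=0: e^2 / (e^2 + 1)
        expected = np.exp(2) / (np.exp(2) + 1)
        assert catrep.decision_prob(1.0, 0.0, 2.0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.8808, abs=1e-4)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            catrep.decision_prob(0.5, 0.5, -1.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        p=st.floats(0, 1),
        c=st.floats(-0.3, 0.3),
        alpha=st.floats(0.01, 50),
    )
    def test_depends_only_on_difference(self, p, c, alpha):
        q = 1 - p
        base = catrep.decision_prob(p, q, alpha)
        if 0 <= p + c <= 1 and 0 <= q + c <= 1:
            shifted = catrep.decision_prob(p + c, q + c, alpha)
            assert shifted == pytest.approx(base, abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(alpha=st.floats(0.1, 50), seed=st.integers(0, 1000))
    def test_strictly_increasing_in_p_cx(self, alpha, seed):
        rng = np.random.default_rng(seed)
        ps = np.sort(rng.uniform(0, 1, size=5))
        vals = catrep.decision_prob(ps, 1 - ps, alpha)
        assert np.all(np.diff(vals) > 0)


class TestFitAlpha:
    def test_saturating_case_hits_upper_bound(self):
        series = _series([1.0] * 20, [1] * 20)
        alpha, sse = catrep.fit_alpha(series)
        assert alpha == ALPHA_BOUNDS[1]
        assert sse == pytest.approx(20 * (1 - catrep.decision_prob(1, 0, 50)) ** 2)

    def test_single_trial_monotone_sse(self):
        series = _series([0.8], [1])
        grid = np.arange(0, 50.0001, 0.01)
        sses = [(1 - catrep.decision_prob(0.8, 0.2, a)) ** 2 for a in grid]
        assert np.all(np.diff(sses) < 0)
        alpha, _ = catrep.fit_alpha(series)
        assert alpha == ALPHA_BOUNDS[1]

    def test_coin_flip_responses_give_small_alpha(self):
        rng = np.random.default_rng(12)
        n = 1000
        p = rng.uniform(0, 1, size=n)
        y = rng.integers(0, 2, size=n)
        alpha, sse = catrep.fit_alpha(_series(p, y))
        assert alpha < 1.0
        assert sse == pytest.approx(n / 4, rel=0.05)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_exhaustive_grid(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        p = rng.uniform(0, 1, size=n)
        y = (rng.uniform(size=n) < p).astype(int)
        series = _series(p, y)
        alpha, sse = catrep.fit_alpha(series)
        grid = np.arange(0.0, 50.0 + 1e-9, 1e-3)
        pr = 1.0 / (1.0 + np.exp(-np.outer(grid, 2 * p - 1)))
        grid_sse = ((y - pr) ** 2).sum(axis=1)
        k = int(np.argmin(grid_sse))
        assert sse <= grid_sse[k] + 1e-9
        assert abs(alpha - grid[k]) < 1e-3 or sse < grid_sse[k] + 1e-9

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            catrep.fit_alpha(_series([], []))


class TestRmsd:
    def test_perfect_predictions(self):
        s = _series([1.0, 0.0, 1.0], [1, 0, 1]).with_alpha(50.0)
        s.p_response = s.observed.astype(float)
        assert catrep.rmsd(s) == 0.0

    def test_constant_half(self):
        s = _series([0.5] * 10, [1, 0] * 5)
        s.p_response = np.full(10, 0.5)
        assert catrep.rmsd(s) == pytest.approx(0.5)

    def test_hand_case(self):
        s = _series([0, 0, 0], [1, 0, 1])
        s.p_response = np.array([0.9, 0.2, 0.6])
        assert catrep.rmsd(s) == pytest.approx(np.sqrt(0.21 / 3), abs=1e-12)
        assert catrep.rmsd(s) == pytest.approx(0.2646, abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            catrep.rmsd(_series([], []))


class TestSelectFittingTrials:
    def test_yn_density_selects_target_yes(self, within_rb_yn_session):
        trials = catrep.select_fitting_trials(within_rb_yn_session, "density", "A")
        assert trials
        assert all(t.target == "A" and t.response == "yes" for t in trials)

    def test_ab_density_selects_pressed_button(self, within_rb_ab_session):
        trials = catrep.select_fitting_trials(within_rb_ab_session, "density", "A")
        assert trials
        assert all(t.implied_category == "A" for t in trials)

    def test_ab_boundary_selects_pair_presses(self, within_rb_ab_session):
        trials = catrep.select_fitting_trials(
            within_rb_ab_session, "boundary", ("A", "B")
        )
        assert trials
        assert all(t.implied_category in ("A", "B") for t in trials)

    def test_yn_boundary_selects_pair_questions(self, within_rb_yn_session):
        trials = catrep.select_fitting_trials(
            within_rb_yn_session, "boundary", ("C", "D")
        )
        assert trials
        assert all(t.target in ("C", "D") for t in trials)

    def test_never_pressed_category_is_empty(self, within_rb_ab_session):
        session = copy.deepcopy(within_rb_ab_session)
        for t in session.trials:
            if t.implied_category == "A" and t.is_pair_question:
                record_response(t, "B")
        assert catrep.select_fitting_trials(session, "density", "A") == []


class TestFitDensityParams:
    def test_recovers_generative_means(self, within_rb_ab_session):
        params = catrep.fit_density_params(within_rb_ab_session)
        gen = {"A": 0.30, "B": 0.67, "C": 1.03, "D": 1.40}
        for lab, target in gen.items():
            if params.counts[lab] >= 20:
                assert params.means[lab][0] == pytest.approx(target, abs=0.08)

    def test_underdetermined_category_raises(self, within_rb_yn_session):
        session = copy.deepcopy(within_rb_yn_session)
        for t in session.trials:
            if t.phase == "train" and t.target == "C" and t.response == "yes":
                record_response(t, "no")
        with pytest.raises(UnderdeterminedCategoryError) as exc:
            catrep.fit_density_params(session)
        assert "C" in exc.value.labels

    def test_identical_stimuli_hit_variance_floor(self):
        # Hand-built fragment: every A-press sits at the same dim2 value.
        trials = []
        for i in range(1, 13):
            lab = "A" if i % 2 else "B"
            t = Trial(
                index=i,
                block=4,
                phase="train",
                question="A|B",
                dim1=1.9 + 0.01 * i,
                dim2=0.3 if lab == "A" else 0.6 + 0.01 * i,
                true_category=lab,
            )
            record_response(t, lab)
            trials.append(t)
        session = Session("p", "AB", "RB", seed=0, trials=trials)
        params = catrep.fit_density_params(
            session, trial_window=(1, 12), required=("A", "B")
        )
        assert params.covs["A"][0, 0] == VARIANCE_FLOOR
        assert "variance_floor:A" in params.flags

    def test_ii_mode_is_bivariate(self):
        cohort = catrep.simulate_cohort("II", "AB", 1, 0, seed=5)
        params = catrep.fit_density_params(cohort.sessions[0])
        assert params.mode == "bivariate"
        assert params.means["B"].shape == (2,)
        assert params.covs["B"].shape == (2, 2)


class TestFitBoundaryParams:
    @staticmethod
    def _policy_session(c_ab, c_cd, sigma, seed=0):
        """Fill an RB A/B schedule from a known cumulative-Gaussian policy."""
        from scipy.special import ndtr

        session = copy.deepcopy(catrep.build_schedule("RB", "AB", seed=seed))
        rng = np.random.default_rng(seed + 1)
        for t in session.trials:
            pair = t.question_pair()
            c = c_ab if pair == ("A", "B") else c_cd
            if t.phase == "test":
                continue
            p_upper = float(ndtr((t.dim2 - c) / sigma))
            record_response(t, pair[1] if rng.random() < p_upper else pair[0])
        return session

    def test_recovers_known_policy(self):
        session = self._policy_session(c_ab=0.485, c_cd=1.215, sigma=0.1, seed=3)
        params = catrep.fit_boundary_params(session, trial_window=(1, 500))
        assert params.c_ab == pytest.approx(0.485, abs=0.05)
        assert params.c_cd == pytest.approx(1.215, abs=0.05)
        assert params.sigma_ab == pytest.approx(0.1, rel=0.5)
        assert params.sigma_cd == pytest.approx(0.1, rel=0.5)

    def test_off_center_criterion_recovered(self):
        session = self._policy_session(c_ab=0.85, c_cd=1.215, sigma=0.1, seed=3)
        params = catrep.fit_boundary_params(session, trial_window=(1, 500))
        assert params.c_ab == pytest.approx(0.85, abs=0.05)

    def test_separable_responses_floor_sigma(self):
        session = copy.deepcopy(catrep.build_schedule("RB", "AB", seed=4))
        for t in session.training_trials():
            pair = t.question_pair()
            c = 0.485 if pair == ("A", "B") else 1.215
            record_response(t, pair[1] if t.dim2 > c else pair[0])
        params = catrep.fit_boundary_params(session, trial_window=(1, 500))
        assert params.sigma_ab == pytest.approx(SIGMA_FLOOR, rel=1e-3)
        zs = [t.dim2 for t in session.training_trials() if t.question == "A|B"]
        assert min(zs) < params.c_ab < max(zs)

    def test_all_one_response_not_identifiable(self):
        session = copy.deepcopy(catrep.build_schedule("RB", "AB", seed=4))
        for t in session.training_trials():
            record_response(t, t.question_pair()[0])
        with pytest.raises(NonIdentifiableBoundError):
            catrep.fit_boundary_params(session, trial_window=(1, 500))


class TestSeriesConstruction:
    def test_training_series_covers_window(self, within_rb_ab_session):
        params = catrep.fit_density_params(within_rb_ab_session)
        series = training_region_probs(within_rb_ab_session, params)
        assert len(series) == 200
        assert series.trial_index.min() >= 301 and series.trial_index.max() <= 500
        assert np.all((series.p_region >= 0) & (series.p_region <= 1))

    def test_test_series_is_block6(self, within_rb_ab_session):
        params = catrep.fit_boundary_params(within_rb_ab_session)
        series = transfer_region_probs(within_rb_ab_session, params)
        assert len(series) == 100
        assert series.trial_index.min() == 501

    def test_response_prob_monotone_in_region_prob(self, within_rb_ab_session):
        params = catrep.fit_density_params(within_rb_ab_session)
        series = training_region_probs(within_rb_ab_session, params).with_alpha(8.0)
        order = np.argsort(series.p_region)
        assert np.all(np.diff(series.p_response[order]) >= 0)
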