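"""Tuning-curve fits, BIC responsiveness and selectivity indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from v1energy.tuning import (
    DoubleGaussianTuning,
    AnimalSummary,
    angdir,
    bic_score,
    collapse_directions,
    compute_dsi,
    compute_osi,
    double_gaussian,
    fit_double_gaussian,
    select_spatial_frequency,
    summarize_animal,
)

DIRECTIONS = np.arange(0.0, 360.0, 30.0)


class TestAngdir:
    @pytest.mark.parametrize(
        "x,expected",
        [(0, 0), (180, 180), (190, 170), (350, 10), (-30, 30), (360, 0), (540, 180)],
    )
    def test_examples(self, x, expected):
        assert angdir(x) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-720, 720, allow_nan=False))
    def test_range_and_periodicity(self, x):
        d = angdir(x)
        assert 0.0 <= d <= 180.0
        assert d == pytest.approx(angdir(x + 360.0), abs=1e-9)
        assert d == pytest.approx(angdir(-x), abs=1e-9)


class TestDoubleGaussian:
    def test_peak_value_closed_form(self):
        sigma = 30.0
        val = double_gaussian(90.0, 0.1, 1.0, 0.4, 90.0, sigma)
        assert val == pytest.approx(0.1 + 1.0 + 0.4 * np.exp(-(180.0**2) / (2 * sigma**2)))

    def test_flat_when_amplitudes_zero(self):
        assert np.allclose(double_gaussian(DIRECTIONS, 0.25, 0.0, 0.0, 90.0, 30.0), 0.25)

    def test_null_lobe_sits_opposite_the_preferred(self):
        vals = double_gaussian(DIRECTIONS, 0.0, 1.0, 0.5, 90.0, 20.0)
        assert vals[DIRECTIONS == 90.0] == pytest.approx(1.0, abs=1e-8)
        assert vals[DIRECTIONS == 270.0] == pytest.approx(0.5, abs=1e-8)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            double_gaussian(0.0, 0.0, 1.0, 0.0, 0.0, 0.0)


class TestBicScore:
    @pytest.mark.parametrize(
        "n,mean_rss,k,expected",
        [
            (12, 1.0, 0, 0.0),
            (12, 1.0, 5, 5 * np.log(12)),
            (12, np.e, 0, 12.0),
        ],
    )
    def test_direct_arithmetic(self, n, mean_rss, k, expected):
        assert bic_score(n, mean_rss, k) == pytest.approx(expected, abs=1e-12)

    def test_perfect_fit_is_floored_finite(self):
        assert np.isfinite(bic_score(12, 0.0, 5))

    def test_rejects_negative_rss(self):
        with pytest.raises(ValueError):
            bic_score(12, -1.0, 0)


class TestFit:
    def test_noiseless_parameter_recovery(self):
        truth = dict(c=0.1, rp=1.0, rn=0.4, theta_pref=90.0, sigma=30.0)
        y = double_gaussian(DIRECTIONS, *truth.values())
        fit = fit_double_gaussian(DIRECTIONS, y)
        assert fit.c == pytest.approx(truth["c"], abs=1e-3)
        assert fit.rp == pytest.approx(truth["rp"], abs=1e-3)
        assert fit.rn == pytest.approx(truth["rn"], abs=1e-3)
        assert fit.theta_pref == pytest.approx(truth["theta_pref"], abs=1e-3)
        assert fit.sigma == pytest.approx(truth["sigma"], abs=1e-3)
        assert fit.responsive

    def test_flat_zero_responses_are_not_responsive(self):
        fit = fit_double_gaussian(DIRECTIONS, np.zeros_like(DIRECTIONS))
        assert not fit.responsive

    def test_bic_margin_is_inclusive_at_ten(self):
        # a synthetic fit record at exactly the threshold counts as responsive
        est = DoubleGaussianTuning(bic_margin=10.0)
        y = double_gaussian(DIRECTIONS, 0.0, 1.0, 0.2, 60.0, 30.0)
        est.fit(DIRECTIONS, y)
        assert est.fit_.delta_bic >= 10.0 and est.responsive_
        # the decision rule itself: delta exactly 10 -> responsive
        assert (10.0 >= est.bic_margin) is True

    def test_trial_level_input_matches_direction_mean_parameters(self, rng):
        y_means = double_gaussian(DIRECTIONS, 0.05, 1.2, 0.3, 120.0, 25.0)
        theta_trials = np.repeat(DIRECTIONS, 5)
        y_trials = np.repeat(y_means, 5)
        f_means = fit_double_gaussian(DIRECTIONS, y_means)
        f_trials = fit_double_gaussian(theta_trials, y_trials)
        assert f_trials.theta_pref == pytest.approx(f_means.theta_pref, abs=1e-6)
        assert f_trials.rp == pytest.approx(f_means.rp, abs=1e-6)
        assert f_trials.n_obs == 60 and f_means.n_obs == 12

    def test_needs_six_directions(self):
        with pytest.raises(ValueError):
            fit_double_gaussian([0, 45, 90, 135, 180], np.ones(5))

    def test_sklearn_params_roundtrip(self):
        est = DoubleGaussianTuning(bic_margin=7.0)
        assert est.get_params()["bic_margin"] == 7.0
        est.set_params(sigma_starts=(20.0,))
        assert est.get_params()["sigma_starts"] == (20.0,)


class TestSelectivity:
    def test_osi_worked_example(self):
        osi = compute_osi([0, 30, 60, 90, 120, 150], [2, 1, 0, 0, 0, 1])
        assert osi == pytest.approx(0.75, abs=1e-12)

    def test_osi_equal_responses_is_zero(self):
        assert compute_osi(np.arange(0, 180, 30), np.ones(6)) == pytest.approx(0.0, abs=1e-12)

    def test_osi_single_nonzero_is_one(self):
        assert compute_osi(np.arange(0, 180, 30), [0, 0, 1, 0, 0, 0]) == pytest.approx(1.0)

    def test_dsi_worked_example(self):
        dsi = compute_dsi([0.0, 90.0], [1.0, 0.5])
        assert dsi == pytest.approx(np.abs(1 + 0.5j) / 1.5, abs=1e-12)

    def test_dsi_opposite_directions_cancel(self):
        assert compute_dsi([0.0, 180.0], [1.0, 1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_dsi_single_nonzero_is_one(self):
        assert compute_dsi(DIRECTIONS, [0] * 11 + [1]) == pytest.approx(1.0)

    def test_negative_responses_zeroed(self):
        # the negative entry must not contribute to either sum
        with_neg = compute_osi([0, 30, 60, 90, 120, 150], [2, -5, 0, 0, 0, 1])
        without = compute_osi([0, 30, 60, 90, 120, 150], [2, 0, 0, 0, 0, 1])
        assert with_neg == pytest.approx(without, abs=1e-12)

    def test_all_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            compute_osi([0, 30, 60], [-1, 0, -2])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0.01, 10.0), min_size=6, max_size=6),
        st.floats(0.1, 100.0),
        st.floats(-180.0, 180.0),
    )
    def test_bounds_scale_and_rotation_invariance(self, responses, scale, rotation):
        theta = np.arange(0, 180, 30.0)
        r = np.asarray(responses)
        osi = compute_osi(theta, r)
        assert 0.0 <= osi <= 1.0 + 1e-12
        assert compute_osi(theta, scale * r) == pytest.approx(osi, abs=1e-9)
        assert compute_osi(theta + rotation, r) == pytest.approx(osi, abs=1e-9)
        dsi = compute_dsi(theta, r)
        assert 0.0 <= dsi <= 1.0 + 1e-12
        assert compute_dsi(theta, scale * r) == pytest.approx(dsi, abs=1e-9)


def _table(rows):
    return pd.DataFrame(rows, columns=["neuron", "direction_deg", "sf_cpd", "trial", "response"])


class TestTableOps:
    def test_sf_argmax(self):
        rows = [("n1", 0.0, sf, 0, resp) for sf, resp in
                [(0.02, 0.1), (0.04, 0.3), (0.16, 0.2), (0.32, 0.05)]]
        assert select_spatial_frequency(_table(rows), "n1") == 0.04

    def test_sf_tie_breaks_low(self):
        rows = [("n1", 0.0, 0.04, 0, 0.3), ("n1", 0.0, 0.16, 0, 0.3)]
        assert select_spatial_frequency(_table(rows), "n1") == 0.04

    def test_sf_single(self):
        rows = [("n1", 0.0, 0.32, 0, 0.1)]
        assert select_spatial_frequency(_table(rows), "n1") == 0.32

    def test_collapse_pairs_opposite_directions(self):
        rows = [("n1", 0.0, 0.04, 0, 0.4), ("n1", 180.0, 0.04, 0, 0.2)]
        omeans = collapse_directions(_table(rows), "n1", 0.04)
        assert omeans.loc[0.0] == pytest.approx(0.3)

    def test_collapse_full_direction_set_groupby_oracle(self, rng):
        resp = rng.normal(0.5, 0.2, size=len(DIRECTIONS))
        rows = [("n1", d, 0.04, 0, r) for d, r in zip(DIRECTIONS, resp)]
        omeans = collapse_directions(_table(rows), "n1", 0.04)
        assert len(omeans) == 6
        for ori in omeans.index:  # independent group-by-mod-180 average
            members = [r for d, r in zip(DIRECTIONS, resp) if d % 180 == ori]
            assert len(members) == 2
            assert omeans.loc[ori] == pytest.approx(np.mean(members), abs=1e-12)

    def test_collapse_constant_responses(self):
        rows = [("n1", d, 0.04, 0, 0.7) for d in DIRECTIONS]
        omeans = collapse_directions(_table(rows), "n1", 0.04)
        assert np.allclose(omeans, 0.7)


class _Sel:
    def __init__(self, osi, dsi, responsive):
        self.osi, self.dsi, self.responsive = osi, dsi, responsive


class TestAnimalSummary:
    def test_single_neuron(self):
        s = summarize_animal([_Sel(0.6, 0.3, True)], "m1", "male", "CTR")
        assert s.median_osi == 0.6 and s.n_responsive == 1

    def test_odd_count_median(self):
        sels = [_Sel(o, o / 2, True) for o in (0.2, 0.6, 1.0)]
        assert summarize_animal(sels).median_osi == 0.6

    def test_nonresponsive_excluded_before_median(self):
        # hand-checked 5-neuron fixture: responsive OSIs {0.1, 0.5, 0.9} -> 0.5
        sels = [
            _Sel(0.1, 0.1, True), _Sel(0.5, 0.2, True), _Sel(0.9, 0.3, True),
            _Sel(0.99, 0.9, False), _Sel(0.98, 0.8, False),
        ]
        s = summarize_animal(sels, "m2", "female", "FR")
        assert s.median_osi == pytest.approx(0.5)
        assert s.n_responsive == 3

    def test_no_responsive_neurons_rejected(self):
        with pytest.raises(ValueError):
            summarize_animal([_Sel(0.5, 0.5, False)], "m3")
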