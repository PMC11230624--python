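"""Synthetic-data generators: determinism, ground-truth round trips."""

import numpy as np
import pytest

from v1energy.simulate import (
    CellSpec,
    CohortSpec,
    NeuronGroundTruth,
    SimulationConfig,
    leptin_cohort_spec,
    simulate_cohort,
    simulate_fret_experiment,
    simulate_grating_session,
    simulate_pupil_video,
)
from v1energy.traces import DffTraceSet, extract_grating_response
from v1energy.tuning import double_gaussian


class TestGratingSession:
    def test_unresponsive_noiseless_traces_are_constant(self):
        config = SimulationConfig(seed=1, n_trials=1, sfs=(0.04,))
        truth = NeuronGroundTruth(c=0.0, rp=0.0, rn=0.0, responsive=False)
        traces, _ = simulate_grating_session(config, [truth])
        assert np.allclose(traces.fluorescence, config.baseline_fluorescence)

    def test_same_seed_bitwise_identical(self):
        config = SimulationConfig(seed=42, n_trials=2, sfs=(0.04,))
        truths = [NeuronGroundTruth(noise=0.1, trial_noise=0.1, theta_pref=45.0)]
        a, pa = simulate_grating_session(config, truths)
        b, pb = simulate_grating_session(config, truths)
        assert np.array_equal(a.fluorescence, b.fluorescence)
        assert pa.events.equals(pb.events)

    def test_noiseless_roundtrip_matches_generating_curve(self, noiseless_session):
        # oracle: evaluate the generating double Gaussian at each direction
        s = noiseless_session
        dff = DffTraceSet(
            dff=s["true_dff"], f0=np.full(3, 100.0), frame_rate=s["config"].frame_rate
        )
        tab = extract_grating_response(dff, s["protocol"])
        for i, truth in enumerate(s["truths"]):
            sub = tab[(tab["neuron"] == f"roi{i:03d}") & (tab["sf_cpd"] == truth.sf_pref)]
            means = sub.groupby("direction_deg")["response"].mean()
            expected = double_gaussian(
                means.index.to_numpy(), truth.c, truth.rp, truth.rn,
                truth.theta_pref, truth.sigma,
            )
            assert np.max(np.abs(means.to_numpy() - expected)) < 1e-6

    def test_off_preference_sf_attenuated(self, noiseless_session):
        s = noiseless_session
        dff = DffTraceSet(
            dff=s["true_dff"], f0=np.full(3, 100.0), frame_rate=s["config"].frame_rate
        )
        tab = extract_grating_response(dff, s["protocol"])
        truth = s["truths"][0]
        sub = tab[tab["neuron"] == "roi000"]
        at_pref = sub[sub["sf_cpd"] == truth.sf_pref]
        off_pref = sub[sub["sf_cpd"] != truth.sf_pref]
        peak_dir = truth.theta_pref
        r_pref = at_pref[at_pref["direction_deg"] == peak_dir]["response"].mean()
        r_off = off_pref[off_pref["direction_deg"] == peak_dir]["response"].mean()
        assert r_off == pytest.approx(0.5 * r_pref, abs=1e-6)

    def test_protocol_lists_every_event(self):
        config = SimulationConfig(seed=3, n_trials=3, sfs=(0.04, 0.16))
        truths = [NeuronGroundTruth()]
        _, protocol = simulate_grating_session(config, truths)
        assert len(protocol) == 12 * 3 * 2
        counts = protocol.events.groupby(["direction_deg", "sf_cpd"]).size()
        assert (counts == 3).all()

    def test_empty_truths_rejected(self):
        with pytest.raises(ValueError):
            simulate_grating_session(SimulationConfig(seed=1), [])

    def test_empty_directions_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, directions=())

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            NeuronGroundTruth(rp=0.1, rn=0.5)  # rn > rp
        with pytest.raises(ValueError):
            NeuronGroundTruth(rp=1.0, rn=0.0, responsive=False)


class TestFretGenerator:
    def test_default_trial_count_is_33(self):
        exp = simulate_fret_experiment(8.0)
        assert len(exp.times_min) == 33
        assert exp.n_baseline == 3 and exp.n_post == 30

    def test_nonpositive_half_time_rejected(self):
        with pytest.raises(ValueError):
            simulate_fret_experiment(0.0)
        with pytest.raises(ValueError):
            simulate_fret_experiment(-3.0)

    def test_degenerate_plateau_separation_rejected(self):
        with pytest.raises(ValueError):
            simulate_fret_experiment(8.0, baseline_ratio=1.0, plateau_ratio=1.0)
        with pytest.raises(ValueError):
            simulate_fret_experiment(8.0, baseline_ratio=np.inf)

    def test_unreachable_half_time_rejected(self):
        with pytest.raises(ValueError, match="plateau"):
            simulate_fret_experiment(20.0, post_trials=30)

    def test_determinism(self):
        a = simulate_fret_experiment(8.0, noise=0.05, seed=9)
        b = simulate_fret_experiment(8.0, noise=0.05, seed=9)
        assert np.array_equal(a.ratios, b.ratios)

    def test_baseline_is_flat(self):
        exp = simulate_fret_experiment(8.0, noise=0.0)
        assert np.allclose(exp.ratios[:3], exp.ratios[0])
        assert np.all(exp.times_min[:3] < 0)


class TestPupilGenerator:
    def test_determinism(self):
        a, _ = simulate_pupil_video((15, 10), noise=5.0, seed=4, frame_count=3)
        b, _ = simulate_pupil_video((15, 10), noise=5.0, seed=4, frame_count=3)
        assert np.array_equal(a, b)

    def test_truth_diameter_formula(self):
        _, truth = simulate_pupil_video((20, 5))
        assert truth.diameter == pytest.approx(2 * np.sqrt(20 * 5))

    def test_pupil_must_fit_frame(self):
        with pytest.raises(ValueError, match="bounds"):
            simulate_pupil_video((120, 120), frame_shape=(200, 200))

    def test_minimum_diameter_enforced(self):
        with pytest.raises(ValueError, match=">= 4"):
            simulate_pupil_video((1.5, 1.5))


class TestCohortGenerator:
    def test_zero_dispersion_gives_cell_means(self):
        spec = CohortSpec(
            endpoint="e",
            cells={
                ("male", "CTR"): CellSpec(5.0, 0.0, 3),
                ("male", "FR"): CellSpec(2.0, 0.0, 3),
                ("female", "CTR"): CellSpec(4.0, 0.0, 3),
                ("female", "FR"): CellSpec(3.0, 0.0, 3),
            },
        )
        tab = simulate_cohort(spec, seed=0)
        got = tab.groupby(["sex", "diet"])["value"].unique()
        assert got[("male", "CTR")] == [5.0]
        assert got[("female", "FR")] == [3.0]

    def test_leptin_fixture_has_70_rows_with_exact_cell_counts(self):
        tab = simulate_cohort(leptin_cohort_spec(), seed=5)
        assert len(tab) == 70
        counts = tab.groupby(["sex", "diet"]).size()
        assert counts[("male", "CTR")] == 17 and counts[("male", "FR")] == 19
        assert counts[("female", "CTR")] == 23 and counts[("female", "FR")] == 11

    def test_large_n_sample_mean_converges(self):
        spec = CohortSpec(endpoint="e", cells={("male", "CTR"): CellSpec(6.45, 2.0, 10_000)})
        tab = simulate_cohort(spec, seed=7)
        # law of large numbers: SEM = 0.02, allow 4 SEM
        assert tab["value"].mean() == pytest.approx(6.45, abs=0.08)

    def test_small_cell_rejected(self):
        with pytest.raises(ValueError):
            CellSpec(1.0, 0.5, 1)

    def test_determinism(self):
        a = simulate_cohort(leptin_cohort_spec(), seed=3)
        b = simulate_cohort(leptin_cohort_spec(), seed=3)
        assert a.equals(b)
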