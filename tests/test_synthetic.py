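import numpy as np
import pytest
from scipy import signal as sps

import ibp
from ibp.synthetic import (
    CohortSpec,
    PlantedEvent,
    SignalSpec,
    make_background,
    make_coupled_epoch,
    make_electrode_layout,
    measure_rates,
    simulate_cohort,
)


class TestBackground:
    def test_length_and_determinism(self):
        spec = SignalSpec(duration_s=300, fs=1000, seed=5)
        x = make_background(spec)
        assert x.shape == (300_000,)
        assert np.allclose(x.mean(), 0, atol=1e-9)
        np.testing.assert_array_equal(x, make_background(spec))

    def test_spectral_slope_is_minus_alpha(self):
        # log-log Welch slope over 10 realizations should sit near -1
        slopes = []
        for seed in range(10):
            x = make_background(SignalSpec(duration_s=60, seed=seed))
            f, pxx = sps.welch(x, fs=1000, nperseg=4096)
            sel = (f > 1) & (f < 400)
            slopes.append(np.polyfit(np.log(f[sel]), np.log(pxx[sel]), 1)[0])
        assert abs(np.mean(slopes) + 1.0) < 0.2

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SignalSpec(duration_s=-1)
        with pytest.raises(ValueError):
            SignalSpec(fs=500)  # cannot represent the 80-300 Hz band


class TestInjection:
    def test_oscillation_duration_and_locality(self, short_background, fs):
        ev = PlantedEvent("oscillation", t0=5.0, f0=120, n_cycles=8, amplitude=50)
        assert ev.duration_s == pytest.approx(8 / 120)
        y = ibp.inject_oscillation(short_background, ev, fs)
        diff = np.abs(y - short_background)
        t = np.arange(diff.size) / fs
        outside = (t < 4.9) | (t > 5.2)
        assert diff[outside].max() == 0.0
        assert diff[~outside].max() > 0

    def test_zero_amplitude_is_identity(self, short_background, fs):
        ev = PlantedEvent("oscillation", t0=2.0, f0=100, n_cycles=8, amplitude=0)
        np.testing.assert_array_equal(
            ibp.inject_oscillation(short_background, ev, fs), short_background
        )
        ev2 = PlantedEvent("sharp_transient", t0=2.0, amplitude=0, width_ms=30)
        np.testing.assert_array_equal(
            ibp.inject_sharp_transient(short_background, ev2, fs), short_background
        )

    def test_out_of_bounds_event_rejected(self, short_background, fs):
        ev = PlantedEvent("oscillation", t0=9.99, f0=100, n_cycles=8, amplitude=10)
        with pytest.raises(ValueError):
            ibp.inject_oscillation(short_background, ev, fs)

    def test_transient_rings_in_band_but_is_not_oscillatory(self, fs):
        # the high-pass filtering confound: the band-passed transient stands
        # far out of the band-passed background
        spec = SignalSpec(duration_s=10, seed=3)
        x = make_background(spec)
        ev = PlantedEvent("sharp_transient", t0=5.0, amplitude=300, width_ms=30)
        y = ibp.inject_sharp_transient(x, ev, fs)
        bp = ibp.bandpass_zero_phase(y - x, 80, 300, fs)
        bg = ibp.bandpass_zero_phase(x, 80, 300, fs)
        assert np.abs(bp).max() > 5 * bg.std()

    def test_event_kind_validation(self):
        with pytest.raises(ValueError):
            PlantedEvent("oscillation", t0=0, f0=50, n_cycles=8)  # below band
        with pytest.raises(ValueError):
            PlantedEvent("oscillation", t0=0, f0=100, n_cycles=2)
        with pytest.raises(ValueError):
            PlantedEvent("wiggle", t0=0)


class TestCoupledEpoch:
    def test_dominant_slow_peak_at_requested_frequency(self):
        spec = SignalSpec(duration_s=60, noise_sd=0, seed=0)
        x = make_coupled_epoch(spec, slow_f=3.5, mod_depth=0.5)
        f, pxx = sps.welch(x, fs=1000, nperseg=8192)
        low = f < 10
        assert abs(f[low][np.argmax(pxx[low])] - 3.5) < 0.2

    def test_mod_depth_validation(self):
        spec = SignalSpec(duration_s=10, noise_sd=0)
        with pytest.raises(ValueError):
            make_coupled_epoch(spec, mod_depth=1.5)
        with pytest.raises(ValueError):
            make_coupled_epoch(spec, slow_f=5.0)


class TestLayout:
    def test_masks_consistent_and_deterministic(self):
        lay = make_electrode_layout(100, seed=1)
        assert len(lay) == 100
        derived = ~(lay["soz"] | lay["lesion"] | lay["spiking"])
        np.testing.assert_array_equal(lay["non_epileptic"], derived)
        ok = ~lay["artifact"]
        assert (lay["resected"] & ok).any() and (~lay["resected"] & ok).any()
        lay2 = make_electrode_layout(100, seed=1)
        assert lay.equals(lay2)

    def test_distinct_coordinates(self):
        lay = make_electrode_layout(50, seed=2)
        coords = lay[["x_mm", "y_mm", "z_mm"]].to_numpy()
        from scipy.spatial.distance import pdist

        assert pdist(coords).min() > 0

    def test_incomplete_resection_spares_soz(self):
        lay = make_electrode_layout(60, seed=3, resect_soz_fully=False)
        assert (lay["soz"] & ~lay["resected"]).any()
        lay2 = make_electrode_layout(60, seed=3, resect_soz_fully=True)
        assert not (lay2["soz"] & ~lay2["resected"]).any()


class TestCohort:
    def test_determinism_and_truth_recovery(self):
        spec = CohortSpec(n_patients=10, seed=7)
        a, b = simulate_cohort(spec), simulate_cohort(spec)
        assert a.clinical.equals(b.clinical)
        # outcome probabilities recomputable exactly from the stored design
        lin = a.intercept + a.design.to_numpy() @ a.true_beta
        np.testing.assert_allclose(
            1 / (1 + np.exp(-lin)), a.clinical["success_prob"], rtol=1e-12
        )

    def test_null_cohort_success_rate_matches_target(self):
        # with all coefficients zero the success probability is constant at
        # the target rate; the empirical rate is binomial around it
        spec = CohortSpec(n_patients=135, true_beta=np.zeros(11), seed=11)
        c = simulate_cohort(spec)
        assert np.allclose(c.clinical["success_prob"], spec.target_success_rate)
        p = spec.target_success_rate
        se = np.sqrt(p * (1 - p) / 135)
        assert abs(c.clinical["success"].mean() - p) < 4 * se

    def test_biomarker_effect_direction(self):
        # strongly positive biomarker coefficient: complete resection of
        # high-rate territory must raise the success frequency
        beta = np.zeros(11)
        beta[-1] = 5.0
        agg = {"hi": [], "lo": []}
        c = simulate_cohort(CohortSpec(n_patients=200, true_beta=beta, seed=13))
        med = c.clinical["subtraction_biomarker"].median()
        hi = c.clinical[c.clinical["subtraction_biomarker"] > med]["success"].mean()
        lo = c.clinical[c.clinical["subtraction_biomarker"] <= med]["success"].mean()
        assert hi > lo

    def test_epileptic_channels_have_elevated_rates(self):
        c = simulate_cohort(CohortSpec(n_patients=5, epileptic_rate_multiplier=5, seed=2))
        p = c.patients[0]
        epi = ~p.layout["non_epileptic"].to_numpy()
        assert p.true_rate[epi].mean() > 2 * p.true_rate[~epi].mean()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_patients=1)
        with pytest.raises(ValueError):
            CohortSpec(frac_non_epileptic=1.5)
        with pytest.raises(ValueError):
            CohortSpec(true_beta=np.zeros(3))

    def test_measured_rates_track_truth(self):
        c = simulate_cohort(CohortSpec(n_patients=4, seed=3))
        tables = measure_rates(c, seed=1)
        p = c.patients[0]
        t = tables[p.patient_id]
        # SLL sensitivity is 1.0: measured mean tracks the generative mean
        assert t["rate_SLL_80"].mean() == pytest.approx(p.true_rate.mean(), rel=0.25)
        # conservative detector measures fewer events than inclusive one
        assert t["rate_STE_80"].sum() < t["rate_SLL_80"].sum()
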