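"""Event/burst detection, drug effects, charge density, synchrony, QC."""

import numpy as np
import pytest

from rettphys import (BurstSpec, DataError, EphysSimParams, EventTrain,
                      ParameterError, QCRecord, Trace, charge_density,
                      detect_bursts, detect_events, drug_effect, ei_ratio,
                      estimate_noise_sd, frequency_timecourse, gen_psc_pair,
                      paired_correlation, qc_filter)


class TestNoiseSD:
    def test_constant_trace_zero(self):
        tr = Trace(np.full(2000, 5.0), 0.001)
        assert estimate_noise_sd(tr, (0.0, 1.0)) == 0.0

    def test_white_noise_within_5_percent(self):
        rng = np.random.default_rng(0)
        tr = Trace(rng.normal(0, 3.0, 50_000), 0.0005)
        assert estimate_noise_sd(tr, (0.0, 25.0)) == pytest.approx(3.0, rel=0.05)

    def test_offset_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 2.0, 5000)
        a = estimate_noise_sd(Trace(v, 0.001), (0.0, 5.0))
        b = estimate_noise_sd(Trace(v + 100.0, 0.001), (0.0, 5.0))
        assert a == pytest.approx(b)

    def test_short_window_rejected(self):
        tr = Trace(np.zeros(1000), 0.001)
        with pytest.raises(DataError):
            estimate_noise_sd(tr, (0.0, 0.05))


class TestDetectEvents:
    def test_ten_sigma_events_all_detected(self, planted_event_trace):
        tr, times = planted_event_trace(10.0, n_events=5, noise_sd=1.0)
        train = detect_events(tr, 1.0)
        assert len(train) == 5
        assert np.allclose(train.times, times, atol=0.005)

    def test_two_sigma_events_never_detected(self, planted_event_trace):
        tr, _ = planted_event_trace(2.0, n_events=5, noise_sd=0.0)
        assert len(detect_events(tr, 1.0)) == 0

    def test_flat_trace_empty(self):
        tr = Trace(np.zeros(5000), 0.0005)
        assert len(detect_events(tr, 1.0)) == 0

    def test_zero_noise_recall_and_precision(self, planted_event_trace):
        for n_ev in (1, 4, 8):
            tr, times = planted_event_trace(10.0, n_events=n_ev, noise_sd=0.0)
            train = detect_events(tr, 1.0)
            assert len(train) == n_ev            # precision: no extras
            assert np.allclose(train.times, times, atol=0.005)  # recall

    def test_recall_non_increasing_with_noise(self, planted_event_trace):
        recalls = []
        for noise in (0.5, 2.0, 5.0):
            hits = 0
            for seed in range(5):
                tr, times = planted_event_trace(10.0, n_events=8,
                                                noise_sd=noise, seed=seed)
                det = detect_events(tr, noise).times
                hits += sum(np.any(np.abs(det - t) < 0.01) for t in times)
            recalls.append(hits / 40)
        assert recalls[0] >= recalls[1] >= recalls[2]

    def test_degenerate_threshold_rejected(self, planted_event_trace):
        tr, _ = planted_event_trace(10.0)
        with pytest.raises(ParameterError):
            detect_events(tr, 0.0)

    def test_positive_polarity(self, planted_event_trace):
        tr, times = planted_event_trace(10.0, n_events=3, polarity="positive")
        train = detect_events(tr, 1.0, polarity="positive")
        assert len(train) == 3

    def test_amplitude_measured_on_raw_signal(self, planted_event_trace):
        tr, _ = planted_event_trace(12.0, n_events=3, noise_sd=0.0)
        train = detect_events(tr, 1.0)
        assert np.allclose(train.amplitudes, 12.0, rtol=0.05)


class TestFrequencyTimecourse:
    def test_uniform_train(self):
        train = EventTrain(np.arange(10) + 0.5, np.ones(10), np.ones(10),
                           duration=10.0)
        centers, hz = frequency_timecourse(train, 1.0)
        assert np.allclose(hz, 1.0)

    def test_counts_conserved(self):
        rng = np.random.default_rng(2)
        t = np.sort(rng.uniform(0, 30, 77))
        train = EventTrain(t, np.ones(77), np.ones(77), duration=30.0)
        _, hz = frequency_timecourse(train, 0.7)
        assert hz.sum() * 0.7 == pytest.approx(77)

    def test_empty_train_zero(self):
        train = EventTrain(np.empty(0), np.empty(0), np.empty(0), duration=5.0)
        _, hz = frequency_timecourse(train, 1.0)
        assert (hz == 0).all()

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(3)
        lam, T = 4.0, 200.0
        t = np.sort(rng.uniform(0, T, rng.poisson(lam * T)))
        train = EventTrain(t, np.ones(t.size), np.ones(t.size), duration=T)
        _, hz = frequency_timecourse(train, 1.0)
        assert hz.mean() == pytest.approx(lam, abs=3 * np.sqrt(lam / T))


class TestDrugEffect:
    @staticmethod
    def _train(rates, spans):
        t = np.concatenate([np.arange(a, b, 1 / r) for (a, b), r in zip(spans, rates)])
        return EventTrain(t, np.ones(t.size), np.ones(t.size), duration=spans[-1][1])

    def test_inhibition(self):
        train = self._train([2.0, 1.0, 2.0], [(0, 60), (60, 90), (120, 180)])
        eff = drug_effect(train, (0, 60), (60, 90), (120, 180))
        assert eff.normalized_effect == pytest.approx(0.5)
        assert eff.washout_ok

    def test_excitation(self):
        train = self._train([2.0, 3.0, 2.0], [(0, 60), (60, 90), (120, 180)])
        eff = drug_effect(train, (0, 60), (60, 90), (120, 180))
        assert eff.normalized_effect == pytest.approx(1.5)

    def test_washout_exclusion_rule(self):
        # washout at 2.5 Hz vs baseline 2 Hz: 25% > 20% -> excluded
        train = self._train([2.0, 1.0, 2.5], [(0, 60), (60, 90), (120, 180)])
        eff = drug_effect(train, (0, 60), (60, 90), (120, 180))
        assert not eff.washout_ok
        # exactly 20% deviation is still acceptable
        train = self._train([2.0, 1.0, 2.4], [(0, 60), (60, 90), (120, 180)])
        assert drug_effect(train, (0, 60), (60, 90), (120, 180)).washout_ok

    def test_zero_baseline_rejected(self):
        train = self._train([1.0], [(60, 90)])
        with pytest.raises(DataError):
            drug_effect(train, (0, 60), (60, 90), (120, 180))

    def test_unordered_windows_rejected(self):
        train = self._train([2.0], [(0, 60)])
        with pytest.raises(ParameterError):
            drug_effect(train, (0, 60), (30, 90), (120, 180))


class TestDetectBursts:
    @staticmethod
    def _fixture(events_per_burst, elevation, noise=0.0, seed=7):
        p = EphysSimParams(baseline_rate=0.0, noise_sd=noise, seed=seed,
                           burst_spec=BurstSpec(rate_hz=0.15,
                                                events_per_burst=events_per_burst,
                                                elevation_pA=elevation))
        trace, _, times, _ = gen_psc_pair(p, duration=40.0)
        train = detect_events(trace, 2.0, detrend=0.2)
        n_planted = round(len(times) / events_per_burst)
        return train, trace, n_planted

    def test_planted_bursts_recovered(self):
        train, trace, n_planted = self._fixture(3, 80.0, noise=2.0)
        assert len(detect_bursts(train, trace)) == n_planted

    def test_exact_boundary_qualifies(self):
        # minimum of three events on exactly 60 pA elevation
        train, trace, n_planted = self._fixture(3, 60.0, noise=0.0)
        assert len(detect_bursts(train, trace)) == n_planted

    def test_too_few_events_no_burst(self):
        train, trace, _ = self._fixture(2, 80.0, noise=2.0)
        assert len(detect_bursts(train, trace)) == 0

    def test_low_elevation_no_burst(self):
        train, trace, _ = self._fixture(5, 40.0, noise=2.0)
        assert len(detect_bursts(train, trace)) == 0

    def test_isolated_events_no_burst(self):
        p = EphysSimParams(baseline_rate=1.0, noise_sd=2.0, seed=3)
        trace, _, _, _ = gen_psc_pair(p, duration=30.0)
        train = detect_events(trace, 2.0, detrend=0.2)
        assert len(train) > 5
        assert len(detect_bursts(train, trace)) == 0

    def test_burst_metrics_positive(self):
        train, trace, _ = self._fixture(5, 80.0, noise=2.0)
        for b in detect_bursts(train, trace):
            assert b.duration > 0 and b.charge > 0
            assert b.charge_density == pytest.approx(b.charge / b.duration)
            assert b.n_events >= 3


class TestChargeDensity:
    def test_rectangular_event_analytic(self):
        # 10 pA for 10 ms in a 1 s trace: charge 0.1 pC -> CD 0.1 pC/s
        fs = 10_000.0
        v = np.zeros(int(fs))
        v[2000:2000 + int(0.010 * fs)] = -10.0
        train = detect_events(Trace(v, 1 / fs), 1.0, smooth=0.0005)
        assert len(train) == 1
        assert charge_density(train, 1.0) == pytest.approx(0.1, rel=0.02)

    def test_concatenation_is_duration_weighted_mean(self):
        t1 = EventTrain([1.0], [10.0], [2.0], duration=10.0)
        t2 = EventTrain([1.0], [10.0], [6.0], duration=20.0)
        cd1, cd2 = charge_density(t1, 10.0), charge_density(t2, 20.0)
        merged = EventTrain([1.0, 11.0], [10.0, 10.0], [2.0, 6.0], duration=30.0)
        assert charge_density(merged, 30.0) == pytest.approx(
            (cd1 * 10 + cd2 * 20) / 30)

    def test_normalization_to_control(self):
        train = EventTrain([1.0], [10.0], [3.0], duration=10.0)
        cd, norm = charge_density(train, 10.0, control_reference=0.6)
        assert cd == pytest.approx(0.3) and norm == pytest.approx(0.5)
        with pytest.raises(ParameterError):
            charge_density(train, 10.0, control_reference=0.0)

    def test_resampling_invariance(self, psc_kernel):
        kernel, fs = psc_kernel
        cds = []
        for mult in (1, 4):
            f = fs * mult
            t = np.arange(0, 0.06, 1 / f)
            k = np.exp(-t / 0.010) - np.exp(-t / 0.002)
            k /= k.max()
            v = np.zeros(int(2 * f))
            i0 = int(0.5 * f)
            v[i0:i0 + k.size] -= 30.0 * k
            train = detect_events(Trace(v, 1 / f), 1.0)
            cds.append(charge_density(train, 2.0))
        assert cds[0] == pytest.approx(cds[1], rel=0.01)


class TestEIRatio:
    def test_equal_densities(self):
        assert ei_ratio(0.5, 0.5) == 1.0

    def test_linearity(self):
        assert ei_ratio(0.25, 0.5) == pytest.approx(0.5 * ei_ratio(0.5, 0.5))

    def test_zero_denominator(self):
        with pytest.raises(ParameterError):
            ei_ratio(1.0, 0.0)

    def test_mecp2_like_ratio_below_wt(self):
        # E up and I down shifts the balance toward excitation
        wt = ei_ratio(ipsc_cd=0.8, epsc_cd=0.8)
        mecp2 = ei_ratio(ipsc_cd=0.4, epsc_cd=1.4)
        assert mecp2 < wt


class TestPairedCorrelation:
    def test_self_correlation_is_one(self):
        p = EphysSimParams(seed=4)
        a, _, _, _ = gen_psc_pair(p, duration=20.0)
        r, lags, xc = paired_correlation(a, a)
        assert r == pytest.approx(1.0)
        assert xc[lags == 0.0] == pytest.approx(1.0)

    def test_independent_traces_near_zero(self):
        p = EphysSimParams(pair_correlation=0.0, seed=8)
        a, b, _, _ = gen_psc_pair(p, duration=60.0)
        r, _, _ = paired_correlation(a, b)
        n_bins = int(60.0 / 0.01)
        assert abs(r) < 3 / np.sqrt(n_bins)

    def test_correlated_pair_exceeds_uncorrelated(self):
        ra, rb = [], []
        for seed in range(3):
            a, b, _, _ = gen_psc_pair(
                EphysSimParams(pair_correlation=0.8, seed=seed), 30.0)
            ra.append(paired_correlation(a, b)[0])
            a, b, _, _ = gen_psc_pair(
                EphysSimParams(pair_correlation=0.0, seed=seed), 30.0)
            rb.append(paired_correlation(a, b)[0])
        assert min(ra) > max(rb)

    def test_symmetry_and_bounds(self):
        p = EphysSimParams(pair_correlation=0.5, seed=2)
        a, b, _, _ = gen_psc_pair(p, duration=20.0)
        rab, _, _ = paired_correlation(a, b)
        rba, _, _ = paired_correlation(b, a)
        assert rab == pytest.approx(rba)
        assert -1.0 <= rab <= 1.0

    def test_zero_variance_rejected(self):
        flat = Trace(np.zeros(1000), 0.001)
        with pytest.raises(DataError):
            paired_correlation(flat, flat)


class TestQCFilter:
    @pytest.mark.parametrize("rec,decision", [
        (QCRecord(-50.0, "P0"), "exclude"),                 # beyond P0 bound
        (QCRecord(-20.0, "P15", holding_current_drift_pct=20.0), "exclude"),
        (QCRecord(-20.0, "P15", input_resistance_drift_pct=5.0), "keep"),
        (QCRecord(-35.0, "P15"), "keep"),                   # within P15 bound
        (QCRecord(-45.0, "P15"), "exclude"),
        (QCRecord(-29.0, "P0", input_resistance_drift_pct=15.0), "keep"),  # 15% is not >15%
    ])
    def test_exclusion_rules(self, rec, decision):
        assert qc_filter(rec).decision == decision

    def test_exactly_one_reason(self):
        rec = qc_filter(QCRecord(-50.0, "P0", input_resistance_drift_pct=30.0))
        assert rec.decision == "exclude"
        assert "holding current" in rec.reason and "drift" not in rec.reason

    def test_inverted_sign_reading(self):
        rec = qc_filter(QCRecord(-20.0, "P0"), invert_holding_sign=True)
        assert rec.decision == "exclude"

    def test_unknown_age_class(self):
        with pytest.raises(DataError):
            qc_filter(QCRecord(-20.0, "P7"))
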