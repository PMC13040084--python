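"""Time-frequency maps, interaction contrasts, and the γ-burst pipeline."""

import numpy as np
import pytest

from resilnet import spectral, synthdata
from resilnet.spectral import TFRMap
from resilnet.synthdata import SimConfig

FS = 1000.0


def sinusoid(freq, dur=3.0, amp=1.0, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestMorletTfr:
    def test_peak_frequency_of_pure_tone(self):
        tfr = spectral.morlet_tfr(sinusoid(10.0), FS)
        prof = tfr.power.mean(axis=1)
        assert tfr.freqs[np.argmax(prof)] == pytest.approx(10.0, abs=1.0)

    def test_power_scales_quadratically_with_amplitude(self):
        p1 = spectral.morlet_tfr(sinusoid(10.0, amp=1.0), FS).power
        p2 = spectral.morlet_tfr(sinusoid(10.0, amp=2.0), FS).power
        # compare away from the padded edges
        sl = slice(500, 2500)
        ratio = p2[8, sl].mean() / p1[8, sl].mean()
        assert ratio == pytest.approx(4.0, rel=0.02)

    def test_white_noise_spectrum_flat_after_normalization(self):
        rng = np.random.default_rng(0)
        trials = rng.standard_normal((30, 3000))
        tfr = spectral.morlet_tfr(trials, FS, freqs=np.arange(10.0, 41.0, 2.0))
        prof = tfr.power[:, 500:2500].mean(axis=1)
        # Morlet power of white noise is flat across frequency
        norm = prof / prof.mean()
        se = norm.std() / np.sqrt(norm.size)
        assert np.abs(norm - 1.0).max() < max(5 * norm.std(), 0.3)

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            spectral.morlet_tfr(sinusoid(10.0), FS, freqs=np.array([600.0]))


class TestMultitaperTfr:
    def test_peak_frequency_within_smoothing_bandwidth(self):
        tfr = spectral.multitaper_tfr(sinusoid(80.0), FS)
        prof = np.nanmean(tfr.power, axis=1)
        peak = tfr.freqs[np.nanargmax(prof)]
        assert abs(peak - 80.0) <= 0.2 * 80.0

    def test_power_nonnegative(self):
        rng = np.random.default_rng(1)
        tfr = spectral.multitaper_tfr(rng.standard_normal(2500), FS)
        assert np.nanmin(tfr.power) >= 0.0

    def test_matches_windowed_periodogram_on_chirp(self):
        # independent oracle: Welch periodogram on sliding windows
        from scipy import signal as sps

        t = np.arange(3000) / FS
        x = np.sin(2 * np.pi * (60 + 10 * t) * t)  # slow chirp 60->120 Hz
        tfr = spectral.multitaper_tfr(x, FS, freqs=np.arange(50.0, 131.0, 2.0))
        mid = 1500
        inst_freq = 60 + 20 * t[mid]  # d/dt of phase / 2pi
        prof = tfr.power[:, mid]
        peak = tfr.freqs[np.nanargmax(prof)]
        win = x[mid - 400 : mid + 400] * np.hanning(800)
        f = np.fft.rfftfreq(800, 1 / FS)
        oracle_peak = f[np.argmax(np.abs(np.fft.rfft(win)) ** 2)]
        assert abs(peak - oracle_peak) <= 0.2 * oracle_peak

    def test_window_longer_than_trial_rejected(self):
        with pytest.raises(ValueError):
            spectral.multitaper_tfr(sinusoid(80.0, dur=0.05), FS)


def _flat_map(value=0.0, times=None, freqs=None):
    times = np.linspace(0, 1, 11) if times is None else times
    freqs = np.arange(44.0, 151.0, 2.0) if freqs is None else freqs
    return TFRMap(times=times, freqs=freqs,
                  power=np.full((freqs.size, times.size), value))


class TestInteractionMap:
    KEYS = ("NegIncong", "NeutIncong", "NegCong", "NeutCong")

    def test_identical_conditions_cancel(self):
        maps = {k: _flat_map(3.0) for k in self.KEYS}
        out = spectral.interaction_map(maps)
        np.testing.assert_allclose(out.power, 0.0)

    def test_additive_main_effects_cancel(self):
        rng = np.random.default_rng(2)
        base = rng.random((54, 11))
        emo = rng.random((54, 11))
        cog = rng.random((54, 11))
        maps = {}
        for k in self.KEYS:
            p = base.copy()
            if k.startswith("Neg"):
                p = p + emo
            if "Incong" in k:
                p = p + cog
            m = _flat_map()
            m.power = p
            maps[k] = m
        np.testing.assert_allclose(spectral.interaction_map(maps).power, 0.0,
                                   atol=1e-12)

    def test_planted_interaction_bump_recovered(self):
        maps = {k: _flat_map() for k in self.KEYS}
        bump = np.zeros((54, 11))
        bump[20, 5] = 2.5
        maps["NegIncong"].power = maps["NegIncong"].power + bump
        out = spectral.interaction_map(maps)
        np.testing.assert_allclose(out.power, bump)

    def test_grid_mismatch_rejected(self):
        maps = {k: _flat_map() for k in self.KEYS}
        maps["NegCong"] = _flat_map(times=np.linspace(0, 2, 11))
        with pytest.raises(ValueError):
            spectral.interaction_map(maps)


class TestExtractExtremes:
    def test_zero_map_extremes_are_zero(self):
        ext = spectral.extract_extremes(_flat_map(0.0), band=(44, 150))
        assert ext.min_value == 0.0 == ext.max_value

    def test_equals_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        m = _flat_map()
        m.power = rng.standard_normal(m.power.shape)
        band = (60.0, 100.0)
        ext = spectral.extract_extremes(m, band=band)
        fmask = (m.freqs >= band[0]) & (m.freqs <= band[1])
        sub = m.power[fmask]
        assert ext.min_value == sub.min()
        assert ext.max_value == sub.max()
        # coordinates point back at the extreme cells
        fi = list(m.freqs).index(ext.max_tf[1])
        ti = list(m.times).index(ext.max_tf[0])
        assert m.power[fi, ti] == ext.max_value

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            spectral.extract_extremes(_flat_map(), band=(500, 600))


class TestFirBandpass:
    def test_center_frequency_passes(self):
        x = sinusoid(60.0)
        y = spectral.fir_bandpass(x, FS)
        assert y[500:-500].std() >= 0.9 * x[500:-500].std()

    def test_dc_rejected_exactly(self):
        y = spectral.fir_bandpass(np.ones(2000), FS)
        assert np.abs(y.mean()) < 1e-3

    def test_zero_phase_no_lag(self):
        x = sinusoid(60.0)
        y = spectral.fir_bandpass(x, FS)
        xc = np.correlate(x[500:2500], y[500:2500], mode="full")
        lag = np.argmax(xc) - (len(xc) // 2)
        assert lag == 0

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            spectral.fir_bandpass(np.ones(100), FS, band=(80.0, 40.0))


@pytest.fixture(scope="module")
def burst_data():
    cfg = SimConfig(seed=17, fs=FS, duration=2.0, burst_rate=1.0, burst_snr=2.0)
    trials, gt = synthdata.gen_burst_signal(cfg, 140, 2.0)
    return cfg, trials, gt


@pytest.fixture(scope="module")
def learned_dictionary(burst_data):
    _, trials, _ = burst_data
    return spectral.learn_dictionary(trials[:100], fs=FS, seed=1)


class TestLearnDictionary:
    def test_planted_waveform_recovered(self):
        # training = noiseless repeats of one canonical burst
        blen = 100
        core = np.hanning(blen) * np.sin(2 * np.pi * 60 * np.arange(blen) / FS)
        trials = np.zeros((40, 2000))
        for i, tr in enumerate(trials):
            tr[400 + 7 * i : 400 + 7 * i + blen] = core
        dico = spectral.learn_dictionary(trials, fs=FS, n_atoms=5, seed=0)
        ref = spectral.fir_bandpass(core, FS)
        ref = ref / np.linalg.norm(ref)
        best = max(
            np.abs(np.correlate(atom, ref, mode="full")).max()
            for atom in dico.atoms
        )
        assert best > 0.9

    def test_atoms_unit_norm_and_count(self, learned_dictionary):
        assert learned_dictionary.atoms.shape[0] == 30
        np.testing.assert_allclose(
            np.linalg.norm(learned_dictionary.atoms, axis=1), 1.0, atol=1e-9
        )

    def test_same_seed_identical_dictionary(self, burst_data):
        _, trials, _ = burst_data
        a = spectral.learn_dictionary(trials[:60], fs=FS, seed=4)
        b = spectral.learn_dictionary(trials[:60], fs=FS, seed=4)
        np.testing.assert_array_equal(a.atoms, b.atoms)

    def test_insufficient_training_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            spectral.learn_dictionary(rng.standard_normal((2, 400)), fs=FS)


class TestDetectBursts:
    def test_burst_free_background_yields_no_detections(self, learned_dictionary):
        cfg = SimConfig(seed=23, fs=FS, duration=2.0, burst_rate=0.0)
        trials, _ = synthdata.gen_burst_signal(cfg, 5, 2.0)
        events = spectral.detect_bursts(trials, learned_dictionary)
        assert len(events) == 0

    def test_planted_bursts_found_within_25ms(self, burst_data, learned_dictionary):
        _, trials, gt = burst_data
        test_trials = trials[100:]
        true_times = gt.burst_times[100:]
        events = spectral.detect_bursts(test_trials, learned_dictionary)
        by_trial = {}
        for ev in events:
            by_trial.setdefault(ev.trial, []).append(ev.peak_time)
        hits = total = 0
        for j, truth in enumerate(true_times):
            det = np.asarray(by_trial.get(j, []))
            for t0 in truth:
                total += 1
                if det.size and np.min(np.abs(det - t0)) <= 0.025:
                    hits += 1
        assert total >= 30
        assert hits / total >= 0.9

    def test_false_alarm_rate_bounded(self, learned_dictionary):
        cfg = SimConfig(seed=29, fs=FS, duration=2.0, burst_rate=0.0)
        trials, _ = synthdata.gen_burst_signal(cfg, 50, 2.0)
        events = spectral.detect_bursts(trials, learned_dictionary)
        assert len(events) / (50 * 2.0) <= 0.1


class TestBurstIei:
    def _ev(self, trial, t):
        return spectral.BurstEvent(trial=trial, peak_time=t, atom=0, power=1.0)

    def test_within_trial_differences(self):
        events = [self._ev(0, 0.2), self._ev(0, 0.5)]
        np.testing.assert_allclose(spectral.burst_iei(events), [0.3])

    def test_single_burst_per_trial_gives_nothing(self):
        events = [self._ev(0, 0.2), self._ev(1, 0.5), self._ev(2, 0.9)]
        assert spectral.burst_iei(events).size == 0

    def test_cross_trial_gaps_never_counted(self):
        events = [self._ev(0, 1.9), self._ev(1, 0.1), self._ev(1, 0.6)]
        np.testing.assert_allclose(spectral.burst_iei(events), [0.5])

    def test_generator_iei_mean_matches_order_statistic_oracle(self):
        # long trials, sparse bursts: refractory thinning is negligible and
        # burst times are Poisson-many uniforms in the margin-trimmed
        # window, so the pooled mean IEI has the exact closed form
        # E[(n-1) * w/(n+1)] / E[n-1] over n ~ Poisson(rate * w).
        rate, trial_len, margin = 0.5, 20.0, 0.1
        cfg = SimConfig(seed=31, fs=FS, duration=trial_len, burst_rate=rate)
        _, gt = synthdata.gen_burst_signal(cfg, 60, trial_len)
        ieis = np.concatenate([np.diff(t) for t in gt.burst_times if t.size >= 2])
        w = trial_len - 2 * margin
        lam = rate * trial_len  # Poisson count drawn for the full trial
        from scipy import stats as sps

        n = np.arange(2, 200)
        pmf = sps.poisson.pmf(n, lam)
        expected = np.sum(pmf * (n - 1) * w / (n + 1)) / np.sum(pmf * (n - 1))
        se = ieis.std() / np.sqrt(ieis.size)
        assert abs(ieis.mean() - expected) < 3 * se + 0.1 * expected
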