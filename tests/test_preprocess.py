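"""Bipolar montage, kriging artifact interpolation, filtering/resampling."""

import numpy as np
import pytest
from scipy import signal as sps

from criticaldyn import preprocess as pp
from criticaldyn import synthetic as syn
from criticaldyn.synthetic import Recording, StimEvent


def make_rec(signal, sf=1000.0, labels=None, events=None):
    signal = np.atleast_2d(signal)
    labels = labels or [f"A{i + 1}" for i in range(signal.shape[0])]
    return Recording(signal=signal, sampling_rate_hz=sf,
                     channel_labels=labels, events=events or [])


class TestBipolarMontage:
    def test_identical_contacts_cancel(self):
        x = np.random.default_rng(0).standard_normal(1000)
        rec = make_rec(np.vstack([x, x]), labels=["A1", "A2"])
        bp = pp.bipolar_montage(rec)
        assert bp.channel_labels == ["A1-A2"]
        assert np.allclose(bp.signal, 0.0)

    def test_three_contacts_give_two_channels(self):
        rng = np.random.default_rng(1)
        rec = make_rec(rng.standard_normal((3, 500)),
                       labels=["H1", "H2", "H3"])
        bp = pp.bipolar_montage(rec)
        assert bp.channel_labels == ["H1-H2", "H2-H3"]

    def test_common_mode_line_noise_rejected(self):
        sf = 1000.0
        t = np.arange(int(10 * sf)) / sf
        line = 50.0 * np.sin(2 * np.pi * 50.0 * t)
        rng = np.random.default_rng(2)
        mono = np.vstack([line + rng.standard_normal(t.size),
                          line + rng.standard_normal(t.size)])
        rec = make_rec(mono, sf=sf, labels=["A1", "A2"])
        bp = pp.bipolar_montage(rec)

        def power_50hz(x):
            f, p = sps.periodogram(x, sf)
            return p[np.argmin(np.abs(f - 50.0))]

        assert power_50hz(bp.signal[0]) / power_50hz(mono[0]) < 0.1

    def test_single_contact_lead_dropped(self):
        rng = np.random.default_rng(3)
        rec = make_rec(rng.standard_normal((3, 500)),
                       labels=["A1", "A2", "B1"])
        bp = pp.bipolar_montage(rec)
        assert bp.channel_labels == ["A1-A2"]


class TestArtifactRemoval:
    def test_zero_noise_gives_exact_connecting_line(self):
        sf = 1000.0
        x = np.zeros(int(2 * sf))
        x[:900] = 5.0  # flat before; SD of preceding 50 ms is 0
        x[999:1009] = 500.0  # artifact inside the [-2, +10] ms window
        rec = make_rec(x, sf=sf,
                       events=[StimEvent(1.0, "S1", 0.5, 3.0, "single_pulse")])
        out = pp.remove_stim_artifact(rec, seed=0)
        a, b = 998, 1010  # [-2, +10] ms around sample 1000
        left, right = out.signal[0, a - 1], out.signal[0, b + 1]
        m = b - a + 1
        expect = left + (right - left) * np.arange(1, m + 1) / (m + 1)
        assert np.allclose(out.signal[0, a:b + 1], expect)

    def test_samples_outside_windows_untouched(self):
        rng = np.random.default_rng(4)
        sf = 1000.0
        x = rng.standard_normal(int(3 * sf))
        rec = make_rec(x, sf=sf,
                       events=[StimEvent(1.5, "S1", 0.5, 3.0, "single_pulse")])
        out = pp.remove_stim_artifact(rec, seed=1)
        changed = np.flatnonzero(out.signal[0] != x)
        lo = int(1.5 * sf) - 2
        hi = int(1.5 * sf) + 10
        assert changed.min() >= lo and changed.max() <= hi

    def test_injected_artifact_removed_to_baseline(self):
        cfg = syn.SyntheticConfig(sampling_rate_hz=1000.0, seed=5,
                                  isi_range_s=(2.0, 3.0), evoked_gain=0.0)
        rec = syn.generate_session(cfg, n_stimulations=8)
        out = pp.remove_stim_artifact(rec, seed=2)
        sf = rec.sampling_rate_hz
        base_sd = np.std(out.signal[0, : int(4 * sf)])
        # the 2000 µV injected square artifact (~38 SD) must be gone; the
        # interpolated span may still wander a few SD like the background
        for e in rec.events:
            i0 = int(e.onset_s * sf)
            peri = out.signal[0, i0 - 2 : i0 + 10]
            assert np.abs(peri - out.signal[0, i0 - 50:i0 - 10].mean()).max() \
                < 5 * base_sd

    def test_window_truncated_at_edge_rejected(self):
        x = np.zeros(1000)
        rec = make_rec(x, sf=1000.0,
                       events=[StimEvent(0.0, "S1", 0.5, 3.0, "single_pulse")])
        with pytest.raises(ValueError, match="truncated"):
            pp.remove_stim_artifact(rec)


class TestFilterAndResample:
    def test_line_frequency_attenuated_20db(self):
        sf = 2000.0
        t = np.arange(int(8 * sf)) / sf
        x = np.sin(2 * np.pi * 50.0 * t)
        rec = make_rec(x, sf=sf)
        out = pp.filter_and_resample(
            rec, pp.PreprocessConfig(species_profile="mouse",
                                     bandpass_hz=(0.5, 200.0),
                                     resample_hz=None))
        mid = slice(int(sf), int(7 * sf))  # avoid filter edges
        atten = 20 * np.log10(np.std(out.signal[0, mid]) / np.std(x[mid]))
        assert atten <= -20.0

    def test_in_band_tone_preserved(self):
        sf = 2000.0
        t = np.arange(int(8 * sf)) / sf
        x = np.sin(2 * np.pi * 10.0 * t)
        rec = make_rec(x, sf=sf)
        out = pp.filter_and_resample(
            rec, pp.PreprocessConfig(species_profile="mouse",
                                     bandpass_hz=(0.5, 200.0),
                                     resample_hz=None))
        mid = slice(int(sf), int(7 * sf))
        assert np.std(out.signal[0, mid]) == pytest.approx(np.std(x[mid]),
                                                           rel=0.05)

    def test_resampling_sample_count_exact(self):
        rng = np.random.default_rng(6)
        rec = make_rec(rng.standard_normal(int(4 * 2000)), sf=2000.0)
        out = pp.filter_and_resample(
            rec, pp.PreprocessConfig(species_profile="human"))
        assert out.sampling_rate_hz == 500.0
        assert out.signal.shape[1] == 2000

    def test_zero_phase_no_lag(self):
        sf = 1000.0
        rng = np.random.default_rng(7)
        x = sps.lfilter([1.0], [1.0, -0.95], rng.standard_normal(int(8 * sf)))
        rec = make_rec(x, sf=sf)
        out = pp.filter_and_resample(
            rec, pp.PreprocessConfig(species_profile="mouse",
                                     bandpass_hz=(0.5, 200.0),
                                     resample_hz=None))
        xc = sps.correlate(out.signal[0], x, mode="full")
        lag = np.argmax(xc) - (x.size - 1)
        assert lag == 0

    def test_cutoff_above_nyquist_rejected(self):
        rec = make_rec(np.zeros(1000), sf=1000.0)
        with pytest.raises(ValueError, match="Nyquist"):
            pp.filter_and_resample(
                rec, pp.PreprocessConfig(bandpass_hz=(0.5, 800.0),
                                         resample_hz=None))

    def test_idempotent_on_band_limited_data(self):
        # content well inside the 0.5-200 Hz band (2-80 Hz) is untouched by
        # a second pass; broadband input would keep losing transition-band
        # energy on every pass
        rng = np.random.default_rng(8)
        sos = sps.butter(6, [2.0 / 1000, 80.0 / 1000], btype="bandpass",
                         output="sos")
        x = sps.sosfiltfilt(sos, rng.standard_normal(int(10 * 2000)))
        stop = sps.butter(6, [40.0 / 1000, 60.0 / 1000], btype="bandstop",
                          output="sos")
        x = sps.sosfiltfilt(stop, x)  # line-noise-free by construction
        rec = make_rec(x, sf=2000.0)
        cfg = pp.PreprocessConfig(species_profile="mouse",
                                  bandpass_hz=(0.5, 200.0), resample_hz=None)
        once = pp.filter_and_resample(rec, cfg)
        twice = pp.filter_and_resample(once, cfg)
        mid = slice(2000, -2000)
        rms1 = np.sqrt(np.mean(once.signal[0, mid] ** 2))
        rms2 = np.sqrt(np.mean(twice.signal[0, mid] ** 2))
        assert abs(rms2 - rms1) / rms1 < 0.01
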