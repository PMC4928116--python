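"""ERP pipeline: filtering, segmentation, artifact rules, peaks."""
import numpy as np
import pytest

from fafnet import erp as E
from fafnet.config import ArtifactRules, EEGGroundTruth, ParadigmConfig
from fafnet.synth import generate_eeg_session

FS = 1000.0


class TestBandpass:
    def test_passband_tone_preserved(self):
        t = np.arange(0, 10, 1 / FS)
        x = np.sin(2 * np.pi * 10.0 * t)
        y = E.bandpass(x, FS)
        mid = slice(2000, 8000)
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_slow_drift_attenuated(self):
        t = np.arange(0, 40, 1 / FS)
        x = np.sin(2 * np.pi * 0.1 * t)
        y = E.bandpass(x, FS)
        assert np.abs(y[5000:-5000]).max() < 0.1

    def test_zeros_stay_zero_and_invalid_band_errors(self):
        assert np.allclose(E.bandpass(np.zeros(4000), FS), 0.0)
        with pytest.raises(ValueError):
            E.bandpass(np.zeros(4000), FS, low_hz=20.0, high_hz=1.0)


class TestSegment:
    def test_epoch_count_and_length(self):
        data = np.zeros((3, 80_000))
        ev = np.arange(1000, 71_000, 700)
        eps = E.segment(data, FS, ev, np.full(len(ev), 50.0), ["a", "b", "c"])
        assert eps.n_epochs == len(ev)
        assert eps.data.shape[-1] == 701

    def test_content_matches_direct_slice(self, rng):
        data = rng.standard_normal((2, 5000))
        eps = E.segment(data, FS, np.array([1000]), np.array([50.0]), ["a", "b"])
        np.testing.assert_array_equal(eps.data[0], data[:, 800:1501])

    def test_event_near_edge_dropped_with_log(self):
        data = np.zeros((1, 2000))
        eps = E.segment(data, FS, np.array([500, 1900]), np.array([50.0, 50.0]), ["a"])
        assert eps.n_epochs == 1
        assert eps.dropped_events == [1]


class TestArtifacts:
    def _eps(self, data):
        n_ep, n_ch, _ = data.shape
        return E.EpochSet(data=data, times_ms=np.arange(-200, 501), fs=FS,
                          channel_names=[f"ch{i}" for i in range(n_ch)],
                          magnitudes_cents=np.full(n_ep, 50.0))

    def test_all_zero_nothing_flagged(self):
        eps = E.detect_artifacts(self._eps(np.zeros((5, 3, 701))))
        assert not eps.flags.any()
        assert eps.epoch_keep.all() and eps.file_ok

    def test_step_at_epoch_edge_flagged(self):
        """A 100-uV step in the last samples: the truncated moving-average
        window cannot track it and the residual exceeds 55 uV."""
        data = np.zeros((10, 2, 701))
        data[1, 0, -15:] = 100.0
        eps = E.detect_artifacts(self._eps(data))
        assert eps.flags[1, 0]
        assert not eps.flags[:, 1].any()
        assert not eps.bad_channels  # 1/10 epochs stays under the 20% rule
        assert eps.epoch_keep.tolist() == [True, False] + [True] * 8

    def test_slow_ramp_not_flagged(self):
        data = np.zeros((2, 2, 701))
        data[0, 0] = np.linspace(0, 50, 701)  # moving average tracks it
        eps = E.detect_artifacts(self._eps(data))
        assert not eps.flags.any()

    def test_bad_channel_rule_20_percent(self):
        """30 of 100 epochs contaminated on one channel -> channel bad, and
        epochs are no longer rejected on its account."""
        cfg = ParadigmConfig(n_vocalizations=20, eeg_channels=6)
        truth = EEGGroundTruth(noise_sd_uv=0.0, theta_amp_uv=0.0,
                               artifacts=tuple((e, 2, 200.0) for e in range(30)))
        sess = generate_eeg_session(cfg, truth, seed=13)
        eps = E.segment(sess.eeg, FS, sess.event_samples_eeg,
                        sess.event_magnitudes_cents, sess.channel_names)
        eps = E.detect_artifacts(eps)
        assert eps.channel_names[2] in eps.bad_channels
        assert len(eps.bad_channels) == 1
        assert eps.epoch_keep.all()
        assert eps.file_ok

    def test_file_rejected_over_10_bad_channels(self, rng):
        data = np.zeros((10, 14, 701))
        data[:5, :11, -10:] = 400.0  # 11 channels contaminated in 50% of epochs
        eps = E.detect_artifacts(self._eps(data))
        assert len(eps.bad_channels) == 11
        assert not eps.file_ok

    def test_retained_fraction_monotone_in_artifact_count(self):
        # artifact counts stay below the 20%-of-50-epochs bad-channel rescue,
        # where rejection is monotone in contamination
        cfg = ParadigmConfig(n_vocalizations=10, eeg_channels=6)
        fractions = []
        for n_art in (0, 4, 8):
            truth = EEGGroundTruth(noise_sd_uv=0.0, theta_amp_uv=0.0,
                                   artifacts=tuple((e, 1, 300.0) for e in range(n_art)))
            sess = generate_eeg_session(cfg, truth, seed=14)
            eps = E.detect_artifacts(E.segment(
                sess.eeg, FS, sess.event_samples_eeg,
                sess.event_magnitudes_cents, sess.channel_names))
            fractions.append(eps.epoch_keep.mean())
        assert fractions[0] == 1.0
        assert fractions[0] >= fractions[1] >= fractions[2]
        assert fractions[2] < 1.0


class TestRereference:
    def _eps(self, data, names):
        return E.EpochSet(data=data, times_ms=np.arange(data.shape[-1]), fs=FS,
                          channel_names=names,
                          magnitudes_cents=np.full(data.shape[0], 50.0))

    def test_manual_subtraction_oracle(self, rng):
        data = rng.standard_normal((2, 3, 50))
        names = ["Cz", "M1", "M2"]
        expect = data - data[:, 1:3].mean(axis=1, keepdims=True)
        eps = E.rereference(self._eps(data.copy(), names))
        np.testing.assert_allclose(eps.data, expect)

    def test_channel_equal_to_mastoid_mean_becomes_zero(self):
        data = np.zeros((1, 3, 20))
        data[0, 1] = 4.0
        data[0, 2] = 2.0
        data[0, 0] = 3.0  # equals the mastoid average
        eps = E.rereference(self._eps(data, ["Cz", "M1", "M2"]))
        np.testing.assert_allclose(eps.data[0, 0], 0.0)

    def test_rereference_idempotent_once_mastoids_zeroed(self, rng):
        data = rng.standard_normal((1, 3, 30))
        eps = E.rereference(self._eps(data, ["Cz", "M1", "M2"]))
        once = eps.data.copy()
        twice = E.rereference(eps).data
        np.testing.assert_allclose(twice, once)

    def test_missing_mastoid_errors(self):
        with pytest.raises(KeyError):
            E.rereference(self._eps(np.zeros((1, 2, 10)), ["Cz", "M1"]))


class TestAverageAndPeaks:
    def _avg(self, data, names=("Cz",), bad=()):
        return E.ERPAverage(data=data, times_ms=np.arange(-200, 501), fs=FS,
                            channel_names=list(names), bad_channels=list(bad),
                            n_retained=10, retained_fraction=1.0)

    def test_constant_offset_zero_after_baseline(self):
        eps = E.EpochSet(data=np.full((6, 2, 701), 11.0),
                         times_ms=np.arange(-200, 501), fs=FS,
                         channel_names=["a", "b"],
                         magnitudes_cents=np.full(6, 50.0))
        avg = E.average_and_baseline(eps)
        np.testing.assert_allclose(avg.data, 0.0, atol=1e-12)
        assert avg.retained_fraction == 1.0

    def test_average_within_clt_bound_of_template(self, rng):
        t = np.arange(-200, 501, dtype=float)
        template = -5.0 * np.exp(-0.5 * ((t - 130) / 15.0) ** 2)
        n = 150
        noise_sd = 1.0
        data = template + rng.normal(0, noise_sd, (n, 1, len(t)))
        eps = E.EpochSet(data=data, times_ms=t, fs=FS, channel_names=["Cz"],
                         magnitudes_cents=np.full(n, 50.0))
        avg = E.average_and_baseline(eps)
        corrected = template - template[t < 0].mean()
        assert np.abs(avg.data[0] - corrected).max() < 5 * noise_sd / np.sqrt(n)

    def test_gaussian_negativity_measured_exactly(self):
        t = np.arange(-200, 501, dtype=float)
        data = (-5.0 * np.exp(-0.5 * ((t - 130) / 15.0) ** 2))[None, :]
        pk = E.measure_peak(self._avg(data), "N1", "Cz")
        assert pk.amplitude_uv == pytest.approx(-5.0, abs=1e-9)
        assert pk.latency_ms == 130.0

    def test_flat_waveform_tiebreak_to_window_start(self):
        pk = E.measure_peak(self._avg(np.zeros((1, 701))), "P2", "Cz")
        assert pk.amplitude_uv == 0.0
        assert pk.latency_ms == 160.0

    def test_two_equal_maxima_earlier_latency(self):
        t = np.arange(-200, 501, dtype=float)
        data = np.zeros((1, len(t)))
        data[0, np.searchsorted(t, 200)] = 3.0
        data[0, np.searchsorted(t, 250)] = 3.0
        pk = E.measure_peak(self._avg(data), "P2", "Cz")
        assert pk.latency_ms == 200.0

    def test_bad_electrode_missing_value(self):
        pk = E.measure_peak(self._avg(np.zeros((1, 701)), bad=("Cz",)), "N1", "Cz")
        assert pk.missing

    def test_latency_always_inside_search_window(self, rng):
        data = rng.standard_normal((1, 701))
        for comp, (lo, hi) in E.PEAK_WINDOWS_MS.items():
            pk = E.measure_peak(self._avg(data), comp, "Cz")
            assert lo <= pk.latency_ms <= hi


def test_zero_noise_peaks_recovered_exactly(tiny_paradigm, quiet_eeg_truth):
    """Unfiltered zero-noise pipeline recovers programmed N1/P2 to the sample."""
    sess = generate_eeg_session(tiny_paradigm, quiet_eeg_truth, seed=21)
    eps = E.segment(sess.eeg, FS, sess.event_samples_eeg,
                    sess.event_magnitudes_cents, sess.channel_names)
    eps = E.detect_artifacts(eps)
    eps = E.rereference(eps)
    for cond in (50.0, 200.0):
        avg = E.average_and_baseline(eps, cond)
        n1 = E.measure_peak(avg, "N1", "Cz")
        p2 = E.measure_peak(avg, "P2", "Cz")
        assert n1.latency_ms == pytest.approx(quiet_eeg_truth.n1[cond][1], abs=1.0)
        assert p2.latency_ms == pytest.approx(quiet_eeg_truth.p2[cond][1], abs=1.0)
        assert n1.amplitude_uv == pytest.approx(quiet_eeg_truth.n1[cond][0], rel=0.02)
        assert p2.amplitude_uv == pytest.approx(quiet_eeg_truth.p2[cond][0], rel=0.02)


def test_pipeline_order_and_full_run(tiny_paradigm):
    truth = EEGGroundTruth(noise_sd_uv=2.0, theta_amp_uv=5.0,
                           theta_blocks=(((0, 1, 2), 0.5),))
    sess = generate_eeg_session(tiny_paradigm, truth, seed=22)
    eps, averages = E.erp_pipeline(sess.eeg, FS, sess.event_samples_eeg,
                                   sess.event_magnitudes_cents, sess.channel_names)
    assert set(averages) == {50.0, 200.0}
    for avg in averages.values():
        assert avg.data.shape == (tiny_paradigm.eeg_channels, 701)
        np.testing.assert_allclose(avg.data[:, avg.times_ms < 0].mean(axis=1),
                                   0.0, atol=1e-9)
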