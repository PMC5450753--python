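"""Filtering, epoching, artifact handling, and ERP assembly contracts."""

import numpy as np
import pytest

from denserp.headmodel import build_head_model, compute_lead_field, place_sensors
from denserp.preprocessing import (CONDITIONS, ContinuousRecording, EpochSet,
                                   PreprocessingError,
                                   average_reference_and_baseline,
                                   build_erp_dataset, design_bandpass_fir,
                                   detect_bad_channels, extract_epochs,
                                   fir_bandpass, reject_artifact_epochs,
                                   spline_interpolate)

FS = 250.0


def _rec(data, events=()):
    return ContinuousRecording(np.asarray(data, float), FS, list(events))


class TestBandpass:
    def test_zero_in_zero_out(self):
        out = fir_bandpass(_rec(np.zeros((2, 12000))), 0.5, 30.0)
        assert np.all(out.data == 0)
        assert out.data.shape == (2, 12000)

    def test_passband_gain_and_stopband_attenuation(self):
        """Checked against the analytic frequency response of the designed
        kernel and against filtered sinusoids."""
        import scipy.signal
        h = design_bandpass_fir(FS, 0.1, 30.0)
        w, H = scipy.signal.freqz(h, worN=[10.0, 60.0], fs=FS)
        assert 0.99 < abs(H[0]) < 1.01
        assert 20 * np.log10(abs(H[1])) < -40
        t = np.arange(15000) / FS
        mid = slice(5000, 10000)
        ten = fir_bandpass(_rec(np.sin(2 * np.pi * 10 * t)[None, :]), 0.1, 30.0)
        amp10 = np.abs(ten.data[0, mid]).max()
        assert 0.99 < amp10 < 1.01
        sixty = fir_bandpass(_rec(np.sin(2 * np.pi * 60 * t)[None, :]), 0.1, 30.0)
        assert np.abs(sixty.data[0, mid]).max() < 0.01

    def test_zero_phase_impulse_symmetry(self):
        x = np.zeros((1, 12000))
        x[0, 6000] = 1.0
        y = fir_bandpass(_rec(x), 0.1, 30.0).data[0]
        k = 2000
        assert np.allclose(y[6000 - k:6000], y[6000 + k:6000:-1], atol=1e-12)

    def test_record_shorter_than_filter_rejected(self):
        with pytest.raises(PreprocessingError, match="shorter"):
            fir_bandpass(_rec(np.zeros((1, 500))), 0.1, 30.0)


class TestEpoching:
    def test_window_index_arithmetic(self):
        data = np.arange(2000, dtype=float)[None, :]
        es = extract_epochs(_rec(data, [(1000, "partner_accept")]), (-200, 800))
        ep = es.data["partner_accept"][0, 0]
        assert ep.shape == (250,)
        assert ep[0] == 950 and ep[-1] == 1199  # samples [950, 1200)
        assert es.onset_sample() == 50

    def test_condition_partition(self):
        rng = np.random.default_rng(0)
        events = [(300 + 260 * i, CONDITIONS[i % 4]) for i in range(45)]
        es = extract_epochs(_rec(rng.normal(size=(3, 13000)), events), (-200, 800))
        assert sum(v.shape[0] for v in es.data.values()) == 45

    def test_edge_event_skipped_and_logged(self):
        es = extract_epochs(_rec(np.zeros((1, 1000)),
                                 [(10, "partner_accept"), (500, "partner_accept")]),
                            (-200, 800))
        assert es.data["partner_accept"].shape[0] == 1
        assert es.rejection_log["skipped_events"][0]["sample"] == 10


class TestBadChannels:
    def test_flat_channel_not_flagged(self):
        assert detect_bad_channels(np.full((3, 1000), 7.5), FS) == set()

    def test_sustained_step_flagged(self):
        x = np.zeros((2, 1000))
        x[1, 500:] = 300.0  # smoothed range equals the full step size
        assert detect_bad_channels(x, FS) == {1}

    def test_single_sample_spike_survives(self):
        # 80 ms at 250 Hz = 20 samples; smoothed excursion 300/20 = 15 uV
        x = np.zeros((1, 1000))
        x[0, 500] = 300.0
        assert detect_bad_channels(x, FS) == set()
        assert detect_bad_channels(x, FS, threshold_uv=14.0) == {0}


class TestSplineInterpolation:
    def test_constant_field_reproduced(self, sensors):
        epoch = np.full((sensors.n_sensors, 10), 3.25)
        out = spline_interpolate(epoch, {5}, sensors)
        assert np.abs(out[5] - 3.25).max() < 1e-8
        assert np.array_equal(out[0], epoch[0])

    def test_leave_one_out_on_forward_topography(self, head, sensors):
        """A noiseless dipolar scalp pattern is recovered at a held-out
        channel to better than 10% relative error."""
        from test_headmodel import _point_source_space
        K = compute_lead_field(head, _point_source_space([[0.0, -30.0, 50.0]]),
                               sensors, 60).matrix
        topo = (K @ np.array([0.0, -0.5, 1.0]))[:, None]
        worst = 0.0
        for bad in [3, 20, 41]:
            est = spline_interpolate(topo, {bad}, sensors)[bad, 0]
            worst = max(worst, abs(est - topo[bad, 0]))
        assert worst < 0.10 * np.abs(topo).max()

    def test_empty_bad_set_is_noop(self, sensors):
        rng = np.random.default_rng(2)
        epoch = rng.normal(size=(sensors.n_sensors, 5))
        assert np.array_equal(spline_interpolate(epoch, set(), sensors), epoch)

    def test_too_few_good_channels_rejected(self, sensors):
        epoch = np.zeros((sensors.n_sensors, 3))
        with pytest.raises(PreprocessingError, match="good channels"):
            spline_interpolate(epoch, set(range(sensors.n_sensors - 3)), sensors)


class TestArtifactRejection:
    def _epochs(self, arrays):
        return EpochSet("S0", {"partner_accept": np.asarray(arrays, float)},
                        (-200.0, 800.0), FS)

    def test_blink_epoch_rejected_clean_retained(self):
        clean = np.zeros((4, 250))
        blink = np.zeros((4, 250))
        blink[0, 100:130] = 120.0
        blink[0, 130:160] = -120.0  # ~240 uV p2p on a periocular channel
        es = reject_artifact_epochs(self._epochs([clean, blink]), {0}, 150.0)
        assert es.data["partner_accept"].shape[0] == 1
        assert es.rejection_log["rejected_epochs"]["partner_accept"] == 1

    def test_infinite_threshold_retains_all(self):
        rng = np.random.default_rng(3)
        es = reject_artifact_epochs(self._epochs(rng.normal(size=(5, 4, 250)) * 500),
                                    {0, 1}, np.inf)
        assert es.data["partner_accept"].shape[0] == 5

    def test_bookkeeping_retained_plus_rejected(self):
        rng = np.random.default_rng(4)
        arr = rng.normal(scale=80, size=(20, 4, 250))
        es = reject_artifact_epochs(self._epochs(arr), {0}, 150.0)
        assert (es.data["partner_accept"].shape[0]
                + es.rejection_log["rejected_epochs"]["partner_accept"]) == 20


class TestBaselineReference:
    def test_both_projections_vanish_and_commute(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 4, 32, 250)) + 5.0
        out = average_reference_and_baseline(x, FS, (-200, 800))
        assert np.abs(out[..., :50].mean(axis=-1)).max() < 1e-9
        assert np.abs(out.mean(axis=-2)).max() < 1e-9
        # order of the two centering projections does not matter
        y = np.array(x)
        y -= y.mean(axis=-2, keepdims=True)
        y -= y[..., :50].mean(axis=-1, keepdims=True)
        y -= y.mean(axis=-2, keepdims=True)
        assert np.allclose(out, y, atol=1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(8, 250))
        once = average_reference_and_baseline(x, FS, (-200, 800))
        twice = average_reference_and_baseline(once, FS, (-200, 800))
        assert np.abs(once - twice).max() < 1e-12

    def test_constant_epoch_maps_to_zero(self):
        out = average_reference_and_baseline(np.full((8, 250), 4.2), FS, (-200, 800))
        assert np.abs(out).max() < 1e-12


class TestErpAssembly:
    def _epoch_set(self, sid, counts, rng):
        data = {c: rng.normal(size=(n, 4, 250)) for c, n in zip(CONDITIONS, counts)}
        return EpochSet(sid, data, (-200.0, 800.0), FS)

    def test_low_trial_subject_excluded(self):
        rng = np.random.default_rng(7)
        sets = [self._epoch_set("good", [12, 12, 12, 12], rng),
                self._epoch_set("bad", [12, 9, 12, 12], rng)]
        erp = build_erp_dataset(sets, min_trials=10)
        assert erp.subjects == ["good"]
        assert "bad" in erp.excluded

    def test_all_clean_subjects_included(self):
        rng = np.random.default_rng(8)
        sets = [self._epoch_set(f"S{i}", [10] * 4, rng) for i in range(5)]
        assert len(build_erp_dataset(sets, 10).subjects) == 5

    def test_average_of_identical_epochs_is_the_epoch(self):
        rng = np.random.default_rng(9)
        ep = rng.normal(size=(4, 250))
        sets = [EpochSet("S0", {c: np.stack([ep] * 5) for c in CONDITIONS},
                         (-200.0, 800.0), FS)]
        erp = build_erp_dataset(sets, min_trials=5)
        want = average_reference_and_baseline(ep, FS, (-200, 800))
        assert np.allclose(erp.data[0, 0], want, atol=1e-12)

    def test_no_survivors_is_an_error(self):
        rng = np.random.default_rng(10)
        with pytest.raises(PreprocessingError, match="no subjects"):
            build_erp_dataset([self._epoch_set("S0", [2, 2, 2, 2], rng)], 10)
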