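"""Generator contracts: determinism, configured truth, noise structure."""

import numpy as np
import pytest

from denserp.decomposition import parallel_test
from denserp.preprocessing import CONDITIONS, extract_epochs
from denserp.simulate import (ComponentSpec, NoiseModel, SimConfig,
                              SimulationError, gaussian_bump,
                              make_default_ground_truth, simulate_amplitude_tables,
                              simulate_dataset)

NOISELESS = NoiseModel(background_rms=0.0, sensor_rms=0.0, blink_rate=0.0,
                       bad_channel_prob=0.0)


@pytest.fixture(scope="module")
def default_truth(src, lead_field):
    return make_default_ground_truth(src, lead_field)


class TestDefaultGroundTruth:
    def test_latencies_and_validity(self, default_truth):
        specs, _ = default_truth
        assert {s.peak_latency_ms for s in specs} == {124.0, 164.0, 288.0, 364.0}
        for s in specs:
            assert s.fwhm_ms > 0
            assert all(np.isfinite(list(s.condition_amplitudes.values())))

    def test_peer_p3a_effect_is_null(self, default_truth):
        specs, _ = default_truth
        p3a = next(s for s in specs if s.name == "P3a")
        assert p3a.condition_amplitudes["peer_accept"] == \
            p3a.condition_amplitudes["peer_reject"]
        assert p3a.paired_effect("peer_accept", "peer_reject", 30) == 0.0

    def test_configured_effect_sizes(self, default_truth):
        """Standardized paired effects anchored at ~0.33 (P3a partner) and
        ~0.33/0.41 (P3b partner/peer) for 30 trials per condition."""
        specs, _ = default_truth
        p3a = next(s for s in specs if s.name == "P3a")
        p3b = next(s for s in specs if s.name == "P3b")
        assert p3a.paired_effect("partner_accept", "partner_reject", 30) == \
            pytest.approx(0.33, abs=0.02)
        assert p3b.paired_effect("partner_accept", "partner_reject", 30) == \
            pytest.approx(0.33, abs=0.02)
        assert p3b.paired_effect("peer_accept", "peer_reject", 30) == \
            pytest.approx(0.41, abs=0.02)

    def test_topography_normalization(self, default_truth):
        specs, truth = default_truth
        for s in specs:
            ch = truth.measurement_channels[s.name]
            assert truth.topographies[s.name][ch].mean() == pytest.approx(1.0)


class TestSimulateDataset:
    def test_seed_reproducibility(self, src, lead_field, sensors, default_truth):
        specs, _ = default_truth
        cfg = SimConfig(n_subjects=2, trials_per_condition=3, seed=11)
        a, ea, _ = simulate_dataset(cfg, specs, NoiseModel(), lead_field, src, sensors)
        b, eb, _ = simulate_dataset(cfg, specs, NoiseModel(), lead_field, src, sensors)
        assert all(np.array_equal(x.data, y.data) for x, y in zip(a, b))
        assert ea.equals(eb)

    def test_event_table_count(self, src, lead_field, sensors, default_truth):
        specs, _ = default_truth
        cfg = SimConfig(n_subjects=3, trials_per_condition=4, seed=1)
        _, events, _ = simulate_dataset(cfg, specs, NOISELESS, lead_field, src, sensors)
        assert len(events) == 3 * 4 * len(CONDITIONS)

    def test_noiseless_epochs_equal_forward_projection(self, src, lead_field,
                                                       sensors):
        spec = ComponentSpec("P3b", 364.0, 120.0, (0.0, -30.0, 55.0), 12.0,
                             {c: 4.0 for c in CONDITIONS}, 0.0, 0.0)
        cfg = SimConfig(n_subjects=1, trials_per_condition=3, seed=5)
        recs, _, truth = simulate_dataset(cfg, [spec], NOISELESS, lead_field,
                                          src, sensors)
        es = extract_epochs(recs[0], (-200, 800))
        arrs = np.concatenate([es.data[c] for c in es.data])
        assert np.allclose(arrs, arrs[0], atol=1e-10)
        pred = 4.0 * np.outer(truth.topographies["P3b"],
                              gaussian_bump(es.times_ms(), 364.0, 120.0))
        assert np.abs(arrs[0] - pred).max() < 1e-10

    def test_monte_carlo_mean_difference(self, src, lead_field, sensors):
        """Window-mean partner effect within 3 SE of the configured delta."""
        delta, sd = 1.0, 3.0
        spec = ComponentSpec("P3b", 364.0, 120.0, (0.0, -30.0, 55.0), 12.0,
                             {"partner_accept": 4.0 + delta, "partner_reject": 4.0,
                              "peer_accept": 4.0, "peer_reject": 4.0},
                             0.0, sd)
        n_tr = 400
        cfg = SimConfig(n_subjects=1, trials_per_condition=n_tr, seed=6)
        recs, _, truth = simulate_dataset(cfg, [spec], NOISELESS, lead_field,
                                          src, sensors)
        es = extract_epochs(recs[0], (-200, 800))
        ch = truth.measurement_channels["P3b"]
        sl = slice(136, 146)  # 344-384 ms
        wmean = {c: es.data[c][:, ch, sl].mean(axis=(1, 2)).mean()
                 for c in ("partner_accept", "partner_reject")}
        wnorm = gaussian_bump(es.times_ms(), 364.0, 120.0)[sl].mean()
        se = np.sqrt(2.0 / n_tr) * sd * wnorm
        got = wmean["partner_accept"] - wmean["partner_reject"]
        assert abs(got - delta * wnorm) < 3 * se

    def test_blinks_and_bad_channels_logged(self, src, lead_field, sensors,
                                            default_truth):
        specs, _ = default_truth
        cfg = SimConfig(n_subjects=2, trials_per_condition=3, seed=12)
        noise = NoiseModel(blink_rate=20.0, bad_channel_prob=0.2)
        recs, _, truth = simulate_dataset(cfg, specs, noise, lead_field, src, sensors)
        assert any(len(truth.blink_samples[r.subject_id]) > 0 for r in recs)
        assert any(len(truth.bad_channels[r.subject_id]) > 0 for r in recs)

    def test_too_short_iti_rejected(self):
        with pytest.raises(SimulationError, match="inter-trial"):
            SimConfig(iti_s=0.5)


class TestAmplitudeLevelModel:
    def test_null_model_has_equal_means(self, default_truth):
        specs, _ = default_truth
        tabs = simulate_amplitude_tables(specs, 500, 30, seed=0, null_effects=True)
        for name, t in tabs.items():
            d = t[:, 0] - t[:, 1]
            assert abs(d.mean()) < 4 * d.std(ddof=1) / np.sqrt(len(d))

    def test_effect_matches_configuration(self, default_truth):
        specs, _ = default_truth
        p3b = next(s for s in specs if s.name == "P3b")
        t = simulate_amplitude_tables([p3b], 20000, 30, seed=1)["P3b"]
        d = t[:, 0] - t[:, 1]
        got = d.mean() / d.std(ddof=1)
        want = p3b.paired_effect("partner_accept", "partner_reject", 30)
        assert got == pytest.approx(want, abs=0.03)


class TestNoiselessEndToEnd:
    def test_pipeline_recovers_truth_without_noise(self, src, lead_field,
                                                   sensors):
        """With all noise sources at zero (only between-subject amplitude
        variability left, which the spatial ICA needs for observation
        diversity) the full chain recovers each component's peak latency
        within one sample and its scalp map with correlation >= 0.95."""
        from denserp.decomposition import TwoStepDecomposition, best_match
        from denserp.pipeline import DEFAULT_CONFIG, preprocess_recording
        from denserp.preprocessing import build_erp_dataset
        from denserp.simulate import build_ground_truth, iter_subject_recordings
        specs, _ = make_default_ground_truth(src, lead_field)
        specs = [ComponentSpec(s.name, s.peak_latency_ms, s.fwhm_ms,
                               s.source_center, s.source_extent,
                               s.condition_amplitudes, s.subject_sd, 0.0)
                 for s in specs]
        cfg = SimConfig(n_subjects=10, trials_per_condition=10, seed=21)
        truth = build_ground_truth(specs, src, lead_field)
        sets = [preprocess_recording(rec, sensors, DEFAULT_CONFIG["preprocess"])
                for rec, _ in iter_subject_recordings(
                    cfg, specs, truth, NOISELESS, lead_field, src, sensors)]
        erp = build_erp_dataset(sets, min_trials=10)
        res = TwoStepDecomposition(erp, n_temporal=4, n_spatial=4, seed=0,
                                   ica_max_iter=2048).fit()
        times = erp.times_ms()
        dt = 1000.0 / cfg.fs
        for s in specs:
            wv = gaussian_bump(times, s.peak_latency_ms, s.fwhm_ms)
            comp, rt, rs = best_match(res.selected, wv,
                                      truth.topographies[s.name])
            assert rs >= 0.95, f"{s.name}: spatial corr {rs:.4f}"
            assert abs(comp.qc["peak_latency_ms"] - s.peak_latency_ms) <= dt, \
                f"{s.name}: peak {comp.qc['peak_latency_ms']}"


class TestBackgroundOnlyRetention:
    def test_signal_free_observations_retain_almost_nothing(self):
        """Signal-free (white-noise) observations typically retain no
        temporal factors; the full null distribution of the retention rule
        is characterized in the decomposition tests."""
        rng = np.random.default_rng(42)
        rets = [parallel_test(rng.standard_normal((500, 100)), 10, seed=s).retained
                for s in range(10)]
        assert np.median(rets) <= 1
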