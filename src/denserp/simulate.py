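"""Ground-truth-known synthetic dense-array EEG.

The generator emulates the statistical structure of a social-feedback ERP
study: 75 subjects x 4 conditions (partner/peer x acceptance/rejection),
128-channel recordings at 250 Hz containing four stereotyped components --
two occipital N1 deflections (124 and 164 ms, no condition effect), a
frontocentral P3a (288 ms, partner acceptance > rejection only) and a
parietal P3b (364 ms, acceptance > rejection for partner and peer) -- on top
of spatially correlated background EEG (random transient dipoles with a
1/f-shaped spectrum projected through the lead field), stereotyped eye
blinks, occasional bad channels, and white sensor noise.

Every non-noise feature of the output is recorded in :class:`GroundTruth`,
so downstream recovery can be scored against configured truth.

Amplitude convention: each component's scalp topography is normalized so the
mean over its three strongest channels is one, making ``condition_amplitudes``
read directly in uV at the component's measurement channels.  ``trial_sd``
is the per-trial SD of the component amplitude; ``background_window_sd`` is
the additional per-epoch SD that the default background/sensor noise
contributes to a window-mean measurement (calibrated once for the default
noise model).  The implied standardized paired effect at ``n`` trials is
``d = delta / (sqrt(2 * (trial_sd^2 + background_window_sd^2) / n))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from denserp.headmodel import LeadField, SensorArray, SourceSpace
from denserp.preprocessing import CONDITIONS, ContinuousRecording

__all__ = [
    "ComponentSpec",
    "NoiseModel",
    "SimConfig",
    "GroundTruth",
    "make_default_ground_truth",
    "build_ground_truth",
    "subject_event_schedule",
    "simulate_dataset",
    "iter_subject_recordings",
    "simulate_amplitude_tables",
    "gaussian_bump",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ComponentSpec:
    """One stereotyped ERP component with a cortical patch source."""

    name: str
    peak_latency_ms: float
    fwhm_ms: float
    source_center: tuple  # mm
    source_extent: float  # mm, Gaussian patch SD
    condition_amplitudes: dict  # label -> uV at measurement channels
    subject_sd: float  # between-subject SD of the shared amplitude offset
    trial_sd: float  # within-subject trial-to-trial amplitude SD
    background_window_sd: float = 0.0  # per-epoch noise SD of a window-mean

    def __post_init__(self):
        if self.fwhm_ms <= 0:
            raise SimulationError(f"{self.name}: fwhm must be positive")
        if self.source_extent < 0:
            raise SimulationError(f"{self.name}: extent must be non-negative")
        if not all(np.isfinite(list(self.condition_amplitudes.values()))):
            raise SimulationError(f"{self.name}: non-finite amplitude")

    def measurement_sd(self, n_trials: int) -> float:
        """SD of the per-subject condition-mean window amplitude."""
        return float(np.sqrt((self.trial_sd ** 2 + self.background_window_sd ** 2) / n_trials))

    def paired_effect(self, cond_a: str, cond_b: str, n_trials: int) -> float:
        """Standardized paired effect (Cohen's d of the within-subject
        difference) implied by the configured amplitudes and noise."""
        delta = self.condition_amplitudes[cond_a] - self.condition_amplitudes[cond_b]
        return float(delta / (np.sqrt(2.0) * self.measurement_sd(n_trials)))


@dataclass(frozen=True)
class NoiseModel:
    """Noise and artifact generators for the synthetic recordings."""

    background_rms: float = 4.0  # uV, spatially correlated background
    sensor_rms: float = 2.0  # uV, white sensor noise
    blink_rate: float = 3.0  # events / min
    blink_amplitude: float = 120.0  # uV at the most anterior sensors
    blink_topography_scale_deg: float = 35.0  # angular decay of the blink map
    bad_channel_prob: float = 0.02  # per channel, per recording
    transient_rate: float = 200.0  # background dipole events / s
    transient_pool: int = 192  # distinct background dipole locations

    def __post_init__(self):
        for name in ("background_rms", "sensor_rms", "blink_rate",
                     "blink_amplitude", "bad_channel_prob", "transient_rate"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    n_subjects: int = 75
    conditions: tuple = CONDITIONS
    trials_per_condition: int = 30
    fs: float = 250.0
    seed: int = 0
    epoch_window_ms: tuple = (-200.0, 800.0)
    iti_s: float = 1.3  # event-to-event spacing
    lead_in_s: float = 2.0

    def __post_init__(self):
        if self.fs <= 0:
            raise SimulationError("fs must be positive")
        if self.trials_per_condition < 1:
            raise SimulationError("trials_per_condition must be >= 1")
        epoch_s = (self.epoch_window_ms[1] - self.epoch_window_ms[0]) / 1000.0
        if self.iti_s < epoch_s:
            raise SimulationError(
                f"inter-trial interval too short: {self.iti_s} s < epoch {epoch_s} s"
            )


@dataclass
class GroundTruth:
    """Complete provenance of the simulated signal content."""

    specs: list
    topographies: dict  # name -> (channels,), unit mean at measurement chans
    waveforms: dict  # name -> (epoch samples,), unit peak
    measurement_channels: dict  # name -> list of channel indices
    source_weights: dict  # name -> (locations,) patch weights on the grid
    patch_center_index: dict  # name -> index of the grid location at center
    subject_offsets: np.ndarray = None  # (subjects, components)
    events: dict = field(default_factory=dict)  # subject -> DataFrame
    blink_samples: dict = field(default_factory=dict)  # subject -> array
    bad_channels: dict = field(default_factory=dict)  # subject -> list
    trial_amplitudes: dict = field(default_factory=dict)  # subject -> (trials, comps)


def gaussian_bump(times_ms: np.ndarray, peak_ms: float, fwhm_ms: float) -> np.ndarray:
    """Unit-peak Gaussian waveform parameterized by peak latency and FWHM."""
    sd = fwhm_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((times_ms - peak_ms) / sd) ** 2)


def _patch_topography(center, extent, src: SourceSpace, K: LeadField):
    """Forward-project a radially oriented Gaussian patch; return the raw
    scalp map, the patch weights, and the index of the nearest grid node."""
    loc = src.locations
    d = np.linalg.norm(loc - np.asarray(center, float), axis=1)
    center_idx = int(np.argmin(d))
    if extent > 0:
        w = np.exp(-0.5 * (d / extent) ** 2)
        w[d > 3.0 * extent] = 0.0
    else:
        w = np.zeros(len(loc))
        w[center_idx] = 1.0
    r = np.linalg.norm(loc, axis=1)
    rhat = np.where(r[:, None] > 0, loc / np.maximum(r, 1e-300)[:, None], [0.0, 0.0, 1.0])
    moments = (w[:, None] * rhat).ravel()  # radial orientation
    topo = K.matrix @ moments
    return topo, w, center_idx


def build_ground_truth(specs, src: SourceSpace, K: LeadField,
                       n_measurement_channels: int = 3) -> GroundTruth:
    """Forward-project each spec's patch and assemble the provenance record.

    Topographies are normalized so the mean over each component's
    ``n_measurement_channels`` strongest channels is one (the package's
    documented stand-in for a published electrode montage), making condition
    amplitudes read directly in uV at those channels.
    """
    topos, meas, weights, centers = {}, {}, {}, {}
    for spec in specs:
        topo_raw, w, cidx = _patch_topography(spec.source_center, spec.source_extent, src, K)
        top = np.argsort(np.abs(topo_raw))[::-1][:n_measurement_channels]
        scale = topo_raw[top].mean()
        topos[spec.name] = topo_raw / scale
        meas[spec.name] = sorted(int(i) for i in top)
        weights[spec.name] = w / scale
        centers[spec.name] = cidx
    return GroundTruth(list(specs), topos, {}, meas, weights, centers)


def make_default_ground_truth(src: SourceSpace, K: LeadField,
                              n_measurement_channels: int = 3) -> tuple:
    """Default four-component truth (N1a, N1b, P3a, P3b) on a lead-field
    context; returns ``(specs, truth)``.

    Condition amplitudes are the published condition means; ``trial_sd``
    defaults realize standardized paired effects of ~0.33 for the partner
    P3a contrast and ~0.33/0.41 for the partner/peer P3b contrasts at 30
    trials per condition, with the peer P3a contrast exactly null.
    """
    # per-trial amplitude SDs calibrated for 30 trials/condition:
    # target SD of the paired subject-level difference = delta / d_target,
    # minus the default background's window-mean contribution (in quadrature).
    specs = [
        ComponentSpec("N1a", 124.0, 60.0, (15.0, -52.0, 0.0), 12.0,
                      {c: -1.2 for c in CONDITIONS}, subject_sd=1.5,
                      trial_sd=5.8, background_window_sd=5.2),
        ComponentSpec("N1b", 164.0, 70.0, (-15.0, -52.0, 7.0), 12.0,
                      {c: -3.3 for c in CONDITIONS}, subject_sd=1.5,
                      trial_sd=6.0, background_window_sd=4.9),
        ComponentSpec("P3a", 288.0, 120.0, (0.0, 25.0, 35.0), 12.0,
                      {"partner_accept": 2.05, "partner_reject": 1.37,
                       "peer_accept": 1.75, "peer_reject": 1.75},
                      subject_sd=2.0, trial_sd=6.7, background_window_sd=4.4),
        ComponentSpec("P3b", 364.0, 120.0, (0.0, -30.0, 55.0), 12.0,
                      {"partner_accept": 4.32, "partner_reject": 3.40,
                       "peer_accept": 4.06, "peer_reject": 2.93},
                      subject_sd=2.0, trial_sd=9.2, background_window_sd=5.5),
    ]
    return specs, build_ground_truth(specs, src, K, n_measurement_channels)


def _component_waveforms(specs, cfg: SimConfig) -> dict:
    w0, w1 = cfg.epoch_window_ms
    n = int(round((w1 - w0) * cfg.fs / 1000.0))
    t = w0 + np.arange(n) * 1000.0 / cfg.fs
    return {s.name: gaussian_bump(t, s.peak_latency_ms, s.fwhm_ms) for s in specs}


def _background(rng, noise: NoiseModel, K: LeadField, src: SourceSpace,
                n_channels: int, n_samples: int, fs: float) -> np.ndarray:
    """Spatially correlated background: random transient dipoles with
    1/f-shaped amplitudes projected through the lead field.

    Pulse widths are log-uniform and amplitudes scale as width^-1/2, which
    makes the superposed power spectrum approximately 1/f; the projected
    signal is rescaled so the median channel RMS equals ``background_rms``.
    """
    if noise.background_rms <= 0:
        return np.zeros((n_channels, n_samples))
    n_pool = min(noise.transient_pool, src.n_locations)
    pool = rng.choice(src.n_locations, size=n_pool, replace=False)
    ori = rng.normal(size=(n_pool, 3))
    ori /= np.linalg.norm(ori, axis=1, keepdims=True)
    cols = K.matrix.reshape(K.matrix.shape[0], src.n_locations, 3)[:, pool, :]
    patterns = np.einsum("cpk,pk->cp", cols, ori)  # (channels, pool)

    dur = n_samples / fs
    n_events = rng.poisson(noise.transient_rate * dur)
    if n_events == 0:
        return np.zeros((n_channels, n_samples))
    # pulse widths span the theta/alpha-dominated band of ongoing EEG
    # (~2-12 Hz); amplitudes ~ width^-1/2 shape the ensemble spectrum as 1/f
    # within that band
    lo_s, hi_s = 0.03, 0.12
    width_s = np.exp(rng.uniform(np.log(lo_s), np.log(hi_s), size=n_events))
    amps = rng.normal(size=n_events) * np.sqrt(0.05 / width_s)
    times = rng.integers(0, n_samples, size=n_events)
    members = rng.integers(0, n_pool, size=n_events)

    # quantize widths into a few bins and convolve impulse trains per bin
    bins = np.geomspace(lo_s, hi_s, 7)
    which = np.clip(np.digitize(width_s, bins) - 1, 0, 5)
    Q = np.zeros((n_pool, n_samples))
    for b in range(6):
        sel = which == b
        if not sel.any():
            continue
        train = np.zeros((n_pool, n_samples))
        np.add.at(train, (members[sel], times[sel]), amps[sel])
        sd = np.sqrt(bins[b] * bins[b + 1]) * fs  # geometric-mean width, samples
        half = int(np.ceil(4 * sd))
        kern = np.exp(-0.5 * (np.arange(-half, half + 1) / sd) ** 2)
        Q += scipy.signal.fftconvolve(train, kern[None, :], mode="same", axes=1)
    Y = patterns @ Q
    rms = np.median(np.sqrt((Y ** 2).mean(axis=1)))
    if rms > 0:
        Y *= noise.background_rms / rms
    return Y


def blink_pattern(sensors: SensorArray, scale_deg: float = 35.0) -> np.ndarray:
    """Frontal-gradient blink topography, unit at the most anterior sensor."""
    pos = sensors.positions / np.linalg.norm(sensors.positions, axis=1, keepdims=True)
    anterior = pos[np.argmax(sensors.positions[:, 1])]
    ang = np.degrees(np.arccos(np.clip(pos @ anterior, -1.0, 1.0)))
    return np.exp(-ang / scale_deg)


def blink_waveform(fs: float, duration_s: float = 0.3) -> np.ndarray:
    """Stereotyped biphasic blink, peaks +1/-1 (p2p = 2)."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / n
    w = np.sin(2.0 * np.pi * t) * np.hanning(n)
    return w / np.abs(w).max()


def periocular_channels(sensors: SensorArray, k: int = 4) -> list:
    """The k most anterior sensors -- the designated blink-detection set."""
    return sorted(int(i) for i in np.argsort(sensors.positions[:, 1])[::-1][:k])


def subject_event_schedule(cfg: SimConfig, subj_index: int, seed: int):
    """Deterministic event schedule for one subject: (onset samples, label
    indices).  Uses its own seed substream so the schedule can be derived
    without generating data."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, subj_index, 1]))
    n_trials = cfg.trials_per_condition * len(cfg.conditions)
    labels = np.repeat(np.arange(len(cfg.conditions)), cfg.trials_per_condition)
    rng.shuffle(labels)
    onsets = ((cfg.lead_in_s + np.arange(n_trials) * cfg.iti_s) * cfg.fs).astype(int)
    return onsets, labels


def _simulate_subject(subj_index: int, cfg: SimConfig, specs, truth: GroundTruth,
                      noise: NoiseModel, K: LeadField, src: SourceSpace,
                      sensors: SensorArray, seed: int):
    """Build one subject's continuous recording; returns (recording, events,
    subject log dict)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, subj_index, 2]))
    fs = cfg.fs
    onsets, labels = subject_event_schedule(cfg, subj_index, seed)
    n_trials = len(onsets)
    n_samples = int(onsets[-1] + (cfg.lead_in_s + 1.0) * fs)
    C = sensors.n_sensors

    data = _background(rng, noise, K, src, C, n_samples, fs)
    if noise.sensor_rms > 0:
        data += rng.normal(scale=noise.sensor_rms, size=data.shape)

    waves = _component_waveforms(specs, cfg)
    w0 = cfg.epoch_window_ms[0]
    off0 = int(round(w0 * fs / 1000.0))
    n_ep = next(iter(waves.values())).shape[0]
    offsets = rng.normal(size=len(specs)) * np.array([s.subject_sd for s in specs])
    trial_amp = np.empty((n_trials, len(specs)))
    for j, spec in enumerate(specs):
        topo = truth.topographies[spec.name]
        wv = waves[spec.name]
        for ti in range(n_trials):
            cond = cfg.conditions[labels[ti]]
            amp = (spec.condition_amplitudes[cond] + offsets[j]
                   + rng.normal() * spec.trial_sd)
            trial_amp[ti, j] = amp
            a = onsets[ti] + off0
            data[:, a:a + n_ep] += np.outer(topo, amp * wv)

    # eye blinks at Poisson times
    n_blinks = rng.poisson(noise.blink_rate * n_samples / fs / 60.0)
    bw = blink_waveform(fs)
    bp = blink_pattern(sensors, noise.blink_topography_scale_deg)
    blink_samples = np.sort(rng.integers(0, n_samples - bw.size, size=n_blinks))
    for b in blink_samples:
        data[:, b:b + bw.size] += noise.blink_amplitude * np.outer(bp, bw)

    # bad channels replaced by high-amplitude noise (white + slow drift)
    bad = np.nonzero(rng.random(C) < noise.bad_channel_prob)[0].tolist()
    t_s = np.arange(n_samples) / fs
    for c in bad:
        data[c] = (rng.normal(scale=120.0, size=n_samples)
                   + 250.0 * np.sin(2 * np.pi * 0.7 * t_s + rng.uniform(0, 2 * np.pi)))

    sid = f"S{subj_index:03d}"
    events = [(int(s), cfg.conditions[l]) for s, l in zip(onsets, labels)]
    rec = ContinuousRecording(data, fs, events, sid)
    ev_df = pd.DataFrame({"subject": sid,
                          "onset_sample": onsets,
                          "condition": [cfg.conditions[l] for l in labels]})
    log = {"events": ev_df, "blink_samples": blink_samples, "bad_channels": bad,
           "offsets": offsets, "trial_amplitudes": trial_amp}
    return rec, ev_df, log


def iter_subject_recordings(cfg: SimConfig, specs, truth: GroundTruth,
                            noise: NoiseModel, K: LeadField, src: SourceSpace,
                            sensors: SensorArray, seed=None):
    """Yield ``(recording, events)`` per subject, filling ``truth`` in place.

    Identical config and seed give bit-identical output; subjects are
    seeded independently, so the stream order does not matter.
    """
    if not specs:
        raise SimulationError("no component specs given")
    seed = cfg.seed if seed is None else seed
    truth.waveforms = _component_waveforms(specs, cfg)
    n_comp = len(specs)
    if truth.subject_offsets is None or truth.subject_offsets.shape != (cfg.n_subjects, n_comp):
        truth.subject_offsets = np.zeros((cfg.n_subjects, n_comp))
    for i in range(cfg.n_subjects):
        rec, ev, log = _simulate_subject(i, cfg, specs, truth, noise, K, src, sensors, seed)
        truth.subject_offsets[i] = log["offsets"]
        truth.events[rec.subject_id] = log["events"]
        truth.blink_samples[rec.subject_id] = log["blink_samples"]
        truth.bad_channels[rec.subject_id] = log["bad_channels"]
        truth.trial_amplitudes[rec.subject_id] = log["trial_amplitudes"]
        yield rec, ev


def simulate_dataset(cfg: SimConfig, specs, noise: NoiseModel, K: LeadField,
                     src: SourceSpace, sensors: SensorArray, seed=None):
    """Materialize the full dataset: (recordings, event table, GroundTruth).

    Convenience wrapper over :func:`iter_subject_recordings`; for large
    configurations prefer the iterator to keep one recording in memory at a
    time.
    """
    truth = build_ground_truth(specs, src, K)
    recs, evs = [], []
    for rec, ev in iter_subject_recordings(cfg, specs, truth, noise, K, src, sensors, seed):
        recs.append(rec)
        evs.append(ev)
    events = pd.concat(evs, ignore_index=True)
    return recs, events, truth


def simulate_amplitude_tables(specs, n_subjects: int, n_trials: int, seed: int,
                              conditions=CONDITIONS, null_effects: bool = False) -> dict:
    """Amplitude-level generative model for power / type-I Monte-Carlo.

    Draws, for each component, the subjects x conditions table of measured
    window amplitudes implied by the generator's parameters: shared subject
    offset (cancels within subject) plus condition mean plus measurement
    noise of SD ``measurement_sd(n_trials)``.  With ``null_effects`` the
    condition means are replaced by their across-condition average.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for j, spec in enumerate(specs):
        mu = np.array([spec.condition_amplitudes[c] for c in conditions])
        if null_effects:
            mu = np.full_like(mu, mu.mean())
        offs = rng.normal(scale=spec.subject_sd, size=n_subjects)
        eps = rng.normal(scale=spec.measurement_sd(n_trials),
                         size=(n_subjects, len(conditions)))
        out[spec.name] = mu[None, :] + offs[:, None] + eps
    return out
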