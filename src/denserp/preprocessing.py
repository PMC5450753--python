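"""Preprocessing: continuous recordings -> per-subject, per-condition ERPs.

The chain mirrors standard dense-array ERP practice: zero-phase FIR band-pass
(0.1-30 Hz), epoching around feedback events (-200..+800 ms, half-open),
bad-channel detection (80 ms moving average, 200 uV max-min rule) with
spherical-spline replacement, ocular-artifact epoch rejection, per-condition
averaging, baseline correction to the pre-stimulus interval, and common
average referencing.  Subjects with too few artifact-free trials in any
condition are excluded from the ERP dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal
from scipy.ndimage import uniform_filter1d

from denserp.headmodel import SensorArray

__all__ = [
    "ContinuousRecording",
    "EpochSet",
    "ERPDataset",
    "fir_bandpass",
    "extract_epochs",
    "detect_bad_channels",
    "spline_interpolate",
    "reject_artifact_epochs",
    "average_reference_and_baseline",
    "build_erp_dataset",
    "CONDITIONS",
]

#: Canonical condition order used throughout the package.
CONDITIONS = ("partner_accept", "partner_reject", "peer_accept", "peer_reject")


class PreprocessingError(ValueError):
    pass


@dataclass
class ContinuousRecording:
    """Continuous multichannel recording in uV.

    ``events`` is a list of ``(sample_index, condition_label)`` pairs.
    """

    data: np.ndarray  # (channels, samples) uV
    fs: float
    events: list = field(default_factory=list)
    subject_id: str = "S0"

    def __post_init__(self):
        if self.fs <= 0:
            raise PreprocessingError(f"fs must be positive, got {self.fs}")
        n = self.data.shape[1]
        for s, _ in self.events:
            if not (0 <= s < n):
                raise PreprocessingError(f"event sample {s} outside record of {n} samples")


@dataclass
class EpochSet:
    """Per-condition stacks of epochs for one subject.

    ``data[label]`` has shape (trials, channels, samples); the epoch window
    is half-open, so at 250 Hz a -200..+800 ms window holds exactly 250
    samples with sample 50 (0-based) at stimulus onset.
    """

    subject_id: str
    data: dict  # label -> (trials, channels, samples)
    window_ms: tuple
    fs: float
    rejection_log: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        w0, w1 = self.window_ms
        return int(round((w1 - w0) * self.fs / 1000.0))

    def trial_counts(self) -> dict:
        return {k: v.shape[0] for k, v in self.data.items()}

    def onset_sample(self) -> int:
        return int(round(-self.window_ms[0] * self.fs / 1000.0))

    def times_ms(self) -> np.ndarray:
        w0, _ = self.window_ms
        return w0 + np.arange(self.n_samples) * 1000.0 / self.fs


@dataclass
class ERPDataset:
    """subjects x conditions x channels x samples grand-average-ready array,
    baseline-corrected and average-referenced, in uV."""

    data: np.ndarray
    subjects: list
    conditions: tuple
    fs: float
    window_ms: tuple
    trial_counts: np.ndarray  # (subjects, conditions)
    excluded: dict = field(default_factory=dict)  # subject -> reason

    @property
    def n_samples(self) -> int:
        return self.data.shape[-1]

    def times_ms(self) -> np.ndarray:
        w0, _ = self.window_ms
        return w0 + np.arange(self.n_samples) * 1000.0 / self.fs

    def window_slice(self, window_ms) -> slice:
        """Half-open sample slice for a latency window in ms."""
        w0 = self.window_ms[0]
        a = int(round((window_ms[0] - w0) * self.fs / 1000.0))
        b = int(round((window_ms[1] - w0) * self.fs / 1000.0))
        if a < 0 or b > self.n_samples or a >= b:
            raise PreprocessingError(f"window {window_ms} outside epoch {self.window_ms}")
        return slice(a, b)


def design_bandpass_fir(fs: float, low: float, high: float,
                        trans_low: float = 0.1, trans_high: float = 7.5) -> np.ndarray:
    """Hamming-window linear-phase band-pass kernel (odd length, symmetric).

    Built as a cascade of a high-pass with a narrow (``trans_low`` Hz)
    transition and a low-pass with a wide (``trans_high`` Hz) transition, so
    the sluggish low edge does not force absurd length onto the upper edge.
    """
    if not (0 < low < high < fs / 2):
        raise PreprocessingError(f"need 0 < low < high < fs/2, got {low}, {high}, fs={fs}")

    def _taps(trans):
        n = int(np.ceil(3.3 * fs / trans))
        return n + 1 if n % 2 == 0 else n

    h_hp = scipy.signal.firwin(_taps(trans_low), low, window="hamming", pass_zero=False, fs=fs)
    h_lp = scipy.signal.firwin(_taps(trans_high), high, window="hamming", pass_zero=True, fs=fs)
    return np.convolve(h_hp, h_lp)


def fir_bandpass(rec: ContinuousRecording, low: float = 0.1, high: float = 30.0) -> ContinuousRecording:
    """Zero-phase band-pass filter of a continuous recording.

    The symmetric odd-length kernel applied with centered ("same")
    convolution gives exactly zero phase; output length equals input length.
    """
    h = design_bandpass_fir(rec.fs, low, high)
    if rec.data.shape[1] < h.size:
        raise PreprocessingError(
            f"record of {rec.data.shape[1]} samples shorter than filter ({h.size} taps)"
        )
    out = scipy.signal.fftconvolve(rec.data, h[None, :], mode="same", axes=1)
    return ContinuousRecording(out, rec.fs, list(rec.events), rec.subject_id)


def extract_epochs(rec: ContinuousRecording, window_ms=(-200.0, 800.0)) -> EpochSet:
    """Cut one epoch per event, grouped by condition label.

    The window is half-open ``[w0, w1)`` relative to event onset.  Events too
    close to the record edge are skipped and logged.
    """
    w0, w1 = window_ms
    if not (w0 <= 0 < w1):
        raise PreprocessingError(f"window {window_ms} must cover stimulus onset")
    fs = rec.fs
    off0 = int(round(w0 * fs / 1000.0))
    n = int(round((w1 - w0) * fs / 1000.0))
    T = rec.data.shape[1]
    groups: dict = {}
    skipped = []
    for sample, label in rec.events:
        a = sample + off0
        if a < 0 or a + n > T:
            skipped.append({"sample": int(sample), "condition": label, "reason": "edge"})
            continue
        groups.setdefault(label, []).append(rec.data[:, a:a + n])
    data = {k: np.stack(v) for k, v in groups.items()}
    log = {"skipped_events": skipped}
    return EpochSet(rec.subject_id, data, (float(w0), float(w1)), fs, log)


def detect_bad_channels(data: np.ndarray, fs: float,
                        smooth_ms: float = 80.0, threshold_uv: float = 200.0) -> set:
    """Flag channels whose smoothed max-min range exceeds ``threshold_uv``.

    Each channel is smoothed with a centered moving average of
    ``round(smooth_ms * fs / 1000)`` samples before taking the range, so a
    single-sample 300 uV spike (smoothed excursion 300/20 = 15 uV at 250 Hz)
    survives while a sustained 300 uV step is flagged.  ``data`` is
    (channels, samples) -- per-recording concatenated epochs in the pipeline.
    """
    if smooth_ms <= 0:
        raise PreprocessingError(f"smooth_ms must be positive, got {smooth_ms}")
    size = max(1, int(round(smooth_ms * fs / 1000.0)))
    sm = uniform_filter1d(np.asarray(data, float), size=size, axis=1, mode="nearest")
    rng = sm.max(axis=1) - sm.min(axis=1)
    return set(np.nonzero(rng > threshold_uv)[0].tolist())


def _spline_g(cosang: np.ndarray, m: int, terms: int) -> np.ndarray:
    """Perrin-style spherical-spline kernel g(x) on cos(angle)."""
    x = np.asarray(cosang, float)
    g = np.zeros_like(x)
    Pnm1 = np.ones_like(x)
    Pn = x.copy()
    for n in range(1, terms + 1):
        g += (2 * n + 1) / float(n * (n + 1)) ** m * Pn
        Pnp1 = ((2 * n + 1) * x * Pn - n * Pnm1) / (n + 1)
        Pnm1, Pn = Pn, Pnp1
    return g / (4.0 * np.pi)


def spline_interpolate(epoch: np.ndarray, bad: set, sensors: SensorArray,
                       m: int = 4, terms: int = 50, reg: float = 1e-8) -> np.ndarray:
    """Replace bad channels by the spherical-spline estimate fit on the rest.

    Good channels are untouched.  The spline system carries the usual
    constant term, so a topography that is constant across good channels is
    reproduced exactly (up to the ridge ``reg``).
    """
    bad = set(int(b) for b in bad)
    if not bad:
        return epoch.copy()
    C = epoch.shape[0]
    good = [i for i in range(C) if i not in bad]
    if len(good) < 4:
        raise PreprocessingError(f"only {len(good)} good channels; need at least 4")
    if not bad.issubset(range(C)):
        raise PreprocessingError(f"bad-channel indices {bad} outside 0..{C - 1}")
    pos = sensors.positions / np.linalg.norm(sensors.positions, axis=1, keepdims=True)
    cos_gg = np.clip(pos[good] @ pos[good].T, -1.0, 1.0)
    G = _spline_g(cos_gg, m, terms)
    ng = len(good)
    A = np.zeros((ng + 1, ng + 1))
    A[:ng, :ng] = G + reg * np.eye(ng)
    A[:ng, ng] = 1.0
    A[ng, :ng] = 1.0
    V = epoch[good]  # (ng, T)
    rhs = np.vstack([V, np.zeros((1, V.shape[1]))])
    sol = np.linalg.solve(A, rhs)
    c, d = sol[:ng], sol[ng]
    bad_list = sorted(bad)
    cos_bg = np.clip(pos[bad_list] @ pos[good].T, -1.0, 1.0)
    out = epoch.copy()
    out[bad_list] = _spline_g(cos_bg, m, terms) @ c + d
    return out


def reject_artifact_epochs(epochs: EpochSet, blink_channels, p2p_threshold_uv: float = 150.0) -> EpochSet:
    """Drop epochs whose peak-to-peak range on any periocular channel exceeds
    the threshold (ocular-artifact criterion)."""
    if p2p_threshold_uv <= 0:
        raise PreprocessingError("p2p threshold must be positive")
    ch = sorted(int(c) for c in blink_channels)
    kept, rejected = {}, {}
    for label, arr in epochs.data.items():
        if arr.shape[0] == 0 or not ch:
            kept[label] = arr.copy()
            rejected[label] = 0
            continue
        sub = arr[:, ch, :]
        p2p = sub.max(axis=2) - sub.min(axis=2)  # (trials, channels)
        ok = ~(p2p > p2p_threshold_uv).any(axis=1)
        kept[label] = arr[ok]
        rejected[label] = int((~ok).sum())
    log = dict(epochs.rejection_log)
    log["rejected_epochs"] = rejected
    return EpochSet(epochs.subject_id, kept, epochs.window_ms, epochs.fs, log)


def average_reference_and_baseline(data: np.ndarray, fs: float, window_ms) -> np.ndarray:
    """Baseline-correct then common-average-reference.

    Works on any array whose last two axes are (channels, samples).  Per
    channel, the mean over the pre-stimulus samples is subtracted; per
    sample, the cross-channel mean is subtracted.  Both steps are idempotent
    linear projections and commute, so after the pair both the pre-stimulus
    channel means and the cross-channel means vanish.
    """
    w0, _ = window_ms
    n_base = int(round(-w0 * fs / 1000.0))
    if n_base <= 0:
        raise PreprocessingError(f"window {window_ms} has no pre-stimulus baseline")
    out = np.asarray(data, float).copy()
    out -= out[..., :n_base].mean(axis=-1, keepdims=True)
    out -= out.mean(axis=-2, keepdims=True)
    return out


def build_erp_dataset(epoch_sets, min_trials: int = 10,
                      conditions=CONDITIONS) -> ERPDataset:
    """Average retained epochs into a subjects x conditions ERP array.

    A subject is excluded when any condition retains fewer than
    ``min_trials`` artifact-free trials (strict reading of the
    across-all-conditions rule).  Averages are baseline-corrected and
    common-average-referenced.
    """
    if min_trials < 1:
        raise PreprocessingError("min_trials must be >= 1")
    included, rows, counts = [], [], []
    excluded = {}
    fs = window_ms = None
    for es in epoch_sets:
        fs, window_ms = es.fs, es.window_ms
        tc = [es.data.get(c, np.empty((0, 0, 0))).shape[0] for c in conditions]
        if min(tc) < min_trials:
            worst = conditions[int(np.argmin(tc))]
            excluded[es.subject_id] = f"{min(tc)} artifact-free trials in {worst}"
            continue
        rows.append(np.stack([es.data[c].mean(axis=0) for c in conditions]))
        counts.append(tc)
        included.append(es.subject_id)
    if not rows:
        raise PreprocessingError("no subjects survive the minimum-trials rule")
    data = average_reference_and_baseline(np.stack(rows), fs, window_ms)
    return ERPDataset(data, included, tuple(conditions), fs, window_ms,
                      np.asarray(counts), excluded)
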