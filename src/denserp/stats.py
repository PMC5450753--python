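"""Component amplitude statistics: windowed means and pairwise
repeated-measures ANOVA with standardized effect sizes.

A two-level within-subject ANOVA is exactly the square of the paired t-test
(F on 1 and n-1 degrees of freedom).  The effect size reported is
``sqrt(2F/n)`` -- sqrt(2) times Cohen's d of the paired difference -- a
convention reverse-engineered from published component tables and flagged
as such; it is not an authoritative standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from denserp.preprocessing import CONDITIONS

__all__ = [
    "AmplitudeTable",
    "StatResult",
    "window_mean_amplitude",
    "paired_rm_anova",
    "effect_size_from_f",
    "run_planned_contrasts",
    "DEFAULT_COMPONENT_WINDOWS_MS",
]

#: Canonical analysis windows (ms) for the four stereotyped components.
DEFAULT_COMPONENT_WINDOWS_MS = {
    "P3b": (344.0, 384.0),
    "P3a": (268.0, 308.0),
    "N1b": (144.0, 184.0),
    "N1a": (104.0, 144.0),
}


class StatsError(ValueError):
    pass


@dataclass
class AmplitudeTable:
    """Subjects x conditions window-mean amplitudes in uV."""

    values: np.ndarray
    conditions: tuple
    window_ms: tuple
    channels: tuple
    component_id: str = ""

    def __post_init__(self):
        if not np.isfinite(self.values).all():
            raise StatsError("non-finite amplitude values")

    def condition(self, label: str) -> np.ndarray:
        try:
            return self.values[:, self.conditions.index(label)]
        except ValueError:
            raise StatsError(f"condition {label!r} not in table") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.conditions))


@dataclass
class StatResult:
    F: float
    df: tuple
    p: float
    effect_size: float
    means: dict
    warning: str = ""

    def as_dict(self) -> dict:
        return {"F": self.F, "df": list(self.df), "p": self.p,
                "effect_size": self.effect_size, "means": self.means,
                **({"warning": self.warning} if self.warning else {})}


def effect_size_from_f(F: float, n: int) -> float:
    """Standardized effect sqrt(2F/n) for a two-level within-subject design
    (equals sqrt(2) times Cohen's d of the paired difference)."""
    return float(np.sqrt(2.0 * F / n))


def window_mean_amplitude(component, erp, window_ms, channels=None) -> AmplitudeTable:
    """Mean of a component's reconstructed uV waveform over a half-open
    latency window and a channel set, per subject x condition.

    ``channels`` may be labels (resolved against ``erp`` sensor labels via
    the attached sensor array of the model) or integer indices; by default
    the component's three strongest map channels are used.
    """
    sl = erp.window_slice(window_ms)
    m, l = component.spatial_map, component.temporal_loading
    if channels is None:
        ch_idx = np.argsort(np.abs(m))[::-1][:3]
    else:
        ch_idx = np.asarray([int(c) for c in channels])
        if (ch_idx < 0).any() or (ch_idx >= m.size).any():
            raise StatsError(f"channel indices {channels} out of range 0..{m.size - 1}")
    w = float(m[ch_idx].mean()) * float(l[sl].mean())
    values = component.coefficients * w
    return AmplitudeTable(values, erp.conditions, tuple(float(x) for x in window_ms),
                          tuple(int(c) for c in ch_idx),
                          f"T{component.temporal_index}xS{component.spatial_index}")


def paired_rm_anova(table: AmplitudeTable, cond_a: str, cond_b: str,
                    alpha: float = 0.05) -> StatResult:
    """Two-level repeated-measures ANOVA via the within-subject sums of
    squares; F carries (1, n-1) degrees of freedom.

    With zero variance of the paired differences the F ratio is reported as
    the +inf sentinel with p = 0 and a warning string.
    """
    a, b = table.condition(cond_a), table.condition(cond_b)
    n = a.size
    if n < 3:
        raise StatsError(f"need at least 3 subjects, got {n}")
    # within-subject decomposition for 2 conditions: SS_cond on 1 df,
    # SS_error = interaction subject x condition on n-1 df
    grand = np.concatenate([a, b]).mean()
    subj_mean = (a + b) / 2.0
    ss_cond = n * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
    ss_err = (((a - subj_mean) - (a.mean() - grand)) ** 2
              + ((b - subj_mean) - (b.mean() - grand)) ** 2).sum()
    means = {cond_a: float(a.mean()), cond_b: float(b.mean())}
    if ss_err <= 0:
        if ss_cond <= 0:
            return StatResult(0.0, (1, n - 1), 1.0, 0.0, means)
        warnings.warn("zero variance of paired differences; F reported as +inf")
        return StatResult(float("inf"), (1, n - 1), 0.0, float("inf"), means,
                          warning="zero within-subject variance")
    F = float(ss_cond / 1.0 / (ss_err / (n - 1)))
    p = float(scipy.stats.f.sf(F, 1, n - 1))
    return StatResult(F, (1, n - 1), p, effect_size_from_f(F, n), means)


#: The two planned pairwise contrasts of the feedback design.
PLANNED_CONTRASTS = (
    ("partner", "partner_accept", "partner_reject"),
    ("peer", "peer_accept", "peer_reject"),
)


def run_planned_contrasts(components, erp, windows_ms=None, channels=None,
                          alpha: float = 0.05, holm: bool = False) -> dict:
    """Partner and peer acceptance-vs-rejection contrasts for each component.

    For every component the analysis window defaults to the canonical
    window whose center is nearest the component's peak latency; channels
    default to the component's three strongest map channels.  No multiple-
    comparison correction is applied unless ``holm`` is set.
    Returns a JSON-ready report dict; a formatted table is available via
    :func:`format_contrast_report`.
    """
    if windows_ms is None:
        windows_ms = DEFAULT_COMPONENT_WINDOWS_MS
    missing = [c for pair in PLANNED_CONTRASTS for c in pair[1:]
               if c not in erp.conditions]
    if missing:
        raise StatsError(f"conditions missing from ERP dataset: {missing}")
    report = {"alpha": alpha, "components": []}
    pvals = []
    for comp in components:
        peak = comp.qc.get("peak_latency_ms", np.nan)
        name, (w0, w1) = min(
            windows_ms.items(),
            key=lambda kv: abs(0.5 * (kv[1][0] + kv[1][1]) - peak))
        table = window_mean_amplitude(comp, erp, (w0, w1), channels)
        entry = {
            "component": table.component_id,
            "window_label": name,
            "window_ms": [w0, w1],
            "channels": list(table.channels),
            "peak_latency_ms": peak,
            "variance_percent": comp.variance_percent,
            "contrasts": {},
        }
        for cname, ca, cb in PLANNED_CONTRASTS:
            res = paired_rm_anova(table, ca, cb, alpha)
            d = res.as_dict()
            d["significant"] = bool(res.p < alpha)
            entry["contrasts"][cname] = d
            pvals.append((entry["contrasts"][cname], res.p))
        report["components"].append(entry)
    if holm and pvals:
        order = np.argsort([p for _, p in pvals])
        m = len(pvals)
        adj_max = 0.0
        for rank, oi in enumerate(order):
            d, p = pvals[oi]
            adj = min(1.0, (m - rank) * p)
            adj_max = max(adj_max, adj)
            d["p_holm"] = adj_max
            d["significant"] = bool(adj_max < alpha)
    return report


def format_contrast_report(report: dict) -> str:
    """Human-readable table for a planned-contrast report."""
    lines = [f"{'component':>10} {'window':>6} {'contrast':>8} "
             f"{'F(1,df)':>10} {'p':>8} {'effect':>7} {'mean A':>8} {'mean B':>8}"]
    for entry in report["components"]:
        for cname, d in entry["contrasts"].items():
            mA, mB = list(d["means"].values())
            star = "*" if d["significant"] else " "
            lines.append(
                f"{entry['component']:>10} {entry['window_label']:>6} {cname:>8} "
                f"{d['F']:10.2f} {d['p']:8.4f}{star}{d['effect_size']:7.2f} "
                f"{mA:8.2f} {mB:8.2f}")
    return "\n".join(lines)
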