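"""Linear inverse source estimation (LORETA / minimum norm).

The estimate minimizes ``||Phi - K J||^2 + lambda J^T W J`` and is computed
in the numerically stable sensor-space form

    J_hat = W^-1 K^T (K W^-1 K^T + lambda I)^-1 Phi,

with ``W = E^T D^T D E`` for LORETA (discrete-Laplacian smoothness with
lead-field normalization) or the identity for a plain minimum-norm
solution.  Intensities are reported in standardized units: the per-location
moment norm divided by its root mean square over locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from denserp.decomposition import SpatioTemporalComponent
from denserp.headmodel import LeadField, Regularizer, SourceSpace

__all__ = [
    "ScalpTopography",
    "InverseConfig",
    "SourceEstimate",
    "LoretaInverse",
    "loreta_solve",
    "localize_component",
    "peak_sources",
]


class InverseError(ValueError):
    pass


@dataclass
class ScalpTopography:
    """Average-referenced sensor potentials (uV) at one latency."""

    potentials: np.ndarray
    timestamp_ms: float = 0.0
    component_id: str = ""

    def __post_init__(self):
        self.potentials = np.asarray(self.potentials, float)
        scale = np.abs(self.potentials).max()
        if scale > 0 and abs(self.potentials.mean()) > 1e-9 * scale:
            # enforce the average-reference convention rather than reject
            self.potentials = self.potentials - self.potentials.mean()


@dataclass(frozen=True)
class InverseConfig:
    lam: float = 1e-3
    method: str = "LORETA"  # or "MinimumNorm"

    def __post_init__(self):
        if self.lam < 0:
            raise InverseError("lambda must be non-negative")
        if self.method not in ("LORETA", "MinimumNorm"):
            raise InverseError(f"unknown method {self.method!r}")


@dataclass
class SourceEstimate:
    """Estimated dipole moments and standardized intensities."""

    moments: np.ndarray  # (Nv, 3)
    intensity: np.ndarray  # (Nv,), standardized units
    locations: np.ndarray  # (Nv, 3) mm
    raw_norm: np.ndarray = None  # (Nv,), un-standardized moment norms
    component_id: str = ""

    def peaks(self, n_peaks: int = 5, min_separation: float = 20.0) -> list:
        return peak_sources(self, n_peaks, min_separation)

    def plot(self, axes=None):
        """Orthogonal-slice intensity rendering through the peak."""
        from denserp.plotting import plot_source_slices
        return plot_source_slices(self, axes)


class LoretaInverse:
    """Linear inverse model for a fixed lead field and regularizer.

    Factorizes ``W`` once, so repeated topographies are solved cheaply.
    ``fit(phi)`` returns a :class:`SourceEstimate`.
    """

    def __init__(self, K: LeadField, W: Regularizer = None, src: SourceSpace = None,
                 config: InverseConfig = InverseConfig(), jitter: float = 1e-8):
        self.K = K
        self.src = src
        self.config = config
        Km = K.matrix
        n_dip = Km.shape[1]
        if config.method == "MinimumNorm" or W is None:
            Y = Km.T.copy()
        else:
            Wm = W.W.tocsc()
            scale = Wm.diagonal().max()
            Wj = (Wm + (jitter * scale) * sp.identity(n_dip, format="csc")).tocsc()
            solve_W = spla.factorized(Wj)
            Y = np.column_stack([solve_W(Km[i]) for i in range(Km.shape[0])])
            Y = np.ascontiguousarray(Y)
        self._Y = Y  # W^-1 K^T, (3Nv, Ne)
        self._G = Km @ Y  # (Ne, Ne)

    def fit(self, phi: ScalpTopography) -> SourceEstimate:
        lam = self.config.lam
        G = self._G + lam * np.eye(self._G.shape[0])
        try:
            coef = np.linalg.solve(G, phi.potentials)
        except np.linalg.LinAlgError:
            raise InverseError("singular system; use lambda > 0") from None
        J = self._Y @ coef
        # orientation triples when the dipole count allows it, else scalar
        # unconstrained sources (toy systems)
        width = 3 if J.size % 3 == 0 else 1
        moments = J.reshape(-1, width)
        raw = np.linalg.norm(moments, axis=1)
        rms = np.sqrt((raw ** 2).mean())
        intensity = raw / rms if rms > 0 else raw
        loc = self.src.locations if self.src is not None else np.zeros((moments.shape[0], 3))
        return SourceEstimate(moments, intensity, loc, raw, phi.component_id)


def loreta_solve(K: LeadField, W: Regularizer, phi: ScalpTopography,
                 cfg: InverseConfig = InverseConfig(), src: SourceSpace = None) -> SourceEstimate:
    """One-shot regularized inverse solve (see :class:`LoretaInverse`)."""
    if K.matrix.shape[0] != phi.potentials.size:
        raise InverseError(
            f"lead field has {K.matrix.shape[0]} sensors, topography has "
            f"{phi.potentials.size}")
    return LoretaInverse(K, W, src, cfg).fit(phi)


def localize_component(component: SpatioTemporalComponent, erp, K: LeadField,
                       W: Regularizer, cfg: InverseConfig = InverseConfig(),
                       src: SourceSpace = None, condition: str = None) -> SourceEstimate:
    """Source-localize a component's topography at its peak latency.

    The scalp pattern is the component's uV reconstruction at the peak
    sample, averaged over subjects (and over conditions unless one is
    named), re-referenced to the common average.
    """
    l = component.temporal_loading
    peak = int(np.argmax(np.abs(l)))
    coef = component.coefficients
    if condition is not None:
        coef = coef[:, [erp.conditions.index(condition)]]
    w = float(coef.mean()) * float(l[peak])
    phi = ScalpTopography(component.spatial_map * w,
                          timestamp_ms=component.qc.get("peak_latency_ms", 0.0),
                          component_id=f"T{component.temporal_index}xS{component.spatial_index}")
    return loreta_solve(K, W, phi, cfg, src)


def peak_sources(est: SourceEstimate, n_peaks: int = 5,
                 min_separation: float = 20.0) -> list:
    """Greedy non-maximum suppression over intensity.

    Returns up to ``n_peaks`` ``(location_mm, intensity)`` pairs, sorted by
    descending intensity, each at least ``min_separation`` mm from every
    previously accepted peak.
    """
    if n_peaks < 1:
        raise InverseError("n_peaks must be >= 1")
    order = np.argsort(est.intensity)[::-1]
    chosen = []
    for i in order:
        if est.intensity[i] <= 0 and chosen:
            break
        loc = est.locations[i]
        if all(np.linalg.norm(loc - c) >= min_separation for c, _ in chosen):
            chosen.append((loc.copy(), float(est.intensity[i])))
        if len(chosen) == n_peaks:
            break
    return chosen
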