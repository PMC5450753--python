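"""Two-step spatiotemporal component analysis of ERP data.

Step one is a temporal PCA over the subjects x conditions x channels
observations with time points as variables, rotated obliquely (varimax
followed by promax) so that overlapping deflections such as the P3a and P3b
land on separate factors.  Step two is a spatial infomax ICA on the factor
scores, with channels as variables, yielding near-dipolar scalp maps.  The
cross of temporal factors and spatial components gives the candidate
spatiotemporal components; candidates below a total-variance floor
(default 0.5%) are discarded.  Factor counts for both steps default to the
parallel test (eigenvalue scree against size-matched random data).

The front door is :class:`TwoStepDecomposition` / fit() ->
:class:`DecompositionResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = [
    "ParallelTestResult",
    "TemporalFactorSet",
    "SpatialComponentSet",
    "SpatioTemporalComponent",
    "parallel_test",
    "temporal_pca_promax",
    "spatial_infomax_ica",
    "assemble_components",
    "select_components",
    "best_match",
    "TwoStepDecomposition",
    "DecompositionResults",
]


class DecompositionError(ValueError):
    pass


@dataclass
class ParallelTestResult:
    actual_scree: np.ndarray
    mean_random_scree: np.ndarray
    retained: int


@dataclass
class TemporalFactorSet:
    """Obliquely rotated temporal factors.

    ``loadings`` (samples x factors) times ``scores.T`` reproduces the
    retained subspace of the column-centered data.
    """

    loadings: np.ndarray
    scores: np.ndarray
    factor_correlations: np.ndarray
    variance_fraction: np.ndarray
    column_means: np.ndarray
    total_ss: float
    obs_shape: tuple = None  # (subjects, conditions, channels)

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Retained-subspace reconstruction plus the column means."""
        return self.scores @ self.loadings.T + self.column_means


@dataclass
class SpatialComponentSet:
    """Spatial ICA result: maps are unit-norm mixing columns with positive
    peak; activations carry the scale."""

    maps: np.ndarray  # channels x components
    activations: np.ndarray  # observations x components
    unmixing: np.ndarray  # components x channels
    converged: bool
    n_iter: int

    @property
    def n_components(self) -> int:
        return self.maps.shape[1]


@dataclass
class SpatioTemporalComponent:
    """One (temporal factor, spatial component) pair."""

    temporal_loading: np.ndarray  # samples, unitless (unit peak magnitude)
    spatial_map: np.ndarray  # channels, unitless (unit norm, positive peak)
    amplitude: np.ndarray  # subjects x conditions, uV (peak-channel scale)
    coefficients: np.ndarray  # subjects x conditions raw bilinear weights
    variance_percent: float
    temporal_index: int
    spatial_index: int
    qc: dict = field(default_factory=dict)

    @property
    def peak_latency_ms(self):
        return self.qc.get("peak_latency_ms")

    def reconstruction(self) -> np.ndarray:
        """(subjects, conditions, channels, samples) uV reconstruction."""
        return np.einsum("sc,x,t->scxt", self.coefficients,
                         self.spatial_map, self.temporal_loading)


def _scree(data: np.ndarray) -> np.ndarray:
    """Eigenvalues of the correlation matrix, zero-variance columns giving
    zero eigenvalues."""
    X = np.asarray(data, float)
    X = X - X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, ddof=1)
    ok = sd > 0
    if not ok.any():
        return np.zeros(X.shape[1])
    Z = X[:, ok] / sd[ok]
    ev = np.linalg.svd(Z, compute_uv=False) ** 2 / (X.shape[0] - 1)
    out = np.zeros(X.shape[1])
    out[: ev.size] = ev
    return out


def parallel_test(data: np.ndarray, n_surrogates: int = 20, seed: int = 0) -> ParallelTestResult:
    """Horn-style parallel analysis for the number of factors to retain.

    The data's correlation-matrix scree is compared with the mean scree of
    ``n_surrogates`` seeded standard-normal arrays of identical shape; the
    retained count is the length of the leading run of actual eigenvalues
    strictly above the surrogate mean at the same rank.
    """
    if n_surrogates < 10:
        raise DecompositionError(f"n_surrogates must be >= 10, got {n_surrogates}")
    X = np.asarray(data, float)
    actual = _scree(X)
    rng = np.random.default_rng(seed)
    rand = np.zeros_like(actual)
    for _ in range(n_surrogates):
        rand += _scree(rng.standard_normal(X.shape))
    rand /= n_surrogates
    above = actual > rand
    retained = int(np.argmin(above)) if not above.all() else above.size
    if above.size and not above[0]:
        retained = 0
    return ParallelTestResult(actual, rand, retained)


def _promax(varimax_loadings: np.ndarray, kappa: float) -> np.ndarray:
    """Hendrickson-White promax: oblique least-squares rotation of the
    varimax solution toward its own element-wise power-``kappa`` target.
    ``kappa = 1`` returns the varimax loadings unchanged."""
    Lv = varimax_loadings
    target = np.sign(Lv) * np.abs(Lv) ** kappa
    U, *_ = np.linalg.lstsq(Lv, target, rcond=None)
    d = np.sqrt(np.diag(np.linalg.inv(U.T @ U)))
    U = U * d[None, :]
    return Lv @ U


def temporal_pca_promax(data, n_factors: int, kappa: float = 3.0) -> TemporalFactorSet:
    """Covariance-based temporal PCA with varimax-then-promax rotation.

    ``data`` is either an :class:`~denserp.preprocessing.ERPDataset` or a
    2-D observations x variables array (observations = subject x condition x
    channel cells, variables = time points).  Scores are recomputed by least
    squares on the oblique loadings, so ``loadings @ scores.T`` spans
    exactly the retained principal subspace.
    """
    obs_shape = None
    if hasattr(data, "data") and getattr(data, "data").ndim == 4:
        S, Cd, C, T = data.data.shape
        X = data.data.reshape(S * Cd * C, T)
        obs_shape = (S, Cd, C)
    else:
        X = np.asarray(data, float)
    if kappa < 1:
        raise DecompositionError(f"kappa must be >= 1, got {kappa}")
    n_obs, n_var = X.shape
    if n_factors > n_var:
        raise DecompositionError(f"n_factors {n_factors} exceeds {n_var} variables")
    mu = X.mean(axis=0, keepdims=True)
    Xc = X - mu
    Uf, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((sv > sv[0] * 1e-12).sum()) if sv.size else 0
    if n_factors > rank:
        raise DecompositionError(f"n_factors {n_factors} exceeds data rank {rank}")
    # principal-axis loadings: variables x factors, scaled by singular value
    L = Vt[:n_factors].T * (sv[:n_factors] / np.sqrt(max(n_obs - 1, 1)))
    if n_factors > 1:
        # Kaiser normalization: rotate unit-communality rows, then restore
        h = np.linalg.norm(L, axis=1, keepdims=True)
        h[h == 0] = 1.0
        Lv, _ = rotate_factors(L / h, "varimax")
        Lr = _promax(Lv * h, kappa)
    else:
        Lr = L.copy()
    # sign convention: absolutely largest element of each loading positive
    signs = np.sign(Lr[np.argmax(np.abs(Lr), axis=0), np.arange(n_factors)])
    signs[signs == 0] = 1.0
    Lr *= signs[None, :]
    scores, *_ = np.linalg.lstsq(Lr, Xc.T, rcond=None)
    scores = scores.T  # observations x factors
    total_ss = float((Xc ** 2).sum())
    var_frac = np.array([
        (np.outer(scores[:, j], Lr[:, j]) ** 2).sum() / total_ss if total_ss > 0 else 0.0
        for j in range(n_factors)
    ])
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.corrcoef(scores, rowvar=False)
    fc = np.atleast_2d(fc)
    fc[~np.isfinite(fc)] = 0.0
    np.fill_diagonal(fc, 1.0)
    return TemporalFactorSet(Lr, scores, fc, var_frac, mu, total_ss, obs_shape)


def factor_scores_by_channel(tf: TemporalFactorSet) -> np.ndarray:
    """Rearrange temporal-factor scores into the spatial-step layout:
    (subject x condition x factor) observations over channel variables."""
    if tf.obs_shape is None:
        raise DecompositionError("factor set lacks (subjects, conditions, channels) shape")
    S, Cd, C = tf.obs_shape
    k = tf.n_factors
    arr = tf.scores.reshape(S, Cd, C, k)
    return arr.transpose(0, 1, 3, 2).reshape(S * Cd * k, C)


def spatial_infomax_ica(Y: np.ndarray, n_components: int, seed: int = 0,
                        max_iter: int = 1024, tol: float = 1e-7,
                        lrate: float = 0.01, block: int = None) -> SpatialComponentSet:
    """Infomax ICA (logistic nonlinearity, natural-gradient updates).

    ``Y`` is observations x channels.  Data are PCA-whitened to
    ``n_components`` first; the learning rate anneals by 0.9 whenever the
    angle between successive updates exceeds 60 degrees, and iteration stops
    when the Frobenius weight change per pass drops below ``tol``.  The
    default minibatch size follows the usual ``ceil(min(5 ln N, 0.3 N))``
    heuristic.  Non-convergence is reported through the ``converged`` flag,
    not raised.
    """
    Y = np.asarray(Y, float)
    n_obs, C = Y.shape
    if n_components > C:
        raise DecompositionError(f"n_components {n_components} exceeds {C} channels")
    if block is None:
        block = max(8, int(np.ceil(min(5.0 * np.log(n_obs), 0.3 * n_obs))))
    rng = np.random.default_rng(seed)
    mu = Y.mean(axis=0, keepdims=True)
    Yc = Y - mu
    cov = (Yc.T @ Yc) / max(n_obs - 1, 1)
    ev, E = np.linalg.eigh(cov)
    order = np.argsort(ev)[::-1][:n_components]
    ev, E = np.maximum(ev[order], 1e-12), E[:, order]
    whiten = E / np.sqrt(ev)  # channels x comps; Xw = Yc @ whiten
    dewhiten = E * np.sqrt(ev)  # channels x comps
    Xw = Yc @ whiten

    W = np.eye(n_components)
    I = np.eye(n_components)
    prev_dW = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        perm = rng.permutation(n_obs)
        W_start = W.copy()
        for b0 in range(0, n_obs - block + 1, block):
            idx = perm[b0:b0 + block]
            u = Xw[idx] @ W.T
            y = 1.0 / (1.0 + np.exp(-u))
            dW = lrate * (I + ((1.0 - 2.0 * y).T @ u) / block) @ W
            W += dW
            if not np.isfinite(W).all():
                raise DecompositionError("infomax diverged; lower the learning rate")
        dW_pass = W - W_start
        if prev_dW is not None:
            num = (dW_pass * prev_dW).sum()
            den = np.linalg.norm(dW_pass) * np.linalg.norm(prev_dW)
            if den > 0 and num / den < 0.5:  # angle > 60 degrees
                lrate *= 0.9
        prev_dW = dW_pass
        if np.linalg.norm(dW_pass) / max(np.linalg.norm(W_start), 1e-300) < tol:
            converged = True
            break

    unmixing = W @ whiten.T  # components x channels
    maps = np.linalg.pinv(unmixing)  # channels x components
    # activations on the UNcentered data: the observation mean carries the
    # grand-average component amplitude, which downstream statistics need
    activations = Y @ unmixing.T
    # normalization: unit-norm maps with positive peak, scale in activations
    norms = np.linalg.norm(maps, axis=0)
    norms[norms == 0] = 1.0
    signs = np.sign(maps[np.argmax(np.abs(maps), axis=0), np.arange(maps.shape[1])])
    signs[signs == 0] = 1.0
    maps = maps / (norms * signs)[None, :]
    activations = activations * (norms * signs)[None, :]
    unmixing = unmixing * (norms * signs)[:, None]
    if not converged:
        warnings.warn(f"infomax ICA did not converge in {max_iter} passes")
    return SpatialComponentSet(maps, activations, unmixing, converged, it)


def assemble_components(tf: TemporalFactorSet, sc: SpatialComponentSet,
                        erp=None, times_ms=None) -> list:
    """Cross every temporal factor with every spatial component.

    The candidate's reconstruction for a subject/condition cell is
    ``coef[s, c] * map (x) loading`` in uV; ``amplitude`` rescales the
    coefficient by the loading's peak value and the map's mean over its
    three strongest channels, so it reads as uV at the component's peak
    latency and measurement channels (the generator's convention).
    ``variance_percent`` is the candidate reconstruction's share of the
    total (column-centered) data variance.
    """
    if tf.obs_shape is None:
        raise DecompositionError("factor set lacks observation shape metadata")
    S, Cd, C = tf.obs_shape
    kt, ks = tf.n_factors, sc.n_components
    act = sc.activations.reshape(S, Cd, kt, ks)
    if times_ms is None and erp is not None:
        times_ms = erp.times_ms()
    out = []
    for f in range(kt):
        l = tf.loadings[:, f]
        lp_idx = int(np.argmax(np.abs(l)))
        # unit-peak-magnitude loading; scale moves into the coefficients
        l_scale = np.abs(l[lp_idx])
        l_unit = l / l_scale if l_scale > 0 else l
        for c in range(ks):
            m = sc.maps[:, c]
            coef = act[:, :, f, c] * l_scale
            top3 = np.argsort(np.abs(m))[::-1][:3]
            mbar = m[top3].mean()
            amp = coef * l_unit[lp_idx] * mbar
            var_pct = 0.0
            if tf.total_ss > 0:
                var_pct = 100.0 * float((coef ** 2).sum()) * float((l_unit ** 2).sum()) \
                    * float((m ** 2).sum()) / tf.total_ss
            qc = {}
            if times_ms is not None:
                qc["peak_latency_ms"] = float(times_ms[lp_idx])
            out.append(SpatioTemporalComponent(
                temporal_loading=l_unit, spatial_map=m.copy(), amplitude=amp,
                coefficients=coef, variance_percent=var_pct,
                temporal_index=f, spatial_index=c, qc=qc))
    return out


def _map_smoothness(m: np.ndarray, sensor_positions: np.ndarray, k: int = 6) -> float:
    """Mean absolute difference between neighboring sensors over map norm."""
    P = sensor_positions
    d2 = ((P[:, None, :] - P[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    nbr = np.argsort(d2, axis=1)[:, :k]
    diffs = np.abs(m[:, None] - m[nbr])
    nrm = np.linalg.norm(m)
    return float(diffs.mean() / nrm) if nrm > 0 else 0.0


def select_components(candidates, min_variance_percent: float = 0.5,
                      sensors=None) -> list:
    """Variance-filter the candidate components and attach QC measures.

    The remaining published triage (dipole-like scalp maps, identifiable
    ERP morphology) is reported through the QC fields, not automated.
    """
    if min_variance_percent < 0:
        raise DecompositionError("min_variance_percent must be >= 0")
    kept = [c for c in candidates if c.variance_percent >= min_variance_percent]
    kept.sort(key=lambda c: c.variance_percent, reverse=True)
    if sensors is not None:
        for c in kept:
            c.qc["map_smoothness"] = _map_smoothness(c.spatial_map, sensors.positions)
    if not kept:
        warnings.warn("no components pass the variance floor")
    return kept


def best_match(components, temporal_ref: np.ndarray, spatial_ref: np.ndarray):
    """Find the component best matching a reference (waveform, topography)
    pair; returns ``(component, |r_temporal|, |r_spatial|)`` maximizing the
    product of absolute correlations."""
    best, best_rt, best_rs, score = None, 0.0, 0.0, -1.0
    for c in components:
        rt = abs(np.corrcoef(c.temporal_loading, temporal_ref)[0, 1])
        rs = abs(np.corrcoef(c.spatial_map, spatial_ref)[0, 1])
        if rt * rs > score:
            best, best_rt, best_rs, score = c, rt, rs, rt * rs
    return best, best_rt, best_rs


class TwoStepDecomposition:
    """Temporal-PCA + spatial-ICA model of an ERP dataset.

    Parameters
    ----------
    erp : ERPDataset
        Baseline-corrected, average-referenced subject x condition ERPs.
    n_temporal, n_spatial : int or None
        Factor/component counts; ``None`` defers to the parallel test.
    kappa : float
        Promax power (1 = varimax).
    min_variance_percent : float
        Variance floor for candidate selection.
    """

    def __init__(self, erp, n_temporal=None, n_spatial=None, kappa: float = 3.0,
                 min_variance_percent: float = 0.5, n_surrogates: int = 20,
                 seed: int = 0, sensors=None, ica_max_iter: int = 1024,
                 ica_tol: float = 1e-7):
        self.erp = erp
        self.n_temporal = n_temporal
        self.n_spatial = n_spatial
        self.kappa = kappa
        self.min_variance_percent = min_variance_percent
        self.n_surrogates = n_surrogates
        self.seed = seed
        self.sensors = sensors
        self.ica_max_iter = ica_max_iter
        self.ica_tol = ica_tol

    def fit(self) -> "DecompositionResults":
        S, Cd, C, T = self.erp.data.shape
        X = self.erp.data.reshape(S * Cd * C, T)
        pt_temporal = pt_spatial = None
        nt = self.n_temporal
        if nt is None:
            pt_temporal = parallel_test(X, self.n_surrogates, self.seed)
            nt = max(pt_temporal.retained, 1)
        tf = temporal_pca_promax(self.erp, nt, self.kappa)
        Y = factor_scores_by_channel(tf)
        ns = self.n_spatial
        if ns is None:
            pt_spatial = parallel_test(Y, self.n_surrogates, self.seed + 1)
            ns = max(min(pt_spatial.retained, C), 1)
        sc = spatial_infomax_ica(Y, ns, seed=self.seed,
                                 max_iter=self.ica_max_iter, tol=self.ica_tol)
        candidates = assemble_components(tf, sc, erp=self.erp)
        selected = select_components(candidates, self.min_variance_percent, self.sensors)
        return DecompositionResults(self, tf, sc, candidates, selected,
                                    pt_temporal, pt_spatial)


@dataclass
class DecompositionResults:
    """Fitted two-step decomposition with the selected components."""

    model: TwoStepDecomposition
    temporal: TemporalFactorSet
    spatial: SpatialComponentSet
    candidates: list
    selected: list
    parallel_temporal: ParallelTestResult = None
    parallel_spatial: ParallelTestResult = None

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    def plot_component(self, index: int, sensors=None, axes=None):
        """Render one selected component (loading + scalp map)."""
        from denserp.plotting import plot_component
        sensors = sensors if sensors is not None else self.model.sensors
        if sensors is None:
            raise DecompositionError("sensor positions needed for plotting")
        return plot_component(self.selected[index], sensors,
                              self.model.erp.times_ms(), axes)

    def summary(self) -> str:
        lines = [
            "Two-step temporal-PCA / spatial-ICA decomposition",
            f"  temporal factors: {self.temporal.n_factors}"
            + (f" (parallel test over {self.parallel_temporal.actual_scree.size} ranks)"
               if self.parallel_temporal else ""),
            f"  spatial components: {self.spatial.n_components}"
            + ("" if self.spatial.converged else "  [ICA not converged]"),
            f"  candidates: {self.n_candidates}, selected: {len(self.selected)} "
            f"(variance floor {self.model.min_variance_percent}%)",
            "",
            f"  {'component':>10} {'var %':>7} {'peak ms':>8} " +
            " ".join(f"{c:>15}" for c in self.model.erp.conditions),
        ]
        for comp in self.selected:
            means = comp.amplitude.mean(axis=0)
            lines.append(
                f"  T{comp.temporal_index:>2}xS{comp.spatial_index:<2}    "
                f"{comp.variance_percent:7.2f} "
                f"{comp.qc.get('peak_latency_ms', float('nan')):8.0f} "
                + " ".join(f"{m:15.2f}" for m in means))
        return "\n".join(lines)
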