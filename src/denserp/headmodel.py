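"""Spherical volume-conductor head models, sensor/source geometry, and the
EEG lead field.

The forward model is an analytic N-shell concentric-sphere volume conductor:
the potential of a current dipole inside the innermost (brain) shell is
expanded in a Legendre series, and for every degree ``n`` the radial transfer
across the shells is obtained by solving the small linear system given by
continuity of potential and of radial current density at each interface, plus
the no-outflow condition at the scalp surface.  The default model uses four
shells (brain, CSF, skull, scalp) with conductivities 0.25, 1.8, 0.018 and
0.44 S/m and radii 80/82/87/92 mm.

Units: geometry in mm, conductivity in S/m, dipole moments in nA*m, and
potentials (hence lead-field entries) in uV per nA*m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "HeadModel",
    "SensorArray",
    "SourceSpace",
    "LeadField",
    "Regularizer",
    "build_head_model",
    "place_sensors",
    "build_source_space",
    "compute_lead_field",
    "build_regularizer",
    "DEFAULT_RADII_MM",
    "DEFAULT_CONDUCTIVITIES",
]

#: Default 4-shell geometry (mm): brain, CSF, skull, scalp surfaces.
DEFAULT_RADII_MM = (80.0, 82.0, 87.0, 92.0)
#: Literature tissue conductivities (S/m), innermost to outermost.
DEFAULT_CONDUCTIVITIES = (0.25, 1.8, 0.018, 0.44)

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class HeadModelError(ValueError):
    """Invalid head-model geometry or conductivities."""


@dataclass(frozen=True)
class HeadModel:
    """Concentric-shell conductor: radii in mm (outermost = scalp surface),
    one conductivity (S/m) per shell, innermost first."""

    shell_radii: tuple
    shell_conductivities: tuple

    @property
    def n_shells(self) -> int:
        return len(self.shell_radii)

    @property
    def inner_radius(self) -> float:
        return self.shell_radii[0]

    @property
    def scalp_radius(self) -> float:
        return self.shell_radii[-1]


@dataclass(frozen=True)
class SensorArray:
    """Electrode positions (mm) on the scalp sphere with unique labels."""

    positions: np.ndarray  # (Ne, 3) mm
    labels: tuple

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label: {label!r}") from None


@dataclass(frozen=True)
class SourceSpace:
    """Regular voxel grid of dipole locations inside the innermost shell.

    Each location carries the canonical axis-aligned orthonormal orientation
    triple, so the model has ``3 * n_locations`` dipoles in total.
    """

    locations: np.ndarray  # (Nv, 3) mm
    spacing: float  # mm
    orientations: np.ndarray  # (Nv, 3, 3), rows = orientation vectors
    grid_index: np.ndarray  # (Nv, 3) int

    @property
    def n_locations(self) -> int:
        return self.locations.shape[0]

    @property
    def n_dipoles(self) -> int:
        return 3 * self.n_locations


@dataclass(frozen=True)
class LeadField:
    """K: (Ne, 3*Nv) matrix, uV at each sensor per unit (nA*m) dipole moment,
    re-referenced to the common average over sensors."""

    matrix: np.ndarray
    reference_convention: str = "common-average"

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_dipoles(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class Regularizer:
    """LORETA constraint operator W = E^T D^T D E.

    ``D`` is the 7-point discrete Laplacian over source locations extended
    identically over the three orientations, ``E`` the diagonal lead-field
    column-norm weighting (one scalar per location, repeated over its triple).
    """

    W: sp.csr_matrix  # (3Nv, 3Nv)
    D: sp.csr_matrix  # (3Nv, 3Nv)
    E: np.ndarray  # (3Nv,) diagonal of E
    W_location: sp.csr_matrix = field(repr=False, default=None)  # (Nv, Nv) block


def build_head_model(radii, conductivities) -> HeadModel:
    """Validate and construct a concentric-shell head model.

    Parameters
    ----------
    radii : sequence of float
        Shell outer radii in mm, strictly increasing; last = scalp surface.
    conductivities : sequence of float
        One positive conductivity (S/m) per shell, innermost first.
    """
    radii = tuple(float(r) for r in radii)
    conductivities = tuple(float(c) for c in conductivities)
    if len(radii) < 1 or len(radii) != len(conductivities):
        raise HeadModelError(
            f"need matching non-empty radii/conductivities, got "
            f"{len(radii)} radii and {len(conductivities)} conductivities"
        )
    for i, r in enumerate(radii):
        if r <= 0:
            raise HeadModelError(f"shell {i}: non-positive radius {r}")
        if i > 0 and r <= radii[i - 1]:
            raise HeadModelError(
                f"radii not increasing at shell {i}: {radii[i - 1]} -> {r}"
            )
    for i, c in enumerate(conductivities):
        if c <= 0:
            raise HeadModelError(f"shell {i}: non-positive conductivity {c}")
    return HeadModel(radii, conductivities)


def place_sensors(count: int, scalp_radius: float, coverage: float = 0.75) -> SensorArray:
    """Deterministic quasi-uniform electrode layout on a spherical cap.

    A spherical Fibonacci lattice restricted to the top cap covering
    ``coverage`` of the full solid angle (cap measured from the vertex, +z).
    Labels are assigned ``E1..E<count>`` in construction order.  The layout is
    a stand-in for a geodesic net: deterministic, near-uniform, whole-head
    when ``coverage`` is large.
    """
    if count < 4:
        raise HeadModelError(f"need at least 4 sensors, got {count}")
    if not (0.0 < coverage <= 1.0):
        raise HeadModelError(f"coverage must be in (0, 1], got {coverage}")
    i = np.arange(count)
    # offset Fibonacci lattice (boundary offset 0.36 improves uniformity),
    # z spanning the covered cap [1 - 2*coverage, 1]
    eps = 0.36
    z = 1.0 - 2.0 * coverage * (i + eps) / (count - 1 + 2 * eps)
    phi = i * _GOLDEN_ANGLE
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pos = scalp_radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    labels = tuple(f"E{k + 1}" for k in range(count))
    return SensorArray(pos, labels)


def build_source_space(head: HeadModel, spacing: float = 7.0, margin: float = 0.0) -> SourceSpace:
    """Voxelize the innermost shell into a regular grid of dipole locations.

    Locations are kept iff their distance from the center is at most
    ``inner_radius - margin``; each carries the canonical axis-aligned
    orthonormal orientation triple.
    """
    if spacing <= 0:
        raise HeadModelError(f"spacing must be positive, got {spacing}")
    if margin < 0:
        raise HeadModelError(f"margin must be non-negative, got {margin}")
    r_in = head.inner_radius
    if spacing > 2.0 * r_in:
        raise HeadModelError("empty source space: spacing exceeds innermost diameter")
    r_keep = r_in - margin
    n_half = int(np.floor(r_keep / spacing)) if r_keep > 0 else -1
    if n_half < 0:
        raise HeadModelError("empty source space: margin leaves no room")
    axis = np.arange(-n_half, n_half + 1)
    ii, jj, kk = np.meshgrid(axis, axis, axis, indexing="ij")
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    loc = idx * spacing
    keep = np.linalg.norm(loc, axis=1) <= r_keep + 1e-12
    idx, loc = idx[keep], loc[keep].astype(float)
    if loc.shape[0] == 0:
        raise HeadModelError("empty source space")
    orientations = np.broadcast_to(np.eye(3), (loc.shape[0], 3, 3)).copy()
    return SourceSpace(loc, float(spacing), orientations, idx)


def _shell_transfer(head: HeadModel, n_terms: int) -> np.ndarray:
    """Per-degree radial transfer coefficients t_n, n = 1..n_terms.

    For each Legendre degree the potential in shell j is
    ``A_j rho^n + B_j rho^-(n+1)`` (rho = r / scalp radius) plus, in the
    innermost shell, the source's outgoing term with unit coefficient.  The
    2M-1 unknowns solve continuity of potential and of sigma * dPhi/dr at
    every interface and zero radial current at the scalp.  t_n is the
    resulting surface potential per unit source coefficient; for a
    homogeneous sphere t_n = (2n+1)/n.
    """
    M = head.n_shells
    rM = head.scalp_radius
    rho = np.asarray(head.shell_radii) / rM
    sig = np.asarray(head.shell_conductivities)
    t = np.empty(n_terms)
    for n in range(1, n_terms + 1):
        if M == 1:
            t[n - 1] = (2.0 * n + 1.0) / n
            continue
        m = 2 * M - 1
        A = np.zeros((m, m))
        b = np.zeros(m)
        # unknown layout: [A_1, A_2, B_2, ..., A_M, B_M]
        col_A = lambda j: 0 if j == 1 else 2 * j - 3
        col_B = lambda j: 2 * j - 2  # j >= 2
        row = 0
        for k in range(1, M):  # interface between shell k and k+1 at rho[k-1]
            p, q = rho[k - 1] ** n, rho[k - 1] ** (-(n + 1))
            dp, dq = n * rho[k - 1] ** (n - 1), -(n + 1) * rho[k - 1] ** (-(n + 2))
            A[row, col_A(k)] += p
            if k >= 2:
                A[row, col_B(k)] += q
            A[row, col_A(k + 1)] -= p
            A[row, col_B(k + 1)] -= q
            if k == 1:
                b[row] = -q  # source term sits in shell 1
            row += 1
            A[row, col_A(k)] += sig[k - 1] * dp
            if k >= 2:
                A[row, col_B(k)] += sig[k - 1] * dq
            A[row, col_A(k + 1)] -= sig[k] * dp
            A[row, col_B(k + 1)] -= sig[k] * dq
            if k == 1:
                b[row] = -sig[0] * dq
            row += 1
        # outer boundary: no radial current at the scalp (rho = 1)
        A[row, col_A(M)] = n
        A[row, col_B(M)] = -(n + 1)
        x = np.linalg.solve(A, b)
        t[n - 1] = x[col_A(M)] + x[col_B(M)]
    return t


def compute_lead_field(
    head: HeadModel,
    src: SourceSpace,
    sensors: SensorArray,
    series_terms: int = 60,
) -> LeadField:
    """Analytic multi-shell lead field via Legendre-series expansion.

    Every source must lie strictly inside the innermost shell.  The result is
    re-referenced to the common average across sensors, so each column sums
    to zero.

    Raises if the per-source series terms fail to decay over the last ten
    degrees (non-convergence), naming the offending location.
    """
    if series_terms < 20:
        raise HeadModelError(f"series_terms must be >= 20, got {series_terms}")
    P = np.asarray(src.locations, dtype=float)  # (Ns, 3) mm
    S = np.asarray(sensors.positions, dtype=float)  # (Ne, 3) mm
    r_in, r_M = head.inner_radius, head.scalp_radius
    b = np.linalg.norm(P, axis=1)
    bad = np.nonzero(b >= r_in)[0]
    if bad.size:
        raise HeadModelError(
            f"source location {bad[0]} at {P[bad[0]]} mm is not strictly "
            f"inside the innermost shell (radius {r_in} mm)"
        )
    Ns, Ne = P.shape[0], S.shape[0]
    rs_hat = np.where(b[:, None] > 0, P / np.maximum(b, 1e-300)[:, None], [0.0, 0.0, 1.0])
    re_hat = S / np.linalg.norm(S, axis=1, keepdims=True)
    U = re_hat @ rs_hat.T  # (Ne, Ns) cos(angle sensor, source)
    np.clip(U, -1.0, 1.0, out=U)

    t_n = _shell_transfer(head, series_terms)
    x = b / r_M  # eccentricities
    # w[n-1, s] = t_n * x^(n-1); 0**0 == 1 handles a central source
    expo = np.arange(series_terms)[:, None]
    w = t_n[:, None] * np.power(x[None, :], expo)

    # convergence guard: per-source series terms must decay near truncation
    if series_terms >= 21:
        head_mag = np.abs(w[-20:-10, :]).mean(axis=0)
        tail_mag = np.abs(w[-10:, :]).mean(axis=0)
        grow = np.nonzero(tail_mag > head_mag + 1e-300)[0]
        if grow.size:
            s0 = grow[0]
            raise HeadModelError(
                f"lead-field series not converging at source {s0} "
                f"({P[s0]} mm, eccentricity {x[s0]:.4f}); increase series_terms"
            )

    # Legendre recurrences accumulated over degrees:
    #   R_sum = sum_n n * w_n * P_n(u)     (radial moment part)
    #   T_sum = sum_n w_n * P_n'(u)        (tangential part, no 1/sin factor)
    Pnm1 = np.ones_like(U)  # P_0
    Pn = U.copy()  # P_1
    dPnm1 = np.zeros_like(U)  # P_0'
    dPn = np.ones_like(U)  # P_1'
    R_sum = 1.0 * w[0] * Pn
    T_sum = w[0] * dPn
    for n in range(1, series_terms):
        Pnp1 = ((2 * n + 1) * U * Pn - n * Pnm1) / (n + 1)
        dPnp1 = dPnm1 + (2 * n + 1) * Pn
        Pnm1, Pn = Pn, Pnp1
        dPnm1, dPn = dPn, dPnp1
        deg = n + 1
        R_sum += deg * w[n] * Pn
        T_sum += w[n] * dPn

    # uV per nA*m: 1/(4 pi sigma_1 r_M^2[m^2]) * 1e-9[A*m] * 1e6[uV/V]
    C = 1e-3 / (4.0 * np.pi * head.shell_conductivities[0] * (r_M * 1e-3) ** 2)
    K = np.empty((Ne, 3 * Ns))
    for a in range(3):
        rs_a = rs_hat[:, a]  # (Ns,)
        K[:, a::3] = C * (rs_a[None, :] * R_sum + (re_hat[:, a][:, None] - U * rs_a[None, :]) * T_sum)
    K -= K.mean(axis=0, keepdims=True)
    return LeadField(K)


def build_regularizer(lf: LeadField, src: SourceSpace) -> Regularizer:
    """Assemble the LORETA constraint W = E^T D^T D E.

    ``D`` implements the 7-point Laplacian stencil (six axis neighbors +1,
    center minus the number of neighbors actually present -- a Neumann-like
    boundary rule), Kronecker-extended over the orientation triple.  ``E`` is
    diagonal with the Euclidean norm of each location's 3-column lead-field
    block, repeated over its triple, so superficial (high-gain) sources are
    penalized more.
    """
    idx = src.grid_index
    Nv = idx.shape[0]
    lookup = {tuple(v): i for i, v in enumerate(map(tuple, idx))}
    rows, cols, vals = [], [], []
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for i in range(Nv):
        ci, cj, ck = idx[i]
        nbrs = []
        for di, dj, dk in offsets:
            j = lookup.get((ci + di, cj + dj, ck + dk))
            if j is not None:
                nbrs.append(j)
        rows.append(i)
        cols.append(i)
        vals.append(-float(len(nbrs)))
        for j in nbrs:
            rows.append(i)
            cols.append(j)
            vals.append(1.0)
    D_loc = sp.csr_matrix((vals, (rows, cols)), shape=(Nv, Nv))

    K = lf.matrix
    if K.shape[1] != 3 * Nv:
        raise HeadModelError(
            f"lead field has {K.shape[1]} dipoles but source space has {3 * Nv}"
        )
    blk = K.reshape(K.shape[0], Nv, 3)
    e_loc = np.sqrt((blk ** 2).sum(axis=(0, 2)))  # per-location block norm
    E_loc = sp.diags(e_loc)
    W_loc = (E_loc @ (D_loc.T @ D_loc) @ E_loc).tocsr()

    I3 = sp.identity(3, format="csr")
    D = sp.kron(D_loc, I3, format="csr")
    W = sp.kron(W_loc, I3, format="csr")
    E = np.repeat(e_loc, 3)
    return Regularizer(W=W, D=D, E=E, W_location=W_loc)
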