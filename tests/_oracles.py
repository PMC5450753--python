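"""Independent oracles, coded separately from the package implementations.

These deliberately use different mathematical routes (generating-function
closed forms, explicit loops) than the vectorized recurrences inside the
package, so agreement is evidence, not tautology.
"""

import numpy as np


def single_sphere_dipole_potential(R_m, sigma, pos_m, moment, sensor_pos_m):
    """Closed-form surface potential of a dipole in a homogeneous sphere.

    Derived by summing the Legendre series with the homogeneous-sphere
    per-degree coefficient (2n+1)/n via generating functions:

        sum (2n+1) x^(n-1) P_n(u)      = 2 (u - x) g^3 + (g - 1)/x
        sum (2n+1)/n x^(n-1) P_n^1(u)  = sin(g) [2 g^3 + (1+s)/(s (1 - xu + s))]

    with s = sqrt(1 - 2xu + x^2), g = 1/s, x = b/R.  Inputs in SI units;
    returns volts (not referenced).
    """
    b = np.linalg.norm(pos_m)
    if b == 0:
        raise ValueError("oracle requires an eccentric dipole")
    rs = pos_m / b
    out = np.empty(len(sensor_pos_m))
    for k, e in enumerate(sensor_pos_m):
        R = np.linalg.norm(e)
        re = e / R
        u = float(np.clip(rs @ re, -1.0, 1.0))
        x = b / R
        s = np.sqrt(1.0 - 2.0 * x * u + x * x)
        g = 1.0 / s
        mr = float(moment @ rs)
        mt_sin = float(moment @ (re - u * rs))  # m_t * sin(gamma)
        Sr = 2.0 * (u - x) * g ** 3 + (g - 1.0) / x
        St = 2.0 * g ** 3 + (1.0 + s) / (s * (1.0 - x * u + s))
        out[k] = (mr * Sr + mt_sin * St) / (4.0 * np.pi * sigma * R * R)
    return out


def brute_force_laplacian(grid_index):
    """7-point stencil assembled with explicit loops and neighbor search."""
    n = len(grid_index)
    D = np.zeros((n, n))
    index = [tuple(g) for g in grid_index]
    for i, (a, b, c) in enumerate(index):
        nbrs = []
        for da, db, dc in [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                           (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            key = (a + da, b + db, c + dc)
            if key in index:
                nbrs.append(index.index(key))
        D[i, i] = -len(nbrs)
        for j in nbrs:
            D[i, j] = 1.0
    return D


def ball_lattice_points(radius, spacing):
    """Exhaustive enumeration of lattice points with norm <= radius."""
    n = int(np.floor(radius / spacing))
    pts = []
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            for k in range(-n, n + 1):
                p = np.array([i, j, k]) * spacing
                if np.linalg.norm(p) <= radius + 1e-12:
                    pts.append(p)
    return np.array(pts)


def paired_t_squared(a, b):
    """Paired t statistic squared, via scipy's independent implementation."""
    import scipy.stats
    t = scipy.stats.ttest_rel(a, b)
    return t.statistic ** 2, t.pvalue


def greedy_peak_scan(locations, intensity, n_peaks, min_sep):
    """Brute-force non-maximum suppression by repeated full scans."""
    remaining = list(range(len(intensity)))
    chosen = []
    while remaining and len(chosen) < n_peaks:
        best = max(remaining, key=lambda i: intensity[i])
        chosen.append(best)
        remaining = [i for i in remaining
                     if np.linalg.norm(locations[i] - locations[best]) >= min_sep
                     or i == best]
        remaining.remove(best)
    return chosen
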