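"""Lightweight rendering: scalp maps, component loadings, source slices.

All functions accept an ``ax`` (or create one) and return it; the ``save``
helpers write PNG files. Uses the non-interactive Agg backend when no
display is configured.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_scalp_map", "plot_component", "save_component_png",
           "plot_source_slices", "save_source_png"]


def _axes(nrows=1, ncols=1, **kw):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt.subplots(nrows, ncols, **kw)


def _flatten_cap(positions: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant projection of sensor positions (top view,
    vertex at the origin)."""
    p = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    theta = np.arccos(np.clip(p[:, 2], -1.0, 1.0))
    phi = np.arctan2(p[:, 1], p[:, 0])
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


def plot_scalp_map(values, sensors, ax=None, show_sensors=True):
    """Interpolated top-view scalp topography of per-channel values."""
    if ax is None:
        _, ax = _axes(figsize=(4, 4))
    xy = _flatten_cap(sensors.positions)
    v = np.asarray(values, float)
    tpc = ax.tricontourf(xy[:, 0], xy[:, 1], v, levels=24, cmap="RdBu_r")
    if show_sensors:
        ax.plot(xy[:, 0], xy[:, 1], "k.", ms=2)
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.figure.colorbar(tpc, ax=ax, shrink=0.75)
    return ax


def plot_component(component, sensors, times_ms=None, axes=None):
    """Temporal loading plus scalp map for one spatiotemporal component."""
    if axes is None:
        _, axes = _axes(1, 2, figsize=(8, 3.2))
    t = times_ms if times_ms is not None \
        else np.arange(component.temporal_loading.size)
    axes[0].plot(t, component.temporal_loading, lw=1.5)
    axes[0].axhline(0, color="0.7", lw=0.5)
    axes[0].set_xlabel("time (ms)")
    axes[0].set_ylabel("loading")
    axes[0].set_title(
        f"T{component.temporal_index}xS{component.spatial_index} "
        f"({component.variance_percent:.1f}% var)")
    plot_scalp_map(component.spatial_map, sensors, ax=axes[1])
    return axes


def save_component_png(path, component, sensors, times_ms=None):
    axes = plot_component(component, sensors, times_ms)
    fig = axes[0].figure
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    import matplotlib.pyplot as plt
    plt.close(fig)


def plot_source_slices(est, axes=None, tolerance=None):
    """Orthogonal-slice scatter of source intensity (axial, coronal,
    sagittal planes through the intensity peak)."""
    if axes is None:
        _, axes = _axes(1, 3, figsize=(10, 3.2))
    loc, inten = est.locations, est.intensity
    peak = loc[int(np.argmax(inten))]
    tol = tolerance if tolerance is not None else 1.01 * _grid_step(loc)
    planes = [("axial", 2, 0, 1, "x", "y"), ("coronal", 1, 0, 2, "x", "z"),
              ("sagittal", 0, 1, 2, "y", "z")]
    vmax = inten.max() if inten.size else 1.0
    for ax, (name, k, i, j, li, lj) in zip(np.ravel(axes), planes):
        sel = np.abs(loc[:, k] - peak[k]) <= tol / 2
        sc = ax.scatter(loc[sel, i], loc[sel, j], c=inten[sel], s=18,
                        cmap="hot", vmin=0, vmax=vmax)
        ax.set_aspect("equal")
        ax.set_title(f"{name} ({'xyz'[k]} = {peak[k]:.0f} mm)")
        ax.set_xlabel(f"{li} (mm)")
        ax.set_ylabel(f"{lj} (mm)")
    np.ravel(axes)[-1].figure.colorbar(sc, ax=np.ravel(axes).tolist(),
                                       shrink=0.8, label="intensity (s.u.)")
    return axes


def _grid_step(loc: np.ndarray) -> float:
    u = np.unique(loc[:, 2])
    return float(np.diff(u).min()) if u.size > 1 else 1.0


def save_source_png(path, est):
    axes = plot_source_slices(est)
    fig = np.ravel(axes)[0].figure
    fig.savefig(path, dpi=100)
    import matplotlib.pyplot as plt
    plt.close(fig)
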