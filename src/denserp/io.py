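"""File formats: HDF5 result container, sensor-position text files, event
tables (TSV), EDF+ continuous input, and deterministic JSON reports.

One HDF5 container per analysis holds the forward model (/K, /locations,
/orientations, /grid_index, sparse /W), the ERP dataset (/erp), and the
selected components (/components/<k>/...), with units and conventions as
attributes.  JSON reports serialize floats at fixed precision so identical
runs are byte-identical.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

from denserp.headmodel import (HeadModel, LeadField, Regularizer, SensorArray,
                               SourceSpace)
from denserp.preprocessing import ContinuousRecording, ERPDataset

__all__ = [
    "save_forward_model",
    "load_forward_model",
    "write_sensor_positions",
    "read_sensor_positions",
    "write_events_tsv",
    "read_events_tsv",
    "read_continuous_edf",
    "save_erp_dataset",
    "load_erp_dataset",
    "save_components",
    "load_components",
    "json_dump",
]


# ---------------------------------------------------------------- JSON

def _fixed(obj):
    """Recursively coerce numpy scalars/arrays and round floats to 10
    significant digits for byte-stable serialization."""
    if isinstance(obj, dict):
        return {str(k): _fixed(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_fixed(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _fixed(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        return x if not np.isfinite(x) else float(f"{x:.10g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def json_dump(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_fixed(obj), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------- forward

def save_forward_model(path, head: HeadModel, sensors: SensorArray,
                       src: SourceSpace, lf: LeadField, reg: Regularizer = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("K", data=lf.matrix)
        f["K"].attrs["units"] = "uV per nA*m"
        f["K"].attrs["reference_convention"] = lf.reference_convention
        f.create_dataset("locations", data=src.locations)
        f.create_dataset("orientations", data=src.orientations)
        f.create_dataset("grid_index", data=src.grid_index)
        f.create_dataset("sensor_positions", data=sensors.positions)
        f.create_dataset("sensor_labels",
                         data=np.array(sensors.labels, dtype=h5py.string_dtype()))
        f.attrs["shell_radii_mm"] = head.shell_radii
        f.attrs["shell_conductivities_S_per_m"] = head.shell_conductivities
        f.attrs["spacing_mm"] = src.spacing
        if reg is not None:
            W = reg.W.tocoo()
            f.create_dataset("W_row", data=W.row)
            f.create_dataset("W_col", data=W.col)
            f.create_dataset("W_val", data=W.data)
            f.attrs["W_shape"] = W.shape


def load_forward_model(path):
    """Returns (head, sensors, src, lead_field, regularizer_or_None)."""
    with h5py.File(path, "r") as f:
        head = HeadModel(tuple(f.attrs["shell_radii_mm"]),
                         tuple(f.attrs["shell_conductivities_S_per_m"]))
        sensors = SensorArray(f["sensor_positions"][()],
                              tuple(s.decode() if isinstance(s, bytes) else str(s)
                                    for s in f["sensor_labels"][()]))
        src = SourceSpace(f["locations"][()], float(f.attrs["spacing_mm"]),
                          f["orientations"][()], f["grid_index"][()])
        lf = LeadField(f["K"][()], str(f["K"].attrs["reference_convention"]))
        reg = None
        if "W_val" in f:
            shape = tuple(f.attrs["W_shape"])
            W = sp.csr_matrix((f["W_val"][()], (f["W_row"][()], f["W_col"][()])),
                              shape=shape)
            reg = Regularizer(W=W, D=None, E=None)
    return head, sensors, src, lf, reg


# ---------------------------------------------------------------- text formats

def write_sensor_positions(path, sensors: SensorArray) -> None:
    """Whitespace-delimited ``label x y z`` (mm), one sensor per line."""
    with open(path, "w") as fh:
        for lab, (x, y, z) in zip(sensors.labels, sensors.positions):
            fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")


def read_sensor_positions(path) -> SensorArray:
    labels, pos = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            labels.append(parts[0])
            pos.append([float(v) for v in parts[1:4]])
    return SensorArray(np.asarray(pos), tuple(labels))


def write_events_tsv(path, events: pd.DataFrame) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"onset_sample", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"event table needs columns {sorted(required)}")
    return df


def read_continuous_edf(path, subject_id: str = None, events=None) -> ContinuousRecording:
    """Read a continuous EDF+ recording into uV (requires :mod:`mne`)."""
    import mne  # deferred: EDF input is optional

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> uV
    ev = []
    if events is not None:
        ev = [(int(r.onset_sample), str(r.condition)) for r in events.itertuples()]
    return ContinuousRecording(data, float(raw.info["sfreq"]), ev,
                               subject_id or path)


# ---------------------------------------------------------------- ERP / components

def save_epoch_sets(path, epoch_sets) -> None:
    """Store per-subject, per-condition epoch stacks under
    ``/epochs/<subject>/<condition>`` with window metadata."""
    with h5py.File(path, "w") as f:
        for es in epoch_sets:
            g = f.create_group(f"epochs/{es.subject_id}")
            for cond, arr in es.data.items():
                d = g.create_dataset(cond, data=arr)
                d.attrs["units"] = "uV"
            g.attrs["window_ms"] = es.window_ms
            g.attrs["fs"] = es.fs
            g.attrs["rejection_log"] = json.dumps(_fixed(es.rejection_log))


def load_epoch_sets(path) -> list:
    from denserp.preprocessing import EpochSet

    out = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f["epochs"]):
            g = f[f"epochs/{sid}"]
            data = {cond: g[cond][()] for cond in g}
            out.append(EpochSet(sid, data,
                                tuple(float(w) for w in g.attrs["window_ms"]),
                                float(g.attrs["fs"]),
                                json.loads(g.attrs["rejection_log"])))
    return out


def save_erp_dataset(path, erp: ERPDataset) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("erp", data=erp.data)
        d.attrs["units"] = "uV"
        f.create_dataset("trial_counts", data=erp.trial_counts)
        f.create_dataset("subjects",
                         data=np.array(erp.subjects, dtype=h5py.string_dtype()))
        f.attrs["conditions"] = list(erp.conditions)
        f.attrs["fs"] = erp.fs
        f.attrs["window_ms"] = erp.window_ms
        f.attrs["excluded"] = json.dumps(erp.excluded)


def load_erp_dataset(path) -> ERPDataset:
    with h5py.File(path, "r") as f:
        return ERPDataset(
            f["erp"][()],
            [s.decode() if isinstance(s, bytes) else str(s) for s in f["subjects"][()]],
            tuple(str(c) for c in f.attrs["conditions"]),
            float(f.attrs["fs"]),
            tuple(float(w) for w in f.attrs["window_ms"]),
            f["trial_counts"][()],
            json.loads(f.attrs["excluded"]),
        )


def save_components(path, components) -> None:
    from denserp.decomposition import SpatioTemporalComponent  # local to avoid cycle

    with h5py.File(path, "w") as f:
        for i, c in enumerate(components):
            g = f.create_group(f"components/{i}")
            g.create_dataset("loading", data=c.temporal_loading)
            g.create_dataset("map", data=c.spatial_map)
            g.create_dataset("amplitude", data=c.amplitude)
            g["amplitude"].attrs["units"] = "uV"
            g.create_dataset("coefficients", data=c.coefficients)
            g.attrs["variance_percent"] = c.variance_percent
            g.attrs["temporal_index"] = c.temporal_index
            g.attrs["spatial_index"] = c.spatial_index
            g.attrs["qc"] = json.dumps(_fixed(c.qc))
        f.attrs["n_components"] = len(components)


def load_components(path) -> list:
    from denserp.decomposition import SpatioTemporalComponent

    out = []
    with h5py.File(path, "r") as f:
        n = int(f.attrs["n_components"])
        for i in range(n):
            g = f[f"components/{i}"]
            out.append(SpatioTemporalComponent(
                temporal_loading=g["loading"][()],
                spatial_map=g["map"][()],
                amplitude=g["amplitude"][()],
                coefficients=g["coefficients"][()],
                variance_percent=float(g.attrs["variance_percent"]),
                temporal_index=int(g.attrs["temporal_index"]),
                spatial_index=int(g.attrs["spatial_index"]),
                qc=json.loads(g.attrs["qc"]),
            ))
    return out
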