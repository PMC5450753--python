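"""Pipeline orchestration: configuration, stages, manifests, reproducibility.

Stages run in the order simulate -> preprocess -> decompose -> stats ->
localize.  The simulate stage materializes the generative plan (forward
model, component specs, ground truth, event tables); recordings themselves
are regenerated on demand from the seed during preprocessing, so the
on-disk footprint stays small at full study scale.  Every stage writes a
manifest with content digests of its inputs and outputs; re-running a
completed stage with unchanged inputs is a no-op.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from pathlib import Path

import numpy as np

from denserp import headmodel as hm
from denserp import io as dio
from denserp import simulate as sim
from denserp import stats as dstats
from denserp.decomposition import TwoStepDecomposition
from denserp.inverse import InverseConfig, LoretaInverse, localize_component
from denserp.preprocessing import (CONDITIONS, build_erp_dataset,
                                   detect_bad_channels, extract_epochs,
                                   fir_bandpass, reject_artifact_epochs,
                                   spline_interpolate)

__all__ = ["PipelineConfig", "ConfigError", "PipelineError", "run_stage",
           "run_all", "STAGES", "DEFAULT_CONFIG"]

log = logging.getLogger("denserp")

STAGES = ("simulate", "preprocess", "decompose", "stats", "localize")

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "denserp_out",
    "headmodel": {
        "radii_mm": list(hm.DEFAULT_RADII_MM),
        "conductivities": list(hm.DEFAULT_CONDUCTIVITIES),
        "n_sensors": 128,
        "coverage": 0.75,
        "spacing_mm": 7.0,
        "margin_mm": 7.0,
        "series_terms": 60,
    },
    "simulate": {
        "n_subjects": 75,
        "trials_per_condition": 30,
        "fs": 250.0,
        "iti_s": 1.3,
        "background_rms": 4.0,
        "sensor_rms": 2.0,
        "blink_rate": 3.0,
        "blink_amplitude": 120.0,
        "bad_channel_prob": 0.02,
    },
    "preprocess": {
        "low_hz": 0.1,
        "high_hz": 30.0,
        "window_ms": [-200.0, 800.0],
        "smooth_ms": 80.0,
        "bad_channel_threshold_uv": 200.0,
        "p2p_threshold_uv": 150.0,
        "min_trials": 10,
        "n_periocular": 4,
    },
    "decompose": {
        "n_temporal": 0,  # 0 = parallel test
        "n_spatial": 0,
        "kappa": 3.0,
        "min_variance_percent": 0.5,
        "n_surrogates": 20,
    },
    "stats": {"alpha": 0.05, "holm": False},
    "localize": {
        "lambda": 1e-3,
        "method": "LORETA",
        "n_peaks": 5,
        "min_separation_mm": 20.0,
    },
}


class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    pass


def _merge_validate(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, val in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key: {path}{key}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{path}{key} must be a table")
            out[key] = _merge_validate(defaults[key], val, f"{path}{key}.")
        else:
            out[key] = val
    for key, val in defaults.items():
        if key not in out:
            out[key] = _merge_validate(val, {}, f"{path}{key}.") if isinstance(val, dict) else val
    return out


class PipelineConfig:
    """Validated pipeline configuration (TOML-backed, strict keys)."""

    def __init__(self, overrides: dict = None):
        self.data = _merge_validate(DEFAULT_CONFIG, overrides or {})

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            return cls(tomllib.load(fh))

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream below 2^31."""
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence([self.seed, idx])
        return int(ss.generate_state(1)[0] % (2 ** 31))

    def resolved(self) -> dict:
        return json.loads(json.dumps(self.data))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest(stage, inputs, outputs, t0, warnings_list):
    import denserp
    return {
        "stage": stage,
        "inputs": {str(p): _digest(Path(p)) for p in inputs},
        "outputs": {str(p): _digest(Path(p)) for p in outputs},
        "version": denserp.__version__,
        "wall_time_s": time.time() - t0,
        "warnings": list(warnings_list),
    }


def _require(out: Path, files, needed_stage: str):
    missing = [f for f in files if not (out / f).exists()]
    if missing:
        raise PipelineError(
            f"missing {missing}; run the '{needed_stage}' stage first")


def _sim_objects(config: PipelineConfig):
    h = config["headmodel"]
    head = hm.build_head_model(h["radii_mm"], h["conductivities"])
    sensors = hm.place_sensors(h["n_sensors"], head.scalp_radius, h["coverage"])
    src = hm.build_source_space(head, h["spacing_mm"], h["margin_mm"])
    return head, sensors, src


def _sim_config(config: PipelineConfig) -> sim.SimConfig:
    s = config["simulate"]
    p = config["preprocess"]
    return sim.SimConfig(
        n_subjects=int(s["n_subjects"]),
        trials_per_condition=int(s["trials_per_condition"]),
        fs=float(s["fs"]), seed=config.stage_seed("simulate"),
        epoch_window_ms=tuple(p["window_ms"]), iti_s=float(s["iti_s"]))


def _noise_model(config: PipelineConfig) -> sim.NoiseModel:
    s = config["simulate"]
    return sim.NoiseModel(
        background_rms=float(s["background_rms"]),
        sensor_rms=float(s["sensor_rms"]),
        blink_rate=float(s["blink_rate"]),
        blink_amplitude=float(s["blink_amplitude"]),
        bad_channel_prob=float(s["bad_channel_prob"]))


def _stage_simulate(config: PipelineConfig, out: Path):
    head, sensors, src = _sim_objects(config)
    K = hm.compute_lead_field(head, src, sensors,
                              config["headmodel"]["series_terms"])
    reg = hm.build_regularizer(K, src)
    dio.save_forward_model(out / "forward.h5", head, sensors, src, K, reg)
    dio.write_sensor_positions(out / "sensors.txt", sensors)

    specs, truth = sim.make_default_ground_truth(src, K)
    cfg = _sim_config(config)
    events = []
    for i in range(cfg.n_subjects):
        onsets, labels = sim.subject_event_schedule(cfg, i, cfg.seed)
        for o, l in zip(onsets, labels):
            events.append({"subject": f"S{i:03d}", "onset_sample": int(o),
                           "condition": cfg.conditions[l]})
    import pandas as pd
    dio.write_events_tsv(out / "events.tsv", pd.DataFrame(events))
    dio.json_dump({
        "specs": [dataclasses.asdict(s) for s in specs],
        "measurement_channels": truth.measurement_channels,
        "patch_center_mm": {k: src.locations[v].tolist()
                            for k, v in truth.patch_center_index.items()},
        "sim_config": {"n_subjects": cfg.n_subjects,
                       "trials_per_condition": cfg.trials_per_condition,
                       "fs": cfg.fs, "seed": cfg.seed, "iti_s": cfg.iti_s},
    }, out / "ground_truth.json")
    return [], [out / "forward.h5", out / "sensors.txt", out / "events.tsv",
                out / "ground_truth.json"]


def load_specs(out: Path):
    with open(out / "ground_truth.json") as fh:
        gt = json.load(fh)
    return [sim.ComponentSpec(**d) for d in gt["specs"]]


def preprocess_recording(rec, sensors, pp: dict):
    """Canonical preprocessing chain for one continuous recording."""
    rec = fir_bandpass(rec, pp["low_hz"], pp["high_hz"])
    es = extract_epochs(rec, tuple(pp["window_ms"]))
    concat = np.concatenate([es.data[c] for c in sorted(es.data)], axis=0)
    flat = np.moveaxis(concat, 1, 0).reshape(concat.shape[1], -1)
    bad = detect_bad_channels(flat, es.fs, pp["smooth_ms"],
                              pp["bad_channel_threshold_uv"])
    if bad:
        fixed = spline_interpolate(flat, bad, sensors)
        fixed = fixed.reshape(concat.shape[1], concat.shape[0], concat.shape[2])
        fixed = np.moveaxis(fixed, 0, 1)
        i = 0
        for c in sorted(es.data):
            n = es.data[c].shape[0]
            es.data[c] = fixed[i:i + n]
            i += n
    es.rejection_log["bad_channels"] = sorted(bad)
    peri = sim.periocular_channels(sensors, pp["n_periocular"])
    return reject_artifact_epochs(es, peri, pp["p2p_threshold_uv"])


def _stage_preprocess(config: PipelineConfig, out: Path):
    inputs = [out / "forward.h5", out / "ground_truth.json", out / "events.tsv"]
    _require(out, [p.name for p in inputs], "simulate")
    head, sensors, src, K, reg = dio.load_forward_model(out / "forward.h5")
    specs = load_specs(out)
    truth = sim.build_ground_truth(specs, src, K)
    cfg = _sim_config(config)
    noise = _noise_model(config)
    pp = config["preprocess"]
    epoch_sets = []
    logs = {}
    for rec, _ in sim.iter_subject_recordings(cfg, specs, truth, noise, K, src,
                                              sensors, cfg.seed):
        es = preprocess_recording(rec, sensors, pp)
        epoch_sets.append(es)
        logs[rec.subject_id] = {
            "bad_channels": es.rejection_log.get("bad_channels", []),
            "rejected_epochs": es.rejection_log.get("rejected_epochs", {}),
            "retained": es.trial_counts(),
        }
        log.info("preprocessed %s: %s", rec.subject_id, es.trial_counts())
    erp = build_erp_dataset(epoch_sets, pp["min_trials"])
    dio.save_erp_dataset(out / "erp.h5", erp)
    dio.json_dump({"subjects": logs, "excluded": erp.excluded},
                  out / "preprocess_log.json")
    return inputs, [out / "erp.h5", out / "preprocess_log.json"]


def _stage_decompose(config: PipelineConfig, out: Path):
    inputs = [out / "erp.h5"]
    _require(out, ["erp.h5"], "preprocess")
    erp = dio.load_erp_dataset(out / "erp.h5")
    sensors = None
    if (out / "forward.h5").exists():
        _, sensors, _, _, _ = dio.load_forward_model(out / "forward.h5")
        inputs.append(out / "forward.h5")
    d = config["decompose"]
    model = TwoStepDecomposition(
        erp,
        n_temporal=d["n_temporal"] or None,
        n_spatial=d["n_spatial"] or None,
        kappa=d["kappa"],
        min_variance_percent=d["min_variance_percent"],
        n_surrogates=d["n_surrogates"],
        seed=config.stage_seed("decompose"),
        sensors=sensors)
    res = model.fit()
    dio.save_components(out / "components.h5", res.selected)
    report = {
        "n_temporal": res.temporal.n_factors,
        "n_spatial": res.spatial.n_components,
        "n_candidates": res.n_candidates,
        "n_selected": len(res.selected),
        "ica_converged": res.spatial.converged,
        "temporal_variance_fraction": res.temporal.variance_fraction.tolist(),
        "selected": [{
            "component": f"T{c.temporal_index}xS{c.spatial_index}",
            "variance_percent": c.variance_percent,
            "peak_latency_ms": c.qc.get("peak_latency_ms"),
        } for c in res.selected],
    }
    if res.parallel_temporal is not None:
        report["parallel_temporal_retained"] = res.parallel_temporal.retained
    if res.parallel_spatial is not None:
        report["parallel_spatial_retained"] = res.parallel_spatial.retained
    dio.json_dump(report, out / "decomposition.json")
    with open(out / "decomposition.txt", "w") as fh:
        fh.write(res.summary() + "\n")
    return inputs, [out / "components.h5", out / "decomposition.json",
                    out / "decomposition.txt"]


def _stage_stats(config: PipelineConfig, out: Path):
    inputs = [out / "components.h5", out / "erp.h5"]
    _require(out, ["components.h5"], "decompose")
    _require(out, ["erp.h5"], "preprocess")
    comps = dio.load_components(out / "components.h5")
    erp = dio.load_erp_dataset(out / "erp.h5")
    s = config["stats"]
    report = dstats.run_planned_contrasts(comps, erp, alpha=s["alpha"],
                                          holm=s["holm"])
    dio.json_dump(report, out / "stats.json")
    with open(out / "stats.txt", "w") as fh:
        fh.write(dstats.format_contrast_report(report) + "\n")
    import pandas as pd
    frames = []
    for comp in comps:
        peak = comp.qc.get("peak_latency_ms", np.nan)
        name, w = min(dstats.DEFAULT_COMPONENT_WINDOWS_MS.items(),
                      key=lambda kv: abs(0.5 * (kv[1][0] + kv[1][1]) - peak))
        tab = dstats.window_mean_amplitude(comp, erp, w)
        df = tab.to_frame()
        df.insert(0, "component", tab.component_id)
        df.insert(1, "subject", erp.subjects)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(out / "amplitudes.csv", index=False)
    return inputs, [out / "stats.json", out / "stats.txt", out / "amplitudes.csv"]


def _stage_localize(config: PipelineConfig, out: Path):
    inputs = [out / "components.h5", out / "forward.h5", out / "erp.h5"]
    _require(out, ["components.h5"], "decompose")
    _require(out, ["forward.h5"], "simulate")
    comps = dio.load_components(out / "components.h5")
    erp = dio.load_erp_dataset(out / "erp.h5")
    head, sensors, src, K, reg = dio.load_forward_model(out / "forward.h5")
    lc = config["localize"]
    cfg = InverseConfig(lam=lc["lambda"], method=lc["method"])
    inv = LoretaInverse(K, reg, src, cfg)
    results = []
    import h5py
    with h5py.File(out / "sources.h5", "w") as f:
        for comp in comps:
            l = comp.temporal_loading
            peak = int(np.argmax(np.abs(l)))
            w = float(comp.coefficients.mean()) * float(l[peak])
            from denserp.inverse import ScalpTopography
            phi = ScalpTopography(comp.spatial_map * w,
                                  comp.qc.get("peak_latency_ms", 0.0))
            est = inv.fit(phi)
            cid = f"T{comp.temporal_index}xS{comp.spatial_index}"
            g = f.create_group(f"source/{cid}")
            g.create_dataset("J", data=est.moments)
            g.create_dataset("intensity", data=est.intensity)
            g.create_dataset("locations", data=est.locations)
            peaks = est.peaks(lc["n_peaks"], lc["min_separation_mm"])
            results.append({"component": cid,
                            "peak_latency_ms": comp.qc.get("peak_latency_ms"),
                            "peaks": [{"location_mm": p.tolist(), "intensity": v}
                                      for p, v in peaks]})
    dio.json_dump({"method": lc["method"], "lambda": lc["lambda"],
                   "components": results}, out / "sources.json")
    return inputs, [out / "sources.h5", out / "sources.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "decompose": _stage_decompose,
    "stats": _stage_stats,
    "localize": _stage_localize,
}


def run_stage(name: str, config: PipelineConfig, out_dir=None, force: bool = False) -> dict:
    """Execute one pipeline stage; returns its manifest.

    If the stage's manifest exists and all input digests match, the stage
    is skipped (resume semantics) unless ``force`` is set.
    """
    if name not in _STAGE_FUNCS:
        raise ConfigError(f"unknown stage {name!r}; choose from {STAGES}")
    out = Path(out_dir or config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    dio.json_dump(config.resolved(), out / "config_resolved.json")
    man_path = out / f"manifest_{name}.json"
    t0 = time.time()
    if man_path.exists() and not force:
        with open(man_path) as fh:
            old = json.load(fh)
        inputs_ok = all(Path(p).exists() and _digest(Path(p)) == d
                        for p, d in old.get("inputs", {}).items())
        outputs_ok = all(Path(p).exists() for p in old.get("outputs", {}))
        if inputs_ok and outputs_ok:
            log.info("stage %s up to date; skipping", name)
            old["skipped"] = True
            return old
    log.info("running stage %s", name)
    import warnings as _w
    with _w.catch_warnings(record=True) as caught:
        _w.simplefilter("always")
        inputs, outputs = _STAGE_FUNCS[name](config, out)
    man = _manifest(name, inputs, outputs, t0, [str(c.message) for c in caught])
    dio.json_dump(man, man_path)
    log.info("stage %s done in %.1fs", name, man["wall_time_s"])
    return man


def run_all(config: PipelineConfig, out_dir=None, force: bool = False) -> list:
    """Run every stage in order; any stage error aborts with its name."""
    manifests = []
    for name in STAGES:
        try:
            manifests.append(run_stage(name, config, out_dir, force))
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    return manifests
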