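"""Pipeline orchestration: config, staged execution, and the run manifest.

A run executes the stages in method order — simulate/load, preprocess,
time-frequency decomposition into band signals (HHT or FIR front-end),
per-band microstate fit, backfit and parameter extraction — writing every
intermediate artifact under the output directory and recording parameters,
seeds and output checksums in a JSON manifest.  Re-running the same config
reproduces identical checksums.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import bands as bands_mod
from . import io as io_mod
from . import microstate as ms
from .synth import SyntheticSpec, simulate_microstate_eeg

__all__ = ["PipelineConfig", "PipelineError", "default_config", "run_pipeline"]

logger = logging.getLogger("hhtmicrostate")

#: All tunable knobs with their defaults; YAML configs override these keys.
DEFAULTS: dict[str, Any] = {
    "input": {"path": None, "format": None, "fs": None},
    "simulate": {
        "enabled": False, "C": 45, "fs": 250.0, "duration": 10.0, "K": 4,
        "duration_mean_ms": 100.0, "duration_shape": 4.0,
        "source_band": [8.0, 12.0], "amplitude": 10.0, "noise_sigma": 1.0,
        "seed": 0,
    },
    "preprocess": {"lowcut": 0.1, "highcut": 40.0, "keep_channels": None, "rereference": True},
    "bands": {
        "front_end": "hht", "mode": "samplewise", "edge_margin_s": 0.5,
        "n_realizations": 50, "beta": 0.1, "retain_fraction": 0.05,
        "max_imfs": None, "seed": 0,
    },
    "microstate": {
        "k": None, "k_range": [2, 8], "n_restarts": 20, "tol": 1e-6,
        "max_iters": 500, "min_segment_samples": 0, "seed": 0,
    },
    "comparison": {"n_perm": 999, "seed": 0},
    "output_dir": "out",
}


class PipelineError(RuntimeError):
    """A stage failure; carries the failing stage's name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see DEFAULTS for the schema)."""

    values: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(loaded)

    @classmethod
    def from_dict(cls, overrides: dict[str, Any]) -> "PipelineConfig":
        cfg = copy.deepcopy(DEFAULTS)
        for key, val in overrides.items():
            if key not in cfg:
                raise KeyError(f"unknown config section {key!r}")
            if isinstance(cfg[key], dict) and isinstance(val, dict):
                unknown = set(val) - set(cfg[key])
                if unknown:
                    raise KeyError(f"unknown config key(s) {sorted(unknown)} in {key!r}")
                cfg[key].update(val)
            else:
                cfg[key] = val
        return cls(cfg)

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def validate(self) -> None:
        sim = self.values["simulate"]["enabled"]
        path = self.values["input"]["path"]
        if not sim:
            if path is None:
                raise ValueError("either input.path or simulate.enabled is required")
            if not Path(path).exists():
                raise FileNotFoundError(f"input path does not exist: {path}")


def default_config() -> PipelineConfig:
    return PipelineConfig()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return (and write) the run manifest.

    Any stage error aborts with :class:`PipelineError` naming the stage;
    artifacts written so far stay on disk next to a ``failed`` marker.
    """
    config.validate()
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    manifest: dict[str, Any] = {"config": config.values, "artifacts": artifacts}

    def _write_rec(rec: io_mod.EEGRecording, name: str) -> None:
        path = out_dir / f"{name}.bin"
        io_mod.write_recording(rec, path, format="matrix-binary")
        artifacts[f"{name}.bin"] = _sha256(path)
        artifacts[f"{name}.bin.json"] = _sha256(Path(str(path) + ".json"))

    stage = "input"
    try:
        if config["simulate"]["enabled"]:
            s = config["simulate"]
            spec = SyntheticSpec(
                C=s["C"], fs=s["fs"], duration=s["duration"], K=s["K"],
                duration_mean_ms=s["duration_mean_ms"],
                duration_shape=s["duration_shape"],
                source_band=tuple(s["source_band"]),
                amplitude=s["amplitude"], noise_sigma=s["noise_sigma"],
                seed=s["seed"],
            )
            rec, truth = simulate_microstate_eeg(spec)
            truth_path = out_dir / "ground_truth.csv"
            io_mod.write_table(truth.params, truth_path)
            artifacts["ground_truth.csv"] = _sha256(truth_path)
        else:
            i = config["input"]
            rec = io_mod.read_recording(i["path"], format=i["format"], fs=i["fs"])
        _write_rec(rec, "raw")
        logger.info("input: %d channels x %d samples @ %g Hz",
                    rec.n_channels, rec.n_samples, rec.fs)

        stage = "preprocess"
        p = config["preprocess"]
        rec = io_mod.preprocess(
            rec, lowcut=p["lowcut"], highcut=p["highcut"],
            keep_channels=p["keep_channels"], rereference=p["rereference"],
        )
        _write_rec(rec, "preprocessed")

        stage = "bands"
        b = config["bands"]
        if b["front_end"] == "hht":
            band_signals = bands_mod.hht_band_signals(
                rec, mode=b["mode"], n_realizations=b["n_realizations"],
                beta=b["beta"], seed=b["seed"],
                retain_fraction=b["retain_fraction"], max_imfs=b["max_imfs"],
            )
        elif b["front_end"] == "fir":
            band_signals = bands_mod.fir_band_signals(rec)
        else:
            raise ValueError(f"unknown front_end {b['front_end']!r}")
        for name in band_signals.band_names:
            _write_rec(band_signals.as_recording(name, rec), f"band_{name}")

        stage = "microstate"
        m = config["microstate"]
        params_tables = []
        kv_table_rows = []
        targets = {"full": rec}
        for name in band_signals.band_names:
            targets[name] = band_signals.as_recording(name, rec)
        for band_name, band_rec in targets.items():
            if float(np.max(np.abs(band_rec.data))) == 0.0:
                logger.info("band %s is empty; skipped", band_name)
                continue
            g = ms.gfp(band_rec)
            peaks = ms.find_gfp_peaks(g)
            if peaks.size < 2 * max(2, m["k"] or max(m["k_range"])):
                logger.info("band %s has too few GFP peaks; skipped", band_name)
                continue
            maps = ms.extract_peak_maps(band_rec, peaks)
            if m["k"] is not None:
                model = ms.modified_kmeans(
                    maps, m["k"], n_restarts=m["n_restarts"],
                    max_iters=m["max_iters"], tol=m["tol"], seed=m["seed"],
                )
                best_k = m["k"]
            else:
                lo, hi = m["k_range"]
                hi = min(hi, band_rec.n_channels - 2)  # modified k-means bound
                best_k, table, models = ms.select_k(
                    maps, range(lo, hi + 1), n_restarts=m["n_restarts"],
                    max_iters=m["max_iters"], tol=m["tol"], seed=m["seed"],
                )
                model = models[best_k]
                for _, r in table.iterrows():
                    kv_table_rows.append({"band": band_name, **r.to_dict()})
            seq = ms.backfit(model, band_rec, min_segment_samples=m["min_segment_samples"])
            params = ms.microstate_parameters(seq, band_rec, model)
            t = params.table.copy()
            t.insert(0, "band", band_name)
            params_tables.append(t)

            model_path = out_dir / f"model_{band_name}.json"
            model_path.write_text(json.dumps({
                "templates": model.templates.tolist(),
                "K": best_k,
                "gev_total": model.gev_total,
                "cv": model.cv,
                "meta": model.meta,
            }))
            artifacts[model_path.name] = _sha256(model_path)
            labels_path = out_dir / f"labels_{band_name}.csv"
            io_mod.write_table(
                [{"sample": i, "label": int(l)} for i, l in enumerate(seq.labels)],
                labels_path,
            )
            artifacts[labels_path.name] = _sha256(labels_path)

        stage = "params"
        if params_tables:
            import pandas as pd

            all_params = pd.concat(params_tables, ignore_index=True)
            params_path = out_dir / "microstate_params.csv"
            io_mod.write_table(all_params, params_path)
            artifacts[params_path.name] = _sha256(params_path)
        if kv_table_rows:
            kv_path = out_dir / "k_selection.csv"
            io_mod.write_table(kv_table_rows, kv_path)
            artifacts[kv_path.name] = _sha256(kv_path)

    except Exception as exc:  # noqa: BLE001 - every stage error is reported uniformly
        (out_dir / "failed").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(stage, exc) from exc

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
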