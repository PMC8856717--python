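"""End-to-end orchestration: simulate -> detect -> train -> evaluate ->
surrogate, driven by a plain-dict (YAML-friendly) configuration.

Every stage draws its seed deterministically from the single global seed,
so a run is reproducible as a whole and each stage is reproducible in
isolation.  Artifacts are written as CSV/JSON into the output directory,
stamped with the configuration hash and the global seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import classifier as _clf
from . import detector as _det
from . import labeling as _lab
from . import surrogate as _sur
from .evaluation import prediction_metrics
from .signal_io import read_annotation, read_recording, write_annotation
from .spectral import band_energy_series, channel_product
from .synthetic import SyntheticSpec, gaers_spec, generate_recording

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "ConfigError",
           "SMOKE_CONFIG"]

log = logging.getLogger("swdpredict")


class ConfigError(ValueError):
    pass


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: mix the global seed with a CRC32 of
    the stage name, reduced below 2^31."""
    return (global_seed * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


#: A fast, fully wired configuration: 10-min synthetic record, reduced
#: forests and permutation counts.  Useful as a template and smoke test.
SMOKE_CONFIG: dict = {
    "seed": 0,
    "synthetic": {"duration_s": 600.0, "fs": 200.0,
                  "base_swd_rate_per_h": 60.0, "swd_duration_s": [5.0, 10.0],
                  "diurnal_mod_amplitude": 0.0},
    "detector": {"sites": ["S1_L4", "S1_L5", "S1_L6"],
                 "stride_s": 0.05, "target_sensitivity_pct": 90.0},
    "sampling": {"mode": "undersample", "oversample_factor": 4},
    "forest": {"n_trees": 20, "n_forests": 5},
    "surrogate": {"n_randomizations": 20},
    "sweep": {"enabled": True},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    synthetic: dict | None
    input_record: str | None
    input_annotation: str | None
    detector: dict = field(default_factory=dict)
    sampling: dict = field(default_factory=dict)
    forest: dict = field(default_factory=dict)
    surrogate: dict = field(default_factory=dict)
    sweep: dict = field(default_factory=dict)
    train_frac: float = 0.7

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "seed" not in raw:
            raise ConfigError("missing required config field: seed")
        has_synth = "synthetic" in raw
        has_input = "input" in raw
        if not has_synth and not has_input:
            raise ConfigError(
                "missing required config field: synthetic (or input)")
        det = dict(raw.get("detector", {}))
        if "sites" not in det:
            raise ConfigError("missing required config field: detector.sites")
        inp = raw.get("input", {})
        return cls(
            seed=int(raw["seed"]),
            synthetic=dict(raw["synthetic"]) if has_synth else None,
            input_record=inp.get("record"),
            input_annotation=inp.get("annotation"),
            detector=det,
            sampling=dict(raw.get("sampling", {})),
            forest=dict(raw.get("forest", {})),
            surrogate=dict(raw.get("surrogate", {})),
            sweep=dict(raw.get("sweep", {})),
            train_frac=float(raw.get("train_frac", 0.7)),
        )

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def _build_spec(cfg: dict) -> SyntheticSpec:
    known = dict(cfg)
    known.pop("strain", None)
    return gaers_spec(**known)


def _events_frame(events) -> pd.DataFrame:
    rows = []
    for e in events:
        row = {"t": e.t, "label": e.label}
        for bi, b in enumerate(e.band_names):
            for ci, ch in enumerate(e.channels):
                row[f"W_{b}_{ch}"] = e.features[bi * len(e.channels) + ci]
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: dict | RunConfig, out_dir) -> dict:
    """Execute the full prediction pipeline and write its artifacts.

    Returns the metrics report (also written as ``metrics.json``).
    Stage failures abort with a stage-tagged error; artifacts written
    before the failure are retained.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.digest(), "seed": cfg.seed}
    report: dict[str, Any] = {"stamp": stamp, "stages": {}}
    t_start = time.time()

    def _stage(name):
        log.info("stage %s", name)
        report["stages"][name] = {"t_start_s": round(time.time() - t_start, 2)}
        return stage_seed(cfg.seed, name)

    try:
        # --- simulate or load -------------------------------------------
        seed = _stage("simulate")
        if cfg.synthetic is not None:
            spec = _build_spec(cfg.synthetic)
            record, annotation = generate_recording(spec, rng_seed=seed)
            write_annotation(annotation, out / "annotation.csv")
        else:
            record = read_recording(cfg.input_record)
            annotation = read_annotation(cfg.input_annotation)

        # --- spectral features ------------------------------------------
        _stage("spectral")
        stride = cfg.detector.get("stride_s", 0.01)
        energies = band_energy_series(record, stride_s=stride)
        sites = list(cfg.detector["sites"])
        combo = _det.make_combination(sites)
        prod = channel_product(energies, sites)

        # --- threshold sweep (optional) ---------------------------------
        if cfg.sweep.get("enabled", True):
            _stage("sweep")
            sweep = _det.sweep_thresholds(
                record, annotation, combo, grid=cfg.sweep.get("grid"),
                energies=energies)
            sweep.to_csv(out / "sweep.csv", index=False)

        # --- calibrate + detect + label ---------------------------------
        _stage("detect")
        target = cfg.detector.get("target_sensitivity_pct", 90.0)
        calib = _det.calibrate_threshold(record, annotation, combo,
                                         target_sensitivity_pct=target,
                                         energies=energies)
        events = _det.detect_events(
            prod, energies, _det.DetectorConfig(threshold=calib.threshold))
        events, counts = _lab.label_detections(events, annotation)
        base = prediction_metrics(counts.n_tp_swd, counts.n_missed,
                                  counts.n_fp, record.duration_s / 3600.0)
        _events_frame(events).to_csv(out / "events.csv", index=False)
        report["calibration"] = {"threshold": calib.threshold,
                                 "sensitivity_pct": calib.sensitivity_pct,
                                 "reached": calib.reached}
        report["prediction"] = {"sensitivity_pct": base.sensitivity_pct,
                                "fp_per_h": base.fp_per_h,
                                "n_swd": counts.n_swd, "n_fp": counts.n_fp}

        # --- random forest ----------------------------------------------
        seed = _stage("train")
        train_ev, eval_ev = _clf.chronological_split(events,
                                                     record.duration_s,
                                                     cfg.train_frac)
        plan = _clf.SamplingPlan(
            mode=cfg.sampling.get("mode", "undersample"),
            oversample_factor=cfg.sampling.get("oversample_factor", 4),
            rng_seed=seed)
        n_trees = cfg.forest.get("n_trees", 1000)
        model, accs = _clf.select_representative_forest(
            train_ev, eval_ev, plan,
            n_forests=cfg.forest.get("n_forests", 100),
            n_trees=n_trees, base_seed=seed)
        outcome = _clf.classify_events(model, eval_ev)

        eval_swds = [on for on, off in annotation.events
                     if on >= cfg.train_frac * record.duration_s]
        kept_tp_windows = {e.t for e in outcome.kept_events
                           if e.label == _lab.TP}
        n_pred_after = sum(
            any(on - 1.0 <= t <= on for t in kept_tp_windows)
            for on in eval_swds)
        report["classification"] = {
            "balanced_accuracy_pct": outcome.metrics.balanced_accuracy_pct
            if outcome.metrics else None,
            "f1_pct": outcome.metrics.f1_pct if outcome.metrics else None,
            "fp_reduction_pct": outcome.fp_reduction_pct,
            "forest_accuracies_pct": list(np.round(accs, 3)),
            "n_eval_swd": len(eval_swds),
            "n_eval_swd_predicted_after_filter": n_pred_after,
        }
        if outcome.confusion is not None:
            c = outcome.confusion
            report["classification"]["confusion"] = {
                "fp_as_fp": c.fp_as_fp, "fp_as_tp": c.fp_as_tp,
                "tp_as_fp": c.tp_as_fp, "tp_as_tp": c.tp_as_tp}

        # --- surrogate ---------------------------------------------------
        seed = _stage("surrogate")
        table = _clf.build_balanced_training_set(
            train_ev, _clf.SamplingPlan(mode=plan.mode,
                                        oversample_factor=plan.oversample_factor,
                                        rng_seed=seed))
        sur = _sur.permutation_null_test(
            table, eval_ev,
            n_randomizations=cfg.surrogate.get("n_randomizations", 200),
            rng_seed=seed, n_trees=n_trees)
        pd.DataFrame({"null_balanced_accuracy_pct": sur.null_values}
                     ).to_csv(out / "surrogate_null.csv", index=False)
        report["surrogate"] = {
            "observed_balanced_accuracy_pct":
                sur.observed_balanced_accuracy_pct,
            "q95": sur.q95, "p_value": sur.p_value,
            "significant": sur.significant,
        }
    except Exception as err:
        failed = list(report["stages"])[-1] if report["stages"] else "config"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {err}") from err

    report["elapsed_s"] = round(time.time() - t_start, 2)
    (out / "metrics.json").write_text(json.dumps(report, indent=2, default=float))
    return report
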