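"""Persistence formats and end-to-end experiment orchestration.

Conventions used by every format in the package: amplitudes in µV, times
in ms, bin indices 0-based with half-open [start, end) intervals. Raw
recordings go to an HDF5 container (one dataset per channel, metadata as
attributes) with a JSON sidecar holding trial annotations; models go to
JSON; trial logs to newline-delimited JSON; summaries to CSV. Every
artifact records the root seed and package version, and the experiment
runner emits a manifest of output files with content hashes so exact
stages can be checked for bit-identical reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from . import synth_emg, signal_processing as sp, decoders, task_metrics, longitudinal
from .synth_emg import ChannelSpec, GeneratorConfig, SyntheticRecording

PACKAGE_VERSION = "0.1.0"


class FormatError(ValueError):
    """Malformed or truncated artifact file."""


# ---------------------------------------------------------------------------
# Recording container (HDF5 + JSON sidecar)
# ---------------------------------------------------------------------------

def sidecar_path(h5path: Path | str) -> Path:
    return Path(h5path).with_suffix(".trials.json")


def save_recording(rec: SyntheticRecording, h5path: Path | str, seed: int | None = None) -> list[Path]:
    """Persist a recording: one HDF5 dataset per channel plus a JSON
    sidecar with trial annotations. Datasets are written with
    ``track_times=False`` so identical content yields identical bytes."""
    h5path = Path(h5path)
    h5path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(h5path, "w") as f:
        f.attrs["sample_rate"] = rec.sample_rate
        f.attrs["units"] = "uV"
        f.attrs["version"] = PACKAGE_VERSION
        if seed is not None:
            f.attrs["seed"] = seed
        grp = f.create_group("channels")
        for i, ch in enumerate(rec.channel_specs):
            d = grp.create_dataset(ch.name, data=rec.samples[i], track_times=False)
            d.attrs["source_kind"] = ch.source_kind
            d.attrs["noise_floor_rms"] = ch.noise_floor_rms
            d.attrs["order"] = i
            d.attrs["activation_gain"] = json.dumps(dict(ch.activation_gain), sort_keys=True)
        f.create_dataset(
            "labels", data=np.asarray(rec.labels, dtype=object),
            dtype=h5py.string_dtype(), track_times=False,
        )
    side = sidecar_path(h5path)
    side.write_text(json.dumps({
        "version": PACKAGE_VERSION,
        "seed": seed,
        "units": {"amplitude": "uV", "time": "samples"},
        "trials": [{"start": s, "end": e, "cue": c} for s, e, c in rec.trials],
    }, indent=1))
    return [h5path, side]


def load_recording(h5path: Path | str) -> SyntheticRecording:
    h5path = Path(h5path)
    try:
        with h5py.File(h5path, "r") as f:
            rate = float(f.attrs["sample_rate"])
            grp = f["channels"]
            names = sorted(grp, key=lambda n: grp[n].attrs["order"])
            specs, rows = [], []
            for n in names:
                d = grp[n]
                specs.append(ChannelSpec(
                    name=n,
                    source_kind=str(d.attrs["source_kind"]),
                    noise_floor_rms=float(d.attrs["noise_floor_rms"]),
                    activation_gain=json.loads(d.attrs["activation_gain"]),
                ))
                rows.append(d[()])
            labels = np.array([x.decode() if isinstance(x, bytes) else str(x) for x in f["labels"][()]])
    except (OSError, KeyError) as exc:
        raise FormatError(f"cannot read recording container {h5path}: {exc}") from exc
    side = sidecar_path(h5path)
    try:
        meta = json.loads(side.read_text())
        trials = [(t["start"], t["end"], t["cue"]) for t in meta["trials"]]
    except (OSError, KeyError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read trial sidecar {side}: {exc}") from exc
    rec = SyntheticRecording(np.stack(rows), rate, labels, trials, specs)
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# Models (JSON)
# ---------------------------------------------------------------------------

def save_model(model, path: Path | str, seed: int | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(model, decoders.HmmNbModel):
        payload = {
            "kind": "hmm",
            "classes": model.classes,
            "states_per_class": model.states_per_class,
            "initial": model.initial.tolist(),
            "transition": model.transition.tolist(),
            "means": model.means.tolist(),
            "variances": model.variances.tolist(),
            "state_to_class": model.state_to_class.tolist(),
            "emission_domain": model.emission_domain,
            "drift_tolerance": model.drift_tolerance,
        }
    elif isinstance(model, decoders.StaticModel):
        payload = {
            "kind": model.kind,
            "classes": model.classes,
            "means": model.means.tolist(),
            "priors": model.priors.tolist(),
            "variances": None if model.variances is None else model.variances.tolist(),
            "covariance": None if model.covariance is None else model.covariance.tolist(),
        }
    else:
        raise TypeError(f"cannot serialize model of type {type(model)}")
    payload["version"] = PACKAGE_VERSION
    payload["seed"] = seed
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_model(path: Path | str):
    try:
        payload = json.loads(Path(path).read_text())
        kind = payload["kind"]
        if kind == "hmm":
            return decoders.HmmNbModel(
                classes=list(payload["classes"]),
                states_per_class=int(payload["states_per_class"]),
                initial=np.asarray(payload["initial"]),
                transition=np.asarray(payload["transition"]),
                means=np.asarray(payload["means"]),
                variances=np.asarray(payload["variances"]),
                state_to_class=np.asarray(payload["state_to_class"]),
                emission_domain=payload["emission_domain"],
                drift_tolerance=float(payload["drift_tolerance"]),
            )
        return decoders.StaticModel(
            kind=kind,
            classes=list(payload["classes"]),
            means=np.asarray(payload["means"]),
            priors=np.asarray(payload["priors"]),
            variances=None if payload["variances"] is None else np.asarray(payload["variances"]),
            covariance=None if payload["covariance"] is None else np.asarray(payload["covariance"]),
        )
    except (OSError, KeyError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read model {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Trial logs (NDJSON) and summaries (CSV)
# ---------------------------------------------------------------------------

def write_trial_logs(logs: Sequence[task_metrics.TrialLog], path: Path | str, seed: int | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as f:
        f.write(json.dumps({"_meta": True, "version": PACKAGE_VERSION, "seed": seed}) + "\n")
        for log in logs:
            f.write(json.dumps({
                "cue": log.cue,
                "outputs": [str(o) for o in log.outputs],
                "onset_bin": log.onset_bin,
                "success": log.success,
                "success_bin": log.success_bin,
                "bin_width_ms": log.bin_width_ms,
                "arm_position": log.arm_position,
                "latency_ms": task_metrics.compute_latency(log),
            }) + "\n")
    return path


def read_trial_logs(path: Path | str) -> list[task_metrics.TrialLog]:
    logs = []
    try:
        for line in Path(path).read_text().splitlines():
            rec = json.loads(line)
            if rec.get("_meta"):
                continue
            logs.append(task_metrics.TrialLog(
                cue=rec["cue"],
                outputs=np.asarray(rec["outputs"]),
                onset_bin=rec["onset_bin"],
                success=rec["success"],
                success_bin=rec["success_bin"],
                bin_width_ms=rec["bin_width_ms"],
                arm_position=rec["arm_position"],
            ))
    except (OSError, KeyError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read trial log {path}: {exc}") from exc
    return logs


def write_features_csv(features: sp.FeatureSequence, path: Path | str) -> Path:
    """Feature table: bin_start_ms then one MAV column per channel."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = features.channel_names or [f"ch{i}" for i in range(features.n_channels)]
    df = pd.DataFrame(features.mav.T, columns=names)
    df.insert(0, "bin_start_ms", np.arange(features.n_bins) * features.bin_width_ms)
    df.to_csv(path, index=False)
    return path


def write_session_summary(rows: Sequence[dict], path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(list(rows)).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Experiment runner
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end experiment configuration."""

    seed: int = 0
    out_dir: Path = Path("runs/experiment")
    n_sessions: int = 4
    n_trials: int = 8
    drift_sigma: float = 0.5
    sample_rate: int = 1000
    movements: tuple[str, ...] = synth_emg.FUNCTIONAL_GRIPS
    arm_positions: tuple[str, ...] = ("side",)
    stages: tuple[str, ...] = ("simulate", "process", "train", "task", "analyze")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" in raw:
            raw["out_dir"] = Path(raw["out_dir"])
        for key in ("movements", "arm_positions", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(config: RunConfig) -> dict:
    """Run simulate → process → train → task → analyze and write a
    manifest of every produced file with its content hash.

    The decoder is trained once, on session 1, and reused for every
    subsequent session's virtual task — no retraining events occur.
    Rerunning with the same config reproduces byte-identical simulation
    and training artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = synth_emg.default_config(config.movements, sample_rate=config.sample_rate)
    manifest: dict = {
        "version": PACKAGE_VERSION,
        "seed": config.seed,
        "stages": {},
        "files": {},
    }

    def record(stage: str, paths: Sequence[Path]) -> None:
        manifest["stages"].setdefault(stage, [])
        for p in paths:
            rel = str(Path(p).relative_to(out))
            manifest["stages"][stage].append(rel)
            manifest["files"][rel] = _sha256(Path(p))

    def require(stage: str, path: Path) -> Path:
        if not path.exists():
            raise FileNotFoundError(f"stage {stage!r}: missing upstream artifact {path}")
        return path

    sessions: list[tuple[synth_emg.SessionSpec, SyntheticRecording]] | None = None
    if "simulate" in config.stages:
        sessions = synth_emg.generate_longitudinal_series(
            config.n_sessions, config.drift_sigma, gen, seed=config.seed
        )
        paths = []
        for i, (spec, rec) in enumerate(sessions):
            paths += save_recording(rec, out / f"session_{i:02d}.h5", seed=config.seed)
        (out / "sessions.json").write_text(json.dumps({
            "days": [s.day for s, _ in sessions],
            "amplitude_scale": [dict(s.amplitude_scale) for s, _ in sessions],
        }, indent=1))
        paths.append(out / "sessions.json")
        record("simulate", paths)

    def load_sessions():
        recs = []
        meta = json.loads(require("process", out / "sessions.json").read_text())
        for i, day in enumerate(meta["days"]):
            rec = load_recording(require("process", out / f"session_{i:02d}.h5"))
            spec = synth_emg.SessionSpec(day=day, amplitude_scale=meta["amplitude_scale"][i], seed=0)
            recs.append((spec, rec))
        return recs

    feats_cache: list[tuple[sp.FeatureSequence, np.ndarray]] = []
    if "process" in config.stages:
        sessions = sessions or load_sessions()
        paths = []
        for i, (_spec, rec) in enumerate(sessions):
            emg = sp.preprocess(rec) if rec.sample_rate > sp.TARGET_RATE else sp.EmgRecording(
                rec.samples, rec.sample_rate, rec.channel_names
            )
            feats = sp.compute_mav(emg)
            labs = sp.bin_labels(rec.labels, rec.sample_rate)[: feats.n_bins]
            feats_cache.append((feats, labs))
            paths.append(write_features_csv(feats, out / f"features_{i:02d}.csv"))
        record("process", paths)

    model = None
    if "train" in config.stages:
        if not feats_cache:
            raise FileNotFoundError("stage 'train': missing upstream stage 'process'")
        feats, labs = feats_cache[0]
        model = decoders.train_hmm_nb(feats, labs, classes=list(config.movements))
        record("train", [save_model(model, out / "hmm_model.json", seed=config.seed)])

    logs_by_session: list[list[task_metrics.TrialLog]] = []
    if "task" in config.stages:
        if model is None:
            model = load_model(require("task", out / "hmm_model.json"))
        sessions = sessions or load_sessions()
        feats0, labs0 = feats_cache[0]
        rest_stats = sp.rest_mav_stats(feats0, labs0)
        paths = []
        root = np.random.SeedSequence([config.seed, 7])
        task_seeds = root.spawn(len(sessions) * len(config.arm_positions))
        k = 0
        summary_rows = []
        for i, (spec, rec) in enumerate(sessions):
            session_logs: list[task_metrics.TrialLog] = []
            for pos in config.arm_positions:
                cfg = task_metrics.TaskConfig(arm_position=pos, n_trials=config.n_trials)
                source = task_metrics.default_stream_source(
                    rec.channel_specs, spec.amplitude_scale, sample_rate=1000.0
                )
                logs = task_metrics.run_virtual_task(
                    model, source, cfg, rest_stats,
                    seed=int(task_seeds[k].generate_state(1)[0] % (2**31)),
                )
                k += 1
                session_logs.extend(logs)
            acc = task_metrics.compute_accuracy(session_logs)
            summary_rows.append({
                "session": i, "day": spec.day,
                "overall_accuracy_pct": acc.overall,
                "transition_errors": acc.transition_error_count,
                "n_trials": len(session_logs),
                "retrained": False,
            })
            paths.append(write_trial_logs(session_logs, out / f"task_logs_{i:02d}.ndjson", seed=config.seed))
            logs_by_session.append(session_logs)
        paths.append(write_session_summary(summary_rows, out / "task_summary.csv"))
        record("task", paths)

    if "analyze" in config.stages:
        summary = require("analyze", out / "task_summary.csv")
        df = pd.read_csv(summary)
        if len(df) >= 3:
            trend = longitudinal.fit_trend(df["day"], df["overall_accuracy_pct"])
            trend_row = dataclasses.asdict(trend)
        else:
            trend_row = {"note": "too few sessions for a trend"}
        path = out / "trend.json"
        path.write_text(json.dumps({"seed": config.seed, "accuracy_trend": trend_row}, indent=1))
        record("analyze", [path])

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
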