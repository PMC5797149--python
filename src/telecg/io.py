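"""Plain-text file formats and run manifests.

Records are CSV (time_s, mv) with a JSON sidecar holding metadata and
the recorded segments; activity is CSV (epoch_start_s, a_u); events are
JSON-lines (one event per line) with a lossless CSV mirror; beat
annotations are CSV.  A run manifest ties a config hash to per-file
checksums so identical configs are verifiably reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from telecg.detect import BeatAnnotation
from telecg.rhythm import ArrhythmiaEvent
from telecg.sim.activity import ActivitySeries
from telecg.sim.ecg import ECGRecord


# ---------------------------------------------------------------- records

def write_record(record: ECGRecord, basepath: str | Path) -> tuple[Path, Path]:
    base = Path(basepath)
    csv_path = base.with_suffix(".csv")
    meta_path = base.with_suffix(".meta.json")
    t = record.time_axis()
    pd.DataFrame({"time_s": t, "mv": record.signal}).to_csv(csv_path, index=False)
    meta = {
        "animal_id": record.animal_id, "strain": record.strain,
        "phase": record.phase, "session": record.session,
        "t0": record.t0, "fs": record.fs,
        "segments": [list(s) for s in record.segments],
        "artifact_truth": [list(s) for s in record.artifact_truth],
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return csv_path, meta_path


def read_record(basepath: str | Path) -> ECGRecord:
    base = Path(basepath)
    meta = json.loads(base.with_suffix(".meta.json").read_text())
    df = pd.read_csv(base.with_suffix(".csv"))
    rec = ECGRecord(
        animal_id=meta["animal_id"], strain=meta["strain"], phase=meta["phase"],
        session=meta["session"], t0=meta["t0"], fs=meta["fs"],
        signal=df["mv"].to_numpy(float),
        segments=[tuple(s) for s in meta["segments"]],
        artifact_truth=[tuple(s) for s in meta.get("artifact_truth", [])],
    )
    return rec


# --------------------------------------------------------------- activity

def write_activity(activity: ActivitySeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "epoch_start_s": activity.epoch_starts, "a_u": activity.values,
    }).to_csv(path, index=False)
    return path


def read_activity(path: str | Path) -> ActivitySeries:
    df = pd.read_csv(path)
    starts = df["epoch_start_s"].to_numpy(float)
    epoch_len = float(starts[1] - starts[0]) if len(starts) > 1 else 300.0
    return ActivitySeries(t0_clock=float(starts[0]), values=df["a_u"].to_numpy(float),
                          epoch_len=epoch_len)


# ----------------------------------------------------------------- events

def write_events(events: list[ArrhythmiaEvent], path: str | Path,
                 animal_id: str = "") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps({
                "animal": animal_id, "cls": ev.cls, "start": ev.start,
                "end": ev.end, "n_beats": ev.n_beats,
            }) + "\n")
    return path


def read_events(path: str | Path) -> tuple[list[ArrhythmiaEvent], list[str]]:
    events, animals = [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        events.append(ArrhythmiaEvent(cls=d["cls"], start=d["start"], end=d["end"],
                                      n_beats=d["n_beats"]))
        animals.append(d.get("animal", ""))
    return events, animals


def events_to_csv(jsonl_path: str | Path, csv_path: str | Path) -> Path:
    events, animals = read_events(jsonl_path)
    pd.DataFrame([
        {"animal": a, "cls": e.cls, "t_start": e.start, "t_end": e.end,
         "n_beats": e.n_beats}
        for a, e in zip(animals, events)
    ]).to_csv(csv_path, index=False)
    return Path(csv_path)


def csv_to_events(csv_path: str | Path, jsonl_path: str | Path) -> Path:
    df = pd.read_csv(csv_path)
    with open(jsonl_path, "w") as fh:
        for _, r in df.iterrows():
            n = r["n_beats"]
            fh.write(json.dumps({
                "animal": r["animal"], "cls": r["cls"], "start": float(r["t_start"]),
                "end": float(r["t_end"]),
                "n_beats": None if pd.isna(n) else int(n),
            }) + "\n")
    return Path(jsonl_path)


# ------------------------------------------------------------ annotations

def write_annotations(beats: list[BeatAnnotation], path: str | Path) -> Path:
    pd.DataFrame([
        {"time_s": b.time, "sample_index": b.sample_index,
         "r_amplitude": b.r_amplitude, "template_id": b.template_id,
         "match_score": b.match_score, "morphology": b.morphology,
         "p_found": b.p_wave_found, "p_low_confidence": b.p_low_confidence}
        for b in beats
    ]).to_csv(path, index=False)
    return Path(path)


def read_annotations(path: str | Path) -> list[BeatAnnotation]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        tid = r["template_id"]
        score = r["match_score"]
        out.append(BeatAnnotation(
            sample_index=int(r["sample_index"]), time=float(r["time_s"]),
            r_amplitude=float(r["r_amplitude"]),
            template_id=None if pd.isna(tid) else int(tid),
            match_score=None if pd.isna(score) else float(score),
            morphology=str(r["morphology"]), p_wave_found=bool(r["p_found"]),
            p_low_confidence=bool(r["p_low_confidence"]),
        ))
    return out


# ---------------------------------------------------------- truth & epochs

def write_truth_beats(truth, path: str | Path) -> Path:
    pd.DataFrame({
        "time_s": truth.times, "label": truth.labels,
        "event_id": truth.event_id, "p_wave": truth.p_wave,
    }).to_csv(path, index=False)
    return Path(path)


def read_truth_beats(path: str | Path):
    from telecg.sim.beats import BeatTruth

    df = pd.read_csv(path)
    return BeatTruth(
        times=df["time_s"].to_numpy(float),
        labels=df["label"].to_numpy(str),
        event_id=df["event_id"].to_numpy(int),
        p_wave=df["p_wave"].to_numpy(bool),
    )


def write_epochs(epochs, path: str | Path) -> Path:
    pd.DataFrame([
        {"epoch_start_s": e.start, "hr_bpm": e.hr, "valid": e.valid,
         "n_beats": e.n_beats} for e in epochs
    ]).to_csv(path, index=False)
    return Path(path)


def read_epochs(path: str | Path):
    from telecg.epochs import HREpoch

    df = pd.read_csv(path)
    return [HREpoch(start=float(r["epoch_start_s"]), hr=float(r["hr_bpm"]),
                    valid=bool(r["valid"]), n_beats=int(r["n_beats"]))
            for _, r in df.iterrows()]


# ------------------------------------------------------------------ config

@dataclass
class PipelineConfig:
    """Flat configuration; defaults equal the documented design choices."""

    seed: int = 0
    strains: list[str] = field(default_factory=lambda: ["Balb/c", "C57Bl/6", "BS", "FVB"])
    n_per_strain: dict[str, int] = field(
        default_factory=lambda: {"Balb/c": 6, "C57Bl/6": 6, "BS": 6, "FVB": 5})
    fidelity: str = "epoch"
    longterm_duration_h: float = 96.0
    acute_duration_min: float = 330.0
    sampling_rate: float = 1000.0
    premature_ratio: float = 0.8
    pause_ratio: float = 1.15
    reference_k: int = 5
    unmatched_threshold: float = 0.80
    merge_threshold: float = 0.95
    band_low_hz: float = 20.0
    band_high_hz: float = 120.0
    alpha: float = 0.05
    out_dir: str = "study_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return Path(path)


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def config_hash(config: PipelineConfig) -> str:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------- manifest

def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(config: PipelineConfig, files: list[str | Path],
                   path: str | Path, version: str | None = None) -> Path:
    from telecg import __version__

    base = Path(path).parent

    def rel(f: str) -> str:
        p = Path(f)
        try:
            return str(p.relative_to(base))
        except ValueError:
            return str(p)

    manifest = {
        "config_hash": config_hash(config),
        "version": version or __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": {rel(f): file_checksum(f) for f in sorted(map(str, files))},
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return Path(path)
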