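"""Readers/writers for records, beats, configs, and the reference tables.

Record dialect (plain text, one record = three files sharing a base path):

* ``<base>.csv``       — ``sample_index,value_mV``
* ``<base>.ann.csv``   — ``sample_index,symbol``
* ``<base>.json``      — record id, lead, sampling rate

Beats serialize to NPZ (sample matrix + labels + provenance) or CSV (one
row per beat: 300 values then the label).  All writes are atomic
(write-temp-then-rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from importlib import resources
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from .evaluate import (
    ConfusionMatrix,
    metrics_from_matrix,
    round_half_up,
)
from .records import Annotation, Beat, EcgRecord

__all__ = [
    "atomic_write",
    "write_record",
    "read_record",
    "save_beats",
    "load_beats",
    "beats_to_csv",
    "load_config",
    "reference_matrices",
    "verify_reference_tables",
]

REFERENCE_TABLES = ("arrhythmia", "supraventricular", "no_preprocessing")


def atomic_write(path: str | Path, writer: Callable[[Path], None]) -> None:
    """Write via a temp file in the same directory, then rename into place."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    tmp_path = Path(tmp)
    try:
        writer(tmp_path)
        tmp_path.replace(path)
    finally:
        tmp_path.unlink(missing_ok=True)


def write_record(record: EcgRecord, base: str | Path) -> None:
    """Write one record in the CSV dialect under the given base path."""
    base = Path(base)

    def _samples(p: Path) -> None:
        df = pd.DataFrame({"sample_index": np.arange(len(record.samples)),
                           "value_mV": record.samples})
        df.to_csv(p, index=False)

    def _anns(p: Path) -> None:
        df = pd.DataFrame({"sample_index": [a.index for a in record.annotations],
                           "symbol": [a.symbol for a in record.annotations]})
        df.to_csv(p, index=False)

    def _meta(p: Path) -> None:
        p.write_text(json.dumps({"record_id": record.record_id,
                                 "lead": record.lead, "fs": record.fs},
                                indent=2))

    atomic_write(base.with_suffix(".csv"), _samples)
    atomic_write(base.with_suffix(".ann.csv"), _anns)
    atomic_write(base.with_suffix(".json"), _meta)


def read_record(base: str | Path) -> EcgRecord:
    """Read a record written by :func:`write_record`; validates on load."""
    base = Path(base)
    samples_path = base.with_suffix(".csv")
    if not samples_path.exists():
        raise FileNotFoundError(samples_path)
    df = pd.read_csv(samples_path)
    samples = df["value_mV"].to_numpy(dtype=np.float64)
    meta = {"record_id": base.stem, "lead": "MLII", "fs": 360.0}
    meta_path = base.with_suffix(".json")
    if meta_path.exists():
        meta.update(json.loads(meta_path.read_text()))
    anns: list[Annotation] = []
    ann_path = base.with_suffix(".ann.csv")
    if ann_path.exists():
        adf = pd.read_csv(ann_path)
        anns = [Annotation(int(i), str(s))
                for i, s in zip(adf["sample_index"], adf["symbol"])]
    return EcgRecord(meta["record_id"], samples, fs=float(meta["fs"]),
                     lead=meta["lead"], annotations=anns)


def save_beats(beats: list[Beat], path: str | Path) -> None:
    """Beats to NPZ: sample matrix, labels, record ids, peak indices."""
    x = np.stack([b.samples for b in beats])
    labels = np.array([b.label for b in beats])
    rec_ids = np.array([b.record_id for b in beats])
    peaks = np.array([b.peak_index for b in beats])

    def _write(p: Path) -> None:
        with open(p, "wb") as fh:
            np.savez_compressed(fh, samples=x, labels=labels,
                                record_ids=rec_ids, peak_indices=peaks)

    atomic_write(path, _write)


def load_beats(path: str | Path) -> list[Beat]:
    with np.load(path, allow_pickle=False) as data:
        return [Beat(s, str(l), str(r), int(p))
                for s, l, r, p in zip(data["samples"], data["labels"],
                                      data["record_ids"], data["peak_indices"])]


def beats_to_csv(beats: list[Beat], path: str | Path) -> None:
    """Beats to CSV: one row per beat, 300 sample columns then the label."""
    x = np.stack([b.samples for b in beats])
    df = pd.DataFrame(x, columns=[f"s{i}" for i in range(x.shape[1])])
    df["label"] = [b.label for b in beats]
    atomic_write(path, lambda p: df.to_csv(p, index=False))


#: Recognized top-level sections of a run-configuration file.
CONFIG_SECTIONS = ("synth", "preprocess", "segment", "model", "train",
                   "evaluate", "seed", "output_dir")


def load_config(path: str | Path) -> dict:
    """YAML run configuration -> nested dict; unknown sections are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - set(CONFIG_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    """Write a run configuration; a load/save cycle is lossless."""
    unknown = set(cfg) - set(CONFIG_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    atomic_write(path, lambda p: p.write_text(
        yaml.safe_dump(cfg, sort_keys=True)))


# ---------------------------------------------------------------------------
# model archives (NPZ dialect with an embedded JSON manifest)
# ---------------------------------------------------------------------------


def _assign_params(net, arrays: list[np.ndarray]) -> None:
    params = net.params()
    if len(params) != len(arrays):
        raise ValueError("archive does not match model architecture")
    for p, a in zip(params, arrays):
        if p.shape != a.shape:
            raise ValueError(f"parameter shape {a.shape} != expected {p.shape}")
        p[...] = a


def save_autoencoder_bank(bank, path: str | Path) -> None:
    """Bank -> single NPZ archive with a JSON manifest entry."""
    from .models import AutoencoderBank  # noqa: F401  (type context)

    payload: dict[str, np.ndarray] = {}
    manifest = {"classes": list(bank.classes), "kind": "autoencoder-bank"}
    for cls in bank.classes:
        model = bank.models[cls]
        manifest[cls] = {
            "encoder_units": list(model.config.encoder_units),
            "beat_length": model.config.beat_length,
            "n_params": len(model.net.params()),
            "best_epoch": model.history.best_epoch if model.history else 0,
        }
        for i, p in enumerate(model.net.params()):
            payload[f"{cls}_{i}"] = p
        if model.history is not None:
            payload[f"{cls}_monitored"] = np.asarray(model.history.monitored)
    payload["manifest"] = np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8)

    def _write(p: Path) -> None:
        with open(p, "wb") as fh:
            np.savez_compressed(fh, **payload)

    atomic_write(path, _write)


def load_autoencoder_bank(path: str | Path):
    from .models import AutoencoderBank, AutoencoderConfig, LstmAutoencoder
    from .nn_core import TrainingHistory

    with np.load(path, allow_pickle=False) as data:
        manifest = json.loads(bytes(data["manifest"]).decode())
        models = {}
        for cls in manifest["classes"]:
            meta = manifest[cls]
            cfg = AutoencoderConfig(
                encoder_units=tuple(meta["encoder_units"]),
                beat_length=meta["beat_length"])
            model = LstmAutoencoder(cfg, seed=0)
            _assign_params(model.net,
                           [data[f"{cls}_{i}"] for i in range(meta["n_params"])])
            hist = TrainingHistory(best_epoch=meta["best_epoch"])
            key = f"{cls}_monitored"
            if key in data:
                hist.train_loss = data[key].tolist()
            model.history = hist
            models[cls] = model
    return AutoencoderBank(models, classes=tuple(manifest["classes"]))


def save_classifier(clf, path: str | Path) -> None:
    from dataclasses import asdict

    manifest = {
        "kind": "beat-classifier",
        "config": asdict(clf.config),
        "input_channels": clf.net.layers[0].n,
        "beat_length": clf.net.layers[2].W.shape[0] // clf.config.lstm_units,
        "n_params": len(clf.net.params()),
        "best_epoch": clf.history.best_epoch if clf.history else 0,
    }
    payload = {f"p_{i}": p for i, p in enumerate(clf.net.params())}
    payload["manifest"] = np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8)

    def _write(p: Path) -> None:
        with open(p, "wb") as fh:
            np.savez_compressed(fh, **payload)

    atomic_write(path, _write)


def load_classifier(path: str | Path):
    from .models import BeatClassifier, ClassifierConfig
    from .nn_core import TrainingHistory

    with np.load(path, allow_pickle=False) as data:
        manifest = json.loads(bytes(data["manifest"]).decode())
        cfg = ClassifierConfig(**manifest["config"])
        clf = BeatClassifier(cfg, input_channels=manifest["input_channels"],
                             beat_length=manifest["beat_length"], seed=0)
        _assign_params(clf.net,
                       [data[f"p_{i}"] for i in range(manifest["n_params"])])
        clf.history = TrainingHistory(best_epoch=manifest["best_epoch"])
    return clf


# ---------------------------------------------------------------------------
# packaged reference tables
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("ecgbeats").joinpath("data", name)


def reference_matrices() -> dict[str, ConfusionMatrix]:
    """The transcribed reference confusion matrices shipped with the package."""
    out = {}
    for name in REFERENCE_TABLES:
        with resources.as_file(_data_path(f"table_{name}.csv")) as p:
            df = pd.read_csv(p)
        classes = tuple(df["true"].astype(str))
        out[name] = ConfusionMatrix(df[list(classes)].to_numpy(), classes)
    return out


def printed_metrics() -> pd.DataFrame:
    with resources.as_file(_data_path("printed_metrics.csv")) as p:
        return pd.read_csv(p, keep_default_na=False)


def verify_reference_tables() -> pd.DataFrame:
    """Recompute every printed Acc/Se/Pr cell from the reference matrices.

    Returns a frame with columns (table, metric, class, printed, computed,
    match).  Se is computed as the column ratio and Pr as the row ratio —
    the orientation that reproduces the printed tables — and values are
    rounded half-up to two decimals before comparison.  Cells that disagree
    (a handful of truncated or inconsistent printed values) are flagged,
    not forced.
    """
    matrices = reference_matrices()
    reports = {name: metrics_from_matrix(m, orientation="printed")
               for name, m in matrices.items()}
    rows = []
    for _, row in printed_metrics().iterrows():
        rep = reports[row["table"]]
        if row["metric"] == "acc":
            computed = rep.accuracy_rounded
        elif row["metric"] == "se":
            computed = rep.se_rounded(row["class"])
        else:
            computed = rep.pr_rounded(row["class"])
        printed = float(row["printed"])
        rows.append({
            "table": row["table"],
            "metric": row["metric"],
            "class": row["class"],
            "printed": printed,
            "computed": computed,
            "computed_unrounded": round_half_up(
                rep.accuracy_pct if row["metric"] == "acc"
                else (rep.se(row["class"]) if row["metric"] == "se"
                      else rep.pr(row["class"])), 4),
            "match": computed == printed,
        })
    return pd.DataFrame(rows)
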