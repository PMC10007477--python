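"""Plain-text readers and writers for every pipeline artefact.

Formats are deliberately simple: single-column ECG CSV with a ``# fs=<Hz>``
header, two-column RR CSV, tidy per-window index tables, and YAML sidecars
recording the generating spec or analysis configuration next to each data
file.
"""

from __future__ import annotations

from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ecg import EcgRecord
from .hrv import HrvTimeSeries
from .rr import Epoch, RrSeries


def _sidecar(path: Path, meta: object) -> None:
    if meta is None:
        return
    if is_dataclass(meta):
        meta = asdict(meta)
    with open(Path(path).with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, default_flow_style=False)


# -- ECG ---------------------------------------------------------------------

def write_ecg_csv(record: EcgRecord, path, meta: object = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g}\n")
        np.savetxt(fh, record.samples, fmt="%.6g")
    _sidecar(path, meta)


def read_ecg_csv(path, participant_id: str = "") -> EcgRecord:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# fs="):
            raise ValueError(f"{path}: expected '# fs=<Hz>' header, got {header!r}")
        fs = float(header.split("=", 1)[1])
        samples = np.loadtxt(fh)
    return EcgRecord(samples=samples, fs=fs, participant_id=participant_id)


# -- annotations --------------------------------------------------------------

def write_annotations_csv(epochs: list[Epoch], path) -> None:
    frame = pd.DataFrame(
        [{"start_s": e.start, "end_s": e.end, "kind": e.kind, "domain": e.domain} for e in epochs]
    )
    frame.to_csv(path, index=False)


def read_annotations_csv(path) -> list[Epoch]:
    frame = pd.read_csv(path)
    return [
        Epoch(start=row.start_s, end=row.end_s, kind=row.kind, domain=row.domain)
        for row in frame.itertuples()
    ]


# -- RR series ----------------------------------------------------------------

def write_rr_csv(rr: RrSeries, path, meta: object = None) -> None:
    """Two-column CSV (beat_time_s of the later beat, rr_ms) plus quality."""
    path = Path(path)
    frame = pd.DataFrame(
        {
            "beat_time_s": rr.interval_times,
            "rr_ms": rr.intervals,
            "quality": np.where(rr.quality, "ok", "rejected"),
        }
    )
    frame.to_csv(path, index=False, float_format="%.6f")
    _sidecar(path, meta)


def read_rr_csv(path) -> RrSeries:
    frame = pd.read_csv(path)
    later = frame["beat_time_s"].to_numpy(dtype=float)
    iv = frame["rr_ms"].to_numpy(dtype=float)
    first = later[0] - iv[0] / 1000.0
    times = np.concatenate([[first], later])
    quality = (frame.get("quality", pd.Series(["ok"] * len(frame))) == "ok").to_numpy()
    return RrSeries(beat_times=times, intervals=1000.0 * np.diff(times), quality=quality)


# -- per-window index tables ---------------------------------------------------

def write_window_table(
    ts: HrvTimeSeries, path, participant: str = "", epoch: str = "", meta: object = None
) -> None:
    """Tidy CSV: participant, epoch, window_center_s, index, value."""
    path = Path(path)
    tidy = (
        ts.frame.reset_index()
        .melt(id_vars="window_center_s", var_name="index", value_name="value")
        .assign(participant=participant, epoch=epoch)
    )
    cols = ["participant", "epoch", "window_center_s", "index", "value"]
    tidy[cols].to_csv(path, index=False)
    _sidecar(path, meta)


# -- cohort tables -------------------------------------------------------------

def write_cohort_csv(features: pd.DataFrame, scores, dir_path, meta: object = None) -> None:
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    features.to_csv(dir_path / "features.csv", index=False)
    pd.DataFrame({"score": np.asarray(scores)}).to_csv(dir_path / "scores.csv", index=False)
    _sidecar(dir_path / "cohort", meta)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_scores(path) -> np.ndarray:
    frame = pd.read_csv(path)
    col = "score" if "score" in frame.columns else frame.columns[0]
    return frame[col].to_numpy(dtype=float)
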