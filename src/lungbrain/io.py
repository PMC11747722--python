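"""File formats for recordings, trends, design tables and run manifests.

CSV dialect is fixed: comma separator, dot decimal, UTF-8, header row, time
column first (elapsed seconds from recording start).  Period intervals are
half-open ``[start, end)``.  Recordings can also round-trip through HDF5 with
one dataset per channel and a ``sampling_rate`` attribute.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, SynthConfig, config_hash
from .synth import Annotation, WaveformRecording

TIME_COLUMN = "time_s"
DESIGN_COLUMNS = ("animal", "sequence", "block", "period_order", "position",
                  "peep", "label", "period_id", "start_s", "end_s")
_MAX_REL_JITTER = 1e-6


# ---------------------------------------------------------------------------
# recordings


def _annotations_to_json(annotations: list[Annotation]) -> str:
    return json.dumps([
        dict(kind=a.kind, label=a.label, start_s=a.start_s, end_s=a.end_s,
             info=a.info)
        for a in annotations
    ])


def _annotations_from_json(payload: str) -> list[Annotation]:
    return [Annotation(**d) for d in json.loads(payload)]


def write_waveforms_csv(rec: WaveformRecording, path: str | Path) -> Path:
    """Waveform CSV (time + one column per channel) plus a JSON sidecar with
    sampling rate and annotations."""
    path = Path(path)
    df = pd.DataFrame({TIME_COLUMN: rec.time()} | dict(rec.channels))
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(dict(
        sampling_rate=rec.sampling_rate, start_time=rec.start_time,
        annotations=json.loads(_annotations_to_json(rec.annotations)),
    )))
    return path


def read_waveforms_csv(path: str | Path) -> WaveformRecording:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if TIME_COLUMN not in df.columns:
        raise ValueError(f"{path}: missing required column {TIME_COLUMN!r}")
    t = df[TIME_COLUMN].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 2
        raise ValueError(f"{path}: non-monotonic time at row {bad}")
    if (dt.max() - dt.min()) / dt.mean() > _MAX_REL_JITTER:
        raise ValueError(f"{path}: inconsistent sampling interval")
    fs = 1.0 / dt.mean()
    channels = {c: df[c].to_numpy(dtype=float)
                for c in df.columns if c != TIME_COLUMN}
    annotations: list[Annotation] = []
    start_time = 0.0
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = float(meta.get("sampling_rate", fs))
        start_time = float(meta.get("start_time", 0.0))
        annotations = [Annotation(**d) for d in meta.get("annotations", [])]
    return WaveformRecording(channels=channels, sampling_rate=fs,
                             start_time=start_time, annotations=annotations)


def write_waveforms_h5(rec: WaveformRecording, path: str | Path) -> Path:
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["start_time"] = rec.start_time
        f.attrs["annotations"] = _annotations_to_json(rec.annotations)
        for name, x in rec.channels.items():
            f.create_dataset(name, data=x)
    return path


def read_waveforms_h5(path: str | Path) -> WaveformRecording:
    import h5py

    with h5py.File(path, "r") as f:
        channels = {name: f[name][()] for name in f.keys()}
        return WaveformRecording(
            channels=channels,
            sampling_rate=float(f.attrs["sampling_rate"]),
            start_time=float(f.attrs.get("start_time", 0.0)),
            annotations=_annotations_from_json(f.attrs.get("annotations", "[]")),
        )


# ---------------------------------------------------------------------------
# design / trends / tables


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    bad = design[design["start_s"] >= design["end_s"]]
    if not bad.empty:
        raise ValueError(f"design rows with start >= end: {list(bad.index)}")
    for animal, grp in design.groupby("animal"):
        g = grp.sort_values("start_s")
        overlap = g["start_s"].to_numpy()[1:] < g["end_s"].to_numpy()[:-1] - 1e-9
        if overlap.any():
            rows = list(g.index[1:][overlap])
            raise ValueError(f"overlapping periods for {animal!r} at rows {rows}")
    return design


def write_design_csv(design: pd.DataFrame, path: str | Path) -> Path:
    validate_design(design)
    path = Path(path)
    design.to_csv(path, index=False)
    return path


def read_design_csv(path: str | Path) -> pd.DataFrame:
    return validate_design(pd.read_csv(Path(path)))


def write_trends_csv(trend, path: str | Path) -> Path:
    """One row per 10-s block: time, per-channel value and validity flag."""
    path = Path(path)
    df = pd.DataFrame({TIME_COLUMN: trend.time})
    for ch in trend.channels:
        df[ch] = trend.data[ch].to_numpy()
        df[f"{ch}_valid"] = trend.valid[ch].to_numpy()
    df.to_csv(path, index=False)
    return path


def read_trends_csv(path: str | Path):
    from .trends import TrendSeries

    df = pd.read_csv(Path(path))
    channels = [c for c in df.columns
                if c != TIME_COLUMN and not c.endswith("_valid")]
    data = df[channels]
    valid = pd.DataFrame({c: df[f"{c}_valid"].astype(bool) for c in channels})
    time = df[TIME_COLUMN].to_numpy(dtype=float)
    block_s = float(time[1] - time[0]) if len(time) > 1 else 10.0
    return TrendSeries(time=time, data=data, valid=valid, block_s=block_s)


def write_table_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_reports_json(reports: dict, path: str | Path) -> Path:
    def encode(obj):
        if hasattr(obj, "to_dict"):
            return obj.to_dict()
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict(orient="records")
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.bool_):
            return bool(obj)
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    path = Path(path)
    path.write_text(json.dumps(reports, default=encode, indent=2,
                               allow_nan=True))
    return path


# ---------------------------------------------------------------------------
# configs and manifests


def load_config(path: str | Path) -> RunConfig:
    """Run configuration from YAML or JSON."""
    import yaml

    payload = Path(path).read_text()
    data = yaml.safe_load(payload)
    if "synth" in data or "out_dir" in data or "amp_method" in data:
        return RunConfig.from_dict(data)
    return RunConfig(synth=SynthConfig.from_dict(data))


def save_config(cfg: RunConfig | SynthConfig, path: str | Path) -> Path:
    import yaml

    path = Path(path)
    path.write_text(yaml.safe_dump(cfg.as_dict(), sort_keys=True))
    return path


def build_manifest(cfg: RunConfig) -> dict:
    """Deterministic run manifest: seed, config hash and tool versions."""
    return dict(
        package="lungbrain",
        version=__version__,
        seed=cfg.synth.seed,
        config=cfg.as_dict(),
        config_sha256=config_hash(cfg),
        python=platform.python_version(),
        numpy=np.__version__,
        pandas=pd.__version__,
    )


def write_manifest(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(build_manifest(cfg), indent=2, sort_keys=True))
    return path
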