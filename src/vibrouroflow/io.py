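"""Standard-format I/O: WAV vibration records, CSV flow curves, cohort
manifests, and per-session round-trips.

Conventions (documented because the field has none for this device class):
flow CSV has a ``time_s,flow_ml_s`` header with time starting at 0 at
voiding onset; vibration CSV has a single ``sample`` header column; the
manifest carries one row per session with the generator draw encoded as a
JSON string column. WAV files are mono float32 PCM, lossless round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import CorruptInputError
from .types import FlowCurve, PatternLabel, SessionRecord, VibrationRecord

__all__ = ["write_wav", "read_wav", "read_vibration_csv", "write_flow_csv",
           "read_flow_csv", "save_session", "load_session", "save_cohort",
           "load_cohort", "write_manifest", "read_manifest"]

MANIFEST_NAME = "manifest.csv"

_INT_SCALES = {np.dtype("int16"): 2 ** 15, np.dtype("int32"): 2 ** 31,
               np.dtype("uint8"): 2 ** 7}


def write_wav(path, record: VibrationRecord) -> None:
    wavfile.write(str(path), int(record.fs), record.samples.astype(np.float32))


def read_wav(path) -> VibrationRecord:
    """Read a mono WAV file (float or integer PCM; integers are rescaled
    to [-1, 1])."""
    fs, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise CorruptInputError(
            f"{path}: expected mono WAV, got {data.shape[1]} channels")
    if data.dtype in _INT_SCALES:
        offset = 128 if data.dtype == np.dtype("uint8") else 0
        data = (data.astype(np.float64) - offset) / _INT_SCALES[data.dtype]
    else:
        data = data.astype(np.float64)
    if not np.all(np.isfinite(data)):
        raise CorruptInputError(f"{path}: non-finite samples")
    return VibrationRecord(fs=float(fs), samples=data)


def read_vibration_csv(path, fs: float) -> VibrationRecord:
    """One-column CSV (header ``sample``) with an externally supplied rate."""
    df = pd.read_csv(path)
    if "sample" not in df.columns:
        raise CorruptInputError(f"{path}: missing 'sample' header")
    vals = df["sample"].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = int(np.flatnonzero(~np.isfinite(vals))[0]) + 2  # 1-based + header
        raise CorruptInputError(f"{path}: non-finite value at row {bad}")
    return VibrationRecord(fs=fs, samples=vals)


def write_flow_csv(path, curve: FlowCurve, decimals: int = 1) -> None:
    df = pd.DataFrame({"time_s": np.round(curve.times, 3),
                       "flow_ml_s": np.round(curve.flow, decimals)})
    df.to_csv(path, index=False)


def read_flow_csv(path) -> FlowCurve:
    df = pd.read_csv(path)
    for col in ("time_s", "flow_ml_s"):
        if col not in df.columns:
            raise CorruptInputError(f"{path}: missing '{col}' header")
    t = df["time_s"].to_numpy(dtype=float)
    q = df["flow_ml_s"].to_numpy(dtype=float)
    if not np.all(np.isfinite(q)) or not np.all(np.isfinite(t)):
        bad = int(np.flatnonzero(~(np.isfinite(q) & np.isfinite(t)))[0]) + 2
        raise CorruptInputError(f"{path}: non-finite value at row {bad}")
    neg = np.flatnonzero(q < 0)
    if neg.size:
        raise CorruptInputError(
            f"{path}: negative flow at row {int(neg[0]) + 2}")
    dts = np.diff(t)
    if dts.size == 0 or not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise CorruptInputError(f"{path}: time column is not uniformly sampled")
    # printed precision can leave the end samples slightly above zero
    q[0] = q[-1] = 0.0
    return FlowCurve(dt=float(dts[0]), flow=q)


# --- sessions and cohorts -----------------------------------------------------

def save_session(directory, record: SessionRecord) -> None:
    """Write ``<id>.wav``, optional ``<id>_flow.csv`` and ``<id>.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = record.session_id
    write_wav(directory / f"{sid}.wav", record.vibration)
    if record.flow is not None:
        write_flow_csv(directory / f"{sid}_flow.csv", record.flow, decimals=6)
    meta = {
        "session_id": sid,
        "fs": record.vibration.fs,
        "label": int(record.label) if record.label is not None else None,
        "generator_params": _jsonable(record.generator_params),
    }
    (directory / f"{sid}.json").write_text(json.dumps(meta, indent=1))


def load_session(directory, session_id: str) -> SessionRecord:
    directory = Path(directory)
    meta = json.loads((directory / f"{session_id}.json").read_text())
    vib = read_wav(directory / f"{session_id}.wav")
    flow_path = directory / f"{session_id}_flow.csv"
    flow = read_flow_csv(flow_path) if flow_path.exists() else None
    label = meta.get("label")
    return SessionRecord(
        session_id=session_id, vibration=vib, flow=flow,
        label=PatternLabel(label) if label is not None else None,
        generator_params=meta.get("generator_params", {}))


def write_manifest(directory, cohort: Sequence[SessionRecord]) -> None:
    rows = []
    for s in cohort:
        gp = s.generator_params
        rows.append({
            "session_id": s.session_id,
            "label": int(s.label) if s.label is not None else -1,
            "qmax_ml_s": gp.get("qmax"),
            "voided_volume_ml": gp.get("voided_volume"),
            "voiding_time_s": gp.get("voiding_time"),
            "params_json": json.dumps(_jsonable(gp), sort_keys=True),
        })
    pd.DataFrame(rows).to_csv(Path(directory) / MANIFEST_NAME, index=False)


def read_manifest(directory) -> pd.DataFrame:
    return pd.read_csv(Path(directory) / MANIFEST_NAME)


def save_cohort(directory, cohort: Sequence[SessionRecord]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s in cohort:
        save_session(directory, s)
    write_manifest(directory, cohort)


def load_cohort(directory) -> list[SessionRecord]:
    df = read_manifest(directory)
    return [load_session(directory, sid) for sid in df["session_id"]]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
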