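"""CSV/JSON interchange for waveforms, series, protocols, and manifests.

CSV is the interchange format throughout: waveform channels are two-column
``time_s,value`` files, heart-rate series ``time_s,bpm,source``, reserve
series ``time_s,crm_percent,kind``. A per-subject JSON manifest binds the
channel files to their sampling rate, protocol, and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .crm import CRMSeries
from .protocol import LBNPProtocol
from .synthetic import SubjectRecording
from .waveform import Waveform

__all__ = [
    "read_waveform_csv",
    "write_waveform_csv",
    "read_crm_csv",
    "write_crm_csv",
    "write_hr_csv",
    "read_hr_csv",
    "write_recording",
    "protocol_to_dict",
    "protocol_from_dict",
]

#: Relative tolerance on timestamp spacing uniformity.
SPACING_RTOL = 1e-6


def read_waveform_csv(path: str | Path, channel: str = "") -> Waveform:
    """Read a ``time_s,value`` CSV into a Waveform, inferring fs from spacing.

    Timestamps must be uniformly spaced within a relative tolerance of 1e-6;
    the first row violating this is named in the error. Non-numeric cells
    are rejected by the CSV parser.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_s, value)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two rows to infer sampling rate")
    dt = np.diff(t)
    spacing = dt[0]
    bad = np.flatnonzero(np.abs(dt - spacing) > SPACING_RTOL * max(abs(spacing), 1e-12))
    if len(bad):
        # +2: one for the diff offset, one for the header row (1-based data rows)
        raise ValueError(
            f"{path}: non-uniform timestamp spacing at data row {bad[0] + 2} "
            f"(gap {dt[bad[0]]:.6g} s vs expected {spacing:.6g} s)"
        )
    return Waveform(samples=v, fs=1.0 / spacing, t0=float(t[0]), channel=channel)


def write_waveform_csv(w: Waveform, path: str | Path) -> None:
    """Write a waveform as a ``time_s,value`` CSV (full float precision)."""
    df = pd.DataFrame({"time_s": w.times, "value": w.samples})
    df.to_csv(path, index=False, float_format="%.17g")


def write_crm_csv(series: CRMSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {"time_s": series.times, "crm_percent": series.values, "kind": series.kind}
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_crm_csv(path: str | Path) -> CRMSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    kind = str(df["kind"].iloc[0]) if "kind" in df else "prediction"
    return CRMSeries(
        values=df["crm_percent"].to_numpy(dtype=float),
        t0=float(df["time_s"].iloc[0]),
        kind=kind,
    )


def write_hr_csv(hr: pd.Series, path: str | Path, source: str = "") -> None:
    df = pd.DataFrame({"time_s": hr.index, "bpm": hr.values, "source": source})
    df.to_csv(path, index=False, float_format="%.17g")


def read_hr_csv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, float_precision="round_trip")
    return pd.Series(
        df["bpm"].to_numpy(dtype=float), index=df["time_s"].to_numpy(dtype=float),
        name="hr_bpm",
    )


def protocol_to_dict(protocol: LBNPProtocol) -> dict:
    return {
        "steps": [[p, d] for p, d in protocol.steps],
        "hdd_pressure": protocol.hdd_pressure,
        "stop_time": protocol.stop_time,
    }


def protocol_from_dict(d: dict) -> LBNPProtocol:
    return LBNPProtocol(
        steps=tuple((float(p), float(dur)) for p, dur in d["steps"]),
        hdd_pressure=float(d["hdd_pressure"]),
        stop_time=float(d["stop_time"]),
    )


def write_recording(rec: SubjectRecording, out_dir: str | Path) -> Path:
    """Write one subject's channels, reference series, protocol, and manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    channels = {}
    for site, w in rec.ppg.items():
        fname = f"ppg_{site}.csv"
        write_waveform_csv(w, out / fname)
        channels[site] = {"file": fname, "fs": w.fs}
    write_hr_csv(rec.reference_hr, out / "reference_hr.csv", source="reference")
    write_crm_csv(rec.crm_gt, out / "crm_gt.csv")
    with open(out / "protocol.json", "w") as fh:
        json.dump(protocol_to_dict(rec.protocol), fh, indent=2)
    manifest = {
        "channels": channels,
        "reference_hr": "reference_hr.csv",
        "crm_gt": "crm_gt.csv",
        "protocol": "protocol.json",
        "seed": rec.seed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out / "manifest.json"
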