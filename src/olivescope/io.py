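"""Readers and writers for the pipeline's plain-text and TIFF formats."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .ephys import VoltageTrace
from .events import CalciumEvent
from .photometry import FluorescenceTrace

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_vm_csv",
    "write_vm_csv",
    "events_to_frame",
    "write_tiff",
    "read_tiff",
]


def write_trace_csv(path: str | Path, trace: FluorescenceTrace) -> None:
    """Trace table with columns time_s, value, unit."""
    pd.DataFrame({
        "time_s": trace.times,
        "value": trace.values,
        "unit": trace.unit,
    }).to_csv(path, index=False)


def read_trace_csv(path: str | Path, roi_id: str | int = 0) -> FluorescenceTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "value", "unit"):
        if col not in df.columns:
            raise ValueError(f"trace CSV is missing column {col!r}")
    dt = np.diff(df["time_s"].to_numpy())
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("trace CSV must be uniformly sampled")
    return FluorescenceTrace(df["value"].to_numpy(), frame_rate=1.0 / dt[0],
                             roi_id=roi_id, unit=str(df["unit"].iloc[0]))


def write_vm_csv(path: str | Path, trace: VoltageTrace) -> None:
    times = np.arange(len(trace.values)) / trace.sampling_rate
    pd.DataFrame({"time_s": times, "vm_mV": trace.values}).to_csv(path, index=False)


def read_vm_csv(path: str | Path, cell_id: str | int = 0) -> VoltageTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "vm_mV"):
        if col not in df.columns:
            raise ValueError(f"voltage CSV is missing column {col!r}")
    dt = np.diff(df["time_s"].to_numpy())
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("voltage CSV must be uniformly sampled")
    return VoltageTrace(df["vm_mV"].to_numpy(), sampling_rate=round(1.0 / dt[0]),
                        cell_id=cell_id)


def events_to_frame(events: Sequence[CalciumEvent], frame_rate: float
                    ) -> pd.DataFrame:
    """Events table matching the pipeline's events CSV schema."""
    columns = ["roi_id", "onset_s", "peak_s", "rise_time_ms", "f0_fW",
               "f_peak_fW", "dff_peak", "flags"]
    if not events:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame([{
        "roi_id": ev.roi_id,
        "onset_s": ev.onset_frame / frame_rate,
        "peak_s": ev.peak_frame / frame_rate,
        "rise_time_ms": ev.rise_time_ms,
        "f0_fW": ev.f0,
        "f_peak_fW": ev.f_peak,
        "dff_peak": ev.dff_peak,
        "flags": ";".join(ev.flags),
    } for ev in events])


def write_tiff(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)
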