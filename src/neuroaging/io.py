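"""File formats: 8-bit TIFF sections, binary ROI masks, tidy CSV tables, sweeps.

Section images are written as single-channel 8-bit TIFF with the calibration
kept in the caller's config (TIFF tags are not relied upon); ROI masks are
binary TIFF/PNG images; all tabular data (trial tables, motion traces,
ground truth, results) are CSV with a header row; sweeps are two-column
``time,voltage`` CSV with a JSON sidecar of stimulus annotations.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .behavior import MotionTrace, Phase
from .ephys import StimEvent, Sweep
from .ihc import ROIMask, SectionImage, to_single_channel


def write_section(path, image: SectionImage) -> None:
    data = np.clip(np.round(image.intensity), 0, 255).astype(np.uint8)
    tifffile.imwrite(str(path), data)


def read_section(path, pixel_size: float, stain: str = "GFAP") -> SectionImage:
    arr = tifffile.imread(str(path))
    return SectionImage(intensity=to_single_channel(arr), pixel_size=pixel_size, stain=stain)


def write_roi(path, roi: ROIMask) -> None:
    tifffile.imwrite(str(path), roi.mask.astype(np.uint8) * 255)


def read_roi(path, region: str = "HPF") -> ROIMask:
    arr = tifffile.imread(str(path))
    return ROIMask(mask=np.asarray(arr) > 0, region=region)


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_motion_trace(path, trace: MotionTrace) -> None:
    """Long-format CSV: interval start time, motion index, phase name."""
    starts = np.arange(len(trace.values)) * trace.interval
    phase = np.full(len(trace.values), "", object)
    for ph in trace.phases:
        sel = (starts >= ph.start - 1e-9) & (starts + trace.interval <= ph.end + 1e-9)
        phase[sel] = ph.name
    pd.DataFrame({"start_s": starts, "motion_index": trace.values,
                  "phase": phase}).to_csv(path, index=False)


def read_motion_trace(path, motion_threshold: float = 20.0) -> MotionTrace:
    df = pd.read_csv(path)
    starts = df["start_s"].to_numpy(float)
    interval = float(np.diff(starts).mean()) if len(starts) > 1 else 0.5
    phases = []
    labeled = df.fillna({"phase": ""})
    for name, g in labeled[labeled["phase"] != ""].groupby("phase", sort=False):
        phases.append(Phase(str(name), float(g["start_s"].min()),
                            float(g["start_s"].max()) + interval))
    return MotionTrace(values=df["motion_index"].to_numpy(float), interval=interval,
                       phases=tuple(phases), motion_threshold=motion_threshold)


def write_sweep(path, sweep: Sweep) -> None:
    """Two-column CSV plus a ``<path>.json`` sidecar with the annotations."""
    path = Path(path)
    pd.DataFrame({"time_s": sweep.time, "voltage_mv": sweep.voltage}).to_csv(path, index=False)
    sidecar = {
        "sampling_rate_hz": sweep.sampling_rate,
        "stims": [{"time_s": s.time, "intensity_ma": s.intensity, "pulse": s.pulse}
                  for s in sweep.stims],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_sweep(path) -> Sweep:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    stims = tuple(StimEvent(s["time_s"], s.get("intensity_ma", 0.1), s.get("pulse", 0))
                  for s in meta["stims"])
    return Sweep(time=df["time_s"].to_numpy(), voltage=df["voltage_mv"].to_numpy(),
                 sampling_rate=float(meta["sampling_rate_hz"]), stims=stims)
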