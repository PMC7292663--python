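"""Plain-text and TIFF round-trips for the pipeline's data classes.

Recordings and tracks travel as headered CSV; image fields as multi-channel
TIFF with a JSON sidecar carrying channel names, condition metadata and any
simulation ground truth; plates as tidy CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .ephys import IVRecording
from .imaging import ImageField
from .traces import CellTrack

__all__ = [
    "write_recording", "read_recording",
    "write_tracks", "read_tracks",
    "write_field", "read_field",
    "write_plate", "read_plate",
]


def write_recording(rec: IVRecording, path: str | Path) -> None:
    """CSV columns time_s, voltage_mV, current_pA plus a JSON annotation sidecar."""
    path = Path(path)
    pd.DataFrame(
        {"time_s": rec.time_s, "voltage_mV": rec.voltage_mV, "current_pA": rec.current_pA}
    ).to_csv(path, index=False)
    sidecar = path.with_suffix(".annotations.json")
    sidecar.write_text(json.dumps([[t, lab] for t, lab in rec.annotations]))


def read_recording(path: str | Path) -> IVRecording:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(".annotations.json")
    annotations = []
    if sidecar.exists():
        annotations = [(float(t), str(lab)) for t, lab in json.loads(sidecar.read_text())]
    return IVRecording(
        df["time_s"].to_numpy(), df["voltage_mV"].to_numpy(),
        df["current_pA"].to_numpy(), annotations,
    )


def write_tracks(tracks: list[CellTrack], path: str | Path) -> None:
    """Long-format CSV: cell_id, field_id, condition, time_min, channel, intensity."""
    pd.concat([t.to_frame() for t in tracks], ignore_index=True).to_csv(path, index=False)


def read_tracks(path: str | Path) -> list[CellTrack]:
    df = pd.read_csv(path)
    out: list[CellTrack] = []
    for (cell, fld, cond), grp in df.groupby(["cell_id", "field_id", "condition"], sort=False):
        channels = {}
        time_min = None
        for ch, sub in grp.groupby("channel", sort=False):
            sub = sub.sort_values("time_min")
            channels[ch] = sub["intensity"].to_numpy()
            time_min = sub["time_min"].to_numpy()
        out.append(CellTrack(str(cell), str(fld), str(cond), time_min, channels))
    return out


def write_field(fld: ImageField, path: str | Path) -> None:
    """Multi-channel TIFF (channel axis first) with a JSON metadata sidecar."""
    path = Path(path)
    names = sorted(fld.channels)
    stack = np.stack([fld.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack", planarconfig="separate")
    meta = {
        "channels": names,
        "pixel_size_um": fld.pixel_size_um,
        "condition": fld.condition,
        "transfected": fld.transfected,
        "metadata": fld.metadata,
        "ground_truth": None
        if fld.ground_truth is None
        else fld.ground_truth.to_dict(orient="list"),
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def read_field(path: str | Path) -> ImageField:
    path = Path(path)
    stack = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    channels = {name: stack[i] for i, name in enumerate(meta["channels"])}
    gt = meta.get("ground_truth")
    return ImageField(
        channels=channels,
        pixel_size_um=meta["pixel_size_um"],
        condition=meta["condition"],
        transfected=meta["transfected"],
        metadata=meta.get("metadata", {}),
        ground_truth=None if gt is None else pd.DataFrame(gt),
    )


def write_plate(plate: pd.DataFrame, path: str | Path) -> None:
    plate.to_csv(path, index=False)


def read_plate(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
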