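"""Plain-text container IO for recordings and ground truth.

A recording is stored as ``<stem>.csv`` (samples x channels, header =
channel names, microvolts) plus a JSON sidecar ``<stem>.json`` with the
sampling rate, montage name and metadata.  Ground truth goes to
``<stem>.truth.json`` plus a per-sample label CSV.  EDF export is not
supported in this build (no EDF library is available offline); the
container round-trips losslessly to float precision instead.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import make_layout
from .preprocess import Recording
from .synth import GroundTruth

__all__ = ["write_recording", "read_recording", "write_ground_truth", "read_labels"]

_FLOAT_FMT = "%.10e"


def write_recording(rec: Recording, out_dir: str | Path, stem: str) -> Path:
    """Write ``<stem>.csv`` + ``<stem>.json`` under ``out_dir``; returns the CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    header = ",".join(rec.layout.names)
    np.savetxt(csv_path, rec.data, fmt=_FLOAT_FMT, delimiter=",",
               header=header, comments="")
    sidecar = {
        "fs": rec.fs,
        "channel_names": list(rec.layout.names),
        "montage_name": rec.layout.montage_name,
        "meta": rec.meta,
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_recording(path: str | Path) -> Recording:
    """Read a container recording from its CSV (or stem) path."""
    path = Path(path)
    if path.suffix == ".json":
        path = path.with_suffix(".csv")
    elif path.suffix != ".csv":
        path = path.with_name(path.name + ".csv")
    sidecar_path = path.with_suffix(".json")
    if not path.exists():
        raise FileNotFoundError(path)
    if not sidecar_path.exists():
        raise ValueError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("fs", "channel_names"):
        if key not in sidecar:
            raise ValueError(f"sidecar missing required key {key!r}")
    frame = pd.read_csv(path)
    layout = make_layout()
    if list(frame.columns) != list(layout.names) or list(
        sidecar["channel_names"]
    ) != list(layout.names):
        raise ValueError("channel names do not match the 31-channel montage")
    return Recording(
        data=frame.to_numpy(dtype=float),
        fs=float(sidecar["fs"]),
        layout=layout,
        meta=dict(sidecar.get("meta", {})),
    )


def write_ground_truth(gt: GroundTruth, out_dir: str | Path, stem: str) -> Path:
    """Write planted parameters as JSON plus a per-sample label CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "transition_matrix": gt.transition_matrix.tolist(),
        "mean_durations_ms": gt.mean_durations_ms.tolist(),
        "coverage": gt.coverage.tolist(),
        "band_gain": gt.band_gain,
        "class_labels": list(gt.templates.labels),
    }
    json_path = out_dir / f"{stem}.truth.json"
    json_path.write_text(json.dumps(payload, indent=1))
    pd.DataFrame({"label": gt.label_sequence}).to_csv(
        out_dir / f"{stem}.labels.csv", index=False
    )
    return json_path


def read_labels(path: str | Path) -> np.ndarray:
    return pd.read_csv(path)["label"].to_numpy(dtype=int)
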