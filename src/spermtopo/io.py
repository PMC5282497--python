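"""Standard-format I/O: TIFF z-stacks, spot tables and ground-truth tables.

Images are written as multi-page TIFF stacks (one file per channel per cell)
with voxel sizes in a JSON sidecar.  Tabular data is plain CSV with fixed,
documented columns:

* signal tables: ``cell_id, channel, x, y, z, voxels, peak, rendered``
  (plus optional per-cell landmark columns ``tail_x, tail_y[, tail_z],
  head_x, head_y[, head_z]`` for the 2D mode where only centroids and
  manually measured landmarks exist);
* ground-truth tables: ``cell_id, channel, x, y, z, cluster_id,
  radial_region, longitudinal_region, renderable``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from .synthetic import FISH_CHANNELS, GroundTruthSpot
from .types import FishSignal, VoxelImage

KNOWN_CHANNELS = set(FISH_CHANNELS) | {"dapi"}

SIGNAL_COLUMNS = ["cell_id", "channel", "x", "y", "z", "voxels", "peak", "rendered"]
LANDMARK_COLUMNS = ["tail_x", "tail_y", "tail_z", "head_x", "head_y", "head_z"]


def save_stack(image: VoxelImage, path) -> None:
    """Write an intensity stack as TIFF with a JSON voxel-size sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image.data, dtype=np.float32))
    sidecar = {
        "voxel_size_um": list(image.voxel_size),
        "channel": image.channel,
        "axes": "ZYX" if image.data.ndim == 3 else "YX",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_stack(path) -> VoxelImage:
    """Read a TIFF stack written by :func:`save_stack` (sidecar required)."""
    path = Path(path)
    data = tifffile.imread(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing voxel-size sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    return VoxelImage(data, tuple(meta["voxel_size_um"]), channel=meta.get("channel", ""))


def signals_to_frame(
    signals: Iterable[FishSignal], cell_id: str = ""
) -> pd.DataFrame:
    rows = []
    for s in signals:
        c = s.centroid
        rows.append(
            {
                "cell_id": cell_id,
                "channel": s.channel,
                "x": c[0],
                "y": c[1],
                "z": c[2] if len(c) > 2 else np.nan,
                "voxels": s.voxel_count,
                "peak": s.peak_intensity,
                "rendered": bool(s.rendered),
            }
        )
    return pd.DataFrame(rows, columns=SIGNAL_COLUMNS)


def write_spot_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_spot_table(path) -> Dict[str, dict]:
    """Read a signal table, validated, grouped by cell.

    Returns ``{cell_id: {"signals": [FishSignal, ...], "landmarks": {...} | None}}``.
    Raises on missing required columns (naming the column), unknown channels,
    and malformed (non-numeric) rows (naming the file row).
    """
    frame = pd.read_csv(path)
    required = ["cell_id", "channel", "x", "y"]
    for col in required:
        if col not in frame.columns:
            raise ValueError(f"spot table {path} is missing required column '{col}'")
    if len(frame) == 0:
        return {}

    unknown = set(frame["channel"].unique()) - KNOWN_CHANNELS
    if unknown:
        raise ValueError(f"unknown channels in {path}: {sorted(unknown)}")

    has_z = "z" in frame.columns and frame["z"].notna().any()
    numeric_cols = ["x", "y"] + (["z"] if has_z else [])
    for col in numeric_cols:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            # +2: header line plus 1-based file rows
            raise ValueError(
                f"malformed value in column '{col}' at file row {int(bad[0]) + 2}"
            )
        frame[col] = coerced

    landmark_cols = [c for c in LANDMARK_COLUMNS if c in frame.columns]
    out: Dict[str, dict] = {}
    for cell_id, grp in frame.groupby("cell_id", sort=True):
        signals = []
        for _, row in grp.iterrows():
            centroid = (
                [row["x"], row["y"], row["z"]] if has_z else [row["x"], row["y"]]
            )
            rendered = bool(row["rendered"]) if "rendered" in frame.columns else True
            signals.append(
                FishSignal(
                    channel=row["channel"],
                    centroid=centroid,
                    voxel_count=int(row.get("voxels", 1) or (1 if rendered else 0)),
                    peak_intensity=float(row.get("peak", 0.0) or 0.0),
                    rendered=rendered,
                )
            )
        landmarks = None
        if landmark_cols:
            first = grp.iloc[0]
            tail = [first[c] for c in landmark_cols if c.startswith("tail")]
            head = [first[c] for c in landmark_cols if c.startswith("head")]
            landmarks = {
                "tail_point": np.asarray(tail, dtype=float),
                "head_point": np.asarray(head, dtype=float),
            }
        out[str(cell_id)] = {"signals": signals, "landmarks": landmarks}
    return out


def ground_truth_to_frame(spots: Iterable[GroundTruthSpot]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": s.cell_id,
            "channel": s.channel,
            "x": s.position[0],
            "y": s.position[1],
            "z": s.position[2],
            "cluster_id": s.cluster_id,
            "radial_region": s.radial_region,
            "longitudinal_region": s.longitudinal_region,
            "renderable": bool(s.renderable),
        }
        for s in spots
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "channel",
            "x",
            "y",
            "z",
            "cluster_id",
            "radial_region",
            "longitudinal_region",
            "renderable",
        ],
    )
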