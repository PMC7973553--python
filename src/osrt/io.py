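"""File interfaces: task definitions, stream tables, gaze and event tables.

Task definitions are YAML (sequences as 12-digit strings, start offsets,
group kind); streams export as two-column TSV (trial, location) with a
block-boundary sidecar column. Raw gaze tables arrive in screen pixels and
are converted here to cm relative to screen center with y increasing
upward, using the screen geometry (defaults: 1680x1050 px, 47x29 cm,
60 cm viewing distance).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .task import (FS_START_OFFSETS, SEQUENCE_A, SEQUENCE_B, StimulusStream,
                   build_fs_stream)
from .rsgen import generate_rs_stream

__all__ = ["ScreenGeometry", "TaskDefinition", "load_task", "save_task",
           "stream_from_task", "write_stream", "read_stream",
           "read_gaze", "read_events"]


@dataclass(frozen=True)
class ScreenGeometry:
    """Display geometry for pixel -> centered-cm conversion."""

    resolution: tuple[int, int] = (1680, 1050)
    size_cm: tuple[float, float] = (47.0, 29.0)
    viewing_distance_cm: float = 60.0

    def px_to_cm(self, x_px, y_px) -> tuple[np.ndarray, np.ndarray]:
        """Convert pixel coordinates (origin top-left, y down) to cm relative
        to screen center with y increasing upward."""
        rx, ry = self.resolution
        sx, sy = self.size_cm
        x = (np.asarray(x_px, dtype=float) - rx / 2.0) * (sx / rx)
        y = (ry / 2.0 - np.asarray(y_px, dtype=float)) * (sy / ry)
        return x, y


@dataclass(frozen=True)
class TaskDefinition:
    group: str                      # "FS" | "RS"
    main: tuple[int, ...] = SEQUENCE_A
    interference: tuple[int, ...] = SEQUENCE_B
    start_offsets: tuple[int, ...] = FS_START_OFFSETS
    n_blocks: int = 8
    block_len: int = 108
    rs_seed: int | None = None


def _digits(s) -> tuple[int, ...]:
    if isinstance(s, str):
        return tuple(int(ch) for ch in s if ch.isdigit())
    return tuple(int(x) for x in s)


def load_task(path: str | Path) -> TaskDefinition:
    raw = yaml.safe_load(Path(path).read_text())
    return TaskDefinition(
        group=str(raw["group"]).upper(),
        main=_digits(raw.get("main", "342312143241")),
        interference=_digits(raw.get("interference", "341243142132")),
        start_offsets=tuple(raw.get("start_offsets", FS_START_OFFSETS)),
        n_blocks=int(raw.get("n_blocks", 8)),
        block_len=int(raw.get("block_len", 108)),
        rs_seed=raw.get("rs_seed"),
    )


def save_task(task: TaskDefinition, path: str | Path) -> None:
    doc = {
        "group": task.group,
        "main": "".join(map(str, task.main)),
        "interference": "".join(map(str, task.interference)),
        "start_offsets": list(task.start_offsets),
        "n_blocks": task.n_blocks,
        "block_len": task.block_len,
    }
    if task.rs_seed is not None:
        doc["rs_seed"] = task.rs_seed
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def stream_from_task(task: TaskDefinition) -> StimulusStream:
    if task.group == "FS":
        return build_fs_stream(task.main, task.interference, task.start_offsets)
    return generate_rs_stream(n_blocks=task.n_blocks, block_len=task.block_len,
                              seed=task.rs_seed)


def write_stream(stream: StimulusStream, path: str | Path) -> None:
    df = pd.DataFrame({
        "trial": np.arange(1, len(stream.targets) + 1),
        "location": stream.targets,
        "block": stream.block_index,
        "block_start": stream.boundary_flags.astype(int),
    })
    df.to_csv(path, sep="\t", index=False)


def read_stream(path: str | Path,
                block_labels: tuple[str, ...] | None = None) -> StimulusStream:
    df = pd.read_csv(path, sep="\t")
    n_blocks = int(df["block"].max())
    if block_labels is None:
        block_labels = ("main",) * n_blocks
    return StimulusStream(targets=df["location"].to_numpy(),
                          block_index=df["block"].to_numpy(),
                          block_labels=block_labels)


def read_gaze(path: str | Path,
              geometry: ScreenGeometry | None = None) -> pd.DataFrame:
    """Read a delimited gaze table (participant, time_ms, x_px, y_px) and
    convert to centered cm."""
    if geometry is None:
        geometry = ScreenGeometry()
    df = pd.read_csv(path, sep="\t")
    x, y = geometry.px_to_cm(df["x_px"], df["y_px"])
    return pd.DataFrame({"participant": df["participant"],
                         "time_ms": df["time_ms"], "x": x, "y": y})


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a delimited trial-event table (participant, block, trial,
    target_loc, onset_ms, offset_ms, key, key_time_ms)."""
    return pd.read_csv(path, sep="\t")
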