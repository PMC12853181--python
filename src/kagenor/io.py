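"""File formats: DeepLabCut-style and tidy keypoint CSV, label CSV,
schedule YAML/JSON, and metadata-stamped report tables.

CSV dialect: comma, UTF-8, '.' decimal; report files carry '#'-prefixed
metadata header lines (config, seed, package version) so every output is
traceable; no timestamps, so reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    ExplorationSeries,
    KeypointTrack,
    PhaseSchedule,
    TrackFormatError,
)
from .synthetic import CorridorVisit

__all__ = [
    "write_keypoints_dlc",
    "write_keypoints_tidy",
    "read_keypoints",
    "write_labels",
    "read_labels",
    "write_schedule",
    "read_schedule",
    "write_visits",
    "read_visits",
    "write_report",
    "read_report",
]

DLC_SCORER = "kagenor"


def write_keypoints_dlc(track: KeypointTrack, path: str | Path) -> None:
    """Write a track as DeepLabCut-style CSV (scorer/bodyparts/coords
    header rows, frame index in the first column)."""
    df = track.data.copy()
    df.columns = pd.MultiIndex.from_tuples(
        [(DLC_SCORER, bp, coord) for bp, coord in df.columns],
        names=["scorer", "bodyparts", "coords"],
    )
    df.to_csv(path, index_label=None)


def write_keypoints_tidy(track: KeypointTrack, path: str | Path) -> None:
    """Write a track as tidy CSV (frame, time_s, bodypart, x, y, likelihood)."""
    rows = []
    time_s = track.time_s
    for part in track.bodyparts:
        xy = track.xy(part)
        lik = track.likelihood(part)
        rows.append(
            pd.DataFrame(
                {
                    "frame": np.arange(track.n_frames),
                    "time_s": time_s,
                    "bodypart": part,
                    "x": xy[:, 0],
                    "y": xy[:, 1],
                    "likelihood": lik,
                }
            )
        )
    # stable sort by frame only, preserving the track's bodypart order
    pd.concat(rows).sort_values("frame", kind="stable").to_csv(path, index=False)


def _validate_frame_spacing(frames: np.ndarray, fill_gaps: bool) -> None:
    if frames.size > 1:
        diffs = np.diff(frames)
        if np.any(diffs <= 0):
            raise TrackFormatError("nonmonotone frame order / time")
        if np.any(diffs > 1) and not fill_gaps:
            raise TrackFormatError(
                f"frame gaps > 1 at {int(frames[np.argmax(diffs > 1)])} (pass fill_gaps=True to forward-fill)"
            )


def read_keypoints(
    path: str | Path,
    dialect: str = "dlc_csv",
    frame_rate: float = 2.0,
    fill_gaps: bool = False,
) -> KeypointTrack:
    """Read a keypoint track; enforces a constant frame period and either
    rejects or forward-fills frame gaps."""
    if dialect == "dlc_csv":
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        if df.columns.nlevels != 3:
            raise TrackFormatError("malformed DLC header: expected 3 header rows")
        df.columns = pd.MultiIndex.from_tuples(
            [(bp, coord) for _, bp, coord in df.columns], names=["bodyparts", "coords"]
        )
        frames = df.index.to_numpy(dtype=np.int64)
        _validate_frame_spacing(frames, fill_gaps)
        if fill_gaps and frames.size:
            df = df.reindex(np.arange(frames[0], frames[-1] + 1)).ffill()
        return KeypointTrack(data=df.reset_index(drop=True), frame_rate=frame_rate)
    if dialect == "tidy_csv":
        tidy = pd.read_csv(path)
        required = {"frame", "bodypart", "x", "y", "likelihood"}
        missing = required - set(tidy.columns)
        if missing:
            raise TrackFormatError(f"tidy keypoints missing column(s): {', '.join(sorted(missing))}")
        frames = np.unique(tidy["frame"].to_numpy(dtype=np.int64))
        order = tidy[tidy["frame"] == frames[0]]["bodypart"].tolist()
        _validate_frame_spacing(frames, fill_gaps)
        wide = tidy.pivot_table(
            index="frame", columns="bodypart", values=["x", "y", "likelihood"], sort=True
        )
        wide = wide.swaplevel(axis=1)
        if fill_gaps:
            wide = wide.reindex(np.arange(frames[0], frames[-1] + 1)).ffill()
        parts = [p for p in order if p in wide.columns.get_level_values(0)]
        cols = pd.MultiIndex.from_product([parts, ["x", "y", "likelihood"]])
        df = wide.reindex(columns=cols)
        df.columns = df.columns.set_names(["bodyparts", "coords"])
        return KeypointTrack(data=df.reset_index(drop=True), frame_rate=frame_rate)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_labels(series: ExplorationSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_labels(path: str | Path, frame_rate: float = 2.0) -> ExplorationSeries:
    df = pd.read_csv(path)
    for col in ("frame", "explore_left", "explore_right"):
        if col not in df.columns:
            raise TrackFormatError(f"labels file missing column {col!r}")
    left = df["explore_left"].to_numpy().astype(bool)
    right = df["explore_right"].to_numpy().astype(bool)
    if np.any(left & right):
        bad = int(df["frame"].to_numpy()[np.argmax(left & right)])
        raise ValueError(f"labels true on both sides at frame {bad}")
    return ExplorationSeries(left, right, frame_rate=frame_rate)


def write_schedule(schedule: PhaseSchedule, path: str | Path) -> None:
    path = Path(path)
    d = schedule.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def read_schedule(path: str | Path) -> PhaseSchedule:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return PhaseSchedule.from_dict(d)


def write_visits(visits: list[CorridorVisit], path: str | Path) -> None:
    pd.DataFrame(
        [{"side": v.side, "start_s": v.start_s, "end_s": v.end_s} for v in visits],
        columns=["side", "start_s", "end_s"],
    ).to_csv(path, index=False)


def read_visits(path: str | Path) -> list[CorridorVisit]:
    df = pd.read_csv(path)
    return [
        CorridorVisit(r.side, float(r.start_s), float(r.end_s)) for r in df.itertuples()
    ]


def write_report(
    df: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None
) -> None:
    """Write a tidy report CSV with '#'-prefixed metadata header lines."""
    path = Path(path)
    lines = [f"# kagenor_version: {__version__}"]
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}: {value}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


def read_report(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition(":")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, meta
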