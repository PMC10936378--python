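"""Readers and writers for the plain-text interchange formats.

* stream CSV: ``t,L1..L6,R1..R6`` — one bilateral binary frame per row,
  ``t`` in seconds with 6 decimals;
* episode TSV: ``phase,foot,start_s,end_s,duration_s,truncated``;
* FoG event TSV: ``kind,start_s,end_s,onset_s``;
* truth TSV: ``start_s,end_s,kind``;
* calibration profile / detection thresholds: JSON with the canonical field
  names.

All writers emit files their paired readers accept losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .detect import CalibrationProfile, DetectionThresholds, FogEvent, EVENT_KINDS
from .errors import FormatError
from .events import PhaseEpisode
from .signals import InsoleStream
from .simulate import TruthLabels

PathLike = Union[str, Path]

_STREAM_COLUMNS = ["t"] + [f"L{i}" for i in range(1, 7)] + [f"R{i}" for i in range(1, 7)]


def write_stream(left: InsoleStream, right: InsoleStream, path: PathLike) -> None:
    """Write aligned bilateral streams to the stream CSV dialect."""
    if len(left) != len(right) or left.sampling_rate != right.sampling_rate:
        raise FormatError("left/right streams must be aligned to share one file")
    data = {"t": [f"{t:.6f}" for t in left.times()]}
    for i in range(6):
        data[f"L{i + 1}"] = left.frames[:, i]
    for i in range(6):
        data[f"R{i + 1}"] = right.frames[:, i]
    pd.DataFrame(data).to_csv(path, index=False)


def read_stream(
    path: PathLike, sampling_rate: float = 32.0
) -> tuple[InsoleStream, InsoleStream]:
    """Read the stream CSV dialect back into aligned left/right streams.

    Validates the header, that all sensor values are 0/1, and that ``t`` is
    strictly increasing with 1/sampling_rate spacing (tolerance 1e-6 s).
    """
    df = pd.read_csv(path)
    if list(df.columns) != _STREAM_COLUMNS:
        raise FormatError(
            f"{path}: malformed header {list(df.columns)}; expected {_STREAM_COLUMNS}"
        )
    if len(df) < 1:
        raise FormatError(f"{path}: stream file has no samples")
    bits = df[_STREAM_COLUMNS[1:]].to_numpy()
    bad = np.argwhere(~np.isin(bits, (0, 1)))
    if bad.size:
        row, col = bad[0]
        raise FormatError(
            f"{path}: non-binary value {bits[row, col]!r} in column "
            f"{_STREAM_COLUMNS[1 + col]} at data row {row + 1}"
        )
    t = df["t"].to_numpy(dtype=float)
    dt = 1.0 / sampling_rate
    gaps = np.diff(t)
    irregular = np.argwhere(np.abs(gaps - dt) > 1e-6)
    if irregular.size:
        row = int(irregular[0][0])
        raise FormatError(
            f"{path}: irregular sample spacing {gaps[row]:.6f} s at data row "
            f"{row + 2} (expected {dt:.6f} s)"
        )
    left = InsoleStream("left", sampling_rate, bits[:, :6].astype(np.uint8), t0=float(t[0]))
    right = InsoleStream("right", sampling_rate, bits[:, 6:].astype(np.uint8), t0=float(t[0]))
    return left, right


def write_episodes(episodes: Sequence[PhaseEpisode], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "phase": ep.phase,
                "foot": ep.foot,
                "start_s": round(ep.start_s, 6),
                "end_s": round(ep.end_s, 6),
                "duration_s": round(ep.duration, 6),
                "truncated": int(ep.truncated),
            }
            for ep in episodes
        ],
        columns=["phase", "foot", "start_s", "end_s", "duration_s", "truncated"],
    ).to_csv(path, sep="\t", index=False)


def write_events(events: Sequence[FogEvent], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "kind": ev.kind,
                "start_s": round(ev.start_s, 6),
                "end_s": round(ev.end_s, 6),
                "onset_s": round(ev.onset_s, 6),
            }
            for ev in events
        ],
        columns=["kind", "start_s", "end_s", "onset_s"],
    ).to_csv(path, sep="\t", index=False)


def read_events(path: PathLike) -> list[FogEvent]:
    df = pd.read_csv(path, sep="\t")
    expected = ["kind", "start_s", "end_s", "onset_s"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: malformed header; expected {expected}")
    return [
        FogEvent(kind=row.kind, start_s=row.start_s, end_s=row.end_s, onset_s=row.onset_s)
        for row in df.itertuples()
    ]


def write_truth(truth: TruthLabels, path: PathLike) -> None:
    pd.DataFrame(
        [
            {"start_s": round(s, 6), "end_s": round(e, 6), "kind": k}
            for s, e, k in truth
        ],
        columns=["start_s", "end_s", "kind"],
    ).to_csv(path, sep="\t", index=False)


def read_truth(path: PathLike) -> TruthLabels:
    """Read truth TSV; rows are sorted and validated (no overlaps)."""
    df = pd.read_csv(path, sep="\t")
    expected = ["start_s", "end_s", "kind"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: malformed header; expected {expected}")
    for i, kind in enumerate(df["kind"]):
        if kind not in EVENT_KINDS:
            raise FormatError(
                f"{path}: unknown kind {kind!r} at data row {i + 1}; expected one of {EVENT_KINDS}"
            )
    return TruthLabels(tuple(df.itertuples(index=False, name=None)))


def write_profile(profile: CalibrationProfile, path: PathLike) -> None:
    Path(path).write_text(profile.to_json() + "\n")


def read_profile(path: PathLike) -> CalibrationProfile:
    return CalibrationProfile.from_json(Path(path).read_text())


def write_thresholds(thresholds: DetectionThresholds, path: PathLike) -> None:
    Path(path).write_text(thresholds.to_json() + "\n")


def read_thresholds(path: PathLike) -> DetectionThresholds:
    return DetectionThresholds.from_json(Path(path).read_text())


def write_metrics_report(report: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
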