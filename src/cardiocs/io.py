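"""Delimited-text persistence for signals and fiducial tables.

Signal format: a header line ``fs,<Hz>`` followed by one sample per line;
lines starting with ``#`` are comments (the writer stores subject/kind
there); both Unix and Windows line endings are accepted.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError
from .fiducials import FiducialSet
from .signal import Signal


def write_signal(signal: Signal, path) -> None:
    lines = [f"# kind,{signal.kind}"]
    if signal.subject_id is not None:
        lines.append(f"# subject_id,{signal.subject_id}")
    lines.append(f"fs,{signal.fs:.17g}")
    lines.extend(f"{v:.17g}" for v in signal.samples)
    Path(path).write_text("\n".join(lines) + "\n")


def read_signal(path) -> Signal:
    path = Path(path)
    fs = None
    kind, subject_id = "generic", None
    samples = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ").strip()
            if body.startswith("kind,"):
                kind = body.split(",", 1)[1].strip()
            elif body.startswith("subject_id,"):
                subject_id = body.split(",", 1)[1].strip()
            continue
        if fs is None:
            if not line.lower().startswith("fs,"):
                raise FormatError(f"{path}:{lineno}: expected 'fs,<Hz>' header, got {line!r}")
            try:
                fs = float(line.split(",", 1)[1])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: bad fs header {line!r}") from exc
            continue
        try:
            samples.append(float(line))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: not a number: {line!r}") from exc
    if fs is None:
        raise FormatError(f"{path}: missing 'fs,<Hz>' header")
    if not samples:
        raise FormatError(f"{path}: no samples")
    return Signal(np.array(samples), fs, subject_id=subject_id, kind=kind)


def write_fiducials(fiducials: FiducialSet, path) -> None:
    """Two-column name,index file; per-beat names suffixed with the beat number."""
    lines = [f"# kind,{fiducials.kind}", f"# fs,{fiducials.fs:.17g}"]
    for b, beat in enumerate(fiducials.beats):
        for name, idx in beat.items():
            lines.append(f"{name}.{b},{idx}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fiducials(path) -> FiducialSet:
    path = Path(path)
    kind, fs = "ecg", 500.0
    beats: dict[int, dict[str, int]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ").strip()
            if body.startswith("kind,"):
                kind = body.split(",", 1)[1].strip()
            elif body.startswith("fs,"):
                fs = float(body.split(",", 1)[1])
            continue
        try:
            name, idx = line.split(",")
            point, beat_no = name.rsplit(".", 1)
            beats.setdefault(int(beat_no), {})[point] = int(idx)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad fiducial line {line!r}") from exc
    return FiducialSet(beats=[beats[b] for b in sorted(beats)], fs=fs, kind=kind)
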