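"""File formats: plain-text event trains, CSV tables, JSON scalars.

Train files are whitespace-separated text, one event per line::

    # comment
    -1.0  1.0      (time [u.t.], amplitude)
    0.0   1.0

The amplitude column may be omitted (default 1).  Tables are RFC-4180 CSV
preceded by '#'-commented metadata lines (resolved configuration and seed),
so every output is reproducible from the file alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .models import ParameterError, SpikeTrain

__all__ = [
    "read_train_file",
    "write_train_file",
    "write_table",
    "read_table",
    "write_json",
]


class TrainParseError(ValueError):
    """Malformed train file (the message names the offending line)."""


def read_train_file(path) -> SpikeTrain:
    """Parse a plain-text event-train file into a :class:`SpikeTrain`."""
    path = Path(path)
    times: list[float] = []
    amps: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) not in (1, 2):
                raise TrainParseError(f"{path}:{lineno}: expected 'time [amplitude]', got {raw!r}")
            try:
                t = float(fields[0])
                a = float(fields[1]) if len(fields) == 2 else 1.0
            except ValueError as exc:
                raise TrainParseError(f"{path}:{lineno}: {exc}") from exc
            if not (np.isfinite(t) and np.isfinite(a)):
                raise TrainParseError(f"{path}:{lineno}: non-finite value")
            times.append(t)
            amps.append(a)
    if not times:
        raise TrainParseError(f"{path}: no events")
    try:
        return SpikeTrain(times, amps)
    except ParameterError as exc:
        raise TrainParseError(f"{path}: {exc}") from exc


def write_train_file(path, train: SpikeTrain, header: str | None = None) -> None:
    """Write a train at full double precision (lossless round trip)."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for t, a in zip(train.times, train.amplitudes):
            fh.write(f"{float(t)!r} {float(a)!r}\n")


def _metadata_lines(metadata: Mapping) -> list[str]:
    return [f"# {key}: {json.dumps(value, default=str)}" for key, value in metadata.items()]


def write_table(path, frame: pd.DataFrame, metadata: Mapping | None = None) -> None:
    """Write a CSV table with a '#'-commented metadata header."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        if metadata:
            fh.write("\n".join(_metadata_lines(metadata)) + "\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    """Read a CSV table written by :func:`write_table` (metadata lines skipped)."""
    return pd.read_csv(path, comment="#")


def write_json(path, payload: Mapping, metadata: Mapping | None = None) -> None:
    """Write scalars plus metadata as a single JSON object."""
    doc = dict(payload)
    if metadata:
        doc["metadata"] = dict(metadata)

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return str(obj)

    Path(path).write_text(json.dumps(doc, indent=2, default=default) + "\n")
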