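"""Plain-text marker-trajectory I/O.

One recording per CSV file with a mandatory header row::

    frame,time,FNR_x,FNR_y,FNR_z,LEPR_x,...

``frame`` is the 0-based frame index, ``time = frame * T`` (redundant, kept
for human inspection), and each marker contributes three ``<name>_{x,y,z}``
columns in declared order.  Values are written with fixed 6-decimal
formatting so write -> read -> write is byte-identical.  Cohort metadata is
a separate CSV table (one row per recording file) so fixtures stay small
and diffable.

Native motion-capture exports (C3D/TAK) are out of scope; convert to this
dialect externally.
"""

from __future__ import annotations

import csv
import os
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidArgumentError
from .recording import Recording, RecordingMeta

_META_COLUMNS = ["participant_id", "group", "limb", "role", "activity", "file"]


def write_recording(rec: Recording, path: str | os.PathLike) -> None:
    """Write one recording to ``path`` in the package CSV dialect."""
    if not rec.markers:
        raise FormatError("refusing to write a recording with no markers")
    names = list(rec.markers)
    header = ["frame", "time"]
    for name in names:
        header += [f"{name}_x", f"{name}_y", f"{name}_z"]
    n = rec.n_samples
    t = rec.sample_interval
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for k in range(n):
            row = [str(k), f"{k * t:.6f}"]
            for name in names:
                row += [f"{v:.6f}" for v in rec.markers[name][k]]
            writer.writerow(row)


def read_recording(path: str | os.PathLike, meta: Optional[RecordingMeta] = None) -> Recording:
    """Read a recording written by :func:`write_recording`.

    The sampling interval is recovered from the ``time`` column.  Raises
    :class:`FormatError` (with the offending 1-based line number where
    applicable) for missing columns, ragged rows, non-numeric or NaN cells,
    or a non-positive sampling interval.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        rows = list(reader)

    if len(header) < 5 or header[:2] != ["frame", "time"]:
        raise FormatError(f"{path}: header must start with 'frame,time' plus marker columns")
    marker_cols = header[2:]
    if len(marker_cols) % 3:
        raise FormatError(f"{path}: marker columns not a multiple of 3")
    names = []
    for i in range(0, len(marker_cols), 3):
        triple = marker_cols[i : i + 3]
        bases = {c.rsplit("_", 1)[0] for c in triple}
        suffixes = [c.rsplit("_", 1)[1] for c in triple]
        if len(bases) != 1 or suffixes != ["x", "y", "z"]:
            raise FormatError(f"{path}: malformed marker column triple {triple}")
        names.append(bases.pop())

    if len(rows) < 2:
        raise FormatError(f"{path}: need at least 2 frames, got {len(rows)}")

    data = np.empty((len(rows), len(header) - 1))
    for r, row in enumerate(rows):
        line_no = r + 2  # 1-based, after the header line
        if len(row) != len(header):
            raise FormatError(f"{path}, line {line_no}: expected {len(header)} fields, got {len(row)}")
        try:
            values = [float(v) for v in row[1:]]
        except ValueError:
            raise FormatError(f"{path}, line {line_no}: non-numeric cell") from None
        if not np.all(np.isfinite(values)):
            raise FormatError(f"{path}, line {line_no}: NaN or infinite cell")
        data[r] = values

    times = data[:, 0]
    t = times[1] - times[0]
    if t <= 0:
        raise FormatError(f"{path}: non-positive sample interval {t}")

    markers = {
        name: data[:, 1 + 3 * i : 4 + 3 * i].copy() for i, name in enumerate(names)
    }
    try:
        return Recording(markers, float(round(t, 9)), meta or RecordingMeta())
    except InvalidArgumentError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_cohort_metadata(metadata: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the cohort metadata table (one row per recording file)."""
    missing = [c for c in _META_COLUMNS if c not in metadata.columns]
    if missing:
        raise InvalidArgumentError(f"metadata table missing columns: {missing}")
    metadata[_META_COLUMNS].to_csv(path, index=False)


def read_cohort_metadata(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata table missing columns: {missing}")
    return df


def write_cohort(recordings: Iterable[Recording], metadata: pd.DataFrame, out_dir: str | os.PathLike) -> None:
    """Write every recording plus the metadata table under ``out_dir``.

    The metadata table must carry a ``file`` column with the per-recording
    file names (relative to ``out_dir``).
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    files = list(metadata["file"])
    recordings = list(recordings)
    if len(files) != len(recordings):
        raise InvalidArgumentError(
            f"{len(recordings)} recordings but {len(files)} metadata rows"
        )
    for rec, fname in zip(recordings, files):
        write_recording(rec, os.path.join(out_dir, fname))
    write_cohort_metadata(metadata, os.path.join(out_dir, "cohort.csv"))
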