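"""Reading and writing paired-observation CSV files, fixtures, manifests.

The on-disk format is a two-column comma-separated file with a header row
naming ``x`` and ``y`` (any column order, extra columns ignored), dot
decimal separator, UTF-8.  Scientific notation is accepted on read; plain
full-precision decimals are written, so a write/read round trip is lossless.
"""

from __future__ import annotations

import csv
import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import TextIO

import numpy as np

from ._exceptions import ValidationError
from .core import XYDataSet

__all__ = [
    "read_xy_csv",
    "write_xy_csv",
    "load_worked_example",
    "RunManifest",
]


def _parse_xy_rows(reader: csv.reader, source: str) -> XYDataSet:
    try:
        header = next(reader)
    except StopIteration:
        raise ValidationError(f"{source}: file is empty") from None
    cols = [h.strip().lower() for h in header]
    try:
        ix, iy = cols.index("x"), cols.index("y")
    except ValueError:
        raise ValidationError(
            f"{source}: header must name columns 'x' and 'y', got {header!r}"
        ) from None
    xs, ys = [], []
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            xs.append(float(row[ix]))
            ys.append(float(row[iy]))
        except (ValueError, IndexError):
            raise ValidationError(
                f"{source}, line {lineno}: could not parse numeric x,y from {row!r}"
            ) from None
    if len(xs) < 2:
        raise ValidationError(
            f"{source}: at least 2 observations are required, found {len(xs)}"
        )
    return XYDataSet(np.array(xs), np.array(ys))


def read_xy_csv(path_or_file: str | Path | TextIO) -> XYDataSet:
    """Read paired observations from a CSV with an x,y header.

    Raises :class:`ValidationError` with the offending line number on
    missing columns, non-numeric cells, or fewer than 2 rows.
    """
    if hasattr(path_or_file, "read"):
        return _parse_xy_rows(csv.reader(path_or_file), "<stream>")
    path = Path(path_or_file)
    with open(path, newline="", encoding="utf-8") as fh:
        return _parse_xy_rows(csv.reader(fh), str(path))


def write_xy_csv(data: XYDataSet, path_or_file: str | Path | TextIO) -> None:
    """Write a dataset as x,y CSV at full float precision."""
    def _write(fh: TextIO) -> None:
        fh.write("x,y\n")
        for x, y in zip(data.x, data.y):
            fh.write(f"{float(x)!r},{float(y)!r}\n")

    if hasattr(path_or_file, "write"):
        _write(path_or_file)
    else:
        with open(path_or_file, "w", encoding="utf-8") as fh:
            _write(fh)


def load_worked_example() -> tuple[XYDataSet, list[XYDataSet]]:
    """The packaged 12-point worked example with its ten printed reshuffles.

    Returns the observed dataset (x in {1, 2, 3}, four observations each)
    and the ten datasets sharing its x vector with the y values reshuffled.
    """
    text = (
        resources.files("ncaperm") / "data" / "worked_example.csv"
    ).read_text("utf-8")
    rows = list(csv.reader(_io.StringIO(text)))
    header, body = rows[0], rows[1:]
    x = np.array([float(r[0]) for r in body])
    observed = XYDataSet(x, np.array([float(r[1]) for r in body]))
    perms = [
        XYDataSet(x, np.array([float(r[j]) for r in body]))
        for j in range(2, len(header))
    ]
    return observed, perms


@dataclass
class RunManifest:
    """Provenance sidecar written next to every file-producing CLI run."""

    command: str
    arguments: dict
    seed: int | None = None
    outputs: list[str] = field(default_factory=list)
    inputs: list[str] = field(default_factory=list)
    config_sha256: str | None = None
    version: str = ""
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @staticmethod
    def hash_text(text: str) -> str:
        return hashlib.sha256(text.encode("utf-8")).hexdigest()

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")
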