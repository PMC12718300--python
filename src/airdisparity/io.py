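"""Readers and writers for the package's plain-text formats.

Rasters (population or concentration grids) are CSV: a header row with
the grid dimensions (``nrows,ncols``) followed by one row per grid row
in row-major order.  Scenario results are CSV with one row per
(step, group), a fixed column order, and a single metadata comment line
carrying the scenario identity.  Floats are written with ``repr`` —
the shortest round-trip representation — so that a write/read cycle is
lossless and byte-identity between repeated runs is meaningful.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .city import PopulationGrid, build_city
from .errors import ParseError, ValidationError
from .scenarios import RESULT_COLUMNS, ScenarioResult, ScenarioSpec

__all__ = [
    "write_raster_csv",
    "read_raster_csv",
    "write_result_csv",
    "read_result_csv",
    "make_fixture_city",
]

_META_PREFIX = "# airdisparity-result"


def write_raster_csv(values: np.ndarray, path: str | Path) -> None:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValidationError("raster must be two-dimensional")
    rows, cols = values.shape
    with open(path, "w", newline="") as fh:
        fh.write(f"{rows},{cols}\n")
        for row in values:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_raster_csv(path: str | Path) -> np.ndarray:
    path = Path(path)
    with open(path, newline="") as fh:
        header = fh.readline().strip()
        try:
            rows, cols = (int(part) for part in header.split(","))
        except Exception:
            raise ParseError(f"expected 'nrows,ncols' header, got {header!r}",
                             line=1) from None
        values = np.empty((rows, cols), dtype=float)
        for i in range(rows):
            line = fh.readline()
            if not line:
                raise ParseError(f"expected {rows} data rows, found {i}",
                                 line=i + 2)
            parts = line.strip().split(",")
            if len(parts) != cols:
                raise ParseError(
                    f"expected {cols} columns, found {len(parts)}", line=i + 2)
            try:
                values[i] = [float(p) for p in parts]
            except ValueError as exc:
                raise ParseError(str(exc), line=i + 2) from None
    return values


def write_result_csv(result: ScenarioResult, path: str | Path) -> None:
    """Persist all per-step records plus a scenario-identity comment line."""
    spec = result.spec_ref
    x0, y0 = spec.source_start
    with open(path, "w", newline="") as fh:
        fh.write(f"{_META_PREFIX} scenario={spec.name} "
                 f"n_steps={spec.n_steps} "
                 f"initial_emissions={spec.initial_emissions!r} "
                 f"source_x={x0!r} source_y={y0!r}\n")
        writer = csv.writer(fh)
        writer.writerow(RESULT_COLUMNS)
        for row in result.records.itertuples(index=False):
            writer.writerow([row.step, row.group] +
                            [repr(float(v)) for v in row[2:]])


def read_result_csv(path: str | Path) -> ScenarioResult:
    """Rebuild a :class:`ScenarioResult` from disk.

    Per-step records round-trip losslessly; the source trajectory is not
    part of the persisted schema, so the reconstructed spec carries
    ``trajectory=None``.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        meta_line = fh.readline().rstrip("\n")
        if not meta_line.startswith(_META_PREFIX):
            raise ParseError("missing result metadata line", line=1)
        meta = dict(part.split("=", 1)
                    for part in meta_line[len(_META_PREFIX):].split()
                    if "=" in part)
        try:
            spec = ScenarioSpec(
                name=meta["scenario"],
                n_steps=int(meta["n_steps"]),
                initial_emissions=float(meta["initial_emissions"]),
                source_start=(float(meta["source_x"]),
                              float(meta["source_y"])),
                trajectory=None,
            )
        except KeyError as exc:
            raise ParseError(f"metadata line missing key {exc}", line=1) from None
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("missing column header", line=2) from None
        if header != RESULT_COLUMNS:
            missing = sorted(set(RESULT_COLUMNS) - set(header))
            raise ParseError(
                f"bad column header (missing {missing})" if missing
                else f"bad column order {header}", line=2)
        rows = []
        for i, parts in enumerate(reader, start=3):
            if not parts:
                continue
            if len(parts) != len(RESULT_COLUMNS):
                raise ParseError(
                    f"expected {len(RESULT_COLUMNS)} fields, found {len(parts)}",
                    line=i)
            try:
                rows.append((int(parts[0]), parts[1],
                             *(float(p) for p in parts[2:])))
            except ValueError as exc:
                raise ParseError(str(exc), line=i) from None
    records = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if records.empty:
        raise ParseError("result file contains no records")
    fractions = np.arange(spec.n_steps, dtype=float) / spec.n_steps
    return ScenarioResult(spec_ref=spec, records=records,
                          emission_fraction_reduced=fractions)


def make_fixture_city(n: int) -> PopulationGrid:
    """A shrunken default city for tests: same construction as
    :func:`~airdisparity.city.build_city`, restricted to 3 ≤ n ≤ 50."""
    if not 3 <= n <= 50:
        raise ValidationError("fixture city size must lie in [3, 50]")
    return build_city(n=n)
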