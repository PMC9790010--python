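"""Readers and writers for spectrum CSVs, the metadata table, and the
processed-library matrix.

All formats are plain comma-separated text:

* spectrum CSV — two numeric columns ``wavenumber_cm1,intensity`` with an
  optional single header line (auto-detected);
* metadata CSV — the nine library metadata columns plus ``noisy_flag``;
* library matrix CSV — first column ``wavenumber_cm1``, one column per
  specimen id, ids in ascending lexicographic order.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .types import (
    METADATA_COLUMNS,
    RawSpectrum,
    SpecimenMetadata,
    SpectrumLibrary,
)

__all__ = [
    "read_spectrum_csv",
    "read_metadata_table",
    "write_metadata_table",
    "write_library",
    "read_library",
]


class SpectrumParseError(ValueError):
    """Malformed spectrum file (bad row, too few rows, non-finite value)."""


class SchemaError(ValueError):
    """Metadata table missing a required column."""


def _as_stream(source) -> tuple[IO[str], bool]:
    if isinstance(source, (str, os.PathLike)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def _is_numeric_row(fields: list[str]) -> bool:
    try:
        for f in fields[:2]:
            float(f)
    except ValueError:
        return False
    return True


def read_spectrum_csv(source, specimen_id: str | None = None,
                      excitation_nm: float | None = None) -> RawSpectrum:
    """Parse a two-column (wavenumber, intensity) CSV into a RawSpectrum.

    The first line is treated as a header iff any of its first two fields
    is non-numeric.  Rows are sorted ascending by wavenumber and exact
    duplicate wavenumbers are collapsed by their mean intensity, so the
    result is invariant to row order.  Any later non-numeric or non-finite
    row raises :class:`SpectrumParseError` naming the 1-based line number.
    """
    stream, close = _as_stream(source)
    if specimen_id is None:
        name = getattr(stream, "name", None)
        specimen_id = Path(name).stem if name else "query"
    try:
        wn: list[float] = []
        iy: list[float] = []
        for lineno, line in enumerate(stream, start=1):
            line = line.strip()
            if not line:
                continue
            fields = [f.strip() for f in line.split(",")]
            if len(fields) < 2:
                raise SpectrumParseError(
                    f"{specimen_id}: line {lineno}: expected >= 2 comma-separated columns"
                )
            if not _is_numeric_row(fields):
                if lineno == 1 and not wn:
                    continue  # header line
                raise SpectrumParseError(
                    f"{specimen_id}: line {lineno}: non-numeric data row {line!r}"
                )
            w, y = float(fields[0]), float(fields[1])
            if not (np.isfinite(w) and np.isfinite(y)):
                raise SpectrumParseError(
                    f"{specimen_id}: line {lineno}: non-finite value"
                )
            wn.append(w)
            iy.append(y)
    finally:
        if close:
            stream.close()

    if len(wn) < 16:
        raise SpectrumParseError(
            f"{specimen_id}: only {len(wn)} valid rows; a spectrum needs >= 16"
        )
    w = np.asarray(wn)
    y = np.asarray(iy)
    order = np.argsort(w, kind="stable")
    w, y = w[order], y[order]
    # collapse exact duplicate wavenumbers by arithmetic mean
    uniq, inverse, counts = np.unique(w, return_inverse=True, return_counts=True)
    if uniq.size != w.size:
        sums = np.zeros(uniq.size)
        np.add.at(sums, inverse, y)
        y = sums / counts
        w = uniq
    if w.size < 16:
        raise SpectrumParseError(
            f"{specimen_id}: only {w.size} distinct wavenumbers; need >= 16"
        )
    return RawSpectrum(specimen_id, w, y, excitation_nm=excitation_nm)


def read_metadata_table(source) -> list[SpecimenMetadata]:
    """Read the specimen metadata CSV (library schema, order-free columns).

    ``noisy_flag`` is optional and defaults to false.  Empty cells map to
    empty strings.  A missing required column raises :class:`SchemaError`;
    a duplicate ``unique_id`` raises ``ValueError``.
    """
    stream, close = _as_stream(source)
    try:
        df = pd.read_csv(stream, dtype=str, keep_default_na=False)
    finally:
        if close:
            stream.close()
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata table missing required column(s): {missing}")
    if "noisy_flag" not in df.columns:
        df["noisy_flag"] = "False"
    dupes = df["unique_id"][df["unique_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate unique_id in metadata table: {sorted(set(dupes))}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SpecimenMetadata(
                **{c: row[c] for c in METADATA_COLUMNS},
                noisy_flag=str(row["noisy_flag"]).strip().lower()
                in {"true", "1", "yes"},
            )
        )
    return records


def write_metadata_table(records: Iterable[SpecimenMetadata], dest) -> None:
    rows = [vars(r) for r in records]
    df = pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + ["noisy_flag"])
    stream, close = (open(dest, "w", encoding="utf-8"), True) if isinstance(
        dest, (str, os.PathLike)
    ) else (dest, False)
    try:
        df.to_csv(stream, index=False)
    finally:
        if close:
            stream.close()


def write_library(lib: SpectrumLibrary, matrix_dest, metadata_dest) -> None:
    """Write a library as a wide matrix CSV plus a metadata CSV.

    Matrix layout: column 1 is ``wavenumber_cm1``; one column per specimen,
    ids ascending lexicographic for deterministic diffs.  The pair
    round-trips bit-identically through :func:`read_library` (values are
    written with ``repr`` precision).
    """
    if len(lib) == 0:
        raise ValueError("refusing to write an empty library")
    order = sorted(range(len(lib.ids)), key=lambda i: lib.ids[i])
    ids = [lib.ids[i] for i in order]
    columns = [lib.grid] + [lib.matrix[i] for i in order]
    write_float_csv(["wavenumber_cm1"] + ids, columns, matrix_dest)
    write_metadata_table([lib.metadata[u] for u in ids], metadata_dest)


def write_float_csv(names: list[str], columns: list[np.ndarray], dest) -> None:
    """Write float columns with shortest round-trip (repr) precision."""
    stream, close = (open(dest, "w", encoding="utf-8"), True) if isinstance(
        dest, (str, os.PathLike)
    ) else (dest, False)
    try:
        stream.write(",".join(names) + "\n")
        for row in zip(*columns):
            stream.write(",".join(repr(float(v)) for v in row) + "\n")
    finally:
        if close:
            stream.close()


def read_library(matrix_source, metadata_source) -> SpectrumLibrary:
    """Inverse of :func:`write_library`."""
    stream, close = _as_stream(matrix_source)
    try:
        df = pd.read_csv(stream, float_precision="round_trip")
    finally:
        if close:
            stream.close()
    if "wavenumber_cm1" != df.columns[0]:
        raise SchemaError("library matrix must start with a wavenumber_cm1 column")
    grid = df["wavenumber_cm1"].to_numpy(dtype=float)
    ids = [c for c in df.columns if c != "wavenumber_cm1"]
    matrix = df[ids].to_numpy(dtype=float).T
    records = read_metadata_table(metadata_source)
    return SpectrumLibrary(
        grid=grid, ids=ids, matrix=matrix, metadata={r.unique_id: r for r in records}
    )
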