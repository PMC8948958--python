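"""Plain-text I/O for Raman spectral datasets.

Two formats are supported:

* a CSV *matrix* file — one header row carrying the metadata column names
  followed by the wavenumber grid, then one row per spectrum
  (metadata cells first, intensities after); and
* per-spectrum *two-column* ASCII files (wavenumber, intensity), the format
  most instrument software exports.

Both round-trip losslessly at double precision.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Metadata columns carried per spectrum, in file order.
META_COLUMNS = ("class", "genetics", "trichome_id", "point_id")


@dataclass
class Spectrum:
    """A single Raman trace: a strictly increasing wavenumber axis (cm^-1),
    matching intensities (arbitrary units) and free-form metadata."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError(
                f"wavenumbers and intensities differ in length "
                f"({self.wavenumbers.size} vs {self.intensities.size})"
            )
        if self.wavenumbers.size >= 2 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("grid not increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite intensities")

    def copy(self) -> "Spectrum":
        return Spectrum(self.wavenumbers.copy(), self.intensities.copy(), dict(self.meta))


@dataclass
class SpectraDataset:
    """A stack of spectra sharing one wavenumber grid.

    ``matrix`` is n_spectra x n_wavenumbers; ``labels`` is a DataFrame with
    one row per spectrum and (at least) the :data:`META_COLUMNS` columns.
    """

    grid: np.ndarray
    matrix: np.ndarray
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.size == 0:
            self.matrix = self.matrix.reshape(0, self.grid.size)
        if self.matrix.shape[1] != self.grid.size:
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns but grid has "
                f"{self.grid.size} points"
            )
        if self.grid.size >= 2 and not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid not increasing")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError(
                f"{len(self.labels)} label rows for {self.matrix.shape[0]} spectra"
            )
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.matrix[i], self.labels.iloc[i].to_dict())

    def subset(self, mask) -> "SpectraDataset":
        mask = np.asarray(mask)
        return SpectraDataset(self.grid, self.matrix[mask], self.labels.loc[mask])

    def classes(self) -> list:
        """Class labels in order of first appearance."""
        return list(dict.fromkeys(self.labels["class"]))

    def copy(self) -> "SpectraDataset":
        return SpectraDataset(self.grid.copy(), self.matrix.copy(), self.labels.copy())


def _parse_float(cell: str, row: int, col: int, path) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ValueError(
            f"{path}: non-numeric cell {cell!r} at row {row}, column {col}"
        ) from None


def read_matrix_csv(path) -> SpectraDataset:
    """Read a dataset from the CSV matrix format.

    The header row holds the metadata column names followed by the
    wavenumber grid; each subsequent row holds the metadata values followed
    by the intensities for one spectrum.  Raises ``ValueError`` with the
    offending row/column on ragged rows, a non-increasing grid, or
    non-numeric cells.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    n_meta = 0
    while n_meta < len(header):
        try:
            float(header[n_meta])
            break
        except ValueError:
            n_meta += 1
    grid = np.array([_parse_float(c, 0, n_meta + j, path) for j, c in enumerate(header[n_meta:])])
    if grid.size == 0:
        raise ValueError(f"{path}: header contains no wavenumbers")
    if grid.size >= 2 and not np.all(np.diff(grid) > 0):
        raise ValueError(f"{path}: grid not increasing")
    meta_names = header[:n_meta]
    records, matrix = [], []
    for i, row in enumerate(rows[1:], start=1):
        if len(row) != len(header):
            raise ValueError(
                f"{path}: ragged row {i} ({len(row)} cells, expected {len(header)})"
            )
        records.append(dict(zip(meta_names, row[:n_meta])))
        matrix.append([_parse_float(c, i, n_meta + j, path) for j, c in enumerate(row[n_meta:])])
    labels = pd.DataFrame.from_records(records) if records else pd.DataFrame(columns=meta_names)
    return SpectraDataset(grid, np.array(matrix, dtype=float).reshape(len(records), grid.size), labels)


def write_matrix_csv(dataset: SpectraDataset, path) -> None:
    """Write ``dataset`` in the CSV matrix format (inverse of
    :func:`read_matrix_csv`); numbers use 17 significant digits so the
    round-trip is exact at double precision."""
    path = Path(path)
    meta_names = [c for c in dataset.labels.columns]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(meta_names + [f"{g:.17g}" for g in dataset.grid])
        for i in range(dataset.n_spectra):
            meta = [str(dataset.labels.iloc[i][c]) for c in meta_names]
            writer.writerow(meta + [f"{v:.17g}" for v in dataset.matrix[i]])


def read_two_column(paths: Sequence, labels: Sequence[Mapping] | None = None) -> SpectraDataset:
    """Assemble a dataset from per-spectrum two-column ASCII files.

    Each file holds two whitespace- or comma-separated numeric columns
    (wavenumber, intensity); lines starting with ``#`` are comments.  All
    spectra are linearly interpolated onto the first file's grid restricted
    to the span common to every file.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no input files")
    if labels is None:
        labels = [{} for _ in paths]
    traces = []
    for path in paths:
        xs, ys = [], []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.replace(",", " ").split()
                if len(parts) < 2:
                    raise ValueError(f"{path}: line {lineno}: expected two columns")
                xs.append(_parse_float(parts[0], lineno, 0, path))
                ys.append(_parse_float(parts[1], lineno, 1, path))
        x = np.array(xs)
        order = np.argsort(x)
        traces.append((x[order], np.array(ys)[order]))
    lo = max(t[0][0] for t in traces)
    hi = min(t[0][-1] for t in traces)
    if lo > hi:
        raise ValueError("empty common wavenumber span across input files")
    ref_x = traces[0][0]
    grid = ref_x[(ref_x >= lo) & (ref_x <= hi)]
    matrix = np.vstack([np.interp(grid, x, y) for x, y in traces])
    records = [{c: dict(m).get(c) for c in META_COLUMNS} for m in labels]
    label_df = pd.DataFrame(records, index=range(len(paths)))
    return SpectraDataset(grid, matrix, label_df)
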