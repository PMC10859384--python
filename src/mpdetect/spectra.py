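"""Spectrum containers and plain-text I/O.

Every downstream step (preprocessing, classification, correlation matching)
consumes intensities laid out on a shared wavenumber grid.  The canonical
instrument grid spans 769-1801 cm^-1 at a 2 cm^-1 step (517 points); grids
are always stored ascending regardless of acquisition order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MP = "MP"
NON_MP = "NON_MP"

GRID_MIN = 769.0
GRID_MAX = 1801.0
GRID_STEP = 2.0


class DegenerateSpectrumError(ValueError):
    """A spectrum is constant (zero variance) where variation is required."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly ascending wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("grid needs at least two wavenumbers")
        if not np.all(np.diff(v) > 0):
            raise ValueError("wavenumber grid must be strictly ascending")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def step(self) -> float:
        return float(np.median(np.diff(self.values)))

    def index_of(self, wavenumbers: Sequence[float]) -> np.ndarray:
        """Indices of exact grid wavenumbers; raises if any is off-grid."""
        idx = np.searchsorted(self.values, wavenumbers)
        idx = np.clip(idx, 0, len(self) - 1)
        ok = np.isclose(self.values[idx], wavenumbers, atol=1e-6)
        if not np.all(ok):
            missing = np.asarray(wavenumbers)[~ok]
            raise ValueError(f"wavenumbers not on grid: {missing.tolist()}")
        return idx

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and np.allclose(
            self.values, other.values
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))


def default_grid() -> WavenumberGrid:
    """Instrument grid: 769..1801 cm^-1 inclusive at 2 cm^-1 (517 points)."""
    n = int(round((GRID_MAX - GRID_MIN) / GRID_STEP)) + 1
    return WavenumberGrid(np.linspace(GRID_MIN, GRID_MAX, n))


@dataclass
class Spectrum:
    """One intensity trace on a grid, intensities in arbitrary units."""

    grid: WavenumberGrid
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        y = np.asarray(self.intensity, dtype=float)
        if y.shape != (len(self.grid),):
            raise ValueError(
                f"intensity length {y.size} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite intensity values")
        self.intensity = y

    def with_intensity(self, y: np.ndarray) -> "Spectrum":
        return Spectrum(self.grid, y, dict(self.meta))


@dataclass
class SpectraMatrix:
    """Stack of spectra sharing one grid, with optional MP/NON_MP labels."""

    grid: WavenumberGrid
    X: np.ndarray  # (n_spectra, n_wavenumbers)
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.grid):
            raise ValueError("matrix columns must match grid length")
        if self.labels is not None:
            if len(self.labels) != X.shape[0]:
                raise ValueError("one label per row required")
            bad = set(self.labels) - {MP, NON_MP}
            if bad:
                raise ValueError(f"unknown labels: {sorted(bad)}")
            self.labels = list(self.labels)
        self.X = X

    def __len__(self) -> int:
        return self.X.shape[0]

    def row(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.X[i].copy(), {"row": i})

    def rows(self) -> Iterable[Spectrum]:
        for i in range(len(self)):
            yield self.row(i)

    def subset(self, idx: np.ndarray) -> "SpectraMatrix":
        labels = [self.labels[i] for i in idx] if self.labels is not None else None
        return SpectraMatrix(self.grid, self.X[idx].copy(), labels)


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column (wavenumber_cm-1, intensity) delimited text file.

    A header line is required.  Rows are sorted into ascending wavenumber
    order; the on-disk order is recorded in ``meta['original_order']``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavenumber, intensity)")
    wn = df.iloc[:, 0].to_numpy(dtype=float)
    y = df.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(wn)
    meta = {"source": str(path)}
    if not np.all(order == np.arange(wn.size)):
        meta["original_order"] = "descending" if np.all(np.diff(wn) < 0) else "unsorted"
    return Spectrum(WavenumberGrid(wn[order]), y[order], meta)


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavenumber_cm-1": s.grid.values, "intensity": s.intensity}
    ).to_csv(path, index=False)


def read_spectra_matrix(path: str | Path) -> SpectraMatrix:
    """Read a spectra-matrix table: first row wavenumbers, optional first
    column of MP/NON_MP labels, one spectrum per subsequent row."""
    df = pd.read_csv(path, sep=None, engine="python")
    labels = None
    if df.columns[0].strip().lower() in {"label", "class"}:
        labels = df.iloc[:, 0].astype(str).tolist()
        df = df.iloc[:, 1:]
    wn = np.array([float(c) for c in df.columns])
    order = np.argsort(wn)
    X = df.to_numpy(dtype=float)[:, order]
    return SpectraMatrix(WavenumberGrid(wn[order]), X, labels)


def write_spectra_matrix(m: SpectraMatrix, path: str | Path) -> None:
    cols = [f"{w:g}" for w in m.grid.values]
    df = pd.DataFrame(m.X, columns=cols)
    if m.labels is not None:
        df.insert(0, "label", m.labels)
    df.to_csv(path, index=False)
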