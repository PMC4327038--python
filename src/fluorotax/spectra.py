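"""Data model and I/O for fluorescence emission spectra.

A :class:`Spectrum` is one measurement on a uniform wavelength grid
(default 1-nm step); a :class:`SpectraSet` is an aligned collection of
measurements sharing one grid, optionally carrying per-measurement class
labels and growth-state indices.

Spectra are exchanged as delimited text (comma-separated, ``.`` decimal,
header row) in two layouts:

* ``wide`` — first column is the wavelength in nm, each remaining column
  one measurement;
* ``long`` — three columns ``measurement_id, wavelength_nm, intensity``.

Labels and growth indices live in a sibling JSON manifest
``<stem>.manifest.json`` mapping ``measurement_id -> {label, growth_index}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectraSet",
    "GridError",
    "SpectraFormatError",
    "BandRangeError",
    "read_spectra",
    "write_spectra",
    "crop_band",
]

#: relative tolerance for grid-step uniformity
_GRID_RTOL = 1e-9


class GridError(ValueError):
    """Wavelength grid is not strictly increasing with a uniform step."""


class SpectraFormatError(ValueError):
    """Input file does not conform to the wide/long layout contract."""


class BandRangeError(ValueError):
    """Requested wavelength band does not intersect the grid."""


def _validate_grid(wavelengths: np.ndarray) -> None:
    if wavelengths.ndim != 1 or wavelengths.size < 2:
        raise GridError("wavelength grid must be 1-D with at least 2 points")
    steps = np.diff(wavelengths)
    if np.any(steps <= 0):
        raise GridError("wavelength grid must be strictly increasing")
    step = steps[0]
    if np.any(np.abs(steps - step) > _GRID_RTOL * max(abs(step), 1.0)):
        raise GridError(
            f"wavelength grid step is not uniform (steps range "
            f"{steps.min():g}..{steps.max():g})"
        )


@dataclass
class Spectrum:
    """One fluorescence measurement on a uniform wavelength grid.

    Parameters
    ----------
    wavelengths : array-like
        Emission wavelengths in nm, strictly increasing, uniform step.
    intensities : array-like
        Fluorescence values (arbitrary units), same length as the grid.
    label : str, optional
        Taxonomic class tag.
    growth_index : int, optional
        Ordinal growth-state index of the culture at measurement time.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    label: str | None = None
    growth_index: int | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        _validate_grid(self.wavelengths)
        if self.intensities.shape != self.wavelengths.shape:
            raise SpectraFormatError(
                "intensities and wavelengths must have the same length"
            )

    @property
    def step(self) -> float:
        """Grid step in nm."""
        return float(self.wavelengths[1] - self.wavelengths[0])

    def replace_intensities(self, values: np.ndarray) -> "Spectrum":
        """New spectrum on the same grid with different intensities."""
        return Spectrum(self.wavelengths.copy(), np.asarray(values, dtype=float),
                        label=self.label, growth_index=self.growth_index)


@dataclass
class SpectraSet:
    """Aligned collection of spectra: matrix of measurements x wavelengths."""

    grid: np.ndarray
    values: np.ndarray
    labels: list[str] | None = None
    growth_indices: list[int] | None = None
    ids: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        _validate_grid(self.grid)
        if self.values.shape[1] != self.grid.size:
            raise SpectraFormatError(
                f"values have {self.values.shape[1]} columns but the grid "
                f"has {self.grid.size} wavelengths"
            )
        n = self.values.shape[0]
        if self.labels is not None and len(self.labels) != n:
            raise SpectraFormatError("labels must cover every measurement row")
        if self.growth_indices is not None and len(self.growth_indices) != n:
            raise SpectraFormatError("growth_indices must cover every row")
        if self.ids is not None and len(self.ids) != n:
            raise SpectraFormatError("ids must cover every row")

    @property
    def n_measurements(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.grid.size

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def spectrum(self, i: int) -> Spectrum:
        """Row ``i`` as a :class:`Spectrum`."""
        return Spectrum(
            self.grid.copy(),
            self.values[i].copy(),
            label=None if self.labels is None else self.labels[i],
            growth_index=(None if self.growth_indices is None
                          else self.growth_indices[i]),
        )

    def spectra(self):
        """Iterate over rows as :class:`Spectrum` objects."""
        for i in range(self.n_measurements):
            yield self.spectrum(i)

    def with_values(self, values: np.ndarray,
                    grid: np.ndarray | None = None) -> "SpectraSet":
        """New set with replaced values (and optionally grid), same metadata."""
        return SpectraSet(
            self.grid.copy() if grid is None else np.asarray(grid, dtype=float),
            np.asarray(values, dtype=float),
            labels=None if self.labels is None else list(self.labels),
            growth_indices=(None if self.growth_indices is None
                            else list(self.growth_indices)),
            ids=None if self.ids is None else list(self.ids),
        )

    def subset(self, rows: Sequence[int] | np.ndarray) -> "SpectraSet":
        """New set keeping only the given measurement rows."""
        rows = np.asarray(rows)
        return SpectraSet(
            self.grid.copy(),
            self.values[rows],
            labels=(None if self.labels is None
                    else [self.labels[i] for i in rows]),
            growth_indices=(None if self.growth_indices is None
                            else [self.growth_indices[i] for i in rows]),
            ids=None if self.ids is None else [self.ids[i] for i in rows],
        )

    def map_rows(self, fn) -> "SpectraSet":
        """Apply a Spectrum -> Spectrum function to every row.

        The function must preserve the grid.
        """
        out = np.empty_like(self.values)
        for i, spec in enumerate(self.spectra()):
            out[i] = fn(spec).intensities
        return self.with_values(out)

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectraSet":
        if not spectra:
            raise SpectraFormatError("cannot build a set from zero spectra")
        grid = spectra[0].wavelengths
        for s in spectra[1:]:
            if s.wavelengths.shape != grid.shape or not np.allclose(
                    s.wavelengths, grid, rtol=0, atol=_GRID_RTOL):
                raise GridError("all spectra must share the same grid")
        labels = [s.label for s in spectra]
        growth = [s.growth_index for s in spectra]
        return cls(
            grid.copy(),
            np.vstack([s.intensities for s in spectra]),
            labels=None if all(l is None for l in labels) else labels,
            growth_indices=None if all(g is None for g in growth) else growth,
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _manifest_path(path: Path) -> Path:
    return path.with_name(path.stem + ".manifest.json")


def _default_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"m{i:0{width}d}" for i in range(n)]


def read_spectra(path: str | Path, layout: str = "wide") -> SpectraSet:
    """Read a spectra set from delimited text.

    Parameters
    ----------
    path : path
        CSV file; a sibling ``<stem>.manifest.json`` with labels and
        growth indices is picked up automatically when present.
    layout : {'wide', 'long'}
        ``wide``: first column wavelength, remaining columns measurements.
        ``long``: ``measurement_id, wavelength_nm, intensity`` rows.
    """
    path = Path(path)
    if layout == "wide":
        df = pd.read_csv(path, float_precision="round_trip")
        if df.shape[1] < 2:
            raise SpectraFormatError("wide layout needs >= 2 columns")
        if df.isna().any().any():
            raise SpectraFormatError("ragged or missing values in wide file")
        grid = df.iloc[:, 0].to_numpy(dtype=float)
        values = df.iloc[:, 1:].to_numpy(dtype=float).T
        ids = [str(c) for c in df.columns[1:]]
    elif layout == "long":
        df = pd.read_csv(path, float_precision="round_trip")
        expected = {"measurement_id", "wavelength_nm", "intensity"}
        if not expected.issubset(df.columns):
            raise SpectraFormatError(
                f"long layout needs columns {sorted(expected)}"
            )
        wide = df.pivot(index="measurement_id", columns="wavelength_nm",
                        values="intensity")
        if wide.isna().any().any():
            raise SpectraFormatError("ragged long file: ids cover different grids")
        # preserve file order of measurement ids
        order = list(dict.fromkeys(df["measurement_id"]))
        wide = wide.loc[order]
        grid = wide.columns.to_numpy(dtype=float)
        values = wide.to_numpy(dtype=float)
        ids = [str(i) for i in wide.index]
    else:
        raise ValueError(f"unknown layout {layout!r}")

    labels = growth = None
    manifest = _manifest_path(path)
    if manifest.exists():
        meta = json.loads(manifest.read_text())
        labels = [meta.get(i, {}).get("label") for i in ids]
        growth = [meta.get(i, {}).get("growth_index") for i in ids]
        if all(l is None for l in labels):
            labels = None
        if all(g is None for g in growth):
            growth = None
    return SpectraSet(grid, values, labels=labels, growth_indices=growth,
                      ids=ids)


def write_spectra(sset: SpectraSet, path: str | Path,
                  layout: str = "wide") -> None:
    """Write a spectra set as delimited text; round-trips losslessly.

    Values are formatted with 17 significant digits so that
    ``read_spectra(write_spectra(s))`` reproduces ``s`` bit-for-bit.
    A labels/growth manifest is emitted alongside when present.
    """
    if sset.n_measurements == 0:
        raise SpectraFormatError("refusing to write an empty spectra set")
    path = Path(path)
    ids = sset.ids if sset.ids is not None else _default_ids(sset.n_measurements)
    if layout == "wide":
        cols = {"wavelength_nm": sset.grid}
        cols.update({mid: sset.values[i] for i, mid in enumerate(ids)})
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    elif layout == "long":
        records = []
        for i, mid in enumerate(ids):
            for j, wl in enumerate(sset.grid):
                records.append((mid, wl, sset.values[i, j]))
        df = pd.DataFrame(records,
                          columns=["measurement_id", "wavelength_nm",
                                   "intensity"])
        df.to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if sset.labels is not None or sset.growth_indices is not None:
        meta = {}
        for i, mid in enumerate(ids):
            entry = {}
            if sset.labels is not None:
                entry["label"] = sset.labels[i]
            if sset.growth_indices is not None:
                entry["growth_index"] = sset.growth_indices[i]
            meta[mid] = entry
        _manifest_path(path).write_text(json.dumps(meta, indent=1))


def crop_band(sset: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Keep wavelengths in the closed interval [lo, hi] nm.

    The default analysis band around the chlorophyll-a emission peak is
    630-730 nm; on a 1-nm grid that keeps 101 points with the peak near
    the band centre.
    """
    if lo >= hi:
        raise BandRangeError(f"need lo < hi, got [{lo}, {hi}]")
    mask = (sset.grid >= lo) & (sset.grid <= hi)
    if not mask.any():
        raise BandRangeError(
            f"band [{lo}, {hi}] nm does not intersect the grid "
            f"[{sset.grid[0]}, {sset.grid[-1]}] nm"
        )
    return sset.with_values(sset.values[:, mask], grid=sset.grid[mask])
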