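"""Reading, validating, restricting and resampling absorbance spectra.

The canonical axis is wavenumber in cm^-1, strictly increasing.  Two CSV
dialects are supported:

* ``csv_long`` — two columns, wavenumber then absorbance, one spectrum per
  file.  A header row is optional and detected automatically.
* ``csv_wide`` — first column wavenumber, one additional column per sample;
  the header row carries the sample ids.

Inputs recorded in nanometres can be converted on read (``nu = 1e7 / lambda``)
with ``axis_unit="nm"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, RangeError

if TYPE_CHECKING:  # pragma: no cover
    from .spline import SplineModel

__all__ = [
    "Spectrum",
    "SpectralGrid",
    "DEFAULT_GRID",
    "read_spectra",
    "write_spectra",
    "restrict_range",
    "resample",
]


@dataclass(frozen=True)
class SpectralGrid:
    """A uniform wavenumber grid, endpoints inclusive."""

    lo: float
    hi: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"grid lo must be < hi (got {self.lo} >= {self.hi})")
        if self.n_points < 4:
            raise ValueError(f"grid needs at least 4 points (got {self.n_points})")

    def points(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_points)

    @property
    def spacing(self) -> float:
        return (self.hi - self.lo) / (self.n_points - 1)


#: Analysis grid used throughout: 4000-10000 cm^-1 (1-2.5 um), 779 points.
DEFAULT_GRID = SpectralGrid(4000.0, 10000.0, 779)


@dataclass
class Spectrum:
    """One absorbance trace on a strictly increasing wavenumber axis.

    Parameters
    ----------
    axis : array-like
        Wavenumbers in cm^-1, strictly increasing.
    absorbance : array-like
        Absorbance values (AU), same length as ``axis``.
    sample_id : str
        Identifier carried through the pipeline.
    group : str or None
        Optional class label, e.g. ``"normal"`` or ``"degraded"``.
    """

    axis: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""
    group: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.axis.ndim != 1 or self.absorbance.ndim != 1:
            raise ValueError("axis and absorbance must be one-dimensional")
        if len(self.axis) != len(self.absorbance):
            raise ValueError(
                f"axis ({len(self.axis)}) and absorbance ({len(self.absorbance)}) "
                "lengths differ"
            )
        if len(self.axis) < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not (np.all(np.isfinite(self.axis)) and np.all(np.isfinite(self.absorbance))):
            raise ValueError("axis and absorbance must be finite")
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("axis must be strictly increasing")

    def __len__(self) -> int:
        return len(self.axis)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.axis[0]), float(self.axis[-1])


def _to_numeric_column(raw: pd.Series, path: Path, colname: str) -> np.ndarray:
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.index[values.isna() & raw.notna()]
    if len(bad) > 0:
        row = int(bad[0])
        raise ParseError(
            f"{path}: non-numeric value {raw.iloc[row]!r} in column {colname!r}, row {row}"
        )
    if values.isna().any():
        row = int(values.index[values.isna()][0])
        raise ParseError(f"{path}: missing value in column {colname!r}, row {row}")
    return values.to_numpy(dtype=float)


def _finalise_axis(
    axis: np.ndarray, path: Path, axis_unit: str
) -> tuple[np.ndarray, np.ndarray | None]:
    """Convert/sort the axis; returns (axis, order) where order is the applied permutation."""
    if axis_unit == "nm":
        axis = 1e7 / axis
    elif axis_unit != "cm-1":
        raise ValueError(f"unknown axis_unit {axis_unit!r} (use 'cm-1' or 'nm')")
    uniq, counts = np.unique(axis, return_counts=True)
    dupes = uniq[counts > 1]
    if len(dupes) > 0:
        raise ParseError(f"{path}: duplicate wavenumber {dupes[0]:g} appears more than once")
    order = None
    if np.any(np.diff(axis) < 0):
        warnings.warn(f"{path}: wavenumber axis not ascending; re-sorting", stacklevel=3)
        order = np.argsort(axis)
        axis = axis[order]
    return axis, order


def _has_header(path: Path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    for tok in first.strip().split(","):
        try:
            float(tok)
        except ValueError:
            return True
    return False


def read_spectra(
    path: str | Path,
    dialect: str = "csv_long",
    axis_unit: str = "cm-1",
) -> list[Spectrum]:
    """Read one (``csv_long``) or many (``csv_wide``) spectra from a CSV file.

    Raises :class:`~nirmix.errors.ParseError` on missing columns, non-numeric
    cells or duplicated wavenumbers; a descending axis is re-sorted with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header = 0 if _has_header(path) else None
    df = pd.read_csv(path, header=header, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected at least 2 columns, found {df.shape[1]}")

    if dialect == "csv_long":
        axis = _to_numeric_column(df.iloc[:, 0], path, str(df.columns[0]))
        absorb = _to_numeric_column(df.iloc[:, 1], path, str(df.columns[1]))
        axis, order = _finalise_axis(axis, path, axis_unit)
        if order is not None:
            absorb = absorb[order]
        return [Spectrum(axis, absorb, sample_id=path.stem)]

    if dialect == "csv_wide":
        axis = _to_numeric_column(df.iloc[:, 0], path, str(df.columns[0]))
        axis, order = _finalise_axis(axis, path, axis_unit)
        spectra = []
        for j in range(1, df.shape[1]):
            name = str(df.columns[j]) if header == 0 else f"{path.stem}_{j}"
            absorb = _to_numeric_column(df.iloc[:, j], path, name)
            if order is not None:
                absorb = absorb[order]
            spectra.append(Spectrum(axis, absorb, sample_id=name))
        return spectra

    raise ValueError(f"unknown dialect {dialect!r} (use 'csv_long' or 'csv_wide')")


def write_spectra(
    spectra: Sequence[Spectrum] | Spectrum,
    path: str | Path,
    dialect: str = "csv_long",
) -> None:
    """Write spectra to CSV; the inverse of :func:`read_spectra`."""
    path = Path(path)
    if isinstance(spectra, Spectrum):
        spectra = [spectra]
    if dialect == "csv_long":
        if len(spectra) != 1:
            raise ValueError("csv_long holds one spectrum per file")
        s = spectra[0]
        pd.DataFrame({"wavenumber": s.axis, "absorbance": s.absorbance}).to_csv(
            path, index=False, float_format="%.17g"
        )
        return
    if dialect == "csv_wide":
        axis = spectra[0].axis
        for s in spectra[1:]:
            if not np.array_equal(s.axis, axis):
                raise ValueError("csv_wide requires a common axis across spectra")
        data = {"wavenumber": axis}
        for s in spectra:
            data[s.sample_id or f"s{id(s)}"] = s.absorbance
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def restrict_range(s: Spectrum, grid: SpectralGrid) -> Spectrum:
    """Drop points outside ``[grid.lo, grid.hi]``; no interpolation is performed."""
    mask = (s.axis >= grid.lo) & (s.axis <= grid.hi)
    if not mask.any():
        raise RangeError(
            f"spectrum {s.sample_id!r} spans {s.span} which does not intersect "
            f"[{grid.lo}, {grid.hi}]"
        )
    if mask.sum() < 2:
        raise RangeError(
            f"spectrum {s.sample_id!r}: fewer than 2 points inside [{grid.lo}, {grid.hi}]"
        )
    return Spectrum(
        s.axis[mask], s.absorbance[mask], sample_id=s.sample_id, group=s.group,
        meta=dict(s.meta),
    )


def resample(
    s: Spectrum,
    grid: SpectralGrid,
    model: "SplineModel | None" = None,
) -> Spectrum:
    """Evaluate a spectrum on a uniform grid.

    With a fitted :class:`~nirmix.spline.SplineModel` the spline is evaluated;
    otherwise piecewise-linear interpolation between samples is used.
    Extrapolation beyond the source span raises :class:`RangeError`.
    """
    x = grid.points()
    eps = 1e-9 * max(1.0, abs(s.axis[-1]))
    if x[0] < s.axis[0] - eps or x[-1] > s.axis[-1] + eps:
        raise RangeError(
            f"grid [{grid.lo}, {grid.hi}] extends beyond spectrum span {s.span}"
        )
    if model is not None:
        y = model(x)
    else:
        y = np.interp(x, s.axis, s.absorbance)
    return Spectrum(x, y, sample_id=s.sample_id, group=s.group, meta=dict(s.meta))
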