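"""Beer's-law classical least-squares unmixing of second-derivative spectra.

With pure-constituent absorptivities e_w, e_c, e_p known on a common grid, a
mixture obeys ``A(nu) = c_w l e_w + c_c l e_c + c_p l e_p``.  Differentiating
twice annihilates additive constant and linear-in-nu baselines, so the
concentrations (times the unknown optical path length l, fixed at 1) are the
least-squares solution of the overdetermined system ``E'' c = d2A`` assembled
over the grid.  The solve goes through a QR factorisation; concentrations are
relative to the pure standards because measured pure-component absorbance
stands in for absorptivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import nnls

from .errors import ConditioningWarning, RangeError, SolveError, WindowError
from .spectra_io import SpectralGrid, Spectrum, restrict_range
from .spline import (
    SmoothingParams,
    SplineModel,
    fit_spline,
    interior_mask,
    place_knots,
    second_derivative,
)

__all__ = [
    "ComponentLibrary",
    "FeatureVector",
    "build_library",
    "solve_concentrations",
    "unmix",
    "window_stability",
]

_COLLINEARITY_COND = 1e8


@dataclass
class FeatureVector:
    """Relative concentration-times-path-length estimates for one spectrum."""

    c_w: float
    c_c: float
    c_p: float
    residual_norm: float = 0.0
    condition_number: float = float("nan")
    sample_id: str = ""
    group: str | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.c_w, self.c_c, self.c_p, self.residual_norm])):
            raise ValueError("feature vector entries must be finite")
        if self.residual_norm < 0:
            raise ValueError("residual_norm must be >= 0")

    @property
    def values(self) -> np.ndarray:
        return np.array([self.c_w, self.c_c, self.c_p])

    def scaled(self, factor: float) -> "FeatureVector":
        """Componentwise rescaling, as induced by a path length l != 1."""
        return replace(
            self,
            c_w=self.c_w * factor,
            c_c=self.c_c * factor,
            c_p=self.c_p * factor,
            residual_norm=self.residual_norm * abs(factor),
        )


@dataclass
class ComponentLibrary:
    """Second-derivative absorptivity matrix of the three constituents.

    ``d2_matrix`` has one column per constituent, evaluated at the grid rows
    listed in ``grid_indices`` (spline edge rows are dropped at build time).
    """

    names: tuple[str, str, str]
    grid: SpectralGrid
    d2_matrix: np.ndarray
    grid_indices: np.ndarray
    condition_number: float = float("nan")

    def __post_init__(self) -> None:
        self.d2_matrix = np.asarray(self.d2_matrix, dtype=float)
        self.grid_indices = np.asarray(self.grid_indices, dtype=int)
        if self.d2_matrix.ndim != 2 or self.d2_matrix.shape[1] != 3:
            raise ValueError("d2_matrix must be k x 3")
        if self.d2_matrix.shape[0] < 3:
            raise ValueError("library needs at least 3 rows")
        if len(self.grid_indices) != self.d2_matrix.shape[0]:
            raise ValueError("grid_indices must index the rows of d2_matrix")
        if np.isnan(self.condition_number):
            self.condition_number = float(np.linalg.cond(self.d2_matrix))


def _check_spans(s: Spectrum, grid: SpectralGrid) -> None:
    if s.axis[0] > grid.lo + 1e-9 or s.axis[-1] < grid.hi - 1e-9:
        raise RangeError(
            f"spectrum {s.sample_id!r} spans {s.span} and does not cover the "
            f"grid [{grid.lo}, {grid.hi}]"
        )


def _d2_on_grid(
    s: Spectrum, grid: SpectralGrid, params: SmoothingParams
) -> tuple[np.ndarray, np.ndarray, SplineModel]:
    """restrict -> fit spline -> analytic d2 -> evaluate on grid.

    Returns (d2 values on the full grid, interior-row mask, fitted model).
    """
    _check_spans(s, grid)
    r = restrict_range(s, grid)
    model = fit_spline(r, place_knots(r, params), params)
    d2 = second_derivative(model)
    x = grid.points()
    mask = interior_mask(model, x, params.edge_exclude_spans)
    vals = np.asarray(d2(x))
    vals[~mask] = 0.0  # edge rows are dropped, never solved on
    return vals, mask, model


def build_library(
    components: Sequence[Spectrum],
    grid: SpectralGrid,
    params: SmoothingParams | None = None,
) -> ComponentLibrary:
    """Smooth, twice-differentiate and stack the three pure-constituent
    spectra into the unmixing design matrix.

    Rows flagged as spline edge regions (in any component) are dropped.  A
    condition number above 1e8 triggers a :class:`ConditioningWarning`.
    """
    params = params or SmoothingParams()
    if len(components) != 3:
        raise ValueError(f"expected exactly 3 component spectra, got {len(components)}")
    cols, masks = [], []
    for comp in components:
        vals, mask, _ = _d2_on_grid(comp, grid, params)
        cols.append(vals)
        masks.append(mask)
    keep = np.logical_and.reduce(masks)
    idx = np.flatnonzero(keep)
    E = np.column_stack(cols)[idx]
    names = tuple(c.sample_id or f"component_{i}" for i, c in enumerate(components))
    lib = ComponentLibrary(names=names, grid=grid, d2_matrix=E, grid_indices=idx)
    if not np.isfinite(lib.condition_number) or lib.condition_number > _COLLINEARITY_COND:
        warnings.warn(
            f"component library nearly collinear (condition number "
            f"{lib.condition_number:.3g})",
            ConditioningWarning,
            stacklevel=2,
        )
    return lib


def _qr_solve(E: np.ndarray, b: np.ndarray, names: Sequence[str]) -> tuple[np.ndarray, float]:
    """Least squares through a reduced QR factorisation."""
    norms = np.linalg.norm(E, axis=0)
    zero = np.flatnonzero(norms == 0)
    if len(zero) > 0:
        raise SolveError(f"component column {names[zero[0]]!r} is identically zero")
    # rank test on column-normalised matrix so disparate band amplitudes do
    # not masquerade as collinearity
    if np.linalg.cond(E / norms) > 1e10:
        worst, pair = 0.0, (0, 1)
        for i in range(E.shape[1]):
            for j in range(i + 1, E.shape[1]):
                cos = abs(E[:, i] @ E[:, j]) / (norms[i] * norms[j])
                if cos > worst:
                    worst, pair = cos, (i, j)
        raise SolveError(
            f"rank-deficient component matrix: columns {names[pair[0]]!r} and "
            f"{names[pair[1]]!r} are collinear (|cos| = {worst:.6f})"
        )
    Q, R = np.linalg.qr(E)
    c = solve_triangular(R, Q.T @ b)
    return c, float(np.linalg.norm(b - E @ c))


def solve_concentrations(
    d2A: np.ndarray,
    lib: ComponentLibrary,
    rows: np.ndarray | None = None,
    nonneg: bool = False,
) -> FeatureVector:
    """Solve ``min_c || E'' c - d2A ||_2`` by QR factorisation.

    ``d2A`` must be aligned with the library rows (length k).  ``rows``
    optionally restricts the solve to a subset of row positions.  With
    ``nonneg=True`` an active-set NNLS solution is returned instead.
    """
    d2A = np.asarray(d2A, dtype=float)
    E = lib.d2_matrix
    if len(d2A) != E.shape[0]:
        raise ValueError(
            f"d2A has {len(d2A)} rows but the library has {E.shape[0]}"
        )
    if rows is not None:
        E = E[rows]
        d2A = d2A[rows]
        if E.shape[0] < 3:
            raise SolveError("fewer than 3 rows selected for the solve")
    if nonneg:
        c, rnorm = nnls(E, d2A)
    else:
        c, rnorm = _qr_solve(E, d2A, lib.names)
    return FeatureVector(
        c_w=float(c[0]),
        c_c=float(c[1]),
        c_p=float(c[2]),
        residual_norm=rnorm,
        condition_number=float(np.linalg.cond(E)),
    )


def unmix(
    s: Spectrum,
    lib: ComponentLibrary,
    params: SmoothingParams | None = None,
    nonneg: bool = False,
) -> FeatureVector:
    """Full pipeline: restrict -> spline fit -> analytic d2 -> resample to the
    library grid -> drop edge rows -> QR least squares."""
    params = params or SmoothingParams()
    vals, mask, _ = _d2_on_grid(s, lib.grid, params)
    d2A = vals[lib.grid_indices]
    rows = np.flatnonzero(mask[lib.grid_indices])
    fv = solve_concentrations(d2A, lib, rows=rows, nonneg=nonneg)
    fv.sample_id = s.sample_id
    fv.group = s.group
    return fv


def window_stability(
    s: Spectrum,
    lib: ComponentLibrary,
    params: SmoothingParams | None = None,
    windows: Sequence[tuple[float, float]] | None = None,
) -> tuple[list[FeatureVector], dict]:
    """Re-solve the unmixing restricted to each spectral window.

    A stable solution barely moves across windows.  The dispersion summary
    reports, per component, the across-window standard deviation divided by
    the pooled mean magnitude, plus the worst case over components.
    """
    params = params or SmoothingParams()
    if windows is None:
        windows = [(lib.grid.lo, lib.grid.hi)]
    vals, mask, _ = _d2_on_grid(s, lib.grid, params)
    d2A = vals[lib.grid_indices]
    gx = lib.grid.points()
    results = []
    for lo, hi in windows:
        n_grid = int(np.count_nonzero((gx >= lo) & (gx <= hi)))
        if n_grid < 50:
            raise WindowError(
                f"window [{lo}, {hi}] contains only {n_grid} grid points (need >= 50)"
            )
        wn = gx[lib.grid_indices]
        rows = np.flatnonzero((wn >= lo) & (wn <= hi) & mask[lib.grid_indices])
        if len(rows) < 3:
            raise WindowError(
                f"window [{lo}, {hi}] leaves {len(rows)} usable rows (need >= 3)"
            )
        fv = solve_concentrations(d2A, lib, rows=rows)
        fv.sample_id = s.sample_id
        fv.group = s.group
        results.append(fv)
    V = np.array([fv.values for fv in results])
    sd = V.std(axis=0, ddof=1) if len(results) > 1 else np.zeros(3)
    pooled = np.mean(np.abs(V), axis=0)
    disp = sd / np.maximum(pooled, np.finfo(float).tiny)
    summary = {
        "per_component": dict(zip(("c_w", "c_c", "c_p"), disp.tolist())),
        "max": float(disp.max()),
        "n_windows": len(results),
    }
    return results, summary
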