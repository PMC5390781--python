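"""Cubic B-spline smoothing with tolerance-driven knot placement and
analytic second derivatives.

A spectrum A(nu) is represented as A(nu) = sum_i c_i B_{i,3}(nu) on a clamped
knot vector.  Interior knots are seeded from the data itself: consecutive
points whose absorbance values differ by at most a tolerance ``tau`` are
treated as redundant and each such run contributes a single candidate knot at
its midpoint.  The fit is ordinary least squares for the control points given
the knot vector, so the whole smoother is a fixed linear operator once the
knots are fixed — the property that makes second-derivative unmixing
baseline-exact and scale-equivariant downstream.

Second derivatives are taken analytically by applying the B-spline derivative
recurrence twice (coefficients differenced and rescaled by knot spans, degree
3 -> 1), not by finite differences of the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline, make_lsq_spline

from .errors import FitError
from .spectra_io import Spectrum

__all__ = [
    "SmoothingParams",
    "SplineModel",
    "place_knots",
    "estimate_noise",
    "fit_spline",
    "second_derivative",
    "interior_mask",
    "smooth_spectrum",
]

_DEGREE = 3


@dataclass
class SmoothingParams:
    """Controls for the B-spline smoother.

    Parameters
    ----------
    tau : float
        Redundancy tolerance in absorbance units: consecutive points with
        ``|dA| <= tau`` collapse into one candidate knot.  ``0`` keeps a
        candidate at every interior data point (knot vector then depends only
        on the wavenumber axis, keeping the smoother linear across samples).
    dof : int, "auto" or None
        Cap on the effective degrees of freedom (number of spline
        coefficients).  ``None`` leaves the tau-driven knots untouched;
        ``"auto"`` picks the smallest dof whose residual RMS does not exceed
        the noise estimate.
    noise_sd : float or "auto"
        Per-point noise level (AU) used by ``dof="auto"``; ``"auto"``
        estimates it from second differences of the data.
    edge_exclude_spans : int
        Number of knot spans at each boundary flagged as edge-affected and
        excluded from downstream unmixing.
    """

    tau: float = 0.0
    dof: int | str | None = None
    noise_sd: float | str = "auto"
    edge_exclude_spans: int = 3

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if isinstance(self.dof, int) and self.dof < 4:
            raise ValueError("dof must be at least 4 (cubic spline)")
        if isinstance(self.dof, str) and self.dof != "auto":
            raise ValueError("dof must be an int, None, or 'auto'")
        if isinstance(self.noise_sd, str) and self.noise_sd != "auto":
            raise ValueError("noise_sd must be a float or 'auto'")
        if self.edge_exclude_spans < 0:
            raise ValueError("edge_exclude_spans must be >= 0")


@dataclass
class SplineModel:
    """A B-spline in (knots, coefficients, degree) form.

    ``len(knots) == len(coefficients) + degree + 1`` always holds; degree is 3
    for a fresh fit and 1 after double differentiation.
    """

    degree: int
    knots: np.ndarray
    coefficients: np.ndarray
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.knots) != len(self.coefficients) + self.degree + 1:
            raise ValueError(
                f"knot/coefficient bookkeeping violated: {len(self.knots)} knots, "
                f"{len(self.coefficients)} coefficients, degree {self.degree}"
            )
        if np.any(np.diff(self.knots) < 0):
            raise ValueError("knots must be non-decreasing")

    def __call__(self, x: np.ndarray | float) -> np.ndarray:
        return BSpline(self.knots, self.coefficients, self.degree, extrapolate=False)(x)

    def _bspline(self) -> BSpline:
        return BSpline(self.knots, self.coefficients, self.degree)

    @property
    def breakpoints(self) -> np.ndarray:
        """Distinct knot values inside the domain (span boundaries)."""
        lo, hi = self.domain
        t = self.knots
        return np.unique(t[(t >= lo) & (t <= hi)])


def place_knots(s: Spectrum, params: SmoothingParams) -> np.ndarray:
    """Seed interior knot candidates from the redundancy structure of the data.

    Consecutive points whose absorbance difference is ``<= tau`` form a run;
    each run collapses to its midpoint wavenumber (lower-index midpoint for
    even-length runs).  Candidates coinciding with the boundary wavenumbers
    are dropped, and a single run covering the whole spectrum yields no
    interior knots at all (the data carry no resolvable feature).
    """
    x, y = s.axis, s.absorbance
    if len(np.unique(x)) < _DEGREE + 1:
        raise FitError(
            f"need at least {_DEGREE + 1} distinct wavenumbers, got {len(np.unique(x))}"
        )
    tau = params.tau
    # run-length scan over |dy| <= tau
    starts = [0]
    for i in range(1, len(y)):
        if abs(y[i] - y[i - 1]) > tau:
            starts.append(i)
    starts.append(len(y))
    if len(starts) == 2:  # one run spans everything: boundary knots only
        return np.empty(0)
    mids = []
    for a, b in zip(starts[:-1], starts[1:]):
        mid = a + (b - a - 1) // 2
        mids.append(x[mid])
    knots = np.asarray(mids, dtype=float)
    return knots[(knots > x[0]) & (knots < x[-1])]


def estimate_noise(s: Spectrum) -> float:
    """Robust per-point noise estimate from second differences.

    For iid Gaussian noise of sd ``sigma`` riding on a smooth trend, the
    second differences have sd ``sigma * sqrt(6)``; a median-absolute-deviation
    estimate of that quantity is rescaled accordingly
    (``1.4826 * MAD(d2) / sqrt(6)``).
    """
    if len(s) < 5:
        raise ValueError("need at least 5 points to estimate noise")
    d2 = np.diff(s.absorbance, n=2)
    mad = np.median(np.abs(d2 - np.median(d2)))
    return float(1.4826 * mad / np.sqrt(6.0))


def _clamped_vector(x: np.ndarray, interior: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [np.repeat(x[0], _DEGREE + 1), interior, np.repeat(x[-1], _DEGREE + 1)]
    )


def _coarsen(interior: np.ndarray, n_keep: int) -> np.ndarray:
    """Uniformly thin a candidate knot list down to ``n_keep`` entries."""
    if n_keep <= 0:
        return np.empty(0)
    if len(interior) <= n_keep:
        return interior
    idx = np.unique(np.round(np.linspace(0, len(interior) - 1, n_keep)).astype(int))
    return interior[idx]


def _sw_feasible(x: np.ndarray, t: np.ndarray) -> bool:
    """Schoenberg-Whitney check: each basis support must hold a data point
    (boundary supports may rely on the clamped endpoints); otherwise the
    least-squares design is singular."""
    n_coef = len(t) - _DEGREE - 1
    lo = t[:n_coef]
    hi = t[_DEGREE + 1 :]
    counts = np.searchsorted(x, hi, side="left") - np.searchsorted(x, lo, side="right")
    counts[0] += 1  # x[0] == t[0] supports the first basis at a clamped end
    counts[-1] += 1  # x[-1] == t[-1] supports the last basis
    return bool(np.all(counts > 0))


def _lsq_fit(x: np.ndarray, y: np.ndarray, interior: np.ndarray) -> BSpline:
    t = _clamped_vector(x, interior)
    if not _sw_feasible(x, t):
        raise np.linalg.LinAlgError("Schoenberg-Whitney conditions violated")
    spl = make_lsq_spline(x, y, t, k=_DEGREE)
    if not np.all(np.isfinite(spl.c)):
        raise np.linalg.LinAlgError("singular spline design")
    return spl


def fit_spline(
    s: Spectrum,
    knots: Sequence[float] | np.ndarray,
    params: SmoothingParams,
) -> SplineModel:
    """Least-squares cubic B-spline fit on a (possibly coarsened) knot vector.

    The control points minimise the sum of squared residuals given the knots.
    If an integer ``params.dof`` is set, interior knots are thinned uniformly
    until the coefficient count does not exceed it; ``dof="auto"`` scans a
    ladder of coefficient counts and keeps the smallest whose residual RMS is
    within the noise estimate.  Noiseless polynomial data of degree <= 3 are
    reproduced exactly for any admissible knots.
    """
    x, y = s.axis, s.absorbance
    if len(np.unique(x)) < _DEGREE + 1:
        raise FitError(
            f"need at least {_DEGREE + 1} distinct wavenumbers, got {len(np.unique(x))}"
        )
    interior = np.asarray(knots, dtype=float)
    # interior knots strictly inside (x[1], x[-2]): the boundary-adjacent data
    # points must support the clamped end baskets or the design is singular
    interior = interior[(interior > x[1]) & (interior < x[-2])]
    # feasibility: n_coef = n_interior + degree + 1 must not exceed n_data
    max_interior = len(x) - (_DEGREE + 1)
    interior = _coarsen(interior, max_interior)

    if params.dof == "auto":
        target = params.noise_sd
        if target == "auto":
            target = estimate_noise(s)
        best = None
        n_full = len(interior) + _DEGREE + 1
        ladder = np.unique(
            np.round(np.geomspace(_DEGREE + 1, max(n_full, _DEGREE + 2), 12)).astype(int)
        )
        for dof in ladder:
            try:
                cand = _lsq_fit(x, y, _coarsen(interior, dof - (_DEGREE + 1)))
            except np.linalg.LinAlgError:
                continue
            rms = float(np.sqrt(np.mean((cand(x) - y) ** 2)))
            best = cand
            if rms <= target:
                break
        if best is None:
            raise FitError("auto-dof search failed; consider a larger tau")
        spl = best
    else:
        if isinstance(params.dof, int):
            interior = _coarsen(interior, params.dof - (_DEGREE + 1))
        spl = None
        n_try = len(interior)
        for _ in range(10):
            try:
                spl = _lsq_fit(x, y, _coarsen(interior, n_try))
                break
            except np.linalg.LinAlgError:
                n_try = int(n_try * 0.8)
        if spl is None:
            raise FitError(
                "rank-deficient spline design (too many knots for the data); "
                "consider a larger tau"
            )
    return SplineModel(
        degree=_DEGREE,
        knots=np.asarray(spl.t, dtype=float),
        coefficients=np.asarray(spl.c, dtype=float),
        domain=(float(x[0]), float(x[-1])),
    )


def second_derivative(m: SplineModel) -> SplineModel:
    """Analytic second derivative of a fitted cubic spline.

    Applies the B-spline derivative recurrence twice: the new control points
    are scaled differences of the originals over knot spans and the degree
    drops 3 -> 1.  Values equal d2A/dnu2 of the fitted spline everywhere in
    the interior of the domain.
    """
    if m.degree != _DEGREE:
        raise ValueError(f"expected a degree-{_DEGREE} model, got degree {m.degree}")
    d2 = m._bspline().derivative(2)
    t = np.asarray(d2.t, dtype=float)
    c = np.asarray(d2.c, dtype=float)[: len(t) - d2.k - 1]  # drop scipy's zero padding
    return SplineModel(degree=d2.k, knots=t, coefficients=c, domain=m.domain)


def interior_mask(
    m: SplineModel, x: np.ndarray, edge_exclude_spans: int = 3
) -> np.ndarray:
    """Boolean mask of ``x`` at least ``edge_exclude_spans`` knot spans from
    either boundary; spline edge effects concentrate in the excluded bands."""
    breaks = m.breakpoints
    n_spans = len(breaks) - 1
    eff = min(edge_exclude_spans, max((n_spans - 1) // 2, 0))
    lo, hi = breaks[eff], breaks[-1 - eff]
    return (x >= lo) & (x <= hi)


def smooth_spectrum(
    s: Spectrum, params: SmoothingParams | None = None
) -> SplineModel:
    """Convenience wrapper: place knots then fit, with default parameters."""
    params = params or SmoothingParams()
    return fit_spline(s, place_knots(s, params), params)
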