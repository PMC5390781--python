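"""Synthetic NIR spectra and feature clusters for end-to-end testing.

Real cartilage NIR measurements are not distributed with the package, so every
stage of the pipeline is exercised against generated data with known ground
truth:

* pure-constituent spectra (water, collagen, proteoglycan) as sums of
  Gaussian bands with broad, overlapping band structure;
* mixture spectra following the Beer-Lambert forward model
  ``A = l * (c_w e_w + c_c e_c + c_p e_p)`` plus an additive baseline
  (offset + slope * nu) and iid Gaussian instrument noise;
* three-dimensional concentration feature clusters for the normal and
  trypsin-degraded tissue states, parameterised by the reported per-group
  means and standard deviations.

The default band tables place the dominant water bands near 5180 and
6900 cm^-1 and the organic (collagen / chondroitin sulphate) bands mostly in
the 4000-5000 cm^-1 combination region; they are illustrative of the
overlapping-band geometry of real constituent spectra, not spectroscopically
calibrated.  All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra_io import DEFAULT_GRID, SpectralGrid, Spectrum

__all__ = [
    "BandSpec",
    "ComponentSpec",
    "MixtureSpec",
    "GroupSpec",
    "StudyConfig",
    "default_component_specs",
    "cartilage_cluster_specs",
    "make_component",
    "make_mixture",
    "make_feature_dataset",
    "make_study",
]

COMPONENT_NAMES = ("water", "collagen", "proteoglycan")


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: amplitude * exp(-(nu-center)^2 / 2 width^2)."""

    center: float  # cm^-1
    width: float  # cm^-1, Gaussian sd
    amplitude: float  # AU

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")


@dataclass(frozen=True)
class ComponentSpec:
    name: str
    bands: tuple[BandSpec, ...]

    def __post_init__(self) -> None:
        if len(self.bands) < 2:
            raise ValueError("a component needs at least 2 bands")
        for b in self.bands:
            if not (4000.0 < b.center < 10000.0):
                raise ValueError(
                    f"band center {b.center} outside the (4000, 10000) cm^-1 window"
                )


def default_component_specs() -> tuple[ComponentSpec, ComponentSpec, ComponentSpec]:
    """Water / collagen / proteoglycan band tables (illustrative)."""
    water = ComponentSpec(
        "water",
        (
            BandSpec(5180.0, 160.0, 1.00),  # O-H combination
            BandSpec(6900.0, 140.0, 0.65),  # O-H first overtone
            BandSpec(8350.0, 260.0, 0.18),
        ),
    )
    collagen = ComponentSpec(
        "collagen",
        (
            BandSpec(4330.0, 90.0, 0.85),  # C-H combination
            BandSpec(4610.0, 110.0, 0.55),  # N-H/amide combination
            BandSpec(5800.0, 170.0, 0.40),  # C-H first overtone
            BandSpec(6680.0, 220.0, 0.22),  # N-H first overtone
        ),
    )
    proteoglycan = ComponentSpec(
        "proteoglycan",
        (
            BandSpec(4240.0, 85.0, 0.70),
            BandSpec(4890.0, 130.0, 0.50),
            BandSpec(5650.0, 150.0, 0.30),
            BandSpec(7050.0, 240.0, 0.15),
        ),
    )
    return water, collagen, proteoglycan


def make_component(spec: ComponentSpec, grid: SpectralGrid = DEFAULT_GRID) -> Spectrum:
    """Render a pure-constituent spectrum on a grid (deterministic)."""
    nu = grid.points()
    a = np.zeros_like(nu)
    for b in spec.bands:
        a += b.amplitude * np.exp(-0.5 * ((nu - b.center) / b.width) ** 2)
    return Spectrum(nu, a, sample_id=spec.name, group=None)


@dataclass(frozen=True)
class MixtureSpec:
    """Forward-model parameters for one tissue-like mixture spectrum."""

    concentrations: tuple[float, float, float]  # (c_w, c_c, c_p)
    path_length: float = 1.0  # mm-equivalent scale factor l
    baseline: tuple[float, float] = (0.0, 0.0)  # (offset AU, slope AU per cm^-1)
    noise_sd: float = 0.0  # AU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.path_length <= 0:
            raise ValueError("path_length must be > 0")


def make_mixture(
    components: tuple[Spectrum, Spectrum, Spectrum] | list[Spectrum],
    spec: MixtureSpec,
    grid: SpectralGrid = DEFAULT_GRID,
) -> tuple[Spectrum, dict]:
    """Beer-Lambert mixture of three constituents plus baseline and noise.

    Returns the spectrum and a ground-truth record of every forward-model
    parameter.  Identical (spec, grid) inputs give bit-identical output.
    """
    if len(components) != 3:
        raise ValueError("expected exactly 3 component spectra")
    nu = grid.points()
    for comp in components:
        if not np.array_equal(comp.axis, nu):
            raise ValueError(f"component {comp.sample_id!r} is not on the target grid")
    c = np.asarray(spec.concentrations, dtype=float)
    E = np.column_stack([comp.absorbance for comp in components])
    a = spec.path_length * (E @ c)
    offset, slope = spec.baseline
    a = a + offset + slope * nu
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        a = a + rng.normal(0.0, spec.noise_sd, size=nu.shape)
    truth = {
        "c_w": float(c[0]),
        "c_c": float(c[1]),
        "c_p": float(c[2]),
        "path_length": spec.path_length,
        "offset": offset,
        "slope": slope,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return Spectrum(nu, a, sample_id=f"mix_seed{spec.seed}", meta=dict(truth)), truth


@dataclass(frozen=True)
class GroupSpec:
    """Diagonal-Gaussian cluster of (c_w, c_c, c_p) feature vectors."""

    label: str
    mean: tuple[float, float, float]
    sd: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sd):
            raise ValueError("group sds must be > 0 componentwise")


def cartilage_cluster_specs() -> tuple[GroupSpec, GroupSpec]:
    """Reported concentration clusters for normal and trypsin-degraded bovine
    cartilage: degradation raises apparent water and depletes collagen and
    proteoglycan."""
    normal = GroupSpec("normal", (0.1418, 0.5949, 0.5571), (0.0169, 0.0446, 0.0517))
    degraded = GroupSpec("degraded", (0.4052, 0.2486, 0.2237), (0.0346, 0.0316, 0.0237))
    return normal, degraded


def make_feature_dataset(
    groups: list[GroupSpec] | tuple[GroupSpec, ...],
    n_per_group: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw iid feature vectors from each group's diagonal Gaussian.

    Returns ``(features, labels)`` with features of shape
    ``(len(groups) * n_per_group, 3)``.
    """
    if n_per_group < 4:
        raise ValueError("need at least 4 samples per group")
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for g in groups:
        feats.append(rng.normal(g.mean, g.sd, size=(n_per_group, 3)))
        labels.extend([g.label] * n_per_group)
    return np.vstack(feats), np.asarray(labels)


@dataclass(frozen=True)
class StudyConfig:
    """Forward-model nuisance parameters for a full synthetic study.

    Defaults emulate averaged FT-NIR acquisition: ~5e-4 AU noise, and a
    systematic between-state baseline offset (degraded spectra recorded at a
    visibly higher raw level) with small per-sample jitter.
    """

    noise_sd: float = 5e-4
    offsets: dict = field(default_factory=lambda: {"normal": 0.08, "degraded": 0.35})
    offset_jitter: float = 0.03
    slope_sd: float = 2e-6  # AU per cm^-1
    path_length: float = 1.0


def make_study(
    n_per_group: int = 145,
    seed: int = 0,
    config: StudyConfig | None = None,
    grid: SpectralGrid = DEFAULT_GRID,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Spectral-domain analogue of a two-state cartilage degradation study.

    Per-sample concentrations are drawn from the normal/degraded clusters and
    rendered through the Beer-Lambert forward model with group-dependent
    baseline offsets, per-sample slopes and instrument noise.  Returns the
    spectra (group label attached) and a ground-truth table.
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(seed)
    components = [make_component(cs, grid) for cs in default_component_specs()]
    spectra: list[Spectrum] = []
    rows = []
    for g in cartilage_cluster_specs():
        conc = rng.normal(g.mean, g.sd, size=(n_per_group, 3))
        for i in range(n_per_group):
            offset = config.offsets.get(g.label, 0.0) + rng.normal(0.0, config.offset_jitter)
            slope = rng.normal(0.0, config.slope_sd)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            mspec = MixtureSpec(
                concentrations=tuple(conc[i]),
                path_length=config.path_length,
                baseline=(offset, slope),
                noise_sd=config.noise_sd,
                seed=sub_seed,
            )
            s, truth = make_mixture(components, mspec, grid)
            s.sample_id = f"{g.label}_{i:03d}"
            s.group = g.label
            spectra.append(s)
            rows.append({"sample_id": s.sample_id, "group": g.label, **truth})
    return spectra, pd.DataFrame(rows)
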