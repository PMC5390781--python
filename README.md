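# nirmix

Constituent-based preprocessing of near-infrared (NIR) absorbance spectra for
tissue characterisation.

NIR spectra of soft tissues are high-dimensional (hundreds of correlated
absorbance values) with broad, overlapping bands, which makes direct
classification data-hungry and hard to interpret. `nirmix` projects each
spectrum onto a three-dimensional, physically meaningful feature space — the
relative concentrations of the main extracellular-matrix constituents water,
collagen and proteoglycan — and classifies tissue states in that space. The
motivating application is detecting enzymatic (trypsin) degradation of
articular cartilage, a model of early osteoarthritic change, from
arthroscopically acquirable NIR measurements.

## Method

1. **B-spline smoothing.** Each absorbance trace on the 4000–10000 cm⁻¹
   analysis grid (779 points) is fitted with a clamped cubic B-spline,
   A(ν) = Σᵢ cᵢ B_{i,3}(ν). Interior knots are seeded from the data: runs of
   consecutive points whose absorbance differs by at most a tolerance τ
   collapse to a single knot, and the knot count can be capped by an explicit
   degrees-of-freedom target or matched to a robust noise estimate.
2. **Analytic second derivative.** d²A/dν² is obtained by applying the
   B-spline derivative recurrence twice (degree 3 → 1). Differentiating twice
   annihilates constant and linear baselines exactly, removing the systematic
   offsets between acquisition sessions.
3. **Beer–Lambert unmixing (CLS).** With pure-component second-derivative
   absorptivities ε″_w, ε″_c, ε″_p stacked as the columns of E″, the mixture
   model d²A = E″·(c_w, c_c, c_p)ᵀ·l is solved by QR least squares over the
   grid rows (spline edge regions excluded). The optical path length l is
   unknown in vivo and fixed at 1, so concentrations are relative.
4. **Mahalanobis classification.** Each group (normal / degraded) is
   summarised by its feature-space mean μ and covariance S; a sample x is
   assigned to the group with the smaller D² = (x−μ)ᵀS⁻¹(x−μ). D² is
   invariant under common invertible linear maps of the feature space, so the
   arbitrary overall scale introduced by fixing l = 1 cannot affect the
   classification — a claim the package verifies both algebraically (scale
   equivariance of the solve) and by a Monte-Carlo experiment that assigns
   every sample an independent random path length (truncated normal,
   μ = 1.66 mm, σ = 0.25 mm, the thickness of bovine patellar cartilage) and
   re-classifies subsamples repeatedly.

Because no raw tissue spectra are distributed, the `nirmix.synthetic` module
generates the full study end-to-end: Gaussian-band constituent spectra,
Beer–Lambert mixtures with baselines and instrument noise, and two-cluster
feature datasets parameterised by the published per-group concentration
statistics.

## Worked example

```python
import numpy as np
from nirmix import DEFAULT_GRID, build_library, unmix, classify_loo
from nirmix.synthetic import default_component_specs, make_component, make_study

grid = DEFAULT_GRID                      # 4000-10000 cm^-1, 779 points
components = [make_component(spec, grid) for spec in default_component_specs()]
library = build_library(components, grid)
print(f"library: {library.d2_matrix.shape[0]} usable grid rows, "
      f"condition number {library.condition_number:.3f}")

spectra, truth = make_study(n_per_group=30, seed=42)
features = np.array([unmix(s, library).values for s in spectra])
labels = np.array([s.group for s in spectra])

row = truth.iloc[0]
print(f"sample {row.sample_id}: true (c_w, c_c, c_p) = "
      f"({row.c_w:.4f}, {row.c_c:.4f}, {row.c_p:.4f}), "
      f"estimated = ({features[0,0]:.4f}, {features[0,1]:.4f}, {features[0,2]:.4f})")

result = classify_loo(features, labels)
print(f"leave-one-out: {result.false_pos} false positive(s), "
      f"{result.false_neg} false negative(s) of {result.total} samples "
      f"(accuracy {result.accuracy:.4f})")
```

Output:

```
library: 771 usable grid rows, condition number 1.651
sample normal_000: true (c_w, c_c, c_p) = (0.1469, 0.5485, 0.5959), estimated = (0.1466, 0.5486, 0.5937)
leave-one-out: 0 false positive(s), 0 false negative(s) of 60 samples (accuracy 1.0000)
```

The library's condition number near 1 says the three second-derivative
component spectra are well separated, the per-sample estimates track the
generator's ground-truth concentrations to a few parts in a thousand despite
baseline offsets and noise, and the two tissue states separate perfectly in
the concentration space.

The same workflow is available from the shell:

```sh
nirmix simulate --n-per-group 30 --seed 42 --out sim/
nirmix unmix --spectra sim/samples.csv \
    --components sim/water.csv,sim/collagen.csv,sim/proteoglycan.csv \
    --truth sim/truth.csv --out features.csv
nirmix classify --features features.csv --protocol loo --out report.json
nirmix robustness --features features.csv --repeats 100 --seed 1 --out robustness.json
```

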