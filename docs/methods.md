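# Methods

This note records the models implemented in `nirmix`, the parameter choices
that matter, the numerical conventions, and what the synthetic data can and
cannot show about real measurements.

## Spectral model and smoothing

A spectrum is a set of absorbance values A(νᵢ) on a strictly increasing
wavenumber axis (cm⁻¹). The analysis grid is uniform over 4000–10000 cm⁻¹
with 779 points (grid spacing ≈ 7.71 cm⁻¹), configurable via `SpectralGrid`.
Inputs recorded in nm are converted by ν = 10⁷/λ and re-sorted on read.

Smoothing fits a clamped cubic B-spline by ordinary least squares on a knot
vector seeded from the data. The knot rule: consecutive points whose
absorbance values differ by at most τ (absorbance units) are redundant; each
maximal redundant run contributes one candidate knot at its midpoint
(lower-index midpoint for even runs). Two degenerate conventions follow from
this rule: a run covering the whole spectrum yields no interior knots (the
data carry no resolvable feature), and candidates coinciding with the
boundary wavenumbers are dropped because the clamped boundary knots already
cover them. Interior knots are further restricted to lie strictly inside
(x₁, x_{n−2}) and checked against the Schoenberg–Whitney conditions; designs
that violate them are thinned until feasible, so the least-squares problem is
always full rank.

Three knobs control smoothness:

* `tau` (AU, default 0): the redundancy tolerance. The default keeps a knot
  at every interior grid point, which makes the knot vector — and therefore
  the entire fit → differentiate → solve pipeline — a *fixed linear operator*
  for all spectra sharing an axis. Linearity is the property the downstream
  guarantees (exact recovery, baseline annihilation, scale equivariance) rest
  on, so the default trades smoothing for exactness and lets the
  least-squares unmixing average the noise instead.
* `dof` (default None): a cap on the number of spline coefficients; interior
  knots are thinned uniformly until the cap is met. `dof="auto"` scans a
  geometric ladder of coefficient counts and keeps the smallest whose
  residual RMS is within the noise estimate.
* `noise_sd` (AU, default `"auto"`): estimated as 1.4826·MAD(Δ²A)/√6 — for
  iid Gaussian noise riding on a smooth trend the second differences have
  standard deviation σ√6, and the median absolute deviation makes the
  estimate robust to the trend itself.

The second derivative is taken analytically: the B-spline derivative
recurrence applied twice yields a degree-1 spline whose coefficients are
scaled differences of the original control points over knot spans.
Derivatives are with respect to wavenumber; since differentiation is linear
and all spectra share the convention, the unmixing is unaffected by the
choice of axis variable. Within `edge_exclude_spans` (default 3) knot spans
of either boundary the fitted curvature is dominated by clamped-end effects;
those grid rows are flagged and excluded from every linear solve.

## Unmixing

The Beer–Lambert model for a three-constituent mixture,
A(ν) = c_w·l·ε_w(ν) + c_c·l·ε_c(ν) + c_p·l·ε_p(ν), becomes after double
differentiation an overdetermined linear system E″·c = d²A over the usable
grid rows, with the second-derivative pure-component spectra as columns.
The solve is least squares through a reduced QR factorisation (never the
normal equations; those appear only as the independent oracle in tests).
Rank problems are detected on the column-normalised matrix (condition number
above 1e10) so that genuinely collinear components are reported by name while
legitimate amplitude disparities between constituents are not mistaken for
collinearity. Each solution carries its residual norm and the condition
number of the solved design.

Conventions: measured pure-component absorbance stands in for absorptivity,
so concentrations are relative to the pure standards; chondroitin sulphate is
the proteoglycan standard; the path length is fixed at l = 1 (unknown in
arthroscopy), making every feature vector determined up to a per-sample
scale; no non-negativity constraint is applied by default (negative estimates
are diagnostic, not clipped), with an NNLS option available; rows are
unweighted.

Solution stability can be probed with `window_stability`, which re-solves the
system restricted to spectral windows (each at least 50 grid points) and
summarises the across-window dispersion per component as sd divided by pooled
mean magnitude. Windows above ≈ 8500 cm⁻¹ contain only band tails of the
organic constituents in the synthetic design and are poorly conditioned;
stability checks should use windows that retain signal from all three
constituents.

## Classification

Each group is summarised by its sample mean and covariance (denominator
n − 1, minimum group size 4; a singular covariance raises an error naming the
deficient direction unless a ridge is requested). D² is computed through a
Cholesky solve. A sample joins the group with the smaller D²; exact ties go
to "normal" with a warning. The positive class is "degraded", so a false
positive is a normal sample labelled degraded, and percentages are taken over
the grand total of classified samples. Because no held-out protocol is
inherent to the method, the package offers both resubstitution and
leave-one-out (each sample scored against models refitted without it);
leave-one-out is the default in the CLI and in the acceptance computation,
being the less optimistic of the two.

D² is invariant under any common invertible affine map of the feature space.
A shared path-length scale is the special case that justifies fixing l = 1.

## Path-length robustness experiment

Per-sample path lengths are drawn iid from a normal distribution with
μ = 1.66 mm and σ = 0.25 mm — the thickness distribution of the bovine
patellar cartilage the method was developed on — truncated below at 0.1 mm
as a safety contract against non-physical draws (the untruncated probability
of such draws is ≈ 10⁻¹⁰). Each of `n_repeats` (default 100) repeats scales
every sample's features by its own length, draws a fresh subsample of
`subsample_fraction` (default 2/3) of each cluster without replacement,
refits both group models on the subsample (a `fixed_models` toggle reuses the
unscaled full-data models instead), classifies the subsample, and records the
confusion counts. The number of repeats and the subsample fraction are
independent knobs. Summaries report the mode (smallest modal value, with all
modes listed), min and max of each count and percentage, and the scaled
cluster mean ± sd both across pooled samples and across per-repeat means,
since either reading of "±" is defensible. The whole report is a pure
function of the seed.

## Synthetic data

Constituent spectra are sums of Gaussian bands (chosen over Lorentzian/Voigt
shapes because they are adequate for exercising the linear algebra and have
closed-form derivatives for cross-checks). The default tables put the
dominant water bands near 5180 and 6900 cm⁻¹ and the collagen/chondroitin
bands mostly in the 4000–5000 cm⁻¹ combination region; they reproduce the
qualitative overlapping-band geometry of real constituent spectra but are
not spectroscopically calibrated. The default library's second-derivative
columns have pairwise correlations below 0.95 and condition number ≈ 1.65,
i.e. the design is identifiable.

Mixtures follow the Beer–Lambert forward model plus an additive baseline
(offset + slope·ν) and iid Gaussian noise. Study defaults: 145 samples per
state (matching the scale of the motivating experiment), noise sd 5·10⁻⁴ AU
(representative of multi-scan-averaged FT-NIR acquisition), group baseline
offsets 0.08 AU (normal) and 0.35 AU (degraded) with 0.03 AU jitter —
emulating the systematic between-session offsets seen in raw tissue spectra —
and slope sd 2·10⁻⁶ AU/cm⁻¹. Feature clusters use the published per-group
means and standard deviations (normal: 0.1418 ± 0.0169, 0.5949 ± 0.0446,
0.5571 ± 0.0517; degraded: 0.4052 ± 0.0346, 0.2486 ± 0.0316,
0.2237 ± 0.0237) with diagonal covariance, since only per-component spreads
are published; full covariances are accepted when supplied.

What the synthetic data do **not** emulate: scattering and its coupling to
path length, instrument line-shape and detector nonlinearity, water-band
saturation, correlated (pink) noise, and the pseudo-replication of multiple
measurement sites on the same joint. Passing tests therefore demonstrate the
correctness and numerical robustness of the algorithms under the stated
forward model, not clinical performance. In particular the two published
clusters are > 7σ apart along the water axis, so the simulation surrogate of
the classification claim yields zero errors at n = 145 per group — comfortably
within the published error rates, but a statement about cluster geometry, not
about real spectra.

## Numerical choices and limitations

* Interpolation-grade default knots make the pipeline exact for noiseless
  linear mixtures (recovery to ~1e−10 relative) but amplify high-frequency
  noise in d²A by ~1/h²; the 700-plus-row least-squares solve averages this
  noise, and the error grows linearly in the noise sd (verified by test).
* Acceptance-scale problem sizes: 100 mixtures for exact recovery, 20 random
  band sums for the derivative oracle, 200 draws per noise level for
  monotonicity, 145 samples per group for the classification surrogate, 100
  repeats for the robustness experiment — each completes in seconds on one
  CPU.
* Finite-difference verification of the analytic second derivative is done
  at knot-span midpoints, where the central second difference of a cubic
  polynomial is exact; stencils straddling knots would add an O(h·|Δf‴|)
  term that reflects the stencil, not the derivative.
* The edge-exclusion default of 3 spans was chosen to cover the support of
  the boundary-clamped basis functions after double differentiation.
* Ties in Mahalanobis distance are resolved toward "normal" (conservative
  for a disease detector: ambiguity does not raise an alarm).
* Classification treats measurement points as independent samples even when
  several derive from one joint; no clustering correction is applied, which
  overstates effective sample size for real multi-site data.
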