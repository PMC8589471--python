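# Methods

## The measurement problem

A tight proximal contact between a first and second molar is characterized
by five quantities: the length of the dividing (adjacent) line between the
teeth in occlusal view, the area of the contact facet on the vertical
partition plane, and the opening angles of the lingual, buccal and
occlusal embrasures. All of them are defined on a *segmented pair* — a 3D
surface point cloud in which every point carries a tooth label — in a
canonical frame with x mesiodistal, y buccolingual (+y buccal) and z
occlusal, all coordinates in millimetres. Inputs that are not pre-aligned
can be brought into this frame with `geometry.normalize_frame` (inter-
centroid axis → x, supplied or PCA-derived occlusal direction → z).

## Synthetic molar pairs

No raw scans ship with the package; the generator in
`interprox.synthetic` produces pairs whose features are known exactly.

Each crown is a superellipse cylinder (exponent 4 — the squarish, rounded
occlusal outline of a molar; defaults 10 mm mesiodistal × 11 mm
buccolingual × 8 mm tall). Its mesial face is carved back to a recession
surface `x = f(y, z)` that is exactly zero on a rectangular contact facet
(width = the ground-truth adjacent line length, height = area/width,
vertically centred) and rises as planar chamfers outside it, the chamfer
slopes chosen as tan(θ/2) of the requested embrasure angles. The mesial
tooth is the mirror image about the contact plane, so the dihedral opening
on each side of the facet equals the requested angle and the two flat
facets coincide — an idealized tight contact. A fixed 80° cervical
opening bounds the facet from below without adding a parameter.

Point budget (default 30,000 per tooth): 45% in an interproximal window
extending 1.8 mm beyond the facet rim, the rest split over the lateral
wall, the remaining mesial face and the caps in rough area proportion.
The densified window emulates the high effective resolution that
curvature-weighted acquisition concentrates on the contact region, and
gives the contact a point spacing of ~0.05 mm. Isotropic Gaussian jitter
(default 0.02 mm, the scale of intraoral-scanner noise) is added last.

What the generator does *not* emulate: anatomical cusps and grooves,
curved (non-planar) embrasure walls, wear facets, plaster/impression
artifacts, and segmentation errors at the tooth boundary. Passing
recovery tests therefore demonstrates correctness of the measurement
definitions and robustness to sampling and isotropic noise — not
performance on clinical segmentations.

Cohort tables are drawn per group from independent normal distributions
with the published means and SDs (250 subjects per group by default); an
optional correlation matrix is applied through a Gaussian copula. The
outcome is either the group label or a Bernoulli draw from a supplied
logistic model.

## Feature measurement

**Contact selection.** For each point of one tooth, the gap to the other
tooth is the distance to the plane fitted over the 12-neighborhood of its
nearest cross-tooth point. Point-to-plane gaps are unbiased under point
jitter, unlike nearest-point distances whose minimum-of-many bias grows
with sampling density; a fitted plane is only trusted when the queried
point projects inside the neighborhood's footprint (guarding against
planes extrapolated across creases). Points with gap ≤ `contact_eps`
(default 0.1 mm, bounding the < 60 µm clinical tightness criterion with
room for noise) are collapsed to gap midpoints.

**Denoising.** Clouds whose estimated jitter (median out-of-plane residual
of local plane fits) exceeds 0.012 mm are first smoothed by
moving-least-squares projection (k = 20), reducing jitter by ~1/√k at the
cost of rounding creases over the neighborhood radius. `denoise="auto"`
(default) applies this only when needed, so noise-free input is measured
untouched.

**Dividing line.** Contact midpoints are projected to the occlusal plane
and ordered along their principal direction. Any threshold rule admits a
selection band of width ≈ eps / (2 sin(θ/2)) along the embrasures beyond
the true facet, which would inflate the line by several percent. The line
ends are therefore refined: a coarse kink of the gap-versus-position
profile locates each edge, and the final end is the intersection of
total-least-squares line fits to the two embrasure flanks just beyond it
(planar walls project to straight flanks, and TLS stays unbiased under
jitter). When the profile never rises above its floor — contact extending
to the edge of the data — the full midpoint extent is kept. Candidates
along the orthogonal embrasures (e.g. the occlusal band when measuring
the horizontal line) are excluded by restricting to the orthogonal core
of the contact. A contiguity rule drops stray midpoints separated from
the dense run. The adjacent line length is the distance between the two
farthest boundary points (equal, by construction, to the maximum pairwise
distance over the boundary).

**Abduction gap angles.** Each line end is extended outward by
`extension_len` (default 1.5 mm — long enough that residual jitter in the
vertex and arms moves the angle little, short enough to stay on the
near-planar embrasure walls); the nearest projected point of each tooth
to the extension point forms one arm, and the angle between the arms at
the end is the embrasure opening. "Nearest point" is made jitter-robust
by taking the median of all points within 0.08 mm of the nearest
distance — a short arc of the flank around the perpendicular foot. The
end with larger y is buccal. The occlusal angle repeats the construction
in the vertical (xz) projection with the maximum-z end of the recomputed
dividing line as vertex.

**Adjacent surface area.** Contact midpoints are projected onto the
vertical partition plane (principal in-plane direction of the contact ×
z). The facet region is the alpha-complex (Delaunay triangles with
circumradius ≤ `alpha`, default 0.5 mm; convex hull fallback when the
complex is empty) of the midpoints below a gap threshold. Two corrections
remove the systematic biases of that estimate: the area is evaluated at
two thresholds above the gap noise floor and extrapolated linearly back
to the floor (cancelling the selection band along the embrasure walls),
and each evaluation adds perimeter × half the point spacing (a sampled
region loses about half a spacing at its rim; the constant was verified
on uniformly sampled rectangles of known area). The thresholds (45% and
90% of the way from the floor to `contact_eps`) sit above the crease-blur
zone of the local plane fits, where the area-versus-threshold relation is
linear.

**Measured accuracy** (random specs, widths 2–5 mm, heights 1.2–2.6 mm,
angles 35–120°): at zero noise the median relative error of every feature
is below 0.4%; at 0.05 mm jitter ≈ 0.2% (length), ≈ 2% (area) and ≈ 4%
(angles). The angle error under heavy noise is dominated by residual
silhouette dilation after smoothing and grows if `extension_len` is
shortened.

## Curvature-weighted subsampling

Dense clouds can be reduced before measurement with `geometric_sample`:
inclusion probability ∝ (surface-variation curvature + `floor_prob`),
without replacement. The curvature score is λ₃/(λ₁+λ₂+λ₃) of the local
covariance (k = 16 neighbors): 0 on planes, up to 1/3 for isotropic
scatter, highest at the facet rim and embrasure creases — exactly where
the impaction-relevant geometry lives. `floor_prob` (default 0.05) keeps
flat regions represented; very large values recover uniform sampling.

## Statistics

* **Normality** — Shapiro–Wilk plus Kolmogorov–Smirnov; the KS p-value
  defaults to the Lilliefors correction since mean and SD are estimated
  from the sample (the naive fitted-normal variant is available).
  Kurtosis is reported as excess kurtosis.
* **Group comparison** — independent two-sample t-test, Welch by default
  (no equal-variance assumption; the published occlusal-angle SDs differ
  by a factor of two), Student's pooled form available, plus a
  summary-statistics variant for printed tables.
* **Correlation** — Spearman by default (the published tables report ρ),
  Pearson available; both convert r to a two-sided p through
  t = r√((n−2)/(1−r²)) on n−2 df, which reproduces the published
  p-values from the published coefficients at n = 50.
* **PCA with communality screening** — correlation-matrix eigendecomposition;
  components with eigenvalue > 1 retained (Kaiser); loadings =
  eigenvector × √eigenvalue with each component's largest loading made
  positive; communality = row sum of squared loadings; the worst item
  below 0.4 is dropped and the analysis re-run until all pass. Every
  round is returned.
* **Logistic regression** — maximum likelihood by IRLS (convergence
  max|Δβ| < 1e−8, 100 iterations), standard errors from the observed
  information, Wald χ² = (β/SE)², odds ratios and 95% CIs as
  exp-transforms. Quasi-separation is detected (diverging coefficients /
  vanishing weights) and raised as a diagnostic rather than returned as a
  silently diverged fit; the full-analysis report records it in metadata
  when a small cohort separates.
* **Analysis subset** — the correlation and PCA stages default to a
  50-per-group subsample: the published correlation p-values are
  consistent with n ≈ 50 even though recruitment was 250 per group, and
  at n = 250 every feature (including the tongue and buccal angles)
  becomes significant, which is not the published pattern. The subset
  size is configurable and surfaced in the report metadata rather than
  silently resolved.
* No multiple-testing correction is applied (none is applied in the
  source analysis); p < 0.05 is flagged.

The published risk scorer applies the fixed coefficients
(0.889, 3.396, −0.071, −0.089; intercept −19.797) on the logit scale.
At the reference feature values (L = 3.52, A = 6.21, θ_b = 54.15,
θ_o = 89.26) the logit is −7.367, i.e. p ≈ 6.3 × 10⁻⁴.

## Pipeline

`run_pipeline` draws per-group pair specs from the cohort distributions
(clipped to the generator's valid windows), generates and measures each
pair, assembles the measured cohort, runs the analysis and scores every
record. One global seed fans out through `numpy.random.SeedSequence`
children, so reruns are byte-identical and stages independently
reproducible. Defaults (20 pairs per group, 18,000 points per tooth)
complete in well under five minutes on one CPU.

## Problem sizes used in the test suite

Recovery sweeps run 12 random specs per noise level at 24,000 points per
tooth; the cohort significance simulations use 100 replicates of 250 (or
50) subjects per group; logistic coverage uses 100 replicates of 20,000
subjects. These sizes keep the full suite around a minute while leaving
the binomial noise of every Monte-Carlo check well inside its margin.

## Known limitations

* The embrasure-wall refinement assumes near-planar walls within ~1 mm of
  the facet rim; strongly curved embrasures would bias the line ends.
* The three-point angle inherits first-order sensitivity to vertex
  placement (≈ 1°/0.02 mm at 90° openings with a 1.5 mm probe); under
  heavy jitter angles are the least accurate feature.
* The facet-area extrapolation assumes the area grows linearly with the
  gap threshold near the floor; highly irregular (fragmented) contacts
  would violate this.
* The 2D input route (`extract_dividing_line` on an already-projected
  cloud) uses plain nearest-neighbor gaps and no wall refinement; it is
  intended for noise-free projections, while `measure_all` always works
  from the 3D surfaces.
* Exact reproduction of the published normality/PCA/logistic tables is
  not possible without the clinical scans; the package instead verifies
  every printed identity that is recomputable (odds ratios, correlation
  p-values, communalities) and all recovery properties on synthetic data.
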