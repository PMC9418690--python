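# Methods

This note records the models behind each pipeline stage, the parameter
choices that matter, what the synthetic data does and does not emulate, and
the numerical decisions a maintainer would want to know.

## Imaging and features

Fields are 5-D arrays `(channel, z, t, y, x)` with named channel roles and
a pixel size in µm (default 1 µm with a warning when metadata is absent).
Analysis starts from the maximum-intensity projection over z.

**Segmentation.** Nuclei: Gaussian smoothing (σ = 2 px), then a threshold
that is the larger of Otsu and a robust noise floor
(median + 5·MAD-σ of the smoothed image); objects below `min_area_px`
(default 60) are dropped. The floor matters because Otsu always splits a
histogram, including a signal-free noise image. Cell bodies: watershed on
the inverted smoothed cytoplasm channel, seeded by nucleus labels and
masked to the Otsu foreground united with the nuclei, so a nucleus without
cytoplasm signal still yields a cell (equal to its nucleus) and the cell
count always equals the nucleus count. Per cell, only the connected
component containing its nucleus is kept. Cells touching the field border
are removed before feature extraction.

**The 28-feature vector.** The feature list is a fixed contract of this
package: 14 morphology features (area, Crofton perimeter, roundness
4πA/P², major/minor axis lengths, axial ratio, eccentricity, solidity,
extent, convex area, skeleton-endpoint protrusion count, nucleus area,
nucleus/cell area ratio, nucleus–cell centroid displacement) and 14
intensity/texture features on the cytoplasm channel (mean, sd, MAD, all
eight SER responses at the 1-px scale, and ridge/edge/valley again at the
2-px scale). Commercial screening software computes a comparable
morphology + SER family but its exact definitions are proprietary; the open
formulation below is the contract here.

**SER responses.** All texture responses are Gaussian-derivative fields,
non-negative and linear in the image: ridge = max(0, −λ_min) and
valley = max(0, +λ_max) of the Hessian at scale σ; edge = gradient
magnitude; spot/hole = ∓Laplacian clamped at zero; saddle =
√(−λ_min·λ_max) where the eigenvalues differ in sign; bright/dark = signed
deviation of the σ-smoothed image from a 4σ local mean. A score over a
region is the mean response divided by the mean σ-smoothed intensity
(+ ε = 10⁻⁶), which makes every score exactly invariant to multiplying the
image by a positive constant and zero on constant images (enforced by an
early exit, since float roundoff in separable filtering otherwise leaves
~10⁻⁷-relative ripple).

**Protrusion counting.** The cell mask is opened with a radius-2 disk to
suppress boundary roughness, skeletonised, and each skeleton endpoint is
traced toward the nearest junction; endpoints whose branch is at least
12 px long count. A disc scores 0; an unbranched elongated cell contributes
both line ends, so a two-protrusion spindle scores 2.

## Shape classification and the screen statistic

Classifiers are one-vs-rest ridge regressions (targets ±1, α = 1) on
z-standardised features — deterministic, convex, closed-form. A cell is
assigned to the top-scoring class only when the top score is positive and
beats the runner-up by at least `decision_margin`. The exemplar pipeline
sets the margin to 1.0, the unit half-range of the ±1 training targets: on
rendered populations, cells resembling an exemplar class score gaps near 2
while genuinely intermediate morphologies score gaps near 0, so the unit
gap is a natural scale separating the two regimes rather than a fitted
constant. A zero margin is available but leaves essentially no cell
unclassified, which contradicts the observed control populations (class
percentages sum to ~94%, not 100%).

pQMS percentages are simple class fractions of all segmented, non-border
cells. Plate normalisation is the sample-sd Z-score against all non-empty
wells of the plate ("whole plate", controls included; a flag excludes
them). A reagent is a hit for a shape when at least `min_replicates` (2)
replicate wells reach |Z| ≥ 1.5 with a consistent sign; conflicting
directions that each fall short do not make a hit. Cross-library
intersection keeps reagents hit in both libraries for at least one shape
each.

The screen-scale hit-calling simulation works at the count level (per-well
multinomial draws from each reagent's planted mixture, Poisson cell counts
around 300/well) rather than rendering ~10⁵ cells per screen; the
image-level and count-level generators share the same mixtures, and the
image-level path is exercised end-to-end by the population-recovery tests.
Reagents are randomised across balanced plates with two technical
replicate wells each, matching the two-replicates-per-plate design the hit
rule presumes.

## Focal-adhesion dynamics

Detection subtracts a wide-Gaussian background (σ = 20 px) and thresholds
at the larger of Otsu and median + 5·MAD-σ of the high-pass image — the
floor keeps Otsu honest when adhesions cover ~1% of the frame — then drops
components under 10 px. Linking is by maximal pixel overlap
(ties: larger overlap, then lower label); on a merge the larger parent
keeps the track, on a split the child with larger overlap keeps it; tracks
shorter than 5 frames are discarded. Kinetics: intensity is
background-subtracted, floored at 1 count, and ln *I* is fit by least
squares over [birth, peak] (assembly) and [peak, death] (disassembly,
rate reported positive); fits need ≥ 3 points and are retained only when
R² > 0.9. "Quick-assembling" adhesions are the upper tercile of assembly
rates, since no published cutoff exists. Dispersion statistics measure each
track's mean centroid against the cloud of all track centroids: distance to
the cloud centroid, and distance to the boundary of its convex hull (zero
on the hull; degenerate clouds of ≤ 2 points fall back to point/segment
distance). Orientation is the angle between the second-moment principal
axes of adhesion and cell, folded into [0°, 90°]; adhesions with axial
ratio < 1.05 are flagged orientation-undefined. Kymographs sample bilinear
interpolation along a line at unit spacing, averaged over `width_px`
parallel offsets; peak alignment shifts each Paxillin/actin trace pair so
the Paxillin maximum sits at offset 0 and averages only over covered
offsets.

## FRET tension

The tension sensor loses FRET under load, so the acceptor/donor ratio
falls as tension rises; the tension index is the reciprocal ratio, which
is invariant to common channel gain. Backgrounds are subtracted per
channel (the series pipeline takes explicit background arguments; the
movie-free default is 0), and frames where either channel is non-positive
after subtraction are masked and counted. Per track the pipeline reports
mean and minimum tension index over retained frames.

## Invasion

Plane depths label plane centres (0/30/60/90 µm; 20 µm thickness is
metadata only). The invasion index is 100 × (cells at 30/60/90 µm)/(all
cells); at-depth fractions (e.g. "≥ 40 µm") are cumulative over planes at
or beyond the stated depth, so the deepest-plane fraction stands in for
"reached ~100 µm" in a four-plane acquisition.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic given a preset and seed; child streams
derive from SHA-256 of (parent seed, key…) truncated below 2³¹, a rule that
is part of the package contract.

**Cell fields.** Silhouettes are parametric: an elliptical body plus
capsule protrusions (spindle: two antipodal; star: 4–6 evenly spaced with
jitter; the "ambiguous" silhouette carrying the unclassified mass has one
short stubby protrusion on a nearly round body, and its stiff-substrate
counterpart is a disc midway between the small- and big-flat radii).
Per-cell size jitter is ~7% (radius) and ~10% (protrusion length).
Foregrounds are constant (nucleus 800, cytoplasm 500 counts) with additive
Gaussian noise (sd 30) and no point-spread blur — the simplest model that
exercises thresholding while keeping every planted parameter analytically
recoverable. Cells are rejection-sampled wholly inside the field with 3-px
clearance, so the planted mixture is exactly the composition of the
analyzable population; border-touching cells (and their removal) are
exercised by dedicated fixtures instead. Population mixtures shipped with
the package encode the reported control and perturbed proportions
(soft control 45/26/23 + 6% unclassified; star-enriched 51%; stiff control
32/49/16 + 3%). What this does not emulate: touching or overlapping cells,
intensity gradients, focus drift, debris — so passing recovery tests show
the quantification logic is right, not that segmentation is robust to
those real-world artefacts.

**Adhesion movies.** Stationary hard-edged ellipses with exponential
intensity profiles (rise k_a to a peak at 45% of the lifetime, then decay
k_d), placed without overlap; noise sd 15 on a background of 40. The
knockdown preset scales area ×1.62, intensity ×1.35 and axial ratio ×1.04
against wild-type with identical kinetics, so the planted morphology folds
are not confounded by lifetime-profile differences; the FAK-inhibitor
preset scales only longevity ×1.25. Lifetimes are clipped normals well
above the 5-frame filter, so the filter removes nothing and the planted
longevity fold survives; movies are 40 frames at 60 s. Not emulated:
moving, merging or splitting adhesions (the linker's merge/split rules are
tested on constructed fixtures), photobleaching, or intensity-dependent
detection dropout.

**Tension series.** Within-track closure follows a raised sin² bump from a
baseline to `closed_fraction_peak` mid-life with track-average
`closed_fraction_mean`; the acceptor/donor ratio is ∝ 1/(1 − closure) with
1% multiplicative channel noise. The shipped pair plants mean/minimum
tension folds of exactly (1−0.54)/(1−0.50) = 0.92 and
(1−0.805)/(1−0.70) = 0.65.

**Ring textures.** Thin Gaussian-profile filaments (σ = 1 px) of amplitude
`contrast × background` on a flat background; geometry streams are keyed by
(seed, index) only, so the paired presets render identical geometry and the
score fold isolates the planted contrast ratio (kd/wt = 0.40/0.25 = 1.6).
Because the SER-Ridge score divides by mean ring intensity, which itself
rises with filament amplitude, the measured median fold sits ~5% below the
planted contrast ratio (≈ 1.51 at the shipped coverage); this bias is
inherent to intensity-normalised texture scores, shrinks with filament
coverage, and is well inside the ±15% recovery tolerance.

**Invasion stacks.** Multinomial allocation over the four planes;
optionally rendered as non-overlapping nucleus discs per plane to exercise
the counting path. Planted per-depth fractions give indices of 33%
(wt: 0.67/0.23/0.08/0.02) and 27% (kd: 0.73/0.19/0.07/0.01), with 10% vs
8% at ≥ 40 µm and 2% vs 1% at the deepest plane.

## Problem sizes and tolerances

End-to-end recovery runs use 2,000-cell populations in 40-cell fields of
1024² px with 50 exemplars per class (±3-point recovery of planted
percentages; residual deviation is dominated by the multinomial draw,
sd ≈ 1 point), 100-track movie pairs (±10% on fold changes), 200-adhesion
tension series (±10%), 100 texture fixtures per condition (±15% on the
median fold), 10,000-cell invasion stacks (±2 points), and 100 simulated
screens for hit calling (sensitivity ≥ 95%, ≤ 1 median false positive —
with two replicates the null rate per reagent is ≈ 2·P(Z ≥ 1.5)² ≈ 0.9%,
i.e. ≈ 0.85 expected false positives among 95 nulls). These sizes make the
whole recovery suite run in a few minutes on one CPU.

## Known limitations

* Segmentation assumes well-separated cells; touching-cell resolution is
  out of scope by design.
* A few percent of true big-flat (and occasionally small-flat) cells fall
  below the decision margin and land in "unclassified", biasing those
  classes slightly low; the bias is within the stated recovery tolerances
  but would grow if the class geometry clusters were moved closer.
* The ring-texture score's intensity normalisation produces the ~5%
  contrast-fold compression described above.
* The FRET model treats the sensor ensemble as a single closure fraction
  per frame; spectral bleed-through and donor-only correction factors are
  not modelled.
* Kinetics fits assume a single peak per track; multi-peaked tracks fit
  only the global peak's two phases.
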