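# Methods

`npcstorm` quantifies nuclear pore complexes (NPCs) from single-molecule
localization microscopy (STORM/SMLM) coordinate tables, and complements the
pore counts with FRAP transport kinetics and nuclear:cytoplasmic (N:C)
partitioning measurements. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic-data tests do and do
not demonstrate.

## The measurement problem

An SMLM acquisition of an antibody-labeled nucleoporin yields a table of
single-molecule localizations (SML): one fitted (x, y) position per
fluorophore blink, with the fitted PSF width sigma and the acquisition
frame. NPCs appear as clusters of localizations — ring-like for coat
nucleoporins such as NUP133 (scaffold ring diameter ~107 nm), dot-like for
antibodies against central-channel or inner-ring epitopes — scattered over
the projected nuclear surface, on top of a background of nonspecific
localizations. The quantities of interest per nucleus are the number and
areal density of pores, the overall SML density, the mean SML count per
pore (a proxy for how much of the target protein each pore incorporates),
and the mean cluster diameter. Two-condition comparisons (e.g. progenitor
vs differentiated cells, 5–15 nuclei per group) use Student's t test per
metric.

## Synthetic-data model

Real acquisitions are emulated by `synthetic_data.simulate_npc_field`:

- **Geometry.** Pore centers form a Poisson process of intensity
  `npc_density` (default 4.0 µm⁻²) over the ROI (default: 64-gon disk of
  radius 5 µm, ~78.5 µm², standing in for the imaged nuclear cap), thinned
  by dart throwing to a hard-core minimum separation (default 150 nm).
  Each pore carries `n_corners` = 8 sites equally spaced on a ring of
  diameter 107 nm at a random rotation.
- **Labeling and blinking.** Each corner site is labeled with probability
  `label_prob` = 0.6; a labeled site produces B blinks with
  B ~ 1 + Poisson(`mean_blinks` − 1), default mean 4. The mean SML per
  pore is therefore 8 × 0.6 × 4 ≈ 19. A zero-variance `fixed` blink law
  exists for exact-counting tests. No on/off dwell-time photophysics, no
  z dimension, no camera noise model.
- **Localization noise.** Each blink is displaced by isotropic Gaussian
  noise with `sigma_loc` = 10.6 nm — the stated ~25 nm image resolution
  interpreted as a FWHM (25/2.355). Blinks get uniform random frames over
  `frame_count` = 20,000 (10 ms exposure movies) and PSF sigmas uniform in
  100–180 nm, i.e. passing the out-of-focus filter.
- **Background.** Uniform (CSR) localizations at `bg_rate` = 40 µm⁻² with
  sigmas uniform in 100–300 nm, so roughly half are removed by the sigma
  filter — mimicking a partially filterable nonspecific background.
- **Drift.** An optional per-frame track (linear by default, sinusoidal
  for stress tests) with a stated total displacement is added to every
  localization according to its frame.

Dot-like (MAB414/NUP93-style) clusters are the same generator with
`ring_diameter` small relative to `sigma_loc`; there is no separate
emitter model.

What the generator does **not** capture: fluorophore re-blinking
correlations in time, multiple antibodies per epitope, partially assembled
pores, nuclear-envelope curvature, and spatially structured background.
Passing tests therefore demonstrate correctness of the pipeline's
machinery under the stated statistical model, not performance on any
particular real dataset.

## Preprocessing

**Sigma filter.** Localizations with fitted PSF width sigma > 200 nm are
rejected as out-of-focus; the threshold is configurable, the default is
the conventional one for this imaging regime.

**Drift correction.** The movie is split into `n_bins` = 10 contiguous
frame bins; each bin is rendered as a 2-D histogram at `render_px` = 20 nm
(~2× the localization noise) on a grid common to all bins, lightly
Gaussian-smoothed (1 px) — with only ~10³ localizations per bin the raw
histogram cross-correlation peak is too noisy for sub-pixel refinement.
Each bin's shift relative to the first is the cross-correlation peak,
refined with a 3×3 intensity centroid. Per-frame drift is linear
interpolation between bin midpoints, **linearly extrapolated** at the
movie's ends: constant end-extrapolation would leave 1/(2·n_bins) of a
linear ramp uncorrected at each end and bias recovered totals low by
1/n_bins (10% — two thirds of the 15 nm error budget at a 100 nm drift).
Shifts are measured against the first bin rather than by
pairwise-redundant least squares; the redundant scheme is a documented
extension point. The canonical pipeline order is drift correction, then
sigma filtering (a config switch reverses it).

## Pore extraction

Clustering is HDBSCAN (scikit-learn implementation; hierarchical
density-based clustering with Excess-of-Mass cluster selection) on the
2-D coordinates, followed by **fragment merging**: clusters whose
centroids lie within `merge_radius` of each other are unioned
(single-linkage on centroids). The default radius, 130 nm ≈ ring diameter
+ 2·sigma_loc, sits strictly between the largest plausible fragment
separation within one pore and the 150 nm minimum center-to-center pore
spacing, so fragments of one pore merge while distinct pores never do.
(HDBSCAN's own `cluster_selection_epsilon` would serve a similar purpose
but is unusable in the installed scikit-learn/numpy combination.)

The default configuration is `min_cluster_size` = 6 with `min_samples`
fixed at 3 rather than tied to `min_cluster_size`. The decoupling is
deliberate and central to the method's use case: with tied
`min_samples`, HDBSCAN's mutual-reachability densities — and hence the
recovered pore count — drop by ~10% when the per-pore localization count
drops ~28% (the partial-incorporation scenario the pipeline exists to
detect). That artifact would convert an unchanged pore density into a
spuriously significant difference. With `min_samples` = 3 and fragment
merging, recovered counts are accurate to a few percent and insensitive
to the blink rate, at the cost of a small, condition-independent
false-positive rate from the background (HDBSCAN reports occasional
low-density structures even in pure CSR noise). `ClusteringConfig`
constructed with `min_samples=None` still ties the two parameters for
users who want classic behavior.

**Monte-Carlo tuning.** `optimize_min_cluster_size` simulates fields with
known pore centers, runs preprocessing + clustering for each candidate
minimum cluster size, greedily matches recovered centroids to true
centers within 75 nm (each truth matched at most once), and selects the
candidate maximizing mean F1, ties toward the smaller value. Greedy
nearest-first matching is adequate because pore separations are large
compared to the match radius. The default candidate grid (4–15) is dense
around the expected optimum for ~19 SML/pore emitter statistics.

**Per-cluster metrics.** Centroid = arithmetic mean of member positions;
SML count = member count; diameter = 2 × mean radial distance of members
from the centroid. This diameter is exact for ideal rings, well-defined
for dot-like clusters, and needs no circle fit; under localization noise
it overestimates a ring's geometric diameter by ≈ sigma²/r (about +1 nm
at the defaults, the Rice-distribution mean). Measured through the full
clustering (rather than true memberships) it gains a further ~+3 nm from
background admixture and occasional bridged pores.

**Per-nucleus statistics.** Pore density = clusters / area; SML density
counts *all* localizations (clustered or noise) divided by the area —
the literal reading of dividing all localization events by the nuclear
area. The area comes from a supplied ROI polygon (shoelace area, nm² →
µm²) or, by default, the convex hull of the localizations, which
approximates the imaged nuclear cap well when pores tile it. Cluster
means are NaN-marked when no cluster exists. Zero-area inputs are
errors, not NaNs.

## FRAP kinetics

Recovery traces I(t), sampled every 10 s to ~500 s post-bleach, are fitted
with the exponential association I(t) = f0 + (plateau − f0)(1 − e^(−kt))
by least squares (three free parameters; floor not pinned to the bleach
minimum, robust to incomplete bleaching). Initialization: f0 = first
sample, plateau = last sample, k = 1/(time of half-span crossing). A flat
trace, solver failure, or non-positive rate yields a flagged,
non-converged fit — never silent defaults. Half-time t½ = ln2/k. The
effective diffusion coefficient follows the uniform-circular-beam
photobleaching analysis: D = γ·w²/(4·t½) with γ = 0.88; a square bleach
region of side L maps to the equal-area circle, w = L/√π (5 µm side →
w = 2.8209 µm). Traces may be normalized by mean pre-bleach intensity;
half-times are invariant to affine intensity transforms either way.

## N:C ratios

Per cell, with nucleus and whole-cell masks supplied (segmentation is out
of scope): cytoplasmic signal = integrated whole-cell signal − integrated
nuclear signal; N:C = nuclear / cytoplasmic. Integrated (summed) signal is
the default because the subtraction rule is only coherent for sums; a
mean-intensity mode exists behind a flag. An optional constant background
is subtracted per pixel before integration (ratios are invariant to
multiplicative rescaling but not to additive offsets, which motivates the
option). Non-positive cytoplasmic signal flags the cell instead of
emitting a number; batch runs collect per-cell errors and continue.

## Group comparison

Two-sample comparisons default to the pooled-variance Student t test
(two-sided), with Welch available since group sizes of 9–15 with
plausible heteroscedasticity are common. Zero pooled variance with equal
means returns the t = 0, p = 1 convention; with unequal means it is an
error. Panels with ≥3 groups go through one-way ANOVA with Tukey HSD as
the post-hoc test. No multiple-testing correction is applied across
metrics. Reports carry mean ± s.d. per group, t, df and p per metric.

## Problem sizes and tolerances in the test suite

Unit and acceptance tests simulate full-size nuclei (78.5 µm², ~314
pores, ~9,000 localizations) where the property under test demands it:
count recovery (10 nuclei, ≤10% error), Monte-Carlo tuning (held-out
F1 ≥ 0.90), drift recovery (100 nm injected, ≤15 nm error, sub-pixel
residual), and the two-condition discrimination experiment (20 replicates
of 10-vs-10 nuclei with the blink rate scaled ×0.72 in one group; pore
density non-significant and SML/cluster significant in ≥90% of
replicates). Distributional moment checks use 30–100 seeds; FRAP rate
recovery uses 200 noisy traces at 2%-of-span noise (<5% median error) and
400 fits for Wald-CI coverage (90–98% band); the t-test type-I error uses
10,000 null replicates (5% ± 0.6%). Smaller ROIs (1.2–3.5 µm radius) are
used where only mechanics, not statistics, are under test.

## Known limitations

- The fragment-merge radius assumes pores are at least ~150 nm apart;
  denser pore fields would need a smaller radius or a different
  anti-splitting mechanism.
- The drift estimator assumes structure-rich fields; featureless or very
  sparse tables (≲50 localizations per bin) are rejected rather than
  guessed at.
- The diameter statistic is a radial moment, not a circle fit; comparing
  absolute diameters across labeling geometries requires the documented
  bias corrections.
- FRAP analysis covers the exponential-association phenomenology only; no
  reaction–diffusion models, spatial profile fitting, or
  acquisition-bleaching correction.
- HDBSCAN on pure uniform noise reports a small number of spurious
  low-density clusters; the pipeline treats this as a condition-independent
  floor rather than attempting zero false positives.
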