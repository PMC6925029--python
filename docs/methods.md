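# Methods

`ctcmorph` implements a harmonized single-cell workflow for comparing
circulating tumor cells (CTCs) in peripheral blood (liquid biopsy) with intact
single cells from tumor touch preparations (solid biopsy): 4-channel
immunofluorescence frames (DAPI, pan-CK, CD45, CDX2) are segmented into
nuclear and whole-cell masks, ~86 morphometric features are measured per cell,
cells are classified into rare-cell categories by explicit rules, and
per-patient statistics quantify how closely the liquid compartment resembles
the solid compartments. Because no public image set accompanies this problem
class, the package ships first-class synthetic generators whose planted ground
truth makes every stage testable end to end.

## Synthetic frames

A frame emulates a leukocyte monolayer with rare tumor cells:

* **Geometry.** WBC nuclei are circles with log-normal radius (default
  6 ± 0.8 px at the synthetic scale); tumor nuclei are ellipses with random
  orientation and log-normal axis jitter (log-sd 0.1), with the base axis set
  so the expected tumor/WBC nuclear area ratio equals
  `tumor_nuclear_scale²` (default 1.6² = 2.56). Cytoplasm is a fixed
  morphological dilation of the nucleus (2 px for WBCs, 4 px for tumor cells),
  chosen so analytic area oracles exist. Non-cluster objects are placed by
  rejection sampling with a minimum 3 px separation between cell masks;
  clusters are built by attaching members until cell masks are 8-adjacent
  while nuclear masks stay ≥ 3 px apart (mirroring CTC clusters, which touch
  through cytoplasm while keeping resolvable nuclei). Infeasible packings
  raise an error rather than silently truncating.
* **Intensity.** Each channel is a constant background plus per-object signal
  (DAPI on nuclei of all cells; CK and CDX2 on tumor cell masks, CDX2 only for
  the positive fraction; CD45 on WBC cell masks) plus additive Gaussian noise
  clipped at zero and quantized to uint16. Per-object levels are drawn once
  from population (mean, sd), and recorded as ground truth. There is no PSF,
  no illumination field and no staining batch effect — sufficient for testing
  segmentation and classification logic, not for benchmarking against real
  microscopy.
* **Determinism.** All randomness flows from one `numpy` generator seeded by
  the spec; identical specs yield byte-identical frames.

## Synthetic cohorts and the planted concordance

The feature-level generator draws a cells × features table per patient and
compartment (liquid, metastasis, primary), default 82 features named after the
morphometry catalogue and 43 cells per compartment.

The headline statistic downstream is the **concordance r**: per patient, each
raw feature is min-max scaled to [0, 1] over that patient's cells, scaled
values are averaged per compartment, and the compartment profiles (vectors
over features) are correlated (Pearson). Making this quantity *controllable*
in a generator is non-trivial: with two compartments pooled, per-feature
min-max scaling centres the range on the midpoint of the two compartment
means, so their deviations are exactly antisymmetric — a generator that plants
only correlated compartment mean-shifts produces strongly *anti*-correlated
scaled profiles regardless of the planted correlation. The generator therefore
plants two components per feature:

1. **Compartment shifts** `δ_cf = d·z_cf` with `corr(z_liquid, z_solid) =
   ρ_δ`, `d = shift_scale × within_sd` (default shift_scale 0.2). These set
   the raw mean-profile Pearson correlation, which converges to the target ρ
   as the number of features grows (ρ_δ is inflated slightly to undo the
   attenuation from within-compartment sampling noise of the empirical
   means).
2. **A shared distribution-shape component.** Within-cell variability follows
   a structured distribution: a small mass (6% per side) of edge-saturated
   cells pinned at ±`within_sd` (emulating detector floor/saturation, which
   pins the patient-level min-max range with almost no sampling noise), and a
   uniform bulk whose centre `m_f` varies per feature but is shared by all
   compartments (feature-specific skew, as real area and intensity features
   have). After min-max scaling the bulk offset becomes a per-feature signal
   common to both compartment profiles; its spread is calibrated analytically
   — including the exact expectations, over the compartment-mean gap, of the
   range-inflation factor — so that the min-max/average estimator is unbiased
   for the same target ρ that the raw profiles carry. Validation by
   simulation (20 replicate cohorts, 500 features, 50 cells/compartment):
   recovered mean r within ±0.05 of ρ for ρ ∈ {0, 0.3, 0.5, 0.6, 0.9}, raw
   Pearson exact.

The calibration is exact for the two-compartment design and approximate when
three compartments are pooled. When explicit `compartment_shift` vectors or
planted archetypes are supplied, the calibration is bypassed (archetype mode
uses plain Gaussian within-noise so cluster-recovery tests see exactly the
planted geometry).

What passing tests on these cohorts do **not** show: robustness to real
feature distributions (heavy tails, mixed scales and units, missingness),
to correlated features, or to segmentation-error-induced artefacts.

## Segmentation

Nuclei: global threshold on DAPI (Otsu by default, fixed value available),
8-connected components, minimum area 20 px (config-exposed; there is no
canonical size filter for this assay). Components are split by a
distance-transform watershed only when they contain more than one marker,
where markers are the connected regions within `split_h` (default 2 px) of the
component's distance peak — a single convex object always yields one marker
(discrete EDT ridge plateaus stay connected), while fused objects with a
valley deeper than `split_h` split into one marker per lobe.

Cells: pixels of the thresholded CK foreground plus a dilated halo around
every nucleus (default 4 px, guaranteeing a cytoplasmic rim for CK-negative
cells such as WBCs and CK-low CTCs) are assigned to the nearest nucleus, and
each cell mask is restricted to the connected component containing its
nucleus. This enforces the mask contract: identical label sets, nucleus ⊆
cell, every pixel in exactly one label, 8-connectivity, 0-based (row, col)
coordinates.

Touching groups are computed from 8-adjacency of cell labels by union-find.

## Morphometry

Catalogue (87 named features): 11 shape descriptors (areas, perimeters,
roundness of nucleus and cell, N/C ratio, eccentricities, nuclear solidity);
5 intensity statistics (mean, sd, cv, integrated, max) × 4 channels × 3
regions (nucleus, cytoplasm, whole cell); 3 distribution descriptors × 4
channels; 4 SDOMs.

* **Roundness** = P²/(4πA); 1 for a circle, larger when elongated.
* **Perimeter.** Default estimator: total subpixel length of the 0.5-level
  marching-squares contour of the Gaussian-smoothed (σ = 1 px) mask. The
  4-direction Crofton approximation is available as an option, but its disk
  roundness oscillates with radius by up to ~4%, whereas the smoothed-contour
  estimate stays within ~1.2% of 1 for all radii ≥ 10 px and is monotone in
  ellipse axis ratio. Roundness may fall marginally below 1 on rasterized
  disks (tolerance ≈ 0.02).
* **N/C ratio** = nuclear area / cytoplasmic area (cell − nucleus); the
  CK-negative fallback mask guarantees a positive denominator. The
  alternative nuclear/cell convention is available by configuration.
* **Distribution descriptors** (defined stand-ins, config-isolated so
  substitutes can be swapped): *heterogeneity* = sd/mean of pixel intensities
  on the cell mask; *margination* = mean intensity over the boundary band
  (pixels within the outer 20% of the equivalent radius) ÷ mean over the
  whole mask; *clumpiness* = fraction of mask pixels exceeding mean + 1 sd
  after 3×3 median smoothing. A uniform field gives 0 / 1 / 0.
* **SDOM** (standard deviations over the mean): `(cell_mean − μ) / σ` where
  μ, σ are the mean and sample sd (n−1) of the per-cell mean intensities of
  the frame's WBC population — the natural negative reference for DAPI, CK
  and CDX2. For CD45 the leukocytes are the *positive* population and cannot
  serve as their own negative reference, so the CD45 SDOM is computed against
  the cell-free image background (mean and sd of pixels outside all dilated
  cell masks). Fewer than 2 WBCs, or zero sd, flags the background
  unavailable and the SDOM propagates as a missing value — deliberately, since
  touch preparations frequently lack WBCs.
* **Units** are px/px²; a pixel size in µm/px converts areas and perimeters
  for reporting only (dimensionless features unaffected).

## Classification

Decision ladder (first match wins): CD45 SDOM ≥ t_cd45 → WBC; CK SDOM ≥ t_ck
with nuclear area > s × (WBC mean nuclear area) → HD-CTC if the nucleus is
intact (solidity ≥ 0.85) else Apoptotic-like; CK-positive but not larger →
CTC-Small; marker-negative but larger → CTC-LowCK; else FalsePositive.
HD-CTCs in touching groups containing ≥ 2 HD-CTCs become CTCC members (other
categories in the group do not count toward the 2). Defaults t_ck = 5,
t_cd45 = 3, s = 1.25 are package defaults, **not assay-calibrated** — only the
CDX2 positivity guide (SDOM 5) is anchored; all are config-exposed. CDX2
binning: positive iff SDOM ≥ 5, an analyst override wins and is flagged,
missing SDOM is indeterminate. When SDOMs are unavailable, absolute
raw-intensity fallbacks may be configured; otherwise a missing-feature error
names the feature.

Counts convert to concentration as `count × leukocyte_concentration /
n_DAPI_nuclei` (cells/mL); a sample is called positive strictly above
4 HD-CTCs/mL.

## Cohort statistics

* **Preprocessing (per patient):** shift each feature to strictly positive
  support (shift = 1 − min when min ≤ 0), maximum-likelihood Box-Cox, drop
  zero-variance features (recorded, and dropped globally so the matrix stays
  rectangular), center and scale. Patients with one cell are an error.
* **Clustering:** complete-linkage agglomerative clustering on euclidean
  distances (scipy linkage). Results are deterministic for a fixed row order
  and all pipeline paths order cells by stable ids; permutation invariance
  under exact distance ties is not guaranteed (scipy's internal tie
  handling), a documented limitation.
* **Branch-level cuts:** level L = L recursive splits of the root; every
  current cluster splits at its top merge, leaves cannot split, so at most
  2^L clusters. Cells are clustered at third-level branching (≤ 8 clusters
  per patient); metaclusters cut the dendrogram of per-patient cluster
  mean-profiles (computed on the per-patient scaled data) at level 2, with
  level-3 sublabels. The composition table reports patient presence and
  percent of total cells per metacluster.
* **Concordance r:** min-max scaling uses the *raw* features (the
  Box-Cox/scaled pathway exists but is not the default). Profiles average
  all features with nonzero range. Constant profiles yield a flagged missing
  value, not silent NaN propagation.
* **ICC:** one-way random-effects ICC(1) = (MSB − MSW)/(MSB + (k̄ − 1)·MSW)
  with the unbalanced-design group-size correction
  k̄ = (N − Σn_i²/N)/(a − 1). The pipeline applies it to the first principal
  component score of the preprocessed data as the per-cell profile summary,
  for all cells and for the liquid / solid subsets.
* **Per-feature tests:** two-tailed Welch t-tests per feature per patient;
  raw p-values are primary, Benjamini-Hochberg-adjusted values are emitted
  alongside. Zero variance on both sides with equal means gives p = 1 by
  convention.
* **Feature correlation:** Spearman ρ over all cells, ordered by
  complete-linkage clustering of 1 − |ρ|.

## Power and inclusion

Two-sample t-test power is computed exactly from the noncentral t
distribution (ncp = d·√(n/2), df = 2n − 2); `n_for_power` returns the
smallest per-group n reaching the target (default 0.8) by bisection.
α = 0.05 two-sided is assumed (config-exposed). Cohen's d uses the pooled
(n−1)-weighted sd. Inclusion of a matched sample pair requires ≥ 20 HD-CTCs
on the first two liquid slides and ≥ 4 solid monolayer clusters of intact
tumor cells (a strictness switch makes the solid criterion a strict >).
Pre/post concentration comparisons use the two-sided paired t-test (Welch for
unpaired groups); identical paired vectors give p = 1 by convention.

## Problem sizes used by the test suite

Frames are 320–400 px square with 25–60 WBCs and 4–6 tumor cells;
classification agreement runs 50 seeds. Concordance recovery uses 20
replicate single-patient cohorts of 2 × 50 cells × 500 features per ρ level;
metacluster recovery uses 10 patients × 80 cells × 82 features; the power
oracle uses 10⁵ Monte-Carlo replicates; the Welch null calibration uses 10⁴
null features. These sizes give sampling errors comfortably below the
asserted tolerances while keeping the default suite fast.

## Known limitations

* Thresholds of the classification ladder are uncalibrated defaults; on real
  data they must be tuned against analyst-reviewed labels.
* The synthetic image model omits PSF blur, illumination gradients,
  overlapping cell stacks and staining batch effects; segmentation accuracy
  on real touch preps is not established by these tests.
* The concordance calibration is derived for two pooled compartments; with
  three compartments the planted ρ is recovered only approximately.
* Complete-linkage results can depend on input order under exact distance
  ties.
* ICC is fixed to the one-way random-effects form.
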