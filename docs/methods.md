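# Methods

This note documents the models behind `gliascreen`, the defaults and why
they were chosen, the numerical decisions that affect results, and what
the synthetic data do and do not establish about real images.

## Synthetic field model

A field is a 512×512 (configurable) 4-channel image at an assumed
0.65 µm/px (10× objective scale).  Objects are jittered ellipses placed by
rejection sampling; per class the generator draws an equivalent diameter,
eccentricity and per-channel signal amplitude from normal distributions
(`simulate.DEFAULT_SHAPE_MODEL`, `DEFAULT_INTENSITY_MODEL`).  The
class-conditional staining rules are enforced by construction:

| class      | Hoechst        | NeuO   | IB4            | DRAQ7  | size |
|------------|----------------|--------|----------------|--------|------|
| neuron     | medium (120)   | bright | –              | –      | ~11 px |
| microglia  | medium (110)   | –      | bright (cytoplasm) | –  | ~12 px |
| astrocyte  | dim (70)       | –      | –              | –      | ~18 px, oval |
| other      | elevated (165) | weak   | –              | –      | ~10.5 px |
| condensed  | intense (230)  | –      | –              | –      | ~6.5 px |
| necrotic   | medium         | –      | –              | bright | ~6 px |
| debris     | very dim (40)  | –      | –              | –      | irregular |

These orderings (astrocyte < neuron < condensed in Hoechst intensity, the
reverse in diameter) are validated as spec invariants; they encode how the
classes are distinguished by eye in real cocultures.  Background is a
constant plus a random planar gradient per channel; noise is scaled
Poisson (shot) plus Gaussian read noise.  `class_densities` are exact
per-field object counts, not Poisson means, so ground truth is available
without sampling ambiguity.

A configurable fraction of neurons is placed touching another nucleus
(centers at 0.92× the sum of mean radii — overlapping masks that share a
rasterized border), and another fraction at the rim of a microglial
cytoplasm so the neuron's boundary pixels pick up IB4 signal, reproducing
the "neuron adjacent to microglia" feature signature.  Microglial IB4
cytoplasm is a scaled, jittered ellipse around the nucleus; the
`irregularity` parameter moves its FormFactor between the amoeboid
(LPS-activated, near-circular) and ramified (resting, boundary-inflated)
presets.

**What the generator does not emulate:** texture within nuclei, optical
blur/PSF, uneven illumination beyond a planar gradient, neurites, truly
ramified (branched) microglial processes, or correlated staining
artifacts.  Passing tests therefore demonstrate that the pipeline's logic
is correct under the stated staining rules and realistic shot noise — not
that any particular accuracy will be reached on real microscope images,
where segmentation is the binding constraint.

## Segmentation

Background subtraction is a grayscale-opening estimate.  The default
structuring element is a flat square implemented as two separable 1-D
openings — exact for a flat square element and fast at the 50 px radius
appropriate to 10× fields; a true disc footprint is available via
`element="disc"` for small radii.

Nuclear segmentation: Gaussian smoothing (σ = 1 px) → Otsu threshold ×
a correction factor (default 0.5) → hole filling → distance-transform
watershed.  The correction factor is needed because Otsu places the
threshold between background and the *bright* nuclei when intensities span
a wide range, which would drop debris and dim astrocyte nuclei; both Otsu
and the correction scale with the image, so labels are invariant to global
intensity scaling.  Declumping seeds are local maxima of the smoothed
(σ = 1) distance transform, h-maxima-suppressed at h = 0.5 with a minimum
separation of 5 px; smoothing the distance map prevents boundary jitter
from spawning split seeds on large oval nuclei while preserving the
two-peak structure of touching ~11 px neuronal nuclei.  Objects under
20 px² are removed.  Any external 0-background integer label mask can be
substituted for this stage.

Segmentation scoring: splits are detected first — a truth object with ≥2
predictions mostly (≥50% of the prediction) inside it, each covering ≥20%
of it and jointly ≥50% — so an exact half-split cannot slip through the
matcher as a "correct" object; remaining predictions match one-to-one
greedily at IoU ≥ 0.5; merges are unmatched predictions covering ≥50% of
each of ≥2 truth objects; the remainder are missed/spurious.  Every truth
object lands in exactly one category, so the counts are conserved.

## Features and classification

The default schema is 14 intensity statistics × 4 channels + 10 shape
descriptors = 66 named columns; it is configuration-driven (extra
percentiles or texture statistics extend it without code changes), because
classification performance, not any specific feature list, is the
meaningful surface.  Perimeter follows the weighted boundary-pixel
convention of `skimage.measure.regionprops`; FormFactor = 4πA/P² is capped
at 1 since digitized perimeters of small discs can undershoot the analytic
circumference.  Location and provenance columns are carried but excluded
from the classifier input.

The classifier is a seeded random forest (100 trees, √p features per
split; an RBF-SVM is available behind a switch).  Training sets are
balanced per class (default 400 objects/class) by seeded sampling without
replacement; pool-limited classes contribute what they have and are
flagged.  Validation is stratified 5-fold cross-validation reported as a
row-stochastic confusion matrix with per-class recall/precision.  The UMAP
embedding standardizes features to zero mean / unit variance first and
uses n_neighbors = 15, min_dist = 0.1 by default.

## Screen simulation

The default design mirrors a realistic screen: 4 biological repeats × 6
plates, 18 × 14 = 252 used wells per plate in a chequerboard LPS± layout,
compounds split into two half-sets of ≤114 so each compound appears exactly
once per plate per LPS level on its 3 plates, plus 6 DMSO and 6
positive-control replicates per plate per LPS level, all randomly placed
per plate.  Baseline well counts default to 2000 neurons, 150 microglia,
120 astrocytes (scaled down ~5× from a full-scale well for tractability;
all configurable).  LPS multiplies expected counts by class-specific
effects — neurons ×0.075, microglia ×2.5, necrotic ×10, astrocytes ×1 —
matching the assay's biology.

Compound effects are archetypes: `neuron_protection` moves the expected
LPS+ neuron count linearly from the LPS+ toward the LPS− baseline
(1 = full protection); multiplicative terms act on microglia (per LPS
state), astrocytes and necrotic cells; `formfactor_shift` adds to the LPS+
median FormFactor.  Three presets encode the hit phenotypes recovered by
clustering: weak protection with untouched glia (~0.57), strong protection
with +39% LPS+ microglia and a negative FormFactor shift (~0.91), and
near-full protection with glial depletion and elevated baseline necrosis
(~0.98).

Count noise is negative-binomial via a gamma-Poisson mixture with
per-class dispersion α (variance µ + αµ²); α defaults to 0.01 (≈10%
overdispersion CV), a standard magnitude for cell-count data.  α = 0 gives
the deterministic rounded-mean limit used by the noise-free contract
tests.  Nuisance structure is multiplicative log-normal per repeat (sd
0.25, reflecting plating-density variation between preparations), plate
(0.06), row and column (0.03 each).  Median FormFactor per well is drawn
from N(0.45, 0.12) without LPS and N(0.72, 0.04) with LPS — highly
variable ramified shapes at rest, convergent amoeboid shapes when
activated — and is missing when a well has no microglia.

## Normalization, assay quality, hit calling

**Adapted Min-Max normalization.** Per repeat, neuron counts map through
(x − med₊)/(med₋ − med₊) where med∓ are the repeat's LPS∓ medians, so the
LPS− median lands exactly on 1 and the LPS+ median on 0; the microglia
direction is reversed.  Anchors default to all wells per repeat (the
repeat-wise medians); a control-only switch exists and should be used when
a large fraction of compounds is active, since active compounds drag the
all-well medians away from the null level.  The transform is invariant to
per-repeat rescaling of raw counts, which is exactly the between-repeat
nuisance it exists to remove.

**CV reduction.** Per condition (compound × LPS) the coefficient of
variation sd/mean is computed on raw and normalized tables and averaged;
conditions whose |mean| is below 5% of the largest |condition mean| in
either table are excluded from both, with a warning.  The floor handles a
structural degeneracy: inactive compounds' normalized LPS+ means are ~0 by
construction of the anchor mapping, where CV is undefined; 5% sits several
standard errors above those means and far below any condition with a real
response.

**Z′-factor** is 1 − 3(σ₊+σ₋)/|µ₊−µ₋| with sample standard deviations;
the robust variant substitutes medians and 1.4826-scaled MADs.

**ROUT outliers.** Robust center = median, robust scale (RSDR) = 68.27th
percentile of absolute residuals (with an N/(N−1) small-sample
correction); the 30% most extreme points are then tested outside-in with a
Benjamini-Hochberg threshold at FDR Q (default 1%) on their t-tail
probabilities.  If the RSDR is zero, points off the median are flagged
(they are infinitely many robust SDs away) and identical samples yield no
flags.  Plate QC robustly standardizes per-plate median class counts of
LPS− control wells (median/MAD, so a deviant plate cannot mask itself by
inflating the column scale), projects onto two principal components and
applies ROUT per component.

**Hit calling.** Responses are per-repeat condition means (repeat =
block).  Within each LPS level a blocked model y ~ treatment + repeat is
fitted (balanced case: closed-form double centering; unbalanced: least
squares with reduced degrees of freedom), and every compound is compared
to DMSO with the model's residual error.  The error term is estimated per
LPS family rather than pooled: after normalization the LPS− response
carries roughly an order of magnitude more variance than the LPS+
response, and a pooled residual would anti-conservatively shrink the LPS−
standard errors (Monte-Carlo null screens showed ~4-5× familywise error
inflation).  Familywise adjustment uses the equicorrelated (ρ = 1/2 in the
balanced case) multivariate-t distribution of the many-to-one contrasts,
evaluated by 96-point Gauss–Hermite × 48-point Gauss–Legendre quadrature;
this agrees with an independent Monte-Carlo evaluation and with
`scipy.stats.dunnett` on one-way layouts to ~10⁻⁴ in p, and critical
values invert the tail to 10⁻⁶.  Analyzing per-repeat means makes the
procedure conservative (the control's many-well mean is treated as a
single observation with compound-level noise); observed null familywise
error is below the nominal 5%, and power for protection ≥ 0.5 normalized
units at N = 4 is essentially 1.  Neurotoxicity calls use identical
machinery on LPS− wells.  No row/column/well position corrections are
applied by default: location effects are small by construction and
treatment positions are randomized.

## Phenotype clustering

The phenotype matrix holds, per compound, the mean (over repeat means) of
six class counts and the median microglial FormFactor, each with and
without LPS (14 columns).  Each parameter is min-max normalized jointly
across its two LPS columns over all compounds; filtering to hits + DMSO
happens after normalization so a hit-only matrix reuses the all-compound
scaling.  A parameter constant across all rows maps to 0.5 with a warning.
Clustering is complete-linkage on Euclidean distances; the cut is k = 3 by
default (the number of mechanistic categories the data support), and ties
are broken by row index, so tie-sensitive inputs should be ordered
deliberately.  DMSO is carried as a reference row but excluded from
category summaries.

## Problem sizes in tests

The test and acceptance workloads are scaled to what the analysis needs,
preserving the design's structure: classifier validation uses 40-45
synthetic fields (~4,700 labeled objects, ≥400 per class); hit-calling
error control uses 200 full-size null screens (227 compounds × 4 repeats)
plus 8 screens with planted effects; normalization and clustering sweeps
use 100-seed batches of scaled-down screens that keep the
triplicate-per-repeat replication of the full design.

## Known limitations

* The classical segmenter is tuned for the synthetic ellipse world; on
  real images a learned segmenter supplied through the external-mask
  interface will outperform it, and the measured >95% correct-object rates
  should not be read as expected real-image performance.
* Morphology is rendered with smooth boundary jitter, not branched
  processes, so FormFactor differences between presets are smaller than
  between genuinely ramified and amoeboid cells.
* The repeated-measures model treats repeat as a fixed block and applies
  no sphericity correction; a Greenhouse-Geisser-corrected or full
  mixed-model backend would be the next refinement for strongly
  heteroscedastic repeats.
* The unbalanced Dunnett path approximates the contrast correlation as
  equicorrelated; with many missing compound×repeat cells the adjustment
  is approximate (though conservative in the regimes tested).
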