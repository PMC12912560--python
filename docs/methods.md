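# Methods

`lungmorph` quantifies distal lung airspaces — alveolar ducts, intermediate
airspaces and alveoli — in calibrated RGB images of H&E-stained mouse lung
sections, and provides the statistical machinery used to validate such
automated readouts against manual mean linear intercept (L_M) scoring. This
note records the model, the parameters that matter, the numerical choices,
and what the synthetic test bed does and does not demonstrate.

## Segmentation model

An H&E section viewed at 20x is modelled as a two-phase image: dark-staining
parenchymal tissue and bright airspace lumina. The pipeline is a fixed
composition of classical operations:

1. **Green channel.** The green channel of the 24-bit RGB input is taken as
   the working grayscale image (no rescaling); for hematoxylin/eosin it
   gives the strongest tissue/background contrast.
2. **Exclusions.** An optional binary sidecar mask (same basename, `_mask`
   suffix; nonzero = excluded) marks vessels, bronchioles, connected
   exudates and pleural spaces. Excluded pixels are blanked to background so
   they never binarize to tissue, are never labeled as airspace, and are
   removed from *both* area denominators: every field satisfies
   `tissue + airspace + excluded = field area` exactly.
3. **Threshold.** Tissue = intensity ≤ `threshold`. The threshold is
   user-calibrated once per equivalently-stained batch; there is
   deliberately no automatic threshold selection (Otsu or similar), because
   staining intensity is a property of the batch, not of each image.
4. **Debris removal.** Connected tissue components smaller than
   `debris_min_um2` (default 50 µm²) are deleted — free-floating exudates
   and particulates inside lumina. Components at or above the cutoff are
   untouched.
5. **Binary opening.** Erosion then dilation with a 3×3 square, one
   iteration — the default of the common interactive tools this pipeline
   mirrors. Removes isolated pixels and smooths contours; idempotent.
6. **Hole filling.** Enclosed background components smaller than
   `hole_max_um2` (default 50 µm²) are filled. A "hole" must be fully
   surrounded by tissue: background connected to the image border is never
   filled, nor are excluded regions. Because only sub-cutoff holes are
   filled, every airspace ≥ 50 µm² is bit-identical before and after — the
   smallest quantified structure (alveolus gate, 150 µm²) is provably
   unaffected, and the test suite asserts this neutrality.
7. **Labeling.** Connected components of non-tissue, non-excluded pixels
   are labeled with 8-connectivity (tissue uses 4-connectivity — the
   standard dual pairing that avoids topological paradoxes on the digital
   grid). Border-touching airspaces are kept by default: ducts frequently
   span field edges at 20x and dropping them biases duct counts downward;
   `exclude_edge` removes them when the opposite bias is preferred.

The order of steps 4–6 is a contract, not a convenience: a sub-cutoff
tissue ring enclosing a sub-cutoff hole is removed entirely under the
canonical order but fused into a surviving blob if filling precedes debris
removal. A regression test pins the order.

## Measurement and classification

Each labeled airspace is measured as:

* area = pixel count × scale², in µm²;
* perimeter = Crofton estimate (4 directions) × scale, in µm;
* circularity = min(1, 4π·area / perimeter²).

The Crofton perimeter was chosen after calibrating candidate boundary
estimators on digital disks: chain-code (Freeman-weighted) perimeters score
a radius-50-px disk at circularity ≈ 0.91, while the Crofton estimate stays
within ~1% of the analytic circumference from radius 20 px upward, so large
disks score ≥ 0.95 as a circularity measure should. Single-pixel and other
degenerate objects hit the cap at 1.

Classification uses inclusive area/circularity gates:

| class        | area band (µm²)              | circularity |
|--------------|------------------------------|-------------|
| duct         | ≥ `duct_min_area` (4000)     | 0–0.5       |
| intermediate | [`alv_max_area`, `duct_min_area`) | none   |
| alveolus     | [`alv_min_area` (150), `alv_max_area`) | 0.01–1 |
| unclassified | everything else              | —           |

The duct and alveolus gates are the optimized defaults; the alveolus upper
bound `alv_max_area` (default 1500 µm²) defines the buffer band that keeps
ambiguous airspaces — terminal duct regions, alveolar sacs, very large
alveoli — out of both target classes. Its exact value is a declared
analysis choice, not an inferred constant, and it is echoed into every
report header. The intermediate band deliberately carries no circularity
gate. An airspace in the duct band that fails the duct circularity gate is
*unclassified*, not intermediate; the three class area bands are disjoint
by construction, so every airspace receives exactly one class.

Aggregation: per-field summaries (count, mean area, total area, percent of
classified airspace area per class) are averaged per animal with an
unweighted mean over fields of view — matching how manual L_M scores are
averaged — with an area-weighted alternative deliberately out of the
default path. Empty classes report their mean as missing, never as 0, so
group means are not dragged toward zero by fields lacking a class. Six
fields per animal is the expected design; other counts compute with a
warning.

## Mean linear intercept

L_M = AB / N_intersection: the length of a test line divided by the number
of airway walls it crosses. The counting convention (a known source of
observer variation in manual scoring) is fixed operationally: the line is
sampled at 0.25-px steps with nearest-pixel lookup, and one intersection is
one *maximal run of tissue pixels* crossed. A line entirely within tissue
counts one; a line entirely within a lumen counts zero and is flagged
invalid — excluded from averages, never silently infinite. Whether a line
*ending* inside a wall should count extra is left as a documented
convention rather than guessed; the run-counting rule treats endpoints
symmetrically.

Automated scoring replaces manual placement with seeded uniform-random
position and orientation, default two lines per field (twelve per
six-field animal, as in the manual protocol), with rejection and redraw of
lines that leave the field, touch the border margin, or cross an excluded
region — mirroring the manual rule of avoiding bronchioles and vessels.
Placement is deterministic per seed; failures after 200 retries reduce the
measurement count with a warning. Counts are scale-free, so L_M is exactly
equivariant under rescaling: multiplying µm/px by c multiplies every L_M
by c. On analytic stripe fixtures a perpendicular chord recovers the stripe
period to within one pixel width.

## Gate optimization

Because L_M is itself an airspace-size proxy, candidate gates are scored by
how strongly and *stably* their per-animal mean gated area correlates with
manual L_M. The candidate grids are minimum area × circularity range:
ducts {3000, 4000, 5000, 6000} µm² × {[0, 0.5], [0, 1]} (8 combinations);
alveoli {50, 100, 150} µm² × {[0.01, 1], [0.1, 1], [0.25, 1]} (9). Sweep
gates are minimum-area + circularity only (no upper bound); the buffer band
applies at classification time.

For each combination the full-sample Pearson r is computed together with a
leave-one-out family: each of the n animals is excluded in turn and r is
recomputed on the remaining n−1. The median and range of the LOO family
expose combinations whose headline correlation leans on a single animal.
Selection is operationalized as: among combinations whose LOO range
(max − min) is within a configurable stability cap (default 0.25), take the
highest LOO median r; break ties by full-sample r, then by smaller minimum
area. If nothing passes the cap it is relaxed with a warning. The full
ranked table is always emitted — the selection is advisory, reflecting the
human-in-the-loop judgment the procedure formalizes. The LOO statistics are
verified against brute-force recomputation of Pearson r on every
(n−1)-subset to 1e-12.

The p-value attached to a full-sample r is two-sided via the t transform,
t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom. This reproduces the
reference pairs (r = 0.7866, n = 7 → p = 0.0359; r = 0.9475, n = 7 →
p = 0.0012; r = 0.5823, n = 22 → p = 0.0045) to the printed precision.

## Agreement statistics

Area (µm²) and L_M (µm) live on different scales, so agreement is assessed
on z-scores, z = (x − µ)/σ, with the sample (n−1) standard deviation
throughout. Two consequences are exact identities, both enforced at 1e-9
in the test suite across random datasets:

* the Bland–Altman bias of z-scored pairs is 0 (difference of two
  zero-mean series), so only *relative*, not fixed, agreement is assessed;
* the 95% limits of agreement are ±1.96·√(2(1−r)) with r the sample
  Pearson correlation, since var(z_x − z_y) = 2(1 − r).

The multiplier is the normal-quantile 1.96, not a t quantile — confirmed by
back-computation against all four reference LOA/r pairs. A further identity
worth knowing: the linear slope of differences on pair means vanishes for
z-scored pairs (cov(z_x − z_y, z_x + z_y) = var z_x − var z_y = 0), so the
reported proportional-bias slope can only flag numerical issues; genuine
proportional bias survives standardization only as curvature and is judged
from the plot.

Group comparisons use an unpaired two-tailed t-test, gated by a two-sided
F-test on the variance ratio (p = 2·min(cdf, sf) of s²_a/s²_b): Welch's
correction is applied when the F-test p falls below `variance_alpha`
(default 0.05). Shapiro–Wilk normality checks precede Pearson correlations;
non-normal inputs are flagged but the statistics are still returned — the
gate is a report, not a switch, since no fallback behaviour is defined for
its failure.

## Synthetic test bed

No histology images accompany the method, so the package carries a
generator that renders ground-truthed stand-ins (synthetic by construction
and labelled as such): non-overlapping ellipses with sinusoidal boundary
perturbation carved out of a uniform tissue background, H&E-like palette
(tissue green ≈ 70, lumina ≈ 238, threshold 150), 512×512 px at 1.0 µm/px
by default. Axis ratio and perturbation amplitude are the levers that set
circularity: alveoli are near-circular (ratio 1–1.4, amplitude 0.05),
ducts elongated and irregular (ratio 5–6, amplitude 0.12, giving measured
circularity ≈ 0.28–0.45, safely inside the 0–0.5 gate). Class areas are
drawn log-normally and clipped at least 10% inside the classification
bands, so noiseless class recovery is well-defined. A minimum wall
thickness (8 µm) separates all airspaces. Optional vessels (bright lumen in
a thick wall, covered by the emitted exclusion mask) and sub-cutoff exudate
specks exercise the exclusion and debris paths.

Phenotype presets encode the two study conditions per field: `normoxia`
≈ 40 alveoli (median 420 µm²), 5–8 intermediates, 2–3 ducts (median
6000 µm²); `hyperoxia` ≈ 12–18 larger alveoli (median 750 µm²), 4–6
intermediates, 3–5 larger ducts (median 8500 µm²). These choices make the
hyperoxia preset reproduce the qualitative disease signature — larger ducts
occupying a greater share of airspace; fewer, larger alveoli occupying
less; higher L_M — which the end-to-end test verifies on a seeded 3 vs 3
animal × 6 field cohort (a desk-scale version of the 12 vs 10 validation
design).

What passing these tests shows: the pipeline, measurement, classification,
L_M and statistics are internally correct and recover known ground truth
under the stated two-phase image model. What it does not show: performance
on real histology, where staining variability, sectioning artifacts,
partial-volume boundaries, touching airspaces and genuinely ambiguous
structures dominate error. The generator deliberately renders none of
these (intensity noise is available but off by default), so real-image
validation still requires the manual-L_M comparison workflow the package
automates.

## Numerical choices and degeneracies

* Determinism: identical input and configuration give bit-identical label
  maps and tables; all randomness (line placement, synthesis) flows from
  explicit seeds, with per-image seeds spawned from one root.
* Exact-correlation construction: paired fixtures hit a target sample r to
  1e-9 by mixing a centred unit vector with its residual-orthogonal
  complement at angle arccos(r); used wherever a statistic must be tested
  at a known r.
* CSV is the canonical output (shortest-round-trip floats; re-read with
  round-trip parsing to reproduce values bit-exactly); XLSX mirrors CSV
  when enabled. Every output directory receives the serialized
  configuration and its hash.
* Degenerate inputs: all-tissue fields label zero airspaces with a
  warning; an all-true exclusion mask is an error; zero-variance series
  refuse to z-score; LOO subsets with zero variance are flagged and
  excluded from the median.
* Problem sizes used in the shipped tests (chosen as representative desk
  scale): single 512² fields for recovery checks, 256² fields at 2 µm/px
  for batch/CLI round-trips, 3 vs 3 × 6-field cohorts for the
  direction-of-effect run.

## Known limitations

* No stereological estimators (surface density, number-weighted volumes),
  no radial alveolar counts, no 3D reconstruction; no section-thickness or
  shrinkage corrections to L_M.
* The intermediate band's bounds are declared configuration, not values
  recovered from data; results for that class should be read as
  buffer-zone accounting.
* Exclusion masks replace an interactive wand step; the package does not
  auto-detect vessels or bronchioles.
* Classification is per-section-plane: a tangential cut through a large
  airway can legitimately land in the alveolus band, which is exactly the
  ambiguity the buffer band limits but cannot eliminate.
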