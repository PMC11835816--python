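# Methods

This note records the models, conventions and parameter choices behind
the package, and what the synthetic validation does and does not show.

## Study design being analysed

A greenhouse waterlogging trial on kiwifruit: three self-rooted
rootstocks — B ('Bounty 71', *A. macrosperma*), D ('D1') and H
('Hayward', both *A. chinensis* var. *deliciosa*) — and the yellow-fleshed
scion 'Zesy 002' grafted on each (Z/B, Z/D, Z/H). Vines are either
well-watered (WW) or waterlogged (WL, substrate kept saturated) for nine
days; time is indexed as days after waterlogging onset (DAW 1–9).
Imaging (top view and two orthogonal side views, plus a side-view NIR
raster) happens at DAW 1, 2, 3, 4, 7 and 9, NIR at DAW 2, 3 and 9 only.
Gas exchange (gs, E, A, Ci, T_leaf; n = 4 vines per cell) is measured at
DAW 1–4, at 11:00 solar time for rootstocks and 10:00 for grafts.
Support sticks are painted blue specifically so colour rules can remove
them from the images.

## Image indices

**Segmentation.** A pixel is plant iff hue ∈ [`hue_min`, `hue_max`]
(default 40–190°), saturation ≥ 0.15, value ≥ 0.10, and hue ∉ the blue
window (200–260°). The plant window deliberately brackets the 60–180°
analysis bands with margin; all thresholds are config-overridable
because any real deployment must tune them to its illumination.
Connected components below 20 px are removed by default (sensor-noise
robustness); ground-truth recovery tests disable this cleanup so the
comparison is exact. Hue is always expressed in degrees on [0°, 360°);
any half-range raster encoding is converted at read time by the shared
HSV helper.

**Projected shoot area.** PSA = Area(TV) + Area(0°SV) + Area(90°SV),
times a calibration factor in cm²/px. The calibration is a required
input with no default — it is a property of the camera geometry, not of
the method. PSA is exactly linear in the calibration and additive over
views; the three-view sum averages out leaf overlap visible from any
single direction.

**Solidity.** S = plant pixel area / filled convex-hull pixel area.
The hull is the convex hull of plant *pixel centres*; a raster pixel
belongs to the filled hull iff its centre lies inside or on the hull
polygon, decided with exact integer half-plane tests (hull vertices are
lattice points, so there is no floating-point boundary ambiguity). The
per-plant value is the mean over the two side views; the top view can
be included by config. The side-view default keeps S consistent with
the other side-view indices (SI, NIR) and with reporting a single S per
plant.

**Colour.** The hue histogram of plant pixels uses 360 one-degree bins
centred on integer degrees (bin k covers [k−0.5, k+0.5)), so a
single-hue plant at 120° has weighted mean hue exactly 120°. HUE is the
linear (non-circular) weighted mean over the pooled side-view
histogram; linearity is safe because segmentation excludes blues and
the achromatic background, leaving no mass near the 0°/360° wrap — a
documented limitation if the plant window were widened across the wrap.
GAS and GerAS count bins 60–180 and 80–180 inclusive (membership at bin
resolution); SI = (GAS − GerAS)/GAS ∈ [0, 1] and is undefined
(explicitly signalled, never 0 or 1 by fiat) when GAS = 0. GAS/GerAS
and SI are pooled over both side views; pooling equals per-view
averaging up to view-size weights and keeps SI identical to the
generator's ground truth.

**NIR.** The water proxy is the arithmetic mean of the side-view NIR
raster over the RGB-derived plant mask, on the raw 8-bit scale with no
reflectance calibration (reported values sit in ≈150–200). Physics:
water absorbs near 1,450 nm, so high tissue water content ⇒ low
reflected intensity. RGB and NIR rasters are assumed co-aligned and
same-size; real-data registration is an upstream config-level rescale.

## Gas-exchange metrics

WUEi = A/gs (µmol CO₂ mol⁻¹ H₂O) is computed per record and then
averaged — not as a ratio of means — because it is defined per
measurement; records with gs ≤ 0 are retained with WUEi missing and a
log entry. Percent changes use the reduction convention
100 × (1 − WL/WW) (positive = reduction) with a companion
percent-increase form; values are reported both raw and rounded to the
nearest whole percent, matching how such changes are narrated. Response
fits of A or E against gs are ordinary least-squares polynomials of
explicitly requested degree (1 or 2, never silently selected), with R²
from the residual sum of squares. Diurnal profiles are per-hour group
means ± SE within a single DAW; n = 1 groups get an undefined SE, empty
groups are omitted with a log entry. Hours are kept as configured local
solar time strings; no timezone arithmetic.

## Statistics

At each DAW and for each variable: a two-way ANOVA
(treatment × cultivar) with the interaction always included, using
Type II sums of squares — on the balanced designs generated here Type II
equals classical (Type I) ANOVA, and it remains sensible for mildly
unbalanced real data; a one-way WW-vs-WL ANOVA within each cultivar
(equivalent to a pooled-variance t test for two groups); Tukey HSD
adjusted pairwise p-values from the studentized range distribution.
α = 0.05 by default, configurable. Each DAW is tested independently
with no multiplicity correction across days or variables — a deliberate
statistical caveat of the per-day reporting style, not an oversight.

**Compact letter displays.** Letter classes are the maximal cliques of
the non-significance graph (nodes = groups, edge iff adjusted p ≥ α),
enumerated with Bron–Kerbosch and lettered in order of descending group
mean; lowercase letters mark main-effect comparisons, uppercase the
treatment × cultivar cells. The clique construction guarantees the
validity condition — two groups share a letter iff they do not differ
significantly — which simpler insert-and-absorb heuristics can violate
when an absorbed member blocks a later pair. Degenerate zero-variance
comparisons map 0/0 studentized ranges to p = 1 (tied constant groups
do not differ).

Shapiro–Wilk (per group) and Levene (across groups) run as advisory
checks: results are reported, the pipeline proceeds regardless; groups
with n < 3 or zero variance are skipped with an explicit reason.

## Synthetic data generator

The generator defines the study conditions under which everything is
tested.

*Images.* Leaves are filled discs (radius jittered ±30%) on a uniform
mid-grey, zero-saturation background that no hue threshold can capture;
the stick is a pure-blue (220°) vertical bar (a small disc in the top
view). Each plant pixel gets an integer-degree hue — a
`chlorosis_fraction` of them uniform on 62–78° (yellowing band), the
rest uniform on 85–175° (green band) — painted at S = V = 1. With two
RGB channels exactly 0/255, the uint8 round trip perturbs hue by at
most ≈0.12°, so every pixel is recovered in its assigned one-degree bin
and the ≥2° margins keep band membership exact: segmentation and
colorimetry can be validated pixel-perfectly. Default raster size is
800 × 600 (tests use smaller rasters; every index is a pixel count,
ratio or mean, so conclusions do not depend on resolution). NIR plant
pixels take the single value round(I_max − w·(I_max − I_min)) with
defaults I_min = 100, I_max = 220 bracketing the realistic 150–200
range on an 8-bit scale. Ground truth (per-view pixel counts, pooled
side-view hue histogram, GAS/GerAS, SI, mean NIR) records rendered,
post-clipping, post-overlap pixels.

*Experiment-level trajectories.* Per-cultivar waterlogging
susceptibility (B 0.1, D 1.0, H 0.8, Z/B 0.3, Z/D 1.2, Z/H 0.9) scales
three linear-in-DAW stress responses in WL plants: chlorosis
0.05 + 0.04·s·DAW (capped 0.85), water content 0.75 − 0.05·s·DAW
(floored 0.10), and a canopy size factor that at full susceptibility
halves the leaf radius by DAW 9 (≈70% projected-area loss, the
magnitude seen in the most sensitive graft). WW plants hold basal
values and grow +2% radius per day. Cultivar leaf-radius factors
(B 0.7 … Z/H 1.15) reproduce the large PSA differences between
cultivars. These are fixed study conditions, not tuning knobs.

*Physiology.* The default effect model takes its numbers from the
bundled published group means: WW cell means per DAW as baselines (gs
backed out exactly as A/WUEi), printed WL/WW ratios as multiplicative
treatment effects, n = 4 replicates, and per-variable replicate noise
equal to the median printed SE·√n. Transpiration E, not tabulated, gets
cultivar-level baselines in the reported 2.3–4.6 mmol m⁻² s⁻¹ range and
follows the gs effect, since E tracks stomatal closure. Noise is
additive Gaussian; gs and E are floored at small positive values
(10⁻³ / 10⁻²) because conductance and transpiration are physically
positive. A missing effect entry for a requested cell is a hard error.

*What passing does not show.* Synthetic plants have no specular
highlights, shadows, soil, pots, overlapping neighbours, illumination
drift between sessions, or sensor noise; hue compositions are two clean
uniform bands rather than continuous chlorophyll gradients; NIR fields
are spatially constant. Pixel-perfect recovery here therefore validates
the *index definitions and their implementation*, not the robustness of
any particular threshold set on real photographs — on real data the
segmentation window is the sensitive choice and must be tuned.

## Numerical and degenerate-input conventions

Undefined quantities (solidity/HUE/SI/NIR of an empty plant, WUEi at
gs ≤ 0, percent change from a zero mean) raise an explicit
`UndefinedResult` at the scalar level; the batch pipeline catches these
per plant-day, stores NaN and a QC flag (`empty_mask`, `undefined_si`,
`missing_nir`, …) so downstream statistics can filter explicitly.
Zero segmented pixels is a valid empty mask, not an error. Missing
views skip the plant-day with a log entry; malformed plant ids abort
the run. Batch outputs use a fixed row order and float format so reruns
are byte-identical; all randomness flows from explicit integer seeds.

## Problem sizes used in validation

Tests render plants at 100×120 to 200×260 px (10–20 k plant pixels),
which already leaves hue-quantisation effects far below the tested
tolerances; ANOVA calibration uses 1,000 null simulations at n = 4–5
per cell (the study's replication), giving a binomial SE of ≈0.7% on
the 5% rejection rate; hull-area exactness is checked against an
independent shapely point-in-polygon oracle on randomized masks up to
1,000 px; letter-display validity on 100 randomized group layouts. The
analysis drivers render 216 plant-days at 150×200 px.

## Implementation notes

Standard steps ride on the usual stack: scikit-image (HSV conversion,
drawing, component filtering), scipy (convex hulls, classical tests),
statsmodels (OLS/ANOVA, Tukey HSD), pandas (tables), imageio (PNG I/O),
click (CLI). The index definitions, the hull fill, the letter-display
construction and the generator are implemented here. The compact letter
display and the integer-exact hull fill are validated against
independent oracles (adjusted-p graph checks; shapely point-in-polygon
scans) rather than against the code paths that produce them.

## Known limitations

* Linear weighted mean hue breaks for hue distributions spanning the
  0°/360° wrap (cannot occur with the default plant window).
* Band membership at bin resolution can misassign hues within 0.5° of
  a band edge on real (non-synthetic) images.
* No colour constancy or illumination correction across sessions.
* NIR registration is assumed; no multi-wavelength unmixing or absolute
  water content (g/g).
* DAW is treated as independent snapshots — no repeated-measures or
  mixed-effects modelling of the within-plant time course, and no
  correction for testing many DAWs/variables.
* The percent-change convention reports reductions as positive; mixing
  with the increase form requires attention to sign.
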