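# Methods

## Geometry

All computation happens in a frame-local Cartesian system in millimetres,
y-up, polar angles counter-clockwise from +x. Lumen contours are simple
counter-clockwise polygons; devices are circles polygonized with 360
vertices by default (inscribed-polygon area deficit < 0.02 %; the vertex
count is configurable wherever it matters). Region booleans (predicted =
burr circle ∖ lumen, actual = post ∖ pre, overlap = P ∩ A) use shapely's
exact polygon clipping.

**Angular extent.** The angle of a region about the lumen centre is the
measure of the union of the angular intervals its boundary edges subtend
at that centre. Because polygon edges are straight, each edge subtends
exactly the arc ≤ 180° between its endpoint angles, so the extent is
computed by interval union (with 0/360 wrap-around merged) with no ray
sampling; disconnected components contribute the union of their
intervals, not their maximum span. The centre is the centroid of the
**pre**-procedure lumen for P-, A- and O-angles alike — the source
measurements name only "the lumen centre", and fixing the pre-RA centroid
keeps the prediction computable before the procedure. The centre lying
inside the region is a geometric error (ablation lives in the wall).

**Clearances.** Device-to-device clearance is exact circle arithmetic:
centre distance minus both radii, clamped at zero (containment and
overlap are contact). Device-to-intima clearance is the distance from the
device surface to the lumen contour, the relevant surface for a device
sitting inside the lumen. Whether the original workstation measured
surface-to-surface or centre-to-centre distances is unknowable from the
source; surface-to-surface is used because the contact definition
("distance = 0") only makes sense for surfaces. Measured clearances below
10⁻⁶ mm are snapped to exactly 0 so that *contact ⇔ clearance = 0* holds
as an identity, not a float comparison.

**Lumen diameters** are full chord lengths through the lumen centroid at
1° steps over [0°, 180°); for non-convex contours a chord may exit and
re-enter, in which case the total in-lumen length is used (occurrences
are logged). Minimum and mean of the 180 chords are reported.

**Actual ablation** counts only removed tissue (post ∖ pre). Apparent
lumen loss (pre ∖ post — prolapse, recoil, registration error) is never
mixed into A; it is surfaced per frame as `lumen_loss_area`.

## Per-frame metrics and exclusions

%Correct area = 100·O/P and %Error area = 100·(A−O)/A, with angle
analogues from angular extents. Frames whose P- or A-area falls below
ε = 0.001 mm² carry undefined percentages: they are flagged `excluded`
with a reason instead of propagating NaNs or silent zeros. Exclusion by
A is mode-independent by construction (A does not depend on where the
prediction circle is drawn). Calcification is typed annotation-first:
any nodular annotation wins (no geometric protrusion criterion exists in
the source); otherwise merged non-overlapping arc coverage ≥ 270° is
circumferential (the boundary resolves high), below is eccentric.
Burr/lumen ratio is burr diameter over the per-frame mean lumen diameter.

## Lesion aggregation

Volumes are rectangle-rule integrals, Σ areaᵢ × spacing (default 1 mm),
over the lesion's analysis region — the longest contiguous run of frames
with measurable ablation. Volume percentages are ratios of integrated
volumes and therefore P-weighted: %Correct volume is *not* the mean of
the per-frame percentages, and lies outside their range whenever P-areas
differ across frames. Mean angles and mean percentages average included
frames only.

## Cohort statistics

The four-group split uses cohort medians of %Correct and %Error area
with "high" = ≥ median (deterministic half-open tie rule). Finding
cross-tabs use the χ² test; Fisher's exact test replaces it when the
table collapses to 2×2 with an expected cell < 5 (scipy offers Fisher
only for 2×2; larger sparse tables keep χ² and are flagged
`chi2_low_expected` in the result).

Logistic modelling follows a screen-then-fit design: one-predictor fits,
retain p < 0.15, joint fit of the retained set, odds ratios with Wald
95 % CIs (two-sided p < 0.05 significant). Distance predictors are
rescaled to 0.1-mm units before fitting so ORs read "per 0.1-mm
increase". Complete separation drops the candidate with a warning. Frames
are treated as independent observations, a deliberate simplification the
per-frame design shares with its field; a per-lesion cluster-robust
covariance is available (`cluster_col=`) but off by default.

The ROC cutoff criterion is the Youden index (sensitivity + specificity
− 1) for the rule *score > c*, ties broken toward the smaller cutoff, so
a clearance ROC whose information is "contact vs not" yields cutoff
"> 0.0 mm". AUC is computed from the Mann–Whitney U statistic (ties half
weight), which makes the pair-counting identity AUC = U/(n₁n₀) exact;
the p-value is the asymptotic-normal Mann–Whitney test of AUC ≠ 0.5.
Mode comparisons report per-stratum (contact / non-contact) medians and
two-sided Mann–Whitney p per accuracy metric.

## Synthetic cohort generator

The generator is the package's stand-in for unavailable patient imaging,
and its defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| lesions × frames | 55 × U{5..12} (≈470 frames) | cohort scale of the application domain |
| lumen area | lognormal, median 2.91 mm², log-sd 0.31 (radius) | pre-RA lumen area median/IQR |
| lumen shape | ellipse (axis ratio 1–1.35) + harmonics 2–5, rel. amplitude 0.04 | realistic non-circular contours, star-shaped hence simple |
| catheter | 0.9 mm; against the wall with p = 0.6, else exp(0.19 mm) clearance | catheter–intima median 0.00, IQR 0–0.09 mm |
| wire | 0.229 mm; touching the catheter in 75.3 % of frames, else exp(0.30 mm) clearance on a 0.05-mm grid | observed contact fraction; tangential-to-wall placement gives wire–intima median ≈ 0.2 mm |
| burr diameter | {1.5: 19, 1.75: 26, 2.0: 8, 2.15: 1, 2.25: 1} per lesion | clinical first-burr usage mix |
| ablation centre | catheter centre if contact else wire centre, + N(0, 0.25 mm)² jitter + N(0, 0.1 mm) radial depth noise | the mechanism under test: the catheter displaces the wire it touches |
| findings | logistic in the out-of-prediction fraction: deep injury −4.8 + 3.5·f, flap −4.0 + 3.0·f | marginal rates ≈ 4 % / 11 %, concentrated in high-error frames |

The post lumen is the pre lumen united with the burr disc at the
(jittered) effective centre, so post ⊇ pre holds exactly and
A-area = post area − pre area is an identity the geometry layer is tested
against. Depth noise perturbs the disc centre, never the contour, to
preserve that invariant. The contact flag is drawn once per frame and
preserved across geometric retries so infeasible placements cannot bias
the cohort contact fraction; a lumen too small to hold a separated wire
falls back to contact (as it physically must) with a log message.
Randomness flows from one integer seed; per-lesion substreams are spawned
from (seed, lesion index), so any lesion regenerates identically in
isolation.

What the generator does **not** emulate: speckle, light attenuation and
segmentation error; wire migration during repeated burr passes (jitter is
its only surrogate); calcium arcs influencing where the burr bites;
longitudinal correlation beyond the shared lesion-level size factor; and
lumen loss (post ⊇ pre always, so the `lumen_loss_area` diagnostic is
exercised only by hand-built fixtures). Passing tests therefore show the
*pipeline* is correct and the *statistics recover known mechanisms* —
they do not validate predictive accuracy on real imaging.

A separate lightweight simulator (`simulate_distance_outcome`) draws
(clearance, outcome) pairs with log-odds increasing by log(1.7) per
0.1 mm for logistic/ROC recovery experiments at chosen n.

## Numerical and interface choices

- Circle polygonization 360 vertices (configurable); closed-form tests
  use 720 to keep discretization below the 10⁻³ mm² tolerance.
- ε = 0.001 mm² exclusion threshold; contact threshold 10⁻⁶ mm.
- Frame indexing is 0-based; z in mm increases along the pullback
  (distal → proximal). Geometry is stored as JSON (schema-validated,
  version 1), flat metric tables as CSV.
- Clockwise input contours are re-oriented with a warning;
  self-intersecting or degenerate (< 10⁻⁶ mm²) contours are errors that
  name the offending frame.
- Test problem sizes: the Monte-Carlo geometry cross-check uses 200
  frames × 10⁶ points; logistic recovery uses 100 replicate cohorts of
  n = 500; screen calibration 500 simulations of n = 400 — sizes chosen
  to keep sampling error well inside the asserted tolerances.

## Known limitations

Frame independence in the statistics (see above); the median-split
groups are cohort-relative, so group counts are not comparable across
cohorts with different accuracy distributions; the wire-based prediction
shares the frame-exclusion rule with the catheter-based one but its
P-area can vanish (wire deep in the lumen), which is reported as an
exclusion rather than 0 % correct; and with a weak ROC (AUC ≈ 0.6) the
Youden cutoff on a single ~500-frame cohort scatters a few grid steps
around the population optimum — single-cohort cutoffs should be read
with that in mind.
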