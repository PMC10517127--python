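# Methods

This note records the measurement conventions, the synthetic image model,
and the design choices made where the procedure left room for
interpretation. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Corrected perivascular reflectivity

The core measurement, per eye and analyzed quadrant:

| step | operation | convention |
|---|---|---|
| 1 | quadrant split | four equal corner blocks; Q1 top-left, row-major; even side required |
| 2 | threshold | mean + 2·SD of the analyzed OCTA **quadrant**; sample SD (ddof = 1); whole-frame scope selectable |
| 3 | binarize | strict `pixel > threshold`, so a constant quadrant yields an empty mask rather than an all-true one; inclusive comparison selectable |
| 4 | particle filter | keep connected components of area **≥ 3 px**, 8-connectivity; both the minimum area and 4-connectivity selectable |
| 5 | transfer | HSS mask indexes the co-registered structural quadrant; arithmetic mean over mask-true pixels |
| 6 | normalize | divide by the mean of the **full** structural frame (one overall value per eye); quadrant-only denominator selectable |

Rationale for the contentious defaults: "bigger than three pixels" and
"three pixels or more" both circulate as descriptions of this kind of
particle filter; `>= 3` is operative here because three consecutive pixels
(≈ 28 µm at 9.375 µm/px) is the stated minimum meaningful vessel calibre at
a 20 µm lateral resolution. The quadrant-scope threshold follows from the
measurement being defined per obstructive quadrant; per-eye reporting of a
single threshold simply reports the analyzed quadrant's value. Whether
threshold statistics are quadrant- or frame-scope is exposed as
`threshold_scope` and never chosen silently.

Degenerate inputs are loud: an empty HSS mask raises a typed
`EmptyMaskError` ("no HSS area"), never a NaN; a zero overall mean raises
`DegenerateImageError`; an odd image side raises `GeometryError`. Eyes
failing the device quality gate (score < 65) are excluded before
measurement with a logged reason.

Invariants enforced by tests: quadrant reassembly is bit-exact; every HSS
pixel exceeds its stored threshold and every component has at least the
minimum area (flood-fill recount); the corrected ratio is invariant (to
1e-12) under uniform structural gain; it equals exactly 1 for a constant
structural image; and it strictly increases when intensity is added inside
the HSS area only.

The contralateral quadrant is the diagonally opposite one by default
(`Q1↔Q4`, `Q2↔Q3`); a per-eye `contralateral` metadata column can override
it, since clinical practice may prefer the horizontally mirrored quadrant
across the raphe.

## Vessel density and FAZ morphometrics

Vessel density = 100 × (pixels strictly above the arithmetic mean of
in-scope pixels) / (in-scope pixel count), where "in scope" excludes the
FAZ mask from both the threshold statistics and the denominator (the FAZ
is excluded *before* binarization). A constant region returns 0% with a
warning.

FAZ area is pixel count × pitch²; the perimeter estimator is a package
convention because device-software estimators are undocumented and
perimeter dominates circularity. Default: marching-squares — the 0.5-level
contour of the binary mask (after 1-px zero padding) as a polyline, summed
segment length. A digital disc of radius 40 px measures circularity ≈ 0.91;
the Crofton-formula estimator (selectable, `perimeter_estimator="crofton"`)
gives ≈ 1.01. Circularities are therefore comparable within, not across,
pipelines. A naive crack-length (edge-count) perimeter was rejected: it
overestimates a disc's perimeter by 4/π and drives disc circularity to
≈ 0.62.

## Statistics

- **ICC**: two-way random effects, absolute agreement — ICC(2,1) single
  measures, ICC(2,k) average measures — implemented directly from the
  two-way ANOVA mean squares and cross-checked against an independent
  implementation in tests. Zero between-subject variance returns 0 with a
  warning. The exact variant used by any given clinical report is rarely
  stated; this choice is the standard one for two independent graders
  rating the same eyes.
- **Group comparison**: one-way ANOVA, then all pairwise independent
  t-tests, Student (pooled variance) by default to match common statistical
  package defaults, Welch selectable (and automatic when a group has zero
  variance). Bonferroni family = the three pairwise comparisons;
  adjusted P = min(1, 3 × raw P).
- **Regression**: outcome and each predictor z-scored with sample SD;
  binary covariates coded 0/1 before standardization, so the univariate
  standardized β equals the Pearson correlation (identity tested to 1e-10).
  Predictors with univariate P < 0.2 enter one joint multivariate fit.
  Missing covariates are dropped listwise per model with logged counts; a
  rank-deficient multivariate design raises an error naming the collinear
  predictors.
- **Duration sub-analysis**: disease eyes split at 36 months from diagnosis
  to scan; independent t-tests on reflectivity and injection rate between
  strata, plus within-stratum simple regressions (standardized β, R², P).
  A stratum with n < 3 skips its regression with a warning.

## Synthetic cohort generator

The generator exists because no public scans accompany this measurement
problem; it fabricates inputs with known planted structure so every
pipeline stage is testable end to end.

**Vessel tree.** Correlated random walks on the pixel grid: the first
branch enters from a field edge; each subsequent branch sprouts from an
existing centreline pixel in (or heads toward) the currently least-covered
quadrant, keeping the tree connected and the quadrants comparably
vascularized — necessary because all downstream statistics are per
quadrant. Branches accrue until dilated coverage (centreline dilated to
5 px width) reaches the target fraction, 0.35 by default; near the target,
branch length shrinks to the remaining deficit so the achieved coverage
stays within ±20% of the target. A central disc (radius 0.1125 × side
≈ 0.34 mm) is cleared and doubles as the FAZ mask.

**OCTA intensity model** (8-bit units): Gaussian stromal background
N(90, 25²); on vessels, base 120 plus Rayleigh(45) speckle multiplied by a
smooth log-normal *flow-heterogeneity field* (log-SD 0.4, correlation
length 5% of the image side); the whole frame is then smoothed with a
σ = 0.8 px Gaussian to emulate the ~2 px speckle grain of a 20 µm-resolution
scan. The heterogeneity field is what makes the mean + 2 SD threshold
well-behaved: the HSS becomes the brightest vessel segments — contiguous
particles of realistic size — rather than isolated speckle peaks, and the
HSS area stays stable across quadrant vessel-coverage variation. Without
it, a purely bimodal model pushes the threshold above the 8-bit ceiling in
vessel-rich quadrants and empties the mask.

**Structural intensity model**: Gaussian background N(110, 10²), +36 on
vessels, and the planted elevation **δ** added on the *perivascular band* —
the vessel mask dilated by 2 px, vessel core included — restricted to the
designated obstructive quadrant, then the same σ = 0.8 smoothing and 8-bit
quantization. The band includes the vessel core deliberately: the HSS mask
lies on the vessels themselves, so an elevation confined to a vessel-free
halo would never intersect it and could not move the ratio.

**Planted cohort structure.** δ ~ N(18, 6²) truncated at 0 for recurrent
eyes, N(4.5, 6²) for indolent, exactly 0 for controls (who get a matched
analysis quadrant but no obstruction). These values were calibrated once so
that the measured group means land in the 1.31 / 1.22 / 1.19 regime
reported for recurrent / indolent / healthy eyes, with thresholds ≈ 200 and
per-quadrant HSS areas ≈ 1000 px at 320 px — the magnitudes a real cohort
table shows. Covariates are drawn from group-specific normal models typical
of an elderly vein-occlusion cohort (ages ≈ 62–65, IOP ≈ 14–16 mmHg,
myopic refraction, arm sizes 45/30/45); the annualized injection rate is
linked linearly to δ (0.30 + 0.11·δ + N(0, 0.6²), clipped at 0, giving
≈ 2.3/yr recurrent vs ≈ 0.8/yr indolent), and refractive error carries a
weak link (0.03 D per unit of group-centred δ).

**What the generator does *not* emulate**: optical speckle statistics,
projection artifacts, segmentation errors, motion lines, inter-eye
registration error, irregular FAZ outlines, and biological covariance
beyond the stated linear links. Passing tests therefore demonstrate that
the measurement chain recovers *planted* structure under this model — not
that the clinical effect itself is reproduced. Measurement noise here is
smaller than biological and device variability in real scans, so P values
on synthetic cohorts are far smaller than clinical ones would be; the
recovery criteria are phrased as ordering/rejection *fractions over
replicates*, not as matching clinical P values.

**Determinism**: one `SeedSequence` per cohort spawns one child generator
per eye; all sampling is NumPy `Generator`-based, so a (seed, config) pair
reproduces images and tables byte-identically. Seeds used anywhere in the
package stay below 2³¹.

**Record-level generator** (`generate_records`): bypasses rendering and
plants an exact population standardized correlation between injection rate
and reflectivity (optionally confined to the < 36-month duration stratum),
plus optional null predictors; variables live on plausible clinical scales
but are deliberately unclipped so planted coefficients are exact. Used for
the statistics-engine recovery and type-I-error checks, where image noise
would only blur the planted coefficient.

## Problem sizes in validation

The replicate recovery study runs 100 cohorts of 45/30/45 eyes at a reduced
128 × 128 px raster — the metric is size-agnostic by construction (the
elevation is additive and coverage fractions are scale-free), and the
reduced raster keeps a 100-replicate study to a couple of minutes on one
CPU. The flagship acceptance run uses the full 320 × 320 px geometry for a
single cohort. Regression recovery uses n = 500 records; the null
calibration uses 1000 replicates of n = 100.

## Known limitations

- Absolute circularity values depend on the perimeter estimator (above);
  only within-pipeline comparisons are meaningful.
- Vessel density tracks the generator's coverage target (default 0.35 →
  ≈ 36%), somewhat below the ≈ 45% typical of real deep-plexus angiograms;
  raising the coverage target raises it, but the default was frozen with
  the reflectivity calibration.
- The particle filter and threshold are faithful to the specified
  procedure; alternative HSS definitions (e.g. RPE-referenced thresholds)
  are out of scope.
- `analyze` assumes structural and OCTA frames are co-registered, as
  produced by a single acquisition; no registration is attempted.
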