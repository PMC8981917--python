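# Methods

This note records the models, conventions and numerical choices behind
`ringmech`, and what the synthetic-data generators do and do not emulate.

## Units and conventions

Canonical internal units are N, mm, s and MPa; stress computed from loads in
N and areas in mm² is dimensionally MPa with no conversion factor, which
removes a whole class of silent unit bugs. Force columns may be declared in
mN on input and are converted on read. Extension is zero at the start of the
test (grips at the initial grip-to-grip distance). CSV files are
comma-separated UTF-8 with a mandatory header and `.` decimal.

## Tensile analysis

**Tension onset.** The specimen is considered in tension at the first
sample whose *raw* (pre-drag-subtraction) load exceeds 5 mN — the load
cell's resolution — and the gauge length is the grip-to-grip distance at
that sample. Drag subtraction then applies to the stresses. Applying the
threshold to the corrected load instead is possible by subtracting first
and passing the corrected trace; the default follows the literal raw-load
rule.

**Stress.** A ring pulled over two pins carries load through two limbs, so
engineering stress is N/(2A₀). A₀ is the elliptical area π(w/2)(h/2) from
paired top-view width and side-view height measurements; both the minimum
and the mean area over measurement positions are first-class conventions
(`minimum` is the default, giving the conservative upper stress bound).
Engineering and true stress–strain are both computed on every curve; the
true measures assume volume conservation and uniform deformation, and the
identities ε_t = ln(1+ε), σ_t = σ(1+ε) are exact by construction.

**Tangent modulus.** Windows are defined in strain units — width 0.08 of
strain, anchored at every sample, right-inclusive — and fitted by ordinary
least squares; the maximum slope over windows ending at or before the
failure sample is the MTM. Strain-width windows (rather than fixed sample
counts) make the estimate independent of sampling rate. Ties resolve to the
earliest window. The load is not smoothed before fitting: at 20 Hz and
0.1%/s a window spans ~1600 samples, which already averages noise, and any
pre-smoothing would bias the slope. Both axes use the engineering
convention by default; the stress and strain conventions can be switched
independently. No window fitting inside the curve (span < 0.08, or < 3
samples) is an error naming the span.

**Failure detection.** The instrument terminates at the first drop in load
greater than 40% of the running maximum. The offline detector reproduces
that rule with two hardenings for noisy records: (i) the rule is armed only
once the running maximum reaches 20% of the record's overall peak, so the
near-zero pre-tension region cannot trigger it, and (ii) a candidate drop
must be sustained — the next sample, if one exists, must also sit below the
threshold. With load noise at 1% of peak, a false trigger then requires two
consecutive ≥4σ excursions, which is effectively impossible, while a true
rupture (a sustained drop to well below 60% of peak) always fires. If no
drop qualifies, the last sample is returned with `failure_detected=False`;
such specimens keep their MTM but are excluded from UTS/failure-strain
group statistics, since only completed failures carry those endpoints.

**UTS.** Peak stress at or before the failure sample, taken from a 5-sample
rolling median of the stress rather than the pointwise maximum: the raw max
of noisy samples is biased upward by the largest noise excursion near the
peak, whereas the short median is unbiased on monotone ramps and
insensitive to single-sample load-cell spikes. A window of 1 disables it.
Failure strain is the strain at the termination sample (the operational
definition of failure); the strain at peak stress is reported alongside for
comparison with conventions that read failure at the UTS.

## Morphometry

Segmentation is a global Otsu threshold followed by removal of components
smaller than 64 px and selection of the largest component; a second
component of comparable size (≥ 25% of the largest) is an error rather than
a guess. Thickness is measured along 360 radial rays (0.1 px radial step,
nearest-neighbour lookup) as the distance between the first and last
foreground crossing. The ray origin is the centroid of the enclosed lumen,
not of the ring mass: for a non-uniform ring the mass centroid is pulled
toward the thick side and rays from it cross the wall obliquely,
overestimating thickness by several percent. Rays with no crossing are
recorded missing; more than 10% missing is an error.

The coefficient of variation uses the sample SD (n−1 denominator), which
matters at the small n of per-ring summaries; the denominator is
configurable. Rasterization limits accuracy to roughly ±0.5 px per
boundary, so a profile's CV has a floor of about 0.3 px divided by the mean
thickness (~0.02 for a 20 px ring); recovered CV is only meaningful for
rings whose true variation exceeds that floor.

## Collagen assay

The standard curve is an OLS line of absorbance on standard mass (µg), with
the 0-µg standard defining the intercept (no separate blank-subtraction
step); a non-positive slope is an assay failure. Unknowns invert the line,
scaled by an optional dilution factor; masses outside the standards' range
are flagged as extrapolations and negative inversions clamp to zero with a
flag. Per-cell content divides by the seeded cell number (3×10⁵ per well by
convention) because endpoint cell counts are not generally available; the
number is overridable.

## Group statistics

The normality gate runs Shapiro–Wilk per group and Levene across groups,
each at α = 0.05, and routes to the parametric branch only if every test
passes; a zero-variance group forces the nonparametric route. Note the
joint null pass rate of k+1 tests at α = 0.05 is ~0.95^(k+1) (≈ 81% for
three groups), so the gate is deliberately conservative. It is advisory:
either branch can be forced.

The parametric branch is one-way ANOVA with Tukey HSD (statsmodels). The
nonparametric branch is the tie-corrected Kruskal–Wallis H (scipy) with the
Conover–Iman post-hoc computed on pooled average ranks: pairwise t
statistics use the pooled rank variance S², the (N−1−H)/(N−k) shrinkage and
N−k degrees of freedom. Pairwise p-values are unadjusted by default (the
conventional default for this post-hoc); Holm or any statsmodels method is
available by flag. Compact letters use the insert-and-absorb construction,
which guarantees exactly that two groups share a letter iff their pairwise
p ≥ α.

Spearman's ρ is the Pearson correlation of average ranks with the
t-approximation p-value; Bonferroni multiplies by the number of unique
off-diagonal pairs actually tested (constant variables are recorded missing
and do not count).

## Synthetic data

The constitutive model is the simplest C¹ J-curve with an exactly known
linear slope: a quadratic toe of extent ε_toe joining a line of slope E
with continuous value and slope, so σ(ε) = E(ε − ε_toe/2) in the linear
region. The pull ends one sample after the stress reaches the target peak,
with a single-sample drop to (1 − drop)·peak that unambiguously triggers
the 40% rule. Because the model determines the strain at which σ = uts
(ε_toe/2 + uts/E), `failure_strain` is derived unless explicitly supplied,
in which case it truncates the pull early. Load noise is additive i.i.d.
Gaussian on load only — crosshead position is servo-controlled in the real
instrument — and gripper drag is a smooth monotone tanh profile bounded by
its amplitude, shared between specimen traces and the specimen-free
baseline. All generators are pure functions of (parameters, seed) using an
explicit `numpy` generator; no global RNG state.

Default study conditions mirror the reference protocol: 5 mm grip distance,
0.1%/s strain rate (5 µm/s), 20 Hz sampling, 40% termination drop.
Synthetic cohorts use a 0.6 × 0.6 mm limb cross-section, peak stress
proportional to modulus (uts = 0.13·E, the middle of the observed
strength/stiffness ratio for such tissues), load noise at 1% of each
specimen's peak load, 2 mN drag, and 0.02 mm of slack before engagement.
Moduli in recovery sweeps span 5–40 MPa — the range such tissues traverse
over four weeks of maturation — with uts/E in 0.11–0.15 so that an 8%
strain window always fits inside the linear region (a curve whose linear
region is shorter than the window cannot return the generating modulus by
construction).

What the generators do *not* emulate: viscoelasticity, cyclic loading,
crimp mechanics, grip compliance, image vignetting or uneven illumination,
non-Gaussian assay error. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated noise model, not robustness
to every artefact of real instruments.

## Problem sizes

Simulation-based checks use: 20 configurations for tensile parameter
recovery (~3000 samples per trace); 2000 replicates for Kruskal–Wallis
type-I calibration (3 groups × n = 10); 1000 random matrices for the
letter-display invariant; 20 images (256² px) for morphometry recovery;
cohorts of 3 groups × 8 rings for pipeline-level power checks. These sizes
put Monte-Carlo error well below the tolerances they are checked against.

## Known limitations

- The onset-threshold rule records the gauge slightly into the toe, biasing
  MTM upward by the ratio of detected to true gauge length (~0.5% under
  default conditions); this is inherent to the rule, not the estimator.
- The Conover post-hoc without multiplicity adjustment is anti-conservative
  when many groups are compared; use the Holm flag where that matters.
- Thickness morphometry assumes a single annular component with a resolvable
  lumen; overlapping rings or broken rings are rejected, not repaired.
- The collagen inversion is a plain linear calibration; kit-specific
  saturation at high mass is not modelled (flagged as extrapolation
  instead).
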