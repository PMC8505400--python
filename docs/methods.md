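# Methods

## Scope and model

riverwq scores river-water samples with four classical index families and
compares monitoring phases statistically. The reference design it models is
a campaign of 11 industrial-discharge sites on a large tropical river
sampled in three phases (pre-lockdown, lockdown, unlock), with 20
parameters per sample: pH, EC (µS/cm), TDS, turbidity (NTU), Mg, Ca, Cl,
SO₄, NO₃, BOD, DO (mg/l), Zn, Cd, Pb, Ni, Cr, Fe, chlorophyll-a, total
phosphorus (µg/l) and Secchi depth (m).

All four indices are deterministic functions of a concentration vector.
MWQI, HPI and RI are affine in each concentration, which has a consequence
the package exploits throughout: the index of a phase-mean vector equals
the phase mean of per-sample indices. Phase-level index summaries are
therefore computable without per-sample data, and the test suite asserts
the identity exactly on synthetic campaigns. TSI is a mean of logarithms,
so the same identity holds only up to a Jensen gap; at the coefficient of
variation of the reference campaign (< 0.3 for the three trophic
parameters) that gap stays below one TSI unit.

## Standards registry

Permissible limits (BIS 2012 / WHO 2011), MWQI assigned weights, ideal
values, and Hakanson reference/toxic-response constants live in one
YAML-backed registry (`riverwq/data/default_standards.yaml`). Decisions
embedded in the defaults:

* **Units.** Heavy metals, TP and chlorophyll-a are µg/l and EC is µS/cm.
  Zn concentrations near 40,000 are only physically plausible in µg/l; the
  registry is explicit about units so no auto-conversion is attempted
  beyond what a user declares in a custom config.
* **pH rating band.** pH is rated by deviation from the ideal 7.0 relative
  to the *upper* BIS band 8.5 (using the lower band 6.5 as S makes
  S − V negative and produces negative ratings for alkaline water). Users
  can set `permissible_limit: 6.5` in a custom config to rate against the
  lower band.
* **DO rating.** Ideal 14.6 mg/l (100% saturation at 23 °C), standard
  6 mg/l, so saturated water rates 0 and water at the limit rates 100.
* **Missing values.** An index is computed only over its full declared
  parameter set; a missing member aborts that index for that sample (with
  the code named in the error) rather than renormalising weights, because
  the assigned weights are global constants, not per-sample quantities.
  Validation records absence explicitly (`"tsi incomplete"`), never
  zero-fills.

## Classification boundaries

The published class schemes print touching ranges ("50–100", "100–200").
The package resolves the boundaries from each scheme's unambiguous printed
anchors: MWQI and HPI anchor their lowest class inclusively ("≤ 50",
"0–25"), so those schemes are lower-exclusive/upper-inclusive; RI and TSI
anchor their lowest class with a strict upper bound ("< 150", "< 30"), so
those schemes are lower-inclusive/upper-exclusive. Each scheme partitions
[0, ∞) with no gaps or overlaps, which a property test verifies on a dense
grid including boundary neighbourhoods. Values are kept unrounded for
computation and comparison; rounding to two decimals happens only at the
presentation layer (CLI, class-percentage table).

## Comparison statistics

* Descriptives use the sample (n−1) standard deviation.
* Percent change is (b − a)/a·100 on unrounded statistics; a zero baseline
  is an error, not a silent NaN.
* Pearson correlations use two-sided p-values from the t-distribution on
  n−2 df (scipy), starred at p < 0.05/0.01/0.001. A zero-variance
  parameter's pairs are reported as missing rather than dropped.
* The omnibus test is one-way fixed-effects ANOVA (scipy). The post-hoc is
  the classic Fisher LSD: unadjusted pairwise t tests on the pooled
  within-group mean square at α = 0.05, with no multiplicity correction —
  chosen because it is the textbook LSD procedure and no correction
  is part of the reference design. When every group is constant scipy's F
  is undefined; the package reports the classical degenerate convention
  F = 0, p = 1.

## Synthetic campaign generator

The generator emulates the sampling design: `n_sites` records per phase,
each parameter drawn independently from a normal distribution with the
configured per-phase mean and SD, truncated below at 0 (pH to [0, 14]).
The default statistics table is the reference campaign's printed phase
means and SDs; it is a study-condition constant, not a tuning dial.

Two numerical choices:

* **Mean calibration.** Truncation shifts the mean of a raw truncated
  normal above its location parameter — materially so for high-CV
  parameters (lockdown turbidity 5.63 ± 3.52 shifts by ≈ 0.4; unlock DO
  6.34 ± 5.01 by ≈ 1.0). Because every downstream linear index inherits a
  mean bias directly, the generator instead solves (Brent root find on the
  truncated-normal mean) for the underlying location whose *truncated*
  mean equals the configured mean. Configured means are thus unbiased at
  any n; the realized SD is slightly below the configured scale under
  heavy truncation, which is accepted and matters only for second-moment
  summaries.
* **Independence.** Only marginal moments are emulated; cross-parameter
  correlations are not imposed by default, so synthetic correlation
  matrices test machinery, not field structure. An optional Gaussian-copula
  hook accepts a user correlation matrix (rank-correlation fidelity is
  approximate after truncation).

What passing tests on synthetic data do show: the index formulas, class
logic, linearity identities, and the statistical machinery are correct.
What they do not show: anything about spatial autocorrelation along the
river, covariance between pollutants, or non-normal field distributions.

## Known limitations and reference-value notes

* The published campaign's HPI phase means are not reproducible from its
  own phase-mean concentrations and stated limits (the formulas give
  ≈ 189.6 for the pre-lockdown phase against a reported 335.29, likely
  computed with different unstated standards); the package treats HPI
  numerically per its stated formulas and validates only its class
  behaviour against reported values.
* The reported lockdown-phase MWQI mean is likewise not reproducible from
  the lockdown phase means under any turbidity limit consistent with the
  pre-lockdown value; only the pre-lockdown MWQI is used as a numerical
  anchor.
* The reference campaign's narrative places RI = 537 in "moderate"
  contamination; its own bounds put it in *Heavily contaminated*
  [300, 600), and the package follows the bounds. Similarly the narrative's
  unlock turbidity decline of −45.84% conflicts with the value implied by
  its phase means (−45.20%), which the package reproduces.
* Problem sizes used in tests and the acceptance script: campaigns of 11
  sites × 3 phases (the design size) for pipeline checks, 1,000 sites for
  generator moment recovery, and 1,000 random vectors for oracle
  equivalence — all chosen as the smallest sizes at which the respective
  statistical bounds are sharp.
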