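# Methods

This note documents the statistical model behind `stockid`, the choices made
where the design was genuinely open, and what the synthetic-data suites do
and do not demonstrate.

## Allometric size correction

Morphometric characters of fishes grow allometrically: `y ≈ a · TL^b`. All
regressions are therefore fit on natural logs (`ln y` on `ln TL`); the log
base is a convention only, but natural logs keep adjusted magnitudes in the
range conventional for adult sea-lamprey trunk measurements (e.g. an
adjusted trunk length of 6.45 back-transforms to e^6.45 ≈ 633 mm at the
reference length).

The correction uses the *common within-group slope* `b_c` from an ANCOVA
(separate intercepts per group, one slope), applied to every character
including those whose slopes are formally heterogeneous across groups — a
deliberate simplification that keeps the adjustment identical for every
specimen. The adjusted value is
`ln y − b_c (ln TL − ln TL_ref)` with `TL_ref` the grand-mean total length of
the data set. Characters whose log-log slope is not significant at the
configured `alpha` bypass the correction entirely (slope 0, pure log
transform): removing a non-existent size effect would only inject slope
noise.

Degenerate cases: a constant character is defined to have slope 0, r² = 0,
p = 1 (no length relationship); a constant length vector is an error.

Outlier screens: specimens with any |standardized residual| > 3 sd in the
per-character log-log regressions are removed (morphometrics); meristic
counts use Tukey fences at k = 3 × IQR (the SPSS "extreme value"
convention). Characters with zero IQR — near-constant discrete counts — are
skipped by the fence rule: collapsed fences would flag every value away from
the median, which is a statement about discreteness, not outliers. Both
thresholds are configuration options.

## Multivariate screening

The two-way crossed MANOVA uses a sum-to-zero coded design (intercept, group,
sex, interaction); effect tests are the standard contrast tests on that
design, which coincide with the usual Type-III convention and, in the
balanced synthetic designs, with every other convention. Pillai's trace and
Wilks' Λ are both reported with their standard approximate F tests (the
computation is delegated to `statsmodels`' multivariate testing machinery;
tests cross-check it against an independently computed Hotelling T² in the
two-group case). The partial effect size is Pillai's V/s and the observed
power is taken from the noncentral F implied by the sample statistic
(λ = F · df1), matching common statistical-package output. With a single
response every statistic collapses to the univariate ANOVA F, which is
computed directly. Per-variable follow-up Fs use the same design; the
dimorphism filter removes variables whose sex effect has p < α at a raw
α = 0.05 — deliberately liberal, with no multiplicity correction, since a
falsely removed character only costs information while a retained dimorphic
character biases the classifier.

PERMANOVA is computed in-package because the two-way crossed design is
needed. Distances are Euclidean on z-scored variables (meristic counts are
commensurate, and this choice reproduces the familiar ANOVA-like SS table).
The SS partition is sequential-orthogonal over (group, sex, group × sex),
which is exactly additive on every input and equals the Type-III partition
under balance; pseudo-F = MS_term / MS_residual, and p-values use free
permutation of observations with p = (#{F* ≥ F} + 1)/(n_perm + 1). The
number of distinct permutations actually sampled is reported. Residual
permutation is deliberately not implemented; free permutation is valid for
the balanced-ish crossed designs this package targets.

## Stepwise discriminant analysis

Selection follows the "maximize Mahalanobis D²" stepwise convention: at each
step, among candidates whose partial F-to-enter (from the Wilks'-Λ ratio of
nested variable sets, F = (df2/df1)·(1−ratio)/ratio) clears the threshold,
the variable maximizing the *minimum* pairwise D² between groups enters;
afterwards any included variable whose partial F falls below the removal
threshold leaves. Thresholds default to F-to-enter 3.84 / F-to-remove 2.71
(the SPSS defaults; the entry threshold must exceed the removal threshold to
prevent cycling, and a visited-state set guards the loop). An empty
selection is a legal outcome, reported as "no discriminating variables",
not an error.

The discriminant functions are the generalized eigenvectors of
`B v = λ W v`, scaled so each score has unit pooled within-group variance;
loadings are pooled within-group variable–score correlations; variance
shares are λ_f/Σλ; Wilks' Λ = Π 1/(1+λ_f) with Bartlett's χ² on p(K−1) df.
Sign convention: each function is oriented so its largest-magnitude loading
is positive, making reports reproducible. Classification is nearest centroid
in function space with equal priors (group sizes are deliberately balanced
by subsampling); ties break to the lowest group index — random tie-breaking
is forbidden by contract.

Cross-validation keeps the variable set fixed from the full-data stepwise
run and refits only the discriminant functions per leave-one-out fold,
matching the "cross-validated classification" convention of the statistical
packages this analysis style comes from. Press's Q = (N − nK)²/(N(K−1)) with
n the total correct count, referred to χ²(1).

The stratified subsample reduces the largest group to the size of the
runner-up by default, with proportional allocation across river × sex strata
and largest-remainder rounding (quotas never deviate from exact
proportionality by more than one specimen).

## Fatty-acid conventions

"ND" (not detected) entries are structural zeros: exactly 0%, preserved by
closure and by the generator. Components without an omega annotation (e.g.
C20:2) count toward their saturation class but no omega series. The
DHA/EPA ratio is reported as undefined (None) when EPA is absent, never as
infinity. The MDA variable rules (chain length in [10, 22]; C14:1 and
odd-chain monounsaturates out; components detected nowhere out; unparseable
names out) are each individually toggleable.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *marginal* structure the analyses assume:

* total length ~ Normal(864 mm, 60 mm) truncated positive by resampling
  (the adult size range of the emulated survey; truncation bias is
  negligible at this coefficient of variation);
* characters `exp(mean(group, sex) + b (ln TL − ln TL̄) + ε)`, ε Gaussian on
  the log scale, with the shipped per-character log-means matching published
  adjusted group/sex means, slope 1 by default (eye diameter: slope 0, the
  one character with no length relationship) and residual sd 0.05 — a ~5%
  coefficient of variation typical of calliper morphometrics;
* meristics as rounded Gaussians matching published marginal means/sds;
* fatty-acid profiles as logistic-normal: multiplicative log-normal noise
  (dispersion 0.35, matching the published coefficients of variation) on a
  group mean composition, re-closed to 100%, with per-group ND sets held at
  exact zero. Logistic-normal rather than Dirichlet noise preserves the zero
  structure and gives the heavier-tailed profiles real chromatograms show.

The published mean compositions cover only the major identified fatty acids
and sum to ~76–90%; the shipped defaults therefore include a per-group
`other` remainder component, representing the unlisted minor fatty acids, so
each configured magnitude is preserved exactly while compositions close to
100% within 1e-9. `other` is screened out of class sums and the MDA rules as
unparseable.

Within-group covariance is **diagonal** on the log scale (no published
covariances exist to emulate; the flag is the per-character residual sds).
Consequently, passing tests demonstrate the pipeline's behaviour under
independence plus the configured mean structure — they say nothing about how
correlated real characters would share discriminant weight. The default
fatty-acid configuration classifies near-perfectly because structural-zero
patterns are themselves group signatures; real surveys, where detection
limits blur ND status, sit between that and the weaker morphometric regime.

`null_config` pools all group effects (sex effects retained), giving exact
null data for calibration suites.

## Test-suite study conditions

* MANOVA type-I calibration: 500 simulations of a balanced 3 × 2 design,
  n = 60, three responses, using Wilks' p (Rao's F is exact for three
  groups); the rejection rate must fall in the exact binomial 99% interval
  around 0.05. The small problem size keeps the suite fast without touching
  the exactness of the test.
* Planted-signal recovery: three informative characters with 2-sd
  separations in orthogonal group-mean directions plus one noise distractor,
  n = 25/group. At the default F-to-enter, each null variable clears the
  bar with probability ≈ 2.5% per run, so "exactly the three planted
  variables" has a true rate near 97% with one distractor; with many
  distractors that event is impossible at the ≥ 95% level by construction,
  which is why the suite plants exactly one. The same arithmetic applies to
  the slope-heterogeneity and dimorphism screens: a test at α = 0.05 falsely
  flags 5% of null characters *by definition*, so those suites assert full
  recovery of the planted characters plus a false-positive rate near α,
  not zero false positives.
* End-to-end "clean signal" demonstration: residual sd 0.05 with 6-sd group
  separations rather than literally zero noise — with zero noise the
  within-group scatter is singular and, more subtly, any third marker is
  informationally redundant given two others (three group-mean patterns
  cannot be linearly independent in a two-dimensional contrast space), so
  the strictly noise-free case cannot select all three markers. The
  demonstration also runs its dimorphism screen at α = 0.001 because the
  configuration contains no sex effect: any removal would be a pure false
  positive unrelated to the property under test.

## Known limitations

* No curvilinear allometry; no quadratic or regularized discriminant
  analysis; selection re-run per cross-validation fold is not the default
  reported rate.
* PERMANOVA's sequential SS partition differs from Type-III output of other
  software on strongly unbalanced designs.
* The observed-power column follows the post-hoc noncentral-F convention and
  inherits its well-known circularity; it is reported for table
  compatibility, not inference.
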