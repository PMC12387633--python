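# Methods

## Scope and data model

`mbmetab` analyses one *study*: n samples assigned to g conditions and
observed through B blocks (samples × variables matrices from different
analytical platforms).  The canonical layout is four conditions (CG, CPT,
CPDMS, CP — three adherent supports and one planktonic culture) with five
replicates each, and four blocks: X1 LC-HRMS² features (1049 variables),
X2/X3 GC-MS features from apolar and mid-polar fractions (26 and 42
variables) and X4 binned ¹H NMR spectra (8800 columns).  All sizes are
configurable; nothing in the code assumes these particular widths.

## Preprocessing chain

Applied per block, in a fixed order enforced by state flags:

1. **PQN.**  Each sample row is divided by the median of its elementwise
   ratios to a reference spectrum; the default reference is the columnwise
   median over samples.  Ratios are computed only over entries positive in
   both the row and the reference, so injected zeros (missing features)
   cannot poison the median.  The quotient-median construction cancels any
   per-row dilution factor *exactly* for a fixed reference; note that the
   default data-driven reference itself moves when rows are rescaled, so
   strict elementwise invariance statements (and the tests asserting them
   at 1e-10) hold for an explicitly fixed reference.
2. **Zero replacement + log (MS blocks X1–X3 only).**  Exact zeros are
   replaced by 1000 and the block is log-transformed.  The replacement
   intensity is a convention for making the log defined on missing
   features; it sits well below typical feature intensities (~10⁵) and
   its artefacts are part of what the synthetic studies exercise.  Log
   base 10 by default; the base only rescales columns (absorbed by UV
   scaling) but matters for the Pareto-scaled block, so it is
   configurable.  Zero replacement happens after PQN so that PQN sees the
   true missingness pattern.
3. **Centering and column scaling.**  Columns are mean-centered, then
   divided by the column SD (unit variance; X2–X4) or by its square root
   (Pareto; X1 — a compromise that keeps some weight on high-intensity
   LC-MS features).  SDs use the n−1 convention (configurable).  Constant
   columns are centered and left undivided.
4. **Block scaling.**  The whole block is divided by the square root of
   its total column variance, making the block's total variance 1.  We
   read "scaling each block by its own variance" as producing *unit total
   variance*; literal division by the variance would not.  Without this
   step the 8800-column NMR block would dominate the 26-column GC-MS
   block in the multiblock fit purely by width.

For cross-validation the whole chain is fit on training rows only
(`StudyPreprocessor.fit`) and replayed verbatim on held-out rows
(`apply`); parameters serialise to JSON for audit.

## NMR binning

`bin_spectrum` integrates an already-processed, aligned 1D spectrum into
uniform chemical-shift buckets over [0.2, 9.0) ppm, default width
0.001 ppm → 8800 columns.  Solvent windows (residual water 4.74–4.94 ppm,
methanol 3.26–3.36 ppm) are *masked in place* by default: the bins stay as
columns but are zeroed, which reconciles region exclusion with the
8800-column count (dropping the 300 excluded bins would leave 8500; a
`drop` mode provides that reading).  Bins are left-closed/right-open;
bin-edge overlap uses a 1e-6-width tolerance so exactly-touching bins are
not masked.

## PCA, PLS, MBPLS

PCA is SVD of the centered matrix.  PLS2 is classic NIPALS with Y-side
scores, deflating X and Y by the X-score.  MBPLS uses the NIPALS-style
super-score construction: per component, block weights w_b ∝ X_bᵀu (unit
norm), block scores t_b = X_b w_b, super weights w_T ∝ Tᵀu (unit norm)
over the block-score matrix T, super score t = T w_T, and Y-score update
u = Yq/qᵀq with q = Yᵀt/tᵀt.  After convergence both the blocks and Y are
deflated by the super score.  With a single block the scheme reduces
*exactly* to PLS2, which the tests assert.

Design/numerical choices:

* Y is the full one-hot coding (no reference-cell drop) and is centered
  inside the fit — the g conditions are treated symmetrically.
* u is initialised with the Y column of maximal variance, ties to the
  lowest index; convergence is ‖Δu‖ ≤ 1e-10 (relative).
* The iteration cap is 5000.  With a rank-3 centered one-hot Y the fourth
  component's leading directions can be nearly degenerate; the power-type
  iteration then converges linearly with ratio ≈ the eigenvalue ratio
  (observed ~0.98/iteration, i.e. ~1500 iterations), so a cap of a few
  hundred would reject perfectly valid fits.
* Deflation uses the super score for every block (and Y).  Block-score
  deflation is a known alternative; super-score deflation keeps the
  residual spaces of all blocks orthogonal to the consensus component and
  makes per-block explained variance additive.  The choice is recorded in
  the model metadata.
* Sign convention: the largest-|entry| of the concatenated block weights
  of each component is made positive, so refits are bit-identical.
* Per-block contribution is exported two ways: R²₍b,a₎ — the incremental
  fraction of block b's initial sum of squares removed by component a's
  deflation (the default, what a per-block explained-variance bar chart
  shows) — and squared super weights.
* `n_components` defaults to 4 (one fewer than the number of samples per
  condition; with 4 conditions the centered Y has rank 3, and the fourth
  component mops up within-coalition structure).

## Validation

* **R²Y** = 1 − SS(Y−Ŷ)/SS(Y centered) on the training fit.
* **Q²Y** uses leave-one-out: for every held-out sample the *entire*
  chain — PQN reference, zero replacement, column means/divisors, block
  divisors and the MBPLS fit — is recomputed from the remaining n−1
  samples.  Q²Y = 1 − PRESS/Σ(yᵢ−ȳ_train)², reported cumulatively per
  component count; negative values are meaningful (no predictive power).
  Refitting preprocessing inside folds is the leakage-free reading, and a
  test asserts fold parameters are recomputable from training rows alone.
* **AUROC** is computed one-vs-rest per class from the LOO-predicted Y
  columns via the rank (Mann–Whitney) statistic with half credit for
  ties; macro = unweighted mean.  Cross-validated scores are the honest
  input; the optimistic fitted-score AUROC is exported alongside for
  comparison.

A null caveat from the tests: at these sample sizes the LOO Q²Y of pure
noise is *usually* negative but positive excursions occur by chance (up to
~0.3 at n=12), so the null property is asserted distributionally, not
per-seed.

## Discriminant variables and biplots

Selection: per block and per axis, threshold = min|w| + 0.75·(max|w| −
min|w|) on the MBPLS block weights; variables at or above it are
discriminant.  This "upper quarter of the range" rule is deliberately
sparse — on the default synthetic study it selects ~10–30 of 1049 LC-MS
features per axis, the same order as real per-axis marker tables — and it
is precision- rather than recall-oriented: with 2-SD planted effects at
n=20 the per-variable weight noise is large, so weaker true effects fall
below the threshold while the selected set stays strongly enriched in
true effects.  Count-based (`top-quarter-count`) and fraction-of-max
rules are available; zero-range weight vectors select everything
(pathological inputs only).

Direction: a selected variable is "increased in" the conditions whose
super-score centroid on its axis shares the sign of its weight and
exceeds 0.1 × the axis score SD (smaller centroids are neutral); if no
condition passes the gate the single best-aligned condition is returned,
so the set is never empty.  For a one-vs-rest axis this yields either the
separated condition or the complementary coalition.

Stability: the model is refit on every LOO fold and each selected
variable votes on selection and weight sign.  By default fold axes are
compared as fitted (canonical sign frame): without real structure the
near-degenerate components rotate freely under resampling and chance
selections flip signs, which is exactly the instability being flagged.
With `align=True` fold components are first matched to the reference
model by super-score correlation — appropriate when several genuine
components of comparable strength may swap order between folds.  The flag
is exported in the marker table.

Biplot coordinates: a block's unit-norm weight vector spreads its mass
over p_b variables (entries ~1/√p_b) while its block divisor grows with
width, so each variable's weight pair is multiplied by its block divisor,
then one uniform positive factor per panel normalises the largest radius
to 1; scores are scaled by their own uniform factor.  Uniform scaling
preserves every point's angle to the component axes exactly, and the
compensation puts a 26-column and an 8800-column block on one display
scale (a variable duplicated across two blocks lands at the same
coordinate, which the tests assert).

## Annotation arithmetic

Monoisotopic masses come from a shipped, versioned isotope table
(most-abundant isotopes of H, C, N, O, Na, P, S, K; CODATA/AME values).
Two electron-mass conventions coexist deliberately: *display* masses of
fragment-ion formulas neglect the electron (printed diagnostic values
such as 236.1498 for C₁₀H₂₂NO₅⁺ match this convention at 4 decimals),
while *adduct m/z* values subtract mₑ per positive charge (protonated
catechol C₆H₆O₂ → 111.0441).  Both are explicit flags.

The DGTA/DGTS betaine-lipid headgroup is detected from the diagnostic
fragment pair m/z 236.1498 (C₁₀H₂₂NO₅⁺) and 144.1025 (C₇H₁₄NO₂⁺); both
ions are required by default (any-of is configurable) within a ppm
tolerance.  The two lipid classes are isobaric and are never
distinguished — the class is reported as "DGTA/S".  Acyl chains are
identified by neutral loss: for a candidate chain C:D(;Ox) the acid
(CₙH₂ₙ₋₂dO₂₊ₓ) and ketene (CₙH₂ₙ₋₂₋₂dO₁₊ₓ) masses are subtracted from the
precursor and fragments matched within tolerance; output order is
candidate-major and independent of fragment order.  Observed-vs-printed
ppm errors in published tables are not always re-derivable from any
single convention (instrument-software recalibration); the implementation
sticks to the standard (obs − theo)/theo × 10⁶.

Kovats/Van den Dool & Kratz retention indices interpolate linearly in
retention time between bracketing n-alkanes (RI = 100n exactly on rungs);
extrapolation beyond the ladder is refused unless requested.

## Synthetic studies

The generator emulates the study conditions end to end so the whole
pipeline is testable without instrument data.  What it reproduces: the
4×5 design; the four block widths; log-normal MS intensities (baseline
log₁₀ intensity ~ N(5, 0.8)); within-group log₁₀ noise (SD 0.4);
intensity-dependent dropout producing exact zeros in X1–X3 (expected rate
0.10, probability decreasing linearly with intensity rank — low-abundance
features vanish first); an NMR block synthesised as Lorentzian peaks
(HWHM 0.4–0.8 bin widths, evaluated on a ±2-bin window so peaks ≥3 bins
apart cannot bleed into each other's bins) on a fine ppm axis and passed
through the same `bin_spectrum` used for real data; and one multiplicative
dilution factor per sample (Uniform(0.5, 2)), shared by all blocks — the
nuisance PQN exists to remove.

Group structure is planted along three contrasts: C1 CP vs the rest, C2
CG vs the rest, and C3 CPT vs CPDMS.  Effects are ±2 within-group SD on
the log scale, signs alternating so "increased-in" is exercised both
ways; C1 and C2 are one-sided (the singled-out condition moves), C3 is
two-sided (CPT +Δ/2, CPDMS −Δ/2, keeping the planted group-mean
difference at Δ) so that every condition, including CPDMS, carries an
active signature — with a purely one-sided C3, CPDMS is defined only
negatively and its one-vs-rest ranking saturates well below 1.  Default
plant counts are 20 per block for C1 and up to 20 for C2/C3 (the
26-variable X2 only accommodates 3+3 beside C1's 20; sets are disjoint
within a block).  Each planted NMR variable is a dedicated peak centred
on its bin.  One global seed spawns independent child streams per block
plus one for dilution (`SeedSequence.spawn`), so blocks can be
regenerated independently; identical config + seed is bit-identical.

What the generator does *not* emulate — hence what passing tests do not
show about real data: correlated variables (real metabolomes are heavily
co-regulated; here non-planted variables are independent), chromatographic
drift and batch effects, isotope patterns and adduct redundancy among MS
features, peak-shape variation and misalignment in NMR, heteroscedastic
technical noise, and any relationship between blocks beyond the shared
design.  Effect sizes and noise levels are the package's own choices
(no public data exist to calibrate against) and are set so that the
default study is strongly separated — the regime in which the validated
model attains macro AUROC 1 — while remaining biologically plausible
(≈2.5-fold median effect on a 0.4-decade within-group spread, 10%
missingness).

## Problem sizes in tests

The unit and property suites run on a reduced-dimension study
(60/12/16/440 variables, same 4×5 design) where leave-one-out loops take
fractions of a second; the full-size 1049/26/42/8800 study is exercised
in the generator-shape, selection and acceptance tests and by
`scripts/acceptance.py` (a full LOO evaluation at that size takes on the
order of a second per fold or less).  Statistical panel tests (null AUROC
calibration, null Q²Y) use 20–50 fixed seeds.

## Known limitations

* NIPALS-style MBPLS extracts components sequentially; it is not the
  kernel/eigen formulation and offers no OPLS-style orthogonal filtering.
* The selection rule's sensitivity is bounded by per-variable weight noise
  at n=20 (see above); recall-oriented use should prefer the count rule.
* `loo_q2y` refits everything per fold; cost scales linearly with n and
  the fold engine implements LOO only (the scheme the validation metrics
  are defined for here).
* The PQN "dilution invariance" is exact only against a fixed reference;
  with the default data-driven reference the result is invariant up to
  the induced reference shift.
* The annotation module does no spectral-library search, formula
  prediction or retention-time modelling; it is the deterministic
  arithmetic layer beneath such tools.
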