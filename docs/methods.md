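# Methods

This note documents the statistical procedures, the defaults and the
numerical conventions of `morphoscore`, and what the synthetic cohorts do
and do not establish.

## Data model

A cohort is one row per embryo: absolute morphokinetic parameters
`t2, t3, t4, t5` (hours post-ICSI of the divisions to 2–5 blastomeres), the
derived intervals `cc2 = t3 − t2` and `s2 = t4 − t3`, and a binary
blastocyst outcome. Ingest enforces `t2 ≤ t3 ≤ t4 ≤ t5` on present fields
and non-negative times, and rejects a supplied `cc2`/`s2` that disagrees
with the derivable difference by more than 1e-9 h (derived values are the
single source of truth). `s2 = 0` is valid: the imaging cadence (≈7 min)
cannot resolve shorter intervals. Unlabeled records are accepted — a frozen
model must score them — but never enter any fitting stage. Input dialect:
comma-separated UTF-8 with a header, `.` decimals, missing as empty cell or
`NA`. Timings are carried as full-precision floats; published one-decimal
tables are a display format.

## Quantile convention

Every quantile in the package — descriptive summaries, compartment
boundaries, Sc quartiles — uses linear interpolation between order
statistics (the "type 7" estimator, numpy's default). One convention is
fixed globally because the compartment boundaries at fit time and the
quartile reports must agree exactly.

## Descriptive statistics and normality

Per parameter per outcome group the package reports n, the five-number
summary and two normality tests: Kolmogorov–Smirnov with the Lilliefors
correction (mean and sd estimated) and Shapiro–Wilk (Royston approximation
via scipy). The Lilliefors p-value is Monte-Carlo: the null distribution of
the statistic depends only on n, so R seeded replicates (default 10 000;
2 000 inside the pipeline report) are simulated once per sample size and
shared; `p = (1 + #{D* ≥ D}) / (R + 1)` is never exactly zero. A cell is
labelled normal only when **both** tests give p ≥ 0.05 — the conservative
reading of a two-test screen with a single verdict. An empty or degenerate
cell yields a flagged row, not an exception.

## Compartments and individual scores

Compartment boundaries are the pooled-population Q1/median/Q3 per parameter
(all records non-missing for that parameter, both outcome groups).
Intervals are left-closed, right-open with C1 open below and C4 closed by
+∞, so any real value — including values outside the fitting range — maps
to exactly one compartment at apply time. A boundary coinciding with the
sample minimum (within 1e-12) produces a zero-width compartment that is
structurally merged with its right neighbour *before* any rate is computed;
fewer than three effective compartments is an error. This is exactly the
`s2` situation, where ≥25 % of values equal 0 and C1+C2 fuse.

Per-compartment formation rates are computed on labeled records non-missing
for the parameter. The 0/1/2 score assignment:

* four effective compartments — among all six pairs **except** (C2, C3),
  fuse the pair with the smallest absolute rate difference (non-adjacent
  pairs are admissible; this is required to reproduce the published rows in
  which C1 pairs with C4). Rank the three levels by rate descending — a
  fused level ranks by the mean of its two rates, and any monotone summary
  gives the same order on the published rows — and assign 2/1/0;
* three effective compartments (structural merge) — rank directly.

Tie-breaks are deterministic and documented: equal rate differences prefer
the pair containing the lower-indexed compartment; equal level rates rank
the lower-indexed compartment higher. A three-way rate tie has no
defensible ranking and raises an error. The three-level scale is fixed: a
binary scale cannot express the high/average/low structure the rates show,
and no parameter exhibits four distinct levels.

## Logistic regression

Individual scores enter as numeric 0/1/2 covariates, one odds ratio each
(per unit of score; the 0→2 contrast is OR²). Dummy coding would produce
two ORs per parameter and is deliberately not used. Estimation is
maximum-likelihood Newton/IRLS with step-halving, which makes the
log-likelihood provably non-decreasing per iteration (asserted);
convergence is a score max-norm below 1e-8 within 50 iterations. A
coefficient passing |β| > 15 on the 0–2 score scale (OR > 3·10⁶) is treated
as complete or quasi-complete separation and reported as non-identifiable,
as are single-class outcomes, zero-variance predictors and rank-deficient
designs. Inference is Wald on the log-odds scale (CIs and p-values), the
default of the legacy statistics packages this workflow mirrors.

Model building: univariate screen of all six scores (per-parameter complete
cases; failures are reported, not fatal), then backward elimination at
α = 0.05 among the significant candidates on their joint complete cases.
The published analysis names univariate pre-screening and a final
three-predictor model without stating the multivariate selection rule;
backward elimination is the standard reading and is a package choice, not a
fidelity claim.

## The Sc score and its evaluation

`Sc = Σ s_k · OR_k` with weights at full floating precision — the published
quartile boundary 5.26 is not reachable from the 3-decimal printed ORs
(2.929 + 2.356 = 5.285), indicating the original also used unrounded
weights. Sc is evaluated on the complete cases for the retained parameters
(records missing any retained score are excluded and counted; the reference
analysis likewise covers 236 of 432 embryos without stating its exclusion
rule — our rule is a package choice).

* **Quartile report**: Sc quartiles (type 7, left-closed) with per-quarter
  formation rates and a Pearson χ² test of independence on the 2×4 table,
  no continuity correction, df = k − 1. The quartile boundaries are frozen
  into the model and reused verbatim when reporting on validation cohorts.
* **Mann–Whitney**: U from midranks; exact enumeration of all label
  arrangements when n₁ + n₂ ≤ 12 (two-sided p doubles the smaller tail,
  capped at 1), otherwise the normal approximation with tie-corrected
  variance and 0.5 continuity correction. Identical samples give z = 0,
  p = 1 by convention (the tie-corrected variance vanishes).
* **ROC**: higher Sc predicts formation; positive means score ≥ threshold.
  Thresholds are the midpoints between consecutive distinct scores plus one
  sentinel below the minimum and one above the maximum — the exact, finite
  set of attainable operating points. Trapezoidal AUC over this grid equals
  the tie-adjusted Mann–Whitney probability U/(n₁n₀) to machine precision
  (a test asserts 1e-12). The 95 % CI is DeLong by default (Hanley–McNeil
  behind a flag), clipped to [0, 1]; the method used by the original
  analysis is unknowable from its report.
* **Cut-off**: minimal sum of squared coordinates, i.e. argmin of
  (1 − sens)² + (1 − spec)² — the evaluated point closest to (0, 1); ties
  prefer higher specificity, then the lower threshold. Youden's J is
  available, never the default. Degenerate input (all scores equal) admits
  only the operating points (1, 0) and (0, 1), both with objective 1.0; the
  tie-break returns the higher-specificity endpoint deterministically.
  Validation recomputes a fresh cut-off on the validation curve and reports
  it alongside the stored one, mirroring the practice of quoting a new
  operating point on the validation cohort.

## Frozen model artifact

JSON, schema `morphoscore-model-v1`: parameters, full-precision weights,
schemes (boundaries + merges), score maps, Sc-quartile boundaries, cut-off,
metadata (n, seed, package version — deliberately no timestamp, so a refit
on identical input and seed is byte-identical). Serialization uses `repr`
float precision and sorted keys: serialize → deserialize → serialize is
byte-stable and Sc survives the round trip exactly.

## Synthetic cohorts

The generator reconstructs a cohort from group-conditional five-number
summaries (defaults: the reference cohort's published values), an overall
formation probability (default 0.3611) and t5 missingness among
non-developed embryos (default 0.69, the fraction implied by the reference
complete-case accounting, 191 of 276).

* Each group×parameter marginal is the piecewise-linear quantile function
  through its five knots, truncated at the observed min/max.
* The four absolute times are coupled by a latent Gaussian chain with
  adjacent correlations (t2–t3: 0.90, t3–t4: 0.995, t4–t5: 0.95). The
  near-unity t3–t4 value reflects biology — the synchrony interval s2 is
  tiny relative to the spread of either time — and is also what keeps the
  heavily overlapping group marginals orderable: in the non-developed group
  t3 and t4 share their maximum, so at moderate correlation order
  violations are frequent and any repair visibly distorts the marginals.
* **Stratified marginals**: within each group, each latent column's ranks
  are mapped onto a jittered uniform grid (rank + U)/m before inversion.
  The copula's rank structure is untouched; each marginal becomes a
  stratified sample whose quantiles match the targets to O(1/m). Without
  this, the long upper-tail segments of the summaries (t5's tail spans
  ~46 h over 25 % of mass) leave >1 h of pure sampling noise in a sample
  quartile even when the marginal is exact.
* **Order repair**: residual violations are clamped backward,
  t_k := min(t_k, t_{k+1}); t5 is never modified and the perturbation stays
  inside the already-overlapping tails (measured worst quartile deviation
  ≈0.2 h at m ≈ 3000). The clamp incidentally creates a point mass at
  s2 = 0, as in real imaging data.
* **Stratified missingness**: t5 is blanked for every k-th non-developed
  record in t5 rank order. The published t5 summaries describe *observed*
  values, and i.i.d. blanking would re-inject O(1/√m) quartile noise into
  the surviving subsample.

What the generator does **not** emulate: the `cc2`/`s2` marginals are
implied by the joint law of the absolute times and cannot simultaneously
match their own published rows (no copula on absolute times can); patient-
level clustering is ignored (as in the reference analysis); missingness is
independent of the other parameters given the outcome group, whereas real
arrest correlates with slow division throughout. Consequently the
per-compartment rates of a synthetic cohort need not match the published
per-compartment rate rows — those rows also reflect an informative
complete-case restriction that is itself irreconcilable with the published
marginal summaries (their average is ≈62 %, the complete-case prevalence,
not 36.11 %). Pipeline tests on synthetic cohorts therefore establish that
the machinery recovers the structure the generator encodes (monotone
quartile rates, AUC ≈ 0.75–0.80, transferability of the frozen model), not
that it reproduces cohort-specific published coefficients.

`simulate_from_logistic` is the second generator: known logistic
coefficients over independent 0/1/2 scores, used for parameter-recovery and
CI-coverage calibration (coverage within [92 %, 97 %] at n = 500 over 1000
replicates in the suite).

## Problem sizes used by the shipped runs

The analysis scripts and the acceptance script use the reference study
sizes (432 derivation / 271 validation embryos); calibration checks of the
generator use n = 5000; coverage and recovery simulations use 100–1000
replicates at n = 500–5000. These sizes make every stochastic check stable
under its stated tolerance while keeping a full run in seconds.

## Known limitations

* Embryos are treated as independent; the ~5.6 embryos per patient violate
  this mildly, and no mixed-effects correction is attempted (none was in
  the reference analysis).
* The score's three-level scale and the C2/C3 pairing exclusion are
  design constraints adopted from the reference methodology, not data-driven
  choices; alternative binnings are out of scope.
* Wald inference can be optimistic near separation; the package refuses to
  report such fits instead of regularising them.
* The implantation/live-birth endpoint is explicitly out of scope.
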