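# Methods

## Model and assumptions

`mr2step` performs two-sample Mendelian randomization from GWAS summary
statistics.  For instrument j, let β_exp,j (se_exp,j) be its association
with the exposure and β_out,j (se_out,j) with the outcome, harmonized to a
common effect allele.  Under the instrumental-variable assumptions
(relevance, independence from confounders, exclusion restriction) each Wald
ratio θⱼ = β_out,j / β_exp,j estimates the causal effect θ, and the package
combines them with first-order inverse-variance weights
wⱼ = β²_exp,j / se²_out,j.

Estimators:

* **IVW (fixed)** — θ̂ = Σwⱼθⱼ / Σwⱼ, se = (Σwⱼ)^(-1/2).  Equivalent to
  weighted least squares of β_out on β_exp through the origin.
* **IVW-MRE** (primary model) — the fixed-effects SE multiplied by
  max(1, √(Q/(k−1))) where Q is Cochran's Q at θ̂.  The floor means
  over-dispersion widens the interval but under-dispersion never narrows
  it below the fixed-effects SE — the dominant convention in two-sample MR
  software.
* **MR-Egger** — weighted regression of β_out on β_exp with a free
  intercept (weights 1/se²_out), after orienting all instruments to a
  non-negative exposure effect; a nonzero intercept estimates the average
  directional pleiotropy.  Coefficient SEs use the residual scale floored
  at 1; inference is on t(k−2), and the Egger CI uses the t quantile so the
  interval and p-value agree.
* **Weighted median** — linear interpolation of the order-sorted ratios at
  standardized cumulative weight 1/2; consistent when valid instruments
  carry a majority of weight.
* **Simple / weighted mode** — argmax over a 512-point grid of a Gaussian
  KDE of the ratios (uniform or IVW kernel weights), bandwidth = Silverman's
  rule on the ratio scale times a configurable factor (default 1);
  consistent when the largest cluster of instruments is valid.
* **Maximum likelihood** — β_exp,j ~ N(μⱼ, se²_exp,j),
  β_out,j ~ N(θμⱼ, se²_out,j); the μⱼ profile out analytically, leaving the
  objective Σ (β_out,j − θβ_exp,j)² / (se²_out,j + θ²se²_exp,j), minimized
  from the IVW-fixed start (BFGS); se(θ̂) from the numerical curvature of
  the profile log-likelihood.  Unlike IVW it propagates exposure-side
  uncertainty.

Non-Egger p-values and 95% CIs are normal-based (z = 1.959964).  Binary
traits are on the log-odds scale, reported as OR = exp(β) with
exponentiated CI bounds.  The median and mode SEs come from a seeded
parametric bootstrap (default 1000 draws) of θⱼ* ~ N(θⱼ, se(θⱼ)²) with
fixed weights.  The Wald-ratio SE is first-order (se_out/|β_exp|); a
second-order option propagating se_exp exists but is off by default.

## Instrument selection and harmonization

Selection: p < 5×10⁻⁸, relaxed once to 5×10⁻⁶ when fewer than 4 SNPs
survive the full filter (the policy for sparsely instrumented traits such
as single metabolites); greedy clumping keeping the lowest-p index SNP and
removing same-chromosome candidates within 10,000 kb at r² ≥ 0.001 (both
conditions required — the conjunction is standard clumping semantics; ties
in p break by chromosome and position for determinism); per-SNP strength
from R² = 2β²·EAF·(1−EAF) (valid for standardized effects) and
F = R²/(1−R²)·(N−k−1)/k with k = 1 per SNP, excluding F < 10.  A set-level
F with the selected k is reported alongside.

Harmonization drops SNPs missing from the outcome (no proxy lookup),
sign-flips swapped allele pairs (mirroring EAF), attempts strand
complementation exactly once, and handles palindromic (A/T, C/G) SNPs by
frequency: minor-allele frequency above 0.42 in either dataset ⇒ dropped
as strand-ambiguous; otherwise orientation is inferred from whether the
effect-allele frequencies fall on the same side of 0.5.  Keeping
low-MAF palindromes with inferred orientation (rather than dropping all
palindromes) matches the convention implied by an MAF-threshold rule; the
0.42 cutoff leaves a 0.08 guard band around 0.5 where inference would be
unreliable.

## Sensitivity diagnostics

Cochran's Q about the IVW-fixed estimate (df = k−1) or the Egger fit
(df = k−2) with upper-tail chi-square p-values; the IVW-basis Q is the one
feeding the MRE scale.  Leave-one-out re-estimates IVW-MRE k times plus a
full-set row.  MR-PRESSO computes the weighted residual sum of squares of
each outcome effect about its leave-one-out IVW prediction and compares it
to n_sim seeded parametric simulations of both effect columns; p-values
carry a +1 pseudo-count (resolution 1/(n_sim+1), never exactly 0), and
per-SNP outlier p-values are Bonferroni-multiplied by k.  With the default
n_sim = 1000 the smallest achievable adjusted p is k/1001, so outlier
detection in sets of k ≳ 50 requires raising n_sim (the validation suite
uses 4999 for 60-instrument sets).  The distortion test of the original
MR-PRESSO procedure is not implemented — only the global and outlier tests.
Heterogeneity policy: the primary estimate is always IVW-MRE; a Q p-value
below 0.05 is recorded as justification rather than switching models.

## Two-step mediation

The total effect (exposure→outcome) is IVW-MRE on the exposure's
instruments.  Step 1 regresses each mediator on the same instruments;
step 2 instruments the mediator itself (5×10⁻⁸, relaxed to 5×10⁻⁶) against
the outcome — a univariable estimate with no adjustment for the exposure.
Indirect effect β₁β₂ with delta-method SE √(β₂²se₁² + β₁²se₂²); proportion
mediated PM = indirect/total with delta variance
se²_ind/total² + indirect²·se²_total/total⁴.  Both delta formulas assume
independence between the two steps (disjoint instruments) and between
indirect and total (shared outcome data ignored) — a stated first-order
approximation.  PM outside [0,1] (inconsistent mediation) is flagged, not
rejected.  The screen passes a mediator when both stage p-values are below
0.05; Benjamini–Hochberg q-values over the panel are computed on the
step-2 p-values (the multiplicity-heavy stage) and reported alongside, but
the screen itself uses the raw threshold.  Mediators without usable step-2
instruments are reported with status `no_instruments` and excluded from
the FDR.

## Synthetic data generator

The generator emulates a disease → metabolite-panel → outcome summary-level
study.  Per SNP: EAF ~ U(0.05, 0.95); the standardized-trait standard
error se = 1/√(2n·EAF(1−EAF)) (chosen so the R²/F formulas above are
exact); observed beta = true effect + N(0, se²); two-sided normal p.  True
effects: instrument effects γⱼ ~ N(mu_gamma, sigma_gamma²) on the
exposure-raising allele (defaults 0.05 and 0.01 — strong instruments, F
roughly 40–600 at n = 200,000, in the range a well-powered disease GWAS
yields); mediator instruments δ with the same distribution; horizontal
pleiotropy αⱼ ~ N(mu_alpha, sigma_alpha²) on a configurable invalid
fraction; outcome effect
γⱼ(θ_direct + Σβ₁β₂) + Σδⱼβ₂ + αⱼ.  Effects are defined relative to the
exposure-raising allele, so the Egger intercept targets mu_alpha directly;
with zero-mean instrument effects the post-orientation sign flips would
average directional pleiotropy away.  The outcome also carries its own
independent genetic architecture (60 SNPs by default, null on the
exposure), which is what reverse MR instruments.  LD is emulated as a
shared causal signal within blocks (non-lead SNPs scaled by √r²_within)
plus the reported pairwise r² table — enough to exercise clumping without
genotype simulation.  A configurable fraction of SNPs (default 10%) gets
palindromic allele pairs.  Fixed seeds give bit-identical output.

Reference scenarios: 200 SNPs, 60 instruments, n = 200,000 per GWAS,
θ_direct = 0.05 (sized so the full pipeline runs in seconds);
the mediation variant uses θ_direct = 0.03, β₁ = 0.2, β₂ = 0.1
(total 0.05, true PM 0.4) with 12 instruments per mediator, the median
instrument count of a large metabolite panel.  The calibration suite uses:
a null scenario (θ_direct = 0) for type-I error and p-value uniformity; a
pleiotropy-recovery scenario (all instruments invalid, mu_alpha = 0.002,
θ_direct = 0 — a null slope isolates the intercept, since with a nonzero
slope exposure-side measurement error attenuates the slope and leaks a
small offset into the intercept); and a robustness scenario (30% invalid,
mu_alpha = 0.01 = 20% of the mean instrument effect, sigma_alpha = 0.005)
where the weighted median visibly outperforms IVW.  Monte-Carlo estimator
calibration runs on the generator's direct harmonized-instrument path
(`simulate_instrument_set`), which skips file round-trips and re-selection;
the mediation and screen checks run the full selection/harmonization
machinery.

What the generator does **not** emulate: realistic MAF spectra and
annotation, sample overlap between cohorts, binary-trait liability-scale
subtleties (all traits are standardized quantitative; a case/control SE
helper uses the effective sample size n_case·n_ctrl/(n_case+n_ctrl)),
correlated mediators (the panel is mutually independent given the
exposure), weak-instrument regimes, and population stratification.
Passing tests therefore validate the statistical machinery under its own
assumptions, not robustness to those real-data complications.

## Numerical conventions and edge cases

* p-values are floored at the smallest subnormal double, never 0; the
  MC p-values in MR-PRESSO use the +1 pseudo-count.
* Degenerate exact-fit data (zero residual scale) floor the Egger and MRE
  scales at 1 rather than reporting zero SEs; an all-identical ratio set
  gives the common value as the mode with a bootstrap SE.
* Clumping, significance ties and report tables are fully deterministic;
  one global seed fans out to per-stage seeds by fixed offsets so stages
  are independently reproducible.
* Validation flags (p/z inconsistency, confounder links) never drop or
  alter data — published summary files commonly carry rounded p-values, so
  rows are flagged, not removed; malformed rows (indels, out-of-range
  numerics) are dropped at parse with a logged count.
* Display tables round to 3 decimals; machine-readable TSV/JSON keep full
  double precision.

## Known limitations

Univariable models only: no multivariable MR (step 2 of the mediation is
unadjusted), no MR-RAPS/CAUSE/Steiger filtering, no proxy-SNP lookup, no
reference-panel LD computation, and no figure rendering (plot-ready tables
are exported instead).  The delta-method mediation CIs ignore covariance
through shared outcome data; the reported indirect-effect coverage in the
test suite quantifies the practical effect of that approximation under the
reference scenario.
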