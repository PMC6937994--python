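# Methods

## Model

A patient's probability of critical illness is updated through the odds form
of Bayes' theorem. With pretest probability `p`, pretest odds are
`o = p / (1 − p)`; a test result with likelihood ratio `LR` gives post-test
odds `o' = o × LR` and posterior `o' / (1 + o')`. For a test with
sensitivity `se` and specificity `sp`, a positive result carries
`LR+ = se / (1 − sp)` and a negative result `LR− = (1 − se) / sp`.

Serial tests are chained under **conditional independence given disease
status**: the posterior after several results equals a single update by the
product of their LRs, and the update is invariant to the order of the tests.
This is the central modelling assumption. It is almost certainly optimistic
for procalcitonin and lactate — both respond to the severity of the same
septic process, so their errors are likely positively correlated and the
chained posterior overstates certainty — but no data are available in this
setting to estimate the correlation, so the package deliberately exposes no
correlation knob and states the limitation instead.

Branch probabilities use the matching generative model: a branch of results
`r_1..r_k` has mass
`p · Π P(r_i | diseased) + (1 − p) · Π P(r_i | healthy)`. Under this model
the chain is exactly coherent: branch masses sum to 1 and the
posterior-weighted branch masses average back to the pretest (law of total
probability). Both identities are enforced in tests at 1e−12 / 1e−10.

## Inputs and parameters

- **Test accuracies** (fixture defaults, from pooled meta-analyses):
  PCT sens 88% (CI 80–93), spec 81% (CI 67–90); lactate sens 72.7%
  (CI 43.4–90.2), spec 96.2% (CI 90.6–98.5). Positivity cuts: PCT
  < 0.5 ng/mL negative, > 2.0 ng/mL positive, 0.5–2.0 an explicit
  *indeterminate* band (the source text calls these "two groups" but lists
  three bins; the contradiction is preserved visibly — indeterminate values
  are flagged for clinical review rather than silently collapsed); lactate
  > 2 mmol/L positive.
- **Pretest strata**: CURB-65 score 3 → intermediate, 14.0%; scores 4–5 →
  high, 27.8%; score 2 is "physician's discretion" and carries no pretest
  probability, so it is excluded from chaining; scores 0–1 are outpatient.
- **Printed vs recomputed LRs.** The published lactate LR+ is 19.0 while the
  same table's accuracies give 19.13. The fixture stores both: printed
  values drive table/figure reproduction, recomputed values drive the
  generative model and simulator. All other printed LRs agree with their
  accuracies at two decimals.

## Rounding policies

Published posteriors behave like values read off a Fagan nomogram, so the
default policy `nomogram` rounds every posterior to the nearest whole
percent *before* gains are computed (93 − 14 = 79 percentage points,
B-NND = 1/0.79 = 1.27; unrounded chaining gives 93.47). Policy `none` keeps
full precision, under which ADG + pretest = post-test holds exactly. The
B-NND integer presentation follows the published tables (nearest integer:
3.45 → 3, 1.61 → 2), even though the number-needed-to-treat convention the
measure is modelled on rounds up.

Four published values are internally inconsistent with whole-percent
arithmetic and are reported as *known discrepancies* by the verification
mode rather than matched: lactate LR+ 19.0 (vs 19.13), high-stratum PCT+
ADG 36.3 (vs 64 − 27.8 = 36.2) and RDG 130.6 (vs 130.2), high-stratum
lactate+ RDG 216.6 (vs 216.5). The narrative 83%/7% posteriors attached to
the negative-LR sequential figure cannot be reproduced from any chaining of
the printed inputs and are excluded from verification. Posterior confidence
intervals: the package computes them by evaluating the update at LR-interval
bounds (from accuracy-CI corners), labelled approximate; the source reports
posterior CIs without a stated method, so they are not verified against it.

## Stage-comparison ANOVA

The positive-LR model is compared as k = 3 groups of n = 2: the stratum
pretests {14.0, 27.8}, the post-PCT posteriors {43, 64}, and the full-chain
posteriors {93, 97} (whole percent). F = (SSB/2)/(SSW/3) with an F(2, 3)
upper-tail p-value gives F = 25.56, p = 0.013. The implementation is the
explicit sum-of-squares decomposition (needed for the degenerate SSW = 0 →
infinite-F contract); `scipy.stats.f_oneway` is the independent oracle in
tests at 1e−10. With two observations per group the test is fragile and best
read as a stage-separation summary, not an inference about patients. The
negative-LR model ({14, 27.8}, {2, 5}, {1, 2}) is not significant
(F = 6.82, p = 0.077), matching the published claim.

## Disposition rules

Only one branch→disposition mapping is published verbatim: intermediate
CURB-65 with PCT+ and lactate+ warrants ICU admission. The default ruleset
implements that rule first, then routes every other branch by posterior
thresholds chosen as this package's own defaults: ≥ 0.90 ICU, 0.50–0.90
step-down, 0.15–0.50 observation, < 0.15 ward for the admitted strata and
outpatient otherwise. Rules are ordered, first-match-wins, and the set is
rejected at load time unless its fully-wildcarded rules cover the whole
posterior axis (totality). All thresholds are overridable in the YAML
config. The tree exports to DOT and JSON; the JSON round-trips to identical
assignments.

## Monte-Carlo simulator

The simulator draws disease status Bernoulli(prevalence) and each test
result conditionally on status (positive with probability `se` if diseased,
`1 − sp` if healthy), independent across tests given status — i.e. it
simulates the chaining assumption as ground truth. It therefore validates
the *arithmetic* of the chain, not the independence assumption itself:
agreement between empirical and analytic posteriors says nothing about how
correlated the real biomarkers are, and the simulator generates binary
outcomes only, not biomarker concentrations or CURB-65 covariates. Default
problem sizes: 200,000 patients for single-cohort checks, 50 seeds × 50,000
for the coverage property (every branch posterior within 4 binomial SEs in
≥ 99% of checks); both run in seconds. All draws come from
`numpy.random.default_rng(seed)` and identical (seed, config) pairs
reproduce counts exactly.

## Numerical conventions

- Library APIs use proportions in [0, 1]; config files and the CLI use
  percentages, converted only at the boundary.
- An infinite LR+ (spec = 1) is first-class and yields posterior 1;
  pretest 0 and 1 are absorbing; LR = 1 is an exact identity.
- Whole-percent rounding is half-up (`floor(100p + 0.5)`), matching the
  published tables; reported LRs are rounded to 2 decimals, gains to 1.
- Branch enumeration order is deterministic: configured test order,
  positive before negative, first test most significant. Output files embed
  the config hash and rounding policy, so reruns are byte-identical.

## Limitations

Beyond the independence assumption: the pooled accuracies are treated as
fixed inputs (no meta-analytic uncertainty propagation beyond the CI-corner
LR intervals); the 2-observations-per-group ANOVA has minimal power; the
disposition thresholds other than the ICU rule are package defaults, not
validated clinical policy; and the whole framework is a mathematical
estimation that would need prospective validation before clinical use.
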