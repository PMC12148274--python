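# Methods

## The counterfactual estimand

The package estimates, for a fixed cohort of medical inpatients, the
expected number of 14-day VTE and in-hospital major-bleeding events under
alternative prophylaxis assignment rules, holding the patients and their
predicted risks fixed and varying only who is treated. The estimand is
purely expectational: per patient, the predicted event probability under
the assigned treatment status, summed over the cohort. There is no
time-to-event structure, no competing-risk correction, and the two outcomes
are treated as independent and equally weighted — one VTE counts the same
as one major bleed. These simplifications mirror the decision-analytic
framing the package implements; relaxing them (severity weights,
within-patient dependence of thrombosis and bleeding) would change the
frontier quantitatively but not the machinery.

Treatment effects are homogeneous: every treated patient's VTE probability
is multiplied by (1 − RRR) and bleeding probability by RR, capped at 1. The
cap matters only for extreme bleeding risks (the plausible maximum ~0.79
times RR up to 1.92 exceeds certainty) and is this package's choice; an
expectation cannot exceed 1.

## Strategies and boundary conventions

Six rules are implemented (see `strategies.py`). Thresholds follow the
published high-risk cut-points with their inequality directions fixed as:
VTE probability threshold inclusive (≥ 1%), bleeding threshold exclusive
(< 0.78%), Padua inclusive (≥ 4), IMPROVE exclusive (< 7). The
benefit-harm-weighing rule (`cc_minimize_events`) treats a
high-VTE-high-bleed patient iff RRR·p_vte > (RR−1)·p_bleed, i.e. iff the
expected VTEs prevented exceed the expected bleeds caused; ties are not
treated. A `raw_risk` mode (treat iff p_vte > p_bleed) is retained as a
configuration option because the informal phrase "VTE risk outweighs
bleeding risk" admits both readings; `expected_events` is the default
because the strategy's purpose is minimizing total events. The weighing
therefore depends on the treatment-effect parameters, and by default the
rule's membership is re-derived in every sensitivity-grid cell
(`reindicate=False` freezes it at base case for comparison).

## Frontier construction

Strategies are points (P, E): prophylaxis per 100 patients, total expected
events per 100. The frontier is the lower convex hull anchored at the
least-treating point and truncated where E stops strictly decreasing.
"Dominated" covers strict dominance (more treatment, no fewer events) and
extended dominance (a convex combination of two other strategies beats the
point) — the convex-hull operationalization standard in cost-effectiveness
analysis. Incremental NNT = (P₂−P₁)/(E₁−E₂) between consecutive hull
points; hull convexity makes successive NNTs strictly increasing, which the
tests assert on every instance. Degenerate choices: exact (P, E)
duplicates collapse onto one frontier position; a tie in P keeps the
lower-E point; a point exactly collinear on a hull segment is counted
dominated (it adds no efficiency and would produce a repeated NNT). For
display, NNTs are rounded to the nearest integer below 100 and the nearest
5 above; machine outputs keep full precision.

## Synthetic cohort generator

The generator emulates the statistical structure the evaluation needs, not
any real population:

* **Risk marginals.** Each risk is log-normal with location ln(median) and
  scale √(2·ln(mean/median)) — the unique log-normal matching the two
  published location statistics — then clipped to the published range of
  each risk model's output. Defaults: VTE mean 1.26%, median 0.74%, range
  [0.31%, 45.3%]; bleeding mean 0.52%, median 0.21%, range [0.017%,
  78.6%]; n = 46,025. Clipping puts a point mass (~20% of patients) at the
  VTE floor, consistent with a risk model whose minimum achievable
  prediction is the floor itself; it shifts the mean by under 2%.
* **Risk correlation.** (ln p_vte, ln p_bleed) are jointly Gaussian with
  correlation 0.2 by default. Thrombosis and bleeding risk share drivers,
  so a modest positive value is realistic; materially higher values leak
  the prescribing model's VTE-risk slope into an apparent bleeding-risk
  response (through the correlation) larger than the near-flat response the
  generator is meant to emulate. The value is exposed in `SynthConfig` and
  swept in tests.
* **Prescribing model.** The observed flag is Bernoulli with logit
  a + b·z(ln p_vte) + c·z(ln p_bleed), c = 0 by default. Two parameters
  cannot hit three calibration targets (overall rate 61.7%, bottom/top
  VTE-decile rates 50%/87%) under a symmetric standardized log-risk, so the
  slope is root-found (brentq) to the 37-point top-minus-bottom decile
  spread and the intercept to the overall rate; the achieved decile
  endpoints (~46%/84%) are recorded in the cohort metadata. Infeasible
  targets (low ≥ overall, unreachable spread) raise `CalibrationError`.
* **Scores.** Padua (0–10) and IMPROVE (0–12) are monotone transforms of
  the risk ranks with Gaussian noise on the rank scale (default sd 0.1).
  The score boundary (Padua 4, IMPROVE 7) is pinned to the same population
  quantile as the corresponding probability-threshold crossing, so at zero
  noise the score rule and probability rule flag identical patients, and at
  the default noise they agree on roughly 9 of 10 patients.

What passing tests on these cohorts establish: the estimator, frontier and
grid are correct as algorithms, and the generator hits its documented
targets. What they do not establish: any real cohort's absolute event
rates or NNTs, which depend on the true joint risk distribution — with a
real cohort table (delimited text through `read_cohort`), the same pipeline
produces the real numbers. The generator's scores are rank-derived, not
item-based, so score-specific phenomena (e.g. the score rules selecting far
fewer patients than probability rules, as real score distributions can) are
outside what the synthetic cohort can show.

## Numerical and testing choices

* Probabilities are fractions in (0, 1) internally; percent only at output.
  Predicted risks of exactly 0 or 1 are rejected as data errors.
* Cohort I/O round-trips bit-exactly: floats are written shortest-repr and
  parsed with exact `astype(float)` (the fast `pd.to_numeric` parser loses
  final digits).
* The Monte-Carlo companion (`simulate_events`) draws each patient's two
  outcomes independently at the adjusted probabilities, chunked to bound
  memory, reproducible by seed. The analytic-vs-simulation agreement tests
  run nearly 100 simultaneous 3-standard-error comparisons, so a marginal
  exceedance is expected by chance even when the expectation is exact; a
  comparison that exceeds 3 SE is confirmed against an additional
  independent 30,000-replicate batch at the same rule, which shrinks the
  standard error and so *raises* power against genuine bias.
* Test problem sizes: full generator calibration runs at n = 46,025 (the
  default cohort size); oracle-equivalence simulations at n = 10³ and 10⁴
  with 10,000 replicates; the frontier is checked against an exhaustive
  dominance oracle on 500 random instances of up to 8 strategies; the grid
  against a loop-over-patients reimplementation at n = 400 to 10
  significant digits.
* Quantiles in prescribing reports are equal-count with ties broken by row
  order; with the VTE floor mass, the bottom deciles can share one risk
  value, so gradient tests assert a monotone trend (Spearman ≥ 0.9, no
  decile dropping beyond sampling noise) rather than strict monotonicity.

## Known limitations

Homogeneous treatment effects; no mortality, cost, heparin-induced
thrombocytopenia, or severity weighting; no repeated admissions; exclusion
criteria (therapeutic anticoagulation, missing model inputs) are assumed
applied before the table reaches the package. The synthetic prescribing
model is a single logistic in log-risk — it reproduces marginal gradients,
not physician-level or hospital-level heterogeneity.
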