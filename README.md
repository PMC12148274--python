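# vteppx

Counterfactual evaluation of pharmacological venous-thromboembolism (VTE)
prophylaxis strategies for medical inpatients.

Hospital-acquired VTE is common and partly preventable: prophylactic
anticoagulation cuts symptomatic VTE risk by roughly a quarter to a half,
but raises major-bleeding risk by roughly a third to nearly double. Whether
a given patient should receive prophylaxis therefore depends on *both* of
their risks, and physicians are known to both over-treat low-VTE-risk
patients and under-treat high-risk ones. `vteppx` asks, at cohort scale:
*if prophylaxis had been assigned by an explicit risk-based rule instead of
physician judgment, how many events would have been expected, and at what
treatment cost?*

The package is a library first (import it from Python), with an `examples/`
directory of narrative scripts and a thin `vteppx` command-line pipeline.

## The model

Each admission carries predicted probabilities $p^{vte}_i$ (14-day VTE) and
$p^{bleed}_i$ (in-hospital major bleeding) from validated logistic risk
models, point-based Padua and IMPROVE scores, and the observed prescribing
flag. A **strategy** is a deterministic rule mapping these features to a
treat/don't-treat indication — six are built in, from `no_prophylaxis`
through score- and probability-threshold rules to `near_universal`
(everyone at bleeding risk < 0.78%). For treated patients, risks are
adjusted by the treatment effect (base case: efficacy RRR = 0.52, harm
RR = 1.37):

$$p^{vte}_i \mapsto p^{vte}_i\,(1-\mathrm{RRR}), \qquad
  p^{bleed}_i \mapsto \min(p^{bleed}_i \cdot \mathrm{RR},\, 1).$$

Summing adjusted risks gives expected VTE and bleeding events; rates are
reported per 1,000 patients. Strategies are compared on the **incremental
number needed to treat**

$$\mathrm{NNT} = \frac{P_{S2}-P_{S1}}{E_{S1}-E_{S2}},$$

with $P$ the prophylaxis rate per 100 patients and $E$ the total expected
events per 100; the **efficiency frontier** is the lower convex hull of the
$(P, E)$ points anchored at no-prophylaxis, and strategies above it are
dominated. A sensitivity grid re-runs everything over the plausible
efficacy (27–52%) and harm (+37–92%) ranges.

Because no patient-level data ship with the package, a calibrated synthetic
generator produces cohorts with the right structure: correlated log-normal
risk pairs moment-matched to published marginals, physician prescribing
that responds to VTE risk but not bleeding risk, and risk scores that agree
imperfectly with the probability thresholds.

## Worked example

```python
from vteppx import (ProphylaxisParams, SynthConfig, build_frontier,
                    default_strategies, evaluate_strategies, generate_cohort)

cohort = generate_cohort(SynthConfig(n=10_000, seed=42))
outcomes = evaluate_strategies(cohort, default_strategies(), ProphylaxisParams())
frontier = build_frontier(outcomes)
```

`python examples/03_efficiency_frontier.py` prints (abridged):

```
            strategy  prophylaxis_per_100  total_per_1000  dominated  incremental_nnt
      no_prophylaxis                 0.00          18.190      False              NaN
cc_minimize_bleeding                29.45          14.736      False           85.269
          guidelines                29.71          14.824       True              NaN
  cc_minimize_events                36.06          14.024      False           92.915
          physicians                61.84          14.635       True              NaN
      near_universal                82.62          13.737      False         1621.832
```

Reading: with no prophylaxis this cohort expects 18.2 events per 1,000.
Treating the ~29% of patients picked by the minimize-bleeding rule averts
one event per ~85 patients treated. Physicians treated 62% of patients yet
expected *more* total events than the minimize-events rule achieved at 36%
— physicians are dominated (off the frontier). Pushing on to near-universal
prophylaxis prevents very little more, at ~1,600 additional patients
treated per event prevented. `examples/04_sensitivity_grid.py` shows how
this picture shifts over the efficacy × harm ranges.

The same pipeline runs from a shell:

```sh
vteppx all --n 10000 --seed 42 --out-dir out/   # synth -> run -> sensitivity
vteppx demo-nnt                                  # (50-20)/(1.6-1.3) = 100
```

Cohorts are plain delimited text (see `vteppx.cohort.DEFAULT_SCHEMA` for
column names), so real predictions can be substituted for synthetic ones.

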