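"""Expected events under each prophylaxis strategy at the base case.

For every strategy, each treated patient's VTE risk is reduced by 52% and
bleeding risk increased by 37%; summing adjusted risks gives the expected
events per 1,000 patients. More prophylaxis always means fewer VTEs and
more bleeds — the strategies differ in how efficiently they trade the two.
"""

from vteppx import (
    ProphylaxisParams,
    SynthConfig,
    default_strategies,
    evaluate_strategies,
    generate_cohort,
    outcomes_table,
)

cohort = generate_cohort(SynthConfig(n=10_000, seed=42))
params = ProphylaxisParams(efficacy_rrr=0.52, harm_rr=1.37)
outcomes = evaluate_strategies(cohort, default_strategies(), params)

df = outcomes_table(outcomes)
print(df.round(2).to_string(index=False))
print(
    "\nEach row: % treated, then expected VTE / major-bleeding / total "
    "events per 1,000 patients.\nNote the score-based and "
    "probability-threshold rules treat half as many patients as physicians "
    "did,\nat a similar total event rate."
)
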