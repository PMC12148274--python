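"""Sensitivity of event rates and NNTs to prophylaxis efficacy and harm.

Trial estimates bound prophylaxis efficacy between a 27% and 52% VTE
reduction and harm between a +37% and +92% bleeding increase. The grid
re-runs the entire evaluation at each corner; strategy membership for the
benefit-harm-weighing rule is re-derived inside every cell.
"""

from vteppx import SynthConfig, default_strategies, generate_cohort, render_table, run_grid

cohort = generate_cohort(SynthConfig(n=10_000, seed=42))
cells = run_grid(cohort, default_strategies())

print(render_table(cells))
print(
    "NNTs are shown only for strategies on the cell's efficiency frontier "
    "('-' = dominated).\nHigher harm shifts the frontier toward the "
    "bleeding-averse rules; higher efficacy\nlowers every strategy's VTE rate."
)
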