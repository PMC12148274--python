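"""Incremental NNT and the efficiency frontier.

First the textbook two-strategy example: going from treating 20% of
patients (total events 1.6 per 100) to 50% (1.3 per 100) treats 30 more
patients per 100 to prevent 0.3 events per 100 — an incremental NNT of 100.

Then the full frontier on a synthetic cohort: strategies are sorted by
treatment rate, the lower convex hull of (prophylaxis rate, total events)
is the frontier, and everything above it is dominated.
"""

from vteppx import (
    ProphylaxisParams,
    SynthConfig,
    build_frontier,
    default_strategies,
    evaluate_strategies,
    frontier_table,
    generate_cohort,
    nnt_from_rates,
    round_nnt_display,
)

nnt = nnt_from_rates(20.0, 1.6, 50.0, 1.3)
print(f"worked example: (50 - 20) / (1.6 - 1.3) = {nnt:.0f}\n")

cohort = generate_cohort(SynthConfig(n=10_000, seed=42))
outcomes = evaluate_strategies(
    cohort, default_strategies(), ProphylaxisParams()
)
frontier = build_frontier(outcomes)

print(frontier_table(frontier).round(3).to_string(index=False))
print("\nfrontier path and incremental NNTs:")
points = frontier.frontier_points
for base, nxt, nnt in zip(points, points[1:], frontier.incremental_nnt):
    print(
        f"  {base.strategy_name} -> {nxt.strategy_name}: "
        f"NNT {round_nnt_display(nnt):,} "
        f"(exact {nnt:.1f})"
    )
print(
    "\nEach NNT is the number of additional patients treated per additional "
    "event prevented\nrelative to the previous frontier strategy; it rises "
    "steeply once low-risk patients\nare being treated."
)
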