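"""Efficacy x harm sensitivity analysis over the strategy set.

Randomized trials bound prophylaxis efficacy (relative VTE reduction)
between 27% and 52% and harm (relative bleeding increase) between +37% and
+92%. The grid re-runs the whole evaluation — indication assignment,
expected events, efficiency frontier — at each (efficacy, harm) pair; the
default grid is the four corners of those ranges.

By default the ``cc_minimize_events`` membership is re-derived inside every
cell (its weighing rule references the cell's treatment effects); a flag
allows freezing indications at the base case for comparison.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .estimator import StrategyOutcome, expected_events
from .frontier import FrontierResult, build_frontier, round_nnt_display
from .strategies import ProphylaxisParams, StrategySpec, assign_prophylaxis

__all__ = [
    "DEFAULT_EFFICACY_VALUES",
    "DEFAULT_HARM_VALUES",
    "SensitivityCell",
    "run_grid",
    "render_table",
    "grid_long_table",
]

DEFAULT_EFFICACY_VALUES = (0.27, 0.52)
DEFAULT_HARM_VALUES = (1.37, 1.92)

#: Report row order (reference strategy excluded from display rows).
TABLE_ROW_ORDER = (
    "physicians",
    "guidelines",
    "cc_minimize_bleeding",
    "cc_minimize_events",
    "near_universal",
)

DISPLAY_NAMES = {
    "no_prophylaxis": "No Prophylaxis",
    "physicians": "Physicians",
    "guidelines": "Guidelines",
    "cc_minimize_bleeding": "Minimize-Bleeding",
    "cc_minimize_events": "Minimize-Events",
    "near_universal": "Near-Universal",
}


@dataclasses.dataclass(frozen=True)
class SensitivityCell:
    """One grid cell: the parameter pair, outcomes, and frontier."""

    efficacy_rrr: float
    harm_rr: float
    outcomes: tuple[StrategyOutcome, ...]
    frontier: FrontierResult


def run_grid(
    cohort: Cohort,
    strategies: Sequence[StrategySpec],
    efficacy_values: Sequence[float] = DEFAULT_EFFICACY_VALUES,
    harm_values: Sequence[float] = DEFAULT_HARM_VALUES,
    reindicate: bool = True,
    base_params: ProphylaxisParams | None = None,
) -> list[SensitivityCell]:
    """Evaluate every strategy at every (efficacy, harm) grid point.

    A ``no_prophylaxis`` reference is injected if absent so every cell's
    frontier has its anchor. With ``reindicate=False`` indications are
    frozen at ``base_params`` (default base case) and only the risk
    adjustment varies across cells.
    """
    if len(efficacy_values) == 0 or len(harm_values) == 0:
        raise ValueError("sensitivity grid must contain at least one cell")
    specs = list(strategies)
    if not any(s.name == "no_prophylaxis" for s in specs):
        specs.insert(0, StrategySpec(name="no_prophylaxis"))

    cells: list[SensitivityCell] = []
    for eff in efficacy_values:
        for harm in harm_values:
            params = ProphylaxisParams(efficacy_rrr=eff, harm_rr=harm)
            indic_params = (
                params if reindicate else (base_params or ProphylaxisParams())
            )
            outcomes = tuple(
                expected_events(
                    cohort,
                    assign_prophylaxis(cohort, spec, indic_params),
                    params,
                    spec.name,
                )
                for spec in specs
            )
            cells.append(
                SensitivityCell(
                    efficacy_rrr=eff,
                    harm_rr=harm,
                    outcomes=outcomes,
                    frontier=build_frontier(outcomes),
                )
            )
    return cells


def _cell_nnts(cell: SensitivityCell) -> dict[str, float]:
    """Strategy -> full-precision incremental NNT for frontier points."""
    fr = cell.frontier
    out: dict[str, float] = {}
    for seg, idx in enumerate(fr.frontier_indices[1:]):
        out[fr.points[idx].strategy_name] = fr.incremental_nnt[seg]
    return out


def render_table(cells: Sequence[SensitivityCell]) -> str:
    """Plain-text sensitivity report, one block per grid cell.

    Rows are ordered physicians, guidelines, minimize-bleeding,
    minimize-events, near-universal; event rates are shown to 2 decimals and
    incremental NNTs only for strategies on the cell's efficiency frontier
    ("-" otherwise).
    """
    if len(cells) == 0:
        raise ValueError("no cells to render")
    lines: list[str] = []
    header = (
        f"{'Strategy':<22}{'VTE/1,000':>12}{'Bleed/1,000':>13}"
        f"{'Total/1,000':>13}{'Incremental NNT':>18}"
    )
    for cell in cells:
        eff_pct = 100.0 * cell.efficacy_rrr
        harm_pct = 100.0 * (cell.harm_rr - 1.0)
        lines.append(
            f"Efficacy {eff_pct:.0f}% (VTE reduction), "
            f"Harm +{harm_pct:.0f}% (bleeding increase)"
        )
        lines.append(header)
        nnts = _cell_nnts(cell)
        by_name = {o.strategy_name: o for o in cell.outcomes}
        ordered = [n for n in TABLE_ROW_ORDER if n in by_name]
        ordered += [
            o.strategy_name
            for o in cell.outcomes
            if o.strategy_name not in ordered
            and o.strategy_name != "no_prophylaxis"
        ]
        for name in ordered:
            o = by_name[name]
            nnt_str = (
                f"{round_nnt_display(nnts[name]):,}" if name in nnts else "-"
            )
            lines.append(
                f"{DISPLAY_NAMES.get(name, name):<22}{o.vte_rate:>12.2f}"
                f"{o.bleed_rate:>13.2f}{o.total_rate:>13.2f}{nnt_str:>18}"
            )
        lines.append("")
    return "\n".join(lines)


def grid_long_table(cells: Sequence[SensitivityCell]) -> pd.DataFrame:
    """Machine-readable long format: one row per (cell, strategy)."""
    rows = []
    for cell in cells:
        nnts = _cell_nnts(cell)
        dom = dict(
            zip(
                (p.strategy_name for p in cell.frontier.points),
                cell.frontier.dominated,
            )
        )
        for o in cell.outcomes:
            rows.append(
                {
                    "efficacy": cell.efficacy_rrr,
                    "harm": cell.harm_rr,
                    "strategy": o.strategy_name,
                    "prophylaxis_per_100": o.prophylaxis_rate,
                    "vte_per_1000": o.vte_rate,
                    "bleed_per_1000": o.bleed_rate,
                    "total_per_1000": o.total_rate,
                    "dominated": dom[o.strategy_name],
                    "incremental_nnt": nnts.get(o.strategy_name, np.nan),
                }
            )
    return pd.DataFrame(rows)
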