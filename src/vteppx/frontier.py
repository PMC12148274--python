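"""Incremental number-needed-to-treat and the prophylaxis efficiency frontier.

Each strategy is a point in the plane (P, E): P = prophylaxis rate per 100
eligible patients, E = expected total events (VTE + major bleeding) per 100
individuals. Moving from a less-treating strategy S1 to a more-treating S2,

    incremental NNT = (P2 - P1) / (E1 - E2)

is the number of additional patients treated per additional event
prevented. The efficiency frontier is the lower convex hull of the points,
anchored at the least-treating strategy (no prophylaxis), truncated where
events stop falling; points strictly above it are "dominated" — either
directly (more treatment, no fewer events) or by extended dominance (a
blend of two other strategies prevents events more cheaply). Convexity of
the hull makes incremental NNTs strictly increase along the frontier.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .estimator import StrategyOutcome

__all__ = [
    "incremental_nnt",
    "nnt_from_rates",
    "FrontierResult",
    "build_frontier",
    "frontier_table",
    "round_nnt_display",
]


def nnt_from_rates(p1: float, e1: float, p2: float, e2: float) -> float:
    """Incremental NNT from raw per-100 rates: ``(p2 - p1) / (e1 - e2)``.

    ``p`` = prophylaxis per 100 patients, ``e`` = total events per 100
    patients; strategy 2 must treat more than strategy 1. Returns ``inf``
    when the comparator prevents no additional events (it is dominated).
    """
    if p2 <= p1:
        raise ValueError(
            "comparator must have the higher prophylaxis rate; swap the "
            f"arguments (got base P={p1}, comparator P={p2})"
        )
    if e1 <= e2:
        return math.inf
    return (p2 - p1) / (e1 - e2)


def incremental_nnt(base: StrategyOutcome, comparator: StrategyOutcome) -> float:
    """Incremental NNT between two strategy outcomes.

    Event rates are stored per 1,000 and converted to the per-100 scale of
    the NNT formula.
    """
    return nnt_from_rates(
        base.prophylaxis_rate,
        base.total_rate / 10.0,
        comparator.prophylaxis_rate,
        comparator.total_rate / 10.0,
    )


@dataclasses.dataclass(frozen=True)
class FrontierResult:
    """Strategies ordered by treatment rate, with dominance and NNTs.

    ``points`` is sorted by ascending prophylaxis rate (ties by lower total
    event rate). ``dominated[i]`` flags points off the frontier.
    ``frontier_indices`` indexes the frontier points within ``points``;
    ``incremental_nnt[k]`` is the NNT of the segment arriving at frontier
    point ``k + 1`` (one fewer entries than frontier points).
    """

    points: tuple[StrategyOutcome, ...]
    dominated: tuple[bool, ...]
    frontier_indices: tuple[int, ...]
    incremental_nnt: tuple[float, ...]

    @property
    def anchor(self) -> StrategyOutcome:
        """The least-treating frontier point (the no-prophylaxis reference)."""
        return self.points[self.frontier_indices[0]]

    @property
    def frontier_points(self) -> tuple[StrategyOutcome, ...]:
        return tuple(self.points[i] for i in self.frontier_indices)


def _lower_hull(px: np.ndarray, ey: np.ndarray) -> list[int]:
    """Indices of the lower convex hull of points sorted by x.

    Strictly convex turns only: collinear middle points are excluded, which
    later marks them dominated (they add no efficiency over the segment
    through their neighbours).
    """
    hull: list[int] = []
    for i in range(len(px)):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            cross = (px[k] - px[j]) * (ey[i] - ey[j]) - (ey[k] - ey[j]) * (
                px[i] - px[j]
            )
            if cross <= 0:  # k is above or on segment j->i
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def build_frontier(outcomes: Sequence[StrategyOutcome]) -> FrontierResult:
    """Order outcomes, flag dominated strategies, compute frontier NNTs.

    All outcomes must share the same treatment-effect parameters. The input
    order is irrelevant. Exact duplicate (P, E) points collapse onto one
    frontier position; a tie in P with different E keeps the lower-E point
    as the candidate and marks the other dominated.
    """
    if len(outcomes) < 2:
        raise ValueError("need at least two strategy outcomes to build a frontier")
    param_set = {(o.params.efficacy_rrr, o.params.harm_rr) for o in outcomes}
    if len(param_set) > 1:
        raise ValueError(
            "all outcomes on one frontier must share identical prophylaxis "
            f"parameters; got {sorted(param_set)}"
        )

    order = sorted(
        range(len(outcomes)),
        key=lambda i: (outcomes[i].prophylaxis_rate, outcomes[i].total_rate),
    )
    points = tuple(outcomes[i] for i in order)
    px = np.array([p.prophylaxis_rate for p in points], dtype=float)
    ey = np.array([p.total_rate / 10.0 for p in points], dtype=float)

    # Candidate set: per distinct P keep the first (lowest-E) point.
    cand: list[int] = []
    for i in range(len(points)):
        if cand and px[i] == px[cand[-1]]:
            continue
        cand.append(i)

    hull_local = _lower_hull(px[cand], ey[cand])
    hull = [cand[h] for h in hull_local]

    # Truncate once events stop strictly decreasing: any hull vertex after
    # the minimum-E vertex treats more without preventing more.
    frontier = [hull[0]]
    for i in hull[1:]:
        if ey[i] < ey[frontier[-1]]:
            frontier.append(i)

    frontier_set = {(px[i], ey[i]) for i in frontier}
    dominated = tuple((px[i], ey[i]) not in frontier_set for i in range(len(points)))
    nnts = tuple(
        nnt_from_rates(px[a], ey[a], px[b], ey[b])
        for a, b in zip(frontier[:-1], frontier[1:])
    )
    return FrontierResult(
        points=points,
        dominated=dominated,
        frontier_indices=tuple(frontier),
        incremental_nnt=nnts,
    )


def round_nnt_display(nnt: float) -> int:
    """Report-granularity rounding: nearest integer below 100, nearest 5 at
    or above 100. Machine outputs keep full precision."""
    if not math.isfinite(nnt):
        raise ValueError("cannot display a non-finite NNT")
    if nnt < 100:
        return int(round(nnt))
    return int(5 * round(nnt / 5.0))


def frontier_table(result: FrontierResult) -> pd.DataFrame:
    """Delimited-text-ready frontier export, one row per strategy point.

    ``incremental_nnt`` is the full-precision NNT of the segment arriving at
    a frontier point (NaN for the anchor and for dominated points).
    """
    nnt_col = np.full(len(result.points), np.nan)
    for seg, idx in enumerate(result.frontier_indices[1:]):
        nnt_col[idx] = result.incremental_nnt[seg]
    return pd.DataFrame(
        {
            "strategy": [p.strategy_name for p in result.points],
            "prophylaxis_per_100": [p.prophylaxis_rate for p in result.points],
            "total_per_1000": [p.total_rate for p in result.points],
            "dominated": list(result.dominated),
            "incremental_nnt": nnt_col,
        }
    )
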