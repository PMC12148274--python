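"""Independent brute-force oracles used by the tests.

These deliberately share no code with the package: dominance is decided by
exhaustive pairwise/segment checks, and the sensitivity-grid rates are
recomputed with plain Python loops over patient records.
"""

from __future__ import annotations


def brute_force_dominated(points: list[tuple[float, float]]) -> list[bool]:
    """Exhaustive dominance check on (P, E) points.

    A point is dominated iff a single other point weakly beats it on both
    axes (strictly on at least one), or the segment between two other
    points passes below it at its own prophylaxis rate (extended
    dominance).
    """
    n = len(points)
    dom = [False] * n
    for i, (pi, ei) in enumerate(points):
        for j, (pj, ej) in enumerate(points):
            if j == i:
                continue
            if (pj <= pi and ej < ei) or (pj < pi and ej <= ei):
                dom[i] = True
        for j in range(n):
            for k in range(n):
                if i in (j, k) or j >= k:
                    continue
                pj, ej = points[j]
                pk, ek = points[k]
                if pk < pj:
                    pj, ej, pk, ek = pk, ek, pj, ej
                if pj <= pi <= pk and pk > pj:
                    lam = (pi - pj) / (pk - pj)
                    if ej + lam * (ek - ej) < ei:
                        dom[i] = True
    return dom


def slow_strategy_rates(
    records, name: str, eff: float, harm: float
) -> tuple[float, float, float]:
    """Straight-line per-patient recomputation of one strategy's rates.

    Returns (prophylaxis per 100, VTE per 1,000, bleeding per 1,000) using
    the published thresholds, with no shared code or vectorisation.
    """
    treat = []
    for r in records:
        if name == "no_prophylaxis":
            t = False
        elif name == "physicians":
            t = r.physician_prophylaxis
        elif name == "guidelines":
            t = r.padua_score >= 4 and r.improve_score < 7
        elif name == "cc_minimize_bleeding":
            t = r.p_vte >= 0.01 and r.p_bleed < 0.0078
        elif name == "cc_minimize_events":
            t = r.p_vte >= 0.01 and (
                r.p_bleed < 0.0078 or eff * r.p_vte > (harm - 1.0) * r.p_bleed
            )
        elif name == "near_universal":
            t = r.p_bleed < 0.0078
        else:
            raise ValueError(name)
        treat.append(t)
    n = len(records)
    sum_v = sum(
        r.p_vte * (1.0 - eff) if t else r.p_vte for r, t in zip(records, treat)
    )
    sum_b = sum(
        min(r.p_bleed * harm, 1.0) if t else r.p_bleed
        for r, t in zip(records, treat)
    )
    return 100.0 * sum(treat) / n, 1000.0 * sum_v / n, 1000.0 * sum_b / n
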