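"""Prophylaxis strategies: deterministic decision rules over patient risk.

Six strategies are compared:

``no_prophylaxis``
    Treat nobody. Reference point for incremental comparisons.
``physicians``
    What actually happened — the observed prescribing flag.
``guidelines``
    Score-based rule: high VTE risk by Padua (>= 4 points) and low bleeding
    risk by IMPROVE (< 7 points).
``cc_minimize_bleeding``
    Probability-threshold rule: 14-day VTE risk >= 1% and in-hospital
    bleeding risk < 0.78%.
``cc_minimize_events``
    As above, but also treats patients at high risk of both outcomes when
    the expected benefit of prophylaxis outweighs its expected harm.
``near_universal``
    Treat everyone at low bleeding risk, regardless of VTE risk.

All thresholds are configurable; the defaults are the published high-risk
cut-points of the underlying risk models.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cohort import Cohort

__all__ = [
    "STRATEGY_NAMES",
    "ProphylaxisParams",
    "StrategySpec",
    "ConfigurationError",
    "assign_prophylaxis",
    "prophylaxis_rate",
    "default_strategies",
]

STRATEGY_NAMES = (
    "no_prophylaxis",
    "physicians",
    "guidelines",
    "cc_minimize_bleeding",
    "cc_minimize_events",
    "near_universal",
)

WEIGHING_MODES = ("expected_events", "raw_risk")


class ConfigurationError(ValueError):
    """A strategy was requested with an invalid name, mode, or missing data."""


@dataclasses.dataclass(frozen=True)
class ProphylaxisParams:
    """Treatment-effect pair applied to every treated patient.

    Attributes
    ----------
    efficacy_rrr
        Relative reduction in VTE probability under prophylaxis, a fraction
        in (0, 1). Base case 0.52 (52% reduction); plausible range 0.27-0.52.
    harm_rr
        Multiplicative relative risk applied to bleeding probability, >= 1.
        Base case 1.37 (+37%); plausible range 1.37-1.92.
    """

    efficacy_rrr: float = 0.52
    harm_rr: float = 1.37

    def __post_init__(self) -> None:
        if not (0.0 < self.efficacy_rrr < 1.0):
            raise ValueError(
                f"efficacy_rrr must lie in (0, 1), got {self.efficacy_rrr}"
            )
        if self.harm_rr < 1.0:
            raise ValueError(f"harm_rr must be >= 1, got {self.harm_rr}")


@dataclasses.dataclass(frozen=True)
class StrategySpec:
    """A named decision rule mapping patient features to an indication.

    Boundary conventions: VTE threshold inclusive (>= 1%), bleeding
    threshold exclusive (< 0.78%), Padua inclusive (>= 4), IMPROVE exclusive
    (< 7).

    ``weighing_mode`` is used only by ``cc_minimize_events``:
    ``expected_events`` treats a both-high-risk patient iff
    ``efficacy_rrr * p_vte > (harm_rr - 1) * p_bleed`` (prevented VTEs exceed
    caused bleeds); ``raw_risk`` treats iff ``p_vte > p_bleed``.
    """

    name: str
    padua_min: int = 4
    improve_max: int = 7
    vte_threshold: float = 0.01
    bleed_threshold: float = 0.0078
    weighing_mode: str = "expected_events"

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ConfigurationError(
                f"unknown strategy '{self.name}'; valid names: "
                + ", ".join(STRATEGY_NAMES)
            )
        if self.weighing_mode not in WEIGHING_MODES:
            raise ConfigurationError(
                f"unknown weighing_mode '{self.weighing_mode}'"
            )
        if self.vte_threshold <= 0 or self.bleed_threshold <= 0:
            raise ConfigurationError("risk thresholds must be strictly positive")


def default_strategies(**overrides) -> list[StrategySpec]:
    """All six strategies with shared threshold overrides applied."""
    return [StrategySpec(name=name, **overrides) for name in STRATEGY_NAMES]


def _weigh_favorable(
    p_vte: np.ndarray,
    p_bleed: np.ndarray,
    params: ProphylaxisParams,
    mode: str,
) -> np.ndarray:
    if mode == "expected_events":
        # Strict inequality: a patient whose expected benefit exactly equals
        # the expected harm is not treated.
        return params.efficacy_rrr * p_vte > (params.harm_rr - 1.0) * p_bleed
    return p_vte > p_bleed


def assign_prophylaxis(
    cohort: Cohort, spec: StrategySpec, params: ProphylaxisParams
) -> np.ndarray:
    """Boolean indication vector: who receives prophylaxis under ``spec``.

    Deterministic: identical inputs give identical vectors. ``params``
    enters only through the ``cc_minimize_events`` weighing rule.
    """
    pv, pb = cohort.p_vte, cohort.p_bleed
    name = spec.name

    if name == "no_prophylaxis":
        return np.zeros(cohort.n, dtype=bool)
    if name == "physicians":
        return cohort.physician_prophylaxis.astype(bool)
    if name == "guidelines":
        padua, improve = cohort.padua_score, cohort.improve_score
        if padua is None or improve is None:
            raise ConfigurationError(
                "guidelines strategy requires padua_score and improve_score columns"
            )
        return (padua >= spec.padua_min) & (improve < spec.improve_max)
    if name == "cc_minimize_bleeding":
        return (pv >= spec.vte_threshold) & (pb < spec.bleed_threshold)
    if name == "cc_minimize_events":
        favorable = _weigh_favorable(pv, pb, params, spec.weighing_mode)
        return (pv >= spec.vte_threshold) & (
            (pb < spec.bleed_threshold) | favorable
        )
    if name == "near_universal":
        return pb < spec.bleed_threshold
    raise ConfigurationError(f"unknown strategy '{name}'")  # pragma: no cover


def prophylaxis_rate(indications: np.ndarray) -> float:
    """Treatment rate per 100 patients: ``100 * mean(indications)``."""
    indications = np.asarray(indications)
    if indications.size == 0:
        raise ValueError("cannot compute a prophylaxis rate on an empty vector")
    return 100.0 * float(np.count_nonzero(indications)) / indications.size
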