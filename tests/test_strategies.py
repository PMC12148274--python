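import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vteppx import (
    Cohort,
    ConfigurationError,
    ProphylaxisParams,
    StrategySpec,
    assign_prophylaxis,
    default_strategies,
    prophylaxis_rate,
)


def _cohort(p_vte, p_bleed, ppx=None, padua=None, improve=None):
    n = len(p_vte)
    data = {
        "patient_id": [f"p{i}" for i in range(n)],
        "p_vte": p_vte,
        "p_bleed": p_bleed,
        "physician_prophylaxis": ppx if ppx is not None else [False] * n,
    }
    if padua is not None:
        data["padua_score"] = pd.array(padua, dtype="Int64")
        data["improve_score"] = pd.array(improve, dtype="Int64")
    return Cohort(pd.DataFrame(data))


def _assign(cohort, name, params=None, **spec_kw):
    return assign_prophylaxis(
        cohort, StrategySpec(name=name, **spec_kw), params or ProphylaxisParams()
    )


class TestRules:
    def test_low_bleed_high_vte_patient_indicated_by_all_cc_rules(self):
        c = _cohort([0.02], [0.001])
        for name in ("cc_minimize_bleeding", "cc_minimize_events", "near_universal"):
            assert _assign(c, name)[0]

    def test_guidelines_improve_boundary_is_exclusive(self):
        c = _cohort(
            [0.02, 0.02], [0.001, 0.001], padua=[5, 5], improve=[3, 7]
        )
        ind = _assign(c, "guidelines")
        assert ind[0] and not ind[1]

    def test_padua_boundary_is_inclusive(self):
        c = _cohort([0.02, 0.02], [0.001, 0.001], padua=[4, 3], improve=[0, 0])
        ind = _assign(c, "guidelines")
        assert ind[0] and not ind[1]

    def test_vte_threshold_inclusive_bleed_threshold_exclusive(self):
        c = _cohort([0.01, 0.0099], [0.0077, 0.0078])
        ind = _assign(c, "cc_minimize_bleeding")
        assert ind[0] and not ind[1]
        assert not _assign(c, "near_universal")[1]

    def test_minimize_events_weighs_benefit_against_harm(self):
        # 0.52 * 0.05 = 0.026 > 0.37 * 0.02 = 0.0074: high-bleed patient
        # still treated under minimize-events but not minimize-bleeding.
        c = _cohort([0.05], [0.02])
        assert not _assign(c, "cc_minimize_bleeding")[0]
        assert _assign(c, "cc_minimize_events")[0]

    def test_weighing_modes_can_disagree(self):
        # expected-events favourable (0.52*0.02 > 0.37*0.025) but raw risk
        # unfavourable (0.02 < 0.025).
        c = _cohort([0.02], [0.025])
        assert _assign(c, "cc_minimize_events", weighing_mode="expected_events")[0]
        assert not _assign(c, "cc_minimize_events", weighing_mode="raw_risk")[0]

    def test_exact_benefit_harm_tie_not_treated(self):
        params = ProphylaxisParams(efficacy_rrr=0.5, harm_rr=1.5)
        c = _cohort([0.02], [0.02])  # 0.5*0.02 == 0.5*0.02
        assert not _assign(c, "cc_minimize_events", params=params)[0]

    def test_physicians_reproduces_observed_flag(self):
        c = _cohort([0.01] * 3, [0.001] * 3, ppx=[True, False, True])
        assert list(_assign(c, "physicians")) == [True, False, True]

    def test_no_prophylaxis_all_false(self, tiny_cohort):
        assert not _assign(tiny_cohort, "no_prophylaxis").any()

    def test_guidelines_without_scores_is_configuration_error(self):
        c = _cohort([0.01], [0.001])
        with pytest.raises(ConfigurationError, match="padua"):
            _assign(c, "guidelines")

    def test_unknown_strategy_name_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown strategy"):
            StrategySpec(name="treat_everyone")

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ProphylaxisParams(efficacy_rrr=0.0)
        with pytest.raises(ValueError):
            ProphylaxisParams(harm_rr=0.9)

    def test_determinism(self, small_cohort, base_params):
        for spec in default_strategies():
            a = assign_prophylaxis(small_cohort, spec, base_params)
            b = assign_prophylaxis(small_cohort, spec, base_params)
            assert np.array_equal(a, b)


class TestRate:
    def test_half_treated_is_fifty(self):
        assert prophylaxis_rate(np.array([True, False])) == 50.0

    def test_none_treated_is_zero(self):
        assert prophylaxis_rate(np.zeros(10, dtype=bool)) == 0.0

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            prophylaxis_rate(np.array([], dtype=bool))


@given(
    risks=st.lists(
        st.tuples(
            st.floats(min_value=1e-4, max_value=0.5),
            st.floats(min_value=1e-5, max_value=0.79),
        ),
        min_size=1,
        max_size=40,
    ),
    eff=st.floats(min_value=0.05, max_value=0.95),
    harm=st.floats(min_value=1.0 + 1e-6, max_value=3.0),
)
def test_treatment_set_nesting(risks, eff, harm):
    """minimize-bleeding indications are a subset of both minimize-events
    and near-universal, for any cohort and any treatment-effect pair."""
    pv = [r[0] for r in risks]
    pb = [r[1] for r in risks]
    c = _cohort(pv, pb)
    params = ProphylaxisParams(efficacy_rrr=eff, harm_rr=harm)
    bleeding = _assign(c, "cc_minimize_bleeding", params=params)
    events = _assign(c, "cc_minimize_events", params=params)
    universal = _assign(c, "near_universal", params=params)
    assert not (bleeding & ~events).any()
    assert not (bleeding & ~universal).any()
    assert prophylaxis_rate(bleeding) <= prophylaxis_rate(events)
    assert prophylaxis_rate(bleeding) <= prophylaxis_rate(universal)


def test_minimize_events_collapses_to_minimize_bleeding_at_zero_efficacy(
    small_cohort,
):
    params = ProphylaxisParams(efficacy_rrr=1e-12, harm_rr=1.37)
    events = _assign(small_cohort, "cc_minimize_events", params=params)
    bleeding = _assign(small_cohort, "cc_minimize_bleeding", params=params)
    assert np.array_equal(events, bleeding)
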