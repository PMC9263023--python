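"""Decision-engine unit and property tests: zone partition, titration
formula, responsiveness logic, reset bookkeeping and the decision tree."""

import math
from dataclasses import replace

import pytest
from hypothesis import given, settings, strategies as st

from vasoloop import (
    ControllerConfig,
    ControllerState,
    InterventionKind,
    MapZone,
    Responsiveness,
    VitalsWindow,
    assess_responsiveness,
    classify_map,
    decide,
    maybe_reset_responsiveness,
    titration_delta,
)

CFG = ControllerConfig(weight_kg=70.0)


def window(map_avg, cvp_avg=8.0, t=7200.0):
    return VitalsWindow(time_s=t, map_avg=map_avg, cvp_avg=cvp_avg)


def state(**kw):
    return ControllerState(**{"ne_rate": 0.1, **kw})


# ---------------------------------------------------------------------------
# classify_map
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "map_avg, zone",
    [
        (60.0, MapZone.NORMO),          # band inclusive at 60
        (70.0, MapZone.NORMO),          # band inclusive at 70
        (70.01, MapZone.HYPER),
        (50.0, MapZone.MODERATE_HYPO),  # moderate band inclusive at 50
        (59.99, MapZone.MODERATE_HYPO),
        (49.99, MapZone.SEVERE_HYPO),
        (0.0, MapZone.SEVERE_HYPO),
        (120.0, MapZone.HYPER),
    ],
)
def test_classify_map_boundaries(map_avg, zone):
    assert classify_map(map_avg, CFG) is zone


@given(st.floats(min_value=0.0, max_value=300.0))
@settings(derandomize=True, max_examples=200)
def test_zone_partition_is_exhaustive_and_exclusive(map_avg):
    zone = classify_map(map_avg, CFG)
    in_zone = {
        MapZone.SEVERE_HYPO: map_avg < 50,
        MapZone.MODERATE_HYPO: 50 <= map_avg < 60,
        MapZone.NORMO: 60 <= map_avg <= 70,
        MapZone.HYPER: map_avg > 70,
    }
    assert in_zone[zone]
    assert sum(in_zone.values()) == 1


@pytest.mark.parametrize("bad", [float("nan"), float("inf"), -1.0])
def test_classify_map_rejects_degenerate_input(bad):
    with pytest.raises(ValueError):
        classify_map(bad, CFG)


# ---------------------------------------------------------------------------
# titration_delta
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "map_avg, ne, scale, expected",
    [
        (65.0, 0.3, 1, 0.0),            # at target: no step
        (55.0, 0.04, 1, 0.0144),        # 1 x 0.0072 x 10 x 0.2
        (75.0, 0.09, 2, 0.0432),        # 2 x 0.0072 x 10 x 0.3
    ],
)
def test_titration_delta_hand_arithmetic(map_avg, ne, scale, expected):
    assert titration_delta(map_avg, ne, scale, CFG) == pytest.approx(expected, rel=1e-12)


def test_titration_delta_sqrt_floor_keeps_controller_live():
    # even at NE = 0 the step is positive away from target
    assert titration_delta(55.0, 0.0, 1, CFG) == pytest.approx(
        0.0072 * 10 * math.sqrt(0.02), rel=1e-12
    )


@given(
    st.floats(min_value=0.0, max_value=150.0),
    st.floats(min_value=0.0, max_value=150.0),
    st.floats(min_value=0.0, max_value=1.0),
    st.floats(min_value=0.0, max_value=1.0),
)
@settings(derandomize=True, max_examples=200)
def test_titration_delta_monotone(map_a, map_b, ne_a, ne_b):
    """Non-decreasing in |MAP - 65| and in the NE rate."""
    if abs(map_a - 65) <= abs(map_b - 65):
        assert titration_delta(map_a, ne_a, 1, CFG) <= titration_delta(map_b, ne_a, 1, CFG)
    if ne_a <= ne_b:
        assert titration_delta(70.0, ne_a, 1, CFG) <= titration_delta(70.0, ne_b, 1, CFG)


def test_titration_delta_rejects_negative_ne():
    with pytest.raises(ValueError):
        titration_delta(55.0, -0.1, 1, CFG)


# ---------------------------------------------------------------------------
# responsiveness
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "base, post, verdict",
    [
        (52.0, 57.0, Responsiveness.RESPONSIVE),       # boundary inclusive at +5
        (52.0, 56.9, Responsiveness.NON_RESPONSIVE),
        (52.0, 52.0, Responsiveness.NON_RESPONSIVE),
        (52.0, 40.0, Responsiveness.NON_RESPONSIVE),
    ],
)
def test_assess_responsiveness_threshold(base, post, verdict):
    assert assess_responsiveness(base, post, CFG) is verdict


@pytest.mark.parametrize(
    "count, elapsed, status, expect_reset",
    [
        (4, 600.0, Responsiveness.RESPONSIVE, True),     # four interventions
        (2, 3600.0, Responsiveness.NON_RESPONSIVE, True),  # one hour elapsed
        (3, 3599.0, Responsiveness.RESPONSIVE, False),   # neither condition
    ],
)
def test_maybe_reset_responsiveness(count, elapsed, status, expect_reset):
    s = state(
        responsiveness=status,
        interventions_since_test=count,
        last_test_time_s=1000.0,
    )
    out = maybe_reset_responsiveness(s, 1000.0 + elapsed, CFG)
    if expect_reset:
        assert out.responsiveness is Responsiveness.UNKNOWN
    else:
        assert out == s


# ---------------------------------------------------------------------------
# decide: the tree
# ---------------------------------------------------------------------------

def kinds(actions):
    return [a.kind for a in actions]


def test_severe_hypotension_bolus_plus_pressor():
    actions, new = decide(window(45.0, cvp_avg=5.0), state(ne_rate=0.1), CFG)
    assert kinds(actions) == [InterventionKind.FLUID_BOLUS, InterventionKind.NE_INCREASE]
    assert all(a.branch == "severe_hypotension" for a in actions)
    assert actions[0].magnitude == 350.0
    # scale 2 titration from the severe branch
    assert new.ne_rate == pytest.approx(0.1 + 2 * 0.0072 * 20 * math.sqrt(0.1))
    assert new.interventions_since_test == 1  # one decision event for the reset counter


def test_normotension_no_intervention():
    actions, new = decide(window(65.0), state(ne_rate=0.1), CFG)
    assert actions == []
    assert new.ne_rate == 0.1


def test_normotension_corner_high_ne_low_cvp():
    actions, _ = decide(window(65.0, cvp_avg=5.0), state(ne_rate=0.6), CFG)
    assert kinds(actions) == [InterventionKind.FLUID_BOLUS]
    assert actions[0].branch == "normotension_corner"


@pytest.mark.parametrize("ne, cvp", [(0.5, 5.0), (0.6, 6.0), (0.1, 8.0)])
def test_normotension_corner_requires_both_conditions(ne, cvp):
    actions, _ = decide(window(65.0, cvp_avg=cvp), state(ne_rate=ne), CFG)
    assert actions == []


def test_normotension_quiet_region_grid():
    """Exhaustive grid over the normo band with NE <= 0.5 or CVP >= 6."""
    for map_avg in [60.0, 62.5, 65.0, 67.5, 70.0]:
        for ne in [0.0, 0.1, 0.3, 0.5]:
            for cvp in [2.0, 6.0, 10.0]:
                actions, _ = decide(window(map_avg, cvp_avg=cvp), state(ne_rate=ne), CFG)
                assert actions == []
        for cvp in [6.0, 8.0, 12.0]:
            for ne in [0.6, 0.9]:
                actions, _ = decide(window(map_avg, cvp_avg=cvp), state(ne_rate=ne), CFG)
                assert actions == []


def test_hypertension_weans_pressor():
    actions, new = decide(window(75.0), state(ne_rate=0.09), CFG)
    assert kinds(actions) == [InterventionKind.NE_DECREASE]
    assert actions[0].branch == "hypertension_wean"
    assert new.ne_rate == pytest.approx(0.09 - 0.0072 * 10 * 0.3)


def test_hypertension_at_ne_floor_does_nothing():
    actions, new = decide(window(72.0), state(ne_rate=0.0), CFG)
    assert actions == []
    assert new.ne_rate == 0.0


def test_moderate_unknown_fires_test_bolus():
    actions, new = decide(window(55.0), state(interventions_since_test=3), CFG)
    assert kinds(actions) == [InterventionKind.TEST_BOLUS]
    assert new.active_test is not None
    assert new.active_test.baseline_map == 55.0
    assert new.last_test_time_s == 7200.0
    assert new.interventions_since_test == 0


def test_moderate_responsive_is_fluid_avid():
    actions, _ = decide(
        window(55.0), state(responsiveness=Responsiveness.RESPONSIVE), CFG
    )
    assert kinds(actions) == [InterventionKind.FLUID_BOLUS]
    assert actions[0].branch == "moderate_hypotension_responsive"


def test_moderate_non_responsive_is_pressor_avid():
    actions, new = decide(
        window(55.0, cvp_avg=8.0), state(responsiveness=Responsiveness.NON_RESPONSIVE), CFG
    )
    assert kinds(actions) == [InterventionKind.NE_INCREASE]
    assert actions[0].branch == "moderate_hypotension_pressor"
    assert new.ne_rate > 0.1


def test_cvp_based_fluid_bolus_breaks_pressor_cycling():
    actions, _ = decide(
        window(55.0, cvp_avg=4.0), state(responsiveness=Responsiveness.NON_RESPONSIVE), CFG
    )
    assert kinds(actions) == [InterventionKind.FLUID_BOLUS]
    assert actions[0].branch == "cvp_based_fluid_bolus"


def test_pressor_resistance_bolus_at_max_ne():
    actions, new = decide(
        window(55.0, cvp_avg=8.0),
        state(ne_rate=CFG.ne_max, responsiveness=Responsiveness.NON_RESPONSIVE),
        CFG,
    )
    assert kinds(actions) == [InterventionKind.FLUID_BOLUS]
    assert actions[0].branch == "pressor_resistance"
    assert new.ne_rate == CFG.ne_max


def test_four_interventions_then_moderate_tick_retests():
    """The reset rule re-arms the test bolus after 4 interventions."""
    s = state(
        responsiveness=Responsiveness.RESPONSIVE,
        interventions_since_test=4,
        last_test_time_s=6000.0,
    )
    actions, new = decide(window(55.0), s, CFG)
    assert kinds(actions) == [InterventionKind.TEST_BOLUS]
    assert new.interventions_since_test == 0


def test_decide_defers_with_test_in_flight():
    from vasoloop import ActiveTest

    s = state(active_test=ActiveTest(baseline_map=55.0, start_s=7000.0))
    actions, new = decide(window(45.0), s, CFG)
    assert actions == []
    assert new == s


def test_decide_rejects_invalid_window():
    with pytest.raises(ValueError):
        decide(VitalsWindow(time_s=0.0, map_avg=float("nan"), cvp_avg=8.0), state(), CFG)


# ---------------------------------------------------------------------------
# fuzzed sequence properties
# ---------------------------------------------------------------------------

@given(
    st.lists(
        st.tuples(
            st.floats(min_value=0.0, max_value=150.0),
            st.floats(min_value=0.0, max_value=20.0),
        ),
        min_size=1,
        max_size=60,
    )
)
@settings(derandomize=True, max_examples=100, deadline=None)
def test_ne_rate_never_leaves_bounds(vitals_seq):
    s = ControllerState(ne_rate=0.02)
    t = 0.0
    for map_avg, cvp in vitals_seq:
        t += 60.0
        actions, s = decide(window(map_avg, cvp_avg=cvp, t=t), s, CFG)
        assert CFG.ne_min <= s.ne_rate <= CFG.ne_max
        # a test bolus leaves the in-flight marker: clear it as the loop
        # driver would after assessment
        if s.active_test is not None:
            s = replace(s, active_test=None, responsiveness=Responsiveness.NON_RESPONSIVE)


@given(
    st.floats(min_value=0.0, max_value=150.0),
    st.floats(min_value=0.0, max_value=20.0),
    st.floats(min_value=0.0, max_value=0.99),
    st.sampled_from(list(Responsiveness)),
    st.integers(min_value=0, max_value=6),
)
@settings(derandomize=True, max_examples=200, deadline=None)
def test_decide_is_pure_and_deterministic(map_avg, cvp, ne, resp, count):
    w = window(map_avg, cvp_avg=cvp)
    s = state(ne_rate=ne, responsiveness=resp, interventions_since_test=count,
              last_test_time_s=7000.0)
    out1 = decide(w, s, CFG)
    out2 = decide(w, s, CFG)
    assert out1 == out2


@given(st.floats(min_value=0.0, max_value=49.99), st.floats(min_value=0.0, max_value=0.9))
@settings(derandomize=True, max_examples=100)
def test_severe_always_bolus_and_pressor_increase(map_avg, ne):
    """Below NE max, severe hypotension pairs a bolus with an NE increase."""
    actions, _ = decide(window(map_avg, cvp_avg=5.0), state(ne_rate=ne), CFG)
    assert sorted(kinds(actions), key=lambda k: k.value) == [
        InterventionKind.FLUID_BOLUS,
        InterventionKind.NE_INCREASE,
    ]
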