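import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from remindersim import (
    accuracy,
    choice_probability,
    compute_oip,
    equivalent_gain_value,
    fit_aip,
    measures_from_trials,
    metacognitive_bias,
    reminder_bias,
)
from remindersim.task_engine import FORCED_EXTERNAL, FORCED_INTERNAL, TrialPlan, TrialResult

from .conftest import make_agent
from .oracles import grid_fit_aip, profile_location


def _forced_session(hit_counts, trial_type=FORCED_INTERNAL):
    session = []
    for i, k in enumerate(hit_counts):
        plan = TrialPlan(
            trial_index=2 * i + 2,
            trial_type=trial_type,
            framing="gain",
            offer_raw=None,
            target_positions=tuple(range(7, 17)),
        )
        outcomes = tuple([1] * k + [0] * (10 - k))
        strategy = "internal" if trial_type == FORCED_INTERNAL else "external"
        session.append((plan, TrialResult(strategy, outcomes)))
    return session


def test_accuracy_is_hits_over_targets():
    session = _forced_session([6, 7, 6, 7])
    assert accuracy(session, FORCED_INTERNAL) == pytest.approx(26 / 40)
    assert accuracy(_forced_session([10, 10]), FORCED_INTERNAL) == 1.0
    with pytest.raises(ValueError):
        accuracy(session, FORCED_EXTERNAL)


@pytest.mark.parametrize(
    "offer_raw, framing, experiment, expected",
    [
        (-9, "loss", 1, 1.0),
        (-1, "loss", 1, 9.0),
        (3, "loss", 2, 7.0),
        (8, "loss", 2, 2.0),
        (5, "gain", 1, 5.0),
        (5, "gain", 2, 5.0),
    ],
)
def test_equivalent_gain_value(offer_raw, framing, experiment, expected):
    assert equivalent_gain_value(offer_raw, framing, experiment) == expected


@pytest.mark.parametrize(
    "offer_raw, framing, experiment",
    [(0, "gain", 1), (10, "gain", 1), (1, "loss", 2), (-10, "loss", 1), (0, "loss", 1)],
)
def test_equivalent_gain_value_rejects_out_of_range(offer_raw, framing, experiment):
    with pytest.raises(ValueError):
        equivalent_gain_value(offer_raw, framing, experiment)


@given(offer=hst.integers(2, 8))
def test_exp2_loss_transform_is_an_involution(offer):
    once = equivalent_gain_value(offer, "loss", 2)
    assert equivalent_gain_value(once, "loss", 2) == offer


def test_compute_oip_examples():
    assert compute_oip(0.55, 1.00, bounds=(1, 9)) == pytest.approx(5.5)
    assert compute_oip(0.90, 0.90, bounds=(1, 9)) == 9.0  # ratio 1 -> 10, clamped
    assert compute_oip(0.10, 0.95, bounds=(2, 8)) == 2.0
    with pytest.raises(ValueError):
        compute_oip(0.5, 0.0)
    with pytest.raises(ValueError):
        compute_oip(1.2, 0.9)


def test_bias_and_metacognition_arithmetic():
    assert reminder_bias(6.2, 4.2) == pytest.approx(2.0)
    assert reminder_bias(5.0, 5.0) == 0.0
    assert reminder_bias(3.0, 5.0) == pytest.approx(-2.0)  # bias toward memory
    assert metacognitive_bias(60.0, 0.65) == pytest.approx(-5.0)
    assert metacognitive_bias(80.0, 0.80) == 0.0
    assert metacognitive_bias(95.0, 0.90) == pytest.approx(5.0)


def test_fit_aip_degenerate_patterns_hit_the_bounds():
    always = [(o, 1) for o in range(1, 10)]
    never = [(o, 0) for o in range(1, 10)]
    fit_always = fit_aip(always, bounds=(1, 9))
    fit_never = fit_aip(never, bounds=(1, 9))
    assert fit_always.location == 1.0 and fit_always.degenerate
    assert fit_never.location == 9.0 and fit_never.degenerate


def test_fit_aip_step_data_lands_mid_gap():
    """A perfect step between offers 5 and 6 pins the slope at its cap and
    the location inside the step interval, matching the grid maximizer."""
    data = [(o, 0) for o in range(2, 6)] + [(o, 1) for o in range(6, 9)]
    fit = fit_aip(data, bounds=(2, 8))
    assert 5.0 < fit.location < 6.0
    assert fit.slope == pytest.approx(50.0, rel=1e-6)
    oracle = grid_fit_aip([d[0] for d in data], [d[1] for d in data], (2, 8))
    assert fit.location == pytest.approx(oracle, abs=0.01)


def test_fit_aip_matches_grid_oracle_on_random_data(rng):
    for _ in range(25):
        bounds = (1.0, 9.0) if rng.random() < 0.5 else (2.0, 8.0)
        offers = np.arange(bounds[0], bounds[1] + 1)
        loc = rng.uniform(*bounds)
        slope = rng.uniform(0.5, 5.0)
        y = (rng.random(offers.size) < 1 / (1 + np.exp(-slope * (offers - loc)))).astype(int)
        if y.min() == y.max():
            continue
        fit = fit_aip(list(zip(offers, y)), bounds=bounds)
        oracle = grid_fit_aip(offers, y, bounds)
        assert fit.location == pytest.approx(oracle, abs=0.01)


def test_profile_location_monotone_in_lowest_offer_choice(rng):
    """At any fixed slope, turning the lowest-offer choice from memory to
    reminders can only pull the likelihood-maximizing location down (a
    monotone-likelihood-ratio property; with the slope also free, the MLE can
    instead flatten the curve and the crossing may move either way)."""
    offers = np.arange(1.0, 10.0)
    checked = 0
    while checked < 15:
        y = (rng.random(9) < (offers - 1) / 10).astype(int)
        if y[0] == 1 or y.max() == 0:
            continue
        y2 = y.copy()
        y2[0] = 1
        for slope in (0.5, 1.0, 2.0, 5.0):
            before = profile_location(offers, y, slope, (1, 9), loc_step=0.01)
            after = profile_location(offers, y2, slope, (1, 9), loc_step=0.01)
            assert after <= before + 1e-9
        checked += 1


def test_fit_aip_recovers_a_known_indifference_point(rng):
    agent = make_agent(subjective_ip=4.5, choice_slope=2.0, lapse=0.0)
    offers = np.repeat(np.arange(1.0, 10.0), 200)
    probs = np.array([choice_probability(agent, o, "gain") for o in offers])
    y = (rng.random(offers.size) < probs).astype(int)
    fit = fit_aip(list(zip(offers, y)), bounds=(1, 9))
    assert fit.location == pytest.approx(4.5, abs=0.15)
    assert fit.slope == pytest.approx(2.0, rel=0.25)


def test_fit_aip_input_validation():
    with pytest.raises(ValueError):
        fit_aip([], bounds=(1, 9))
    with pytest.raises(ValueError):
        fit_aip([(1, 2)], bounds=(1, 9))


def test_measures_table_structure(exp2_cohort):
    config, participants, trials = exp2_cohort
    measures = measures_from_trials(trials, 2, participants=participants)
    assert set(measures["framing"]) == {"gain", "loss"}
    assert measures.groupby("participant_id").size().eq(2).all()
    lo, hi = 2.0, 8.0
    assert measures["aip"].between(lo, hi).all()
    assert measures["oip"].between(lo, hi).all()
    # the bias column is exactly OIP - AIP
    np.testing.assert_allclose(
        measures["reminder_bias"], measures["oip"] - measures["aip"], atol=1e-12
    )
    assert {"metacog_internal_bias", "metacog_external_bias"} <= set(measures.columns)
    # pooled accuracy: the metacognitive columns repeat within participant
    per = measures.groupby("participant_id")["metacog_internal_bias"].nunique()
    assert per.eq(1).all()
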