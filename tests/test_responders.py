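import numpy as np
import pandas as pd
import pytest

from stresscue import (
    CYCLIC_MAPPING,
    ResponderModel,
    consistency_scores,
    expected_scores,
    simulate_cohort,
    simulate_responses,
)
from stresscue.design import as_trials_frame, full_design
from stresscue.exceptions import UnsupportedModelError


def test_pure_duration_follower_echoes_duration_profile(trials):
    rs = simulate_responses(trials, ResponderModel(w_duration=1.0), seed=0)
    frame = as_trials_frame(trials)
    assert (rs.responses.to_numpy() == frame["duration"].to_numpy()).all()


def test_cyclic_mapping_never_matches_duration(trials):
    model = ResponderModel(w_duration=1.0, mapping=dict(CYCLIC_MAPPING))
    rs = simulate_responses(trials, model, seed=0)
    frame = as_trials_frame(trials)
    assert (rs.responses.to_numpy() != frame["duration"].to_numpy()).all()


def test_simulation_is_seed_deterministic(trials):
    model = ResponderModel(w_duration=0.3, w_pitch=0.2)
    a = simulate_responses(trials, model, seed=42)
    b = simulate_responses(trials, model, seed=42)
    c = simulate_responses(trials, model, seed=43)
    assert a.responses.equals(b.responses)
    assert not a.responses.equals(c.responses)


def test_cohort_members_differ_but_cohort_is_reproducible(trials):
    model = ResponderModel(w_pitch=0.5)
    a = simulate_cohort(trials, model, 4, seed=5, group="g")
    b = simulate_cohort(trials, model, 4, seed=5, group="g")
    assert [x.participant_id for x in a] == ["g001", "g002", "g003", "g004"]
    for x, y in zip(a, b):
        assert x.responses.equals(y.responses)
    assert not a[0].responses.equals(a[1].responses)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"w_duration": -0.1},
        {"w_duration": 0.8, "w_intensity": 0.8},
        {"w_duration": 0.5, "w_random": 0.9},
        {"bias": (0.5, 0.5, 0.5)},
        {"mapping": {"AP": "AP", "PE": "AP", "U": "U"}},
        {"position_weights": {"loudness": {"AP": 0.5}}},
        {"position_weights": {"pitch": {"XX": 0.5}}},
    ],
)
def test_invalid_models_are_rejected(kwargs):
    with pytest.raises(ValueError):
        ResponderModel(**kwargs)


@pytest.mark.parametrize(
    "weights, expected",
    [
        ((1.0, 0.0, 0.0), (1.0, 0.0, 0.0)),
        ((0.5, 0.5, 0.0), (0.5, 0.5, 0.0)),
        ((0.25, 0.25, 0.0), (0.25, 0.25, 0.0)),
    ],
)
def test_expected_scores_worked_examples(weights, expected):
    wd, wi, wp = weights
    es = expected_scores(ResponderModel(w_duration=wd, w_intensity=wi, w_pitch=wp))
    assert (es.dc, es.ic, es.pc) == pytest.approx(expected)
    assert es.oc == pytest.approx(sum(expected))


def test_expected_scores_derangement_extreme():
    model = ResponderModel(w_duration=1.0, mapping=dict(CYCLIC_MAPPING))
    es = expected_scores(model)
    assert es.dc == pytest.approx(-0.5)
    assert es.ic == es.pc == pytest.approx(0.0)


def test_expected_scores_ignore_bias():
    a = expected_scores(ResponderModel(w_pitch=0.4))
    b = expected_scores(ResponderModel(w_pitch=0.4, bias=(0.8, 0.1, 0.1)))
    assert a == b


def test_expected_scores_refuse_position_weights():
    model = ResponderModel(w_pitch=0.2, position_weights={"pitch": {"U": 0.9}})
    with pytest.raises(UnsupportedModelError):
        expected_scores(model)


def test_parameter_recovery_on_repeated_design(design):
    """Simulated scores converge to the closed-form expectations.

    100 stacked passes of the design (8100 trials) bring the Monte-Carlo
    error of each cue consistency down to ~1.5 * sqrt(p(1-p)/n) < 0.01;
    the recovered weights must sit within 3 such standard errors.
    """
    reps = 100
    stacked = pd.concat([design] * reps, ignore_index=True)
    stacked.insert(0, "trial_index", np.arange(1, len(stacked) + 1))
    model = ResponderModel(w_duration=0.2, w_intensity=0.3, w_pitch=0.4)
    rs = simulate_responses(stacked, model, seed=2024)
    scores = consistency_scores(stacked, rs)
    expected = expected_scores(model)
    n = len(stacked)
    for got, want in zip((scores.dc, scores.ic, scores.pc), expected[:3]):
        p = (want + 0.5) / 1.5
        se = 1.5 * np.sqrt(p * (1 - p) / n)
        assert abs(got - want) <= 3 * se


def test_position_specific_weights_shape_the_profile(trials):
    """A responder using pitch only in final-stress profiles shows it
    in the pitch-by-position subscores: high at U, near zero elsewhere."""
    model = ResponderModel(
        position_weights={"pitch": {"AP": 0.0, "PE": 0.0, "U": 0.9}}
    )
    frame = as_trials_frame(trials)
    reps = 30
    stacked = pd.concat([frame.drop(columns="trial_index")] * reps, ignore_index=True)
    stacked.insert(0, "trial_index", np.arange(1, len(stacked) + 1))
    rs = simulate_responses(stacked, model, seed=9)
    scores = consistency_scores(stacked, rs)
    pbp = scores.param_by_position
    assert pbp[("pitch", "U")] > 0.7
    assert abs(pbp[("pitch", "AP")]) < 0.12
    assert abs(pbp[("pitch", "PE")]) < 0.12
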