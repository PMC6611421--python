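import numpy as np
import pandas as pd
import pytest

from conftest import deterministic_responses, naive_scores, uniform_random_responses
from stresscue import (
    consistency_scores,
    match_indicators,
    rescale,
    score_table,
    sd_across_cells,
)
from stresscue.design import PARAM_SHORT, PARAMETERS, POSITIONS, as_trials_frame
from stresscue.exceptions import IncompleteDataError

SUCC = {"AP": "PE", "PE": "U", "U": "AP"}


@pytest.mark.parametrize(
    "p, expected", [(1 / 3, 0.0), (1.0, 1.0), (0.0, -0.5), (0.5, 0.25)]
)
def test_rescale_values(p, expected):
    assert rescale(p) == pytest.approx(expected)


def test_rescale_rejects_out_of_range():
    with pytest.raises(ValueError):
        rescale(1.2)
    with pytest.raises(ValueError):
        rescale(-0.01)


def test_match_indicators_against_profiles(trials):
    frame = as_trials_frame(trials)
    rs = deterministic_responses(trials, lambda row: row["duration"])
    ind = match_indicators(trials, rs)
    assert (ind["duration"] == 1).all()
    # on a trial with three pairwise-distinct profiles any response matches
    # exactly one cue; on a congruent trial a hit scores on all three
    distinct = frame[
        (frame["duration"] != frame["intensity"])
        & (frame["duration"] != frame["pitch"])
        & (frame["intensity"] != frame["pitch"])
    ]
    sums = ind.loc[distinct["trial_index"]].sum(axis=1)
    assert (sums == 1).all()
    congruent = frame[
        (frame["duration"] == frame["intensity"]) & (frame["intensity"] == frame["pitch"])
    ]
    rs_pe = deterministic_responses(trials, lambda row: "PE")
    ind_pe = match_indicators(trials, rs_pe)
    hit = congruent[congruent["duration"] == "PE"]
    assert (ind_pe.loc[hit["trial_index"]].sum(axis=1) == 3).all()


def test_pure_duration_follower_scores(trials):
    rs = deterministic_responses(trials, lambda row: row["duration"])
    s = consistency_scores(trials, rs)
    assert (s.dc, s.ic, s.pc, s.oc) == pytest.approx((1.0, 0.0, 0.0, 1.0))
    assert s.sd_cells == pytest.approx(np.sqrt(6 / 26))
    assert s.n_trials == 81


@pytest.mark.parametrize("position", POSITIONS)
def test_constant_response_bias_cancels_exactly(trials, position):
    """A stimulus-independent strategy scores exactly 0 on every cue:
    each profile equals the fixed position on exactly 1/3 of trials.
    The cells do not individually vanish (the position-matched third hit
    1, the rest -0.5) — their large spread is what the sd axis flags."""
    rs = deterministic_responses(trials, lambda row: position)
    s = consistency_scores(trials, rs)
    assert (s.dc, s.ic, s.pc, s.oc) == (0.0, 0.0, 0.0, 0.0)
    for cue in PARAMETERS:
        assert s.param_by_position[cue].mean() == pytest.approx(0.0)
    assert s.cell_scores.mean() == pytest.approx(0.0)
    # 9 cells at 1.0 and 18 at -0.5: sd = sqrt(13.5/26)
    assert s.sd_cells == pytest.approx(np.sqrt(13.5 / 26))


def test_cyclic_anti_duration_responder(trials):
    rs = deterministic_responses(trials, lambda row: SUCC[row["duration"]])
    s = consistency_scores(trials, rs)
    assert (s.dc, s.ic, s.pc) == pytest.approx((-0.5, 0.0, 0.0))
    assert s.oc == pytest.approx(-0.5)


def test_sd_across_cells_requires_27_values():
    assert sd_across_cells([0.0] * 27) == 0.0
    with pytest.raises(ValueError):
        sd_across_cells([0.0] * 26)


def test_aggregation_identities_on_random_responders(trials):
    rng = np.random.default_rng(123)
    for _ in range(10):
        rs = uniform_random_responses(trials, rng)
        s = consistency_scores(trials, rs)
        assert s.oc == pytest.approx(s.dc + s.ic + s.pc)
        for cue, xc in zip(PARAMETERS, (s.dc, s.ic, s.pc)):
            assert s.param_by_position[cue].mean() == pytest.approx(xc)
            assert s.cell_scores.xs(cue, level="parameter").mean() == pytest.approx(xc)
        assert s.cell_scores.mean() == pytest.approx(s.oc / 3)


def test_vectorized_scores_equal_naive_recount(trials):
    """Oracle equivalence: the module's scores match an independent
    double-loop recount on 100 random response sets."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        rs = uniform_random_responses(trials, rng)
        s = consistency_scores(trials, rs)
        ref = naive_scores(trials, rs)
        assert s.dc == pytest.approx(ref["DC"])
        assert s.ic == pytest.approx(ref["IC"])
        assert s.pc == pytest.approx(ref["PC"])
        assert s.oc == pytest.approx(ref["OC"])
        assert s.sd_cells == pytest.approx(ref["sd_cells"])
        for key, val in ref["pbp"].items():
            assert s.param_by_position[key] == pytest.approx(val)
        for key, val in ref["cells"].items():
            assert s.cell_scores[key] == pytest.approx(val)


def test_incomplete_responses_are_rejected_by_default(trials):
    rs = deterministic_responses(trials, lambda row: row["pitch"])
    truncated = rs.responses.iloc[:-1]
    with pytest.raises(IncompleteDataError):
        consistency_scores(trials, truncated)
    s = consistency_scores(trials, truncated, allow_incomplete=True)
    assert not s.complete
    assert s.n_trials == 80
    assert s.pc == pytest.approx(1.0)


def test_invalid_response_values_are_rejected(trials):
    rs = deterministic_responses(trials, lambda row: "XX")
    with pytest.raises(ValueError):
        consistency_scores(trials, rs)


def test_score_table_layout(trials):
    sets = [
        deterministic_responses(trials, lambda row: row["pitch"], "p1", "A"),
        deterministic_responses(trials, lambda row: "PE", "p2", "B"),
    ]
    table = score_table(trials, sets, include_cells=True)
    assert list(table["participant_id"]) == ["p1", "p2"]
    for param in PARAMETERS:
        for pos in POSITIONS:
            assert f"{PARAM_SHORT[param]}_{pos}" in table.columns
    cell_cols = [c for c in table.columns if c.startswith(("dididi_", "gugugu_", "tatata_"))]
    assert len(cell_cols) == 27
    assert table.loc[1, "OC"] == 0.0
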