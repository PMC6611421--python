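import numpy as np
import pandas as pd
import pytest

from stresscue import full_design, randomized_lists
from stresscue.design import as_trials_frame
from stresscue.responders import ResponseSet


@pytest.fixture(scope="session")
def design():
    return full_design()


@pytest.fixture(scope="session")
def trials(design):
    """One randomized complete pass through the 81-condition design."""
    return randomized_lists(design, 1, seed=7)[0]


def deterministic_responses(trials, rule, participant_id="det", group="synthetic"):
    """Build a ResponseSet whose response on each trial is rule(row)."""
    frame = as_trials_frame(trials)
    values = [rule(row) for _, row in frame.iterrows()]
    series = pd.Series(values, index=frame["trial_index"].to_numpy(), name="response")
    series.index.name = "trial_index"
    return ResponseSet(participant_id=participant_id, group=group, responses=series)


def uniform_random_responses(trials, rng, participant_id="rand", group="synthetic"):
    frame = as_trials_frame(trials)
    values = rng.choice(["AP", "PE", "U"], size=len(frame))
    series = pd.Series(values, index=frame["trial_index"].to_numpy(), name="response")
    series.index.name = "trial_index"
    return ResponseSet(participant_id=participant_id, group=group, responses=series)


def naive_scores(trials, responses):
    """Independent double-loop recount of all consistency quantities.

    Deliberately unvectorized: walks every trial, tallies matches per
    cue overall, per (cue, position) and per (nonword, position, cue)
    cell, and rescales each proportion by hand.
    """
    frame = as_trials_frame(trials)
    series = responses.responses if isinstance(responses, ResponseSet) else responses
    cues = ("duration", "intensity", "pitch")
    overall = {c: [0, 0] for c in cues}
    pbp = {}
    cells = {}
    for _, row in frame.iterrows():
        resp = series.loc[row["trial_index"]]
        for cue in cues:
            pos = row[cue]
            hit = int(resp == pos)
            overall[cue][0] += hit
            overall[cue][1] += 1
            k = (cue, pos)
            pbp.setdefault(k, [0, 0])
            pbp[k][0] += hit
            pbp[k][1] += 1
            ck = (row["nonword"], pos, cue)
            cells.setdefault(ck, [0, 0])
            cells[ck][0] += hit
            cells[ck][1] += 1

    def resc(hits, n):
        return 1.5 * hits / n - 0.5

    dc, ic, pc = (resc(*overall[c]) for c in cues)
    cell_scores = {k: resc(*v) for k, v in cells.items()}
    sd = float(np.std(list(cell_scores.values()), ddof=1))
    return {
        "DC": dc,
        "IC": ic,
        "PC": pc,
        "OC": dc + ic + pc,
        "pbp": {k: resc(*v) for k, v in pbp.items()},
        "cells": cell_scores,
        "sd_cells": sd,
    }
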