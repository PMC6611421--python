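"""Chance-corrected consistency scores for three-alternative stress judgments.

For each acoustic cue X (duration, intensity, pitch) a response is
*consistent* with X on a trial when the chosen stress position equals
X's profile on that trial.  The raw consistency is the proportion p of
consistent trials, which sits at 1/3 under stimulus-independent
responding on a balanced design; the affine rescaling ``1.5 p - 0.5``
maps it to a score with 0 at chance, 1 at perfect consistency and -0.5
at perfect anti-consistency.  DC, IC and PC are the rescaled scores for
the three cues; OC = DC + IC + PC summarizes how much of the behaviour
any cue accounts for.

Finer-grained variants use the same rescaled proportion within subsets
of trials: the 27 *cell* scores, one per (non-word x profile position x
cue) cell (9 trials each on the 81-trial design), and the 9 cue-by-
position scores pooling non-words (27 trials each).  The standard
deviation across the 27 cells measures within-participant heterogeneity
and is the second axis of the random-response region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import PARAM_SHORT, PARAMETERS, POSITIONS, as_trials_frame, validate_trials
from .exceptions import IncompleteDataError
from .responders import ResponseSet

N_CELLS = 27  # 3 non-words x 3 positions x 3 cues on the canonical design


@dataclass(frozen=True)
class ConsistencyScores:
    """The full consistency-score family for one participant.

    ``cell_scores`` is indexed by (nonword, position, parameter) in
    canonical order; ``param_by_position`` by (parameter, position).
    Exact identities on a balanced design: OC = DC + IC + PC, the mean
    of a cue's three position scores equals that cue's overall score,
    and the mean of all cells equals OC / 3.
    """

    dc: float
    ic: float
    pc: float
    oc: float
    cell_scores: pd.Series
    param_by_position: pd.Series
    sd_cells: float
    n_trials: int
    complete: bool = True

    def as_dict(self, include_cells: bool = False) -> dict[str, float]:
        """Flatten to the canonical CSV column layout."""
        out = {
            "DC": self.dc,
            "IC": self.ic,
            "PC": self.pc,
            "OC": self.oc,
            "sd_cells": self.sd_cells,
            "n_trials": self.n_trials,
        }
        for (param, pos), v in self.param_by_position.items():
            out[f"{PARAM_SHORT[param]}_{pos}"] = v
        if include_cells:
            for (nw, pos, param), v in self.cell_scores.items():
                out[f"{nw}_{PARAM_SHORT[param]}_{pos}"] = v
        return out


def rescale(p):
    """Map a raw match proportion in [0, 1] to the [-0.5, 1] score scale.

    ``1.5 p - 0.5``: chance (1/3) maps to 0, certainty to 1, never-match
    to -0.5.  Accepts scalars or arrays.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("proportions must lie in [0, 1]")
    out = 1.5 * arr - 0.5
    return float(out) if np.isscalar(p) else out


def _aligned_responses(frame: pd.DataFrame, responses) -> pd.Series:
    """Validate and align a response series/set to the trial frame order."""
    series = responses.responses if isinstance(responses, ResponseSet) else responses
    if not isinstance(series, pd.Series):
        raise TypeError("responses must be a ResponseSet or a Series by trial_index")
    trial_idx = frame["trial_index"].to_numpy()
    missing = set(trial_idx) - set(series.index)
    if missing:
        raise IncompleteDataError(
            f"responses missing for trials {sorted(missing)[:5]} "
            f"({len(missing)} in total)"
        )
    extra = set(series.index) - set(trial_idx)
    if extra:
        raise IncompleteDataError(f"responses for unknown trials {sorted(extra)[:5]}")
    if series.index.has_duplicates:
        raise IncompleteDataError("duplicate responses for some trials")
    aligned = series.reindex(trial_idx)
    bad = set(aligned) - set(POSITIONS)
    if bad:
        raise ValueError(f"invalid response values: {sorted(map(str, bad))}")
    return aligned


def match_indicators(trials, responses) -> pd.DataFrame:
    """Per-trial binary consistency indicators, one column per cue.

    Entry (t, X) is 1 iff the response on trial t equals cue X's profile
    on trial t.
    """
    frame = as_trials_frame(trials)
    aligned = _aligned_responses(frame, responses)
    out = pd.DataFrame(
        {
            cue: (aligned.to_numpy() == frame[cue].to_numpy()).astype(int)
            for cue in PARAMETERS
        },
        index=pd.Index(frame["trial_index"].to_numpy(), name="trial_index"),
    )
    return out


def sd_across_cells(cell_scores) -> float:
    """Sample standard deviation (ddof=1) across the 27 cell scores."""
    arr = np.asarray(cell_scores, dtype=float)
    if arr.size != N_CELLS:
        raise ValueError(f"expected {N_CELLS} cell scores, got {arr.size}")
    return float(np.std(arr, ddof=1))


def consistency_scores(trials, responses, allow_incomplete: bool = False) -> ConsistencyScores:
    """Compute DC/IC/PC/OC, the cell and cue-by-position subscores, and sd_cells.

    By default the trial list must be a complete balanced design and the
    responses must cover it exactly; ``allow_incomplete=True`` instead
    scores whatever trials have responses (raw proportions on available
    trials), in which case the chance-level interpretation of 0 holds
    only approximately and ``complete`` is flagged False.
    """
    if allow_incomplete:
        frame = as_trials_frame(trials)
        series = responses.responses if isinstance(responses, ResponseSet) else responses
        keep = frame["trial_index"].isin(series.index)
        frame = frame.loc[keep].reset_index(drop=True)
        if frame.empty:
            raise IncompleteDataError("no scorable trials")
        complete = len(series) == len(as_trials_frame(trials))
    else:
        frame = validate_trials(trials)
        complete = True

    ind = match_indicators(frame, responses)
    overall = rescale(ind.mean(axis=0).to_numpy())
    dc, ic, pc = (float(v) for v in overall)

    nonwords = sorted(set(frame["nonword"]))
    cell_index = pd.MultiIndex.from_product(
        [nonwords, POSITIONS, PARAMETERS], names=["nonword", "position", "parameter"]
    )
    cell_vals = {}
    pbp_vals = {}
    ind_arr = ind.to_numpy()
    for j, cue in enumerate(PARAMETERS):
        profile = frame[cue].to_numpy()
        for pos in POSITIONS:
            pos_mask = profile == pos
            pbp_vals[(cue, pos)] = (
                rescale(float(ind_arr[pos_mask, j].mean())) if pos_mask.any() else np.nan
            )
            for nw in nonwords:
                mask = pos_mask & (frame["nonword"].to_numpy() == nw)
                cell_vals[(nw, pos, cue)] = (
                    rescale(float(ind_arr[mask, j].mean())) if mask.any() else np.nan
                )
    cell_scores = pd.Series([cell_vals[k] for k in cell_index], index=cell_index)
    pbp_index = pd.MultiIndex.from_product(
        [PARAMETERS, POSITIONS], names=["parameter", "position"]
    )
    param_by_position = pd.Series([pbp_vals[k] for k in pbp_index], index=pbp_index)

    finite = cell_scores.dropna().to_numpy()
    if finite.size == N_CELLS:
        sd = sd_across_cells(finite)
    else:
        sd = float(np.std(finite, ddof=1)) if finite.size > 1 else float("nan")

    return ConsistencyScores(
        dc=dc,
        ic=ic,
        pc=pc,
        oc=dc + ic + pc,
        cell_scores=cell_scores,
        param_by_position=param_by_position,
        sd_cells=sd,
        n_trials=len(frame),
        complete=complete,
    )


def score_table(trials, response_sets, include_cells: bool = False) -> pd.DataFrame:
    """Score many participants against one trial list into a tidy table."""
    rows = []
    for rs in response_sets:
        scores = consistency_scores(trials, rs)
        row = {"participant_id": rs.participant_id, "group": rs.group}
        row.update(scores.as_dict(include_cells=include_cells))
        rows.append(row)
    return pd.DataFrame(rows)
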