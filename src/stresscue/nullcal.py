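"""Monte-Carlo calibration of the random-response region.

A participant who ignores the stimuli entirely and guesses uniformly
among the three positions still produces a distribution of OC and
sd-of-cells values; the random-response region is the rectangle in
(OC, sd_cells) space that contains the central ``level`` fraction of
those null OC values and the lower ``level`` fraction of the null sd
values.  Participants inside the box are behaviourally
indistinguishable from guessing.

On a single pass of the 81-trial design, OC lives on the lattice of
multiples of 1/54 (OC = total matches / 54 - 1.5), so quantiles are
taken nearest-rank (inverse empirical CDF) rather than interpolated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import PARAMETERS, POSITIONS, design_hash, validate_trials
from .scoring import ConsistencyScores

_POS_CODE = {p: i for i, p in enumerate(POSITIONS)}


@dataclass(frozen=True)
class NullCalibration:
    """Empirical null distribution summaries for one design shape."""

    n_sims: int
    seed: int
    level: float
    oc_low: float
    oc_high: float
    sd_high: float
    n_trials: int
    design_digest: str
    oc_samples: np.ndarray = field(repr=False)
    sd_samples: np.ndarray = field(repr=False)

    def to_json(self, path) -> None:
        payload = {
            "n_sims": self.n_sims,
            "seed": self.seed,
            "level": self.level,
            "oc_low": self.oc_low,
            "oc_high": self.oc_high,
            "sd_high": self.sd_high,
            "n_trials": self.n_trials,
            "design_digest": self.design_digest,
            "oc_samples": [float(x) for x in self.oc_samples],
            "sd_samples": [float(x) for x in self.sd_samples],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "NullCalibration":
        with open(path) as fh:
            payload = json.load(fh)
        payload["oc_samples"] = np.asarray(payload["oc_samples"], dtype=float)
        payload["sd_samples"] = np.asarray(payload["sd_samples"], dtype=float)
        return cls(**payload)


@dataclass(frozen=True)
class ClassificationResult:
    participant_id: str
    oc: float
    sd_cells: float
    in_random_region: bool
    oc_exceedance_p: float


def _null_samples(frame: pd.DataFrame, n_sims: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized OC and sd_cells samples for uniform-guessing responders."""
    profiles = np.column_stack(
        [frame[cue].map(_POS_CODE).to_numpy() for cue in PARAMETERS]
    )  # (n_trials, 3)
    n_trials = profiles.shape[0]
    responses = rng.integers(0, 3, size=(n_sims, n_trials))
    # matches[s, t, j] = simulated participant s matched cue j on trial t
    matches = responses[:, :, None] == profiles[None, :, :]
    oc = (1.5 * matches.mean(axis=1) - 0.5).sum(axis=1)

    nonwords = sorted(set(frame["nonword"]))
    nw_arr = frame["nonword"].to_numpy()
    cells = []
    for nw in nonwords:
        for pos_code in range(3):
            for j in range(3):
                mask = (nw_arr == nw) & (profiles[:, j] == pos_code)
                cells.append(1.5 * matches[:, mask, j].mean(axis=1) - 0.5)
    cell_scores = np.column_stack(cells)  # (n_sims, 27)
    sd = cell_scores.std(axis=1, ddof=1)
    return oc, sd


def simulate_null(trials, n_sims: int = 10_000, seed: int = 0, level: float = 0.95) -> NullCalibration:
    """Calibrate the random-response region by Monte-Carlo simulation.

    Simulates ``n_sims`` uniform-guessing participants on the given
    complete design, computes each one's OC and sd of the 27 cell
    scores, and takes nearest-rank empirical quantiles: the central
    ``level`` range for OC and the one-sided upper ``level`` bound for
    sd_cells.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    frame = validate_trials(trials)
    rng = np.random.default_rng(seed)
    oc, sd = _null_samples(frame, n_sims, rng)
    alpha = 1.0 - level
    oc_low, oc_high = np.quantile(oc, [alpha / 2, 1 - alpha / 2], method="inverted_cdf")
    sd_high = np.quantile(sd, level, method="inverted_cdf")
    return NullCalibration(
        n_sims=n_sims,
        seed=seed,
        level=level,
        oc_low=float(oc_low),
        oc_high=float(oc_high),
        sd_high=float(sd_high),
        n_trials=len(frame),
        design_digest=design_hash(frame),
        oc_samples=oc,
        sd_samples=sd,
    )


def oc_exceedance_p(null: NullCalibration, oc: float) -> float:
    """One-sided upper Monte-Carlo p-value with the add-one convention."""
    return float((1 + np.sum(null.oc_samples >= oc)) / (null.n_sims + 1))


def classify(null: NullCalibration, scores, participant_id: str = "") -> ClassificationResult:
    """Locate one participant relative to the random-response box.

    ``scores`` may be a ConsistencyScores or any mapping with ``OC`` and
    ``sd_cells`` entries (e.g. a row of a score table).  Box membership
    is boundary-inclusive on both axes.
    """
    if isinstance(scores, ConsistencyScores):
        oc, sd, n_trials = scores.oc, scores.sd_cells, scores.n_trials
    else:
        oc, sd = float(scores["OC"]), float(scores["sd_cells"])
        n_trials = int(scores.get("n_trials", null.n_trials))
        participant_id = participant_id or str(scores.get("participant_id", ""))
    if n_trials != null.n_trials:
        raise ValueError(
            f"design-shape mismatch: scores use {n_trials} trials, "
            f"calibration used {null.n_trials}"
        )
    inside = (null.oc_low <= oc <= null.oc_high) and (sd <= null.sd_high)
    return ClassificationResult(
        participant_id=participant_id,
        oc=oc,
        sd_cells=sd,
        in_random_region=bool(inside),
        oc_exceedance_p=oc_exceedance_p(null, oc),
    )


def classify_table(null: NullCalibration, scores: pd.DataFrame) -> pd.DataFrame:
    """Classify every row of a score table; returns a tidy table."""
    required = {"participant_id", "OC", "sd_cells"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"score table lacks columns {sorted(missing)}")
    rows = []
    for _, row in scores.iterrows():
        res = classify(null, row)
        rows.append(
            {
                "participant_id": res.participant_id,
                "group": row.get("group", ""),
                "OC": res.oc,
                "sd_cells": res.sd_cells,
                "in_random_region": res.in_random_region,
                "oc_exceedance_p": res.oc_exceedance_p,
            }
        )
    return pd.DataFrame(rows)
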