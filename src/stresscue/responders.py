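"""Synthetic responders: generative mixture models over cue-following strategies.

A responder is modelled per trial as an i.i.d. mixture: with probability
``w_duration`` / ``w_intensity`` / ``w_pitch`` the response follows the
corresponding cue's stress profile (optionally routed through a fixed
permutation of the three positions, emulating systematic misperception
such as hearing an AP duration pattern as PE), and with probability
``w_random`` the response is stimulus-independent, drawn from ``bias``
(uniform by default — pure guessing; any other bias models a position
preference).

On a balanced design the expected consistency scores of such a mixture
have a closed form: with the identity mapping the expected consistency
for cue X is exactly ``w_X`` and the expected overall consistency is the
sum of the three cue weights; a derangement mapping (no fixed point)
flips cue X's expectation to ``-0.5 * w_X``.  The stimulus-independent
component contributes nothing, whatever its bias — that cancellation is
the point of the balanced design.

Optionally, ``position_weights`` makes a cue's weight depend on the
stress position its profile indicates on the current trial (e.g. "uses
pitch only when the pitch contour marks the final syllable"), emulating
parameter-by-position interactions.  No closed form is provided for that
case; use simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .design import PARAMETERS, POSITIONS, as_trials_frame
from .exceptions import UnsupportedModelError

IDENTITY_MAPPING: dict[str, str] = {p: p for p in POSITIONS}

#: The cyclic successor permutation AP -> PE -> U -> AP (a derangement).
CYCLIC_MAPPING: dict[str, str] = {"AP": "PE", "PE": "U", "U": "AP"}

_SIMPLEX_TOL = 1e-9


class ExpectedScores(NamedTuple):
    dc: float
    ic: float
    pc: float
    oc: float


@dataclass(frozen=True)
class ResponseSet:
    """One participant's responses over a trial sequence.

    ``responses`` maps trial_index -> chosen position label; it must
    cover the associated trial list exactly (checked at scoring time).
    """

    participant_id: str
    group: str
    responses: pd.Series
    provenance: dict | None = None


@dataclass(frozen=True)
class ResponderModel:
    """Mixture weights, response bias and cue-profile mapping.

    Parameters
    ----------
    w_duration, w_intensity, w_pitch : float
        Probabilities of following each cue's profile on a trial.
    w_random : float, optional
        Probability of the stimulus-independent component.  Defaults to
        the simplex remainder ``1 - (w_duration + w_intensity + w_pitch)``.
    bias : tuple of float
        Distribution over (AP, PE, U) for the stimulus-independent
        component; uniform by default.
    mapping : dict
        Bijection on {AP, PE, U} applied to a followed cue's profile
        before responding; identity by default.
    position_weights : dict, optional
        ``{cue: {position: weight}}`` overrides: on a trial where cue's
        profile indicates `position`, that cue's mixture weight is
        replaced by the override and ``w_random`` absorbs the remainder.
    """

    w_duration: float = 0.0
    w_intensity: float = 0.0
    w_pitch: float = 0.0
    w_random: float | None = None
    bias: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    mapping: dict[str, str] = field(default_factory=lambda: dict(IDENTITY_MAPPING))
    position_weights: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        cue_sum = self.w_duration + self.w_intensity + self.w_pitch
        if self.w_random is None:
            object.__setattr__(self, "w_random", 1.0 - cue_sum)
        w = self.weights
        if any(x < -_SIMPLEX_TOL for x in w):
            raise ValueError(f"mixture weights must be nonnegative, got {w}")
        if abs(sum(w) - 1.0) > 1e-6:
            raise ValueError(f"mixture weights must sum to 1, got {sum(w)}")
        if len(self.bias) != 3 or any(b < 0 for b in self.bias):
            raise ValueError("bias must be 3 nonnegative probabilities")
        if abs(sum(self.bias) - 1.0) > 1e-6:
            raise ValueError(f"bias must sum to 1, got {sum(self.bias)}")
        if sorted(self.mapping) != sorted(POSITIONS) or sorted(
            self.mapping.values()
        ) != sorted(POSITIONS):
            raise ValueError("mapping must be a bijection on {AP, PE, U}")
        if self.position_weights is not None:
            for cue, table in self.position_weights.items():
                if cue not in PARAMETERS:
                    raise ValueError(f"unknown cue in position_weights: {cue!r}")
                for pos, v in table.items():
                    if pos not in POSITIONS:
                        raise ValueError(f"unknown position {pos!r} for cue {cue!r}")
                    if not 0.0 <= v <= 1.0:
                        raise ValueError("position_weights entries must be in [0, 1]")

    @property
    def weights(self) -> tuple[float, float, float, float]:
        return (self.w_duration, self.w_intensity, self.w_pitch, self.w_random)

    def n_fixed_points(self) -> int:
        return sum(self.mapping[p] == p for p in POSITIONS)


def expected_scores(model: ResponderModel) -> ExpectedScores:
    """Closed-form expected (DC, IC, PC, OC) on a complete balanced design.

    Derivation: the raw proportion of responses matching cue X is
    ``p_X = w_X * f/3 + (1 - w_X)/3`` where ``f`` is the number of fixed
    points of the mapping (cross-cue and stimulus-independent components
    each match with probability exactly 1/3 by full crossing).  The
    ``1.5 p - 0.5`` rescaling then gives ``XC = 0.5 * w_X * (f - 1)``:
    ``w_X`` under the identity, ``-0.5 w_X`` under a derangement.
    """
    if model.position_weights is not None:
        raise UnsupportedModelError(
            "expected_scores has no closed form with position_weights; "
            "use simulate_responses and score the result"
        )
    f = model.n_fixed_points()
    dc, ic, pc = (0.5 * w * (f - 1) for w in model.weights[:3])
    return ExpectedScores(dc, ic, pc, dc + ic + pc)


def _trial_weight_matrix(model: ResponderModel, profiles: np.ndarray) -> np.ndarray:
    """Per-trial mixture weights, shape (n_trials, 4); column 3 is w_random."""
    n = profiles.shape[0]
    w = np.tile(np.asarray(model.weights, dtype=float), (n, 1))
    if model.position_weights:
        for j, cue in enumerate(PARAMETERS):
            table = model.position_weights.get(cue)
            if not table:
                continue
            for pos, value in table.items():
                w[profiles[:, j] == pos, j] = value
        w[:, 3] = 1.0 - w[:, :3].sum(axis=1)
        if (w[:, 3] < -_SIMPLEX_TOL).any():
            raise ValueError(
                "position_weights overrides push cue weights above 1 on some trials"
            )
        w[:, 3] = np.clip(w[:, 3], 0.0, 1.0)
    return w


def simulate_responses(
    trials,
    model: ResponderModel,
    seed,
    participant_id: str = "sim",
    group: str = "synthetic",
) -> ResponseSet:
    """Draw one synthetic participant's responses over a trial list.

    Each trial independently samples a mixture component; cue components
    answer ``mapping(profile)``, the stimulus-independent component
    samples from ``bias``.  ``seed`` may be an int or a numpy Generator /
    SeedSequence; the same seed yields an identical response set.
    """
    frame = as_trials_frame(trials)
    rng = np.random.default_rng(seed)
    profiles = frame[list(PARAMETERS)].to_numpy()
    w = _trial_weight_matrix(model, profiles)
    u = rng.random(len(frame))
    component = (u[:, None] < np.cumsum(w, axis=1)).argmax(axis=1)

    responses = np.empty(len(frame), dtype=object)
    for j in range(3):
        mask = component == j
        if mask.any():
            responses[mask] = [model.mapping[p] for p in profiles[mask, j]]
    mask = component == 3
    if mask.any():
        responses[mask] = rng.choice(POSITIONS, size=int(mask.sum()), p=model.bias)

    series = pd.Series(responses, index=frame["trial_index"].to_numpy(), name="response")
    series.index.name = "trial_index"
    return ResponseSet(
        participant_id=participant_id,
        group=group,
        responses=series,
        provenance={"model": model, "seed": seed if np.isscalar(seed) else None},
    )


def simulate_cohort(
    trials,
    model: ResponderModel,
    n_participants: int,
    seed: int,
    group: str = "synthetic",
    id_prefix: str | None = None,
) -> list[ResponseSet]:
    """Simulate a cohort; participant k uses child k of ``SeedSequence(seed)``."""
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    prefix = id_prefix if id_prefix is not None else group
    children = np.random.SeedSequence(seed).spawn(n_participants)
    return [
        simulate_responses(
            trials, model, child, participant_id=f"{prefix}{k:03d}", group=group
        )
        for k, child in enumerate(children, start=1)
    ]
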