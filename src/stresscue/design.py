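"""Fully crossed stimulus design and randomized trial lists.

The task presents trisyllabic non-words whose three acoustic cues —
syllable duration, RMS intensity and pitch contour — each independently
carry the profile of one of three stress positions: antepenultimate
(``AP``, first syllable), penultimate (``PE``, second) or ultimate
(``U``, third).  Crossing the three cue profiles with each other and
with the non-word token yields the complete design; with the canonical
three non-words that is 3 x 3 x 3 x 3 = 81 conditions, of which nine
are *congruent* (all three profiles indicate the same position) and 72
are *dissociated*.

The full crossing is what makes the downstream consistency scores
interpretable: every pair of factors is balanced, so a listener's
response bias toward any particular position cancels exactly out of
every cue-consistency score.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import SchemaError

#: Stress-position labels in canonical order (first/second/third syllable).
POSITIONS: tuple[str, ...] = ("AP", "PE", "U")

#: Syllable stressed under each label (1-based).
SYLLABLE_INDEX: dict[str, int] = {"AP": 1, "PE": 2, "U": 3}

#: Acoustic cue names in canonical order.
PARAMETERS: tuple[str, ...] = ("duration", "intensity", "pitch")

#: One-letter cue abbreviations used in identifiers and CSV columns.
PARAM_SHORT: dict[str, str] = {"duration": "D", "intensity": "I", "pitch": "P"}

#: The non-word tokens of the canonical experiment.
DEFAULT_NONWORDS: tuple[str, ...] = ("dididi", "gugugu", "tatata")

DESIGN_COLUMNS = ["condition_id", "nonword", "duration", "intensity", "pitch"]


def condition_id(nonword: str, duration: str, intensity: str, pitch: str) -> str:
    """Build the canonical identifier, e.g. ``tatata-D:AP-I:U-P:PE``."""
    return f"{nonword}-D:{duration}-I:{intensity}-P:{pitch}"


@dataclass(frozen=True)
class TrialSequence:
    """One randomized presentation order of a complete design.

    Attributes
    ----------
    list_id : str
        Identifier of the pre-randomized list.
    seed : int
        Master seed the permutation was derived from.
    trials : pandas.DataFrame
        Columns ``trial_index`` (1-based, consecutive) plus the design
        columns; the multiset of conditions equals the design.
    """

    list_id: str
    seed: int
    trials: pd.DataFrame

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.trials)


def full_design(nonwords=DEFAULT_NONWORDS) -> pd.DataFrame:
    """Generate the full Cartesian crossing nonword x duration x intensity x pitch.

    Order is deterministic: non-words in the given order, then duration,
    intensity and pitch each in AP < PE < U order.

    Parameters
    ----------
    nonwords : sequence of str
        Non-word tokens; must be non-empty and free of duplicates.

    Returns
    -------
    pandas.DataFrame
        One row per condition with columns ``condition_id, nonword,
        duration, intensity, pitch``.
    """
    nonwords = list(nonwords)
    if not nonwords:
        raise ValueError("nonwords must be non-empty")
    if len(set(nonwords)) != len(nonwords):
        raise ValueError("duplicate non-word tokens")
    rows = [
        {
            "condition_id": condition_id(nw, d, i, p),
            "nonword": nw,
            "duration": d,
            "intensity": i,
            "pitch": p,
        }
        for nw, d, i, p in itertools.product(nonwords, POSITIONS, POSITIONS, POSITIONS)
    ]
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def congruent_subset(design: pd.DataFrame) -> pd.DataFrame:
    """Return the conditions whose three cue profiles all agree.

    These correspond to the unmanipulated base recordings; with k
    non-words there are exactly 3k of them.
    """
    _check_design_frame(design)
    mask = (design["duration"] == design["intensity"]) & (
        design["intensity"] == design["pitch"]
    )
    return design.loc[mask].reset_index(drop=True)


def randomized_lists(
    design: pd.DataFrame, n_lists: int, seed: int
) -> list[TrialSequence]:
    """Produce ``n_lists`` independent random permutations of the design.

    Each list is a complete pass through the design (every condition
    exactly once), shuffled by an unbiased Fisher-Yates permutation from
    a seeded generator; list k uses the k-th child of
    ``numpy.random.SeedSequence(seed)`` so lists are mutually
    independent yet fully reproducible.
    """
    _check_design_frame(design)
    if n_lists < 1:
        raise ValueError(f"n_lists must be >= 1, got {n_lists}")
    children = np.random.SeedSequence(seed).spawn(n_lists)
    out = []
    for k, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        perm = rng.permutation(len(design))
        trials = design.iloc[perm].reset_index(drop=True)
        trials.insert(0, "trial_index", np.arange(1, len(design) + 1))
        out.append(TrialSequence(list_id=f"list{k}", seed=seed, trials=trials))
    return out


def as_trials_frame(trials) -> pd.DataFrame:
    """Coerce a TrialSequence or design/trials DataFrame to a trials frame.

    A plain design frame (no ``trial_index``) is given the canonical
    1..n presentation order — scores are invariant to trial order, so
    any complete frame is an acceptable stand-in for a randomized list.
    """
    if isinstance(trials, TrialSequence):
        frame = trials.trials
    elif isinstance(trials, pd.DataFrame):
        frame = trials
    else:
        raise TypeError(f"expected TrialSequence or DataFrame, got {type(trials)!r}")
    missing = [c for c in DESIGN_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"trials frame lacks columns {missing}")
    if "trial_index" not in frame.columns:
        frame = frame.copy()
        frame.insert(0, "trial_index", np.arange(1, len(frame) + 1))
    return frame


def validate_trials(trials) -> pd.DataFrame:
    """Check that a trial frame is a complete balanced design (k passes).

    Every condition of the full design over the frame's non-words must
    appear the same number of times, trial indices must be consecutive
    from 1, and all profile values must be valid positions.  Returns the
    validated frame.
    """
    frame = as_trials_frame(trials)
    idx = frame["trial_index"].to_numpy()
    if not np.array_equal(np.sort(idx), np.arange(1, len(frame) + 1)):
        raise SchemaError("trial_index must be consecutive integers from 1")
    for col in PARAMETERS:
        bad = set(frame[col]) - set(POSITIONS)
        if bad:
            raise SchemaError(f"invalid {col} profile values: {sorted(bad)}")
    expected = full_design(sorted(set(frame["nonword"])))
    counts = frame["condition_id"].value_counts()
    unknown = set(counts.index) - set(expected["condition_id"])
    if unknown:
        raise SchemaError(f"unknown condition ids: {sorted(unknown)[:3]}...")
    per = counts.reindex(expected["condition_id"]).fillna(0).astype(int)
    if per.nunique() != 1 or per.iloc[0] < 1:
        missing = list(per.index[per == 0])
        if missing:
            raise SchemaError(f"incomplete design; missing conditions e.g. {missing[:3]}")
        raise SchemaError("unbalanced design: conditions appear unequally often")
    return frame


def design_hash(trials) -> str:
    """Short stable digest of the multiset of conditions (order-free)."""
    frame = as_trials_frame(trials)
    payload = ",".join(sorted(frame["condition_id"])).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _check_design_frame(design: pd.DataFrame) -> None:
    if not isinstance(design, pd.DataFrame):
        raise TypeError("design must be a DataFrame")
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise SchemaError(f"design frame lacks columns {missing}")
    if design["condition_id"].duplicated().any():
        raise SchemaError("condition_id values must be unique within a design")
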