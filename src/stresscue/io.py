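"""CSV/JSON/YAML readers and writers, run configuration, and the pipeline.

All artifacts are plain text: comma-separated UTF-8 CSV with a mandatory
header and decimal points, JSON for calibrations and reports, YAML for
configurations and responder-model files.  Response files accept either
position labels (AP/PE/U) or the key codes 1/2/3 used in the experiment
(key 1 = AP, 2 = PE, 3 = U).  All randomness flows from configured
seeds, so rerunning a pipeline with the same configuration reproduces
every artifact bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .design import (
    DEFAULT_NONWORDS,
    DESIGN_COLUMNS,
    TrialSequence,
    as_trials_frame,
    full_design,
    randomized_lists,
)
from .exceptions import IncompleteDataError, SchemaError
from .nullcal import NullCalibration, classify_table, simulate_null
from .report import plot_group_scores, plot_random_region, summarize_groups
from .responders import ResponderModel, ResponseSet, simulate_cohort
from .scoring import score_table

KEY_TO_POSITION = {"1": "AP", "2": "PE", "3": "U", "AP": "AP", "PE": "PE", "U": "U"}

RESPONSE_COLUMNS = [
    "participant_id",
    "group",
    "list_id",
    "trial_index",
    "condition_id",
    "response",
]


# ---------------------------------------------------------------------------
# design / trials

def write_design(design: pd.DataFrame, path) -> None:
    design[DESIGN_COLUMNS].to_csv(path, index=False)


def read_design(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in DESIGN_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"design file lacks columns {missing}")
    return frame[DESIGN_COLUMNS]


def write_trials(lists: list[TrialSequence], path) -> None:
    rows = []
    for seq in lists:
        frame = seq.trials[["trial_index", "condition_id"]].copy()
        frame.insert(0, "list_id", seq.list_id)
        rows.append(frame)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_trials(path, design: pd.DataFrame) -> dict[str, TrialSequence]:
    """Rejoin a trial-list file with its design; returns {list_id: TrialSequence}."""
    frame = pd.read_csv(path, dtype={"list_id": str, "condition_id": str})
    for col in ("list_id", "trial_index", "condition_id"):
        if col not in frame.columns:
            raise SchemaError(f"trials file lacks column {col!r}")
    unknown = set(frame["condition_id"]) - set(design["condition_id"])
    if unknown:
        raise SchemaError(f"unknown condition ids: {sorted(unknown)[:3]}")
    out = {}
    for list_id, sub in frame.groupby("list_id", sort=True):
        merged = sub.merge(design, on="condition_id", how="left", validate="m:1")
        merged = merged.sort_values("trial_index").reset_index(drop=True)
        out[str(list_id)] = TrialSequence(
            list_id=str(list_id),
            seed=-1,  # unknown from file; seed lives in the config
            trials=merged[["trial_index"] + DESIGN_COLUMNS],
        )
    return out


# ---------------------------------------------------------------------------
# responses

def write_responses(response_sets: list[ResponseSet], trials, path, list_id: str = "list1") -> None:
    frame = as_trials_frame(trials)
    cond = frame.set_index("trial_index")["condition_id"]
    rows = []
    for rs in response_sets:
        for trial_index, response in rs.responses.items():
            rows.append(
                {
                    "participant_id": rs.participant_id,
                    "group": rs.group,
                    "list_id": list_id,
                    "trial_index": int(trial_index),
                    "condition_id": cond.get(trial_index, ""),
                    "response": response,
                }
            )
    pd.DataFrame(rows, columns=RESPONSE_COLUMNS).to_csv(path, index=False)


def read_responses(path, trials=None, allow_incomplete: bool = False) -> list[ResponseSet]:
    """Read a trial-level response file into ResponseSet objects.

    ``trials`` (a TrialSequence or trials frame) enables validation of
    condition ids and, unless ``allow_incomplete``, completeness of each
    participant's responses (the error names missing conditions).
    Response values may be AP/PE/U or the key codes 1/2/3.
    """
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in RESPONSE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"responses file lacks columns {missing}")
    frame["trial_index"] = frame["trial_index"].astype(int)

    decoded = []
    for i, raw in enumerate(frame["response"]):
        key = str(raw).strip()
        if key not in KEY_TO_POSITION:
            raise ValueError(f"unparseable response {raw!r} at data row {i + 1}")
        decoded.append(KEY_TO_POSITION[key])
    frame["response"] = decoded

    ref = as_trials_frame(trials) if trials is not None else None
    if ref is not None:
        cond = ref.set_index("trial_index")["condition_id"]
        unknown = set(frame["condition_id"]) - set(cond)
        if unknown:
            raise SchemaError(f"unknown condition ids: {sorted(unknown)[:3]}")

    out = []
    for (pid, group), sub in frame.groupby(["participant_id", "group"], sort=True):
        if sub["trial_index"].duplicated().any():
            dupes = sub.loc[sub["trial_index"].duplicated(), "trial_index"].tolist()
            raise SchemaError(
                f"duplicate responses for participant {pid!r}, trials {dupes[:5]}"
            )
        if ref is not None and not allow_incomplete:
            missing_cond = sorted(
                set(ref["condition_id"]) - set(sub["condition_id"])
            )
            if missing_cond:
                raise IncompleteDataError(
                    f"participant {pid!r} lacks responses for conditions "
                    f"{missing_cond[:3]} ({len(missing_cond)} in total)"
                )
        series = pd.Series(
            sub["response"].to_numpy(),
            index=sub["trial_index"].to_numpy(),
            name="response",
        )
        series.index.name = "trial_index"
        out.append(ResponseSet(participant_id=str(pid), group=str(group), responses=series))
    return out


# ---------------------------------------------------------------------------
# models and configuration

def read_model(path) -> ResponderModel:
    """Load a responder model from a YAML mapping of constructor fields."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return model_from_dict(payload)


def model_from_dict(payload: dict) -> ResponderModel:
    kwargs = dict(payload)
    if "bias" in kwargs:
        kwargs["bias"] = tuple(float(b) for b in kwargs["bias"])
    return ResponderModel(**kwargs)


@dataclass
class CohortSpec:
    group: str
    n: int
    model: ResponderModel


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    seed: int = 0
    n_sims: int = 10_000
    level: float = 0.95
    nonwords: tuple[str, ...] = DEFAULT_NONWORDS
    n_lists: int = 3
    cohorts: list[CohortSpec] = field(default_factory=list)
    out_dir: str = "stresscue_out"
    include_cells: bool = False
    plots: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError(f"level must lie in (0, 1), got {self.level}")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.n_lists < 1:
            raise ValueError("n_lists must be >= 1")
        for cohort in self.cohorts:
            if cohort.n < 1:
                raise ValueError(f"cohort {cohort.group!r} must have n >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        cohorts = [
            CohortSpec(
                group=str(c["group"]),
                n=int(c["n"]),
                model=model_from_dict(c.get("model", {})),
            )
            for c in payload.pop("cohorts", [])
        ]
        if "nonwords" in payload:
            payload["nonwords"] = tuple(payload["nonwords"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(cohorts=cohorts, **payload)


def demo_config(out_dir, seed: int = 0, n_sims: int = 10_000, plots: bool = False) -> RunConfig:
    """Three synthetic cohorts emulating the canonical group profiles.

    Adult-like responders are pitch-dominant, typically-developing-child-
    like responders use the same cues weakly, and the dyslexic-like
    cohort is the uniform-guessing stand-in.  Cue weights equal the
    group mean consistencies they are meant to emulate (expected XC =
    w_X under the identity mapping); group sizes follow the study
    (15 / 18 / 15).
    """
    return RunConfig(
        seed=seed,
        n_sims=n_sims,
        out_dir=str(out_dir),
        plots=plots,
        cohorts=[
            CohortSpec("AC", 15, ResponderModel(w_duration=0.078, w_intensity=0.042, w_pitch=0.614)),
            CohortSpec("TD", 18, ResponderModel(w_duration=0.075, w_intensity=0.023, w_pitch=0.131)),
            CohortSpec("DD", 15, ResponderModel(w_random=1.0)),
        ],
    )


# ---------------------------------------------------------------------------
# pipeline

def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """design -> simulate -> score -> calibrate -> classify -> report.

    Returns the paths of the written artifacts.  Reruns with the same
    configuration are bit-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    design = full_design(config.nonwords)
    lists = randomized_lists(design, config.n_lists, seed=config.seed)
    paths["design"] = out / "design.csv"
    write_design(design, paths["design"])
    paths["trials"] = out / "trials.csv"
    write_trials(lists, paths["trials"])

    # All participants are simulated against list1's frame; the scores
    # are invariant to presentation order, so list assignment is moot here.
    response_sets: list[ResponseSet] = []
    cohort_seed_root = config.seed + 1
    for c_idx, cohort in enumerate(config.cohorts):
        response_sets.extend(
            simulate_cohort(
                lists[0],
                cohort.model,
                cohort.n,
                seed=cohort_seed_root + c_idx,
                group=cohort.group,
            )
        )

    paths["responses"] = out / "responses.csv"
    write_responses(response_sets, lists[0], paths["responses"])

    scores = score_table(lists[0], response_sets, include_cells=config.include_cells)
    paths["scores"] = out / "scores.csv"
    scores.to_csv(paths["scores"], index=False)

    calib = simulate_null(
        lists[0], n_sims=config.n_sims, seed=config.seed + 101, level=config.level
    )
    paths["calibration"] = out / "calibration.json"
    calib.to_json(paths["calibration"])

    classified = classify_table(calib, scores)
    paths["classified"] = out / "classified.csv"
    classified.to_csv(paths["classified"], index=False)

    summary = summarize_groups(scores, classified)
    paths["summary"] = out / "group_summary.csv"
    summary.to_csv(paths["summary"])

    report = {
        "version": __version__,
        "seed": config.seed,
        "n_sims": config.n_sims,
        "level": config.level,
        "oc_low": calib.oc_low,
        "oc_high": calib.oc_high,
        "sd_high": calib.sd_high,
        "groups": {
            str(g): {
                "n": int(summary.loc[g, "n"]),
                "OC_mean": float(summary.loc[g, "OC_mean"]),
                "n_random": int(summary.loc[g, "n_random"]),
                "prop_random": float(summary.loc[g, "prop_random"]),
            }
            for g in summary.index
        },
    }
    paths["report"] = out / "report.json"
    with open(paths["report"], "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    if config.plots:
        paths["fig_scores"] = out / "group_scores.png"
        plot_group_scores(summary, paths["fig_scores"])
        paths["fig_region"] = out / "random_region.png"
        plot_random_region(classified, calib, paths["fig_region"])

    return paths
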