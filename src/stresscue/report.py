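"""Group-level descriptive summaries and figures.

Aggregates participant score tables into per-group means, dispersions,
t-based 95% confidence intervals and random-compatibility proportions,
plus the cue-by-position profile tables; optional figures mirror the
standard presentation (grouped bars with CIs; OC vs cell-SD scatter with
the dashed random-response box).  Inferential group comparisons are
deliberately out of scope — only descriptives and Monte-Carlo
exceedance p-values are exposed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .design import PARAM_SHORT, PARAMETERS, POSITIONS

SCORE_COLS = ("DC", "IC", "PC", "OC")
PBP_COLS = tuple(
    f"{PARAM_SHORT[param]}_{pos}" for param in PARAMETERS for pos in POSITIONS
)


def _ci_half_width(sd: float, n: int, level: float = 0.95) -> float:
    if n < 2 or not np.isfinite(sd):
        return float("nan")
    return float(stats.t.ppf(0.5 + level / 2, n - 1) * sd / np.sqrt(n))


def summarize_groups(
    scores: pd.DataFrame, classified: pd.DataFrame, ci_level: float = 0.95
) -> pd.DataFrame:
    """Per-group descriptive statistics of the consistency scores.

    Every participant in ``scores`` must have a row in ``classified``.
    Single-participant groups get NaN dispersion/CI (flagged, not an
    error).  Group OC mean equals the sum of the group DC/IC/PC means by
    construction.
    """
    if scores.empty:
        raise ValueError("empty score table")
    missing = set(scores["participant_id"]) - set(classified["participant_id"])
    if missing:
        raise ValueError(
            f"participants missing a classification: {sorted(missing)[:5]}"
        )
    flags = classified.set_index("participant_id")["in_random_region"]
    rows = []
    for group, sub in scores.groupby("group", sort=True):
        n = len(sub)
        row: dict = {"group": group, "n": n}
        for col in SCORE_COLS:
            vals = sub[col].to_numpy(dtype=float)
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if n > 1 else float("nan")
            row[f"{col}_mean"] = mean
            row[f"{col}_sd"] = sd
            row[f"{col}_ci"] = _ci_half_width(sd, n, ci_level)
        member = flags.reindex(sub["participant_id"]).astype(bool)
        row["n_random"] = int(member.sum())
        row["prop_random"] = float(member.mean())
        for col in PBP_COLS:
            if col in sub.columns:
                row[f"{col}_mean"] = float(sub[col].mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def position_profile(scores: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-group 3x3 table of cue-by-position mean subscores.

    Returns ``{group: DataFrame}`` with cues as rows (duration,
    intensity, pitch) and positions as columns (AP, PE, U).
    """
    if scores.empty:
        raise ValueError("empty score table")
    missing = [c for c in PBP_COLS if c not in scores.columns]
    if missing:
        raise ValueError(f"score table lacks subscore columns {missing}")
    out = {}
    for group, sub in scores.groupby("group", sort=True):
        mat = np.array(
            [
                [sub[f"{PARAM_SHORT[param]}_{pos}"].mean() for pos in POSITIONS]
                for param in PARAMETERS
            ]
        )
        out[group] = pd.DataFrame(mat, index=list(PARAMETERS), columns=list(POSITIONS))
    return out


def plot_group_scores(summary: pd.DataFrame, path) -> None:
    """Grouped bar chart of mean DC/IC/PC/OC per group with 95% CIs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = summary.index.tolist()
    x = np.arange(len(SCORE_COLS))
    width = 0.8 / max(len(groups), 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    for i, group in enumerate(groups):
        means = [summary.loc[group, f"{c}_mean"] for c in SCORE_COLS]
        cis = [summary.loc[group, f"{c}_ci"] for c in SCORE_COLS]
        ax.bar(x + i * width, means, width, yerr=cis, capsize=3, label=str(group))
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xticks(x + width * (len(groups) - 1) / 2)
    ax.set_xticklabels(SCORE_COLS)
    ax.set_ylabel("Consistency score")
    ax.legend(title="group")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_random_region(classified: pd.DataFrame, calibration, path) -> None:
    """Scatter of OC vs sd_cells with the dashed random-response box."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for group, sub in classified.groupby("group", sort=True):
        ax.scatter(sub["sd_cells"], sub["OC"], label=str(group), alpha=0.8)
    ax.add_patch(
        plt.Rectangle(
            (0.0, calibration.oc_low),
            calibration.sd_high,
            calibration.oc_high - calibration.oc_low,
            fill=False,
            linestyle="--",
            edgecolor="gray",
        )
    )
    ax.set_xlabel("SD across 27 cell scores")
    ax.set_ylabel("Overall Consistency (OC)")
    ax.legend(title="group")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
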