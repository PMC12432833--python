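"""Leave-one-run-out functional channel-of-interest selection.

Selection always happens on data independent of the data used to estimate
responses: within a task via run-level cross-validation, across tasks by
defining on all runs of the localizer and testing on the other task.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .core import SearchSpace, ValidationError

__all__ = [
    "ContrastSpec",
    "Fold",
    "FcoiEstimate",
    "loro_select",
    "cross_task_estimate",
    "selection_histogram",
]


@dataclass(frozen=True)
class ContrastSpec:
    """Defining contrast of one fCOI type."""

    fcoi_type: str  # 'language' | 'md'
    defining_task: str
    positive_condition: str
    negative_condition: str


@dataclass
class Fold:
    held_out_run: int
    selected_channel: int
    training_contrast: float
    responses: pd.DataFrame  # held-out block rows for the selected channel


@dataclass
class FcoiEstimate:
    subject_id: str
    search_space: str
    contrast: ContrastSpec
    folds: list[Fold] = field(default_factory=list)
    skipped_folds: list[tuple[int, str]] = field(default_factory=list)
    cross_task_channel: int | None = None
    cross_task_responses: pd.DataFrame | None = None
    n_valid_runs: int = 0

    @property
    def usable(self) -> bool:
        return bool(self.folds)

    def held_out_rows(self) -> pd.DataFrame:
        if not self.folds:
            return pd.DataFrame()
        return pd.concat([f.responses for f in self.folds], ignore_index=True)


def _condition_means(rows: pd.DataFrame) -> pd.DataFrame:
    """Per (run, channel, condition) mean HbO."""
    return (
        rows.groupby(["run_index", "channel_id", "condition"], as_index=False)["mean_hbo"]
        .mean()
    )


def _training_contrast(
    cond_means: pd.DataFrame,
    training_runs: list[int],
    space: SearchSpace,
    contrast: ContrastSpec,
) -> pd.Series | None:
    """Unweighted mean over training runs of per-run condition means; returns
    the positive − negative contrast per eligible channel (channels present in
    every training run), or None if no channel qualifies."""
    sub = cond_means[cond_means["run_index"].isin(training_runs)]
    sub = sub[sub["channel_id"].isin(space.member_channels)]
    if sub.empty:
        return None
    pivot = sub.pivot_table(
        index="channel_id", columns=["run_index", "condition"], values="mean_hbo"
    )
    # Eligible: defined for both conditions in every training run.
    complete = pivot.dropna(axis=0)
    if complete.empty:
        return None
    per_run = {}
    try:
        for run in training_runs:
            run_block = complete[run]
            per_run[run] = run_block[contrast.positive_condition] - run_block[
                contrast.negative_condition
            ]
    except KeyError:  # a training run lacks one condition entirely
        return None
    return pd.DataFrame(per_run).mean(axis=1)


def _argmax_channel(contrast_by_channel: pd.Series) -> tuple[int, float]:
    """Peak channel; ties broken by lowest channel id (deterministic)."""
    best = contrast_by_channel.max()
    winners = sorted(contrast_by_channel.index[contrast_by_channel == best])
    return int(winners[0]), float(best)


def loro_select(
    table: pd.DataFrame,
    subject_id: str,
    space: SearchSpace,
    contrast: ContrastSpec,
    valid_col: str | None = None,
) -> FcoiEstimate:
    """Leave-one-run-out selection within one search space.

    For each valid run ``r`` of the defining task: average per-channel
    condition means over the remaining valid runs, pick the in-space channel
    maximizing the positive − negative mean HbO contrast, and record that
    channel's block-level rows from run ``r`` only.
    """
    valid_col = valid_col or f"valid_{space.name}"
    rows = table[(table["subject_id"] == subject_id)
                 & (table["task_id"] == contrast.defining_task)]
    if valid_col in rows.columns:
        rows = rows[rows[valid_col]]
    est = FcoiEstimate(subject_id, space.name, contrast)
    runs = sorted(rows["run_index"].unique())
    est.n_valid_runs = len(runs)
    if len(runs) < 2:
        est.skipped_folds.append((-1, "fewer than 2 valid runs"))
        return est
    cond_means = _condition_means(rows)
    for held_out in runs:
        training = [r for r in runs if r != held_out]
        assert held_out not in training
        stat = _training_contrast(cond_means, training, space, contrast)
        if stat is None or stat.empty:
            est.skipped_folds.append((held_out, "no in-space channel kept in all training runs"))
            continue
        channel, value = _argmax_channel(stat)
        held_rows = rows[(rows["run_index"] == held_out) & (rows["channel_id"] == channel)]
        est.folds.append(Fold(int(held_out), channel, value, held_rows.reset_index(drop=True)))
    return est


def cross_task_estimate(
    table: pd.DataFrame,
    subject_id: str,
    space: SearchSpace,
    contrast: ContrastSpec,
    other_task: str,
    valid_col: str | None = None,
) -> FcoiEstimate:
    """Define the fCOI on all valid runs of the localizer task, then extract
    that channel's block responses from every valid run of the other task.

    Defining and testing on the same task without a hold-out is double
    dipping and is refused.
    """
    if other_task == contrast.defining_task:
        raise ValidationError(
            "cross-task estimation on the defining task is double dipping; use loro_select"
        )
    valid_col = valid_col or f"valid_{space.name}"
    defining = table[(table["subject_id"] == subject_id)
                     & (table["task_id"] == contrast.defining_task)]
    testing = table[(table["subject_id"] == subject_id) & (table["task_id"] == other_task)]
    if valid_col in table.columns:
        defining = defining[defining[valid_col]]
        testing = testing[testing[valid_col]]
    est = FcoiEstimate(subject_id, space.name, contrast)
    runs = sorted(defining["run_index"].unique())
    est.n_valid_runs = len(runs)
    if not runs or testing.empty:
        est.skipped_folds.append((-1, "subject not valid in both tasks"))
        return est
    stat = _training_contrast(_condition_means(defining), runs, space, contrast)
    if stat is None or stat.empty:
        est.skipped_folds.append((-1, "no in-space channel kept in all defining runs"))
        return est
    channel, _ = _argmax_channel(stat)
    est.cross_task_channel = channel
    est.cross_task_responses = testing[testing["channel_id"] == channel].reset_index(drop=True)
    return est


def selection_histogram(estimates: list[FcoiEstimate]) -> Counter:
    """Counts of selected channels per fold across subjects (one fCOI type ×
    search space at a time); counts sum to the number of successful folds."""
    if not estimates:
        raise ValidationError("need at least one estimate")
    counts: Counter = Counter()
    for est in estimates:
        for fold in est.folds:
            counts[fold.selected_channel] += 1
    return counts
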