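"""Block-level response extraction and run/participant exclusion rules.

Responses are windowed means of baseline-corrected block segments; exclusion
bookkeeping is carried per search space, since a run can be valid for one
space's analyses but not another's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    ChannelMask,
    ConcentrationSeries,
    EventBlock,
    SearchSpace,
    TaskSpec,
    ValidationError,
)
from .io import BLOCK_TABLE_COLUMNS

__all__ = [
    "baseline_correct_block",
    "block_mean",
    "build_block_table",
    "apply_exclusions",
    "ExclusionReport",
]

logger = logging.getLogger(__name__)


def baseline_correct_block(
    conc: ConcentrationSeries,
    block: EventBlock,
    baseline_s: float = 2.0,
    segment_end_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Block segment minus the per-channel mean over the ``baseline_s`` window
    immediately preceding onset.

    Returns ``(hbo_segment, hbr_segment)`` with time running from block onset,
    or ``None`` (with a warning) if the onset leaves no room for the baseline.
    """
    fs = conc.sampling_rate_hz
    if block.onset_s < baseline_s:
        logger.warning("block at %.1fs dropped: onset precedes the %.1fs baseline window",
                       block.onset_s, baseline_s)
        return None
    onset_i = int(round(block.onset_s * fs))
    base_i = int(round((block.onset_s - baseline_s) * fs))
    end_s = block.end_s if segment_end_s is None else block.onset_s + segment_end_s
    end_i = min(int(round(end_s * fs)), conc.n_time)
    if onset_i >= end_i:
        raise ValidationError("empty block segment")
    base_hbo = conc.hbo[base_i:onset_i].mean(axis=0)
    base_hbr = conc.hbr[base_i:onset_i].mean(axis=0)
    return conc.hbo[onset_i:end_i] - base_hbo, conc.hbr[onset_i:end_i] - base_hbr


def block_mean(
    segment: np.ndarray, fs: float, window: tuple[float, float]
) -> np.ndarray:
    """Arithmetic mean over onset-relative times in the half-open window
    ``[start_s, end_s)``; one value per channel."""
    start_s, end_s = window
    i0 = int(round(start_s * fs))
    i1 = int(round(end_s * fs))
    i1 = min(i1, segment.shape[0])
    if i1 <= i0:
        raise ValidationError(f"analysis window [{start_s}, {end_s}) is empty at fs={fs}")
    return segment[i0:i1].mean(axis=0)


@dataclass
class PreprocessedRun:
    """One preprocessed run ready for block extraction."""

    subject_id: str
    task_id: str
    run_index: int
    conc: ConcentrationSeries
    mask: ChannelMask
    events: list[EventBlock]


def build_block_table(
    runs: list[PreprocessedRun],
    task_specs: dict[str, TaskSpec],
    baseline_s: float = 2.0,
) -> pd.DataFrame:
    """One row per kept channel × block across all runs, deterministic order.

    Columns follow :data:`fcoi_nirs.io.BLOCK_TABLE_COLUMNS`. Pruned channels
    contribute no rows; runs with zero usable blocks are logged and omitted.
    """
    rows = []
    for run in sorted(runs, key=lambda r: (r.subject_id, r.task_id, r.run_index)):
        task = task_specs[run.task_id]
        kept_idx = np.flatnonzero(run.mask.kept)
        kept_ids = [run.conc.channel_ids[i] for i in kept_idx]
        usable = 0
        for bi, block in enumerate(run.events):
            seg = baseline_correct_block(run.conc, block, baseline_s)
            if seg is None:
                continue
            hbo_seg, hbr_seg = seg
            mean_hbo = block_mean(hbo_seg, run.conc.sampling_rate_hz, task.analysis_window)
            mean_hbr = block_mean(hbr_seg, run.conc.sampling_rate_hz, task.analysis_window)
            usable += 1
            for i, cid in zip(kept_idx, kept_ids):
                rows.append(
                    (
                        run.subject_id,
                        run.task_id,
                        run.run_index,
                        cid,
                        bi,
                        block.condition,
                        mean_hbo[i],
                        mean_hbr[i],
                    )
                )
        if usable == 0:
            logger.warning(
                "run %s/%s/%d has no usable blocks; omitted",
                run.subject_id, run.task_id, run.run_index,
            )
    return pd.DataFrame(rows, columns=list(BLOCK_TABLE_COLUMNS))


@dataclass
class ExclusionReport:
    """Outcome of the run/participant exclusion rules, per search space."""

    excluded_runs: pd.DataFrame  # subject_id, task_id, run_index, space, reason
    excluded_subjects: pd.DataFrame  # subject_id, task_id, space, reason
    surviving_counts: pd.DataFrame  # space, task_id, n_subjects, n_runs


def apply_exclusions(
    table: pd.DataFrame,
    masks: dict[tuple[str, str, int], ChannelMask],
    search_spaces: list[SearchSpace],
    channel_ids: tuple[int, ...],
    min_runs: int = 2,
    max_bad_fraction: float = 1.0 / 3.0,
    per_space: bool = True,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the run and participant exclusion rules.

    A run is dropped for a search space when the pruned fraction of the
    space's channels is *strictly greater* than ``max_bad_fraction``; then a
    subject is dropped for a (task, space) when fewer than ``min_runs`` valid
    runs remain. The returned table is the input plus one boolean validity
    column per space (``valid_<space>``); rows invalid for every requested
    space are removed, so row-count conservation is exact.

    With ``per_space=False`` the 1/3 rule is evaluated over all montage
    channels and applied identically to every space.
    """
    id_to_idx = {cid: i for i, cid in enumerate(channel_ids)}
    excluded_runs = []
    run_valid: dict[str, dict[tuple[str, str, int], bool]] = {s.name: {} for s in search_spaces}
    for key, mask in masks.items():
        subject, task, run = key
        for space in search_spaces:
            if per_space:
                member_idx = [id_to_idx[c] for c in sorted(space.member_channels)]
            else:
                member_idx = list(range(len(channel_ids)))
            pruned = sum(0 if mask.kept[i] else 1 for i in member_idx)
            frac = pruned / len(member_idx)
            ok = not (frac > max_bad_fraction)
            run_valid[space.name][key] = ok
            if not ok:
                excluded_runs.append(
                    (subject, task, run, space.name,
                     f"{pruned}/{len(member_idx)} space channels pruned")
                )

    excluded_subjects = []
    subject_valid: dict[str, set[tuple[str, str]]] = {s.name: set() for s in search_spaces}
    for space in search_spaces:
        counts: dict[tuple[str, str], int] = {}
        for (subject, task, run), ok in run_valid[space.name].items():
            if ok:
                counts[(subject, task)] = counts.get((subject, task), 0) + 1
        subjects = {(subj, task) for (subj, task, _run) in run_valid[space.name]}
        for subj, task in sorted(subjects):
            if counts.get((subj, task), 0) < min_runs:
                excluded_subjects.append(
                    (subj, task, space.name, f"fewer than {min_runs} valid runs")
                )
            else:
                subject_valid[space.name].add((subj, task))

    out = table.copy()
    for space in search_spaces:
        valid_col = []
        for subject, task, run in zip(out["subject_id"], out["task_id"], out["run_index"]):
            key = (subject, task, int(run))
            ok = run_valid[space.name].get(key, False)
            ok = ok and (subject, task) in subject_valid[space.name]
            valid_col.append(bool(ok))
        out[f"valid_{space.name}"] = valid_col
    space_cols = [f"valid_{s.name}" for s in search_spaces]
    out = out[out[space_cols].any(axis=1)].reset_index(drop=True)

    surviving = []
    for space in search_spaces:
        col = f"valid_{space.name}"
        for task in sorted(out["task_id"].unique()):
            sel = out[(out["task_id"] == task) & out[col]]
            surviving.append(
                (
                    space.name,
                    task,
                    sel["subject_id"].nunique(),
                    len(sel.groupby(["subject_id", "run_index"])) if len(sel) else 0,
                )
            )
    report = ExclusionReport(
        excluded_runs=pd.DataFrame(
            excluded_runs, columns=["subject_id", "task_id", "run_index", "space", "reason"]
        ),
        excluded_subjects=pd.DataFrame(
            excluded_subjects, columns=["subject_id", "task_id", "space", "reason"]
        ),
        surviving_counts=pd.DataFrame(
            surviving, columns=["space", "task_id", "n_subjects", "n_runs"]
        ),
    )
    return out, report
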