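"""End-to-end cohort analysis: preprocess runs, build the block table, apply
exclusions, select fCOIs, and fit the condition models for every analysis
cell. Shared by the CLI and by recovery tests."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .blocks import ExclusionReport, PreprocessedRun, apply_exclusions, build_block_table
from .core import ChannelMask, PreprocessConfig, ValidationError
from .fcoi import ContrastSpec, FcoiEstimate, cross_task_estimate, loro_select
from .preprocess import preprocess_run
from .simulate import Cohort
from .stats import ModelFit, dissociation_report, fit_condition_model

__all__ = ["CohortAnalysis", "preprocess_cohort", "analyze_cohort", "CONTRASTS"]

CONTRASTS = {
    "language": ContrastSpec("language", "language", "intact", "degraded"),
    "md": ContrastSpec("md", "md", "hard", "easy"),
}


@dataclass
class CohortAnalysis:
    block_table: pd.DataFrame
    exclusions: ExclusionReport
    estimates: dict[tuple[str, str], list[FcoiEstimate]]  # (space, fcoi_type) -> per subject
    cross_estimates: dict[tuple[str, str], list[FcoiEstimate]]
    fits: dict[tuple[str, str, str], ModelFit]  # (space, fcoi_type, tested task)
    dissociation_table: pd.DataFrame = field(default=None)
    dissociation_flag: bool | None = None


def preprocess_cohort(
    cohort: Cohort, config: PreprocessConfig | None = None
) -> tuple[list[PreprocessedRun], dict[tuple[str, str, int], ChannelMask]]:
    runs: list[PreprocessedRun] = []
    masks: dict[tuple[str, str, int], ChannelMask] = {}
    for rec in cohort.recordings:
        conc, mask, _prov = preprocess_run(rec, config)
        runs.append(
            PreprocessedRun(rec.subject_id, rec.task_id, rec.run_index, conc, mask, rec.events)
        )
        masks[(rec.subject_id, rec.task_id, rec.run_index)] = mask
    return runs, masks


def analyze_cohort(
    cohort: Cohort,
    config: PreprocessConfig | None = None,
    min_runs: int = 2,
    max_bad_fraction: float = 1.0 / 3.0,
) -> CohortAnalysis:
    runs, masks = preprocess_cohort(cohort, config)
    table = build_block_table(runs, cohort.task_specs)
    if table.empty:
        raise ValidationError("cohort produced an empty block table")
    table, report = apply_exclusions(
        table, masks, cohort.search_spaces, cohort.montage.channel_ids,
        min_runs=min_runs, max_bad_fraction=max_bad_fraction,
    )
    subjects = sorted(table["subject_id"].unique())

    estimates: dict[tuple[str, str], list[FcoiEstimate]] = {}
    cross_estimates: dict[tuple[str, str], list[FcoiEstimate]] = {}
    fits: dict[tuple[str, str, str], ModelFit] = {}
    for space in cohort.search_spaces:
        for fcoi_type, contrast in CONTRASTS.items():
            other_task = "md" if contrast.defining_task == "language" else "language"
            within = [loro_select(table, s, space, contrast) for s in subjects]
            cross = [
                cross_task_estimate(table, s, space, contrast, other_task) for s in subjects
            ]
            estimates[(space.name, fcoi_type)] = within
            cross_estimates[(space.name, fcoi_type)] = cross

            within_rows = [e.held_out_rows() for e in within if e.usable]
            if within_rows:
                rows = pd.concat(within_rows, ignore_index=True)
                try:
                    fits[(space.name, fcoi_type, contrast.defining_task)] = fit_condition_model(
                        rows, contrast.positive_condition, contrast.negative_condition
                    )
                except ValidationError:
                    pass
            other = CONTRASTS[other_task]
            cross_rows = [
                e.cross_task_responses
                for e in cross
                if e.cross_task_responses is not None and len(e.cross_task_responses)
            ]
            if cross_rows:
                rows = pd.concat(cross_rows, ignore_index=True)
                try:
                    fits[(space.name, fcoi_type, other_task)] = fit_condition_model(
                        rows, other.positive_condition, other.negative_condition
                    )
                except ValidationError:
                    pass

    analysis = CohortAnalysis(table, report, estimates, cross_estimates, fits)
    analysis.dissociation_table, analysis.dissociation_flag = dissociation_report(fits)
    return analysis
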