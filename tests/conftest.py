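import numpy as np
import pandas as pd
import pytest

from fcoi_nirs.core import (
    ExtinctionTable,
    Montage,
    PreprocessConfig,
)
from fcoi_nirs.simulate import (
    adult_like_scenario,
    make_sim_montage,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def adult_montage() -> Montage:
    return make_sim_montage("adult", 11)


@pytest.fixture(scope="session")
def toddler_montage() -> Montage:
    return make_sim_montage("toddler", 6)


@pytest.fixture(scope="session")
def adult_extinction(adult_montage) -> ExtinctionTable:
    return ExtinctionTable.for_wavelengths(adult_montage.wavelengths_nm)


@pytest.fixture()
def config() -> PreprocessConfig:
    return PreprocessConfig()


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small but complete cohort exercising both tasks (3 subjects)."""
    scenario = adult_like_scenario(
        n_subjects=3, n_language_runs=3, n_md_runs=2, n_extra_channels=8
    )
    return simulate_cohort(scenario, seed=7)


def make_block_table(
    rng: np.random.Generator,
    n_subjects: int = 6,
    n_runs: int = 4,
    channels=(1, 2, 3),
    task_id: str = "language",
    conditions=("intact", "degraded"),
    blocks_per_condition: int = 2,
    effects: dict | None = None,
    subject_sd: float = 0.2,
    noise_sd: float = 0.3,
) -> pd.DataFrame:
    """Directly simulated block-response table (no signal pipeline): one row
    per subject x run x channel x block, with channel-specific condition
    effects on the preferred (first) condition."""
    effects = effects or {}
    rows = []
    for s in range(n_subjects):
        subject = f"sub{s + 1:02d}"
        intercept = rng.normal(0.0, subject_sd)
        for run in range(1, n_runs + 1):
            bi = 0
            for cond in conditions:
                for _ in range(blocks_per_condition):
                    for ch in channels:
                        eff = effects.get(ch, 0.0) if cond == conditions[0] else 0.0
                        val = eff + intercept + rng.normal(0.0, noise_sd)
                        rows.append((subject, task_id, run, ch, bi, cond, val, -val / 3))
                    bi += 1
    return pd.DataFrame(
        rows,
        columns=["subject_id", "task_id", "run_index", "channel_id", "block_index",
                 "condition", "mean_hbo", "mean_hbr"],
    )
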