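"""Synthetic fNIRS cohort generator with known ground truth.

Generates block-design ΔHbO/ΔHbR responses with channel-specific condition
selectivity, systemic physiological oscillations, slow drifts, white noise,
a shared global component with spatially smooth channel weights, and motion
spikes/step shifts, rendered to raw intensities through the forward
Beer–Lambert model. Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    ADULT_LANGUAGE,
    ADULT_MD,
    TODDLER_GONOGO,
    TODDLER_LANGUAGE,
    ChannelMask,
    ConcentrationSeries,
    EventBlock,
    ExtinctionTable,
    Montage,
    REASON_OK,
    RunRecording,
    SearchSpace,
    TaskSpec,
    ValidationError,
)
from .io import adult_search_spaces, toddler_search_spaces

__all__ = [
    "DesignSpec",
    "SimTruth",
    "Scenario",
    "Cohort",
    "make_design",
    "hrf",
    "simulate_conc",
    "add_noise_and_artifacts",
    "conc_to_intensity",
    "simulate_cohort",
    "make_sim_montage",
    "adult_like_scenario",
    "toddler_like_scenario",
    "null_scenario",
]

MOLAR_PER_UM = 1e-6


# ---------------------------------------------------------------------------
# Simulated montages
# ---------------------------------------------------------------------------

# Printed MNI coordinates (mm) of the inferior-frontal channels of the two
# device layouts; the remaining simulated channels are placed on a scalp
# sphere to provide whole-head context for the spatial filter.
ADULT_IFG_CHANNELS: dict[int, tuple[float, float, float]] = {
    5: (64.9643, 5.7288, 27.8566),
    13: (61.2752, 22.4516, 12.4687),
    14: (57.049, 37.9202, -2.4401),
    17: (53.2021, 33.3479, 29.3424),
    19: (49.1243, 47.253, 15.4105),
    20: (36.6861, 51.5968, 29.9235),
    68: (-38.2423, 52.8662, 27.4047),
    69: (-43.5347, 37.7257, 38.1227),
    70: (-50.5051, 46.6936, 10.4438),
    71: (-54.2983, 33.6329, 22.7694),
    72: (-56.3003, 37.7076, -7.1488),
    73: (-59.7137, 21.7772, 5.0031),
    75: (-66.014, 6.3358, 19.328),
}

TODDLER_IFG_CHANNELS: dict[int, tuple[float, float, float]] = {
    17: (77.67, 19.00, 17.33),
    18: (69.67, 20.33, 44.67),
    25: (69.33, 42.67, 13.33),
    26: (60.33, 42.67, 40.33),
    27: (59.67, 60.33, 5.67),
    56: (46.00, 42.33, 59.67),
    57: (33.00, 36.00, 73.00),
    59: (33.67, 62.67, 50.67),
    64: (-57.67, -46.33, 79.33),
    66: (-70.33, 18.33, 39.00),
}

ADULT_WAVELENGTHS = (760.0, 850.0)
TODDLER_WAVELENGTHS = (730.0, 808.0, 850.0)
SAMPLING_RATE_HZ = 11.0


def _scalp_points(n: int, radius: float) -> np.ndarray:
    """Deterministic spread of points over the upper 2/3 of a head sphere."""
    pts = []
    golden = math.pi * (3.0 - math.sqrt(5.0))
    i = 0
    while len(pts) < n:
        # Fibonacci lattice restricted to z >= -0.3 R (no points under the chin)
        z = 1.0 - 2.0 * (i + 0.5) / (2 * n + 8)
        if z >= -0.3:
            r = math.sqrt(max(0.0, 1.0 - z * z))
            theta = golden * i
            pts.append((radius * r * math.cos(theta), radius * r * math.sin(theta), radius * z))
        i += 1
    return np.asarray(pts)


def make_sim_montage(group: str = "adult", n_extra: int = 11) -> Montage:
    """Simulation montage: the printed IFG channels plus scalp filler channels.

    Channel ids of the IFG channels match the published search-space labels;
    filler ids are drawn from the remaining device channel numbers.
    """
    if group == "adult":
        ifg = ADULT_IFG_CHANNELS
        wavelengths = ADULT_WAVELENGTHS
        max_id = 79
    elif group == "toddler":
        ifg = TODDLER_IFG_CHANNELS
        wavelengths = TODDLER_WAVELENGTHS
        max_id = 81
    else:
        raise ValueError(f"unknown montage group {group!r}")
    ids = sorted(ifg)
    positions = [np.asarray(ifg[i], dtype=float) for i in ids]
    filler_ids = [i for i in range(1, max_id + 1) if i not in ifg][:n_extra]
    radius = float(np.mean([np.linalg.norm(p) for p in positions]))
    for p in _scalp_points(n_extra, radius):
        positions.append(p)
    ids = ids + filler_ids

    src, det, channels = [], [], []
    half = Montage.SEPARATION_NOMINAL_MM / 2.0
    for k, pos in enumerate(positions):
        u = pos / max(np.linalg.norm(pos), 1e-9)
        ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        tang = np.cross(u, ref)
        tang /= np.linalg.norm(tang)
        src.append(pos + half * tang)
        det.append(pos - half * tang)
        channels.append((k, k))
    return Montage(
        wavelengths_nm=wavelengths,
        source_positions=np.asarray(src),
        detector_positions=np.asarray(det),
        channels=tuple(channels),
        sampling_rate_hz=SAMPLING_RATE_HZ,
        channel_ids=tuple(ids),
    )


# ---------------------------------------------------------------------------
# Block designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Deterministic block/fixation layout of one run of a task."""

    task: TaskSpec
    n_runs: int
    blocks_per_run: tuple[tuple[str, int], ...]  # (condition, count)
    lead_in_s: float
    lead_out_s: float
    pre_block_gap_s: float = 0.0  # e.g. instruction screen, not analyzed

    def __post_init__(self):
        for cond, count in self.blocks_per_run:
            if cond not in self.task.condition_labels:
                raise ValidationError(f"design condition {cond!r} not in task")
            if count < 1:
                raise ValidationError("block counts must be >= 1")

    @property
    def n_blocks(self) -> int:
        return sum(c for _, c in self.blocks_per_run)

    @property
    def run_duration_s(self) -> float:
        n = self.n_blocks
        t = self.task
        return (
            self.lead_in_s
            + n * (self.pre_block_gap_s + t.block_duration_s)
            + (n - 1) * t.fixation_duration_s
            + self.lead_out_s
        )


ADULT_LANGUAGE_DESIGN = DesignSpec(ADULT_LANGUAGE, 8, (("intact", 3), ("degraded", 1)), 10.0, 10.0)
ADULT_MD_DESIGN = DesignSpec(ADULT_MD, 4, (("easy", 1), ("hard", 1)), 10.0, 10.0)
TODDLER_LANGUAGE_DESIGN = DesignSpec(TODDLER_LANGUAGE, 4, (("intact", 1), ("degraded", 1)), 6.0, 6.0)
TODDLER_GONOGO_DESIGN = DesignSpec(
    TODDLER_GONOGO, 4, (("easy", 1), ("hard", 1)), 10.0, 10.0, pre_block_gap_s=3.0
)


def make_design(spec: DesignSpec, subject_index: int, run_index: int) -> list[EventBlock]:
    """Event schedule for one run, counterbalanced across subjects and runs.

    The condition sequence is the design's block list rotated by
    ``(subject_index + run_index) mod n_blocks`` — a deterministic
    counterbalance that alternates two-block designs by parity and cycles
    the minority-condition position in longer designs.
    """
    conditions: list[str] = []
    for cond, count in spec.blocks_per_run:
        conditions.extend([cond] * count)
    rot = (int(subject_index) + int(run_index)) % len(conditions)
    conditions = conditions[rot:] + conditions[:rot]

    t = spec.task
    events = []
    onset = spec.lead_in_s
    for i, cond in enumerate(conditions):
        if i > 0:
            onset += t.fixation_duration_s
        onset += spec.pre_block_gap_s
        events.append(EventBlock(cond, onset, t.block_duration_s))
        onset += t.block_duration_s
    if events[-1].end_s + spec.lead_out_s > spec.run_duration_s + 1e-9:
        raise ValidationError("blocks exceed the run duration")
    return events


# ---------------------------------------------------------------------------
# Hemodynamics
# ---------------------------------------------------------------------------

def hrf(
    t,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma impulse response with unit peak amplitude.

    Gamma shapes are chosen so the positive lobe's mode sits at ``peak_s``
    and the undershoot's at ``undershoot_s``; h(0) = 0.
    """
    t = np.asarray(t, dtype=float)

    def gamma_density(x, shape):
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = np.exp(
            (shape - 1) * np.log(x[pos]) - x[pos] - math.lgamma(shape)
        )
        return out

    a1 = peak_s + 1.0
    a2 = undershoot_s + 1.0
    grid = np.arange(0.0, undershoot_s * 3, 0.05)
    raw_grid = gamma_density(grid, a1) - undershoot_ratio * gamma_density(grid, a2)
    peak = raw_grid.max()
    raw = gamma_density(np.atleast_1d(t), a1) - undershoot_ratio * gamma_density(
        np.atleast_1d(t), a2
    )
    out = raw / peak
    return out if np.ndim(t) else float(out[0])


def _hrf_kernel(fs: float, length_s: float = 40.0) -> np.ndarray:
    """HRF sampled at fs, normalized to unit area so that a long boxcar
    convolved with it plateaus at the boxcar's amplitude."""
    t = np.arange(0.0, length_s, 1.0 / fs)
    k = hrf(t)
    return k / np.sum(k)


def block_regressor(events, condition: str, n_time: int, fs: float) -> np.ndarray:
    """Boxcar-convolved-with-HRF regressor for one condition, plateau 1."""
    box = np.zeros(n_time)
    for ev in events:
        if ev.condition != condition:
            continue
        i0 = int(round(ev.onset_s * fs))
        i1 = min(int(round(ev.end_s * fs)), n_time)
        box[i0:i1] = 1.0
    kernel = _hrf_kernel(fs)
    return np.convolve(box, kernel)[:n_time]


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Per-channel effect sizes and noise parameters of one simulated subject."""

    channel_ids: tuple[int, ...]
    language_effect_um: np.ndarray  # ΔHbO amplitude for intact − degraded
    md_effect_um: np.ndarray  # hard − easy
    base_response_um: float = 0.1
    white_sd_um: float = 0.35
    drift_sd_um: float = 0.1
    cardiac_freq_hz: float = 1.2
    cardiac_amp_um: float = 0.05
    respiration_freq_hz: float = 0.25
    respiration_amp_um: float = 0.05
    mayer_freq_hz: float = 0.1
    mayer_amp_um: float = 0.05
    global_amp_um: float = 0.15
    spike_rate_per_min: float = 0.5
    spike_amp_od: float = 0.05
    shift_rate_per_min: float = 0.2
    shift_amp_od: float = 0.02
    hbr_ratio: float = -1.0 / 3.0
    baseline_intensity: float = 1e5
    seed: int = 0

    def __post_init__(self):
        self.language_effect_um = np.asarray(self.language_effect_um, dtype=float)
        self.md_effect_um = np.asarray(self.md_effect_um, dtype=float)
        n = len(self.channel_ids)
        if self.language_effect_um.shape != (n,) or self.md_effect_um.shape != (n,):
            raise ValidationError("effect arrays must be one value per channel")
        if self.hbr_ratio >= 0:
            raise ValidationError("hbr_ratio must be negative")
        for name in (
            "base_response_um", "white_sd_um", "drift_sd_um", "cardiac_amp_um",
            "respiration_amp_um", "mayer_amp_um", "global_amp_um",
            "spike_rate_per_min", "spike_amp_od", "shift_rate_per_min", "shift_amp_od",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def effect_for_task(self, task_id: str) -> np.ndarray:
        if task_id == "language":
            return self.language_effect_um
        if task_id == "md":
            return self.md_effect_um
        raise ValidationError(f"unknown task_id {task_id!r}")


def simulate_conc(
    truth: SimTruth, events, task: TaskSpec, n_time: int, fs: float
) -> ConcentrationSeries:
    """Noise-free signal part: per channel, ΔHbO is the sum over blocks of the
    condition amplitude times a boxcar∗HRF regressor; ΔHbR = hbr_ratio·ΔHbO."""
    for ev in events:
        if ev.end_s > n_time / fs + 1e-9:
            raise ValidationError("event outside the run span")
    n_ch = len(truth.channel_ids)
    hbo = np.zeros((n_time, n_ch))
    effect = truth.effect_for_task(task.task_id)
    for cond in task.condition_labels:
        reg = block_regressor(events, cond, n_time, fs)
        amp_um = np.full(n_ch, truth.base_response_um)
        if cond == task.preferred_condition:
            amp_um = amp_um + effect
        hbo += np.outer(reg, amp_um * MOLAR_PER_UM)
    hbr = truth.hbr_ratio * hbo
    mask = ChannelMask(np.ones(n_ch, dtype=bool), [REASON_OK] * n_ch)
    return ConcentrationSeries(hbo, hbr, mask, fs, truth.channel_ids)


# ---------------------------------------------------------------------------
# Noise, artifacts, forward model
# ---------------------------------------------------------------------------

def _smooth_weights(positions: np.ndarray, rng: np.random.Generator,
                    corr_deg: float = 120.0, sd: float = 0.25) -> np.ndarray:
    """Spatially smooth positive channel weights for the global component:
    a Gaussian random field over angular distance with a correlation length
    much larger than the spatial filter's sigma."""
    centered = positions - positions.mean(axis=0)
    unit = centered / np.linalg.norm(centered, axis=1, keepdims=True)
    ang = np.arccos(np.clip(unit @ unit.T, -1.0, 1.0))
    k = np.exp(-0.5 * (np.degrees(ang) / corr_deg) ** 2)
    k /= k.sum(axis=1, keepdims=True)
    z = rng.standard_normal(len(positions))
    w = 1.0 + sd * (k @ z) / np.std(k @ z) if np.std(k @ z) > 0 else np.ones(len(positions))
    return np.clip(w, 0.2, None)


def add_noise_and_artifacts(
    conc: ConcentrationSeries,
    truth: SimTruth,
    positions: np.ndarray,
    rng: np.random.Generator,
) -> tuple[ConcentrationSeries, list[dict]]:
    """Contaminate a clean series and return it with an artifact manifest.

    Adds (in µM, converted to molar): white noise, a random cubic drift,
    cardiac/respiratory/Mayer sinusoids with per-channel phase, and a shared
    in-band global oscillation with spatially smooth weights. Motion events
    are *scheduled* here (listed in the manifest) but applied in the OD
    domain by :func:`conc_to_intensity`, where TDDR operates.
    """
    n_time, n_ch = conc.hbo.shape
    fs = conc.sampling_rate_hz
    t = conc.times
    tn = t / t[-1] if n_time > 1 else t

    noise = rng.standard_normal((n_time, n_ch)) * truth.white_sd_um
    # slow drift: random cubic polynomial, sd-scaled
    coef = rng.standard_normal((3, n_ch)) * truth.drift_sd_um
    noise += coef[0] * tn[:, None] + coef[1] * tn[:, None] ** 2 + coef[2] * tn[:, None] ** 3
    for f_hz, amp in (
        (truth.cardiac_freq_hz, truth.cardiac_amp_um),
        (truth.respiration_freq_hz, truth.respiration_amp_um),
        (truth.mayer_freq_hz, truth.mayer_amp_um),
    ):
        if amp > 0:
            phase = rng.uniform(0, 2 * np.pi, n_ch)
            noise += amp * np.sin(2 * np.pi * f_hz * t[:, None] + phase)
    if truth.global_amp_um > 0:
        ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
        g = truth.global_amp_um * (
            np.sin(2 * np.pi * 0.03 * t + ph1) + 0.6 * np.sin(2 * np.pi * 0.06 * t + ph2)
        )
        weights = _smooth_weights(positions, rng)
        noise += np.outer(g, weights)

    hbo = conc.hbo + noise * MOLAR_PER_UM
    hbr = conc.hbr + truth.hbr_ratio * noise * MOLAR_PER_UM \
        + rng.standard_normal((n_time, n_ch)) * truth.white_sd_um * abs(truth.hbr_ratio) * MOLAR_PER_UM

    duration_min = n_time / fs / 60.0
    manifest: list[dict] = []
    for kind, rate, amp in (
        ("spike", truth.spike_rate_per_min, truth.spike_amp_od),
        ("shift", truth.shift_rate_per_min, truth.shift_amp_od),
    ):
        if rate <= 0 or amp <= 0:
            continue
        count = rng.poisson(rate * duration_min)
        for time_s in np.sort(rng.uniform(2.0, n_time / fs - 2.0, count)):
            manifest.append(
                {
                    "kind": kind,
                    "time_s": float(time_s),
                    "amp_od": float(amp * rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])),
                }
            )
    out = ConcentrationSeries(hbo, hbr, conc.mask, fs, conc.channel_ids)
    return out, manifest


def motion_od(manifest, n_time: int, fs: float, n_ch: int) -> np.ndarray:
    """Render scheduled motion events as an additive OD time course [t, c]."""
    t = np.arange(n_time) / fs
    od = np.zeros((n_time, n_ch))
    for ev in manifest:
        if ev["kind"] == "spike":
            wave = ev["amp_od"] * np.exp(-np.abs(t - ev["time_s"]) / 0.25)
        elif ev["kind"] == "shift":
            wave = ev["amp_od"] * (t >= ev["time_s"]).astype(float)
        else:
            raise ValidationError(f"unknown motion kind {ev['kind']!r}")
        od += wave[:, None]
    return od


def conc_to_intensity(
    conc: ConcentrationSeries,
    montage: Montage,
    extinction: ExtinctionTable,
    baseline_intensity: float | np.ndarray,
    manifest=(),
    ppf: float = 1.0,
    subject_id: str = "sim",
    task_id: str = "language",
    run_index: int = 1,
    events=(),
) -> RunRecording:
    """Forward modified Beer–Lambert model: concentrations → raw intensities.

    ΔOD(λ,t,c) = [ε_hbo(λ)·ΔHbO + ε_hbr(λ)·ΔHbR]·d_cm(c)·ppf(λ) + motion OD;
    intensity = baseline · exp(−ΔOD).
    """
    extinction.for_montage(montage)
    baseline = np.broadcast_to(
        np.asarray(baseline_intensity, dtype=float),
        (montage.n_channels, montage.n_wavelengths),
    )
    if np.any(baseline <= 0):
        raise ValidationError("baseline intensity must be strictly positive")
    e = extinction.matrix()  # (n_wl, 2)
    d_cm = montage.separation_mm / 10.0
    # od[t, c, w]
    od = (
        conc.hbo[:, :, None] * e[None, None, :, 0]
        + conc.hbr[:, :, None] * e[None, None, :, 1]
    ) * d_cm[None, :, None] * ppf
    if manifest:
        od = od + motion_od(manifest, conc.n_time, conc.sampling_rate_hz, montage.n_channels)[
            :, :, None
        ]
    intensity = baseline[None, :, :] * np.exp(-od)
    return RunRecording(subject_id, task_id, run_index, intensity, list(events), montage)


# ---------------------------------------------------------------------------
# Scenarios and cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """Complete description of a simulated cohort."""

    name: str
    group: str  # 'adult' | 'toddler'
    n_subjects: int
    language_design: DesignSpec
    md_design: DesignSpec
    true_channels: tuple[tuple[str, str, int], ...]  # (space, fcoi_type, channel id)
    language_effect_um: float = 0.5
    md_effect_um: float = 0.5
    n_extra_channels: int = 11
    truth_overrides: tuple[tuple[str, float], ...] = ()

    def montage(self) -> Montage:
        return make_sim_montage(self.group, self.n_extra_channels)

    def search_spaces(self, montage: Montage) -> list[SearchSpace]:
        loader = adult_search_spaces if self.group == "adult" else toddler_search_spaces
        return loader(montage)

    def build_truth(self, montage: Montage, seed: int) -> SimTruth:
        ids = montage.channel_ids
        lang = np.zeros(len(ids))
        md = np.zeros(len(ids))
        for _space, fcoi_type, ch in self.true_channels:
            idx = montage.index_of(ch)
            if fcoi_type == "language":
                lang[idx] = self.language_effect_um
            elif fcoi_type == "md":
                md[idx] = self.md_effect_um
            else:
                raise ValidationError(f"unknown fCOI type {fcoi_type!r}")
        truth = SimTruth(ids, lang, md, seed=seed, **dict(self.truth_overrides))
        return truth


# True channels are placed at well-separated in-space positions so the
# spatial filter's focal crosstalk stays small relative to block noise.
ADULT_TRUE_CHANNELS = (
    ("LIFG", "language", 70),
    ("LIFG", "md", 75),
    ("RIFG", "language", 17),
    ("RIFG", "md", 5),
)
TODDLER_TRUE_CHANNELS = (
    ("LIFG", "language", 57),
    ("LIFG", "md", 64),
    ("RIFG", "language", 25),
    ("RIFG", "md", 18),
)


def _design(base: DesignSpec, n_runs: int | None) -> DesignSpec:
    if n_runs is None or n_runs == base.n_runs:
        return base
    return DesignSpec(
        base.task, n_runs, base.blocks_per_run, base.lead_in_s, base.lead_out_s,
        base.pre_block_gap_s,
    )


def adult_like_scenario(
    n_subjects: int = 20,
    n_language_runs: int | None = None,
    n_md_runs: int | None = None,
    effect_um: float = 0.5,
    n_extra_channels: int = 46,
    **overrides: float,
) -> Scenario:
    """Default adult-like scenario: bilateral language and MD selectivity."""
    return Scenario(
        name="adult_like",
        group="adult",
        n_subjects=n_subjects,
        language_design=_design(ADULT_LANGUAGE_DESIGN, n_language_runs),
        md_design=_design(ADULT_MD_DESIGN, n_md_runs),
        true_channels=ADULT_TRUE_CHANNELS,
        language_effect_um=effect_um,
        md_effect_um=effect_um,
        n_extra_channels=n_extra_channels,
        truth_overrides=tuple(overrides.items()),
    )


def toddler_like_scenario(
    n_subjects: int = 22,
    n_language_runs: int | None = None,
    n_md_runs: int | None = None,
    effect_um: float = 0.5,
    n_extra_channels: int = 30,
    **overrides: float,
) -> Scenario:
    """Toddler-like scenario: RIFG language and LIFG MD effects are zero, so
    only LIFG is language-selective and only RIFG is demand-selective."""
    true_channels = tuple(
        (space, kind, ch)
        for space, kind, ch in TODDLER_TRUE_CHANNELS
        if not ((space == "RIFG" and kind == "language") or (space == "LIFG" and kind == "md"))
    )
    return Scenario(
        name="toddler_like",
        group="toddler",
        n_subjects=n_subjects,
        language_design=_design(TODDLER_LANGUAGE_DESIGN, n_language_runs),
        md_design=_design(TODDLER_GONOGO_DESIGN, n_md_runs),
        true_channels=true_channels,
        language_effect_um=effect_um,
        md_effect_um=effect_um,
        n_extra_channels=n_extra_channels,
        truth_overrides=tuple(overrides.items()),
    )


def null_scenario(n_subjects: int = 20, group: str = "adult", n_extra_channels: int = 11,
                  n_language_runs: int | None = None, n_md_runs: int | None = None,
                  **overrides: float) -> Scenario:
    """Zero effects everywhere: selection operates on pure noise."""
    base = adult_like_scenario(
        n_subjects, n_language_runs, n_md_runs, 0.0, n_extra_channels, **overrides
    ) if group == "adult" else toddler_like_scenario(
        n_subjects, n_language_runs, n_md_runs, 0.0, n_extra_channels, **overrides
    )
    return Scenario(
        name="null",
        group=base.group,
        n_subjects=base.n_subjects,
        language_design=base.language_design,
        md_design=base.md_design,
        true_channels=base.true_channels,
        language_effect_um=0.0,
        md_effect_um=0.0,
        n_extra_channels=base.n_extra_channels,
        truth_overrides=base.truth_overrides,
    )


@dataclass
class Cohort:
    """A simulated cohort: recordings plus everything needed to analyze them."""

    scenario: Scenario
    seed: int
    montage: Montage
    search_spaces: list[SearchSpace]
    recordings: list[RunRecording]
    truths: dict[str, SimTruth]  # per subject
    manifest: dict  # JSON-serializable ground-truth manifest

    @property
    def task_specs(self) -> dict[str, TaskSpec]:
        return {
            "language": self.scenario.language_design.task,
            "md": self.scenario.md_design.task,
        }

    def true_channel(self, space: str, fcoi_type: str) -> int | None:
        for s, k, ch in self.scenario.true_channels:
            if s == space and k == fcoi_type:
                return ch
        return None


def _simulate_run(
    scenario: Scenario,
    montage: Montage,
    extinction: ExtinctionTable,
    truth: SimTruth,
    design: DesignSpec,
    subject_index: int,
    run_index: int,
    seed_key,
) -> tuple[RunRecording, list[dict]]:
    fs = montage.sampling_rate_hz
    events = make_design(design, subject_index, run_index)
    n_time = int(round(design.run_duration_s * fs))
    clean = simulate_conc(truth, events, design.task, n_time, fs)
    rng = np.random.default_rng(seed_key)
    noisy, manifest = add_noise_and_artifacts(clean, truth, montage.channel_positions, rng)
    rec = conc_to_intensity(
        noisy,
        montage,
        extinction,
        truth.baseline_intensity,
        manifest,
        subject_id=f"sub{subject_index + 1:02d}",
        task_id=design.task.task_id,
        run_index=run_index,
        events=events,
    )
    return rec, manifest


def simulate_cohort(scenario: Scenario, seed: int) -> Cohort:
    """Generate a full cohort, reproducibly from the seed."""
    montage = scenario.montage()
    extinction = ExtinctionTable.for_wavelengths(montage.wavelengths_nm)
    spaces = scenario.search_spaces(montage)
    recordings: list[RunRecording] = []
    truths: dict[str, SimTruth] = {}
    motion: dict[str, dict] = {}
    for si in range(scenario.n_subjects):
        subject_id = f"sub{si + 1:02d}"
        truth = scenario.build_truth(montage, seed)
        truths[subject_id] = truth
        motion[subject_id] = {}
        for task_code, design in ((0, scenario.language_design), (1, scenario.md_design)):
            for run in range(1, design.n_runs + 1):
                rec, manifest = _simulate_run(
                    scenario, montage, extinction, truth, design, si, run,
                    seed_key=[seed, si, task_code, run],
                )
                recordings.append(rec)
                motion[subject_id][f"{design.task.task_id}_run{run}"] = manifest
    manifest = {
        "scenario": scenario.name,
        "group": scenario.group,
        "seed": int(seed),
        "n_subjects": scenario.n_subjects,
        "true_channels": [list(tc) for tc in scenario.true_channels],
        "language_effect_um": scenario.language_effect_um,
        "md_effect_um": scenario.md_effect_um,
        "motion": motion,
    }
    return Cohort(scenario, seed, montage, spaces, recordings, truths, manifest)
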