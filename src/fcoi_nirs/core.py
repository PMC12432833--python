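"""Domain types for continuous-wave fNIRS recordings and their analysis.

Conventions used throughout the package:

* arrays are indexed ``[time, channel]`` or ``[time, channel, wavelength]``;
* channel order is the row order of the montage definition and is invariant
  across every array in the pipeline;
* channels carry integer ids (labels) that search spaces refer to — ids are
  decoupled from array positions;
* ``t = 0`` is the first sample of a run and event onsets are in seconds
  relative to run start.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Montage",
    "ExtinctionTable",
    "SearchSpace",
    "EventBlock",
    "TaskSpec",
    "RunRecording",
    "ChannelMask",
    "PreprocessConfig",
    "ConcentrationSeries",
    "ValidationError",
    "ADULT_LANGUAGE",
    "ADULT_MD",
    "TODDLER_LANGUAGE",
    "TODDLER_GONOGO",
    "TASK_SPECS",
    "EXTINCTION_COEFFICIENTS",
]


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


def _as_array(x, shape_hint: str, dtype=float) -> np.ndarray:
    arr = np.asarray(x, dtype=dtype)
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValidationError(f"{shape_hint} contains non-finite values")
    return arr


@dataclass(frozen=True)
class Montage:
    """Optode geometry and acquisition parameters for one probe layout.

    Parameters
    ----------
    wavelengths_nm
        Two or three distinct LED wavelengths in 600–1000 nm.
    source_positions, detector_positions
        ``(n, 3)`` coordinates in mm.
    channels
        Ordered ``(source_index, detector_index)`` pairs (0-based into the
        position arrays). Row order defines channel order everywhere.
    channel_ids
        Integer label per channel; defaults to ``1..n_channels``.
    sampling_rate_hz
        Uniform sampling rate.
    """

    wavelengths_nm: tuple[float, ...]
    source_positions: np.ndarray
    detector_positions: np.ndarray
    channels: tuple[tuple[int, int], ...]
    sampling_rate_hz: float
    channel_ids: tuple[int, ...] = ()

    SEPARATION_NOMINAL_MM = 30.0
    SEPARATION_TOL_MM = 5.0

    def __post_init__(self):
        object.__setattr__(self, "wavelengths_nm", tuple(float(w) for w in self.wavelengths_nm))
        object.__setattr__(self, "source_positions", _as_array(self.source_positions, "source_positions"))
        object.__setattr__(self, "detector_positions", _as_array(self.detector_positions, "detector_positions"))
        object.__setattr__(self, "channels", tuple((int(s), int(d)) for s, d in self.channels))
        if not self.channel_ids:
            object.__setattr__(self, "channel_ids", tuple(range(1, len(self.channels) + 1)))
        else:
            object.__setattr__(self, "channel_ids", tuple(int(c) for c in self.channel_ids))
        self._validate()

    def _validate(self):
        wl = self.wavelengths_nm
        if not 2 <= len(wl) <= 3:
            raise ValidationError(f"expected 2 or 3 wavelengths, got {len(wl)}")
        if len(set(wl)) != len(wl):
            raise ValidationError("wavelengths must be distinct")
        if any(not (600.0 <= w <= 1000.0) for w in wl):
            raise ValidationError("wavelengths must lie within 600–1000 nm")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        ns, nd = len(self.source_positions), len(self.detector_positions)
        for s, d in self.channels:
            if not (0 <= s < ns and 0 <= d < nd):
                raise ValidationError(f"channel ({s}, {d}) references a missing optode")
        if len(self.channel_ids) != len(self.channels):
            raise ValidationError("channel_ids length must match channels")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValidationError("channel_ids must be unique")
        sep = self.separation_mm
        lo = self.SEPARATION_NOMINAL_MM - self.SEPARATION_TOL_MM
        hi = self.SEPARATION_NOMINAL_MM + self.SEPARATION_TOL_MM
        if np.any((sep < lo) | (sep > hi)):
            bad = np.flatnonzero((sep < lo) | (sep > hi))
            raise ValidationError(
                f"source–detector separations outside {lo}–{hi} mm for channel rows {bad.tolist()}"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_wavelengths(self) -> int:
        return len(self.wavelengths_nm)

    @property
    def channel_positions(self) -> np.ndarray:
        """Midpoint of each source–detector pair, ``(n_channels, 3)`` mm."""
        src = self.source_positions[[s for s, _ in self.channels]]
        det = self.detector_positions[[d for _, d in self.channels]]
        return 0.5 * (src + det)

    @property
    def separation_mm(self) -> np.ndarray:
        src = self.source_positions[[s for s, _ in self.channels]]
        det = self.detector_positions[[d for _, d in self.channels]]
        return np.linalg.norm(src - det, axis=1)

    def index_of(self, channel_id: int) -> int:
        """Array position for a channel id."""
        try:
            return self.channel_ids.index(int(channel_id))
        except ValueError:
            raise KeyError(f"channel id {channel_id} not in montage") from None


# Molar extinction coefficients (1/(M*cm)) for oxy-/deoxyhemoglobin at the
# wavelengths used by the supported devices, from compiled in-vitro spectra.
# These are implementation constants: every analysis is contrast-based and
# the forward/inverse round trip validates them independently of their
# absolute accuracy.
EXTINCTION_COEFFICIENTS: dict[float, tuple[float, float]] = {
    730.0: (390.0, 1102.2),
    760.0: (586.0, 1548.5),
    808.0: (856.0, 717.1),
    850.0: (1058.0, 691.3),
}


@dataclass(frozen=True)
class ExtinctionTable:
    """Per-wavelength molar extinction coefficients for HbO and HbR."""

    wavelengths_nm: tuple[float, ...]
    epsilon_hbo: tuple[float, ...]
    epsilon_hbr: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "wavelengths_nm", tuple(float(w) for w in self.wavelengths_nm))
        object.__setattr__(self, "epsilon_hbo", tuple(float(e) for e in self.epsilon_hbo))
        object.__setattr__(self, "epsilon_hbr", tuple(float(e) for e in self.epsilon_hbr))
        n = len(self.wavelengths_nm)
        if len(self.epsilon_hbo) != n or len(self.epsilon_hbr) != n:
            raise ValidationError("extinction table lengths inconsistent")
        if any(e <= 0 for e in self.epsilon_hbo + self.epsilon_hbr):
            raise ValidationError("extinction coefficients must be positive")
        if n >= 2 and not np.isfinite(np.linalg.cond(self.matrix())):
            raise ValidationError("extinction system is singular")

    @classmethod
    def for_wavelengths(cls, wavelengths_nm: Sequence[float]) -> "ExtinctionTable":
        hbo, hbr = [], []
        for w in wavelengths_nm:
            try:
                eo, er = EXTINCTION_COEFFICIENTS[float(w)]
            except KeyError:
                raise ValidationError(f"no packaged extinction coefficients at {w} nm") from None
            hbo.append(eo)
            hbr.append(er)
        return cls(tuple(float(w) for w in wavelengths_nm), tuple(hbo), tuple(hbr))

    def matrix(self) -> np.ndarray:
        """``(n_wavelengths, 2)`` matrix with columns (eps_hbo, eps_hbr)."""
        return np.column_stack([self.epsilon_hbo, self.epsilon_hbr])

    def for_montage(self, montage: Montage) -> "ExtinctionTable":
        if self.wavelengths_nm != montage.wavelengths_nm:
            raise ValidationError(
                f"extinction wavelengths {self.wavelengths_nm} do not match montage "
                f"{montage.wavelengths_nm}"
            )
        return self


@dataclass(frozen=True)
class SearchSpace:
    """Named set of channel ids plausibly overlying one anatomical region."""

    name: str
    member_channels: frozenset[int]

    def __post_init__(self):
        object.__setattr__(self, "member_channels", frozenset(int(c) for c in self.member_channels))
        if not self.member_channels:
            raise ValidationError(f"search space {self.name!r} is empty")

    def validate_against(self, montage: Montage) -> "SearchSpace":
        unknown = self.member_channels - set(montage.channel_ids)
        if unknown:
            raise ValidationError(
                f"search space {self.name!r} references channels absent from the montage: "
                f"{sorted(unknown)}"
            )
        return self


@dataclass(frozen=True)
class EventBlock:
    condition: str
    onset_s: float
    duration_s: float

    def __post_init__(self):
        if self.onset_s < 0:
            raise ValidationError("onset_s must be >= 0")
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be > 0")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


def validate_events(events: Sequence[EventBlock]) -> None:
    """Blocks within a run must be non-overlapping with increasing onsets."""
    for prev, cur in zip(events, events[1:]):
        if cur.onset_s <= prev.onset_s:
            raise ValidationError("event onsets must be strictly increasing")
        if cur.onset_s < prev.end_s:
            raise ValidationError(
                f"events overlap: {prev.condition}@{prev.onset_s} and {cur.condition}@{cur.onset_s}"
            )


@dataclass(frozen=True)
class TaskSpec:
    """Block-design task description including its analysis window."""

    task_id: str
    condition_labels: tuple[str, str]
    preferred_condition: str
    block_duration_s: float
    fixation_duration_s: float
    analysis_window: tuple[float, float]  # seconds post block onset
    runs_expected: int

    def __post_init__(self):
        if self.preferred_condition not in self.condition_labels:
            raise ValidationError("preferred_condition must be one of condition_labels")
        start, end = self.analysis_window
        if not (0 <= start < end):
            raise ValidationError("analysis window must satisfy 0 <= start < end")
        if end > self.block_duration_s + 1e-9:
            raise ValidationError("analysis window extends beyond the block")

    @property
    def nonpreferred_condition(self) -> str:
        a, b = self.condition_labels
        return b if self.preferred_condition == a else a


# Analysis windows all begin 5 s post onset to absorb hemodynamic lag; the
# end matches the block length of each task variant.
ADULT_LANGUAGE = TaskSpec("language", ("intact", "degraded"), "intact", 20.0, 10.0, (5.0, 20.0), 8)
ADULT_MD = TaskSpec("md", ("hard", "easy"), "hard", 34.0, 10.0, (5.0, 33.0), 4)
TODDLER_LANGUAGE = TaskSpec("language", ("intact", "degraded"), "intact", 17.0, 6.0, (5.0, 17.0), 4)
TODDLER_GONOGO = TaskSpec("md", ("hard", "easy"), "hard", 12.0, 10.0, (5.0, 12.0), 4)

TASK_SPECS: dict[str, TaskSpec] = {
    "adult_language": ADULT_LANGUAGE,
    "adult_md": ADULT_MD,
    "toddler_language": TODDLER_LANGUAGE,
    "toddler_gonogo": TODDLER_GONOGO,
}


@dataclass
class RunRecording:
    """Raw intensities for one subject/task/run plus its event schedule."""

    subject_id: str
    task_id: str
    run_index: int
    intensity: np.ndarray  # [n_time, n_channels, n_wavelengths], positive
    events: list[EventBlock]
    montage: Montage

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.run_index < 1:
            raise ValidationError("run_index must be >= 1")
        if self.intensity.ndim != 3:
            raise ValidationError("intensity must be [time, channel, wavelength]")
        nt, nc, nw = self.intensity.shape
        if nc != self.montage.n_channels or nw != self.montage.n_wavelengths:
            raise ValidationError(
                f"intensity shape {self.intensity.shape} inconsistent with montage "
                f"({self.montage.n_channels} channels x {self.montage.n_wavelengths} wavelengths)"
            )
        validate_events(self.events)
        dur = self.duration_s
        for ev in self.events:
            if ev.end_s > dur + 1e-9:
                raise ValidationError(
                    f"event {ev.condition}@{ev.onset_s}s ends after the recording ({dur:.2f}s)"
                )

    @property
    def n_time(self) -> int:
        return self.intensity.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_time / self.montage.sampling_rate_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_time) / self.montage.sampling_rate_hz


REASON_OK = "ok"
REASON_OUT_OF_RANGE = "out_of_range"
REASON_LOW_SNR = "low_snr"
REASON_MANUAL = "no_cardiac_manual"
PRUNE_REASONS = (REASON_OK, REASON_OUT_OF_RANGE, REASON_LOW_SNR, REASON_MANUAL)


@dataclass
class ChannelMask:
    """Per-channel keep/drop decision for one run."""

    kept: np.ndarray  # bool [n_channels]
    reason: list[str]

    def __post_init__(self):
        self.kept = np.asarray(self.kept, dtype=bool)
        if len(self.reason) != self.kept.size:
            raise ValidationError("reason list length must match mask")
        for k, r in zip(self.kept, self.reason):
            if r not in PRUNE_REASONS:
                raise ValidationError(f"unknown prune reason {r!r}")
            if k != (r == REASON_OK):
                raise ValidationError("reason must be 'ok' iff channel kept")

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    @property
    def any_kept(self) -> bool:
        return bool(self.kept.any())


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the per-run preprocessing chain.

    Step toggles exist so tests can exercise the exact forward/inverse
    round trip with the distorting stages disabled.
    """

    d_range: tuple[float, float] = (1e3, 1e7)
    snr_thresh: float = 5.0
    low_cut_hz: float = 0.01
    high_cut_hz: float = 0.09
    lowpass_order: int = 3
    highpass_order: int = 5
    tddr_tukey_c: float = 4.685
    tddr_split_freq_hz: float = 0.5
    tddr_max_iter: int = 50
    tddr_tol: float = 1e-8
    pca_sigma_deg: float = 46.0
    ppf: float = 1.0
    baseline_window_s: float = 2.0
    manual_exclude_ids: tuple[int, ...] = ()
    enable_detrend: bool = True
    enable_tddr: bool = True
    enable_bandpass: bool = True
    enable_pca: bool = True

    def __post_init__(self):
        lo, hi = self.d_range
        if not lo < hi:
            raise ValidationError("d_range must be increasing")
        if not 0 < self.low_cut_hz < self.high_cut_hz:
            raise ValidationError("require 0 < low_cut_hz < high_cut_hz")
        if self.pca_sigma_deg <= 0:
            raise ValidationError("pca_sigma_deg must be positive")
        if self.ppf <= 0:
            raise ValidationError("ppf must be positive")

    def with_filters_disabled(self) -> "PreprocessConfig":
        return replace(
            self,
            enable_detrend=False,
            enable_tddr=False,
            enable_bandpass=False,
            enable_pca=False,
        )


@dataclass
class ConcentrationSeries:
    """Cleaned ΔHbO/ΔHbR time courses, molar units, plus channel validity."""

    hbo: np.ndarray  # [n_time, n_channels]
    hbr: np.ndarray
    mask: ChannelMask
    sampling_rate_hz: float
    channel_ids: tuple[int, ...]

    def __post_init__(self):
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise ValidationError("hbo and hbr must share a shape")
        if self.hbo.ndim != 2:
            raise ValidationError("concentration arrays must be [time, channel]")
        if self.hbo.shape[1] != self.mask.kept.size:
            raise ValidationError("mask length inconsistent with channel axis")
        kept = self.mask.kept
        if kept.any() and not (
            np.all(np.isfinite(self.hbo[:, kept])) and np.all(np.isfinite(self.hbr[:, kept]))
        ):
            raise ValidationError("non-finite concentration on a kept channel")
        # Pruned channels are flagged missing, never silently zero.
        self.hbo[:, ~kept] = np.nan
        self.hbr[:, ~kept] = np.nan
        self.channel_ids = tuple(int(c) for c in self.channel_ids)

    @property
    def n_time(self) -> int:
        return self.hbo.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_time) / self.sampling_rate_hz
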