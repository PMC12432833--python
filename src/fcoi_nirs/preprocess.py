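"""Per-run preprocessing: raw intensity → cleaned ΔHbO/ΔHbR.

Ordered chain: channel pruning → negative-intensity guard → optical density
→ linear detrend → TDDR motion correction → zero-phase Butterworth band-pass
→ Beer–Lambert inversion → PCA-based spatial filtering of global signal.
Each run is processed in isolation; no cross-run normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import (
    ChannelMask,
    ConcentrationSeries,
    ExtinctionTable,
    Montage,
    PreprocessConfig,
    REASON_LOW_SNR,
    REASON_MANUAL,
    REASON_OK,
    REASON_OUT_OF_RANGE,
    RunRecording,
    ValidationError,
)

__all__ = [
    "ODSeries",
    "prune_channels",
    "intensity_to_od",
    "detrend_linear",
    "correct_motion_tddr",
    "bandpass_filter",
    "od_to_concentration",
    "remove_global_pca",
    "preprocess_run",
    "bandpass_gain",
]

logger = logging.getLogger(__name__)


@dataclass
class ODSeries:
    """Optical density changes, ``[n_time, n_channels, n_wavelengths]``."""

    od: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self):
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim != 3:
            raise ValidationError("od must be [time, channel, wavelength]")

    @property
    def n_time(self) -> int:
        return self.od.shape[0]


# ---------------------------------------------------------------------------
# Pruning and intensity handling
# ---------------------------------------------------------------------------

def prune_channels(rec: RunRecording, config: PreprocessConfig) -> ChannelMask:
    """Keep a channel iff, at every wavelength, the mean raw intensity lies in
    ``d_range`` and mean/SD >= ``snr_thresh``. Constant channels (SD = 0) have
    unbounded SNR and are kept. A manual exclusion list (channels lacking a
    clear cardiac signal on inspection) is honored last."""
    mean = rec.intensity.mean(axis=0)  # (c, w)
    sd = rec.intensity.std(axis=0, ddof=0)
    lo, hi = config.d_range
    in_range = np.all((mean >= lo) & (mean <= hi), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(sd > 0, mean / sd, np.inf)
    snr_ok = np.all(snr >= config.snr_thresh, axis=1)
    kept = in_range & snr_ok
    reasons = []
    manual = set(config.manual_exclude_ids)
    for i, cid in enumerate(rec.montage.channel_ids):
        if not in_range[i]:
            reasons.append(REASON_OUT_OF_RANGE)
        elif not snr_ok[i]:
            reasons.append(REASON_LOW_SNR)
        elif cid in manual:
            reasons.append(REASON_MANUAL)
            kept[i] = False
        else:
            reasons.append(REASON_OK)
    mask = ChannelMask(kept, reasons)
    if not mask.any_kept:
        logger.warning(
            "all channels pruned for %s %s run %s; run unusable",
            rec.subject_id, rec.task_id, rec.run_index,
        )
    return mask


def guard_negative_intensity(rec: RunRecording, mask: ChannelMask) -> tuple[np.ndarray, int]:
    """Replace non-positive samples on kept channels by the channel's smallest
    positive observed value; returns (intensity, number of repaired samples)."""
    intensity = rec.intensity.copy()
    repaired = 0
    bad = intensity <= 0
    bad[:, ~mask.kept, :] = False
    if bad.any():
        for c in np.flatnonzero(mask.kept):
            for w in range(intensity.shape[2]):
                col = intensity[:, c, w]
                idx = col <= 0
                if idx.any():
                    pos = col[col > 0]
                    if pos.size == 0:
                        raise ValidationError(
                            f"channel row {c} wavelength {w} has no positive samples"
                        )
                    col[idx] = pos.min()
                    repaired += int(idx.sum())
    return intensity, repaired


def intensity_to_od(rec: RunRecording, mask: ChannelMask,
                    intensity: np.ndarray | None = None) -> ODSeries:
    """ΔOD(t) = −ln(I(t) / mean_t I(t)) per channel × wavelength."""
    x = rec.intensity if intensity is None else intensity
    od = np.zeros_like(x, dtype=float)
    kept = mask.kept
    sub = x[:, kept, :]
    if np.any(sub <= 0):
        t, c, w = [int(v[0]) for v in np.nonzero(sub <= 0)]
        row = np.flatnonzero(kept)[c]
        raise ValidationError(
            f"non-positive intensity at sample {t}, channel row {row}, wavelength {w}"
        )
    od[:, kept, :] = -np.log(sub / sub.mean(axis=0, keepdims=True))
    od[:, ~kept, :] = np.nan
    return ODSeries(od, rec.montage.sampling_rate_hz)


# ---------------------------------------------------------------------------
# Detrend, TDDR, band-pass (per channel × wavelength)
# ---------------------------------------------------------------------------

def _apply_flat(od: ODSeries, func) -> ODSeries:
    nt, nc, nw = od.od.shape
    flat = od.od.reshape(nt, nc * nw)
    valid = ~np.isnan(flat).any(axis=0)
    out = flat.copy()
    if valid.any():
        out[:, valid] = func(flat[:, valid])
    return ODSeries(out.reshape(nt, nc, nw), od.sampling_rate_hz)


def detrend_linear(od: ODSeries) -> ODSeries:
    """Subtract the least-squares line over the full run, per trace."""
    if od.n_time < 3:
        raise ValidationError("need at least 3 samples to detrend")

    def fit(x):
        t = np.arange(x.shape[0], dtype=float)
        design = np.column_stack([np.ones_like(t), t])
        coef, *_ = np.linalg.lstsq(design, x, rcond=None)
        return x - design @ coef

    return _apply_flat(od, fit)


def _tddr_weights(deriv: np.ndarray, tukey_c: float, max_iter: int, tol: float) -> np.ndarray:
    """Iteratively reweighted robust location of derivative traces (Tukey
    biweight), vectorized over columns; returns final observation weights."""
    w = np.ones_like(deriv)
    for _ in range(max_iter):
        mu = np.sum(w * deriv, axis=0) / np.sum(w, axis=0)
        dev = deriv - mu
        sigma = 1.4826 * np.median(np.abs(dev), axis=0)
        degenerate = sigma == 0
        sigma = np.where(degenerate, 1.0, sigma)
        r = dev / (tukey_c * sigma)
        w_new = np.where(np.abs(r) < 1, (1 - r**2) ** 2, 0.0)
        # a zero robust scale means no motion structure: leave trace untouched
        w_new[:, degenerate] = 1.0
        if np.max(np.abs(w_new - w)) < tol:
            return w_new
        w = w_new
    logger.warning("TDDR did not converge within %d iterations", max_iter)
    return w


def _tddr_1d_weights(deriv: np.ndarray, tukey_c: float, max_iter: int, tol: float) -> np.ndarray:
    return _tddr_weights(deriv[:, None], tukey_c, max_iter, tol)[:, 0]


def correct_motion_tddr(od: ODSeries, fs: float | None = None,
                        config: PreprocessConfig | None = None) -> ODSeries:
    """Temporal derivative distribution repair.

    Per trace: split at ``split_freq_hz``; robustly reweight the low-frequency
    part's first differences (Tukey biweight) and rebuild it by cumulative
    summation of the weighted, centered derivative; add the high-frequency
    part back. Nonlinear by design; spikes and step shifts are suppressed
    while smooth structure passes through.
    """
    config = config or PreprocessConfig()
    fs = fs or od.sampling_rate_hz
    if fs <= 2 * config.tddr_split_freq_hz:
        raise ValidationError("sampling rate must exceed twice the TDDR split frequency")
    sos = signal.butter(3, config.tddr_split_freq_hz, btype="low", fs=fs, output="sos")

    def fix(x):
        low = signal.sosfiltfilt(sos, x, axis=0)
        high = x - low
        deriv = np.diff(low, axis=0)
        w = _tddr_weights(deriv, config.tddr_tukey_c, config.tddr_max_iter, config.tddr_tol)
        mu = np.sum(w * deriv, axis=0) / np.sum(w, axis=0)
        corrected = np.vstack([np.zeros(x.shape[1]), np.cumsum(w * (deriv - mu), axis=0)])
        out = corrected - corrected.mean(axis=0) + low.mean(axis=0)
        return out + high

    return _apply_flat(od, fix)


def _bandpass_sos(config: PreprocessConfig, fs: float):
    if config.high_cut_hz >= fs / 2:
        raise ValidationError("high_cut_hz must be below Nyquist")
    low = signal.butter(config.lowpass_order, config.high_cut_hz, btype="low", fs=fs,
                        output="sos")
    high = signal.butter(config.highpass_order, config.low_cut_hz, btype="high", fs=fs,
                         output="sos")
    return low, high


def bandpass_filter(od: ODSeries, config: PreprocessConfig | None = None,
                    fs: float | None = None) -> ODSeries:
    """Zero-phase cascade of a Butterworth low-pass (order 3 at the high cut)
    and high-pass (order 5 at the low cut), applied forward–backward."""
    config = config or PreprocessConfig()
    fs = fs or od.sampling_rate_hz
    low, high = _bandpass_sos(config, fs)

    def fix(x):
        return signal.sosfiltfilt(high, signal.sosfiltfilt(low, x, axis=0), axis=0)

    return _apply_flat(od, fix)


def bandpass_gain(freq_hz: float, config: PreprocessConfig, fs: float) -> float:
    """Analytic amplitude gain of the zero-phase band-pass at one frequency
    (the forward–backward pass squares each filter's magnitude response)."""
    low, high = _bandpass_sos(config, fs)
    w = 2 * np.pi * freq_hz / fs
    _, h_low = signal.sosfreqz(low, worN=[w])
    _, h_high = signal.sosfreqz(high, worN=[w])
    return float(np.abs(h_low[0]) ** 2 * np.abs(h_high[0]) ** 2)


# ---------------------------------------------------------------------------
# Beer–Lambert inversion and spatial filtering
# ---------------------------------------------------------------------------

def od_to_concentration(
    od: ODSeries,
    montage: Montage,
    extinction: ExtinctionTable,
    config: PreprocessConfig,
    mask: ChannelMask,
) -> ConcentrationSeries:
    """Solve ΔOD(λ) = [ε_hbo(λ)·ΔHbO + ε_hbr(λ)·ΔHbR]·d_cm·ppf for each
    channel: exact inverse for two wavelengths, least squares for three."""
    extinction.for_montage(montage)
    e = extinction.matrix()  # (n_wl, 2)
    if np.linalg.cond(e) > 1e8:
        raise ValidationError("extinction system is ill-conditioned")
    pinv = np.linalg.pinv(e)  # (2, n_wl)
    d_cm = montage.separation_mm / 10.0
    nt, nc, nw = od.od.shape
    scaled = od.od / (d_cm[None, :, None] * config.ppf)
    conc = np.einsum("kw,tcw->tck", pinv, scaled)  # (t, c, 2)
    hbo = np.where(mask.kept[None, :], conc[:, :, 0], np.nan)
    hbr = np.where(mask.kept[None, :], conc[:, :, 1], np.nan)
    return ConcentrationSeries(hbo, hbr, mask, od.sampling_rate_hz, montage.channel_ids)


def _smoothing_matrix(positions: np.ndarray, sigma_deg: float) -> np.ndarray:
    """Row-normalized Gaussian kernel in pairwise angular distance on the
    head-centered unit sphere."""
    centered = positions - positions.mean(axis=0)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = centered / norms
    ang_deg = np.degrees(np.arccos(np.clip(unit @ unit.T, -1.0, 1.0)))
    k = np.exp(-0.5 * (ang_deg / sigma_deg) ** 2)
    return k / k.sum(axis=1, keepdims=True)


def remove_global_pca(
    conc: ConcentrationSeries,
    channel_positions: np.ndarray,
    sigma_deg: float = 46.0,
) -> ConcentrationSeries:
    """PCA-based spatial filter for global systemic components.

    Per chromophore: PCA across kept channels, Gaussian smoothing of each
    spatial loading vector in angular distance (σ in degrees), reconstruction
    of the spatially smooth (global) signal from the smoothed loadings, and
    subtraction. Spatially sharp (focal) structure is preserved. Fewer than
    three kept channels: pass-through with a warning.
    """
    kept = conc.mask.kept
    if kept.sum() < 3:
        logger.warning("fewer than 3 kept channels; skipping PCA spatial filter")
        return conc
    k = _smoothing_matrix(channel_positions[kept], sigma_deg)

    def clean(x):
        sub = x[:, kept]
        # X = U S Vt; global = U S (K V)t = X Kt. Keeping all components lets
        # the smoothing kernel decide what is global.
        u, s, vt = np.linalg.svd(sub, full_matrices=False)
        smoothed_vt = (k @ vt.T).T
        global_part = (u * s) @ smoothed_vt
        out = x.copy()
        out[:, kept] = sub - global_part
        return out

    return ConcentrationSeries(
        clean(conc.hbo), clean(conc.hbr), conc.mask, conc.sampling_rate_hz, conc.channel_ids
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def preprocess_run(
    rec: RunRecording,
    config: PreprocessConfig | None = None,
    extinction: ExtinctionTable | None = None,
) -> tuple[ConcentrationSeries, ChannelMask, list[dict]]:
    """Apply the full ordered chain to one run.

    Returns the cleaned concentrations, the channel mask, and a provenance
    log (one entry per step, with parameters and enabled status).
    """
    config = config or PreprocessConfig()
    extinction = extinction or ExtinctionTable.for_wavelengths(rec.montage.wavelengths_nm)
    provenance: list[dict] = []

    def log_step(name: str, enabled: bool = True, **params):
        provenance.append({"step": name, "enabled": enabled, **params})

    mask = prune_channels(rec, config)
    log_step("prune_channels", d_range=list(config.d_range), snr_thresh=config.snr_thresh,
             n_pruned=int((~mask.kept).sum()))

    intensity, repaired = guard_negative_intensity(rec, mask)
    log_step("negative_intensity_guard", n_repaired=repaired)

    od = intensity_to_od(rec, mask, intensity)
    log_step("intensity_to_od", reference="run mean", log="natural")

    if config.enable_detrend:
        od = detrend_linear(od)
    log_step("detrend_linear", enabled=config.enable_detrend)

    if config.enable_tddr and mask.any_kept:
        od = correct_motion_tddr(od, config=config)
    log_step("correct_motion_tddr", enabled=config.enable_tddr,
             tukey_c=config.tddr_tukey_c, split_freq_hz=config.tddr_split_freq_hz)

    if config.enable_bandpass:
        od = bandpass_filter(od, config)
    log_step("bandpass_filter", enabled=config.enable_bandpass,
             low_cut_hz=config.low_cut_hz, high_cut_hz=config.high_cut_hz,
             lowpass_order=config.lowpass_order, highpass_order=config.highpass_order)

    conc = od_to_concentration(od, rec.montage, extinction, config, mask)
    log_step("od_to_concentration", ppf=config.ppf)

    if config.enable_pca and mask.any_kept:
        conc = remove_global_pca(conc, rec.montage.channel_positions, config.pca_sigma_deg)
    log_step("remove_global_pca", enabled=config.enable_pca, sigma_deg=config.pca_sigma_deg)

    return conc, mask, provenance
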