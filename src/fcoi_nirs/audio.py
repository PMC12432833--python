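"""Degraded-speech construction for localizer stimuli.

Output = low-pass-filtered speech (350 Hz pass band) plus an unintelligible
noise track built by permuting the original samples, imposing the intact
clip's amplitude envelope, and low-pass filtering (8 kHz pass, 10 kHz stop).
The result keeps the clip's prosodic/rhythmic contour without intelligible
content.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.io import wavfile

from .core import ValidationError

__all__ = ["AudioClip", "amplitude_envelope", "degrade_speech", "read_wav", "write_wav"]


@dataclass
class AudioClip:
    samples: np.ndarray
    rate_hz: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("only mono clips are supported")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples must be finite")
        if self.rate_hz <= 0:
            raise ValidationError("rate_hz must be positive")
        if not (17.0 <= self.duration_s <= 20.0):
            warnings.warn(
                f"clip duration {self.duration_s:.1f}s outside the 17–20s localizer range",
                stacklevel=2,
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    def normalized(self) -> "AudioClip":
        peak = np.max(np.abs(self.samples))
        if peak == 0:
            return self
        return AudioClip(self.samples / peak, self.rate_hz)


def read_wav(path) -> AudioClip:
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return AudioClip(data.astype(float), int(rate))


def write_wav(clip: AudioClip, path) -> None:
    peak = np.max(np.abs(clip.samples))
    samples = clip.samples / peak if peak > 1 else clip.samples
    wavfile.write(path, clip.rate_hz, (samples * 32767).astype(np.int16))


def amplitude_envelope(clip: AudioClip, smoothing_hz: float = 30.0) -> np.ndarray:
    """Non-negative amplitude envelope at the audio rate: magnitude of the
    analytic signal, low-pass smoothed; length equals the clip length."""
    if clip.samples.size == 0:
        raise ValidationError("empty clip")
    env = np.abs(signal.hilbert(clip.samples))
    sos = signal.butter(4, smoothing_hz, btype="low", fs=clip.rate_hz, output="sos")
    smoothed = signal.sosfiltfilt(sos, env)
    return np.clip(smoothed, 0.0, None)


def _speech_path(clip: AudioClip, cutoff_hz: float = 350.0, order: int = 8) -> np.ndarray:
    # Order 8 gives > 40 dB attenuation one octave above the cut even before
    # the forward–backward pass doubles it.
    sos = signal.butter(order, cutoff_hz, btype="low", fs=clip.rate_hz, output="sos")
    return signal.sosfiltfilt(sos, clip.samples)


def _noise_lowpass(x: np.ndarray, rate_hz: int, pass_hz: float = 8000.0,
                   stop_hz: float = 10000.0) -> np.ndarray:
    order, wn = signal.buttord(pass_hz, stop_hz, gpass=3, gstop=40, fs=rate_hz)
    sos = signal.butter(order, wn, btype="low", fs=rate_hz, output="sos")
    return signal.sosfiltfilt(sos, x)


def degrade_speech(
    clip: AudioClip,
    seed: int = 0,
    noise_to_speech_rms: float = 1.0,
    frame_s: float | None = None,
) -> AudioClip:
    """Render a clip unintelligible while preserving its prosodic rhythm.

    ``frame_s`` switches the time-point shuffle from sample granularity to
    frames of that length. The permutation is seeded and deterministic.
    """
    if not np.any(clip.samples):
        raise ValidationError("cannot degrade an all-zero clip")
    if clip.rate_hz < 22050:
        warnings.warn("sample rates below 22.05 kHz are not recommended", stacklevel=2)
    rng = np.random.default_rng(seed)
    x = clip.samples
    if frame_s:
        frame = max(1, int(round(frame_s * clip.rate_hz)))
        n_frames = x.size // frame
        head = x[: n_frames * frame].reshape(n_frames, frame)
        shuffled = np.concatenate(
            [head[rng.permutation(n_frames)].ravel(), x[n_frames * frame:]]
        )
    else:
        shuffled = x[rng.permutation(x.size)]

    speech = _speech_path(clip)
    envelope = amplitude_envelope(clip)
    noise = _noise_lowpass(shuffled * envelope, clip.rate_hz)
    speech_rms = np.sqrt(np.mean(speech**2))
    noise_rms = np.sqrt(np.mean(noise**2))
    gain = noise_to_speech_rms * speech_rms / noise_rms if noise_rms > 0 else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return AudioClip(speech + gain * noise, clip.rate_hz)
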