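"""Voiced-segment recovery from audio and pause extraction.

A pause, in the study sense, is a silence between two consecutive
voiced speech segments lasting strictly longer than 2 seconds.  The
audio path is: spectral-gating noise reduction -> short-time-energy
voice activity detection (VAD) -> gap scan over the voiced timeline.

VAD defaults (25 ms frames, 10 ms hop, energy threshold at 3x the
noise-floor RMS, 200 ms minimum segment, 150 ms gap bridging) are
conventional speech-processing values; all are configurable through
:class:`VadParams`.  Pauses are interview-global: no speaker
attribution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

__all__ = [
    "SpeechTimeline",
    "PauseSet",
    "VadParams",
    "read_wav_mono",
    "denoise",
    "detect_speech_segments",
    "extract_pauses",
]


@dataclass(frozen=True)
class SpeechTimeline:
    """Ordered, non-overlapping voiced intervals in seconds."""

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end in self.segments:
            if end <= start:
                raise ValueError(f"segment ({start}, {end}) has end <= start")
            if start < prev_end:
                raise ValueError("timeline segments overlap or are unordered")
            prev_end = end

    @classmethod
    def from_pairs(cls, pairs: Sequence[Sequence[float]]) -> "SpeechTimeline":
        return cls(tuple((float(a), float(b)) for a, b in pairs))

    def shift(self, offset_s: float) -> "SpeechTimeline":
        return SpeechTimeline(tuple((a + offset_s, b + offset_s) for a, b in self.segments))

    def save(self, path: str | Path) -> None:
        lines = [f"{a:.6f}\t{b:.6f}" for a, b in self.segments]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "SpeechTimeline":
        pairs = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if line.strip():
                a, b = line.split("\t")
                pairs.append((float(a), float(b)))
        return cls.from_pairs(pairs)


@dataclass(frozen=True)
class PauseSet:
    """Inter-segment silences longer than ``threshold_s``."""

    pauses: tuple[tuple[float, float], ...]
    threshold_s: float = 2.0

    def __len__(self) -> int:
        return len(self.pauses)

    def durations(self) -> np.ndarray:
        return np.array([b - a for a, b in self.pauses])


@dataclass(frozen=True)
class VadParams:
    frame_s: float = 0.025
    hop_s: float = 0.010
    energy_threshold_rel: float = 3.0  # multiplier over the noise-floor RMS
    min_segment_s: float = 0.200
    merge_gap_s: float = 0.150
    noise_floor_quantile: float = 0.10

    def __post_init__(self) -> None:
        for name in ("frame_s", "hop_s", "energy_threshold_rel", "min_segment_s", "merge_gap_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hop_s > self.frame_s:
            raise ValueError("hop_s must be <= frame_s")


def read_wav_mono(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a PCM WAV file as float64 mono (stereo is downmixed)."""
    sample_rate, data = wavfile.read(str(path))
    signal = np.asarray(data, dtype=np.float64)
    if np.issubdtype(np.asarray(data).dtype, np.integer):
        signal = signal / np.iinfo(np.asarray(data).dtype).max
    if signal.ndim == 2:
        signal = signal.mean(axis=1)
    return signal, int(sample_rate)


def denoise(
    signal: np.ndarray,
    sample_rate: int,
    gate_rel: float = 2.0,
    attenuation: float = 0.05,
    noise_quantile: float = 0.10,
    peak_frac: float = 0.35,
) -> np.ndarray:
    """Spectral-gating noise reduction.

    The stationary noise profile is the per-frequency mean magnitude of
    the lowest-energy ``noise_quantile`` fraction of STFT frames.  A
    time-frequency bin is attenuated by ``attenuation`` only when it is
    both below ``gate_rel`` times that profile *and* below ``peak_frac``
    of its own frequency bin's temporal peak — the second condition
    keeps steady tonal components intact even when the recording has no
    silent stretch to estimate noise from.  Output length equals input
    length.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size == 0:
        raise ValueError("empty signal")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    if not np.any(signal):
        return np.zeros_like(signal)
    nperseg = max(64, min(1024, int(0.032 * sample_rate)))
    hop = nperseg // 4
    stft = ShortTimeFFT(hann(nperseg, sym=False), hop=hop, fs=sample_rate, fft_mode="onesided")
    spec = stft.stft(signal)
    mag = np.abs(spec)
    frame_energy = (mag**2).sum(axis=0)
    n_noise = max(1, int(np.ceil(noise_quantile * frame_energy.size)))
    quiet = np.argsort(frame_energy, kind="stable")[:n_noise]
    noise_profile = mag[:, quiet].mean(axis=1, keepdims=True)
    bin_peak = mag.max(axis=1, keepdims=True)
    noisy = (mag < gate_rel * noise_profile) & (mag < peak_frac * bin_peak)
    gain = np.where(noisy, attenuation, 1.0)
    out = stft.istft(spec * gain, k1=signal.size)
    return np.asarray(out[: signal.size], dtype=np.float64)


def _frame_rms(signal: np.ndarray, sample_rate: int, params: VadParams) -> tuple[np.ndarray, int, int]:
    frame = max(1, int(round(params.frame_s * sample_rate)))
    hop = max(1, int(round(params.hop_s * sample_rate)))
    n = signal.size
    if n < frame:
        pad = np.zeros(frame)
        pad[:n] = signal
        signal, n = pad, frame
    n_frames = 1 + (n - frame) // hop
    sq = np.concatenate([[0.0], np.cumsum(signal**2)])
    starts = np.arange(n_frames) * hop
    rms = np.sqrt((sq[starts + frame] - sq[starts]) / frame)
    return rms, frame, hop


def detect_speech_segments(
    signal: np.ndarray, sample_rate: int, params: VadParams | None = None
) -> SpeechTimeline:
    """Short-time-energy VAD over a (denoised) mono signal.

    The voicing threshold is ``energy_threshold_rel`` times the
    noise-floor RMS (a low quantile of frame RMS), capped at a fraction
    of the peak RMS so that continuous speech with no silent frames is
    still detected.  Segments shorter than ``min_segment_s`` are
    dropped; inter-segment gaps shorter than ``merge_gap_s`` bridged.
    """
    if params is None:
        params = VadParams()
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size == 0:
        return SpeechTimeline(())
    rms, frame, hop = _frame_rms(signal, sample_rate, params)
    noise_floor = np.quantile(rms, params.noise_floor_quantile)
    threshold = max(
        min(params.energy_threshold_rel * noise_floor, 0.3 * rms.max()),
        1e-10,
    )
    voiced = rms > threshold
    if not voiced.any():
        return SpeechTimeline(())
    edges = np.flatnonzero(np.diff(np.concatenate([[0], voiced.view(np.int8), [0]])))
    starts_f, ends_f = edges[::2], edges[1::2]
    hop_s = hop / sample_rate
    frame_s = frame / sample_rate
    segs = [(s * hop_s, (e - 1) * hop_s + frame_s) for s, e in zip(starts_f, ends_f)]
    # bridge short gaps, then drop short segments
    merged: list[list[float]] = []
    for a, b in segs:
        if merged and a - merged[-1][1] < params.merge_gap_s:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    kept = [(a, b) for a, b in merged if b - a >= params.min_segment_s]
    return SpeechTimeline.from_pairs(kept)


def extract_pauses(timeline: SpeechTimeline, threshold_s: float = 2.0) -> PauseSet:
    """Scan inter-segment gaps; keep those strictly longer than ``threshold_s``.

    A gap exactly equal to the threshold is not a pause ("longer than"
    is read strictly).
    """
    if threshold_s < 0:
        raise ValueError("threshold_s must be >= 0")
    segs = timeline.segments  # SpeechTimeline validates ordering on construction
    pauses = []
    for (_, end_prev), (start_next, _) in zip(segs, segs[1:]):
        if start_next - end_prev > threshold_s:
            pauses.append((end_prev, start_next))
    return PauseSet(tuple(pauses), threshold_s=threshold_s)


def pauses_from_audio(
    signal: np.ndarray,
    sample_rate: int,
    params: VadParams | None = None,
    threshold_s: float = 2.0,
) -> PauseSet:
    """Full audio path: denoise -> VAD -> pause extraction."""
    cleaned = denoise(signal, sample_rate)
    timeline = detect_speech_segments(cleaned, sample_rate, params)
    return extract_pauses(timeline, threshold_s)
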