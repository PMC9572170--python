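"""Log-mel spectrogram slicing of interview audio.

Mono WAV input is resampled to 16 kHz, framed with a 512-sample window and
256-sample hop (~30 ms / ~15 ms), projected onto 128 mel bands
(Slaney-style filterbank by default), log-compressed, and cut along time
into non-overlapping slices of 64 frames (~1 s), yielding one 128x64
matrix per second of speech. Trailing incomplete slices are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

__all__ = ["AudioIngest", "mel_filterbank", "wav_to_slices", "frame_count"]


@dataclass(frozen=True)
class AudioIngest:
    sample_rate: int = 16_000
    frame_length: int = 512
    hop: int = 256
    n_mels: int = 128
    slice_frames: int = 64
    htk: bool = False               # mel scale convention (Slaney default)
    log_floor_db: float = -80.0


def _hz_to_mel(f, htk: bool):
    f = np.asarray(f, dtype=float)
    if htk:
        return 2595.0 * np.log10(1.0 + f / 700.0)
    # Slaney: linear below 1 kHz, logarithmic above
    f_sp, brk = 200.0 / 3, 1000.0
    logstep = np.log(6.4) / 27.0
    mel = np.where(f < brk, f / f_sp, brk / f_sp + np.log(np.maximum(f, 1e-9) / brk) / logstep)
    return mel


def _mel_to_hz(m, htk: bool):
    m = np.asarray(m, dtype=float)
    if htk:
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    f_sp, brk = 200.0 / 3, 1000.0
    brk_mel = brk / f_sp
    logstep = np.log(6.4) / 27.0
    return np.where(m < brk_mel, m * f_sp, brk * np.exp(logstep * (m - brk_mel)))


def mel_filterbank(sr: int, n_fft: int, n_mels: int, htk: bool = False) -> np.ndarray:
    """Triangular mel filterbank (n_mels, 1 + n_fft // 2), area-normalized."""
    n_bins = 1 + n_fft // 2
    fft_freqs = np.linspace(0.0, sr / 2.0, n_bins)
    mel_pts = np.linspace(_hz_to_mel(0.0, htk), _hz_to_mel(sr / 2.0, htk), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts, htk)
    weights = np.zeros((n_mels, n_bins))
    for i in range(n_mels):
        lo, mid, hi = hz_pts[i : i + 3]
        up = (fft_freqs - lo) / max(mid - lo, 1e-9)
        down = (hi - fft_freqs) / max(hi - mid, 1e-9)
        weights[i] = np.maximum(0.0, np.minimum(up, down))
        enorm = 2.0 / (hi - lo)     # Slaney area normalization
        weights[i] *= enorm
    return weights


def frame_count(n_samples: int, ingest: AudioIngest = AudioIngest()) -> int:
    """Number of complete analysis frames (no padding)."""
    if n_samples < ingest.frame_length:
        return 0
    return (n_samples - ingest.frame_length) // ingest.hop + 1


def wav_to_slices(source, ingest: AudioIngest = AudioIngest()) -> list:
    """Cut a mono WAV file (or ``(rate, samples)`` pair) into 128x64 log-mel
    slices.

    Returns a list of (n_mels, slice_frames) arrays in dB units (floored at
    ``log_floor_db`` relative to the maximum).
    """
    if isinstance(source, (str, Path)):
        rate, data = wavfile.read(source)
    else:
        rate, data = source
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValueError("empty audio")
    if data.ndim == 2:              # average channels to mono
        data = data.mean(axis=1)
    if np.issubdtype(np.asarray(data).dtype, np.integer):
        data = data / 32768.0
    if rate != ingest.sample_rate:
        g = np.gcd(int(rate), ingest.sample_rate)
        data = resample_poly(data, ingest.sample_rate // g, int(rate) // g)

    n_frames = frame_count(len(data), ingest)
    if n_frames == 0:
        return []
    idx = np.arange(ingest.frame_length)[None, :] \
        + ingest.hop * np.arange(n_frames)[:, None]
    frames = data[idx] * get_window("hann", ingest.frame_length, fftbins=True)
    mag = np.abs(np.fft.rfft(frames, axis=1))
    mel = mel_filterbank(ingest.sample_rate, ingest.frame_length, ingest.n_mels,
                         ingest.htk)
    spec = mel @ mag.T              # (n_mels, n_frames)
    db = 20.0 * np.log10(np.maximum(spec, 1e-10))
    db = np.maximum(db, db.max() + ingest.log_floor_db)

    n_slices = n_frames // ingest.slice_frames
    return [db[:, i * ingest.slice_frames : (i + 1) * ingest.slice_frames].copy()
            for i in range(n_slices)]
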