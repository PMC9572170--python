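"""Cleaning of raw sensor streams into 5-min analysis windows.

Implements the filtering rules of the statistical and detection pipelines:

* RR stream: drop identical consecutive 5 Hz readouts to recover the beat
  sequence, remove values outside [300, 2000] ms, fill missed-pulse gaps by
  linear interpolation, and truncate each 5-min window to its first 270 s
  (90%) of cumulative beat time.
* Motion (20 Hz triaxial): reject windows with more than 50 missing samples,
  nearest-neighbour fill the rest, keep the first 5940 (99%) samples, and
  suppress high-frequency sensor noise with a wavelet shrinkage step.
* Day tensors: stack 5-min features into 288-row day matrices, median-filling
  missing runs of up to 10 consecutive hours and rejecting longer ones.

All window and day boundaries are half-open and anchored at the subject-local
midnight epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "PreprocessConfig",
    "RRWindow",
    "MotionWindow",
    "Rejection",
    "dedupe_rr",
    "clean_rr_window",
    "clean_motion_window",
    "denoise_axis",
    "label_state",
    "build_day_tensor",
    "motion_window_grid",
    "WINDOW_S",
]

WINDOW_S = 300.0


@dataclass(frozen=True)
class PreprocessConfig:
    rr_min_ms: float = 300.0
    rr_max_ms: float = 2000.0
    #: a beat-to-beat gap longer than ``gap_factor`` times the local median RR
    #: is declared a missed-pulse run and filled by linear interpolation
    gap_factor: float = 1.75
    median_beats: int = 11          # rolling-median window (beats)
    rr_keep_s: float = 270.0        # 90% cumulative-time truncation
    min_beats: int = 10             # below this a window is rejected as sparse
    motion_nominal: int = 6000      # 5 min at 20 Hz
    motion_keep: int = 5940         # first 99% of samples
    max_missing: int = 50
    wavelet: str = "db4"
    denoise_levels: int = 2
    denoise_mode: str = "zero"      # "zero" | "soft"
    tensor_slots: int = 288
    max_gap_slots: int = 120        # 10 h at 5-min resolution
    fill_halfwidth: int = 12        # +/- window (slots) for median filling


@dataclass
class RRWindow:
    subject_id: str
    window_start: float
    rr: np.ndarray                  # cleaned RR values, ms
    beat_times: np.ndarray          # cleaned beat times, s (window-relative)
    n_raw: int
    pct_valid: float
    short_window: bool = False      # fewer than rr_keep_s seconds of beats


@dataclass
class MotionWindow:
    subject_id: str
    window_start: float
    modality: str
    samples: np.ndarray             # (motion_keep, 3), denoised, no missing


@dataclass(frozen=True)
class Rejection:
    subject_id: str
    window_start: float
    modality: str
    reason: str                     # sparse | missing | gap


# ---------------------------------------------------------------------------

def dedupe_rr(times: np.ndarray, values: np.ndarray):
    """Collapse identical consecutive readout values to the first occurrence.

    The 5 Hz wrist readout repeats the latest detected RR until the next
    beat; dropping consecutive duplicates recovers the event (beat) sequence
    with the beat time taken as the readout time of the first occurrence.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        return times[:0], values[:0]
    keep = np.empty(len(values), dtype=bool)
    keep[0] = True
    np.not_equal(values[1:], values[:-1], out=keep[1:])
    return times[keep], values[keep]


def _rolling_median(x: np.ndarray, win: int) -> np.ndarray:
    if len(x) <= win:
        return np.full(len(x), np.median(x))
    half = win // 2
    padded = np.pad(x, half, mode="edge")
    return np.median(np.lib.stride_tricks.sliding_window_view(padded, win), axis=1)


def clean_rr_window(beat_times, rr, window_start: float,
                    config: PreprocessConfig = PreprocessConfig(),
                    subject_id: str = ""):
    """Clean the beat events of one 5-min window into an :class:`RRWindow`.

    Returns a :class:`Rejection` when fewer than ``config.min_beats`` valid
    beats remain.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    rr = np.asarray(rr, dtype=float)
    n_raw = len(rr)
    ok = (rr >= config.rr_min_ms) & (rr <= config.rr_max_ms)
    t, v = beat_times[ok], rr[ok]
    if len(v) < config.min_beats:
        return Rejection(subject_id, window_start, "rr", "sparse")

    # missed-pulse gaps: inter-beat time exceeding gap_factor x local median RR
    med = _rolling_median(v, config.median_beats)
    dts = np.diff(t) * 1000.0
    gap_idx = np.flatnonzero((dts > config.gap_factor * med[:-1]) & (med[:-1] > 0))
    if len(gap_idx):
        t_parts, v_parts = [], []
        prev = 0
        for i in gap_idx:
            n_miss = int(round(dts[i] / med[i])) - 1
            if n_miss <= 0:
                continue
            t_parts.append(t[prev : i + 1])
            v_parts.append(v[prev : i + 1])
            frac = np.arange(1, n_miss + 1) / (n_miss + 1)
            t_parts.append(t[i] + frac * (t[i + 1] - t[i]))
            v_parts.append(v[i] + frac * (v[i + 1] - v[i]))
            prev = i + 1
        t_parts.append(t[prev:])
        v_parts.append(v[prev:])
        t = np.concatenate(t_parts)
        v = np.concatenate(v_parts)

    # truncate to the beats whose cumulative time lies within the first 270 s
    cum = np.cumsum(v) / 1000.0
    keep = cum <= config.rr_keep_s
    short = bool(cum[-1] < config.rr_keep_s)
    t, v = t[keep], v[keep]
    if len(v) < config.min_beats:
        return Rejection(subject_id, window_start, "rr", "sparse")
    pct_valid = float(ok.sum()) / n_raw if n_raw else 0.0
    return RRWindow(subject_id, window_start, v, t - window_start,
                    n_raw=n_raw, pct_valid=min(pct_valid, 1.0),
                    short_window=short)


# ---------------------------------------------------------------------------

def denoise_axis(x: np.ndarray, config: PreprocessConfig = PreprocessConfig()):
    """Suppress the finest wavelet detail bands of one signal axis.

    Default mode zeroes the ``denoise_levels`` finest db4 detail bands
    (high-frequency sensor noise); mode "soft" applies universal soft
    thresholding per band instead.
    """
    wav = pywt.Wavelet(config.wavelet)
    lev = min(config.denoise_levels, pywt.dwt_max_level(len(x), wav.dec_len))
    if lev < 1:
        return np.asarray(x, dtype=float)
    coeffs = pywt.wavedec(x, wav, level=lev, mode="symmetric")
    for i in range(1, lev + 1):          # coeffs[-1] is the finest band
        band = coeffs[-i]
        if config.denoise_mode == "zero":
            coeffs[-i] = np.zeros_like(band)
        else:
            sigma = np.median(np.abs(band - np.median(band))) / 0.6745
            thresh = sigma * np.sqrt(2.0 * np.log(max(len(x), 2)))
            coeffs[-i] = pywt.threshold(band, thresh, mode="soft")
    return pywt.waverec(coeffs, wav, mode="symmetric")[: len(x)]


def clean_motion_window(samples: np.ndarray, window_start: float,
                        modality: str = "acc",
                        config: PreprocessConfig = PreprocessConfig(),
                        subject_id: str = ""):
    """Clean one nominal 6000-sample triaxial window.

    ``samples`` is (6000, 3) with NaN rows marking missing samples. Windows
    with more than ``max_missing`` missing samples are rejected; remaining
    gaps are nearest-neighbour filled, the first 5940 samples kept, and each
    axis denoised.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.shape != (config.motion_nominal, 3):
        raise ValueError(f"expected ({config.motion_nominal}, 3) window, got {samples.shape}")
    missing = np.isnan(samples).any(axis=1)
    n_missing = int(missing.sum())
    if n_missing > config.max_missing:
        return Rejection(subject_id, window_start, modality, "missing")
    if n_missing == config.motion_nominal:
        return Rejection(subject_id, window_start, modality, "sparse")
    if n_missing:
        valid_idx = np.flatnonzero(~missing)
        miss_idx = np.flatnonzero(missing)
        pos = np.searchsorted(valid_idx, miss_idx)
        left = valid_idx[np.clip(pos - 1, 0, len(valid_idx) - 1)]
        right = valid_idx[np.clip(pos, 0, len(valid_idx) - 1)]
        nearest = np.where(miss_idx - left <= right - miss_idx, left, right)
        samples = samples.copy()
        samples[miss_idx] = samples[nearest]
    kept = samples[: config.motion_keep]
    out = np.column_stack([denoise_axis(kept[:, a], config) for a in range(3)])
    return MotionWindow(subject_id, window_start, modality, out)


def motion_window_grid(times: np.ndarray, values: np.ndarray,
                       window_start: float, rate: float = 20.0,
                       nominal: int = 6000) -> np.ndarray:
    """Place irregular/missing samples onto the nominal window grid.

    Returns (nominal, 3) with NaN rows where no sample landed on a grid slot.
    """
    if len(times) == nominal:       # complete window: grid placement is 1:1
        return np.asarray(values, dtype=float)
    grid = np.full((nominal, 3), np.nan)
    if len(times):
        idx = np.round((np.asarray(times) - window_start) * rate).astype(int)
        ok = (idx >= 0) & (idx < nominal)
        grid[idx[ok]] = values[ok]
    return grid


# ---------------------------------------------------------------------------

def label_state(window_start: float, diary, window_s: float = WINDOW_S) -> str:
    """awake/sleep label from the diary: sleep iff the window midpoint falls
    inside a sleep episode (half-open episodes)."""
    mid = window_start + window_s / 2.0
    return "sleep" if diary.is_asleep(mid) else "awake"


# ---------------------------------------------------------------------------

def build_day_tensor(day_matrix: np.ndarray,
                     config: PreprocessConfig = PreprocessConfig(),
                     subject_id: str = "", day_start: float = 0.0):
    """Fill gaps in a (288, F) day matrix of 5-min features.

    A slot is missing when any of its features is NaN. Runs of up to
    ``max_gap_slots`` (10 h) missing slots are filled per feature with the
    median over the surrounding ``+/- fill_halfwidth`` slots (falling back to
    the day median); any longer run rejects the day.
    """
    m = np.asarray(day_matrix, dtype=float)
    if m.shape[0] != config.tensor_slots:
        raise ValueError(f"expected {config.tensor_slots} slots, got {m.shape[0]}")
    missing = np.isnan(m).any(axis=1)
    if missing.all():
        return Rejection(subject_id, day_start, "tensor", "gap")
    # longest run of consecutive missing slots
    run, longest = 0, 0
    for flag in missing:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    if longest > config.max_gap_slots:
        return Rejection(subject_id, day_start, "tensor", "gap")
    if not missing.any():
        return m.copy()
    out = m.copy()
    day_median = np.nanmedian(np.where(missing[:, None], np.nan, m), axis=0)
    for slot in np.flatnonzero(missing):
        lo = max(0, slot - config.fill_halfwidth)
        hi = min(config.tensor_slots, slot + config.fill_halfwidth + 1)
        nbhd = m[lo:hi][~missing[lo:hi]]
        out[slot] = np.median(nbhd, axis=0) if len(nbhd) else day_median
    return out
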