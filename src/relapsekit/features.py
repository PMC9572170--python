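"""Per-window descriptors of motion and heart-rate-variability signals.

For each cleaned 5-min window the module computes:

* short-time energy (STE) of the triaxial accelerometer/gyroscope norm,
* the Lomb-Scargle periodogram of the (unevenly spaced) RR series and the
  normalized LF (0.04-0.15 Hz) / HF (0.15-0.40 Hz) band powers and their
  ratio,
* sample entropy (SampEn), the Higuchi fractal dimension, and the multiscale
  fractal dimension profile D(s, t) estimated from morphological graph
  covers with its fd[1]/min/max/mean/std summaries,
* the Poincare plot dispersions SD1/SD2 and mean HR / RR,
* daily step counts and the sleep/wake ratio over days with enough recording.

Normalized band powers follow the percent-of-(LF+HF) convention, so
``lf_pct + hf_pct == 100`` for every window where the bands carry power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import lombscargle as _scipy_lombscargle

from . import _fast
from .preprocessing import WINDOW_S, MotionWindow, RRWindow

__all__ = [
    "FeatureConfig",
    "Periodogram",
    "BandPowers",
    "MFDProfile",
    "DETECTION_FEATURES",
    "STAT_FEATURES",
    "short_time_energy",
    "lomb_scargle",
    "band_powers",
    "sample_entropy",
    "higuchi_fd",
    "higuchi_curve_lengths",
    "mfd_profile",
    "morphological_cover_widths",
    "poincare_sd",
    "time_of_day_trig",
    "daily_activity",
    "interval_features",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

#: Column order of the 10 detection features (the DayTensor layout).
DETECTION_FEATURES = [
    "ste_acc", "ste_gyr", "hr_mean", "rr_mean", "lf_pct",
    "hf_pct", "sd1", "sin_t", "cos_t", "pct_valid",
]

#: The 14 feature types aggregated (mean, std) into 28 per-subject values.
STAT_FEATURES = [
    "ste_acc", "ste_gyr", "sampen", "higuchi", "mfd_fd1", "mfd_min",
    "mfd_max", "mfd_mean", "mfd_std", "sd1", "sd2", "lf_pct", "hf_pct",
    "lf_hf_ratio",
]


@dataclass(frozen=True)
class FeatureConfig:
    sampen_m: int = 2
    sampen_r: float = 0.2           # tolerance as a fraction of the window SD
    higuchi_kmax: int = 10
    mfd_max_scale: int = 30         # samples
    mfd_scale_window: int = 5       # scales per local log-log regression
    mfd_frame_len: int = 64         # samples per time frame of D(s, t)
    mfd_frame_hop: int = 32
    ls_fmin: float = 0.001          # Hz
    ls_fmax: float = 0.5
    ls_nfreq: int = 1024
    ls_center: bool = True

    def __post_init__(self):
        if self.sampen_m < 1 or self.sampen_r <= 0 or self.higuchi_kmax < 2:
            raise ValueError("invalid feature configuration")

    def ls_grid(self) -> np.ndarray:
        return np.linspace(self.ls_fmin, self.ls_fmax, self.ls_nfreq)


@dataclass
class Periodogram:
    freqs: np.ndarray               # Hz, strictly increasing
    power: np.ndarray               # unnormalized P_LS, ms^2 scale
    n: int


@dataclass
class BandPowers:
    lf_pct: float
    hf_pct: float
    ratio: float


@dataclass
class MFDProfile:
    scales: np.ndarray              # smallest scale of each regression window
    dimensions: np.ndarray          # D(s, t), shape (n_scales, n_frames)

    @property
    def fd1(self) -> float:
        return float(self.dimensions[0].mean())

    def summaries(self) -> dict:
        d = self.dimensions
        return {
            "mfd_fd1": self.fd1,
            "mfd_min": float(d.min()),
            "mfd_max": float(d.max()),
            "mfd_mean": float(d.mean()),
            "mfd_std": float(d.std()),
        }


# ---------------------------------------------------------------------------
# motion
# ---------------------------------------------------------------------------

def short_time_energy(samples: np.ndarray) -> float:
    """Mean squared Euclidean norm of the triaxial signal (window-length
    invariant power convention)."""
    samples = np.asarray(samples, dtype=float)
    return float(np.mean(np.sum(samples * samples, axis=1)))


# ---------------------------------------------------------------------------
# spectral
# ---------------------------------------------------------------------------

def lomb_scargle(times, values, freqs=None,
                 config: FeatureConfig = FeatureConfig(),
                 center: bool | None = None) -> Periodogram:
    """Unnormalized Lomb-Scargle periodogram on a frequency grid (Hz).

    The input is mean-centered before evaluation by default (pass
    ``center=False`` to evaluate the raw formula, which lets DC leak into the
    low-frequency band).
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(values, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 samples for spectral analysis")
    if np.any(np.diff(t) <= 0):
        raise ValueError("sample times must be strictly increasing")
    if freqs is None:
        freqs = config.ls_grid()
    freqs = np.asarray(freqs, dtype=float)
    if center if center is not None else config.ls_center:
        x = x - x.mean()
    omega = 2.0 * np.pi * freqs
    steps = np.diff(omega)
    uniform_grid = len(omega) < 2 or np.allclose(steps, steps[0], rtol=1e-9, atol=0.0)
    if _fast._HAVE_NUMBA and uniform_grid:
        power = _fast.lomb_scargle_kernel(np.ascontiguousarray(t),
                                          np.ascontiguousarray(x),
                                          np.ascontiguousarray(omega))
    else:
        power = _scipy_lombscargle(t, x, omega)
    return Periodogram(freqs=freqs, power=np.maximum(power, 0.0), n=len(x))


def _band_integral(freqs, power, lo, hi) -> float:
    """Trapezoidal integral over [lo, hi] with interpolated band edges."""
    inside = (freqs > lo) & (freqs < hi)
    f = np.concatenate(([lo], freqs[inside], [hi]))
    p = np.concatenate((
        [np.interp(lo, freqs, power)], power[inside], [np.interp(hi, freqs, power)]
    ))
    return float(np.trapezoid(p, f))


def band_powers(pgram: Periodogram) -> BandPowers | None:
    """Normalized LF/HF powers (percent of LF+HF) and their ratio.

    Returns None (flagged window) when the two bands carry no power.
    """
    if pgram.freqs[0] > LF_BAND[0] or pgram.freqs[-1] < HF_BAND[1]:
        raise ValueError("frequency grid does not cover the LF and HF bands")
    lf = _band_integral(pgram.freqs, pgram.power, *LF_BAND)
    hf = _band_integral(pgram.freqs, pgram.power, *HF_BAND)
    total = lf + hf
    if total <= 0:
        return None
    return BandPowers(
        lf_pct=100.0 * lf / total,
        hf_pct=100.0 * hf / total,
        ratio=lf / hf if hf > 0 else math.inf,
    )


# ---------------------------------------------------------------------------
# complexity
# ---------------------------------------------------------------------------

def sample_entropy(x, m: int = 2, r: float = 0.2) -> float:
    """SampEn(m, r * SD): -log of the conditional probability that sequences
    matching for m points (Chebyshev distance <= r*SD, self-matches excluded)
    also match for m+1 points.

    Returns NaN when no template pair matches at either length.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= m + 1:
        raise ValueError("sequence too short for the requested embedding")
    sd = x.std()
    if sd == 0:
        return 0.0                  # every pair matches at both lengths
    tol = r * sd

    if _fast._HAVE_NUMBA:
        b, a = _fast.sampen_counts(np.ascontiguousarray(x), m, tol)
    else:
        n_templates = n - m         # same template count at both lengths
        d = np.zeros((n_templates, n_templates))
        for k in range(m):
            col = x[k : k + n_templates]
            np.maximum(d, np.abs(col[:, None] - col[None, :]), out=d)
        b = int(((d <= tol).sum() - n_templates) // 2)
        col = x[m : m + n_templates]  # extend the same templates by one point
        np.maximum(d, np.abs(col[:, None] - col[None, :]), out=d)
        a = int(((d <= tol).sum() - n_templates) // 2)
    if a == 0 or b == 0:
        return float("nan")
    return float(-math.log(a / b))


def higuchi_curve_lengths(x, k_max: int = 10) -> np.ndarray:
    """Mean normalized curve length L(k) for k = 1..k_max (average over the
    k possible offsets)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 * k_max:
        raise ValueError("sequence too short for k_max")
    lengths = np.empty(k_max)
    for k in range(1, k_max + 1):
        lm = []
        for m0 in range(k):
            idx = np.arange(m0, n, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((len(idx) - 1) * k)
            lm.append(dist * norm / k)
        lengths[k - 1] = np.mean(lm)
    return lengths


def higuchi_fd(x, k_max: int = 10) -> float:
    """Least-squares slope of log L(k) against log(1/k)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    lengths = higuchi_curve_lengths(x, k_max)
    k = np.arange(1, k_max + 1)
    good = lengths > 0
    if good.sum() < 2:
        return 1.0
    slope = np.polyfit(np.log(1.0 / k[good]), np.log(lengths[good]), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# multiscale fractal dimension (morphological covers)
# ---------------------------------------------------------------------------

def morphological_cover_widths(x, max_scale: int) -> np.ndarray:
    """Dilation-minus-erosion of the signal graph by flat structuring
    elements of half-width s = 1..max_scale (edge-replicated), shape
    (max_scale, len(x))."""
    x = np.asarray(x, dtype=float)
    widths = np.empty((max_scale, len(x)))
    for s in range(1, max_scale + 1):
        size = 2 * s + 1
        widths[s - 1] = (maximum_filter1d(x, size, mode="nearest")
                         - minimum_filter1d(x, size, mode="nearest"))
    return widths


def mfd_profile(x, config: FeatureConfig = FeatureConfig()) -> MFDProfile:
    """Local multiscale fractal dimension profile D(s, t).

    Cover areas A(s, t) are the per-frame sums of the morphological cover
    width at each scale; the dimension follows the Minkowski-Bouligand
    log-log law (cover area ~ s^(2-D)), estimated as 2 minus the
    least-squares slope of log A against log s over a sliding window of
    ``mfd_scale_window`` scales, clipped into [1, 2]. Constant stretches
    (zero cover area) are assigned the smooth-curve limit D = 1.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    S = config.mfd_max_scale
    n = len(x)
    if n < 2 * S:
        raise ValueError("sequence too short for the maximum scale")
    widths = morphological_cover_widths(x, S)

    # frame the boundary-unaffected region (samples with full +/-S support)
    lo, hi = S, n - S
    if hi - lo < 8:
        lo, hi = 0, n
    L, hop = config.mfd_frame_len, config.mfd_frame_hop
    if hi - lo <= L:
        starts = [lo]
        L = hi - lo
    else:
        starts = list(range(lo, hi - L + 1, hop))
    areas = np.stack([widths[:, s0 : s0 + L].sum(axis=1) for s0 in starts], axis=1)

    W = config.mfd_scale_window
    scales = np.arange(1, S + 1)
    n_windows = S - W + 1
    log_s = np.log(scales)
    # stacked sliding scale windows: (n_windows, W, n_frames)
    blocks = np.stack([areas[j : j + W] for j in range(n_windows)])
    degenerate = (blocks <= 0).any(axis=1)          # (n_windows, n_frames)
    with np.errstate(divide="ignore", invalid="ignore"):
        la = np.log(np.maximum(blocks, 1e-300))
    ls = np.stack([log_s[j : j + W] for j in range(n_windows)])
    ls_c = ls - ls.mean(axis=1, keepdims=True)      # (n_windows, W)
    denom = (ls_c**2).sum(axis=1)                   # (n_windows,)
    la_c = la - la.mean(axis=1, keepdims=True)
    slopes = np.einsum("jw,jwf->jf", ls_c, la_c) / denom[:, None]
    dims = 2.0 - slopes
    dims[degenerate] = 1.0                          # smooth/constant limit
    np.clip(dims, 1.0, 2.0, out=dims)
    return MFDProfile(scales=scales[:n_windows], dimensions=dims)


# ---------------------------------------------------------------------------
# Poincare and time encodings
# ---------------------------------------------------------------------------

def poincare_sd(rr) -> tuple:
    """(SD1, SD2): dispersion of the lag-1 return map perpendicular to and
    along the identity line.

    SD1 uses the uncentered RMS of successive differences (the classical
    SD1 = RMSSD / sqrt(2) identity holds exactly); SD2 is the population SD
    of the rotated along-identity coordinate.
    """
    rr = np.asarray(rr, dtype=float)
    if len(rr) < 3:
        raise ValueError("need at least 3 beats")
    d = (rr[1:] - rr[:-1]) / math.sqrt(2.0)
    s = (rr[1:] + rr[:-1]) / math.sqrt(2.0)
    return float(np.sqrt(np.mean(d * d))), float(s.std())


def time_of_day_trig(window_start: float) -> tuple:
    """sin/cos encoding of seconds-of-day over a 24 h period."""
    phase = 2.0 * math.pi * (window_start % 86400.0) / 86400.0
    return math.sin(phase), math.cos(phase)


# ---------------------------------------------------------------------------
# daily activity
# ---------------------------------------------------------------------------

def daily_activity(steps: pd.DataFrame, diary, recorded_hours: dict,
                   min_hours: float = 20.0) -> pd.DataFrame:
    """Per-day step totals and sleep/wake ratio over well-recorded days.

    ``steps`` has columns (day, steps); ``recorded_hours`` maps day index to
    hours of usable recording. Days with fewer than ``min_hours`` recorded
    hours are excluded. The sleep/wake ratio is slept hours divided by awake
    hours within the recorded time (NaN-flagged when no awake time remains).
    """
    rows = []
    day_steps = steps.groupby("day")["steps"].sum()
    for day, hours in sorted(recorded_hours.items()):
        if hours < min_hours:
            continue
        d0, d1 = day * 86400.0, (day + 1) * 86400.0
        slept = sum(max(0.0, min(e, d1) - max(s, d0)) for s, e in diary.episodes) / 3600.0
        slept = min(slept, hours)
        awake = hours - slept
        ratio = slept / awake if awake > 0 else float("nan")
        rows.append({"day": day, "steps": float(day_steps.get(day, 0.0)),
                     "sleep_wake_ratio": ratio, "recorded_hours": hours})
    return pd.DataFrame(rows, columns=["day", "steps", "sleep_wake_ratio", "recorded_hours"])


# ---------------------------------------------------------------------------
# per-interval assembly
# ---------------------------------------------------------------------------

def interval_features(window_start: float,
                      rr_window: RRWindow | None = None,
                      acc_window: MotionWindow | None = None,
                      gyr_window: MotionWindow | None = None,
                      state: str = "awake",
                      config: FeatureConfig = FeatureConfig(),
                      mode: str = "full") -> dict:
    """All descriptors of one 5-min slot; absent modalities yield NaN.

    ``mode="detection"`` computes only the 10 DayTensor features;
    ``mode="full"`` adds the nonlinear HRV descriptors used by the group
    statistics.
    """
    if rr_window is None and acc_window is None and gyr_window is None:
        raise ValueError("at least one modality must be present")
    sin_t, cos_t = time_of_day_trig(window_start)
    out = {name: float("nan") for name in set(DETECTION_FEATURES) | set(STAT_FEATURES)}
    out.update({"window_start": window_start, "state": state,
                "sin_t": sin_t, "cos_t": cos_t})

    if acc_window is not None:
        out["ste_acc"] = short_time_energy(acc_window.samples)
    if gyr_window is not None:
        out["ste_gyr"] = short_time_energy(gyr_window.samples)

    if rr_window is not None:
        rr = rr_window.rr
        out["rr_mean"] = float(rr.mean())
        out["hr_mean"] = float(np.mean(60000.0 / rr))
        out["pct_valid"] = rr_window.pct_valid
        sd1, sd2 = poincare_sd(rr)
        out["sd1"], out["sd2"] = sd1, sd2
        try:
            bp = band_powers(lomb_scargle(rr_window.beat_times, rr, config=config))
        except ValueError:
            bp = None
        if bp is not None:
            out["lf_pct"], out["hf_pct"], out["lf_hf_ratio"] = bp.lf_pct, bp.hf_pct, bp.ratio
        if mode == "full":
            out["sampen"] = sample_entropy(rr, config.sampen_m, config.sampen_r)
            try:
                out["higuchi"] = higuchi_fd(rr, config.higuchi_kmax)
                out.update(mfd_profile(rr, config).summaries())
            except ValueError:
                pass
    return out
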