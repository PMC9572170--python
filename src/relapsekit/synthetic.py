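"""Synthetic wearable cohort generator.

Produces controls and patients with multi-day raw sensor streams (triaxial
accelerometer/gyroscope at 20 Hz, a 5 Hz RR-interval readout, per-minute step
counts), sleep diaries, relapse annotations, and spectrogram-slice "interview
sessions", so that the whole preprocessing / feature / statistics / anomaly
detection stack can be exercised with known ground truth.

The generative model is deliberately the simplest one with the right
second-order structure:

* RR intervals follow ``baseline + LF sinusoid (0.1 Hz) + HF sinusoid
  (0.25 Hz) + AR(1) noise``, emitted by a 5 Hz readout that repeats the last
  beat value until the next beat (reproducing the duplicated-readout artifact
  a downstream cleaner must remove).
* Motion is a circadian-gated two-state (active/rest) bout process while the
  subject is awake, near-quiescent during sleep.
* Group differences are injected as standardized shifts on subject-level
  latent traits (see ``SUPPORTED_EFFECTS``); relapse windows (plus a milder
  linear prodrome ramp) shift the same latents by ``anomaly_magnitude``
  scaled by severity (low/moderate/severe -> 0.5/1.0/1.5).

All randomness flows from integer-seeded ``numpy.random.SeedSequence`` state,
so identical configurations give byte-identical output on any platform.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import _fast

__all__ = [
    "ArtifactRates",
    "CohortConfig",
    "RelapseSpec",
    "RelapseAnnotation",
    "SensorStream",
    "SleepDiary",
    "SubjectProfile",
    "SyntheticSession",
    "Cohort",
    "SubjectData",
    "make_profiles",
    "simulate_subject",
    "simulate_subject_day",
    "simulate_cohort",
    "simulate_sessions",
    "day_condition",
    "write_cohort",
]

DAY_SECONDS = 86_400
WINDOW_SECONDS = 300.0
ACC_RATE = 20.0
RR_READOUT_RATE = 5.0
STEPS_RATE = 1.0 / 60.0

SEVERITY_LEVELS = ("low", "moderate", "severe")
_SEVERITY_ALIASES = {"mid": "moderate"}
SEVERITY_MULTIPLIER = {"low": 0.5, "moderate": 1.0, "severe": 1.5}

#: Fraction of full relapse magnitude reached at relapse onset by the
#: linearly rising prodrome ramp.
PRODROME_PEAK_FRACTION = 0.5

# --- bout process constants (per-second two-state Markov chain) -------------
ACTIVE_MEAN_S = 15.0
REST_MEAN_S = 22.5
DUTY = ACTIVE_MEAN_S / (ACTIVE_MEAN_S + REST_MEAN_S)
#: Relative SD of the active-time fraction within one 5-min interval for the
#: default switching rates (a property of the Markov chain, measured once by
#: long simulation; used when inverting the STE-variability latent).
DUTY_CV = 0.283

REST_AMP_ACC = 0.15      # m/s^2 axis noise while awake but at rest
SLEEP_AMP_ACC = 0.05
GYR_OVER_ACC = 24.0      # deg/s per m/s^2 amplitude ratio for rest/sleep floors

#: Population distributions of subject-level latent traits, on the scale of
#: the downstream per-subject aggregate each one calibrates:
#: name -> (mean, sd, lower clip, upper clip).
POPULATION = {
    "ste_acc_mean": (6.5, 1.2, 2.0, 20.0),
    "ste_acc_std": (4.0, 1.0, 1.4, 12.0),
    "ste_gyr_mean": (4000.0, 900.0, 1000.0, 12000.0),
    "ste_gyr_std": (2500.0, 600.0, 900.0, 8000.0),
    "rr_mean": (850.0, 60.0, 500.0, 1400.0),
    "hr_mean": (71.0, 5.0, 45.0, 110.0),
    "sd1_mean": (30.0, 6.0, 8.0, 80.0),
    "lf_pct_mean": (31.0, 2.5, 5.0, 95.0),
    "sampen_mean": (0.80, 0.05, 0.50, 0.95),   # realized through the AR(1) phi
    "sino_total_amp": (35.0, 6.0, 10.0, 90.0),  # LF+HF sinusoid energy scale (ms)
    "sleep_onset_h": (23.5, 0.5, 21.5, 26.0),
    "sleep_duration_h": (8.0, 0.4, 6.0, 10.5),
    "step_rate_hz": (1.9, 0.15, 1.2, 2.6),
}

#: Feature handles accepted in ``CohortConfig.effect_sizes`` (standardized
#: subject-level shifts, patient minus control).
SUPPORTED_EFFECTS = (
    "ste_acc_mean", "ste_acc_std", "ste_gyr_mean", "ste_gyr_std",
    "rr_mean", "hr_mean", "sd1_mean", "lf_pct_mean", "sampen_mean",
)

#: Latent shifts applied per unit of effective relapse magnitude, in units of
#: the corresponding population SD (activity drops and becomes more erratic,
#: heart rate rises, short-term vagal variability falls, LF share rises).
RELAPSE_SHIFT_SD = {
    "ste_acc_mean": -0.6,
    "ste_acc_std": +0.6,
    "ste_gyr_mean": -0.6,
    "ste_gyr_std": +0.6,
    "rr_mean": -0.6,
    "sd1_mean": -0.4,
    "lf_pct_mean": +0.5,
}

RR_AR_PHI_DEFAULT = 0.80
LF_HZ = 0.10
HF_HZ = 0.25


def canonical_severity(severity: str) -> str:
    s = _SEVERITY_ALIASES.get(severity, severity)
    if s not in SEVERITY_LEVELS:
        raise ValueError(
            f"severity must be one of {SEVERITY_LEVELS} (or 'mid'), got {severity!r}"
        )
    return s


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelapseSpec:
    """One annotated relapse episode of one patient."""

    patient_index: int
    start_day: int
    duration_days: int
    severity: str = "moderate"
    psychotic: bool = False
    anomaly_magnitude: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "severity", canonical_severity(self.severity))
        if self.duration_days <= 0:
            raise ValueError("relapse duration_days must be positive")
        if self.start_day < 0:
            raise ValueError("relapse start_day must be >= 0")


@dataclass(frozen=True)
class ArtifactRates:
    """Sensor artifact rates.

    rr_outlier_rate : per-beat probability of an out-of-range RR value
    gap_rate        : expected fraction of recording time lost to readout gaps
    repeat_rate     : per-beat probability of a non-detected pulse (the 5 Hz
                      readout keeps repeating the previous beat value)
    """

    rr_outlier_rate: float = 0.005
    gap_rate: float = 0.0
    repeat_rate: float = 0.005

    def __post_init__(self):
        for name in ("rr_outlier_rate", "gap_rate", "repeat_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CohortConfig:
    n_controls: int
    n_patients: int
    days_per_subject: int
    effect_sizes: dict = field(default_factory=dict)
    relapses: tuple = ()
    prodrome_days: int = 21
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    seed: int = 0

    def __post_init__(self):
        if self.n_controls < 0 or self.n_patients < 0:
            raise ValueError("subject counts must be >= 0")
        if self.days_per_subject <= 0:
            raise ValueError("days_per_subject must be positive")
        if self.prodrome_days < 0:
            raise ValueError("prodrome_days must be >= 0")
        object.__setattr__(self, "relapses", tuple(self.relapses))
        for name in self.effect_sizes:
            if name not in SUPPORTED_EFFECTS:
                raise ValueError(
                    f"unsupported effect handle {name!r}; supported: {SUPPORTED_EFFECTS}"
                )
        if "rr_mean" in self.effect_sizes and "hr_mean" in self.effect_sizes:
            raise ValueError("specify at most one of rr_mean / hr_mean effects")
        for rel in self.relapses:
            if rel.patient_index < 0 or rel.patient_index >= self.n_patients:
                raise ValueError("relapse patient_index outside cohort")
            if rel.start_day + rel.duration_days > self.days_per_subject:
                raise ValueError("relapse window must lie within the simulated period")

    @property
    def n_subjects(self) -> int:
        return self.n_controls + self.n_patients


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass
class SensorStream:
    subject_id: str
    modality: str               # acc | gyr | rr | steps
    times: np.ndarray           # seconds since subject epoch (local midnight day 0)
    values: np.ndarray          # (N,3) for acc/gyr, (N,) otherwise
    nominal_rate: float


@dataclass
class SleepDiary:
    episodes: list              # list of (sleep_start_s, sleep_end_s), ordered

    def is_asleep(self, t: float) -> bool:
        for s, e in self.episodes:
            if s <= t < e:
                return True
        return False

    def sleep_mask(self, times: np.ndarray) -> np.ndarray:
        mask = np.zeros(len(times), dtype=bool)
        for s, e in self.episodes:
            mask |= (times >= s) & (times < e)
        return mask


@dataclass(frozen=True)
class RelapseAnnotation:
    patient_id: str
    start: float                # seconds since epoch
    end: float
    severity: str
    psychotic: bool
    anomaly_magnitude: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("relapse end must be after start")


@dataclass
class SyntheticSession:
    patient_id: str
    session_date: float         # day index (may be fractional)
    state: str                  # clean | pre_relapse | relapse
    slices: np.ndarray          # (n_slices, 128, 64), non-negative


@dataclass
class SubjectProfile:
    subject_id: str
    group: str                  # control | patient
    patient_index: int          # -1 for controls
    latents: dict               # latent trait name -> value (aggregate scale)
    seed_key: tuple


@dataclass
class SubjectData:
    profile: SubjectProfile
    streams: list
    diary: SleepDiary
    annotations: list


@dataclass
class Cohort:
    config: CohortConfig
    subjects: dict              # subject_id -> SubjectData
    manifest: dict


# ---------------------------------------------------------------------------
# latent traits and their realization as generator parameters
# ---------------------------------------------------------------------------

def _solve_amp_modulation(L: float, S: float) -> tuple:
    """Invert (mean, std) STE latents into the bout amplitude and the per-
    interval energy-modulation width.

    Per awake interval the short-time energy is approximately
    ``3 a^2 * duty_k * q_k`` where ``duty_k`` is the realized active
    fraction and ``q_k = max(1 + w e_k, 0.05)`` (``e_k ~ N(0,1)``) modulates
    the bout energy; its relative variance is approximately
    ``DUTY_CV^2 + w^2``, so ``w = sqrt((S/L)^2 - DUTY_CV^2)``.
    """
    w = math.sqrt(max((S / L) ** 2 - DUTY_CV**2, 1e-6))
    w = min(w, 1.2)
    amp = math.sqrt(L / (3.0 * DUTY))
    return amp, w


def _derived_params(latents: dict) -> dict:
    """Map latent traits to the raw generator parameters of one subject."""
    p = {}
    p["acc_amp"], p["acc_mod"] = _solve_amp_modulation(
        latents["ste_acc_mean"], latents["ste_acc_std"]
    )
    p["gyr_amp"], p["gyr_mod"] = _solve_amp_modulation(
        latents["ste_gyr_mean"], latents["ste_gyr_std"]
    )
    if "hr_latent" in latents:
        p["baseline_rr"] = 60000.0 / latents["hr_latent"]
    else:
        p["baseline_rr"] = latents["rr_mean"]
    if not 300.0 <= p["baseline_rr"] <= 2000.0:
        raise ValueError("baseline RR outside the physiological [300, 2000] ms range")
    p["phi"] = latents["sampen_mean"]
    p["rr_noise_sd"] = latents["sd1_mean"] * math.sqrt(1.0 + p["phi"])
    share = min(max(latents["lf_pct_mean"] / 100.0, 0.02), 0.98)
    total = latents["sino_total_amp"]
    p["lf_amp"] = total * math.sqrt(share)
    p["hf_amp"] = total * math.sqrt(1.0 - share)
    p["sleep_onset_s"] = latents["sleep_onset_h"] * 3600.0
    p["sleep_duration_s"] = latents["sleep_duration_h"] * 3600.0
    p["step_rate"] = latents["step_rate_hz"]
    return p


def make_profiles(config: CohortConfig) -> list:
    """Draw subject profiles; groups differ only through ``effect_sizes``."""
    profiles = []
    use_hr = "hr_mean" in config.effect_sizes
    for i in range(config.n_subjects):
        is_patient = i >= config.n_controls
        group = "patient" if is_patient else "control"
        pidx = i - config.n_controls if is_patient else -1
        sid = f"{'P' if is_patient else 'C'}{(pidx if is_patient else i):03d}"
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1, i)))
        latents = {}
        for name, (mu, sd, lo, hi) in POPULATION.items():
            delta = config.effect_sizes.get(name, 0.0) if is_patient else 0.0
            latents[name] = float(np.clip(mu + sd * (rng.standard_normal() + delta), lo, hi))
        if use_hr:
            latents["hr_latent"] = latents["hr_mean"]
        profiles.append(SubjectProfile(sid, group, pidx, latents, (config.seed, i)))
    ids = [p.subject_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    return profiles


# ---------------------------------------------------------------------------
# relapse calendar
# ---------------------------------------------------------------------------

def subject_relapses(profile: SubjectProfile, config: CohortConfig) -> list:
    if profile.group != "patient":
        return []
    out = []
    for rel in config.relapses:
        if rel.patient_index == profile.patient_index:
            out.append(
                RelapseAnnotation(
                    patient_id=profile.subject_id,
                    start=rel.start_day * DAY_SECONDS,
                    end=(rel.start_day + rel.duration_days) * DAY_SECONDS,
                    severity=rel.severity,
                    psychotic=rel.psychotic,
                    anomaly_magnitude=rel.anomaly_magnitude,
                )
            )
    return sorted(out, key=lambda a: a.start)


def day_condition(annotations: list, day: int, prodrome_days: int) -> tuple:
    """Classify one subject-local day and return its effective magnitude.

    Returns ``(label, m_eff)`` with label in {normal, near_relapse, relapse}.
    Inside a relapse window the effective magnitude is
    ``anomaly_magnitude * severity multiplier``; during the ``prodrome_days``
    preceding onset it ramps linearly from 0 up to
    ``PRODROME_PEAK_FRACTION`` of that value.
    """
    d0, d1 = day * DAY_SECONDS, (day + 1) * DAY_SECONDS
    for ann in annotations:
        if ann.start < d1 and d0 < ann.end:
            m = ann.anomaly_magnitude * SEVERITY_MULTIPLIER[ann.severity]
            return "relapse", m
    best = None
    for ann in annotations:
        start_day = ann.start / DAY_SECONDS
        days_until = start_day - day
        if 0 < days_until <= prodrome_days:
            m_full = ann.anomaly_magnitude * SEVERITY_MULTIPLIER[ann.severity]
            ramp = PRODROME_PEAK_FRACTION * (1.0 - (days_until - 1) / max(prodrome_days, 1))
            m = m_full * ramp
            best = max(best or 0.0, m)
    if best is not None:
        return "near_relapse", best
    return "normal", 0.0


def _shifted_latents(latents: dict, m_eff: float) -> dict:
    if m_eff == 0.0:
        return latents
    out = dict(latents)
    for name, gain in RELAPSE_SHIFT_SD.items():
        mu, sd, lo, hi = POPULATION[name]
        out[name] = float(np.clip(out[name] + gain * sd * m_eff, lo, hi))
    if "hr_latent" in out:
        mu, sd, lo, hi = POPULATION["hr_mean"]
        out["hr_latent"] = float(np.clip(out["hr_latent"] + 0.6 * sd * m_eff, lo, hi))
    return out


# ---------------------------------------------------------------------------
# one-day stream synthesis
# ---------------------------------------------------------------------------

def _sleep_episode_for_day(profile, day: int, rng) -> tuple:
    """Sleep episode whose onset falls on `day` (possibly crossing midnight)."""
    par = _derived_params(profile.latents)
    onset = day * DAY_SECONDS + par["sleep_onset_s"] + rng.normal(0.0, 900.0)
    dur = max(4 * 3600.0, par["sleep_duration_s"] + rng.normal(0.0, 900.0))
    return (onset, onset + dur)


def build_diary(profile: SubjectProfile, config: CohortConfig) -> SleepDiary:
    episodes = []
    for day in range(-1, config.days_per_subject):
        rng = np.random.default_rng(
            np.random.SeedSequence(profile.seed_key[0], spawn_key=(2, profile.seed_key[1], day + 1))
        )
        ep = _sleep_episode_for_day(profile, day, rng)
        if episodes and ep[0] < episodes[-1][1]:
            ep = (episodes[-1][1] + 600.0, max(ep[1], episodes[-1][1] + 4 * 3600.0))
        episodes.append(ep)
    # clip to the simulated period
    horizon = config.days_per_subject * DAY_SECONDS
    clipped = [(max(s, 0.0), min(e, horizon)) for s, e in episodes if e > 0 and s < horizon]
    return SleepDiary(episodes=clipped)


def _bout_states(n_seconds: int, awake: np.ndarray, rng) -> np.ndarray:
    """Two-state (0 rest / 1 active) per-second bout chain, forced to rest
    during sleep."""
    p_on = 1.0 / REST_MEAN_S
    p_off = 1.0 / ACTIVE_MEAN_S
    u = rng.random(n_seconds)
    return _fast.bout_chain(u, np.ascontiguousarray(awake), p_on, p_off)


def _gap_mask(times: np.ndarray, gap_rate: float, rng) -> np.ndarray:
    """True for samples removed by readout gaps (mean gap length 60 s)."""
    keep_gap = np.zeros(len(times), dtype=bool)
    if gap_rate <= 0 or len(times) == 0:
        return keep_gap
    span = times[-1] - times[0] + 1.0
    n_gaps = rng.poisson(gap_rate * span / 60.0)
    for _ in range(n_gaps):
        start = times[0] + rng.random() * span
        dur = rng.exponential(60.0)
        keep_gap |= (times >= start) & (times < start + dur)
    return keep_gap


def _apply_beat_artifacts(beat_t, beat_rr, artifact_rates, rng):
    """Inject out-of-range RR outliers and drop non-detected pulses."""
    n = len(beat_rr)
    if artifact_rates.rr_outlier_rate > 0 and n:
        out_mask = rng.random(n) < artifact_rates.rr_outlier_rate
        n_out = int(out_mask.sum())
        if n_out:
            low = rng.random(n_out) < 0.5
            vals = np.where(
                low,
                rng.uniform(60.0, 295.0, n_out),
                rng.uniform(2050.0, 3200.0, n_out),
            )
            beat_rr = beat_rr.copy()
            beat_rr[out_mask] = vals
    if artifact_rates.repeat_rate > 0 and n > 2:
        miss = rng.random(n) < artifact_rates.repeat_rate
        miss[0] = False
        keep = ~miss
        beat_t, beat_rr = beat_t[keep], beat_rr[keep]
    return beat_t, beat_rr


def simulate_interval(profile: SubjectProfile, config: CohortConfig,
                      state: str = "awake", m_eff: float = 0.0,
                      rng: np.random.Generator | None = None) -> dict:
    """Simulate one standalone 5-min interval (beats + motion windows).

    A window-level shortcut for statistical calibration work: the interval
    is drawn from the same stationary generative model as the corresponding
    state within a full day, without synthesizing the surrounding day.
    Returns beat times/values (artifact-injected) and (6000, 3) motion
    arrays for both modalities.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    latents = _shifted_latents(profile.latents, m_eff)
    params = _derived_params(latents)
    n_sec = int(WINDOW_SECONDS)
    asleep = state == "sleep"
    awake = np.full(n_sec, not asleep)
    states = _bout_states(n_sec, awake, rng) if not asleep \
        else np.zeros(n_sec, dtype=np.int8)

    def motion(modality):
        amp = params["acc_amp"] if modality == "acc" else params["gyr_amp"]
        mod = params["acc_mod"] if modality == "acc" else params["gyr_mod"]
        scale = GYR_OVER_ACC if modality == "gyr" else 1.0
        factor = float(_interval_amp_factors(1, mod, rng)[0])
        sec_amp = np.where(states == 1, amp * factor,
                           (REST_AMP_ACC if not asleep else SLEEP_AMP_ACC) * scale)
        per_sample = np.repeat(sec_amp.astype(np.float32), int(ACC_RATE))
        return rng.standard_normal((per_sample.size, 3),
                                   dtype=np.float32) * per_sample[:, None]

    acc_v = motion("acc")
    gyr_v = motion("gyr")

    base = params["baseline_rr"]
    sig_e = params["rr_noise_sd"] * math.sqrt(1.0 - params["phi"] ** 2)
    est = int(n_sec / (base / 1000.0) * 1.3) + 16
    beat_t = np.empty(est)
    beat_rr = np.empty(est)
    noise = rng.standard_normal(est) * sig_e
    n = _fast.rr_beat_loop(0.0, float(n_sec), base,
                           np.full(n_sec, asleep, dtype=bool),
                           params["lf_amp"], params["hf_amp"],
                           rng.random() * 2 * math.pi, rng.random() * 2 * math.pi,
                           params["phi"], noise, beat_t, beat_rr)
    beat_t, beat_rr = _apply_beat_artifacts(beat_t[:n], beat_rr[:n],
                                            config.artifact_rates, rng)
    return {"beats": (beat_t, beat_rr), "acc": acc_v, "gyr": gyr_v,
            "state": state}


def _simulate_rr_day(params, day, asleep_sec, artifact_rates, rng):
    """Beat-level RR sequence for one day plus its 5 Hz repeated readout."""
    t0, t1 = day * DAY_SECONDS, (day + 1) * DAY_SECONDS
    base, phi = params["baseline_rr"], params["phi"]
    sig_e = params["rr_noise_sd"] * math.sqrt(1.0 - phi * phi)
    ph1 = rng.random() * 2 * math.pi
    ph2 = rng.random() * 2 * math.pi

    est = int((t1 - t0) / (base / 1000.0) * 1.3) + 16
    beat_t = np.empty(est)
    beat_rr = np.empty(est)
    noise = rng.standard_normal(est) * sig_e
    n = _fast.rr_beat_loop(
        float(t0), float(t1), float(base), np.ascontiguousarray(asleep_sec),
        float(params["lf_amp"]), float(params["hf_amp"]), float(ph1), float(ph2),
        float(phi), noise, beat_t, beat_rr,
    )
    beat_t, beat_rr = beat_t[:n], beat_rr[:n]
    beat_t, beat_rr = _apply_beat_artifacts(beat_t, beat_rr, artifact_rates, rng)

    # 5 Hz readout repeating the latest beat value
    ro_t = np.arange(math.ceil(t0 * 5), math.floor(t1 * 5)) / 5.0
    ro_t = ro_t[ro_t >= beat_t[0]] if len(beat_t) else ro_t[:0]
    idx = np.searchsorted(beat_t, ro_t, side="right") - 1
    ro_rr = beat_rr[idx] if len(beat_t) else np.empty(0)
    gap = _gap_mask(ro_t, artifact_rates.gap_rate, rng)
    return beat_t, beat_rr, ro_t[~gap], ro_rr[~gap]


def _interval_amp_factors(n_intervals: int, mod: float, rng) -> np.ndarray:
    """Per-5-min-interval bout *amplitude* factors realizing the energy
    modulation ``q = max(1 + w e, 0.05)`` (energy scales with the square of
    the returned amplitude factor)."""
    e = np.clip(rng.standard_normal(n_intervals), -3.0, 3.0)
    return np.sqrt(np.maximum(1.0 + mod * e, 0.05))


def _simulate_motion_day(params, day, awake, states, modality, artifact_rates, rng):
    """20 Hz triaxial stream for one day (array form, gaps removed)."""
    t0 = day * DAY_SECONDS
    amp = params["acc_amp"] if modality == "acc" else params["gyr_amp"]
    mod = params["acc_mod"] if modality == "acc" else params["gyr_mod"]
    rest_amp = REST_AMP_ACC * (GYR_OVER_ACC if modality == "gyr" else 1.0)
    sleep_amp = SLEEP_AMP_ACC * (GYR_OVER_ACC if modality == "gyr" else 1.0)

    n_int = DAY_SECONDS // 300
    factors = _interval_amp_factors(n_int, mod, rng)
    sec_idx = np.arange(DAY_SECONDS)
    sec_amp = np.where(
        states == 1,
        amp * factors[sec_idx // 300],
        np.where(awake, rest_amp, sleep_amp),
    )
    per_sample_amp = np.repeat(sec_amp.astype(np.float32), int(ACC_RATE))
    n = per_sample_amp.size
    values = rng.standard_normal((n, 3), dtype=np.float32) * per_sample_amp[:, None]
    times = t0 + np.arange(n) / ACC_RATE
    gap = _gap_mask(times, artifact_rates.gap_rate, rng)
    return times[~gap], values[~gap]


def _simulate_steps_day(params, day, states, rng):
    t0 = day * DAY_SECONDS
    active_per_min = states.reshape(-1, 60).sum(axis=1)
    counts = rng.poisson(params["step_rate"] * active_per_min).astype(float)
    times = t0 + np.arange(len(counts)) * 60.0
    return times, counts


def simulate_subject_day(profile: SubjectProfile, config: CohortConfig, day: int,
                         diary: SleepDiary | None = None,
                         annotations: list | None = None) -> dict:
    """Simulate one subject-local day; returns a dict of SensorStreams plus
    the day label and effective relapse magnitude."""
    if diary is None:
        diary = build_diary(profile, config)
    if annotations is None:
        annotations = subject_relapses(profile, config)
    label, m_eff = day_condition(annotations, day, config.prodrome_days)
    latents = _shifted_latents(profile.latents, m_eff)
    params = _derived_params(latents)

    rng = np.random.default_rng(
        np.random.SeedSequence(profile.seed_key[0], spawn_key=(3, profile.seed_key[1], day))
    )
    t0 = day * DAY_SECONDS
    sec_times = t0 + np.arange(DAY_SECONDS, dtype=float)
    awake = ~diary.sleep_mask(sec_times)
    states = _bout_states(DAY_SECONDS, awake, rng)

    acc_t, acc_v = _simulate_motion_day(params, day, awake, states, "acc",
                                        config.artifact_rates, rng)
    gyr_t, gyr_v = _simulate_motion_day(params, day, awake, states, "gyr",
                                        config.artifact_rates, rng)
    beat_t, beat_rr, ro_t, ro_rr = _simulate_rr_day(params, day, ~awake,
                                                    config.artifact_rates, rng)
    st_t, st_v = _simulate_steps_day(params, day, states, rng)

    sid = profile.subject_id
    return {
        "acc": SensorStream(sid, "acc", acc_t, acc_v, ACC_RATE),
        "gyr": SensorStream(sid, "gyr", gyr_t, gyr_v, ACC_RATE),
        "rr": SensorStream(sid, "rr", ro_t, ro_rr, RR_READOUT_RATE),
        "steps": SensorStream(sid, "steps", st_t, st_v, STEPS_RATE),
        "beats": (beat_t, beat_rr),
        "label": label,
        "m_eff": m_eff,
    }


def simulate_subject(profile: SubjectProfile, config: CohortConfig):
    """Full-period streams for one subject.

    Returns ``(streams, diary, annotations)``; ``streams`` is a list of four
    SensorStreams (acc, gyr, rr, steps) concatenated over all days. For large
    cohorts prefer iterating :func:`simulate_subject_day`.
    """
    diary = build_diary(profile, config)
    annotations = subject_relapses(profile, config)
    parts = {m: [] for m in ("acc", "gyr", "rr", "steps")}
    for day in range(config.days_per_subject):
        bundle = simulate_subject_day(profile, config, day, diary, annotations)
        for m in parts:
            parts[m].append(bundle[m])
    streams = []
    for m, chunks in parts.items():
        times = np.concatenate([c.times for c in chunks])
        values = np.concatenate([c.values for c in chunks])
        streams.append(SensorStream(profile.subject_id, m, times, values,
                                    chunks[0].nominal_rate))
    return streams, diary, annotations


def simulate_cohort(config: CohortConfig) -> Cohort:
    profiles = make_profiles(config)
    subjects = {}
    calendar = {}
    for prof in profiles:
        streams, diary, annotations = simulate_subject(prof, config)
        subjects[prof.subject_id] = SubjectData(prof, streams, diary, annotations)
        calendar[prof.subject_id] = [
            {"start_day": a.start / DAY_SECONDS, "end_day": a.end / DAY_SECONDS,
             "severity": a.severity, "psychotic": a.psychotic,
             "anomaly_magnitude": a.anomaly_magnitude}
            for a in annotations
        ]
    manifest = {
        "seed": config.seed,
        "days_per_subject": config.days_per_subject,
        "prodrome_days": config.prodrome_days,
        "groups": {p.subject_id: p.group for p in profiles},
        "relapse_calendar": calendar,
        "n_subject_days": config.n_subjects * config.days_per_subject,
    }
    return Cohort(config, subjects, manifest)


# ---------------------------------------------------------------------------
# synthetic interview sessions (spectrogram-slice domain)
# ---------------------------------------------------------------------------

SESSION_PRE_RELAPSE_DAYS = 30
_N_TEMPLATES = 8
_SLICE_SHAPE = (128, 64)


def _session_state(day: float, annotations: list) -> tuple:
    """Apply the 30-day pre-relapse rule to a session date (day units)."""
    t = day * DAY_SECONDS
    for ann in annotations:
        if ann.start <= t < ann.end:
            return "relapse", ann
    for ann in annotations:
        until = (ann.start - t) / DAY_SECONDS
        if 0 < until <= SESSION_PRE_RELAPSE_DAYS:
            return "pre_relapse", ann
    return "clean", None


def _patient_voice_model(patient_id: str):
    """Patient-specific rank-8 spectral template bank (deterministic)."""
    key = zlib.crc32(patient_id.encode("utf8"))
    rng = np.random.default_rng(np.random.SeedSequence(key, spawn_key=(11,)))
    f = np.arange(_SLICE_SHAPE[0])
    templates = np.empty((_N_TEMPLATES, _SLICE_SHAPE[0]))
    for k in range(_N_TEMPLATES):
        center = rng.uniform(5, 120)
        width = rng.uniform(4, 25)
        templates[k] = np.exp(-0.5 * ((f - center) / width) ** 2)
    w_mean = rng.uniform(5.0, 15.0, _N_TEMPLATES)
    shift_dir = rng.standard_normal(_N_TEMPLATES)
    shift_dir /= np.linalg.norm(shift_dir)
    return templates, w_mean, shift_dir


def _render_slices(n_slices, templates, w_mean, noise_sd, rng):
    T = _SLICE_SHAPE[1]
    out = np.empty((n_slices,) + _SLICE_SHAPE)
    for i in range(n_slices):
        # AR(1) positive weights across the 64 frames
        w = np.empty((_N_TEMPLATES, T))
        w[:, 0] = w_mean + rng.standard_normal(_N_TEMPLATES)
        for t in range(1, T):
            w[:, t] = w_mean + 0.9 * (w[:, t - 1] - w_mean) \
                + math.sqrt(1 - 0.81) * rng.standard_normal(_N_TEMPLATES)
        spec = 20.0 + templates.T @ np.maximum(w, 0.0)
        spec = spec + rng.standard_normal(_SLICE_SHAPE) * noise_sd
        out[i] = np.maximum(spec, 0.0)
    return out


def simulate_sessions(patient_id: str, annotations: list, n_sessions: int,
                      anomaly_magnitude: float, seed: int,
                      period_days: float | None = None,
                      mean_slices: float = 30.0) -> list:
    """Synthesize interview sessions as stacks of 128x64 log-mel-like slices.

    Clean slices come from a patient-specific low-rank Gaussian model
    (rank-8 spectral templates plus noise); during pre-relapse/relapse the
    template mixture mean and the noise floor are perturbed proportionally to
    ``anomaly_magnitude`` (scaled by relapse severity, pre-relapse at 60%).
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if period_days is None:
        last = max((a.end / DAY_SECONDS for a in annotations), default=30.0)
        period_days = max(60.0, last + SESSION_PRE_RELAPSE_DAYS)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(21,)))
    templates, w_mean, shift_dir = _patient_voice_model(patient_id)
    dates = np.sort(rng.uniform(0.0, period_days, n_sessions))
    sessions = []
    for date in dates:
        state, ann = _session_state(float(date), annotations)
        if state == "clean":
            m_eff = 0.0
        else:
            m_eff = anomaly_magnitude * SEVERITY_MULTIPLIER[ann.severity]
            if state == "pre_relapse":
                m_eff *= 0.6
        wm = w_mean * (1.0 + 0.25 * m_eff) + shift_dir * (1.5 * m_eff)
        noise_sd = 1.0 * (1.0 + 0.3 * m_eff)
        n_slices = max(1, int(rng.poisson(mean_slices)))
        slices = _render_slices(n_slices, templates, wm, noise_sd, rng)
        sessions.append(SyntheticSession(patient_id, float(date), state, slices))
    return sessions


# ---------------------------------------------------------------------------
# on-disk format (one CSV per subject per modality + JSON sidecars)
# ---------------------------------------------------------------------------

def write_sessions(sessions: list, outdir) -> None:
    """Write interview sessions as one .npz per session plus a JSON index."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    index = []
    for i, s in enumerate(sessions):
        name = f"{s.patient_id}_session{i:03d}.npz"
        np.savez(out / name, slices=s.slices)
        index.append({"file": name, "patient_id": s.patient_id,
                      "session_date": s.session_date, "state": s.state,
                      "n_slices": int(len(s.slices))})
    with open(out / "sessions_index.json", "w") as fh:
        json.dump(index, fh, indent=2)


def read_subject_streams(datadir, subject_id: str) -> dict:
    """Load one subject's modality CSVs back into SensorStreams."""
    datadir = Path(datadir)
    out = {}
    for modality, rate in (("acc", ACC_RATE), ("gyr", ACC_RATE),
                           ("rr", RR_READOUT_RATE), ("steps", STEPS_RATE)):
        path = datadir / f"{subject_id}_{modality}.csv"
        if not path.exists():
            continue
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        times = data[:, 0]
        values = data[:, 1:4] if modality in ("acc", "gyr") else data[:, 1]
        out[modality] = SensorStream(subject_id, modality, times, values, rate)
    return out


def read_cohort_manifest(datadir) -> dict:
    with open(Path(datadir) / "cohort_manifest.json") as fh:
        return json.load(fh)


def read_sleep_diary(datadir, subject_id: str) -> SleepDiary:
    with open(Path(datadir) / f"{subject_id}_sleep.json") as fh:
        episodes = json.load(fh)["episodes"]
    return SleepDiary(episodes=[tuple(ep) for ep in episodes])


def write_cohort(cohort: Cohort, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, sub in cohort.subjects.items():
        for stream in sub.streams:
            path = out / f"{sid}_{stream.modality}.csv"
            if stream.modality in ("acc", "gyr"):
                header, data = "t_sec,x,y,z", np.column_stack([stream.times, stream.values])
            elif stream.modality == "rr":
                hr = 60000.0 / np.maximum(stream.values, 1e-9)
                header, data = "t_sec,rr_ms,hr_bpm", np.column_stack(
                    [stream.times, stream.values, hr])
            else:
                header, data = "t_sec,steps", np.column_stack([stream.times, stream.values])
            np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.6f")
        with open(out / f"{sid}_sleep.json", "w") as fh:
            json.dump({"episodes": [[float(s), float(e)] for s, e in sub.diary.episodes]}, fh)
    with open(out / "cohort_manifest.json", "w") as fh:
        json.dump(cohort.manifest, fh, indent=2)
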