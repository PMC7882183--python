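"""Synthetic cohort and raw-recording generator.

Emulates a small post-stroke cohort instrumented with bilateral transcranial
Doppler during a seated exercise bout: 90 s of rest followed by 6 min of
moderate-intensity exercise, recorded continuously at a nominal 500 Hz.
Every subject carries a known ground truth (resting MCAv and the true
cerebrovascular response, CVR, per hemisphere), so the downstream
preprocessing and statistics can be validated by parameter recovery.

The exercise rise in cycle-mean MCAv is mono-exponential with a short onset
delay.  Ground-truth CVR is *defined* as the noise-free mean increment over
the steady-state analysis window [180, 270) s, and the exponential amplitude
is scaled so that this window mean equals the drawn CVR exactly — making
recovery checks independent of the kinetic shape.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ConfigurationError

HEMISPHERES = ("stroke_affected", "non_affected")

__all__ = [
    "HEMISPHERES",
    "SubjectProfile",
    "SynthParams",
    "GroundTruth",
    "AcquisitionRecording",
    "simulate_cohort",
    "simulate_recording",
    "inject_artifacts",
    "steady_state_window_factor",
    "substream",
]


def substream(seed: int, *tokens) -> np.random.Generator:
    """Derive an independent RNG from a root seed and a path of string tokens.

    Stable hashing (BLAKE2b) of ``seed|token|token...`` means editing one
    subject or adding a bout never reshuffles the draws of any other
    subject/bout.
    """
    key = "|".join([str(seed), *map(str, tokens)]).encode()
    digest = hashlib.blake2b(key, digest_size=8).digest()
    return np.random.default_rng(int.from_bytes(digest, "big"))


@dataclass(frozen=True)
class SubjectProfile:
    """Demographics and clinical flags driving grouping and prescription."""

    subject_id: str
    age: int                      # years, > 17
    sex: str                      # "male" | "female"
    hba1c: float                  # percent glycated hemoglobin
    beta_blocker: bool
    resting_hr: float             # beats/min
    t2dm: bool
    stroke_side: str              # "left" | "right"
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.age <= 17:
            raise ConfigurationError(f"{self.subject_id}: age must exceed 17")
        if not (3.0 <= self.hba1c <= 20.0):
            raise ConfigurationError(f"{self.subject_id}: HbA1c out of range")
        if not (30.0 <= self.resting_hr <= 120.0):
            raise ConfigurationError(f"{self.subject_id}: resting HR out of range")
        if self.sex not in ("male", "female"):
            raise ConfigurationError(f"{self.subject_id}: bad sex label")
        if self.stroke_side not in ("left", "right"):
            raise ConfigurationError(f"{self.subject_id}: bad stroke side")


@dataclass
class SynthParams:
    """Generator configuration.

    Group CVR distributions default to the study conditions this package
    targets: stroke-affected CVR 6.8 +/- 5.0 cm/s in the controlled-glycemia
    group (HbA1c < 7%) vs 0.9 +/- 3.7 cm/s under chronic hyperglycemia, with
    non-affected-side analogues 7.7 +/- 5.7 and 0.1 +/- 3.8 cm/s.
    """

    n_low: int = 13               # HbA1c < 7% group size
    n_high: int = 6               # HbA1c > 7% group size
    rest_mcav_mean: float = 55.0  # cm/s, per hemisphere
    rest_mcav_sd: float = 15.0
    # stroke-affected hemisphere CVR (cm/s)
    cvr_mean_low: float = 6.8
    cvr_sd_low: float = 5.0
    cvr_mean_high: float = 0.9
    cvr_sd_high: float = 3.7
    # non-affected hemisphere CVR (cm/s)
    cvr_mean_low_na: float = 7.7
    cvr_sd_low_na: float = 5.7
    cvr_mean_high_na: float = 0.1
    cvr_sd_high_na: float = 3.8
    hemi_corr: float = 0.7        # between-hemisphere correlation of subject effects
    tau: float = 30.0             # s, exponential time constant of the onset rise
    time_delay: float = 5.0       # s, delay before the rise starts
    pulsatility_amp: float = 20.0 # cm/s, systolic excursion above the cycle mean
    noise_sd: float = 2.0         # cm/s, additive white noise on velocity samples
    artifact_spike_rate: float = 0.0   # events/min
    artifact_spike_mag: float = 15.0   # cm/s, must exceed the 10 cm/s jump rule
    short_rr_rate: float = 0.0         # events/min
    n_bouts: int = 2
    seed: int = 0
    duration: float = 450.0       # s (90 rest + 360 exercise)
    sample_rate: float = 500.0    # Hz
    exercise_onset: float = 90.0  # s
    steady_state_window: tuple = (180.0, 270.0)  # s, defines ground-truth CVR

    def violations(self) -> list:
        v = []
        if self.n_low < 1:
            v.append("n_low: group size must be positive")
        if self.n_high < 1:
            v.append("n_high: group size must be positive")
        for name in ("rest_mcav_sd", "cvr_sd_low", "cvr_sd_high",
                     "cvr_sd_low_na", "cvr_sd_high_na", "noise_sd"):
            if getattr(self, name) < 0:
                v.append(f"{name}: SD must be >= 0")
        if self.artifact_spike_mag <= 10.0:
            v.append("artifact_spike_mag: must exceed 10 cm/s to trip the jump rule")
        if self.tau <= 0:
            v.append("tau: time constant must be positive")
        if self.artifact_spike_rate < 0 or self.short_rr_rate < 0:
            v.append("artifact rates must be >= 0")
        if self.n_bouts < 1:
            v.append("n_bouts: must be >= 1")
        if self.duration < 270.0:
            v.append("duration: steady-state window undefined below 270 s")
        if not (-1.0 < self.hemi_corr < 1.0):
            v.append("hemi_corr: must lie in (-1, 1)")
        if self.sample_rate <= 0:
            v.append("sample_rate: must be positive")
        w0, w1 = self.steady_state_window
        if not (self.exercise_onset + self.time_delay < w0 < w1 <= self.duration):
            v.append("steady_state_window: must follow exercise onset + delay and fit the recording")
        return v

    def validate(self) -> "SynthParams":
        v = self.violations()
        if v:
            raise ConfigurationError("; ".join(v))
        return self


@dataclass
class GroundTruth:
    """Per-subject truth for recovery tests: noise-free rest and CVR per hemisphere."""

    subject_id: str
    rest: dict                    # hemisphere -> cm/s
    cvr: dict                     # hemisphere -> cm/s (steady-state-window mean increment)
    artifact_log: list = field(default_factory=list)  # (bout, time s, kind)


@dataclass
class AcquisitionRecording:
    """One bout's raw multichannel time series with beat-onset markers."""

    subject_id: str
    sample_rate: float
    duration: float
    mcav: dict                    # hemisphere -> np.ndarray of velocity samples (cm/s)
    map_mmhg: np.ndarray
    petco2_mmhg: np.ndarray
    beat_onsets: np.ndarray       # strictly increasing times (s)
    bout_index: int = 0
    visit: str = "3mo"

    @property
    def time(self) -> np.ndarray:
        n = len(self.map_mmhg)
        return np.arange(n) / self.sample_rate

    def channel(self, hemisphere: str) -> np.ndarray:
        return self.mcav[hemisphere]


# ---------------------------------------------------------------------------
# cohort

_GROUPS = {
    # group -> (hba1c range, age mean/sd, p(male), bmi mean/sd, p(smoker),
    #           p(hypertension), p(t2dm))
    "low": ((5.0, 6.8), (59.2, 12.3), 8 / 13, (30.6, 6.2), 5 / 13, 10 / 13, 4 / 13),
    "high": ((7.2, 11.0), (69.8, 17.4), 4 / 6, (27.1, 2.0), 1 / 6, 6 / 6, 0.9),
}


def _correlated_pair(rng, mean1, sd1, mean2, sd2, corr):
    z0, z1 = rng.standard_normal(2)
    x1 = mean1 + sd1 * z0
    x2 = mean2 + sd2 * (corr * z0 + math.sqrt(1.0 - corr ** 2) * z1)
    return x1, x2


def simulate_cohort(params: SynthParams) -> list:
    """Draw ``n_low + n_high`` subjects with ground truth.

    Returns a list of ``(SubjectProfile, GroundTruth)`` ordered low group
    first.  Deterministic given ``params.seed``; each subject consumes an
    independent RNG substream keyed by its id.
    """
    params.validate()
    out = []
    idx = 0
    for group, n in (("low", params.n_low), ("high", params.n_high)):
        (a1c_lo, a1c_hi), (age_m, age_s), p_male, (bmi_m, bmi_s), p_smoke, p_htn, p_t2dm = _GROUPS[group]
        if group == "low":
            cvr_aff = (params.cvr_mean_low, params.cvr_sd_low)
            cvr_na = (params.cvr_mean_low_na, params.cvr_sd_low_na)
        else:
            cvr_aff = (params.cvr_mean_high, params.cvr_sd_high)
            cvr_na = (params.cvr_mean_high_na, params.cvr_sd_high_na)
        for _ in range(n):
            sid = f"S{idx:03d}"
            rng = substream(params.seed, sid, "profile")
            age = int(np.clip(round(rng.normal(age_m, age_s)), 18, 95))
            hba1c = float(rng.uniform(a1c_lo, a1c_hi))
            profile = SubjectProfile(
                subject_id=sid,
                age=age,
                sex="male" if rng.random() < p_male else "female",
                hba1c=hba1c,
                beta_blocker=bool(rng.random() < 0.3),
                resting_hr=float(np.clip(rng.normal(70.0, 10.0), 45.0, 100.0)),
                t2dm=bool(rng.random() < p_t2dm),
                stroke_side="left" if rng.random() < 0.5 else "right",
                covariates={
                    "bmi": float(np.clip(rng.normal(bmi_m, bmi_s), 16.0, 55.0)),
                    "smoker": bool(rng.random() < p_smoke),
                    "hypertension": bool(rng.random() < p_htn),
                },
            )
            trng = substream(params.seed, sid, "truth")
            rest_aff, rest_na = _correlated_pair(
                trng, params.rest_mcav_mean, params.rest_mcav_sd,
                params.rest_mcav_mean, params.rest_mcav_sd, params.hemi_corr)
            cvr_a, cvr_n = _correlated_pair(
                trng, cvr_aff[0], cvr_aff[1], cvr_na[0], cvr_na[1], params.hemi_corr)
            truth = GroundTruth(
                subject_id=sid,
                rest={"stroke_affected": float(max(rest_aff, 25.0)),
                      "non_affected": float(max(rest_na, 25.0))},
                cvr={"stroke_affected": float(cvr_a), "non_affected": float(cvr_n)},
            )
            out.append((profile, truth))
            idx += 1
    return out


# ---------------------------------------------------------------------------
# recordings

def steady_state_window_factor(tau: float, time_delay: float,
                               exercise_onset: float = 90.0,
                               window: tuple = (180.0, 270.0)) -> float:
    """Mean of ``1 - exp(-(t - onset - delay)/tau)`` over the analysis window.

    Closed form of the window average of the saturating exponential; the
    generator divides the drawn CVR by this factor so that the noise-free
    steady-state-window mean increment equals the truth exactly.
    """
    w0, w1 = window
    s = exercise_onset + time_delay
    if w0 < s:
        raise ConfigurationError("steady-state window must start after onset + delay")
    return 1.0 - (tau / (w1 - w0)) * (
        math.exp(-(w0 - s) / tau) - math.exp(-(w1 - s) / tau)
    )


def _pulse_shape(phase: np.ndarray) -> np.ndarray:
    # Systolic bump peaking (value 1) at 20% of the cardiac cycle.
    return np.exp(-(((phase - 0.2) / 0.1) ** 2))


def _beat_onsets(rng, duration: float, resting_hr: float) -> np.ndarray:
    rr0 = 60.0 / resting_hr
    n_est = int(duration / rr0 * 1.3) + 10
    rr = rr0 * (1.0 + 0.01 * rng.standard_normal(n_est))
    rr = np.clip(rr, 0.3 * rr0, 2.0 * rr0)
    onsets = np.concatenate([[0.0], np.cumsum(rr)])
    return onsets[onsets < duration]


def _mono_exp_trend(t, rest, cvr, params):
    s = params.exercise_onset + params.time_delay
    factor = steady_state_window_factor(
        params.tau, params.time_delay, params.exercise_onset,
        params.steady_state_window)
    amp = cvr / factor
    trend = np.full_like(t, rest)
    after = t > s
    trend[after] += amp * (1.0 - np.exp(-(t[after] - s) / params.tau))
    return trend


def _cycle_demeaned_pulse(t, onsets, amp, duration, rng_unused=None):
    """Pulsatile component with *exactly* zero sample mean inside each cycle.

    Exact per-cycle de-meaning keeps cycle-mean velocity equal to the trend,
    so downstream cycle extraction recovers the trend without pulsatility
    bias.
    """
    if len(onsets) < 2:
        return np.zeros_like(t)
    rr = np.diff(onsets)
    idx = np.searchsorted(onsets, t, side="right") - 1
    idx = np.clip(idx, 0, len(onsets) - 2)
    phase = (t - onsets[idx]) / rr[idx]
    pulse = amp * _pulse_shape(np.clip(phase, 0.0, 1.5))
    # subtract each cycle's sample mean (reduceat over cycle boundaries)
    fs_idx = np.searchsorted(t, onsets - 1e-12, side="left")
    fs_idx = np.unique(np.clip(fs_idx, 0, len(t) - 1))
    if fs_idx[0] != 0:
        fs_idx = np.concatenate([[0], fs_idx])
    sums = np.add.reduceat(pulse, fs_idx)
    counts = np.diff(np.concatenate([fs_idx, [len(t)]]))
    means = sums / counts
    seg = np.searchsorted(fs_idx, np.arange(len(t)), side="right") - 1
    return pulse - means[seg]


def simulate_recording(profile: SubjectProfile, truth: GroundTruth,
                       params: SynthParams, bout_index: int = 0) -> AcquisitionRecording:
    """Synthesize one bout's raw 500 Hz recording for a subject.

    Cycle-mean MCAv follows rest + A(1 - exp(-(t - t0 - TD)/tau)) beyond the
    exercise onset t0 (= 90 s) plus delay TD, with A scaled so the noise-free
    mean over the steady-state window equals the subject's true CVR.  A
    pulsatile intra-cycle waveform (zero mean within each cycle) and white
    noise are superimposed.
    """
    if truth.subject_id != profile.subject_id:
        raise ConfigurationError("ground truth does not belong to this profile")
    params.validate()
    fs, dur = params.sample_rate, params.duration
    rng = substream(params.seed, profile.subject_id, "bout", bout_index)
    onsets = _beat_onsets(rng, dur, profile.resting_hr)
    n = int(round(dur * fs))
    t = np.arange(n) / fs

    mcav = {}
    for hemi in HEMISPHERES:
        trend = _mono_exp_trend(t, truth.rest[hemi], truth.cvr[hemi], params)
        pulse = _cycle_demeaned_pulse(t, onsets, params.pulsatility_amp, dur)
        noise = params.noise_sd * rng.standard_normal(n)
        mcav[hemi] = trend + pulse + noise

    ramp = np.zeros(n)
    s = params.exercise_onset + params.time_delay
    after = t > s
    ramp[after] = 1.0 - np.exp(-(t[after] - s) / params.tau)
    map_pulse = _cycle_demeaned_pulse(t, onsets, 15.0, dur)
    map_mmhg = 80.0 + 18.0 * ramp + map_pulse + 2.0 * rng.standard_normal(n)
    petco2 = 35.0 + 4.0 * ramp + 0.5 * rng.standard_normal(n)

    return AcquisitionRecording(
        subject_id=profile.subject_id,
        sample_rate=fs,
        duration=dur,
        mcav=mcav,
        map_mmhg=map_mmhg,
        petco2_mmhg=petco2,
        beat_onsets=onsets,
        bout_index=bout_index,
    )


def inject_artifacts(recording: AcquisitionRecording,
                     params: SynthParams) -> tuple:
    """Superimpose velocity spikes and implausibly short RR intervals.

    Spikes raise one cycle's peak velocity by ``artifact_spike_mag`` (> 10
    cm/s, guaranteed to trip the jump-censoring rule); short-RR events insert
    a spurious beat marker 0.15 s after a real one (instantaneous cardiac
    frequency 6.7 Hz > 5 Hz).  Returns ``(recording, log)`` where ``log``
    lists ``(time_s, kind)``; zero rates return the input unchanged.
    """
    if params.artifact_spike_rate == 0 and params.short_rr_rate == 0:
        return recording, []
    rng = substream(params.seed, recording.subject_id, "artifacts",
                    recording.bout_index)
    dur_min = recording.duration / 60.0
    onsets = recording.beat_onsets.copy()
    t = recording.time
    mcav = {h: v.copy() for h, v in recording.mcav.items()}
    log = []

    n_cycles = len(onsets) - 1
    n_spikes = min(int(rng.poisson(params.artifact_spike_rate * dur_min)),
                   max(n_cycles - 1, 0))
    if n_spikes > 0:
        # skip cycle 0: the first cycle is exempt from the jump rule
        cyc = rng.choice(np.arange(1, n_cycles), size=n_spikes, replace=False)
        for ci in np.sort(cyc):
            t0, t1 = onsets[ci], onsets[ci + 1]
            sl = slice(*np.searchsorted(t, [t0, t1]))
            for hemi in HEMISPHERES:
                seg = mcav[hemi][sl]
                peak_t = t[sl][np.argmax(seg)]
                width = 0.06 * (t1 - t0)
                mcav[hemi][sl] = seg + params.artifact_spike_mag * np.exp(
                    -(((t[sl] - peak_t) / width) ** 2))
            log.append((float(t0), "spike"))

    n_rr = int(rng.poisson(params.short_rr_rate * dur_min))
    if n_rr > 0:
        candidates = np.where(np.diff(onsets) > 0.45)[0]
        n_rr = min(n_rr, len(candidates))
        picks = rng.choice(candidates, size=n_rr, replace=False)
        extra = onsets[np.sort(picks)] + 0.15
        onsets = np.sort(np.concatenate([onsets, extra]))
        for e in extra:
            log.append((float(e), "short_rr"))

    out = replace(recording, mcav=mcav, beat_onsets=onsets)
    return out, sorted(log)
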