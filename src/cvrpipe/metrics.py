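"""Outcome measures and exercise prescription.

The cerebrovascular response to exercise (CVR) is the difference between
mean MCAv over the steady-state exercise window (recording minutes 3-4.5,
i.e. [180, 270) s of a bout that starts with 90 s of rest) and resting MCAv
(mean over the first 90 s).  %dMCAv expresses CVR as a percentage of the
resting value.  Windows are half-open to avoid double-counting boundary
samples.

Exercise prescription follows the heart-rate-reserve (Karvonen) method with
age-predicted maximal heart rate, using the beta-blocker-adjusted equation
when applicable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

REST_WINDOW = (0.0, 90.0)
STEADY_STATE_WINDOW = (180.0, 270.0)

__all__ = [
    "REST_WINDOW",
    "STEADY_STATE_WINDOW",
    "CvrResult",
    "HrPrescription",
    "resting_mcav",
    "steady_state_mcav",
    "compute_cvr",
    "compute_pct_change",
    "cvr_from_series",
    "hr_max",
    "karvonen_range",
]


@dataclass
class CvrResult:
    subject_id: str
    visit: str
    hemisphere: str               # "stroke_affected" | "non_affected"
    mcav_rest: float              # cm/s
    mcav_ss: float                # cm/s
    cvr: float                    # cm/s, mcav_ss - mcav_rest
    pct_change: float             # percent, 100 * cvr / mcav_rest


@dataclass
class HrPrescription:
    hr_max: float
    hr_low: float
    hr_high: float

    def __post_init__(self):
        if not (self.hr_low <= self.hr_high <= self.hr_max):
            raise ValueError("require hr_low <= hr_high <= hr_max")


def _window_mean(series, window) -> float:
    t = np.asarray(series.time, dtype=float)
    v = np.asarray(series.value, dtype=float)
    sel = (t >= window[0]) & (t < window[1]) & ~np.isnan(v)
    if not sel.any():
        raise ValueError(f"no samples in window [{window[0]}, {window[1]}) s")
    return float(v[sel].mean())


def resting_mcav(series, window=REST_WINDOW) -> float:
    """Mean MCAv over the resting period (first 90 s by default)."""
    return _window_mean(series, window)


def steady_state_mcav(series, window=STEADY_STATE_WINDOW) -> float:
    """Mean MCAv over the steady-state exercise window ([180, 270) s)."""
    return _window_mean(series, window)


def compute_cvr(mcav_rest: float, mcav_ss: float) -> float:
    if mcav_rest <= 0:
        raise ValueError("resting MCAv must be positive")
    return mcav_ss - mcav_rest


def compute_pct_change(cvr: float, mcav_rest: float) -> float:
    if mcav_rest <= 0:
        raise ValueError("resting MCAv must be positive")
    return 100.0 * cvr / mcav_rest


def cvr_from_series(series, subject_id: str, hemisphere: str, visit: str = "3mo",
                    rest_window=REST_WINDOW,
                    ss_window=STEADY_STATE_WINDOW) -> CvrResult:
    """Full outcome set for one subject/hemisphere from a cleaned series."""
    rest = resting_mcav(series, rest_window)
    ss = steady_state_mcav(series, ss_window)
    cvr = compute_cvr(rest, ss)
    return CvrResult(
        subject_id=subject_id,
        visit=visit,
        hemisphere=hemisphere,
        mcav_rest=rest,
        mcav_ss=ss,
        cvr=cvr,
        pct_change=compute_pct_change(cvr, rest),
    )


def hr_max(age: float, beta_blocker: bool) -> float:
    """Age-predicted maximal heart rate.

    220 - age off beta-blockade; 164 - 0.72*age on beta-blockade.
    """
    if age <= 0:
        raise ValueError("age must be positive")
    return 164.0 - 0.72 * age if beta_blocker else 220.0 - age


def karvonen_range(hr_max_bpm: float, hr_rest: float,
                   lo: float = 0.45, hi: float = 0.55) -> HrPrescription:
    """Target HR band: intensity * (HRmax - HRrest) + HRrest."""
    if hr_rest >= hr_max_bpm:
        raise ValueError("resting HR must be below maximal HR")
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError("intensities must satisfy 0 < lo <= hi <= 1")
    reserve = hr_max_bpm - hr_rest
    return HrPrescription(
        hr_max=hr_max_bpm,
        hr_low=lo * reserve + hr_rest,
        hr_high=hi * reserve + hr_rest,
    )
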