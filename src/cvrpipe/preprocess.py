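"""Beat-level preprocessing of raw MCAv recordings.

Pipeline per bout and hemisphere:

1. ``extract_cycles`` — summarize each inter-beat interval (RR, mean and
   peak velocity).
2. ``censor_cycles`` — flag artifact cycles: instantaneous cardiac frequency
   1/RR above 5 Hz, or a peak-velocity change of more than 10 cm/s within a
   single cardiac cycle.
3. ``apply_discard_rule`` — drop the whole acquisition if more than 15% of
   cycles were censored.
4. ``resample_to_2hz`` — linear interpolation of surviving cycle means onto
   a uniform 2 Hz grid.
5. ``smooth_3s_9s`` — non-overlapping 3 s block means followed by a 9 s
   (3-block) centered sliding average.
6. ``average_bouts`` — pointwise mean across repeated bouts.

All censoring thresholds are strict inequalities.  The velocity-jump test
compares each cycle's peak against the most recent *accepted* peak, so a
single spiked cycle censors exactly that cycle rather than dragging its
clean successor down with it; the first cycle, having no reference, is
exempt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import AcquisitionRecording

RATE_MAX_HZ = 5.0
JUMP_MAX_CMPS = 10.0
DISCARD_THRESHOLD = 0.15

__all__ = [
    "CycleSeries",
    "CensorMask",
    "SmoothedSeries",
    "BlockSeries",
    "extract_cycles",
    "censor_cycles",
    "apply_discard_rule",
    "resample_to_2hz",
    "smooth_3s_9s",
    "average_bouts",
]


@dataclass
class CycleSeries:
    """Per-cardiac-cycle summaries for one hemisphere of one bout."""

    onset: np.ndarray   # s, cycle start times
    rr: np.ndarray      # s, inter-onset intervals
    mean_v: np.ndarray  # cm/s, time-average velocity within the cycle
    peak_v: np.ndarray  # cm/s, maximum velocity within the cycle
    hemisphere: str = ""
    subject_id: str = ""
    bout_index: int = 0

    def __len__(self):
        return len(self.onset)


@dataclass
class CensorMask:
    censored: np.ndarray          # bool per cycle
    reasons: list                 # None | "rr_implausible" | "velocity_jump"
    censored_fraction: float
    discard: bool                 # censored_fraction > 0.15 at the default threshold


@dataclass
class SmoothedSeries:
    """Values on a uniform 2 Hz (0.5 s) grid; gaps are NaN."""

    time: np.ndarray
    value: np.ndarray
    provenance: list = field(default_factory=list)  # contributing bout indices

    def __post_init__(self):
        if len(self.time) > 1 and not np.allclose(np.diff(self.time), 0.5):
            raise ValueError("SmoothedSeries requires a 0.5 s grid")


@dataclass
class BlockSeries:
    """3 s block means (optionally 9 s smoothed), indexed by block centers."""

    time: np.ndarray
    value: np.ndarray
    provenance: list = field(default_factory=list)


def _nanmean_rows(a: np.ndarray) -> np.ndarray:
    """Row-wise mean ignoring NaN; all-NaN rows yield NaN without warnings."""
    good = ~np.isnan(a)
    counts = good.sum(axis=1)
    sums = np.where(good, a, 0.0).sum(axis=1)
    out = np.full(len(a), np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


def extract_cycles(rec: AcquisitionRecording, hemisphere: str) -> CycleSeries:
    """One summary per inter-onset interval [onset_i, onset_{i+1})."""
    onsets = np.asarray(rec.beat_onsets, dtype=float)
    if len(onsets) < 2:
        raise ValueError("need at least 2 beat onsets to form a cycle")
    v = np.asarray(rec.channel(hemisphere), dtype=float)
    t = rec.time
    idx = np.searchsorted(t, onsets - 1e-12, side="left")
    idx = np.clip(idx, 0, len(t) - 1)
    counts = np.diff(idx)
    if np.any(counts <= 0):
        raise ValueError("beat onsets closer than one sample period")
    sums = np.add.reduceat(v, idx)[:-1]
    peaks = np.maximum.reduceat(v, idx)[:-1]
    return CycleSeries(
        onset=onsets[:-1],
        rr=np.diff(onsets),
        mean_v=sums / counts,
        peak_v=peaks,
        hemisphere=hemisphere,
        subject_id=rec.subject_id,
        bout_index=rec.bout_index,
    )


def censor_cycles(cycles: CycleSeries, rate_max_hz: float = RATE_MAX_HZ,
                  jump_max: float = JUMP_MAX_CMPS) -> CensorMask:
    """Flag artifact cycles; strict ``>`` comparisons on both rules."""
    n = len(cycles)
    if n == 0:
        raise ValueError("empty cycle series")
    censored = np.zeros(n, dtype=bool)
    reasons: list = [None] * n
    last_good_peak = None
    for i in range(n):
        if cycles.rr[i] <= 0 or (1.0 / cycles.rr[i]) > rate_max_hz:
            censored[i] = True
            reasons[i] = "rr_implausible"
            continue
        if last_good_peak is not None and abs(cycles.peak_v[i] - last_good_peak) > jump_max:
            censored[i] = True
            reasons[i] = "velocity_jump"
            continue
        last_good_peak = cycles.peak_v[i]
    frac = float(censored.mean())
    return CensorMask(censored=censored, reasons=reasons,
                      censored_fraction=frac,
                      discard=frac > DISCARD_THRESHOLD)


def apply_discard_rule(mask: CensorMask, threshold: float = DISCARD_THRESHOLD) -> bool:
    """True iff strictly more than ``threshold`` of cycles were censored."""
    return mask.censored_fraction > threshold


def resample_to_2hz(cycles: CycleSeries, mask: CensorMask,
                    duration: float) -> SmoothedSeries:
    """Linearly interpolate surviving cycle means onto the 0.5 s grid [0, duration).

    Each surviving cycle contributes the point ``(onset + rr/2, mean_v)``.
    Grid points outside the convex hull of surviving beats are NaN.
    """
    keep = ~mask.censored
    if keep.sum() < 2:
        raise ValueError("fewer than 2 surviving cycles; acquisition unusable")
    tt = cycles.onset[keep] + cycles.rr[keep] / 2.0
    vv = cycles.mean_v[keep]
    grid = np.arange(0.0, duration - 1e-9, 0.5)
    vals = np.interp(grid, tt, vv)
    vals[(grid < tt[0]) | (grid > tt[-1])] = np.nan
    return SmoothedSeries(time=grid, value=vals,
                          provenance=[cycles.bout_index])


def smooth_3s_9s(series: SmoothedSeries) -> BlockSeries:
    """3 s block means then a centered 9 s (3-block) sliding average.

    Blocks are anchored at the start of the grid; a final partial block is
    dropped.  Edge blocks average over the two available blocks.  NaN samples
    are excluded; an all-NaN window stays NaN.
    """
    per_block = 6  # 3 s of 2 Hz samples
    nb = len(series.value) // per_block
    if nb < 1:
        raise ValueError("series shorter than one 3 s block")
    chunks = series.value[: nb * per_block].reshape(nb, per_block)
    blocks = _nanmean_rows(chunks)
    smoothed = np.empty(nb)
    for i in range(nb):
        window = blocks[max(0, i - 1): i + 2]
        good = window[~np.isnan(window)]
        smoothed[i] = good.mean() if len(good) else np.nan
    centers = series.time[0] + 1.5 + 3.0 * np.arange(nb)
    return BlockSeries(time=centers, value=smoothed,
                       provenance=list(series.provenance))


def average_bouts(series_list: list) -> BlockSeries:
    """Pointwise mean across bouts on a common grid; NaNs excluded pairwise."""
    if not series_list:
        raise ValueError("no surviving bouts: subject unmodelable")
    ref = series_list[0].time
    for s in series_list[1:]:
        if len(s.time) != len(ref) or not np.allclose(s.time, ref):
            raise ValueError("bouts are not on a common grid")
    stack = np.vstack([s.value for s in series_list])
    mean = _nanmean_rows(stack.T)
    prov = sorted({b for s in series_list for b in s.provenance})
    return BlockSeries(time=ref.copy(), value=mean, provenance=prov)
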