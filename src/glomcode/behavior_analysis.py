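"""Fictive- and free-walking behavior analytics.

Walking amplitude is the pointwise magnitude of the 3-axis ball-rotation
vector.  Trials are classified as behaving when the walking amplitude exceeds
an automatically determined threshold (Li's minimum cross entropy) for at
least 25% of the trial's samples.  Saccades are detected as contiguous
excursions of |angular velocity| above a threshold (default 160 deg/s), and
summarised by inter-turn intervals and peri-saccade vs intersaccade
speed/velocity distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SaccadeEventList",
    "BehavingClassification",
    "walking_amplitude",
    "li_threshold",
    "li_cross_entropy",
    "classify_behaving",
    "detect_saccades",
    "saccade_cycle_stats",
    "read_fictrac_csv",
]


@dataclass
class SaccadeEventList:
    onset_times: np.ndarray  # s, strictly increasing
    peak_speeds: np.ndarray  # deg/s per event

    def __post_init__(self) -> None:
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        self.peak_speeds = np.asarray(self.peak_speeds, dtype=float)
        if np.any(np.diff(self.onset_times) <= 0):
            raise ValueError("onset times must be strictly increasing")

    @property
    def inter_turn_intervals(self) -> np.ndarray:
        return np.diff(self.onset_times)

    def __len__(self) -> int:
        return len(self.onset_times)


@dataclass
class BehavingClassification:
    threshold: float  # deg/s
    behaving: np.ndarray  # bool per trial
    fraction_above: np.ndarray  # per trial
    min_fraction: float = 0.25


def walking_amplitude(rot_x, rot_y, rot_z) -> np.ndarray:
    """Pointwise magnitude of the total rotation vector, sqrt(x^2+y^2+z^2)."""
    rot_x, rot_y, rot_z = (np.asarray(a, dtype=float) for a in (rot_x, rot_y, rot_z))
    if not (len(rot_x) == len(rot_y) == len(rot_z)):
        raise ValueError("rotation axes must have equal lengths")
    return np.sqrt(rot_x**2 + rot_y**2 + rot_z**2)


def li_cross_entropy(values: np.ndarray, threshold: float) -> float:
    """Li's cross-entropy criterion for a candidate threshold.

    Splits ``values`` into below/at (background) and above (foreground)
    classes with means mu0, mu1 and scores
    ``-(sum_bg x * log(mu0) + sum_fg x * log(mu1))``; the minimum-cross-
    entropy threshold minimises this over candidates.  Requires non-negative
    data (means must be positive for the logs to be defined; zero-mean
    classes contribute nothing).
    """
    values = np.asarray(values, dtype=float)
    below = values[values <= threshold]
    above = values[values > threshold]
    total = 0.0
    if below.size and below.mean() > 0:
        total += below.sum() * np.log(below.mean())
    if above.size and above.mean() > 0:
        total += above.sum() * np.log(above.mean())
    return -total


def li_threshold(values: np.ndarray) -> float:
    """Minimum cross entropy (Li) threshold.

    Directly minimises Li's cross-entropy criterion over the midpoints of
    consecutive sorted unique values, which is the exhaustive search over all
    distinct below/above partitions of the sample.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("values must be non-negative")
    uniq = np.unique(values)
    if uniq.size < 2:
        raise ValueError("need at least two distinct values to threshold")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    scores = np.array([li_cross_entropy(values, c) for c in candidates])
    return float(candidates[np.argmin(scores)])


def classify_behaving(
    amplitude: np.ndarray,
    time: np.ndarray,
    trial_windows: list[tuple[float, float]],
    min_fraction: float = 0.25,
) -> BehavingClassification:
    """Behaving/non-behaving classification of trials.

    The threshold is determined from the full-session walking amplitude with
    :func:`li_threshold`; a trial is behaving when at least ``min_fraction``
    (default 25%, inclusive) of its samples exceed the threshold.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    time = np.asarray(time, dtype=float)
    thr = li_threshold(amplitude)
    flags = np.zeros(len(trial_windows), dtype=bool)
    fracs = np.zeros(len(trial_windows))
    for i, (t0, t1) in enumerate(trial_windows):
        sel = (time >= t0) & (time < t1)
        if not sel.any():
            raise ValueError(f"trial window {i} ({t0}, {t1}) is empty")
        fracs[i] = np.mean(amplitude[sel] > thr)
        flags[i] = fracs[i] >= min_fraction
    return BehavingClassification(
        threshold=thr, behaving=flags, fraction_above=fracs, min_fraction=min_fraction
    )


def detect_saccades(
    angular_velocity: np.ndarray,
    time: np.ndarray,
    speed_threshold: float = 160.0,
    min_separation: float = 0.1,
) -> SaccadeEventList:
    """Threshold-crossing saccade detector.

    Events are contiguous runs of |angular velocity| >= ``speed_threshold``;
    runs whose gap is shorter than ``min_separation`` are merged.  The onset
    is the first supra-threshold sample of each (merged) excursion and the
    peak speed is the maximum |angular velocity| within it.
    """
    if speed_threshold <= 0:
        raise ValueError("speed threshold must be positive")
    time = np.asarray(time, dtype=float)
    dts = np.diff(time)
    if dts.size and not np.allclose(dts, dts[0], rtol=1e-6):
        raise ValueError("uniform sampling required")
    speed = np.abs(np.asarray(angular_velocity, dtype=float))
    above = speed >= speed_threshold
    if not above.any():
        return SaccadeEventList(np.empty(0), np.empty(0))
    edges = np.diff(above.astype(int))
    starts = np.where(edges == 1)[0] + 1
    ends = np.where(edges == -1)[0] + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(above)]
    # merge excursions separated by less than min_separation
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if time[s] - time[merged[-1][1] - 1] < min_separation:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    onsets = np.array([time[s] for s, _ in merged])
    peaks = np.array([speed[s:e].max() for s, e in merged])
    return SaccadeEventList(onset_times=onsets, peak_speeds=peaks)


def saccade_cycle_stats(
    events: SaccadeEventList,
    angular_velocity: np.ndarray,
    forward_velocity: np.ndarray,
    time: np.ndarray,
    window: float = 0.4,
    n_bins: int = 40,
    ks_decorrelation_s: float = 2.0,
) -> dict:
    """Saccade-cycle summary statistics.

    Partitions samples into peri-saccade (within ``window``/2 of an onset)
    and intersaccade sets, and returns the inter-turn-interval histogram plus
    angular-speed and forward-velocity histograms for both sets (with bin
    edges), raw per-set samples, and a two-sample KS test comparing
    peri/intersaccade forward velocities.  Because locomotor velocity is
    strongly autocorrelated (bouts last seconds), the KS test is computed on
    samples decimated to one per ``ks_decorrelation_s`` within each set, so
    its sample size reflects approximately independent observations.  With
    fewer than two events, ITIs are empty and flagged.
    """
    time = np.asarray(time, dtype=float)
    ang_speed = np.abs(np.asarray(angular_velocity, dtype=float))
    fwd = np.asarray(forward_velocity, dtype=float)
    iti = events.inter_turn_intervals
    peri = np.zeros(len(time), dtype=bool)
    for onset in events.onset_times:
        peri |= np.abs(time - onset) <= window / 2.0
    inter = ~peri

    def _hist(x, lo, hi):
        edges = np.linspace(lo, hi, n_bins + 1)
        counts, _ = np.histogram(x, bins=edges)
        return counts, edges

    iti_hist = _hist(iti, 0.0, max(5.0, iti.max() if iti.size else 5.0))
    s_hi = max(ang_speed.max(), 1.0)
    f_lo, f_hi = min(fwd.min(), 0.0), max(fwd.max(), 1.0)
    out = {
        "iti": iti,
        "iti_flagged_empty": iti.size == 0,
        "iti_hist": iti_hist,
        "peri_mask": peri,
        "angular_speed": {
            "peri": ang_speed[peri],
            "inter": ang_speed[inter],
            "peri_hist": _hist(ang_speed[peri], 0.0, s_hi),
            "inter_hist": _hist(ang_speed[inter], 0.0, s_hi),
        },
        "forward_velocity": {
            "peri": fwd[peri],
            "inter": fwd[inter],
            "peri_hist": _hist(fwd[peri], f_lo, f_hi),
            "inter_hist": _hist(fwd[inter], f_lo, f_hi),
        },
    }
    if peri.any() and inter.any():
        dt = time[1] - time[0] if len(time) > 1 else 1.0
        stride = max(1, int(round(ks_decorrelation_s / dt)))
        a = fwd[peri][::stride]
        b = fwd[inter][::stride]
        if a.size >= 2 and b.size >= 2:
            ks = stats.ks_2samp(a, b)
            out["forward_velocity_ks"] = {
                "statistic": float(ks.statistic), "p": float(ks.pvalue)
            }
    return out


def read_fictrac_csv(path, columns=("rot_x", "rot_y", "rot_z"), time_column="time") -> dict:
    """Read per-frame ball rotations from a FicTrac-style CSV.

    Expects named columns for time (s) and the three rotation-rate axes
    (deg/s, already calibrated); returns a dict of arrays including the
    derived walking amplitude.
    """
    df = pd.read_csv(path)
    missing = [c for c in (time_column, *columns) if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in FicTrac CSV: {missing}")
    out = {"time": df[time_column].to_numpy(float)}
    for c in columns:
        out[c] = df[c].to_numpy(float)
    out["amplitude"] = walking_amplitude(out[columns[0]], out[columns[1]], out[columns[2]])
    return out
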