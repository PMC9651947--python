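"""Response-gain quantification under visual and behavioral conditions.

"Gain" is operationalised as the ratio of condition means of peak probe
amplitudes (ratio-of-means, which is stable when single-trial amplitudes are
small).  The module provides:

- surround speed tuning: probe response vs background speed, normalised to
  the static-background condition,
- gain vs walking amplitude: per-stimulus-mean-normalised amplitudes binned
  by the trial's walking amplitude,
- saccade-timing gain curves: amplitude vs probe-saccade offset, normalised
  to trials with large |offset|,
- the visual x motor independence test: does the jointly measured gain equal
  the product of the two marginal gains?  Deviations get trial-bootstrap
  percentile confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .population_analysis import AmplitudeMatrix

__all__ = [
    "GainTable",
    "TuningCurve",
    "surround_speed_tuning",
    "gain_vs_walking",
    "saccade_timing_gain",
    "build_gain_table",
    "independence_test",
]

logger = logging.getLogger(__name__)

_CONDITIONS = ((0, 0), (1, 0), (0, 1), (1, 1))  # (visual saccade, walking)


@dataclass
class GainTable:
    """Per-glomerulus trial amplitudes for the 2x2 condition design.

    ``cells[(visual, walking)]`` is a trials x glomeruli array; gains are
    condition means normalised by the (0, 0) reference cell, so the reference
    gain is 1 by construction.
    """

    cells: dict[tuple[int, int], np.ndarray]
    glomerulus_names: list[str] | None = None

    def __post_init__(self) -> None:
        for cond in _CONDITIONS:
            if cond not in self.cells or len(self.cells[cond]) == 0:
                raise ValueError(f"empty condition cell {cond}")

    def n_trials(self, cond: tuple[int, int]) -> int:
        return self.cells[cond].shape[0]

    def gains(self) -> dict[tuple[int, int], np.ndarray]:
        ref = self.cells[(0, 0)].mean(axis=0)
        if np.any(ref <= 0):
            raise ValueError("non-positive reference-condition mean amplitude")
        return {cond: self.cells[cond].mean(axis=0) / ref for cond in _CONDITIONS}


@dataclass
class TuningCurve:
    x: np.ndarray  # background speed (deg/s) or saccade-relative time (s)
    y: np.ndarray  # normalised response (per x, possibly per glomerulus)
    sem: np.ndarray
    n: np.ndarray
    normalization: str = "reference"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")


def surround_speed_tuning(
    amps: AmplitudeMatrix, condition_speeds: np.ndarray
) -> TuningCurve:
    """Mean probe amplitude vs background speed, normalised to speed 0.

    ``condition_speeds`` gives the background speed of each trial; a speed-0
    condition must be present.  Returns per-glomerulus curves stacked as
    ``y[speed_index, glomerulus]``.
    """
    speeds = np.asarray(condition_speeds, dtype=float)
    if len(speeds) != amps.n_trials:
        raise ValueError("one background speed per trial required")
    uniq = np.unique(speeds)
    if 0.0 not in uniq:
        raise ValueError("a speed-0 (static background) condition is required")
    ref = amps.values[speeds == 0.0].mean(axis=0)
    if np.any(ref <= 0):
        raise ValueError("zero or negative reference (static-background) mean")
    means, sems, ns = [], [], []
    for v in uniq:
        block = amps.values[speeds == v] / ref
        means.append(block.mean(axis=0))
        sems.append(block.std(axis=0, ddof=1) / np.sqrt(block.shape[0]) if block.shape[0] > 1 else np.zeros(amps.n_glomeruli))
        ns.append(block.shape[0])
    return TuningCurve(
        x=uniq, y=np.stack(means), sem=np.stack(sems), n=np.asarray(ns),
        normalization="static-background mean",
    )


def gain_vs_walking(
    amps: AmplitudeMatrix,
    walking_amplitude: np.ndarray,
    bin_edges: np.ndarray,
    min_trials_per_bin: int = 5,
) -> TuningCurve:
    """Population response gain as a function of walking amplitude.

    Single-trial amplitudes are normalised by their per-stimulus mean
    (averaged across glomeruli to a scalar per-trial gain), then binned by
    walking amplitude.  Bins with fewer than ``min_trials_per_bin`` trials
    are dropped (logged).
    """
    walking = np.asarray(walking_amplitude, dtype=float)
    if len(walking) != amps.n_trials:
        raise ValueError("one walking amplitude per trial required")
    norm = amps.values.astype(float).copy()
    for s in np.unique(amps.labels):
        sel = amps.labels == s
        mu = norm[sel].mean(axis=0)
        norm[sel] = norm[sel] / np.where(mu > 0, mu, 1.0)
    trial_gain = norm.mean(axis=1)
    edges = np.asarray(bin_edges, dtype=float)
    which = np.digitize(walking, edges) - 1
    centers, means, sems, ns = [], [], [], []
    for b in range(len(edges) - 1):
        sel = which == b
        if sel.sum() < min_trials_per_bin:
            if sel.sum() > 0:
                logger.warning("dropping walking bin %d with %d < %d trials",
                               b, int(sel.sum()), min_trials_per_bin)
            continue
        centers.append((edges[b] + edges[b + 1]) / 2.0)
        means.append(trial_gain[sel].mean())
        n = int(sel.sum())
        sems.append(trial_gain[sel].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0)
        ns.append(n)
    if not centers:
        raise ValueError("no walking bin met the minimum trial count")
    return TuningCurve(
        x=np.asarray(centers), y=np.asarray(means), sem=np.asarray(sems),
        n=np.asarray(ns), normalization="per-stimulus mean",
    )


def saccade_timing_gain(
    amps: AmplitudeMatrix,
    saccade_offsets: np.ndarray,
    reference_abs_offset: float = 2.0,
) -> TuningCurve:
    """Response gain vs saccade time relative to the probe response onset.

    ``saccade_offsets`` holds, per trial, the onset time of the background
    saccade relative to the probe response (t = 0 means coincident).  Trials
    with |offset| >= ``reference_abs_offset`` form the reference set; each
    offset's mean amplitude is divided by the reference mean.
    """
    offsets = np.asarray(saccade_offsets, dtype=float)
    if len(offsets) != amps.n_trials:
        raise ValueError("one saccade offset per trial required")
    ref_sel = np.abs(offsets) >= reference_abs_offset
    if not ref_sel.any():
        raise ValueError("no reference trials with |offset| >= "
                         f"{reference_abs_offset}")
    trial_amp = amps.values.mean(axis=1)
    ref = trial_amp[ref_sel].mean()
    if ref <= 0:
        raise ValueError("non-positive reference mean amplitude")
    uniq = np.unique(offsets)
    means, sems, ns = [], [], []
    for off in uniq:
        block = trial_amp[offsets == off] / ref
        means.append(block.mean())
        n = len(block)
        sems.append(block.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0)
        ns.append(n)
    return TuningCurve(
        x=uniq, y=np.asarray(means), sem=np.asarray(sems), n=np.asarray(ns),
        normalization=f"|offset| >= {reference_abs_offset} s mean",
    )


def build_gain_table(
    amps: AmplitudeMatrix, visual: np.ndarray, walking: np.ndarray
) -> GainTable:
    """Partition trials into the 2x2 {visual saccade} x {walking} design."""
    visual = np.asarray(visual).astype(int)
    walking = np.asarray(walking).astype(int)
    if len(visual) != amps.n_trials or len(walking) != amps.n_trials:
        raise ValueError("condition flags must be aligned per trial")
    cells = {}
    for v, w in _CONDITIONS:
        sel = (visual == v) & (walking == w)
        cells[(v, w)] = amps.values[sel]
    return GainTable(cells=cells, glomerulus_names=amps.glomerulus_names)


def independence_test(
    gains: GainTable,
    n_bootstrap: int = 1000,
    ci: float = 0.95,
    seed: int | None = 0,
) -> dict[str, np.ndarray]:
    """Test multiplicative (independent) combination of the two gain sources.

    Per glomerulus: marginal gains ``g_vis`` and ``g_beh`` from the
    single-factor conditions, predicted joint gain ``g_vis * g_beh``,
    observed joint gain from the both-factor cell, and the deviation
    observed - predicted with a seeded trial-bootstrap percentile CI
    (resampling trials within each condition cell).  A deviation CI covering
    zero is consistent with independent, linearly interacting gain controls.
    """
    g = gains.gains()
    predicted = g[(1, 0)] * g[(0, 1)]
    observed = g[(1, 1)]
    deviation = observed - predicted

    rng = np.random.default_rng(seed)
    boot = np.empty((n_bootstrap, deviation.shape[0]))
    cells = gains.cells
    for b in range(n_bootstrap):
        means = {}
        for cond, block in cells.items():
            idx = rng.integers(0, block.shape[0], size=block.shape[0])
            means[cond] = block[idx].mean(axis=0)
        ref = means[(0, 0)]
        boot[b] = means[(1, 1)] / ref - (means[(1, 0)] / ref) * (means[(0, 1)] / ref)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha], axis=0)
    return {
        "g_visual": g[(1, 0)],
        "g_behavior": g[(0, 1)],
        "predicted": predicted,
        "observed": observed,
        "deviation": deviation,
        "ci_low": lo,
        "ci_high": hi,
        "covers_zero": (lo <= 0) & (hi >= 0),
    }
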