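"""Ideal-observer discriminability of a small dark spot over a moving scene.

The task: a dark spot (default 15 deg) sweeps through a circular receptive
field (RF) while the background panorama rotates azimuthally at a constant
speed, mimicking visual input during body rotation.  For each frame we record
the local luminance (mean pixel intensity within the RF) and the local
spatial contrast (variance of pixel intensities normalised by their mean).
Discriminability between "spot present" and "spot absent" conditions is
quantified with d':

    d' = (mean_present - mean_absent) / sqrt((var_present + var_absent) / 2)

where the moments are taken over the frames during which the spot centre is
inside the RF.  For the luminance channel the sign of d' is inverted, because
the dark spot lowers local luminance.  When the pooled variance is zero but
the means differ, discriminability is perfect: d' is +inf and flagged capped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scenes import ImageScene

__all__ = [
    "ReceptiveField",
    "SpotSpec",
    "SceneTrace",
    "DiscriminabilityResult",
    "render_trace",
    "dprime",
    "speed_sweep",
]


@dataclass
class ReceptiveField:
    """Hard-disc receptive field at (azimuth, elevation), degrees."""

    center: tuple[float, float] = (0.0, 0.0)
    diameter: float = 30.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("RF diameter must be positive")


@dataclass
class SpotSpec:
    """Opaque moving disc composited onto the background."""

    diameter: float = 15.0
    intensity: float = 0.0  # dark
    speed: float = 100.0  # deg/s, azimuthal
    path_elevation: float | None = None  # defaults to the RF elevation


@dataclass
class SceneTrace:
    time: np.ndarray  # s, uniform
    luminance: np.ndarray  # mean RF intensity per frame
    contrast: np.ndarray  # var/mean of RF intensities per frame
    window: tuple[float, float]  # interval the spot centre is inside the RF

    def __post_init__(self) -> None:
        if len(self.time) != len(self.luminance) or len(self.time) != len(self.contrast):
            raise ValueError("trace arrays must share a length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def window_mask(self) -> np.ndarray:
        t0, t1 = self.window
        return (self.time >= t0) & (self.time <= t1)


@dataclass
class DiscriminabilityResult:
    background_speed: float
    dprime_luminance: float
    dprime_contrast: float
    image_id: int | str = 0
    capped: bool = False


def _grids(scene: ImageScene) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre azimuth / elevation coordinates in degrees."""
    ny, nx = scene.shape
    az = (np.arange(nx) + 0.5) * scene.pixel_scale[0]
    el = (np.arange(ny) + 0.5) * scene.pixel_scale[1]
    return az, el


def render_trace(
    scene: ImageScene,
    rf: ReceptiveField,
    spot: SpotSpec,
    background_speed: float,
    spot_present: bool,
    duration: float = 2.0,
    dt: float = 0.02,
    start_phase_deg: float = 0.0,
) -> SceneTrace:
    """Render per-frame local luminance and contrast traces.

    The background rotates azimuthally at ``background_speed`` deg/s (nearest
    integer-pixel shift per frame, cylindrical wrap); the spot moves along a
    constant-elevation path so that its centre crosses the RF centre at
    ``duration / 2``.  ``start_phase_deg`` offsets the initial background
    rotation (used to sample different scene regions).
    """
    if spot.diameter > rf.diameter:
        raise ValueError("spot larger than receptive field")
    if background_speed != 0 and not scene.wrap:
        raise ValueError("background rotation requires a wrapping (cylindrical) scene")
    if spot.speed * dt >= spot.diameter:
        raise ValueError("dt too coarse: spot moves more than its diameter per frame")

    az, el = _grids(scene)
    rf_az, rf_el = rf.center
    rf_r = rf.diameter / 2.0
    # local patch around the RF keeps per-frame work proportional to RF size
    span_az = scene.extent_deg[0]
    d_az = np.abs((az - rf_az + span_az / 2) % span_az - span_az / 2)
    col_sel = np.where(d_az <= rf_r + 1e-9)[0]
    row_sel = np.where(np.abs(el - rf_el) <= rf_r + 1e-9)[0]
    if col_sel.size == 0 or row_sel.size == 0:
        raise ValueError("receptive field mask is empty at this resolution")
    az_p = az[col_sel]
    el_p = el[row_sel]
    d_az_p = (az_p - rf_az + span_az / 2) % span_az - span_az / 2
    rf_mask = (d_az_p[None, :] ** 2 + (el_p[:, None] - rf_el) ** 2) <= rf_r**2
    if not rf_mask.any():
        raise ValueError("receptive field mask is empty at this resolution")

    time = np.arange(0.0, duration, dt)
    spot_el = rf.center[1] if spot.path_elevation is None else spot.path_elevation
    spot_az_path = rf_az + spot.speed * (time - duration / 2.0)
    px_scale_az = scene.pixel_scale[0]
    nx = scene.shape[1]

    luminance = np.empty(len(time))
    contrast = np.empty(len(time))
    spot_r2 = (spot.diameter / 2.0) ** 2
    for i, t in enumerate(time):
        shift_px = int(round((background_speed * t + start_phase_deg) / px_scale_az))
        cols = (col_sel + shift_px) % nx
        patch = scene.pixels[np.ix_(row_sel, cols)].copy()
        if spot_present:
            d_spot_az = (az_p - spot_az_path[i] + span_az / 2) % span_az - span_az / 2
            spot_mask = (d_spot_az[None, :] ** 2 + (el_p[:, None] - spot_el) ** 2) <= spot_r2
            patch[spot_mask] = spot.intensity
        vals = patch[rf_mask]
        mu = vals.mean()
        luminance[i] = mu
        contrast[i] = vals.var() / mu if mu > 0 else 0.0

    # window: spot centre within the RF disc (constant-elevation path)
    dz = spot_el - rf_el
    if abs(dz) >= rf_r:
        raise ValueError("spot path does not cross the receptive field")
    half_chord = math.sqrt(rf_r**2 - dz**2)
    t_mid = duration / 2.0
    window = (t_mid - half_chord / spot.speed, t_mid + half_chord / spot.speed)
    return SceneTrace(time=time, luminance=luminance, contrast=contrast, window=window)


def dprime(present: SceneTrace, absent: SceneTrace, channel: str = "luminance") -> tuple[float, bool]:
    """d' between present/absent traces within the spot-crossing window.

    Returns ``(value, capped)`` where ``capped`` marks the zero-pooled-
    variance, nonzero-mean-difference case (perfect discriminability, +/-inf).
    Luminance d' is sign-inverted so that a luminance *decrease* caused by the
    dark spot yields positive d'.
    """
    if channel not in ("luminance", "contrast"):
        raise ValueError(f"unknown channel {channel!r}")
    if len(present.time) != len(absent.time) or not np.allclose(present.time, absent.time):
        raise ValueError("present/absent traces must share a time base")
    mask = present.window_mask()
    if not mask.any():
        raise ValueError("empty spot-crossing window")
    a = getattr(present, channel)[mask]
    b = getattr(absent, channel)[mask]
    diff = a.mean() - b.mean()
    pooled = (a.var() + b.var()) / 2.0  # population (1/N) variances
    if pooled == 0:
        if diff == 0:
            return 0.0, False
        value = math.inf if diff > 0 else -math.inf
    else:
        value = diff / math.sqrt(pooled)
    if channel == "luminance":
        value = -value
    return float(value), not math.isfinite(value)


def speed_sweep(
    images: list[ImageScene],
    speeds: list[float],
    rf: ReceptiveField | None = None,
    spot: SpotSpec | None = None,
    n_reps: int = 1,
    seed: int | None = 0,
    duration: float = 2.0,
    dt: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """d' for every (image, speed, channel), plus per-speed mean +/- SEM.

    Each repetition samples a random initial background phase (seeded), so
    repetitions probe different regions of each panorama.  Returns
    ``(results, summary)`` data frames.  Summary rows aggregate across images
    (and reps); capped (infinite) d' values are excluded from the aggregation
    only when every requested speed is nonzero, otherwise they propagate so a
    static-background condition reports its capped/maximal discriminability.
    """
    if len(images) == 0:
        raise ValueError("empty image list")
    if len(speeds) < 2:
        raise ValueError("need at least two speeds")
    if any(s < 0 for s in speeds):
        raise ValueError("speeds must be non-negative")
    rf = rf or ReceptiveField()
    spot = spot or SpotSpec()
    rng = np.random.default_rng(seed)
    rows = []
    for img_id, scene in enumerate(images):
        phases = rng.uniform(0.0, scene.extent_deg[0], size=n_reps)
        for speed in speeds:
            for rep, phase in enumerate(phases):
                kw = dict(duration=duration, dt=dt, start_phase_deg=float(phase))
                present = render_trace(scene, rf, spot, speed, True, **kw)
                absent = render_trace(scene, rf, spot, speed, False, **kw)
                d_lum, cap_l = dprime(present, absent, "luminance")
                d_con, cap_c = dprime(present, absent, "contrast")
                for channel, val, cap in (("luminance", d_lum, cap_l), ("contrast", d_con, cap_c)):
                    rows.append(
                        dict(image_id=img_id, rep=rep, channel=channel,
                             speed_deg_s=speed, dprime=val, capped=cap)
                    )
    results = pd.DataFrame(rows)
    drop_capped = all(s > 0 for s in speeds)
    agg_src = results[~results["capped"]] if drop_capped else results
    summary = (
        agg_src.groupby(["channel", "speed_deg_s"])["dprime"]
        .agg(mean="mean", sem=lambda v: stats.sem(v) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )
    return results, summary
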