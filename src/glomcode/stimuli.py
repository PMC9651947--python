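"""Parametric visual stimulus generators.

Covers the stimulus families used to probe glomerulus surround suppression:

- random-dot coherence fields (kinematograms): a field of identical dark
  dots moving at one speed, where ``coherence`` sets the fraction of dots
  sharing a common "signal" direction and the rest move in uniformly random
  directions.  By construction the dot count, dot size, speed and intensity
  budget are identical at every coherence level — only motion *coherence*
  varies.
- saccade playback displacement: a linear 70 deg ramp over 200 ms applied to
  a background image, mimicking the retinal input during a walking saccade.
- drifting sine grating plus a small dark probe, parameterised by spatial
  period and speed (temporal frequency = speed / period).
- randomly interleaved trial ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DotField",
    "SaccadeStimulus",
    "GratingProbeStimulus",
    "make_dot_field",
    "saccade_displacement",
    "make_grating_probe",
    "interleave_trials",
]

_SCREEN_EXTENT = (360.0, 120.0)  # azimuth, elevation span in degrees


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass
class DotField:
    """Positions and directions of a constant-speed dot kinematogram."""

    positions: np.ndarray  # frames x n_dots x 2 (azimuth, elevation), degrees
    directions: np.ndarray  # n_dots, degrees
    coherence: float
    signal_direction: float
    speed: float  # deg/s
    dot_diameter: float = 15.0
    dot_intensity: float = 0.0  # dark on mean gray
    dt: float = 0.05

    @property
    def n_dots(self) -> int:
        return self.positions.shape[1]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def _stencil_area_px(self, pixel_scale: float) -> int:
        r_px = self.dot_diameter / 2.0 / pixel_scale
        n = int(math.ceil(r_px)) + 1
        yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
        return int(np.count_nonzero(yy**2 + xx**2 <= r_px**2))

    def frame_stats(self, pixel_scale: float = 1.0) -> dict[str, np.ndarray]:
        """Per-frame dot count and mean intensity of the stimulus budget.

        Each dot contributes its full disc area (overlaps counted with
        multiplicity): this is the intensity budget of the physical stimulus
        and is identical across coherence levels by construction, which is the
        defining design property of the coherence stimulus.  Rasterised frames
        from :meth:`render_frames` composite overlapping dots to the darker
        value and may deviate slightly in mean when dots overlap.
        """
        area = self._stencil_area_px(pixel_scale)
        total_px = int(round(_SCREEN_EXTENT[0] / pixel_scale)) * int(
            round(_SCREEN_EXTENT[1] / pixel_scale)
        )
        counts = np.full(self.n_frames, self.n_dots, dtype=int)
        deficit = self.n_dots * area * (0.5 - self.dot_intensity) / total_px
        mean_intensity = np.full(self.n_frames, 0.5 - deficit)
        return {"n_dots": counts, "mean_intensity": mean_intensity}

    def render_frames(self, pixel_scale: float = 1.0) -> np.ndarray:
        """Rasterise dark discs on a mean-gray screen (overlap -> darker)."""
        nx = int(round(_SCREEN_EXTENT[0] / pixel_scale))
        ny = int(round(_SCREEN_EXTENT[1] / pixel_scale))
        frames = np.full((self.n_frames, ny, nx), 0.5)
        az_axis = (np.arange(nx) + 0.5) * pixel_scale
        el_axis = (np.arange(ny) + 0.5) * pixel_scale
        r2 = (self.dot_diameter / 2.0) ** 2
        for k in range(self.n_frames):
            for az, el in self.positions[k]:
                d_az = (az_axis - az + 180.0) % 360.0 - 180.0
                d_el = (el_axis - el + 60.0) % 120.0 - 60.0
                mask = d_az[None, :] ** 2 + d_el[:, None] ** 2 <= r2
                frames[k][mask] = np.minimum(frames[k][mask], self.dot_intensity)
        return frames


def make_dot_field(
    n_dots: int,
    coherence: float,
    signal_direction: float = 0.0,
    speed: float = 80.0,
    duration: float = 3.0,
    dt: float = 0.05,
    seed: int | None = 0,
    dot_diameter: float = 15.0,
) -> DotField:
    """Build a coherence-``c`` dot kinematogram.

    Exactly ``round(coherence * n_dots)`` dots (round-half-away-from-zero)
    take the signal direction; the rest get independent uniform directions on
    [0, 360).  Initial positions are drawn before directions, so fields that
    share a seed have identical frame-0 geometry at every coherence level.
    Positions advance at constant speed with wrap on both axes.
    """
    if not (0.0 <= coherence <= 1.0):
        raise ValueError("coherence must be in [0, 1]")
    if n_dots < 1:
        raise ValueError("need at least one dot")
    rng = np.random.default_rng(seed)
    az0 = rng.uniform(0.0, _SCREEN_EXTENT[0], size=n_dots)
    el0 = rng.uniform(0.0, _SCREEN_EXTENT[1], size=n_dots)
    n_signal = _round_half_away(coherence * n_dots)
    directions = rng.uniform(0.0, 360.0, size=n_dots)
    directions[:n_signal] = signal_direction

    n_frames = int(round(duration / dt))
    t = np.arange(n_frames)[:, None] * dt
    vaz = speed * np.cos(np.deg2rad(directions))[None, :]
    vel = speed * np.sin(np.deg2rad(directions))[None, :]
    az = (az0[None, :] + vaz * t) % _SCREEN_EXTENT[0]
    el = (el0[None, :] + vel * t) % _SCREEN_EXTENT[1]
    positions = np.stack([az, el], axis=-1)
    return DotField(
        positions=positions,
        directions=directions,
        coherence=coherence,
        signal_direction=signal_direction,
        speed=speed,
        dot_diameter=dot_diameter,
        dt=dt,
    )


@dataclass
class SaccadeStimulus:
    """Background translation mimicking a walking saccade (70 deg / 200 ms)."""

    onset_time: float
    displacement_amplitude: float = 70.0
    duration: float = 0.2

    def displacement(self, t) -> np.ndarray:
        return saccade_displacement(
            t, self.onset_time, self.displacement_amplitude, self.duration
        )


def saccade_displacement(
    t, onset: float, amplitude: float = 70.0, duration: float = 0.2
):
    """Azimuthal background displacement (deg) at time(s) ``t``.

    Zero before onset, a linear (constant-velocity) ramp during
    [onset, onset + duration], and ``amplitude`` afterwards.  The default
    70 deg over 200 ms gives the 350 deg/s ballistic displacement of a
    walking saccade.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.asarray(t, dtype=float)
    frac = np.clip((t - onset) / duration, 0.0, 1.0)
    out = amplitude * frac
    return float(out) if out.ndim == 0 else out


@dataclass
class GratingProbeStimulus:
    spatial_period: float  # degrees
    grating_speed: float  # deg/s
    frames: np.ndarray  # frames x elevation x azimuth
    probe_window: tuple[float, float]
    dt: float

    @property
    def temporal_frequency(self) -> float:
        return self.grating_speed / self.spatial_period


def make_grating_probe(
    spatial_period: float,
    grating_speed: float,
    probe_spec: dict | None = None,
    duration: float = 2.0,
    dt: float = 0.02,
    pixel_scale: float = 1.0,
    contrast: float = 1.0,
    extent: tuple[float, float] = (360.0, 60.0),
) -> GratingProbeStimulus:
    """Drifting sine grating with an optional dark probe sweeping the centre.

    ``probe_spec`` keys: ``diameter`` (deg, default 15), ``intensity``
    (default 0), ``speed`` (deg/s, default 100).  Pass ``None`` to disable the
    probe.  Raises if the grating's temporal frequency exceeds the frame-rate
    Nyquist limit.
    """
    if spatial_period <= 0:
        raise ValueError("spatial_period must be positive")
    tf = grating_speed / spatial_period
    if abs(tf) > 0.5 / dt:
        raise ValueError(
            f"temporal frequency {tf:.3g} Hz exceeds Nyquist for dt={dt}"
        )
    nx = int(round(extent[0] / pixel_scale))
    ny = int(round(extent[1] / pixel_scale))
    az = (np.arange(nx) + 0.5) * pixel_scale
    el = (np.arange(ny) + 0.5) * pixel_scale
    n_frames = int(round(duration / dt))
    times = np.arange(n_frames) * dt

    frames = np.empty((n_frames, ny, nx))
    phase = 2.0 * np.pi * (az[None, :] - grating_speed * times[:, None]) / spatial_period
    grating = 0.5 + 0.5 * contrast * np.sin(phase)
    frames[:] = grating[:, None, :]

    window = (0.0, 0.0)
    if probe_spec is not None:
        diameter = probe_spec.get("diameter", 15.0)
        intensity = probe_spec.get("intensity", 0.0)
        speed = probe_spec.get("speed", 100.0)
        el_c = extent[1] / 2.0
        az_path = extent[0] / 2.0 + speed * (times - duration / 2.0)
        r2 = (diameter / 2.0) ** 2
        for k in range(n_frames):
            d_az = (az - az_path[k] + extent[0] / 2.0) % extent[0] - extent[0] / 2.0
            mask = d_az[None, :] ** 2 + (el[:, None] - el_c) ** 2 <= r2
            frames[k][mask] = intensity
        half = diameter / 2.0 / speed
        window = (duration / 2.0 - half, duration / 2.0 + half)
    return GratingProbeStimulus(
        spatial_period=spatial_period,
        grating_speed=grating_speed,
        frames=frames,
        probe_window=window,
        dt=dt,
    )


def interleave_trials(
    stimulus_specs: list, n_trials_per_spec: int, seed: int | None = 0
) -> list:
    """Randomly interleaved trial order: a seeded permutation of the multiset
    with each spec appearing exactly ``n_trials_per_spec`` times."""
    if len(stimulus_specs) == 0:
        raise ValueError("empty stimulus spec list")
    if n_trials_per_spec < 1:
        raise ValueError("n_trials_per_spec must be >= 1")
    rng = np.random.default_rng(seed)
    idx = np.repeat(np.arange(len(stimulus_specs)), n_trials_per_spec)
    rng.shuffle(idx)
    return [stimulus_specs[i] for i in idx]
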