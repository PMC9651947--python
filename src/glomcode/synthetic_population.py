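"""Ground-truth generators for glomerulus population responses and walking.

The generative model mirrors the statistical structure the analysis stack is
designed to recover:

- a tuning matrix with four functional groups of glomeruli (group-structured
  mean responses across a stimulus panel),
- single-trial peak amplitudes
  ``a[g, t] = g_t * tuning[g, s(t)] * exp(beta_g * b_t) + eps``,
  where ``g_t`` is a log-normal gain shared by all glomeruli on trial ``t``,
  ``b_t`` the standardised walking amplitude of that trial, ``beta_g < 0``
  only for a designated "small-object" modulated subset, and ``eps`` iid
  Gaussian noise,
- each trial rendered as a smooth monophasic calcium-like time course
  (difference-of-exponentials kernel, rise 0.1 s / decay 0.5 s) peaking at
  the trial amplitude,
- fictive walking (3-axis ball rotation at 50 Hz) and free-walking
  trajectories whose angular velocity is a saccade point process with a hard
  refractory period, with forward-velocity bouts generated independently of
  saccade timing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .stimuli import interleave_trials

__all__ = [
    "TuningMatrix",
    "PopulationGroundTruth",
    "TrialTensor",
    "WalkingTrace",
    "TrajectorySegment",
    "generate_tuning",
    "generate_trials",
    "generate_walking",
]


@dataclass
class TuningMatrix:
    """Mean response amplitude (dF/F) of each glomerulus to each stimulus."""

    values: np.ndarray  # glomeruli x stimuli, >= 0
    glomerulus_names: list[str]
    stimulus_names: list[str]
    group_labels: np.ndarray  # functional group index per glomerulus

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("tuning values must be non-negative")
        if len(set(self.glomerulus_names)) != len(self.glomerulus_names):
            raise ValueError("glomerulus names must be unique")
        if len(set(self.stimulus_names)) != len(self.stimulus_names):
            raise ValueError("stimulus names must be unique")

    @property
    def n_glomeruli(self) -> int:
        return self.values.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[1]


@dataclass
class PopulationGroundTruth:
    gain: np.ndarray  # per-trial shared multiplicative gain, > 0
    behavior_coupling: np.ndarray  # per-glomerulus beta (<= 0 for modulated)
    modulated: np.ndarray  # boolean mask over glomeruli
    noise_sd: float
    trial_behavior: np.ndarray  # walking amplitude per trial (raw, >= 0)
    amplitudes: np.ndarray  # trials x glomeruli noiseless-rendered peaks


@dataclass
class TrialTensor:
    """Trial-aligned dF/F responses: glomeruli x trials x timepoints."""

    dff: np.ndarray
    time: np.ndarray  # s relative to stimulus onset
    labels: np.ndarray  # stimulus id per trial
    epoch: tuple[float, float, float] = (1.5, 3.0, 1.5)  # pre, stim, tail
    behavior_amplitude: np.ndarray | None = None
    raw_f: np.ndarray | None = None
    glomerulus_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.dff.shape[1] != len(self.labels):
            raise ValueError("labels length must equal n_trials")
        if self.dff.shape[2] != len(self.time):
            raise ValueError("time length must equal n_timepoints")
        pre = self.epoch[0]
        if not np.any(self.time < 0) or pre <= 0:
            raise ValueError("pre-stimulus window must be non-empty")

    @property
    def n_glomeruli(self) -> int:
        return self.dff.shape[0]

    @property
    def n_trials(self) -> int:
        return self.dff.shape[1]


@dataclass
class WalkingTrace:
    """Three-axis ball rotation rates (deg/s) sampled at 50 Hz by default."""

    time: np.ndarray
    rot_x: np.ndarray
    rot_y: np.ndarray
    rot_z: np.ndarray

    @property
    def amplitude(self) -> np.ndarray:
        """Pointwise magnitude of the total rotation vector."""
        return np.sqrt(self.rot_x**2 + self.rot_y**2 + self.rot_z**2)


@dataclass
class TrajectorySegment:
    time: np.ndarray
    x: np.ndarray  # cm
    y: np.ndarray  # cm
    heading: np.ndarray  # degrees, integral of angular velocity
    angular_velocity: np.ndarray  # deg/s
    forward_velocity: np.ndarray  # cm/s


# ---------------------------------------------------------------------------
# Tuning


def generate_tuning(
    n_glomeruli: int = 13,
    n_stimuli: int = 14,
    n_groups: int = 4,
    seed: int | None = 0,
    base_amplitude: float = 1.0,
) -> TuningMatrix:
    """Group-structured heterogeneous tuning.

    Each functional group owns a contiguous block of "preferred" stimuli with
    strong responses; off-block responses are weak.  Within a group, rows are
    scaled and jittered copies of the group template, so within-group tuning
    correlations exceed across-group ones and complete-linkage clustering
    recovers the groups.
    """
    if n_groups > n_glomeruli:
        raise ValueError("n_groups must not exceed n_glomeruli")
    if n_stimuli < n_groups:
        raise ValueError("need at least one preferred stimulus per group")
    rng = np.random.default_rng(seed)
    group_labels = np.sort(np.arange(n_glomeruli) % n_groups)
    stim_blocks = np.array_split(np.arange(n_stimuli), n_groups)

    templates = np.empty((n_groups, n_stimuli))
    for gi in range(n_groups):
        weak = rng.uniform(0.05, 0.25, size=n_stimuli)
        strong = rng.uniform(0.8, 1.2, size=len(stim_blocks[gi]))
        templates[gi] = weak
        templates[gi, stim_blocks[gi]] = strong

    values = np.empty((n_glomeruli, n_stimuli))
    for g in range(n_glomeruli):
        scale = rng.uniform(0.7, 1.3)
        jitter = rng.normal(0.0, 0.05, size=n_stimuli)
        values[g] = np.clip(templates[group_labels[g]] * scale + jitter, 0.02, None)
    values *= base_amplitude
    return TuningMatrix(
        values=values,
        glomerulus_names=[f"glom{g:02d}" for g in range(n_glomeruli)],
        stimulus_names=[f"stim{s:02d}" for s in range(n_stimuli)],
        group_labels=group_labels,
    )


# ---------------------------------------------------------------------------
# Trials


def _doe_kernel(t: np.ndarray, rise: float = 0.1, decay: float = 0.5) -> np.ndarray:
    """Difference-of-exponentials kernel, peak-normalised to 1, zero for t<0."""
    k = np.where(t >= 0, np.exp(-t / decay) - np.exp(-t / rise), 0.0)
    peak = k.max()
    return k / peak if peak > 0 else k


def generate_trials(
    tuning: TuningMatrix,
    gain_sd: float = 0.4,
    behavior_coupling: float = -1.0,
    modulated_fraction: float = 0.4,
    noise_sd: float = 0.1,
    n_trials_per_stim: int = 30,
    dt: float = 1.0 / 7.22,
    epoch: tuple[float, float, float] = (1.5, 3.0, 1.5),
    walking_fraction: float = 0.5,
    seed: int | None = 0,
) -> tuple[TrialTensor, PopulationGroundTruth]:
    """Simulate single-trial population responses with a shared gain.

    Peak amplitude of glomerulus ``g`` on trial ``t``:
    ``g_t * tuning[g, s(t)] * exp(beta_g * b_t) + eps`` with
    ``g_t ~ LogNormal(0, gain_sd)`` (median 1) shared across glomeruli,
    ``b_t`` the standardised walking amplitude, ``beta_g = behavior_coupling``
    for the modulated subset (first ``modulated_fraction`` of glomeruli,
    emulating the small-object-tuned subset) and 0 elsewhere, and
    ``eps ~ N(0, noise_sd)``.  Trials are rendered as dF/F time courses with
    a monophasic kernel peaking at the trial amplitude; stimulus order is
    randomly interleaved.  Default timebase resamples at the 7.22 Hz imaging
    rate with 1.5 s pre, 3 s stimulus, 1.5 s tail epochs.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    G, S = tuning.values.shape
    labels = np.array(
        interleave_trials(list(range(S)), n_trials_per_stim,
                          seed=rng.integers(2**31)),
        dtype=int,
    )
    T = len(labels)

    gain = np.exp(rng.normal(0.0, gain_sd, size=T))
    # trial behavior: a walking/stationary mixture of walking amplitudes
    walking = rng.random(T) < walking_fraction
    behavior = np.where(walking, rng.gamma(4.0, 5.0, size=T), rng.gamma(1.5, 0.8, size=T))
    b_sd = behavior.std()
    b = (behavior - behavior.mean()) / b_sd if b_sd > 0 else np.zeros(T)

    n_mod = int(round(modulated_fraction * G))
    modulated = np.zeros(G, dtype=bool)
    modulated[:n_mod] = True
    beta = np.where(modulated, behavior_coupling, 0.0)

    clean = gain[None, :] * tuning.values[:, labels] * np.exp(np.outer(beta, b))
    amplitudes = clean + rng.normal(0.0, noise_sd, size=(G, T))

    pre, stim, tail = epoch
    time = np.arange(-pre, stim + tail, dt)
    kernel = _doe_kernel(time)
    dff = amplitudes[:, :, None] * kernel[None, None, :]

    tensor = TrialTensor(
        dff=dff,
        time=time,
        labels=labels,
        epoch=epoch,
        behavior_amplitude=behavior,
        glomerulus_names=list(tuning.glomerulus_names),
    )
    truth = PopulationGroundTruth(
        gain=gain,
        behavior_coupling=beta,
        modulated=modulated,
        noise_sd=noise_sd,
        trial_behavior=behavior,
        amplitudes=clean.T,
    )
    return tensor, truth


# ---------------------------------------------------------------------------
# Walking


def generate_walking(
    duration_s: float = 300.0,
    saccade_rate_hz: float = 0.8,
    refractory_s: float = 0.5,
    peak_speed_mean: float = 350.0,
    peak_speed_sd: float = 80.0,
    dt: float = 0.02,
    seed: int | None = 0,
) -> tuple[WalkingTrace, TrajectorySegment, np.ndarray]:
    """Simulate fictive walking with a saccadic turning structure.

    Saccade onsets follow a renewal process with a hard refractory period:
    inter-onset intervals are ``refractory + Gamma(shape=2)`` with the gamma
    scale set so the mean interval is ``1 / saccade_rate_hz``; the resulting
    inter-turn-interval histogram peaks near 1 s with a long tail.  Each
    saccade is a 200 ms raised-cosine angular-velocity pulse (random sign,
    peak speed ~ N(350, 80) truncated above 180 deg/s).  Forward-velocity
    bouts are generated independently of saccade timing; heading integrates
    angular velocity.  Returns the ball trace, the integrated trajectory, and
    the ground-truth onset times.
    """
    if refractory_s < 0:
        raise ValueError("refractory must be non-negative")
    if saccade_rate_hz <= 0:
        raise ValueError("saccade rate must be positive")
    if saccade_rate_hz * refractory_s >= 1.0:
        raise ValueError("infeasible: saccade_rate * refractory >= 1")
    rng = np.random.default_rng(seed)
    mean_free = 1.0 / saccade_rate_hz - refractory_s
    gamma_scale = mean_free / 2.0

    onsets = []
    t = float(rng.gamma(2.0, gamma_scale))  # first onset needs no refractory
    while t < duration_s - 0.3:
        onsets.append(t)
        t += refractory_s + rng.gamma(2.0, gamma_scale)
    onsets = np.asarray(onsets)

    time = np.arange(0.0, duration_s, dt)
    ang = rng.normal(0.0, 3.0, size=len(time))  # sub-threshold jitter
    sacc_dur = 0.2
    rise_frac = 0.15  # ballistic acceleration: peak speed 30 ms after onset
    for onset in onsets:
        peak = max(220.0, rng.normal(peak_speed_mean, peak_speed_sd))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        idx = (time >= onset) & (time < onset + sacc_dur)
        phase = (time[idx] - onset) / sacc_dur
        pulse = np.where(
            phase < rise_frac, phase / rise_frac, (1.0 - phase) / (1.0 - rise_frac)
        )
        ang[idx] += sign * peak * pulse

    # forward bouts: slow gating noise, independent of saccade timing
    w = int(round(2.0 / dt))
    kernel = np.ones(w) / w
    gate = np.convolve(rng.standard_normal(len(time)), kernel, mode="same") > 0
    wobble = np.convolve(rng.standard_normal(len(time)), kernel, mode="same") * 40.0
    forward = np.clip(8.0 + wobble, 0.0, None) * gate

    # ball channels: z carries the turning signal (attenuated relative to the
    # free-walking trajectory: head-fixed turning attempts move the ball less
    # than free saccades turn the body) plus walking-bout rotational jitter;
    # x/y carry forward + slip components, so forward and rotational movement
    # components are correlated
    rot_z = 0.3 * ang + gate * rng.normal(0.0, 15.0, size=len(time))
    rot_x = forward * 1.5 + rng.normal(0.0, 1.0, size=len(time))
    rot_y = forward * 0.3 + rng.normal(0.0, 1.0, size=len(time))
    trace = WalkingTrace(time=time, rot_x=rot_x, rot_y=rot_y, rot_z=rot_z)

    heading = np.cumsum(ang) * dt
    hx = np.cos(np.deg2rad(heading))
    hy = np.sin(np.deg2rad(heading))
    x = np.cumsum(forward * hx) * dt
    y = np.cumsum(forward * hy) * dt
    traj = TrajectorySegment(
        time=time, x=x, y=y, heading=heading,
        angular_velocity=ang, forward_velocity=forward,
    )
    return trace, traj, onsets
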