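"""End-to-end experiment orchestration.

Each experiment generates its synthetic inputs, runs the corresponding
analysis chain, writes tables (CSV) and a machine-readable JSON summary, and
drops a sidecar JSON next to every artifact recording the configuration hash
and the seeds used.  A single global seed expands deterministically into
per-stage child seeds via ``numpy.random.SeedSequence(seed).spawn``, so any
stage can be rerun in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    behavior_analysis,
    gain_analysis,
    population_analysis,
    scene_discrimination,
    scenes,
    synthetic_population,
)

logger = logging.getLogger(__name__)

EXPERIMENTS = (
    "fig1_discriminability",
    "fig4_decoding",
    "fig5_behavior_gain",
    "fig8_saccade_stats",
    "fig9_independence",
)

__all__ = ["RunConfig", "run_experiment", "stage_seeds", "io_roundtrip", "EXPERIMENTS"]


def io_roundtrip(tensor, truth=None, path=None):
    """Write a dataset to HDF5 and read it back (equality is tested)."""
    import tempfile

    from .io import load_trial_tensor, save_trial_tensor

    if path is None:
        with tempfile.NamedTemporaryFile(suffix=".h5", delete=False) as fh:
            path = fh.name
    save_trial_tensor(path, tensor, truth)
    return load_trial_tensor(path)


@dataclass
class RunConfig:
    """Validated run configuration with per-module parameter blocks."""

    seed: int = 0
    out_dir: str = "results"
    verbosity: str = "INFO"
    scenes: dict = field(default_factory=dict)
    stimuli: dict = field(default_factory=dict)
    generator: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    gain: dict = field(default_factory=dict)

    _FIELDS = ("seed", "out_dir", "verbosity", "scenes", "stimuli",
               "generator", "analysis", "gain")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(cls._FIELDS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if not isinstance(cfg.seed, int):
            raise ValueError("seed must be an integer")
        for block in ("scenes", "stimuli", "generator", "analysis", "gain"):
            if not isinstance(getattr(cfg, block), dict):
                raise ValueError(f"config block {block!r} must be a mapping")
        return cfg

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage child seeds from one global seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _write_sidecar(path: Path, config: RunConfig, seeds: list[int], stage: str) -> None:
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    sidecar.write_text(json.dumps(
        {"stage": stage, "config_hash": config.digest(), "seed": config.seed,
         "stage_seeds": seeds}, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def run_experiment(config: RunConfig, experiment: str) -> dict:
    """Run one named experiment chain; returns the summary dict.

    Writes ``<out_dir>/<experiment>_summary.json`` (plus CSV tables where the
    experiment produces them), each with a provenance sidecar.  Rerunning with
    the same config reproduces the outputs (all stochastic stages are
    seeded).
    """
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}; choose from {EXPERIMENTS}")
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    logger.info("running %s (seed=%d, config=%s)", experiment, config.seed, config.digest())
    runner = {
        "fig1_discriminability": _run_discriminability,
        "fig4_decoding": _run_decoding,
        "fig5_behavior_gain": _run_behavior_gain,
        "fig8_saccade_stats": _run_saccade_stats,
        "fig9_independence": _run_independence,
    }[experiment]
    try:
        summary = runner(config, seeds, out_dir)
    except Exception as exc:  # label the failing stage, keep prior outputs
        raise RuntimeError(f"experiment {experiment!r} failed: {exc}") from exc
    summary["experiment"] = experiment
    summary["seed"] = config.seed
    summary["config_hash"] = config.digest()
    summary_path = out_dir / f"{experiment}_summary.json"
    summary_path.write_text(json.dumps(_jsonable(summary), indent=2, allow_nan=False))
    _write_sidecar(summary_path, config, seeds, experiment)
    return summary


def _finite(x: float) -> float:
    return float(np.clip(x, -1e12, 1e12))


def _run_discriminability(config: RunConfig, seeds: list[int], out_dir: Path) -> dict:
    p = {"n_images": 20, "speeds": [0.0, 20.0, 40.0, 80.0, 160.0, 320.0],
         "height_px": 96, "width_px": 512, "slope": -2.0, **config.scenes}
    images = [
        scenes.generate_pink_image(p["height_px"], p["width_px"], slope=p["slope"],
                                   seed=seeds[0] + i)
        for i in range(p["n_images"])
    ]
    results, summary = scene_discrimination.speed_sweep(
        images, p["speeds"], seed=seeds[1]
    )
    table_path = out_dir / "fig1_discriminability.csv"
    results.to_csv(table_path, index=False)
    _write_sidecar(table_path, config, seeds, "fig1_discriminability")
    from scipy import stats as sstats

    nonzero = summary[summary["speed_deg_s"] > 0]
    rho = {}
    for channel, block in nonzero.groupby("channel"):
        rho[channel] = float(sstats.spearmanr(block["speed_deg_s"], block["mean"]).statistic)
    return {
        "n_images": p["n_images"],
        "speeds": p["speeds"],
        "mean_dprime": {
            ch: {float(r["speed_deg_s"]): _finite(r["mean"]) for _, r in blk.iterrows()}
            for ch, blk in summary.groupby("channel")
        },
        "speed_trend_spearman": rho,
    }


def _make_dataset(config: RunConfig, seeds: list[int]):
    g = {"n_glomeruli": 13, "n_stimuli": 14, "n_trials_per_stim": 30,
         "gain_sd": 0.4, "noise_sd": 0.1, "behavior_coupling": -1.0,
         **config.generator}
    tuning = synthetic_population.generate_tuning(
        g["n_glomeruli"], g["n_stimuli"], seed=seeds[0]
    )
    tensor, truth = synthetic_population.generate_trials(
        tuning,
        gain_sd=g["gain_sd"],
        noise_sd=g["noise_sd"],
        behavior_coupling=g["behavior_coupling"],
        n_trials_per_stim=g["n_trials_per_stim"],
        seed=seeds[1],
    )
    return tuning, tensor, truth


def _run_decoding(config: RunConfig, seeds: list[int], out_dir: Path) -> dict:
    a = {"n_iterations": 100, **config.analysis}
    _, tensor, truth = _make_dataset(config, seeds)
    amps = population_analysis.peak_amplitudes(tensor)
    intact = population_analysis.decode(amps, n_iterations=a["n_iterations"], seed=seeds[2])
    shuffled_amps = population_analysis.shuffle_trials(amps, seed=seeds[3])
    shuffled = population_analysis.decode(
        shuffled_amps, n_iterations=a["n_iterations"], seed=seeds[2], shuffled=True
    )
    corr = population_analysis.trial_correlations(amps)
    pd.DataFrame(corr.values).to_csv(out_dir / "fig4_correlations.csv", index=False)
    _write_sidecar(out_dir / "fig4_correlations.csv", config, seeds, "fig4_decoding")
    decrement = 100.0 * (intact.overall_accuracy - shuffled.overall_accuracy) / intact.overall_accuracy
    return {
        "accuracy_intact": intact.overall_accuracy,
        "accuracy_shuffled": shuffled.overall_accuracy,
        "shuffle_decrement_pct": decrement,
        "chance": 1.0 / len(intact.classes),
        "mean_offdiagonal_correlation": corr.mean_offdiagonal(),
        "confusion_intact": intact.confusion,
    }


def _run_behavior_gain(config: RunConfig, seeds: list[int], out_dir: Path) -> dict:
    n_flies = int(config.analysis.get("n_flies", 8))
    rhos = []
    flagged = None
    modulated = None
    for f in range(n_flies):
        fly_seeds = stage_seeds(seeds[0] + f)
        _, tensor, truth = _make_dataset(
            RunConfig(seed=config.seed, generator=config.generator), fly_seeds
        )
        amps = population_analysis.peak_amplitudes(tensor)
        rhos.append(
            population_analysis.behavior_correlation(amps, tensor.behavior_amplitude)
        )
        modulated = truth.modulated
    rhos = np.stack(rhos)
    test = population_analysis.behavior_correlation_test(rhos)
    score, _, var = population_analysis.shared_gain(amps)
    from scipy import stats as sstats

    gain_rho = float(sstats.spearmanr(score, tensor.behavior_amplitude).statistic)
    curve = gain_analysis.gain_vs_walking(
        amps, tensor.behavior_amplitude, bin_edges=np.array([0, 5, 10, 15, 20, 30, 50])
    )
    df = pd.DataFrame({"glomerulus": range(rhos.shape[1]),
                       "mean_rho": test["mean_rho"], "p_holm": test["p_holm"],
                       "significant": test["significant"], "modulated_truth": modulated})
    df.to_csv(out_dir / "fig5_behavior_rho.csv", index=False)
    _write_sidecar(out_dir / "fig5_behavior_rho.csv", config, seeds, "fig5_behavior_gain")
    return {
        "n_flies": n_flies,
        "mean_rho": test["mean_rho"],
        "significant": test["significant"],
        "modulated_truth": modulated,
        "pc1_variance_explained": var,
        "pc1_behavior_spearman": gain_rho,
        "gain_vs_walking_x": curve.x,
        "gain_vs_walking_y": curve.y,
    }


def _run_saccade_stats(config: RunConfig, seeds: list[int], out_dir: Path) -> dict:
    duration = float(config.generator.get("walk_duration_s", 300.0))
    trace, traj, true_onsets = synthetic_population.generate_walking(
        duration_s=duration, seed=seeds[0]
    )
    events = behavior_analysis.detect_saccades(traj.angular_velocity, traj.time)
    stats_ = behavior_analysis.saccade_cycle_stats(
        events, traj.angular_velocity, traj.forward_velocity, traj.time
    )
    matched = 0
    for t0 in true_onsets:
        if len(events) and np.min(np.abs(events.onset_times - t0)) <= 0.05:
            matched += 1
    recall = matched / len(true_onsets) if len(true_onsets) else float("nan")
    false_events = sum(
        1 for t in events.onset_times
        if len(true_onsets) == 0 or np.min(np.abs(true_onsets - t)) > 0.05
    )
    iti = events.inter_turn_intervals
    return {
        "n_true": int(len(true_onsets)),
        "n_detected": int(len(events)),
        "recall": recall,
        "false_event_fraction": false_events / max(len(events), 1),
        "iti_median_s": float(np.median(iti)) if iti.size else None,
        "iti_below_refractory_fraction": float(np.mean(iti < 0.5)) if iti.size else None,
        "forward_velocity_ks_p": stats_.get("forward_velocity_ks", {}).get("p"),
    }


def _run_independence(config: RunConfig, seeds: list[int], out_dir: Path) -> dict:
    g = {"n_glomeruli": 8, "n_trials_per_cell": 50, "g_visual": 0.6,
         "g_behavior": 0.7, "noise_sd": 0.15, "interaction": 0.0, **config.gain}
    rng = np.random.default_rng(seeds[0])
    G, n = g["n_glomeruli"], g["n_trials_per_cell"]
    base = rng.uniform(0.8, 1.2, size=G)
    cells = {}
    flags = {(0, 0): (1.0, 1.0), (1, 0): (g["g_visual"], 1.0),
             (0, 1): (1.0, g["g_behavior"]),
             (1, 1): (g["g_visual"], g["g_behavior"])}
    values, vis, walk = [], [], []
    for (v, w), (gv, gb) in flags.items():
        mean = base * gv * gb
        if v and w:
            mean = mean + g["interaction"]
        block = mean[None, :] + rng.normal(0.0, g["noise_sd"], size=(n, G))
        values.append(block)
        vis += [v] * n
        walk += [w] * n
    amps = population_analysis.AmplitudeMatrix(
        values=np.vstack(values), labels=np.zeros(4 * n, dtype=int)
    )
    table = gain_analysis.build_gain_table(amps, np.array(vis), np.array(walk))
    res = gain_analysis.independence_test(table, seed=seeds[1])
    df = pd.DataFrame({k: res[k] for k in
                       ("g_visual", "g_behavior", "predicted", "observed",
                        "deviation", "ci_low", "ci_high")})
    df.to_csv(out_dir / "fig9_independence.csv", index=False)
    _write_sidecar(out_dir / "fig9_independence.csv", config, seeds, "fig9_independence")
    return {
        "interaction_injected": g["interaction"],
        "deviation": res["deviation"],
        "ci_low": res["ci_low"],
        "ci_high": res["ci_high"],
        "coverage_fraction": float(np.mean(res["covers_zero"])),
    }
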