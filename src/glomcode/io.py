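"""HDF5 persistence for trial tensors and behavior traces.

Layout (version 1):

    /responses              glomeruli x trials x timepoints dF/F
    /responses@time         timebase (s, relative to stimulus onset)
    /responses@epoch        (pre, stim, tail) seconds
    /labels                 stimulus id per trial
    /behavior/amplitude     per-trial walking amplitude (optional)
    /truth/gain             per-trial shared gain (optional)
    /truth/coupling         per-glomerulus behavior coupling (optional)
    /truth/saccade_times    ground-truth saccade onsets (optional)

Optional groups absent on write stay absent on read.
"""

from __future__ import annotations

import numpy as np
import h5py

from .synthetic_population import PopulationGroundTruth, TrialTensor

LAYOUT_VERSION = "1"

__all__ = ["save_trial_tensor", "load_trial_tensor", "LAYOUT_VERSION"]


def save_trial_tensor(
    path, tensor: TrialTensor, truth: PopulationGroundTruth | None = None
) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["layout_version"] = LAYOUT_VERSION
        ds = h5.create_dataset("responses", data=tensor.dff)
        ds.attrs["time"] = tensor.time
        ds.attrs["epoch"] = tensor.epoch
        labels = np.asarray(tensor.labels)
        if labels.dtype.kind in "UO":
            labels = labels.astype(h5py.string_dtype())
        h5.create_dataset("labels", data=labels)
        if tensor.glomerulus_names is not None:
            h5.create_dataset(
                "glomerulus_names",
                data=np.asarray(tensor.glomerulus_names, dtype=h5py.string_dtype()),
            )
        if tensor.behavior_amplitude is not None:
            h5.create_dataset("behavior/amplitude", data=tensor.behavior_amplitude)
        if tensor.raw_f is not None:
            h5.create_dataset("raw_f", data=tensor.raw_f)
        if truth is not None:
            h5.create_dataset("truth/gain", data=truth.gain)
            h5.create_dataset("truth/coupling", data=truth.behavior_coupling)
            h5.create_dataset("truth/modulated", data=truth.modulated)
            h5.create_dataset("truth/trial_behavior", data=truth.trial_behavior)
            h5.create_dataset("truth/amplitudes", data=truth.amplitudes)
            h5["truth"].attrs["noise_sd"] = truth.noise_sd


def load_trial_tensor(path) -> tuple[TrialTensor, PopulationGroundTruth | None]:
    with h5py.File(path, "r") as h5:
        version = h5.attrs.get("layout_version")
        if version != LAYOUT_VERSION:
            raise ValueError(
                f"layout version mismatch: file has {version!r}, "
                f"reader expects {LAYOUT_VERSION!r}"
            )
        ds = h5["responses"]
        labels = h5["labels"][()]
        if labels.dtype.kind in "SO":
            labels = labels.astype(str)
        names = None
        if "glomerulus_names" in h5:
            names = [n.decode() if isinstance(n, bytes) else str(n)
                     for n in h5["glomerulus_names"][()]]
        tensor = TrialTensor(
            dff=ds[()],
            time=ds.attrs["time"][()],
            labels=labels,
            epoch=tuple(float(v) for v in ds.attrs["epoch"]),
            behavior_amplitude=h5["behavior/amplitude"][()] if "behavior" in h5 else None,
            raw_f=h5["raw_f"][()] if "raw_f" in h5 else None,
            glomerulus_names=names,
        )
        truth = None
        if "truth" in h5:
            truth = PopulationGroundTruth(
                gain=h5["truth/gain"][()],
                behavior_coupling=h5["truth/coupling"][()],
                modulated=h5["truth/modulated"][()].astype(bool),
                noise_sd=float(h5["truth"].attrs["noise_sd"]),
                trial_behavior=h5["truth/trial_behavior"][()],
                amplitudes=h5["truth/amplitudes"][()],
            )
    return tensor, truth
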