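"""HDF5 interchange containers for the pipeline's array types.

Every stage reads and writes these containers so stages can be run (and
tested) independently: predictors, single-channel EEG, TRF sets, ERPs and
click trains, each with its metadata stored as HDF5 attributes.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .deconvolve import ERP, TRFSet
from .predictors import Predictor
from .preprocess import EEGRecording
from .stimuli import ClickTrain
from .synthetic import GroundTruthKernels

__all__ = [
    "save_predictor", "load_predictor",
    "save_eeg", "load_eeg",
    "save_trfset", "load_trfset",
    "save_erp", "load_erp",
    "save_clicks", "load_clicks",
    "save_ground_truth", "load_ground_truth",
]


def save_predictor(path, pred: Predictor) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("series", data=pred.series)
        d.attrs["rate"] = pred.rate
        d.attrs["name"] = pred.name
        d.attrs["applied_lag"] = pred.applied_lag


def load_predictor(path) -> Predictor:
    with h5py.File(path, "r") as f:
        d = f["series"]
        return Predictor(d[...], float(d.attrs["rate"]), str(d.attrs["name"]),
                         float(d.attrs["applied_lag"]))


def save_eeg(path, eeg: EEGRecording) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("series", data=eeg.series)
        d.attrs["rate"] = eeg.rate
        d.attrs["reference"] = eeg.reference
        f.create_dataset("zeroed_segments", data=np.asarray(eeg.zeroed_segments, dtype=float).reshape(-1, 2))


def load_eeg(path) -> EEGRecording:
    with h5py.File(path, "r") as f:
        d = f["series"]
        segs = [tuple(row) for row in f["zeroed_segments"][...]]
        return EEGRecording(d[...], float(d.attrs["rate"]), segs, str(d.attrs["reference"]))


def save_trfset(path, trfs: TRFSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("lags_ms", data=trfs.lags_ms)
        d = f.create_dataset("kernels", data=trfs.kernels)
        f.create_dataset("labels", data=np.asarray(trfs.labels, dtype=float))
        d.attrs["rate"] = trfs.rate
        d.attrs["smoothed"] = trfs.smoothed
        d.attrs["scale_factor"] = trfs.scale_factor
        if trfs.norm_scales is not None:
            f.create_dataset("norm_scales", data=trfs.norm_scales)


def load_trfset(path) -> TRFSet:
    with h5py.File(path, "r") as f:
        d = f["kernels"]
        norm = f["norm_scales"][...] if "norm_scales" in f else None
        return TRFSet(f["lags_ms"][...], d[...], f["labels"][...], float(d.attrs["rate"]),
                      bool(d.attrs["smoothed"]), float(d.attrs["scale_factor"]), norm)


def save_erp(path, erp: ERP) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times_ms", data=erp.times_ms)
        d = f.create_dataset("waveform", data=erp.waveform)
        d.attrs["level"] = np.nan if erp.level is None else erp.level
        d.attrs["n_epochs"] = erp.n_epochs


def load_erp(path) -> ERP:
    with h5py.File(path, "r") as f:
        d = f["waveform"]
        level = float(d.attrs["level"])
        return ERP(f["times_ms"][...], d[...], None if np.isnan(level) else level,
                   int(d.attrs["n_epochs"]))


def save_clicks(path, train: ClickTrain) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("onset_times", data=train.onset_times)
        f.create_dataset("polarities", data=train.polarities)
        d.attrs["click_duration"] = train.click_duration
        d.attrs["sample_rate"] = train.sample_rate


def load_clicks(path) -> ClickTrain:
    with h5py.File(path, "r") as f:
        d = f["onset_times"]
        return ClickTrain(d[...], f["polarities"][...], float(d.attrs["click_duration"]),
                          float(d.attrs["sample_rate"]))


def save_ground_truth(path, kernels: GroundTruthKernels, level_scales: dict | None = None) -> None:
    payload = {
        "levels": list(kernels.levels),
        "latencies_ms": list(kernels.latencies_ms),
        "amplitudes": list(kernels.amplitudes),
        "width_ms": kernels.width_ms,
        "family": kernels.family,
    }
    if level_scales is not None:
        payload["level_scales"] = {str(k): v for k, v in level_scales.items()}
    with open(path, "w") as f:
        json.dump(payload, f, indent=2)


def load_ground_truth(path) -> tuple[GroundTruthKernels, dict | None]:
    with open(path) as f:
        payload = json.load(f)
    scales = payload.pop("level_scales", None)
    if scales is not None:
        scales = {float(k): v for k, v in scales.items()}
    kernels = GroundTruthKernels(
        tuple(payload["levels"]), tuple(payload["latencies_ms"]),
        tuple(payload["amplitudes"]), payload["width_ms"], payload["family"],
    )
    return kernels, scales
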