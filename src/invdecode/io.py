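"""HDF5 container for cohorts of ROI-level trials.

Layout: one group per ``subject_<s>/<stimulus>`` holding datasets
``trials`` (M x R x T float) and ``labels`` (M int, 0=upright, 1=inverted),
with attributes ``fs``, ``t0``, ``roi_names``, ``seed`` and the generating
EffectSpec as a JSON attribute when available.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np

from .atlas import DK_ROI_NAMES
from .datatypes import StimulusDataset, TrialMatrix
from .simulate import EffectSpec


def save_cohort(
    path: str | Path,
    cohort: Mapping[str, list[StimulusDataset]],
    seed: int | None = None,
    effects: Mapping[str, EffectSpec] | None = None,
) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["roi_names"] = np.array(DK_ROI_NAMES, dtype=h5py.string_dtype())
        if seed is not None:
            f.attrs["seed"] = int(seed)
        for stim, datasets in cohort.items():
            for ds in datasets:
                g = f.create_group(f"subject_{ds.subject:03d}/{stim}")
                X, y = ds.stacked()
                g.create_dataset("trials", data=X.astype(np.float64))
                g.create_dataset("labels", data=y.astype(np.int64))
                g.attrs["fs"] = ds.fs
                g.attrs["t0"] = ds.t0
                if effects is not None and stim in effects:
                    g.attrs["effect_spec"] = json.dumps(dataclasses.asdict(effects[stim]))
    return path


def load_cohort(path: str | Path) -> dict[str, list[StimulusDataset]]:
    cohort: dict[str, list[StimulusDataset]] = {}
    with h5py.File(path, "r") as f:
        for subj_key in sorted(k for k in f if k.startswith("subject_")):
            subject = int(subj_key.split("_")[1])
            for stim in f[subj_key]:
                g = f[subj_key][stim]
                X = np.asarray(g["trials"])
                y = np.asarray(g["labels"])
                fs = float(g.attrs["fs"])
                t0 = float(g.attrs["t0"])
                trials = [
                    TrialMatrix(X=X[i], y=int(y[i]), subject=subject, stimulus=stim, fs=fs, t0=t0)
                    for i in range(X.shape[0])
                ]
                cohort.setdefault(stim, []).append(
                    StimulusDataset(trials=trials, subject=subject, stimulus=stim)
                )
    return cohort
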