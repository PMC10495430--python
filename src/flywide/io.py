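"""File formats: HDF5 for activity/traces/geometry, delimited text for
behavior tables, YAML for configs."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .behavior import MARKER_NAMES, Ethogram, MarkerTimeSeries, StateProbabilities
from .fluorescence import DualChannelTraces

__all__ = [
    "save_activity_h5",
    "load_activity_h5",
    "save_behavior_tables",
    "load_behavior_tables",
    "save_config_yaml",
    "load_config_yaml",
]


def save_activity_h5(
    path,
    dff: np.ndarray | None = None,
    traces: DualChannelTraces | None = None,
    coords: np.ndarray | None = None,
    sampling_rate: float | None = None,
    truth_arrays: dict | None = None,
) -> None:
    """Write activity (/activity), raw channels (/red, /green), geometry
    (/coords) and ground-truth arrays (/truth/...) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        if sampling_rate is not None:
            f.attrs["sampling_rate"] = float(sampling_rate)
        if dff is not None:
            f.create_dataset("activity", data=np.asarray(dff))
        if traces is not None:
            f.create_dataset("red", data=traces.red)
            f.create_dataset("green", data=traces.green)
            f.attrs["sampling_rate"] = float(traces.sampling_rate)
        if coords is not None:
            f.create_dataset("coords", data=np.asarray(coords))
        if truth_arrays:
            grp = f.create_group("truth")
            for key, val in truth_arrays.items():
                grp.create_dataset(key, data=np.asarray(val))


def load_activity_h5(path) -> dict:
    out: dict = {}
    with h5py.File(path, "r") as f:
        for key in ("activity", "red", "green", "coords"):
            if key in f:
                out[key] = f[key][()]
        if "sampling_rate" in f.attrs:
            out["sampling_rate"] = float(f.attrs["sampling_rate"])
        if "truth" in f:
            out["truth"] = {k: f["truth"][k][()] for k in f["truth"]}
    return out


def save_behavior_tables(
    prefix,
    probs: StateProbabilities,
    ethogram: Ethogram,
    markers: MarkerTimeSeries | None = None,
) -> list:
    """Write per-frame state probabilities + ethogram labels (one CSV) and
    marker x/y coordinates (another CSV). Returns the written paths."""
    prefix = Path(prefix)
    written = []
    df = pd.DataFrame(probs.probs.T, columns=[f"p_{s}" for s in probs.states])
    df.insert(0, "frame", np.arange(probs.n_frames))
    df["label"] = ethogram.labels
    p1 = prefix.with_suffix(".states.csv")
    df.to_csv(p1, index=False)
    written.append(p1)
    if markers is not None:
        cols = {}
        for j, name in enumerate(MARKER_NAMES):
            cols[f"{name}_x"] = markers.xy[:, j, 0]
            cols[f"{name}_y"] = markers.xy[:, j, 1]
        m = pd.DataFrame(cols)
        m.insert(0, "frame", np.arange(markers.n_frames))
        p2 = prefix.with_suffix(".markers.csv")
        m.to_csv(p2, index=False)
        written.append(p2)
    return written


def load_behavior_tables(states_csv, sampling_rate: float) -> tuple[StateProbabilities, Ethogram]:
    df = pd.read_csv(states_csv)
    state_cols = [c for c in df.columns if c.startswith("p_")]
    states = tuple(c[2:] for c in state_cols)
    probs = StateProbabilities(
        probs=df[state_cols].to_numpy().T, states=states, sampling_rate=sampling_rate
    )
    eth = Ethogram(labels=df["label"].to_numpy(dtype=object), states=states, sampling_rate=sampling_rate)
    return probs, eth


def save_config_yaml(path, config) -> None:
    data = asdict(config) if not isinstance(config, dict) else config

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    with open(path, "w") as f:
        yaml.safe_dump(clean(data), f, sort_keys=False)


def load_config_yaml(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)
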