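"""End-to-end orchestration: synthetic data (or loaded data) -> fluorescence
-> behavior -> encoding -> residual -> clustering -> spatial.

Each stage reads and writes files, so any stage can be re-run in isolation;
a manifest (file list + SHA-256 content hashes + config echo) makes reruns
comparable and regressions detectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import clustering, encoding, residual, spatial
from .behavior import ethogram_from_probs
from .fluorescence import process as fluorescence_process
from .io import (
    load_activity_h5,
    load_behavior_tables,
    save_activity_h5,
    save_behavior_tables,
    save_config_yaml,
)
from .synthetic import (
    BehaviorSimConfig,
    NeuralSimConfig,
    generate_activity,
    generate_behavior,
    generate_cells,
)

__all__ = ["RunConfig", "run_all", "STAGES"]

logger = logging.getLogger("flywide.pipeline")

STAGES = ("synthetic", "fluorescence", "behavior", "encoding", "residual", "clustering", "spatial")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Every stochastic stage derives its seed from ``seed``; the config
    round-trips losslessly through YAML.
    """

    outdir: str = "flywide_run"
    seed: int = 0
    stages: tuple = STAGES
    behavior: BehaviorSimConfig = field(default_factory=BehaviorSimConfig)
    neural: NeuralSimConfig = field(default_factory=NeuralSimConfig)
    polish_fits: bool = False
    n_shifts: int = 5
    max_modes: int | None = 60
    n_shuffles: int = 1000
    sd_thresh: float = 5.0

    def __post_init__(self) -> None:
        if isinstance(self.behavior, dict):
            self.behavior = BehaviorSimConfig(**self.behavior)
        if isinstance(self.neural, dict):
            self.neural = NeuralSimConfig(**self.neural)
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # reproducibility contract: propagate the run seed into the generators
        self.behavior = dataclasses.replace(self.behavior, seed=self.seed)
        self.neural = dataclasses.replace(self.neural, seed=self.seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages and return the output manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest: dict = {"stages": [], "files": {}, "config": None}
    save_config_yaml(out / "config.yaml", config)
    manifest["config"] = str(out / "config.yaml")

    state: dict = {}
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            t0 = time.time()
            logger.info("stage %s starting", stage)
            _run_stage(stage, config, out, state)
            logger.info("stage %s done in %.1fs", stage, time.time() - t0)
            manifest["stages"].append(stage)
    except Exception as exc:
        logger.error("stage failed: %s", exc)
        manifest["failed_stage"] = stage
        _write_manifest(out, manifest)
        raise RuntimeError(f"pipeline aborted in stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest["files"] = {str(p.relative_to(out)): _sha256(p) for p in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _run_stage(stage: str, config: RunConfig, out: Path, state: dict) -> None:
    if stage == "synthetic":
        behavior = generate_behavior(config.behavior)
        cells = generate_cells(config.neural)
        activity = generate_activity(behavior, cells, config.neural)
        state.update(behavior=behavior, coords=cells[0], activity=activity)
        save_behavior_tables(out / "behavior", behavior.state_probs, behavior.ethogram, behavior.markers)
        save_activity_h5(
            out / "raw.h5",
            traces=activity.traces,
            coords=cells[0].xyz,
            truth_arrays={
                "gamma": activity.truth.gamma,
                "tau": activity.truth.tau,
                "phi": activity.truth.phi,
                "alpha": activity.truth.alpha,
                "anticorrelated": activity.truth.anticorrelated_mask.astype(int),
                "motion_cells": activity.truth.motion_cell_mask.astype(int),
            },
        )
        return

    if stage == "fluorescence":
        raw = load_activity_h5(out / "raw.h5")
        from .fluorescence import DualChannelTraces

        traces = DualChannelTraces(green=raw["green"], red=raw["red"], sampling_rate=raw["sampling_rate"])
        act = fluorescence_process(traces)
        state["activity_matrix"] = act
        save_activity_h5(
            out / "activity.h5", dff=act.dff, sampling_rate=act.sampling_rate,
            truth_arrays={"qc_cv2": act.qc_cv2, "kept": act.kept_mask.astype(int)},
        )
        return

    if stage == "behavior":
        raw = load_activity_h5(out / "activity.h5")
        probs, eth = load_behavior_tables(out / "behavior.states.csv", raw["sampling_rate"])
        state["probs"], state["ethogram"] = probs, eth
        return

    if stage == "encoding":
        act = load_activity_h5(out / "activity.h5")
        probs, eth = load_behavior_tables(out / "behavior.states.csv", act["sampling_rate"])
        kept = act["truth"]["kept"].astype(bool)
        dff = act["activity"][kept]
        enc = encoding.PopulationEncoder(probs, polish=config.polish_fits)
        fits = enc.fit_with_significance(dff, n_shifts=config.n_shifts, seed=config.seed)
        df = enc.to_frame(fits)
        df["orig_cell"] = np.where(kept)[0]
        df.to_csv(out / "fits.csv", index=False)
        state["fits"], state["encoder"] = fits, enc
        resid = residual.compute_residuals(dff, fits, probs)
        save_activity_h5(out / "residuals.h5", dff=resid, sampling_rate=act["sampling_rate"])
        return

    if stage == "residual":
        res = load_activity_h5(out / "residuals.h5")["activity"]
        act = load_activity_h5(out / "activity.h5")
        probs, eth = load_behavior_tables(out / "behavior.states.csv", act["sampling_rate"])
        dim = residual.cv_dimensionality(res, max_modes=config.max_modes)
        p = residual.pca_modes(res)
        sparse = residual.participation(p.modes[: max(dim.m, 1)])
        summary = {
            "dimensionality": dim.m,
            "participation_ratio": sparse.pr.tolist(),
            "sparseness_fraction": sparse.fraction.tolist(),
        }
        (out / "residual_summary.json").write_text(json.dumps(summary, indent=2))
        patterns = []
        for j in range(max(dim.m, 1)):
            sel = residual.binarize_mode(p.modes[j], sd_thresh=config.sd_thresh)
            if sel.size >= 2:
                patterns.append({"mode": j, "cells": sel.tolist()})
        (out / "patterns.json").write_text(json.dumps(patterns))
        state["residuals"], state["modes"] = res, p
        return

    if stage == "clustering":
        res = load_activity_h5(out / "residuals.h5")["activity"]
        train, test = residual.split_time_blocks(res.shape[1])
        tree = clustering.build_tree(res[:, train])
        sigs = clustering.test_clusters(tree, res[:, test], seed=config.seed)
        (out / "tree.json").write_text(clustering.tree_to_json(tree, sigs))
        clustering.results_to_frame(tree, sigs).to_csv(out / "clusters.csv", index=False)
        state["tree"], state["cluster_sig"] = tree, sigs
        return

    if stage == "spatial":
        raw = load_activity_h5(out / "raw.h5")
        act = load_activity_h5(out / "activity.h5")
        kept = act["truth"]["kept"].astype(bool)
        coords = raw["coords"][kept]
        folded = spatial.fold_coordinates(coords)
        rows = []
        if (out / "patterns.json").exists():
            for pat in json.loads((out / "patterns.json").read_text()):
                cells = np.array(pat["cells"])
                if cells.size < 2:
                    continue
                st = spatial.shuffle_test(cells, folded, n_shuffles=config.n_shuffles, seed=config.seed)
                rows.append({"source": f"mode{pat['mode']}", "n": cells.size,
                             "observed": st.observed, "p": st.p})
        if (out / "clusters.csv").exists():
            import pandas as pd

            cl = pd.read_csv(out / "clusters.csv")
            for _, row in cl[cl["significant"] == True].iterrows():  # noqa: E712
                cells = np.array([int(c) for c in str(row["members"]).split(";")])
                if cells.size < 2 or cells.size > folded.shape[0] // 2:
                    continue
                st = spatial.shuffle_test(cells, folded, n_shuffles=config.n_shuffles, seed=config.seed)
                rows.append({"source": f"cluster{row['node']}", "n": cells.size,
                             "observed": st.observed, "p": st.p})
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "spatial.csv", index=False)
        return

    raise ValueError(f"unknown stage {stage!r}")  # pragma: no cover
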