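"""End-to-end orchestration: features -> fit -> evaluate -> decode -> maps.

A single TOML config lists the per-trial input files and every stage's
hyperparameters; :func:`run_analysis` executes the stages, isolating
per-trial failures, and writes all artifacts plus a manifest recording
seeds and versions.
"""

from __future__ import annotations

import json
import tomllib
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analyses import label_rules
from .basis import raised_cosine_basis
from .design import build_design_multi
from .evaluate import DataSplit, cross_condition_eval, feature_importance, heldout_nll
from .io import read_annotation, read_features, read_pose, write_features
from .kinematics import assign_roles, compute_features, quadrant_probability
from .maps import fit_social_map, mode_occupancy, social_lag_design
from .model import SONG_MODES, viterbi_decode
from .song import bout_statistics, frame_labels_from_intervals

MODE_INDEX = {m: i for i, m in enumerate(SONG_MODES)}


def load_config(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _labels_to_int(frame_labels: np.ndarray) -> np.ndarray:
    """Map string labels to model classes; agonistic frames count as silence
    for the song-patterning model."""
    return np.array([MODE_INDEX.get(l, MODE_INDEX["silence"]) for l in frame_labels])


def run_analysis(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis described by a config.

    Config layout (TOML)::

        [run]
        seed = 0
        out_dir = "results"
        frame_rate = 30.0

        [model]
        n_states = 3
        n_basis = 10
        n_lags = 120
        n_restarts = 5
        l2 = 1e-3

        [[trials]]
        name = "t1"
        condition = "female"
        pose = "t1_pose.csv"          # or features = "t1_features.csv"
        annotation = "t1_annot.csv"
        heldout = false

    Returns a report dict; every table is also written under ``out_dir``.
    Trials whose inputs fail to load are reported as failed without
    aborting the rest.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    run_cfg = config.get("run", {})
    out = Path(out_dir or run_cfg.get("out_dir", "results"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(run_cfg.get("seed", 0))
    frame_rate = float(run_cfg.get("frame_rate", 30.0))
    mcfg = config.get("model", {})
    basis = raised_cosine_basis(
        n_lags=int(mcfg.get("n_lags", 120)), n_basis=int(mcfg.get("n_basis", 10)),
        frame_rate=frame_rate,
    )

    report: dict = {"trials": {}, "failures": {}}
    trials = []
    for tcfg in config.get("trials", []):
        name = tcfg["name"]
        try:
            if "features" in tcfg:
                feats = read_features(tcfg["features"], frame_rate=frame_rate)
            else:
                pose = read_pose(tcfg["pose"], mm_per_px=float(tcfg.get("mm_per_px", 1.0)),
                                 frame_rate=float(tcfg.get("pose_rate", 100.0)))
                feats = compute_features(pose, target_rate=frame_rate)
                write_features(feats, out / f"{name}_features.csv")
            annot = read_annotation(tcfg["annotation"])
            duration = len(feats) / frame_rate
            frame_labels = frame_labels_from_intervals(annot, duration, frame_rate)[: len(feats)]
            if len(frame_labels) < len(feats):
                frame_labels = np.concatenate(
                    [frame_labels, np.full(len(feats) - len(frame_labels), "silence", object)]
                )
            mask = assign_roles(feats)
            trial = {
                "name": name,
                "condition": tcfg.get("condition", "all"),
                "heldout": bool(tcfg.get("heldout", False)),
                "features": feats,
                "labels_str": frame_labels,
                "labels": _labels_to_int(frame_labels),
                "mask": mask,
            }
            trials.append(trial)
            report["trials"][name] = {
                "n_frames": len(feats),
                "quadrant": quadrant_probability(mask),
                "bout_stats": bout_statistics(frame_labels, frame_rate)["windowed"],
            }
        except Exception as err:  # noqa: BLE001 - per-trial isolation is the contract
            report["failures"][name] = f"{type(err).__name__}: {err}"
            traceback.print_exc()

    if not trials:
        raise ValueError("no trial loaded successfully")

    # -- designs with pooled training statistics ----------------------------
    train_trials = [t for t in trials if not t["heldout"]]
    designs_train, stats = build_design_multi([t["features"] for t in train_trials], basis=basis)
    for t, d in zip(train_trials, designs_train):
        t["design"] = d
    held = [t for t in trials if t["heldout"]]
    if held:
        designs_held, _ = build_design_multi(
            [t["features"] for t in held], basis=basis, stats=stats
        )
        for t, d in zip(held, designs_held):
            t["design"] = d

    # -- model fitting ------------------------------------------------------
    conditions = sorted({t["condition"] for t in trials})
    fit_kwargs = dict(
        n_states=int(mcfg.get("n_states", 3)),
        n_restarts=int(mcfg.get("n_restarts", 5)),
        l2=float(mcfg.get("l2", 1e-3)),
        seed=seed,
        max_iter=int(mcfg.get("max_iter", 100)),
    )
    splits = {
        c: DataSplit(
            train=[(t["design"], t["labels"]) for t in train_trials if t["condition"] == c],
            heldout=[(t["design"], t["labels"]) for t in held if t["condition"] == c],
            condition=c,
        )
        for c in conditions
    }
    evaluable = {c: s for c, s in splits.items() if s.train and s.heldout}
    if len(evaluable) >= 2:
        cc = cross_condition_eval(evaluable, **fit_kwargs)
        models, report["nll"] = cc["models"], cc["nll"]
        model = models["all"]
    else:
        from .model import fit_em

        model, _ = fit_em([(t["design"], t["labels"]) for t in train_trials], **fit_kwargs)
        models = {"all": model}
        if held:
            report["nll"] = {
                "all": {"heldout": heldout_nll(model, [(t["design"], t["labels"]) for t in held])}
            }
    model.save(out / "model_all.json")

    # -- decoding, rules, importance ---------------------------------------
    all_data = [(t["design"], t["labels"]) for t in trials]
    if model.n_states == 3:
        try:
            rules = label_rules(model, all_data)
            report["rules"] = {
                "state_to_rule": rules["state_to_rule"],
                "usage": rules["usage"],
                "song_probs": rules["song_probs"],
            }
        except ValueError as err:
            report["rules"] = {"error": str(err)}
    for t in trials:
        path = viterbi_decode(model, t["design"], t["labels"])
        pd.DataFrame({"frame": np.arange(len(path)), "state": path}).to_csv(
            out / f"{t['name']}_states.csv", index=False
        )
    report["feature_importance"] = feature_importance(
        model,
        [t["features"] for t in train_trials],
        [t["labels"] for t in train_trials],
        seed=seed, basis=basis, stats=stats,
    )

    # -- social map ---------------------------------------------------------
    if config.get("maps", {}).get("enabled", True):
        designs = [social_lag_design(t["features"]) for t in trials]
        smap = fit_social_map(designs, seed=seed,
                              grid_size=int(config.get("maps", {}).get("grid_size", 256)))
        occ = mode_occupancy(smap)
        report["map"] = {
            "n_modes": smap.n_modes,
            "mode_fractions": occ["mode_fractions"].tolist(),
        }

    manifest = {
        "songrules_version": __version__,
        "seed": seed,
        "n_trials": len(trials),
        "conditions": conditions,
        "failures": report["failures"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    def _jsonable(o):
        if isinstance(o, dict):
            return {k: _jsonable(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [_jsonable(v) for v in o]
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return o

    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2, default=str))
    return report
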