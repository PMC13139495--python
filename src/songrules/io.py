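"""Reading and writing the pipeline's file formats.

Pose tables are long-format (frame, fly, bodypart, x, y) in CSV or HDF5;
feature tables are one row per 30 Hz frame; song annotations are interval
tables (onset_s, offset_s, label); audio is mono WAV at 10 kHz.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import BODY_PARTS, FEATURE_NAMES, FeedbackFeatures, PosePair


def read_pose(path: str | Path, mm_per_px: float = 1.0, frame_rate: float = 100.0) -> PosePair:
    """Load a two-fly pose track from a long-format CSV or HDF5 table."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        df = pd.read_hdf(path, key="pose")
    else:
        df = pd.read_csv(path)
    required = {"frame", "fly", "bodypart", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"pose table needs columns {sorted(required)}")
    frames = np.sort(df["frame"].unique())
    T = len(frames)
    frame_idx = {f: i for i, f in enumerate(frames)}
    part_idx = {p: i for i, p in enumerate(BODY_PARTS)}
    xy = np.full((2, T, 6, 2), np.nan)
    fi = df["frame"].map(frame_idx).to_numpy()
    pi = df["bodypart"].map(part_idx).to_numpy()
    fly = df["fly"].to_numpy(dtype=int)
    xy[fly, fi, pi, 0] = df["x"].to_numpy() * mm_per_px
    xy[fly, fi, pi, 1] = df["y"].to_numpy() * mm_per_px
    return PosePair(xy=xy, frame_rate=frame_rate)


def write_pose(pose: PosePair, path: str | Path) -> None:
    path = Path(path)
    T = pose.n_frames
    recs = []
    for fly in range(2):
        for p, part in enumerate(BODY_PARTS):
            recs.append(pd.DataFrame({
                "frame": np.arange(T), "fly": fly, "bodypart": part,
                "x": pose.xy[fly, :, p, 0], "y": pose.xy[fly, :, p, 1],
            }))
    df = pd.concat(recs).sort_values(["frame", "fly"]).reset_index(drop=True)
    if path.suffix in (".h5", ".hdf5"):
        df.to_hdf(path, key="pose", mode="w")
    else:
        df.to_csv(path, index=False)


def write_features(features: FeedbackFeatures, path: str | Path) -> None:
    features.data.to_csv(path, index=False)


def read_features(path: str | Path, frame_rate: float = 30.0) -> FeedbackFeatures:
    df = pd.read_csv(path)
    return FeedbackFeatures(data=df[list(FEATURE_NAMES)], frame_rate=frame_rate)


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"onset_s", "offset_s", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    return df


def read_wav(path: str | Path) -> tuple[int, np.ndarray]:
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    if data.dtype.kind == "i":
        data = data / np.iinfo(data.dtype).max
    if data.ndim > 1:
        data = data.mean(axis=1)
    return rate, np.asarray(data, float)


def write_wav(path: str | Path, data: np.ndarray, rate: int = 10_000) -> None:
    from scipy.io import wavfile

    wavfile.write(path, rate, np.asarray(data, np.float32))
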