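"""Design matrices: lagged feedback cues, basis projection, z-scoring, bias.

Each time point's covariate vector is the 4 s history of all ten feedback
cues, projected onto the raised-cosine basis (10 features x n_basis values),
z-scored column-wise with statistics frozen on the training trials, and
augmented with a trailing constant 1 for the bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .basis import BasisSet, raised_cosine_basis
from .kinematics import FEATURE_NAMES, FeedbackFeatures


@dataclass
class ZScoreStats:
    """Frozen normalization statistics.

    ``mean``/``sd`` are per projected column (10 x n_basis); ``raw_mean``
    is the per-feature mean of the unprojected series, used to pad the
    incomplete history at a trial's start (equivalent to mean-imputing the
    missing lags).
    """

    mean: np.ndarray
    sd: np.ndarray
    raw_mean: np.ndarray

    def __post_init__(self):
        if np.any(self.sd <= 0):
            raise ValueError("z-score sd must be positive for every training column")


@dataclass
class DesignMatrix:
    """(T, 10*n_basis + 1) covariate matrix with trailing bias column."""

    X: np.ndarray
    stats: ZScoreStats
    basis: BasisSet

    @property
    def n_params(self) -> int:
        return self.X.shape[1]


def _features_array(features) -> np.ndarray:
    if isinstance(features, FeedbackFeatures):
        return features.array()
    arr = np.asarray(features, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected (T, {len(FEATURE_NAMES)}) feature array")
    return arr


def _project_history(arr: np.ndarray, basis: BasisSet, raw_mean: np.ndarray) -> np.ndarray:
    """Causal convolution of each feature with each basis column.

    ``lfilter`` realizes u_j[t] = sum_n b_j[n] * s[t-n] with zero initial
    state; running it on the mean-centered signal and adding back
    ``mean * sum(b_j)`` makes the implicit pre-trial padding equal the
    feature mean rather than zero.
    """
    T, F = arr.shape
    D = basis.n_basis
    out = np.empty((T, F * D))
    colsum = basis.matrix.sum(axis=0)
    for f in range(F):
        centered = arr[:, f] - raw_mean[f]
        for j in range(D):
            out[:, f * D + j] = (
                signal.lfilter(basis.matrix[:, j], [1.0], centered)
                + raw_mean[f] * colsum[j]
            )
    return out


def build_design(
    features,
    basis: BasisSet | None = None,
    stats: ZScoreStats | None = None,
) -> DesignMatrix:
    """Build the model's covariate matrix from feedback features.

    When ``stats`` is None this is a training transform: normalization
    statistics are estimated from ``features`` and returned inside the
    result for reuse on held-out data.  Passing training ``stats`` applies
    the frozen transform (no leakage from held-out trials).
    """
    basis = basis or raised_cosine_basis()
    arr = _features_array(features)
    if len(arr) < 1:
        raise ValueError("empty feature track")

    raw_mean = arr.mean(axis=0) if stats is None else stats.raw_mean
    proj = _project_history(arr, basis, raw_mean)
    if stats is None:
        sd = proj.std(axis=0, ddof=0)
        if np.any(sd <= 0):
            raise ValueError("constant projected column; cannot z-score training data")
        stats = ZScoreStats(mean=proj.mean(axis=0), sd=sd, raw_mean=raw_mean)
    z = (proj - stats.mean) / stats.sd
    X = np.hstack([z, np.ones((len(z), 1))])
    return DesignMatrix(X=X, stats=stats, basis=basis)


def build_design_multi(
    features_list: list,
    basis: BasisSet | None = None,
    stats: ZScoreStats | None = None,
) -> tuple[list[DesignMatrix], ZScoreStats]:
    """Design matrices for several trials with pooled training statistics.

    Training statistics (when ``stats`` is None) are estimated on the
    concatenated projections of all trials, then applied to each trial.
    """
    basis = basis or raised_cosine_basis()
    arrays = [_features_array(f) for f in features_list]
    if stats is None:
        pooled = np.vstack(arrays)
        raw_mean = pooled.mean(axis=0)
        proj_all = np.vstack([_project_history(a, basis, raw_mean) for a in arrays])
        sd = proj_all.std(axis=0, ddof=0)
        if np.any(sd <= 0):
            raise ValueError("constant projected column; cannot z-score training data")
        stats = ZScoreStats(mean=proj_all.mean(axis=0), sd=sd, raw_mean=raw_mean)
    designs = [build_design(a, basis=basis, stats=stats) for a in arrays]
    return designs, stats
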