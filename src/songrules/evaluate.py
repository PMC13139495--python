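"""Model evaluation: chance-referenced held-out likelihoods and ablations.

The zero point of all likelihood comparisons is a chance model that always
predicts each song mode's empirical frequency on the evaluation frames.
The normalized log-likelihood (NLL) of a model is its improvement over
chance in bits per sample:

    NLL = (LL(model) - LL(chance)) / (n * log 2)

so the chance model itself scores exactly 0 bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisSet
from .design import DesignMatrix, ZScoreStats, build_design
from .kinematics import FEATURE_NAMES
from .model import N_MODES, HMMGLMParams, fit_em, forward_backward


@dataclass
class DataSplit:
    """Per-condition partition of trials into training and held-out sets."""

    train: list
    heldout: list
    condition: str = ""

    def __post_init__(self):
        train_ids = {id(t) for t in self.train}
        if any(id(t) in train_ids for t in self.heldout):
            raise ValueError("train and heldout sets must be disjoint")


def chance_log_probs(labels_list: list[np.ndarray]) -> np.ndarray:
    """(M,) log frequencies of each song mode over the given frames."""
    counts = np.zeros(N_MODES)
    for y in labels_list:
        counts += np.bincount(np.asarray(y, dtype=int), minlength=N_MODES)
    n = counts.sum()
    if n == 0:
        raise ValueError("no evaluation frames")
    with np.errstate(divide="ignore"):
        return np.log(counts / n)


def chance_loglik(labels_list: list[np.ndarray]) -> float:
    """Total log-likelihood of the chance model on its own frames."""
    logp = chance_log_probs(labels_list)
    ll = 0.0
    for y in labels_list:
        ll += logp[np.asarray(y, dtype=int)].sum()
    return float(ll)


def heldout_nll(
    params: HMMGLMParams,
    datasets: list[tuple[DesignMatrix | np.ndarray, np.ndarray]],
    return_raw: bool = False,
):
    """Normalized held-out log-likelihood in bits per sample.

    The model log-likelihood is the sum over trials of the forward pass's
    terminal mass; the chance reference is computed from the same frames.
    """
    if not datasets:
        raise ValueError("empty held-out set")
    labels = [np.asarray(y, dtype=int) for _, y in datasets]
    ll = sum(forward_backward(params, X, y).loglik for X, y in datasets)
    ll0 = chance_loglik(labels)
    n = sum(len(y) for y in labels)
    nll = (ll - ll0) / (n * np.log(2))
    if return_raw:
        return nll, {"loglik": ll, "chance_loglik": ll0, "n": n}
    return nll


def transition_mode_nll(
    params: HMMGLMParams,
    datasets: list[tuple[DesignMatrix | np.ndarray, np.ndarray]],
    from_mode: int,
    to_mode: int,
) -> dict:
    """Normalized LL restricted to frames where the song switches modes.

    The per-step forward normalizer log_c[t] is the predictive
    log P(y_t | y_{1:t-1}, X), so restricting the sum to switch frames
    evaluates exactly the model's one-step prediction at those points.
    Passing ``from_mode = to_mode = None`` is not supported; use
    :func:`heldout_nll` for the unrestricted quantity.
    """
    ll = 0.0
    chance_labels = []
    n = 0
    for X, y in datasets:
        y = np.asarray(y, dtype=int)
        post = forward_backward(params, X, y)
        t_idx = np.flatnonzero((y[:-1] == from_mode) & (y[1:] == to_mode)) + 1
        if t_idx.size:
            ll += post.log_c[t_idx].sum()
            chance_labels.append(y[t_idx])
            n += t_idx.size
    if n == 0:
        return {"nll_bits": np.nan, "n": 0, "empty": True}
    # chance frequencies from the full evaluation frames, applied at switches
    logp0 = chance_log_probs([np.asarray(y, dtype=int) for _, y in datasets])
    ll0 = sum(logp0[y].sum() for y in chance_labels)
    return {"nll_bits": float((ll - ll0) / (n * np.log(2))), "n": n, "empty": False}


def cross_condition_eval(
    splits: dict[str, DataSplit],
    n_states: int = 3,
    n_restarts: int = 5,
    l2: float = 1e-3,
    seed: int | None = None,
    **fit_kwargs,
) -> dict:
    """Fit per-condition and pooled models; evaluate all on all conditions.

    ``splits`` maps condition name (e.g. ``"female"``, ``"male"``) to a
    :class:`DataSplit` of (design, labels) tuples.  Returns the fitted
    models and an NLL matrix ``nll[model_name][condition]`` on held-out
    trials.  The pooled model is named ``"all"``.
    """
    for name, sp in splits.items():
        if not sp.heldout:
            raise ValueError(f"condition {name!r} has no held-out trials")
    models = {}
    rng = np.random.default_rng(seed)
    for name, sp in splits.items():
        sub = int(rng.integers(2**31))
        models[name], _ = fit_em(sp.train, n_states=n_states, n_restarts=n_restarts,
                                 l2=l2, seed=sub, **fit_kwargs)
    pooled = [d for sp in splits.values() for d in sp.train]
    models["all"], _ = fit_em(pooled, n_states=n_states, n_restarts=n_restarts,
                              l2=l2, seed=int(rng.integers(2**31)), **fit_kwargs)
    nll = {
        mname: {cname: heldout_nll(m, splits[cname].heldout) for cname in splits}
        for mname, m in models.items()
    }
    return {"models": models, "nll": nll}


def feature_importance(
    params: HMMGLMParams,
    features_list: list,
    labels_list: list[np.ndarray],
    seed: int | None = None,
    basis: BasisSet | None = None,
    stats: ZScoreStats | None = None,
) -> dict[str, float]:
    """Permutation importance of each feedback cue.

    Each of the ten features is shuffled across time (before lag
    expansion), the design rebuilt with the frozen training statistics,
    and the model log-likelihood recomputed.  Importance is the drop
    in total log-likelihood relative to the intact data; larger means
    the model leans on that cue more.
    """
    basis = basis if basis is not None else params.basis
    stats = stats if stats is not None else params.stats
    if basis is None or stats is None:
        raise ValueError("basis and z-score statistics required (fit them into params)")
    rng = np.random.default_rng(seed)
    arrays = [np.asarray(getattr(f, "array", lambda: f)(), dtype=float) for f in features_list]
    base_ll = 0.0
    for arr, y in zip(arrays, labels_list):
        d = build_design(arr, basis=basis, stats=stats)
        base_ll += forward_backward(params, d, y).loglik
    out = {}
    for i, name in enumerate(FEATURE_NAMES):
        ll = 0.0
        for arr, y in zip(arrays, labels_list):
            shuf = arr.copy()
            shuf[:, i] = shuf[rng.permutation(len(shuf)), i]
            d = build_design(shuf, basis=basis, stats=stats)
            ll += forward_backward(params, d, y).loglik
        out[name] = float(base_ll - ll)
    return out
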