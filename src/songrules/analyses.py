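"""Downstream analyses on a fitted song-patterning model.

Covers the interpretation layer: naming the hidden states as sensorimotor
rules (whatever / chasing / close), counterfactual sweeps of the courter's
angular position, a 2-D embedding of the filtered decision variables, and
state inference on trials the model was not fitted to.
"""

from __future__ import annotations

import numpy as np

from .design import DesignMatrix, build_design
from .kinematics import FEATURE_NAMES
from .model import (
    PULSE,
    SILENCE,
    SINE,
    SONG_MODES,
    HMMGLMParams,
    emission_probs,
    forward_backward,
    viterbi_decode,
)

RULE_NAMES = ("whatever", "chasing", "close")


def state_emission_profiles(
    params: HMMGLMParams,
    datasets: list[tuple[DesignMatrix | np.ndarray, np.ndarray]],
    weighted: bool = True,
) -> np.ndarray:
    """(K, M) mean emission probabilities per state over the data.

    With ``weighted`` the average is taken under the posterior state
    marginals gamma; otherwise it is the plain mean of each state's
    softmax output over all frames.
    """
    K = params.n_states
    num = np.zeros((K, len(SONG_MODES)))
    den = np.zeros(K)
    for d, y in datasets:
        X = d.X if isinstance(d, DesignMatrix) else np.asarray(d)
        g = forward_backward(params, X, y).gamma if weighted else np.ones((len(X), K)) / 1.0
        for k in range(K):
            p = emission_probs(params.weights[k], X)
            num[k] += g[:, k] @ p
            den[k] += g[:, k].sum()
    return num / den[:, None]


def label_rules(
    params: HMMGLMParams,
    datasets: list[tuple[DesignMatrix | np.ndarray, np.ndarray]],
) -> dict:
    """Map the three states onto the whatever / chasing / close rules.

    The state with the highest mean silence emission becomes *whatever*;
    of the remaining two, the pulse-dominant state becomes *chasing* and
    the sine-dominant one *close*.  Ambiguous profiles (no strict
    ordering) raise rather than guess.  Also returns per-trial rule-usage
    fractions (mean posterior mass, summing to 1) and each rule's mean
    song-mode probabilities.
    """
    if params.n_states != len(RULE_NAMES):
        raise ValueError(f"rule labeling requires K={len(RULE_NAMES)} states, got {params.n_states}")
    prof = state_emission_profiles(params, datasets)
    silence_order = np.argsort(-prof[:, SILENCE])
    whatever = int(silence_order[0])
    rest = [k for k in range(3) if k != whatever]
    a, b = rest
    if prof[a, PULSE] > prof[b, PULSE] and prof[b, SINE] > prof[a, SINE]:
        chasing, close = a, b
    elif prof[b, PULSE] > prof[a, PULSE] and prof[a, SINE] > prof[b, SINE]:
        chasing, close = b, a
    else:
        raise ValueError(
            "ambiguous emission profiles, cannot order pulse/sine dominance: "
            f"{np.array_str(prof, precision=3)}"
        )
    mapping = {whatever: "whatever", chasing: "chasing", close: "close"}

    usage = []
    for d, y in datasets:
        g = forward_backward(params, d, y).gamma
        frac = g.mean(axis=0)
        usage.append({mapping[k]: float(frac[k]) for k in range(3)})
    profiles = {
        mapping[k]: {m: float(p) for m, p in zip(SONG_MODES, prof[k])} for k in range(3)
    }
    return {"state_to_rule": mapping, "usage": usage, "song_probs": profiles}


# ---------------------------------------------------------------------------
# counterfactual position sweep


def counterfactual_position_sweep(
    params: HMMGLMParams,
    features,
    labels: np.ndarray,
    sweep_feature: str = "ctheta",
    sweep_deg: np.ndarray | None = None,
    n_position_bins: int = 36,
) -> dict:
    """Model-predicted song-probability change under swept courter position.

    For every original sample, simulated copies are created in which the
    swept angular feature (``ctheta`` for position, ``ptheta`` for
    orientation) is held at each value of ``sweep_deg`` over its entire
    history, with the relative orientation ``phi`` coupled as
    ``180 - angle``; all other cues keep their observed history.  The
    state used for each sample's prediction is its Viterbi state.  Returns
    the pulse/sine probability differences versus the original prediction,
    aggregated over bins of the original swept feature.

    Because the basis projection is linear, a constant-history feature
    contributes ``value * column_sums`` to the design, so the sweep only
    has to swap two feature blocks of the design row.
    """
    if sweep_feature not in ("ctheta", "ptheta"):
        raise ValueError("sweep_feature must be 'ctheta' or 'ptheta'")
    if params.basis is None or params.stats is None:
        raise ValueError("params must carry basis and z-score statistics")
    sweep_deg = np.arange(0.0, 181.0) if sweep_deg is None else np.asarray(sweep_deg, float)
    basis, stats = params.basis, params.stats
    D = basis.n_basis
    colsum = basis.matrix.sum(axis=0)

    arr = np.asarray(getattr(features, "array", lambda: features)(), dtype=float)
    design = build_design(arr, basis=basis, stats=stats)
    X = design.X
    z_path = viterbi_decode(params, design, labels)

    i_sweep = FEATURE_NAMES.index(sweep_feature)
    i_phi = FEATURE_NAMES.index("phi")
    blocks = {i: slice(i * D, (i + 1) * D) for i in (i_sweep, i_phi)}

    T = len(X)
    p_orig = np.empty((T, 3))
    for k in range(params.n_states):
        idx = np.flatnonzero(z_path == k)
        if idx.size:
            p_orig[idx] = emission_probs(params.weights[k], X[idx])

    def z_block(i: int, value: float) -> np.ndarray:
        raw = value * colsum
        sl = blocks[i]
        return (raw - stats.mean[sl]) / stats.sd[sl]

    d_pulse = np.empty((len(sweep_deg), T))
    d_sine = np.empty((len(sweep_deg), T))
    Xs = X.copy()
    for si, val in enumerate(sweep_deg):
        Xs[:, blocks[i_sweep]] = z_block(i_sweep, val)
        Xs[:, blocks[i_phi]] = z_block(i_phi, 180.0 - val)
        p = np.empty((T, 3))
        for k in range(params.n_states):
            idx = np.flatnonzero(z_path == k)
            if idx.size:
                p[idx] = emission_probs(params.weights[k], Xs[idx])
        d_pulse[si] = p[:, PULSE] - p_orig[:, PULSE]
        d_sine[si] = p[:, SINE] - p_orig[:, SINE]

    # aggregate over the original position
    orig = arr[:, i_sweep]
    edges = np.linspace(0, 180, n_position_bins + 1)
    which = np.clip(np.digitize(orig, edges) - 1, 0, n_position_bins - 1)
    agg_pulse = np.full((len(sweep_deg), n_position_bins), np.nan)
    agg_sine = np.full((len(sweep_deg), n_position_bins), np.nan)
    for b in range(n_position_bins):
        idx = np.flatnonzero(which == b)
        if idx.size:
            agg_pulse[:, b] = d_pulse[:, idx].mean(axis=1)
            agg_sine[:, b] = d_sine[:, idx].mean(axis=1)
    return {
        "sweep_deg": sweep_deg,
        "delta_pulse": d_pulse,
        "delta_sine": d_sine,
        "bin_edges": edges,
        "delta_pulse_by_position": agg_pulse,
        "delta_sine_by_position": agg_sine,
    }


# ---------------------------------------------------------------------------
# decision-space embedding


def filtered_cues(
    params: HMMGLMParams,
    design: DesignMatrix | np.ndarray,
    labels: np.ndarray,
    states: np.ndarray | None = None,
) -> np.ndarray:
    """(T, P) elementwise product of the active filter with the design row.

    The active filter at time t is the one for the inferred state z_t and
    the observed song mode y_t; the products are the per-coefficient
    contributions to that mode's logit (the model's decision variables).
    """
    X = design.X if isinstance(design, DesignMatrix) else np.asarray(design)
    y = np.asarray(labels, dtype=int)
    z = viterbi_decode(params, X, y) if states is None else np.asarray(states, int)
    return params.weights[z, y] * X


def decision_space_embedding(
    params: HMMGLMParams,
    datasets: list[tuple[DesignMatrix | np.ndarray, np.ndarray]],
    seed: int = 0,
    max_samples: int = 20000,
) -> dict:
    """2-D manifold embedding of the filtered decision variables."""
    from .maps import embed_2d

    V, ys = [], []
    for d, y in datasets:
        V.append(filtered_cues(params, d, y))
        ys.append(np.asarray(y, int))
    V = np.vstack(V)
    ys = np.concatenate(ys)
    if len(V) > max_samples:
        step = len(V) // max_samples
        V, ys = V[::step], ys[::step]
    emb = embed_2d(V, seed=seed)
    return {"embedding": emb, "labels": ys}


def infer_states_external(
    params: HMMGLMParams, features, labels: np.ndarray
) -> dict:
    """Posterior and decoded rule sequence on a trial with frozen parameters.

    The design is built with the training z-score statistics stored in the
    model, so unseen trials are transformed exactly as the training data.
    """
    if params.basis is None or params.stats is None:
        raise ValueError("params must carry basis and z-score statistics")
    arr = np.asarray(getattr(features, "array", lambda: features)(), dtype=float)
    if arr.shape[1] != len(FEATURE_NAMES):
        raise ValueError(
            f"feature-set mismatch: expected {len(FEATURE_NAMES)} columns, got {arr.shape[1]}"
        )
    design = build_design(arr, basis=params.basis, stats=params.stats)
    post = forward_backward(params, design, labels)
    path = viterbi_decode(params, design, labels)
    return {"gamma": post.gamma, "path": path, "loglik": post.loglik}
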