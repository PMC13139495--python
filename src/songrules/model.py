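"""Input-driven hidden-state multinomial model of song patterning (HMM-GLM).

A hidden Markov chain over K sensorimotor rules, with a fixed K x K
transition matrix and initial distribution, emits the song mode at each
30 Hz frame through a per-state multinomial GLM: the state's filter bank
maps the basis-projected feedback-cue history to softmax probabilities over
{pulse, sine, silence}.  The silence filter of every state is pinned to
zero, which fixes the softmax gauge.  Fitting is by EM: forward-backward
posteriors in the E-step, closed-form transition/initial updates and
L2-penalized weighted multinomial regression for the filters in the M-step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .basis import BasisSet, raised_cosine_basis
from .design import DesignMatrix, ZScoreStats

SONG_MODES = ("pulse", "sine", "silence")
PULSE, SINE, SILENCE = 0, 1, 2
N_MODES = len(SONG_MODES)


@dataclass
class HMMGLMParams:
    """Parameters of the model: (pi, alpha, {W_k}).

    Attributes
    ----------
    pi : (K,) initial state distribution.
    alpha : (K, K) state transition matrix, rows on the simplex.
    weights : (K, M, P) per-state filter banks; row ``SILENCE`` is zero.
    l2 : ridge penalty per training sample on the free filter entries.
    stats : frozen z-score statistics of the design the model was fit on.
    """

    pi: np.ndarray
    alpha: np.ndarray
    weights: np.ndarray
    l2: float = 1e-3
    stats: ZScoreStats | None = None
    basis: BasisSet | None = None
    seed: int | None = None

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        K = self.pi.size
        if self.alpha.shape != (K, K):
            raise ValueError("alpha must be (K, K)")
        if self.weights.ndim != 3 or self.weights.shape[:2] != (K, N_MODES):
            raise ValueError(f"weights must be (K, {N_MODES}, P)")
        if not np.allclose(self.pi.sum(), 1) or not np.allclose(self.alpha.sum(1), 1):
            raise ValueError("pi and alpha rows must lie on the simplex")
        if not np.allclose(self.weights[:, SILENCE, :], 0):
            raise ValueError("silence filters must be exactly zero")

    @property
    def n_states(self) -> int:
        return self.pi.size

    @property
    def n_params(self) -> int:
        return self.weights.shape[2]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "K": self.n_states,
            "M": N_MODES,
            "modes": list(SONG_MODES),
            "pi": self.pi.tolist(),
            "alpha": self.alpha.tolist(),
            "weights": self.weights.tolist(),
            "l2": self.l2,
            "seed": self.seed,
        }
        if self.stats is not None:
            d["zscore"] = {
                "mean": self.stats.mean.tolist(),
                "sd": self.stats.sd.tolist(),
                "raw_mean": self.stats.raw_mean.tolist(),
            }
        if self.basis is not None:
            d["basis"] = {
                "n_lags": self.basis.n_lags,
                "n_basis": self.basis.n_basis,
                "frame_rate": self.basis.frame_rate,
                "log_stretch": self.basis.log_stretch,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HMMGLMParams":
        stats = None
        if "zscore" in d:
            z = d["zscore"]
            stats = ZScoreStats(
                mean=np.array(z["mean"]), sd=np.array(z["sd"]), raw_mean=np.array(z["raw_mean"])
            )
        basis = None
        if "basis" in d:
            b = d["basis"]
            basis = raised_cosine_basis(
                n_lags=b["n_lags"], n_basis=b["n_basis"],
                frame_rate=b["frame_rate"], log_stretch=b["log_stretch"],
            )
        return cls(
            pi=np.array(d["pi"]), alpha=np.array(d["alpha"]), weights=np.array(d["weights"]),
            l2=d.get("l2", 1e-3), stats=stats, basis=basis, seed=d.get("seed"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "HMMGLMParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class Posteriors:
    """Forward-backward output for one trial.

    ``a_scaled``/``b_scaled`` are the per-step-normalized forward and
    backward variables; ``log_c`` holds the per-step log normalizers, so
    ``log_c[t]`` is the predictive log P(y_t | y_{1:t-1}, X) and their sum
    is the trial log-likelihood.
    """

    a_scaled: np.ndarray   # (T, K)
    b_scaled: np.ndarray   # (T, K)
    log_c: np.ndarray      # (T,)
    gamma: np.ndarray      # (T, K)
    xi: np.ndarray         # (T-1, K, K)
    loglik: float


# ---------------------------------------------------------------------------
# emissions


def emission_logits(weights_k: np.ndarray, X: np.ndarray) -> np.ndarray:
    """(T, M) logits for one state's filter bank on design X."""
    if not np.all(np.isfinite(weights_k)):
        raise ValueError("non-finite filter values")
    return X @ weights_k.T


def emission_probs(weights_k: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Softmax probabilities over song modes for one state.

    Accepts a single design row (P,) or a matrix (T, P); returns the
    matching (M,) or (T, M) simplex.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    logits = emission_logits(weights_k, np.atleast_2d(x))
    logits = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    return p[0] if single else p


def emission_log_probs(params: HMMGLMParams, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(T, K) log P(y_t | x_t, z_t = k) for the observed labels."""
    T = len(y)
    out = np.empty((T, params.n_states))
    rows = np.arange(T)
    for k in range(params.n_states):
        logits = emission_logits(params.weights[k], X)
        logZ = logsumexp(logits, axis=1)
        out[:, k] = logits[rows, y] - logZ
    return out


# ---------------------------------------------------------------------------
# forward-backward


def _fb_core_numpy(pi: np.ndarray, alpha: np.ndarray, B: np.ndarray):
    """Scaled forward/backward recursions on emission likelihoods B (T, K).

    Returns (a, b, log_c) with per-step normalizers; log_c is -inf where
    the forward mass vanished.
    """
    T, K = B.shape
    a = np.empty((T, K))
    b = np.empty((T, K))
    log_c = np.empty(T)
    v = pi * B[0]
    c = v.sum()
    if c <= 0:
        log_c[:] = -np.inf
        return a, b, log_c
    a[0] = v / c
    log_c[0] = np.log(c)
    for t in range(1, T):
        v = (a[t - 1] @ alpha) * B[t]
        c = v.sum()
        if c <= 0:
            log_c[t:] = -np.inf
            return a, b, log_c
        a[t] = v / c
        log_c[t] = np.log(c)
    b[-1] = 1.0
    for t in range(T - 2, -1, -1):
        v = alpha @ (B[t + 1] * b[t + 1])
        b[t] = v / v.sum()
    return a, b, log_c


try:  # jit the inner recursions when numba is available
    from numba import njit

    _fb_core = njit(cache=True)(_fb_core_numpy)
except ImportError:  # pragma: no cover - numba present in supported envs
    _fb_core = _fb_core_numpy


def forward_backward(
    params: HMMGLMParams, design: DesignMatrix | np.ndarray, labels: np.ndarray
) -> Posteriors:
    """Scaled forward-backward recursion.

    Computes the trial log-likelihood, state marginals gamma and pairwise
    transition marginals xi.  Raises when some time point has zero
    emission probability under every state.
    """
    X = design.X if isinstance(design, DesignMatrix) else np.asarray(design)
    y = np.asarray(labels, dtype=int)
    logB = emission_log_probs(params, X, y)              # (T, K)
    T, K = logB.shape
    # shift per step so the scaled recursion never underflows
    shift = logB.max(axis=1)
    if not np.all(np.isfinite(shift)):
        bad = int(np.flatnonzero(~np.isfinite(shift))[0])
        raise ValueError(f"zero emission probability under all states at t={bad}")
    B = np.exp(logB - shift[:, None])                    # (T, K), max 1 per row

    a, b, log_c_scaled = _fb_core(params.pi, params.alpha, B)
    bad = np.flatnonzero(~np.isfinite(log_c_scaled))
    if bad.size:
        raise ValueError(f"zero forward mass at t={int(bad[0])}")
    log_c = log_c_scaled + shift

    gamma = a * b
    gamma /= gamma.sum(axis=1, keepdims=True)

    # xi[t] \propto a_t (outer) alpha * B_{t+1} b_{t+1}
    w = B[1:] * b[1:]
    xi = a[:-1, :, None] * params.alpha[None, :, :] * w[:, None, :]
    xi /= xi.sum(axis=(1, 2), keepdims=True)

    return Posteriors(
        a_scaled=a, b_scaled=b, log_c=log_c, gamma=gamma, xi=xi,
        loglik=float(log_c.sum()),
    )


def viterbi_decode(
    params: HMMGLMParams, design: DesignMatrix | np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Most likely state path (log-domain dynamic program).

    Ties break toward the lower state index.
    """
    X = design.X if isinstance(design, DesignMatrix) else np.asarray(design)
    y = np.asarray(labels, dtype=int)
    logB = emission_log_probs(params, X, y)
    T, K = logB.shape
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)
        log_alpha = np.log(params.alpha)
    delta = log_pi + logB[0]
    back = np.empty((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + log_alpha      # (from, to)
        back[t] = np.argmax(cand, axis=0)      # first max -> lower index
        delta = cand[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# label-only categorical HMM (the HMM-only baseline, and the initializer
# for the full model)


def fit_hmm_only(
    labels_list: list[np.ndarray],
    n_states: int = 3,
    n_restarts: int = 10,
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    sticky_init: float = 0.95,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Baum-Welch fit of a categorical HMM on the song labels alone.

    This is the input-blind baseline: each state emits song modes with a
    fixed probability vector eta_k instead of a GLM.  Returns
    (pi, alpha, eta, loglik) of the best restart; eta has shape (K, M).
    """
    rng = np.random.default_rng(seed)
    ys = [np.asarray(y, dtype=int) for y in labels_list]
    best = None
    for _ in range(n_restarts):
        eta = rng.dirichlet(np.ones(N_MODES), size=n_states)
        alpha = np.full((n_states, n_states), (1 - sticky_init) / max(n_states - 1, 1))
        np.fill_diagonal(alpha, sticky_init if n_states > 1 else 1.0)
        pi = np.full(n_states, 1.0 / n_states)
        prev = -np.inf
        for _ in range(max_iter):
            ll = 0.0
            g0 = np.zeros(n_states)
            xi_sum = np.zeros((n_states, n_states))
            counts = np.zeros((n_states, N_MODES))
            for y in ys:
                B = eta[:, y].T  # (T, K)
                a, b, log_c = _fb_core(pi, alpha, B)
                ll += log_c.sum()
                gamma = a * b
                gamma /= gamma.sum(axis=1, keepdims=True)
                g0 += gamma[0]
                w = B[1:] * b[1:]
                xi = a[:-1, :, None] * alpha[None] * w[:, None, :]
                xi_sum += (xi / xi.sum(axis=(1, 2), keepdims=True)).sum(axis=0)
                for m in range(N_MODES):
                    counts[:, m] += gamma[y == m].sum(axis=0)
            pi = g0 / g0.sum()
            if n_states > 1:
                alpha = xi_sum / xi_sum.sum(axis=1, keepdims=True)
            eta = counts + 1e-8
            eta /= eta.sum(axis=1, keepdims=True)
            if ll - prev < tol * (abs(prev) + 1.0):
                break
            prev = ll
        if best is None or ll > best[3]:
            best = (pi, alpha, eta, ll)
    return best


def intercept_only_params(
    pi: np.ndarray, alpha: np.ndarray, eta: np.ndarray, n_params: int, l2: float = 1e-3
) -> HMMGLMParams:
    """Wrap a categorical HMM as an HMM-GLM with bias-only filters.

    Setting each state's bias to log(eta_i / eta_silence) and all other
    filter entries to zero reproduces eta exactly through the softmax.
    """
    K = len(pi)
    W = np.zeros((K, N_MODES, n_params))
    eta = np.clip(eta, 1e-12, None)
    W[:, :2, -1] = np.log(eta[:, :2] / eta[:, 2:3])
    return HMMGLMParams(pi=pi, alpha=alpha, weights=W, l2=l2)


# ---------------------------------------------------------------------------
# EM fitting


def _mstep_weights(
    W0: np.ndarray,
    X: np.ndarray,
    y_onehot: np.ndarray,
    gamma_k: np.ndarray,
    l2_total: float,
    tol: float = 1e-6,
    maxiter: int = 200,
) -> np.ndarray:
    """Maximize the weighted multinomial emission term for one state.

    Minimizes  -sum_t gamma_t log softmax(W x_t)[y_t] + 0.5 * l2 * ||W_free||^2
    over the pulse and sine filters (silence pinned at zero), warm-started
    from ``W0``.  Returns ``W0`` unchanged if the optimizer fails to improve.
    """
    M, P = W0.shape
    free = [PULSE, SINE]

    def unpack(theta):
        W = np.zeros((M, P))
        W[free] = theta.reshape(len(free), P)
        return W

    def objective(theta):
        W = unpack(theta)
        logits = X @ W.T                                  # (T, M)
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        Z = expl.sum(axis=1, keepdims=True)
        logp = logits - np.log(Z)
        nll = -np.sum(gamma_k * np.sum(y_onehot * logp, axis=1))
        nll += 0.5 * l2_total * np.sum(W[free] ** 2)
        p = expl / Z
        G = ((p - y_onehot) * gamma_k[:, None]).T @ X     # (M, P)
        G[free] += l2_total * W[free]
        return nll, G[free].ravel()

    theta0 = W0[free].ravel()
    f0 = objective(theta0)[0]
    res = minimize(
        objective, theta0, jac=True, method="L-BFGS-B",
        options={"ftol": tol, "gtol": 1e-8, "maxiter": maxiter},
    )
    if res.fun > f0:  # failed inner step: keep previous filters
        return W0
    return unpack(res.x)


def _penalty(params: HMMGLMParams, l2_total: float) -> float:
    return 0.5 * l2_total * float(np.sum(params.weights[:, (PULSE, SINE), :] ** 2))


def penalized_loglik(
    params: HMMGLMParams, datasets: list[tuple[np.ndarray, np.ndarray]], l2_total: float
) -> float:
    """Total data log-likelihood minus the ridge penalty."""
    ll = sum(forward_backward(params, X, y).loglik for X, y in datasets)
    return ll - _penalty(params, l2_total)


def _init_params(
    K: int,
    P: int,
    rng: np.random.Generator,
    sticky: float,
    init_scale: float,
    l2: float,
    labels_list: list[np.ndarray] | None = None,
    init: str = "hmm",
) -> HMMGLMParams:
    """One restart's initial parameter draw.

    ``init="hmm"`` (default for K > 1) first fits a label-only categorical
    HMM from a fresh random start and copies its pi, alpha and per-state
    emission frequencies into bias-only filters, then perturbs all free
    filter entries with small random noise.  Starting every state at a
    distinct emission profile breaks the state symmetry that traps EM in
    merged-state optima when all filters start near zero.  ``init="random"``
    is the plain small-variance random start with a sticky transition
    matrix.
    """
    noise = rng.normal(0.0, init_scale, size=(K, N_MODES, P))
    noise[:, SILENCE, :] = 0.0
    if init == "hmm" and K > 1 and labels_list is not None:
        pi, alpha, eta, _ = fit_hmm_only(
            labels_list, n_states=K, n_restarts=1,
            seed=int(rng.integers(2**31)), max_iter=100,
        )
        params = intercept_only_params(pi, alpha, eta, P, l2=l2)
        params.weights += noise
        params.weights[:, SILENCE, :] = 0.0
        return params
    alpha = np.full((K, K), (1 - sticky) / max(K - 1, 1))
    np.fill_diagonal(alpha, sticky if K > 1 else 1.0)
    return HMMGLMParams(pi=np.full(K, 1.0 / K), alpha=alpha, weights=noise, l2=l2)


def fit_em(
    datasets: list[tuple[DesignMatrix | np.ndarray, np.ndarray]],
    n_states: int = 3,
    n_restarts: int = 20,
    l2: float = 1e-3,
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    sticky_init: float = 0.95,
    init_scale: float = 0.1,
    init: str = "hmm",
    verbose: bool = False,
) -> tuple[HMMGLMParams, list[list[float]]]:
    """Fit the HMM-GLM by EM with random restarts.

    Parameters
    ----------
    datasets : list of (design, labels) per training trial.
    n_states : number of hidden states K.
    n_restarts : independent EM runs from random initializations; the run
        with the best penalized training objective wins.
    l2 : ridge strength per training sample on the free filter entries.
    tol : relative change of the penalized objective that stops EM.

    Returns
    -------
    (best_params, traces) where ``traces[r]`` is restart r's per-iteration
    penalized objective (non-decreasing by the generalized-EM contract).
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if not datasets:
        raise ValueError("need at least one training trial")
    rng = np.random.default_rng(seed)
    prepared = []
    stats = basis = None
    for d, y in datasets:
        X = d.X if isinstance(d, DesignMatrix) else np.asarray(d)
        if isinstance(d, DesignMatrix):
            stats, basis = d.stats, d.basis
        y = np.asarray(y, dtype=int)
        onehot = np.eye(N_MODES)[y]
        prepared.append((X, y, onehot))
    P = prepared[0][0].shape[1]
    n_total = sum(len(y) for _, y, _ in prepared)
    l2_total = l2 * n_total

    best: HMMGLMParams | None = None
    best_obj = -np.inf
    traces: list[list[float]] = []

    for r in range(n_restarts):
        params = _init_params(n_states, P, rng, sticky_init, init_scale, l2,
                              labels_list=[y for _, y, _ in prepared], init=init)
        trace: list[float] = []
        prev_obj = -np.inf
        for it in range(max_iter):
            # E-step
            posts = [forward_backward(params, X, y) for X, y, _ in prepared]
            obj = sum(p.loglik for p in posts) - _penalty(params, l2_total)
            trace.append(obj)
            if verbose:
                print(f"restart {r} iter {it}: {obj:.4f}")
            if np.isfinite(prev_obj) and obj - prev_obj < tol * (abs(prev_obj) + 1e-12):
                break
            prev_obj = obj
            # M-step: closed-form pi and alpha
            gamma0 = np.sum([p.gamma[0] for p in posts], axis=0)
            pi = gamma0 / gamma0.sum()
            xi_sum = np.sum([p.xi.sum(axis=0) for p in posts], axis=0)
            if n_states > 1:
                alpha = xi_sum / xi_sum.sum(axis=1, keepdims=True)
            else:
                alpha = np.ones((1, 1))
            # M-step: filters by weighted multinomial regression
            Xall = np.vstack([X for X, _, _ in prepared])
            Yall = np.vstack([oh for _, _, oh in prepared])
            Gall = np.vstack([p.gamma for p in posts])
            W = params.weights.copy()
            inner_iter = 100 if it == 0 else 25
            for k in range(n_states):
                W[k] = _mstep_weights(
                    W[k], Xall, Yall, Gall[:, k], l2_total, tol=1e-10, maxiter=inner_iter
                )
            params = HMMGLMParams(pi=pi, alpha=alpha, weights=W, l2=l2,
                                  stats=stats, basis=basis, seed=seed)
        traces.append(trace)
        if trace[-1] > best_obj:
            best_obj = trace[-1]
            best = params
    best.seed = seed
    return best, traces


# ---------------------------------------------------------------------------
# state-sequence simulation (generative side, shared with synthetic module)


def sample_states(params: HMMGLMParams, T: int, rng: np.random.Generator) -> np.ndarray:
    """Sample a hidden state path from (pi, alpha)."""
    z = np.empty(T, dtype=int)
    z[0] = rng.choice(params.n_states, p=params.pi)
    for t in range(1, T):
        z[t] = rng.choice(params.n_states, p=params.alpha[z[t - 1]])
    return z


def sample_emissions(params: HMMGLMParams, X: np.ndarray, z: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Sample song modes from each visited state's softmax GLM."""
    y = np.empty(len(z), dtype=int)
    for k in range(params.n_states):
        idx = np.flatnonzero(z == k)
        if idx.size == 0:
            continue
        p = emission_probs(params.weights[k], X[idx])
        cum = np.cumsum(p, axis=1)
        u = rng.random(idx.size)
        y[idx] = (u[:, None] < cum).argmax(axis=1)
    return y
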