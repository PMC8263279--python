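"""Restricted Boltzmann machine with CD-1 training.

The RBM is a bipartite energy model over binary visible and hidden units,

    E(v, h) = -a.v - b.h - v' W h,

whose conditionals factorize: P(h_j=1|v) = sigmoid(b_j + v.w_:j) and
P(v_i=1|h) = sigmoid(a_i + w_i:.h). Normalized real-valued inputs in [0,1]
are treated as Bernoulli probabilities on the visible layer. Training uses
contrastive divergence: the intractable model expectation in the likelihood
gradient

    d log P(v) / d w_ij = <v_i h_j>_data - <v_i h_j>_model

is replaced by the statistics of a short Gibbs chain started at the data.
For models small enough to enumerate, :func:`exact_marginal` provides the
exact product-of-experts marginal P(v) as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.special import expit

__all__ = [
    "RbmParams",
    "CdConfig",
    "energy",
    "hidden_probs",
    "visible_probs",
    "exact_marginal",
    "exact_loglik_grad",
    "init_rbm",
    "cd_step",
    "train_rbm",
]


@dataclass
class RbmParams:
    """W is (m visible x n hidden); a and b are the visible/hidden offsets."""

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        m, n = self.W.shape
        if self.a.shape != (m,) or self.b.shape != (n,):
            raise ValueError(
                f"inconsistent shapes: W {self.W.shape}, a {self.a.shape}, "
                f"b {self.b.shape}"
            )

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "RbmParams":
        return RbmParams(self.W.copy(), self.a.copy(), self.b.copy())


@dataclass(frozen=True)
class CdConfig:
    """Contrastive-divergence hyperparameters. Defaults: 10 epochs, learning
    rate 0.1 and momentum 0.5 for weights and offsets, CD-1, batches of 100,
    Gaussian weight initialization with sigma 0.01.

    ``sample_hidden=False`` switches the negative chain start from a binary
    hidden sample to the mean-field probabilities, making ``cd_step`` fully
    deterministic given the batch (used for order-invariance checks).
    """

    epochs: int = 10
    learning_rate: float = 0.1
    momentum: float = 0.5
    cd_steps: int = 1
    batch_size: int = 100
    init_sigma: float = 0.01
    sample_hidden: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.cd_steps < 1:
            raise ValueError("cd_steps must be >= 1")


def energy(v: np.ndarray, h: np.ndarray, params: RbmParams) -> float:
    """E(v,h) = -a.v - b.h - v'Wh."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != (params.n_visible,) or h.shape != (params.n_hidden,):
        raise ValueError("v/h shapes do not match params")
    return float(-params.a @ v - params.b @ h - v @ params.W @ h)


def hidden_probs(v: np.ndarray, params: RbmParams) -> np.ndarray:
    """P(h_j=1 | v) = sigmoid(b_j + v.w_:j); accepts a vector or a batch."""
    return expit(np.asarray(v, dtype=float) @ params.W + params.b)


def visible_probs(h: np.ndarray, params: RbmParams) -> np.ndarray:
    """P(v_i=1 | h) = sigmoid(a_i + w_i:.h); accepts a vector or a batch."""
    return expit(np.asarray(h, dtype=float) @ params.W.T + params.a)


def _enumerate_states(n: int) -> np.ndarray:
    return np.array(list(product((0.0, 1.0), repeat=n)))


def exact_marginal(params: RbmParams) -> tuple[np.ndarray, np.ndarray]:
    """Exact P(v) over all 2^m visible states via the product-of-experts
    form: P(v) ∝ exp(a.v) Π_j (1 + exp(b_j + v.w_:j)).

    Returns (states, probabilities); refuses models with m + n > 16.
    """
    m, n = params.n_visible, params.n_hidden
    if m + n > 16:
        raise ValueError(f"model too large to enumerate (m+n = {m + n} > 16)")
    states = _enumerate_states(m)
    # log unnormalized: a.v + sum_j log(1 + exp(b_j + v.w_j))
    act = states @ params.W + params.b
    log_unnorm = states @ params.a + np.logaddexp(0.0, act).sum(axis=1)
    log_unnorm -= log_unnorm.max()
    p = np.exp(log_unnorm)
    return states, p / p.sum()


def exact_loglik_grad(
    data: np.ndarray, params: RbmParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact gradient of the mean log-likelihood (dW, da, db) by enumerating
    the model distribution. Oracle for tiny models only."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    h_data = hidden_probs(data, params)
    pos_w = data.T @ h_data / len(data)
    pos_a = data.mean(axis=0)
    pos_b = h_data.mean(axis=0)

    states, p = exact_marginal(params)
    h_model = hidden_probs(states, params)
    neg_w = (states * p[:, None]).T @ h_model
    neg_a = p @ states
    neg_b = p @ h_model
    return pos_w - neg_w, pos_a - neg_a, pos_b - neg_b


def init_rbm(
    n_visible: int, n_hidden: int, config: CdConfig, rng: np.random.Generator
) -> RbmParams:
    """Small Gaussian weights, zero offsets."""
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    W = rng.normal(0.0, config.init_sigma, size=(n_visible, n_hidden))
    return RbmParams(W=W, a=np.zeros(n_visible), b=np.zeros(n_hidden))


def cd_step(
    batch: np.ndarray,
    params: RbmParams,
    velocities: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: CdConfig,
    rng: np.random.Generator,
) -> float:
    """One CD-k parameter update in place; returns the batch's mean squared
    reconstruction error.

    Data-phase statistics use hidden probabilities; the negative chain starts
    from a binary hidden sample; reconstruction statistics use probabilities.
    Updates are momentum-blended velocities:
    Δw_ij = ε(<v_i h_j>_data − <v_i h_j>_recon), and analogously for a, b.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.size == 0:
        raise ValueError("empty batch")
    n = len(batch)

    h_data = hidden_probs(batch, params)
    if config.sample_hidden:
        h_state = (rng.random(h_data.shape) < h_data).astype(float)
    else:
        h_state = h_data
    for step in range(config.cd_steps):
        v_recon = visible_probs(h_state, params)
        h_recon = hidden_probs(v_recon, params)
        if step < config.cd_steps - 1:
            if config.sample_hidden:
                h_state = (rng.random(h_recon.shape) < h_recon).astype(float)
            else:
                h_state = h_recon

    grad_w = (batch.T @ h_data - v_recon.T @ h_recon) / n
    grad_a = (batch - v_recon).mean(axis=0)
    grad_b = (h_data - h_recon).mean(axis=0)

    vel_w, vel_a, vel_b = velocities
    vel_w *= config.momentum
    vel_w += config.learning_rate * grad_w
    vel_a *= config.momentum
    vel_a += config.learning_rate * grad_a
    vel_b *= config.momentum
    vel_b += config.learning_rate * grad_b
    params.W += vel_w
    params.a += vel_a
    params.b += vel_b
    return float(((batch - v_recon) ** 2).mean())


def train_rbm(
    data: np.ndarray, n_hidden: int, config: CdConfig
) -> tuple[RbmParams, list[float]]:
    """Train one RBM by shuffled mini-batch CD.

    Returns the parameters and the per-epoch mean reconstruction error.
    Deterministic given ``config.seed``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.min() < 0 or data.max() > 1:
        raise ValueError("training data must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB10C]))
    params = init_rbm(data.shape[1], n_hidden, config, rng)
    velocities = (
        np.zeros_like(params.W),
        np.zeros_like(params.a),
        np.zeros_like(params.b),
    )
    history: list[float] = []
    n = len(data)
    batch = min(config.batch_size, n)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        errs = []
        for start in range(0, n, batch):
            rows = order[start : start + batch]
            errs.append(cd_step(data[rows], params, velocities, config, rng))
        history.append(float(np.mean(errs)))
    return params, history
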