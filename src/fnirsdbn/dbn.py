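"""Deep belief network: two stacked RBMs plus a softmax output layer.

Training follows the classic recipe: greedy unsupervised layer-wise
pretraining of each RBM by contrastive divergence, then supervised
fine-tuning of the stacked network under the multinomial cross-entropy

    J(w) = -(1/M) Σ_i Σ_j 1{y_i = j} log p(y_i = j | h_i; w)

in two phases: phase 1 adjusts only the softmax output weights on frozen
features; phase 2 backpropagates through both sigmoid layers and adjusts
every parameter. Both phases use Polak-Ribiere conjugate-gradient steps with
a backtracking (Armijo) line search over shuffled mini-batches, blending the
accepted step with a momentum velocity. Classification propagates activation
probabilities (mean-field), never samples.

Hidden-layer widths are chosen by 2-fold cross-validation over a candidate
grid, with folds blocked by trial so the 160 time points of one trial never
straddle a fold boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax as _softmax

from .rbm import CdConfig, RbmParams, hidden_probs, train_rbm

__all__ = [
    "DbnModel",
    "FineTuneConfig",
    "ArchGrid",
    "TrainingHistory",
    "forward",
    "softmax_loss",
    "pretrain",
    "finetune",
    "select_architecture",
    "train_full",
]

_LOG_CLAMP = 1e-12


@dataclass
class DbnModel:
    """16 -> h1 -> h2 -> c classifier. ``softmax_w`` is c x (h2+1); its last
    column is the output offset."""

    rbm1: RbmParams
    rbm2: RbmParams
    softmax_w: np.ndarray
    class_labels: tuple[int, ...] = (0, 1)

    def __post_init__(self) -> None:
        if self.rbm1.n_hidden != self.rbm2.n_visible:
            raise ValueError("rbm1 hidden size must equal rbm2 visible size")
        c = len(self.class_labels)
        if self.softmax_w.shape != (c, self.rbm2.n_hidden + 1):
            raise ValueError(
                f"softmax_w must be {c} x {self.rbm2.n_hidden + 1}, got "
                f"{self.softmax_w.shape}"
            )

    @property
    def hidden_sizes(self) -> tuple[int, int]:
        return (self.rbm1.n_hidden, self.rbm2.n_hidden)

    def copy(self) -> "DbnModel":
        return DbnModel(
            self.rbm1.copy(),
            self.rbm2.copy(),
            self.softmax_w.copy(),
            self.class_labels,
        )


@dataclass(frozen=True)
class FineTuneConfig:
    phase1_iters: int = 30
    phase2_iters: int = 30
    learning_rate: float = 0.3
    momentum: float = 0.5
    cg_line_searches: int = 3
    batch_size: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")


@dataclass(frozen=True)
class ArchGrid:
    """Candidate hidden-layer widths; both layers draw from the same array."""

    candidates: tuple[int, ...] = (10, 20, 30, 40, 50)
    n_folds: int = 2

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.candidates):
            raise ValueError("all candidate unit counts must be >= 1")


@dataclass
class TrainingHistory:
    pretrain_errors: list[list[float]] = field(default_factory=list)
    finetune_loss: list[float] = field(default_factory=list)
    selected_arch: tuple[int, int] | None = None
    cv_table: dict[tuple[int, int], float] | None = None
    seeds: dict[str, int] = field(default_factory=dict)


def _features(x: np.ndarray, model: DbnModel) -> np.ndarray:
    """Mean-field top hidden activations h2 for a batch."""
    h1 = hidden_probs(x, model.rbm1)
    return hidden_probs(h1, model.rbm2)


def forward(x: np.ndarray, model: DbnModel) -> np.ndarray:
    """Class probabilities by deterministic mean-field propagation."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.rbm1.n_visible:
        raise ValueError(
            f"expected {model.rbm1.n_visible} features, got {x.shape[1]}"
        )
    h2 = _features(x, model)
    logits = h2 @ model.softmax_w[:, :-1].T + model.softmax_w[:, -1]
    return _softmax(logits, axis=1)


def softmax_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class; log clamped at 1e-12."""
    probabilities = np.atleast_2d(probabilities)
    labels = np.asarray(labels, dtype=int)
    p_true = probabilities[np.arange(len(labels)), labels]
    return float(-np.log(np.maximum(p_true, _LOG_CLAMP)).mean())


def pretrain(
    samples: np.ndarray, h1: int, h2: int, cd_config: CdConfig
) -> tuple[RbmParams, RbmParams, list[list[float]]]:
    """Greedy layer-wise unsupervised pretraining: rbm1 on the samples, rbm2
    on rbm1's hidden probabilities. Labels are never consulted."""
    rbm1, hist1 = train_rbm(samples, h1, cd_config)
    layer1 = hidden_probs(np.atleast_2d(samples), rbm1)
    cfg2 = CdConfig(
        epochs=cd_config.epochs,
        learning_rate=cd_config.learning_rate,
        momentum=cd_config.momentum,
        cd_steps=cd_config.cd_steps,
        batch_size=cd_config.batch_size,
        init_sigma=cd_config.init_sigma,
        sample_hidden=cd_config.sample_hidden,
        seed=cd_config.seed + 1,
    )
    rbm2, hist2 = train_rbm(layer1, h2, cfg2)
    return rbm1, rbm2, [hist1, hist2]


# ---------------------------------------------------------------------------
# fine-tuning internals: flat parameter vectors and analytic gradients


def _loss_grad_softmax(
    w_flat: np.ndarray, feats: np.ndarray, labels: np.ndarray, shape: tuple
) -> tuple[float, np.ndarray]:
    """Loss and gradient w.r.t. softmax weights only (phase 1)."""
    w = w_flat.reshape(shape)
    m = len(labels)
    logits = feats @ w[:, :-1].T + w[:, -1]
    p = _softmax(logits, axis=1)
    loss = softmax_loss(p, labels)
    delta = p.copy()
    delta[np.arange(m), labels] -= 1.0
    delta /= m
    grad = np.empty_like(w)
    grad[:, :-1] = delta.T @ feats
    grad[:, -1] = delta.sum(axis=0)
    return loss, grad.ravel()


def _pack(model: DbnModel) -> np.ndarray:
    return np.concatenate(
        [
            model.rbm1.W.ravel(),
            model.rbm1.b,
            model.rbm2.W.ravel(),
            model.rbm2.b,
            model.softmax_w.ravel(),
        ]
    )


def _unpack(theta: np.ndarray, model: DbnModel) -> None:
    m1, n1 = model.rbm1.W.shape
    m2, n2 = model.rbm2.W.shape
    c = model.softmax_w.shape[0]
    i = 0
    model.rbm1.W = theta[i : i + m1 * n1].reshape(m1, n1); i += m1 * n1
    model.rbm1.b = theta[i : i + n1]; i += n1
    model.rbm2.W = theta[i : i + m2 * n2].reshape(m2, n2); i += m2 * n2
    model.rbm2.b = theta[i : i + n2]; i += n2
    model.softmax_w = theta[i : i + c * (n2 + 1)].reshape(c, n2 + 1)


def _loss_grad_full(
    theta: np.ndarray, x: np.ndarray, labels: np.ndarray, model: DbnModel
) -> tuple[float, np.ndarray]:
    """Loss and gradient w.r.t. all weights and hidden offsets (phase 2).

    Visible offsets a do not enter the feed-forward pass and are untouched.
    """
    work = model.copy()
    _unpack(theta, work)
    m = len(labels)
    h1 = hidden_probs(x, work.rbm1)
    h2 = hidden_probs(h1, work.rbm2)
    logits = h2 @ work.softmax_w[:, :-1].T + work.softmax_w[:, -1]
    p = _softmax(logits, axis=1)
    loss = softmax_loss(p, labels)

    delta = p.copy()
    delta[np.arange(m), labels] -= 1.0
    delta /= m
    g_sw = np.empty_like(work.softmax_w)
    g_sw[:, :-1] = delta.T @ h2
    g_sw[:, -1] = delta.sum(axis=0)

    d_h2 = delta @ work.softmax_w[:, :-1]
    d_z2 = d_h2 * h2 * (1.0 - h2)
    g_w2 = h1.T @ d_z2
    g_b2 = d_z2.sum(axis=0)

    d_h1 = d_z2 @ work.rbm2.W.T
    d_z1 = d_h1 * h1 * (1.0 - h1)
    g_w1 = x.T @ d_z1
    g_b1 = d_z1.sum(axis=0)

    grad = np.concatenate(
        [g_w1.ravel(), g_b1, g_w2.ravel(), g_b2, g_sw.ravel()]
    )
    return loss, grad


def _cg_minimize(
    fun,
    theta: np.ndarray,
    batches: list[tuple],
    n_iters: int,
    config: FineTuneConfig,
) -> tuple[np.ndarray, list[float]]:
    """Mini-batch Polak-Ribiere CG with Armijo backtracking line search and a
    momentum-blended accepted step. ``fun(theta, *batch)`` -> (loss, grad).

    Returns the iterate with the lowest full-data loss seen at iteration
    boundaries, so the reported final loss never exceeds the initial one.
    """
    theta = theta.copy()
    velocity = np.zeros_like(theta)
    history: list[float] = []

    def full_loss(th: np.ndarray) -> float:
        num = sum(fun(th, *b)[0] * len(b[1]) for b in batches)
        den = sum(len(b[1]) for b in batches)
        return float(num / den)

    best_theta = theta.copy()
    best_loss = full_loss(theta)
    history.append(best_loss)
    for _ in range(n_iters):
        for batch in batches:
            loss, grad = fun(theta, *batch)
            d = -grad
            for _ls in range(config.cg_line_searches):
                gd = float(grad @ d)
                if gd >= 0:  # not a descent direction: reset to steepest
                    d = -grad
                    gd = float(grad @ d)
                    if gd >= 0:
                        break
                # backtracking Armijo line search along d, starting from a
                # step whose displacement is the configured learning rate
                t = config.learning_rate / max(float(np.linalg.norm(d)), 1e-12)
                accepted = False
                for _bt in range(12):
                    trial_loss, _ = fun(theta + t * d, *batch)
                    if trial_loss <= loss + 1e-4 * t * gd:
                        accepted = True
                        break
                    t *= 0.5
                if not accepted:
                    break
                # momentum blend of the accepted step (velocity update rule)
                velocity = config.momentum * velocity + t * d
                theta = theta + velocity
                new_loss, new_grad = fun(theta, *batch)
                beta = max(
                    0.0,
                    float(new_grad @ (new_grad - grad))
                    / max(float(grad @ grad), 1e-300),
                )
                d = -new_grad + beta * d
                loss, grad = new_loss, new_grad
        cur = full_loss(theta)
        history.append(cur)
        if cur < best_loss:
            best_loss = cur
            best_theta = theta.copy()
    return best_theta, history


def finetune(
    model: DbnModel,
    samples: np.ndarray,
    labels: np.ndarray,
    config: FineTuneConfig,
) -> tuple[DbnModel, list[float]]:
    """Two-phase supervised fine-tuning.

    Phase 1 adjusts only the softmax output weights on frozen RBM features;
    phase 2 adjusts all feed-forward parameters by backpropagation. Returns
    the refined model and the concatenated full-data loss history.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if not set(np.unique(labels)) <= set(model.class_labels):
        raise ValueError(
            f"labels {sorted(set(labels))} outside {model.class_labels}"
        )
    model = model.copy()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF17E]))
    n = len(labels)
    order = rng.permutation(n)
    bs = min(config.batch_size, n)
    slices = [order[s : s + bs] for s in range(0, n, bs)]

    # phase 1: softmax only, features computed once
    feats = _features(samples, model)
    shape = model.softmax_w.shape
    batches1 = [(feats[idx], labels[idx], shape) for idx in slices]
    w1, hist1 = _cg_minimize(
        _loss_grad_softmax,
        model.softmax_w.ravel(),
        batches1,
        config.phase1_iters,
        config,
    )
    model.softmax_w = w1.reshape(shape)

    # phase 2: everything
    hist2: list[float] = []
    if config.phase2_iters > 0:
        batches2 = [(samples[idx], labels[idx], model) for idx in slices]
        theta, hist2 = _cg_minimize(
            _loss_grad_full, _pack(model), batches2, config.phase2_iters, config
        )
        _unpack(theta, model)
    return model, hist1 + hist2


def _trial_folds(
    trial_index: np.ndarray, labels: np.ndarray, n_folds: int
) -> list[np.ndarray]:
    """Row masks of trial-blocked, class-stratified folds."""
    trials = np.unique(trial_index)
    if len(trials) < n_folds:
        raise ValueError(f"need >= {n_folds} trials, got {len(trials)}")
    trial_label = {
        t: labels[trial_index == t][0] for t in trials
    }
    assign: dict[int, int] = {}
    for lab in sorted(set(trial_label.values())):
        members = [t for t in trials if trial_label[t] == lab]
        for k, t in enumerate(members):
            assign[t] = k % n_folds
    return [
        np.isin(trial_index, [t for t in trials if assign[t] == f])
        for f in range(n_folds)
    ]


def _fit_once(
    x: np.ndarray,
    y: np.ndarray,
    h1: int,
    h2: int,
    cd_config: CdConfig,
    ft_config: FineTuneConfig,
) -> tuple[DbnModel, TrainingHistory]:
    rbm1, rbm2, pre_hist = pretrain(x, h1, h2, cd_config)
    # small random output weights: with exactly zero softmax weights no
    # gradient reaches the RBM layers in phase 2
    sw_rng = np.random.default_rng(
        np.random.SeedSequence([ft_config.seed, 0x50F7])
    )
    model = DbnModel(
        rbm1=rbm1,
        rbm2=rbm2,
        softmax_w=sw_rng.normal(0.0, 0.1, size=(2, h2 + 1)),
    )
    model, ft_hist = finetune(model, x, y, ft_config)
    history = TrainingHistory(
        pretrain_errors=pre_hist,
        finetune_loss=ft_hist,
        selected_arch=(h1, h2),
        seeds={"cd": cd_config.seed, "finetune": ft_config.seed},
    )
    return model, history


def select_architecture(
    samples: np.ndarray,
    labels: np.ndarray,
    trial_index: np.ndarray,
    grid: ArchGrid,
    cd_config: CdConfig,
    ft_config: FineTuneConfig,
) -> tuple[int, int, dict[tuple[int, int], float]]:
    """Cross-validated hidden-size selection over the grid's Cartesian
    product. Ties break toward the smaller h1+h2, then the smaller h1."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    labels = np.asarray(labels, dtype=int)
    folds = _trial_folds(np.asarray(trial_index), labels, grid.n_folds)
    cv_table: dict[tuple[int, int], float] = {}
    for h1 in grid.candidates:
        for h2 in grid.candidates:
            accs = []
            for f, test_mask in enumerate(folds):
                train_mask = ~test_mask
                model, _ = _fit_once(
                    samples[train_mask], labels[train_mask], h1, h2,
                    cd_config, ft_config,
                )
                p = forward(samples[test_mask], model)
                accs.append(
                    float((p.argmax(axis=1) == labels[test_mask]).mean())
                )
            cv_table[(h1, h2)] = float(np.mean(accs))
    best = max(
        cv_table,
        key=lambda k: (cv_table[k], -(k[0] + k[1]), -k[0]),
    )
    return best[0], best[1], cv_table


def train_full(
    samples: np.ndarray,
    labels: np.ndarray,
    trial_index: np.ndarray,
    grid: ArchGrid,
    cd_config: CdConfig,
    ft_config: FineTuneConfig,
) -> tuple[DbnModel, TrainingHistory]:
    """Architecture selection, pretraining and fine-tuning on the full
    training set; deterministic under fixed seeds."""
    h1, h2, cv_table = select_architecture(
        samples, labels, trial_index, grid, cd_config, ft_config
    )
    model, history = _fit_once(samples, labels, h1, h2, cd_config, ft_config)
    history.cv_table = cv_table
    history.selected_arch = (h1, h2)
    return model, history
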