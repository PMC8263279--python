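"""DBN stack: forward pass, loss, pretraining contracts, two-phase
fine-tuning and architecture selection."""

import numpy as np
import pytest
from scipy.special import expit

from fnirsdbn.dbn import (
    ArchGrid,
    DbnModel,
    FineTuneConfig,
    _fit_once,
    _loss_grad_full,
    _pack,
    finetune,
    forward,
    pretrain,
    select_architecture,
    softmax_loss,
    train_full,
)
from fnirsdbn.rbm import CdConfig, RbmParams, hidden_probs


def make_model(m=4, h1=3, h2=2, rng=None, scale=0.5):
    rng = rng or np.random.default_rng(0)
    return DbnModel(
        rbm1=RbmParams(
            W=rng.normal(0, scale, (m, h1)),
            a=rng.normal(0, scale, m),
            b=rng.normal(0, scale, h1),
        ),
        rbm2=RbmParams(
            W=rng.normal(0, scale, (h1, h2)),
            a=rng.normal(0, scale, h1),
            b=rng.normal(0, scale, h2),
        ),
        softmax_w=rng.normal(0, scale, (2, h2 + 1)),
    )


class TestForward:
    def test_zero_parameters_give_uniform_output(self):
        model = DbnModel(
            rbm1=RbmParams(np.zeros((4, 3)), np.zeros(4), np.zeros(3)),
            rbm2=RbmParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2)),
            softmax_w=np.zeros((2, 3)),
        )
        p = forward(np.full(4, 0.3), model)
        np.testing.assert_allclose(p, 0.5)

    def test_softmax_shift_invariance(self):
        model = make_model()
        x = np.random.default_rng(1).random((5, 4))
        p1 = forward(x, model)
        shifted = model.copy()
        shifted.softmax_w = shifted.softmax_w + 3.7
        np.testing.assert_allclose(p1, forward(x, shifted), atol=1e-12)

    def test_matches_scalar_chain(self):
        model = make_model(m=2, h1=2, h2=2)
        x = np.array([0.2, 0.9])
        h1 = expit(model.rbm1.b + x @ model.rbm1.W)
        h2 = expit(model.rbm2.b + h1 @ model.rbm2.W)
        logits = model.softmax_w[:, :2] @ h2 + model.softmax_w[:, 2]
        expected = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(forward(x, model)[0], expected)

    def test_outputs_are_distributions_for_any_finite_params(self):
        rng = np.random.default_rng(2)
        for scale in (0.1, 5.0, 50.0):
            model = make_model(rng=rng, scale=scale)
            p = forward(rng.random((10, 4)), model)
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(p >= 0) and np.all(p <= 1)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            forward(np.zeros(7), make_model())


class TestSoftmaxLoss:
    def test_perfect_prediction_zero_loss(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert softmax_loss(p, np.array([0, 1])) == 0.0

    def test_uniform_prediction_log2(self):
        p = np.full((4, 2), 0.5)
        assert softmax_loss(p, np.array([0, 1, 0, 1])) == pytest.approx(
            np.log(2)
        )

    def test_mixed_case_matches_hand_average(self):
        p = np.array([[0.8, 0.2], [0.3, 0.7], [0.6, 0.4]])
        labels = np.array([0, 1, 1])
        expected = -(np.log(0.8) + np.log(0.7) + np.log(0.4)) / 3
        assert softmax_loss(p, labels) == pytest.approx(expected)

    def test_zero_probability_clamped(self):
        p = np.array([[0.0, 1.0]])
        loss = softmax_loss(p, np.array([0]))
        assert np.isfinite(loss)
        assert loss == pytest.approx(-np.log(1e-12))


class TestPretrain:
    def test_minimal_architecture_runs(self):
        x = np.random.default_rng(3).random((30, 16))
        rbm1, rbm2, hist = pretrain(x, 1, 1, CdConfig(epochs=2, seed=0))
        assert rbm1.W.shape == (16, 1)
        assert rbm2.W.shape == (1, 1)
        assert [len(h) for h in hist] == [2, 2]

    def test_second_rbm_trains_on_first_layer_activations(self):
        x = np.random.default_rng(4).random((40, 6))
        cfg = CdConfig(epochs=3, seed=1)
        rbm1, rbm2, _ = pretrain(x, 4, 3, cfg)
        from fnirsdbn.rbm import train_rbm
        from dataclasses import replace

        layer1 = hidden_probs(x, rbm1)
        expected, _ = train_rbm(layer1, 3, replace(cfg, seed=cfg.seed + 1))
        np.testing.assert_array_equal(rbm2.W, expected.W)

    def test_unsupervised_contract_no_label_dependence(self):
        # pretraining consumes only the sample matrix; shuffling labels is
        # impossible by construction (no label argument), so reordering
        # samples with their labels jointly must not matter either
        x = np.random.default_rng(5).random((20, 6))
        r1a, r2a, _ = pretrain(x, 3, 2, CdConfig(epochs=2, seed=2))
        r1b, r2b, _ = pretrain(x, 3, 2, CdConfig(epochs=2, seed=2))
        np.testing.assert_array_equal(r1a.W, r1b.W)
        np.testing.assert_array_equal(r2a.W, r2b.W)


class TestFinetune:
    def test_phase1_leaves_rbm_layers_bitwise_unchanged(self):
        rng = np.random.default_rng(6)
        x = rng.random((80, 4))
        y = rng.integers(0, 2, 80)
        model = make_model(rng=rng)
        before_w1 = model.rbm1.W.copy()
        before_w2 = model.rbm2.W.copy()
        before_b1 = model.rbm1.b.copy()
        tuned, _ = finetune(
            model, x, y, FineTuneConfig(phase1_iters=5, phase2_iters=0, seed=0)
        )
        assert np.array_equal(tuned.rbm1.W, before_w1)
        assert np.array_equal(tuned.rbm2.W, before_w2)
        assert np.array_equal(tuned.rbm1.b, before_b1)
        assert not np.array_equal(tuned.softmax_w, model.softmax_w)

    def test_loss_never_ends_above_start(self):
        rng = np.random.default_rng(7)
        x = rng.random((120, 4))
        y = rng.integers(0, 2, 120)
        model = make_model(rng=rng)
        _, history = finetune(
            model, x, y, FineTuneConfig(phase1_iters=4, phase2_iters=4, seed=1)
        )
        assert history[-1] <= history[0] + 1e-12

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(8)
        x = rng.random((12, 3))
        y = rng.integers(0, 2, 12)
        model = make_model(m=3, h1=2, h2=2, rng=rng)
        theta = _pack(model)
        loss, grad = _loss_grad_full(theta, x, y, model)
        eps = 1e-6
        num = np.zeros_like(theta)
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            num[i] = (
                _loss_grad_full(tp, x, y, model)[0]
                - _loss_grad_full(tm, x, y, model)[0]
            ) / (2 * eps)
        denom = max(np.linalg.norm(num), 1e-300)
        assert np.linalg.norm(grad - num) / denom < 1e-5

    def test_linearly_separable_toy_reaches_full_training_accuracy(self):
        # a 2-D separable problem embedded in 16-D
        rng = np.random.default_rng(9)
        n = 100
        y = rng.integers(0, 2, n)
        x = np.full((n, 16), 0.5)
        x[:, 0] = 0.2 + 0.6 * y + rng.normal(0, 0.03, n)
        x[:, 1] = 0.8 - 0.6 * y + rng.normal(0, 0.03, n)
        x = np.clip(x, 0, 1)
        model, _ = _fit_once(
            x, y, 4, 4, CdConfig(epochs=5, seed=3), FineTuneConfig(seed=4)
        )
        pred = forward(x, model).argmax(axis=1)
        assert (pred == y).mean() == 1.0

    def test_class_relabeling_symmetry(self):
        rng = np.random.default_rng(10)
        model = make_model(rng=rng)
        x = rng.random((20, 4))
        p = forward(x, model)
        swapped = model.copy()
        swapped.softmax_w = swapped.softmax_w[::-1].copy()
        p_sw = forward(x, swapped)
        np.testing.assert_allclose(p, p_sw[:, ::-1], atol=1e-12)

    def test_unknown_label_rejected(self):
        model = make_model()
        with pytest.raises(ValueError):
            finetune(
                model,
                np.random.default_rng(0).random((10, 4)),
                np.full(10, 3),
                FineTuneConfig(),
            )


def _toy_trials(n_trials=8, rows=20, seed=0):
    rng = np.random.default_rng(seed)
    y_trial = np.tile([0, 1], n_trials // 2)
    x, y, tri = [], [], []
    for t, lab in enumerate(y_trial):
        block = np.full((rows, 16), 0.5)
        block[:, 0] = 0.25 + 0.5 * lab + rng.normal(0, 0.05, rows)
        x.append(np.clip(block, 0, 1))
        y.append(np.full(rows, lab))
        tri.append(np.full(rows, t))
    return np.vstack(x), np.concatenate(y), np.concatenate(tri)


class TestSelectArchitecture:
    def test_cv_table_covers_grid_product(self):
        x, y, tri = _toy_trials()
        grid = ArchGrid(candidates=(2, 3), n_folds=2)
        cfg = CdConfig(epochs=2, seed=0)
        ft = FineTuneConfig(phase1_iters=2, phase2_iters=2, seed=1)
        h1, h2, table = select_architecture(x, y, tri, grid, cfg, ft)
        assert set(table) == {(2, 2), (2, 3), (3, 2), (3, 3)}
        assert (h1, h2) in table

    def test_tie_breaks_toward_smaller_architecture(self):
        x, y, tri = _toy_trials()
        grid = ArchGrid(candidates=(2, 2, 3), n_folds=2)
        cfg = CdConfig(epochs=2, seed=0)
        ft = FineTuneConfig(phase1_iters=2, phase2_iters=2, seed=1)
        h1a, h2a, _ = select_architecture(x, y, tri, grid, cfg, ft)
        grid_b = ArchGrid(candidates=(2, 3), n_folds=2)
        h1b, h2b, _ = select_architecture(x, y, tri, grid_b, cfg, ft)
        assert (h1a, h2a) == (h1b, h2b)

    def test_folds_are_trial_blocked(self):
        x, y, tri = _toy_trials(n_trials=4)
        from fnirsdbn.dbn import _trial_folds

        folds = _trial_folds(tri, y, 2)
        for mask in folds:
            trials_in_fold = np.unique(tri[mask])
            for t in trials_in_fold:
                assert mask[tri == t].all()

    def test_too_few_trials_rejected(self):
        x, y, tri = _toy_trials(n_trials=2)
        tri = np.zeros_like(tri)  # collapse to a single trial
        with pytest.raises(ValueError):
            select_architecture(
                x, y, tri, ArchGrid(candidates=(2,), n_folds=2),
                CdConfig(epochs=1), FineTuneConfig(),
            )


class TestTrainFull:
    def test_deterministic_and_bookkeeping(self):
        x, y, tri = _toy_trials()
        grid = ArchGrid(candidates=(2,), n_folds=2)
        cfg = CdConfig(epochs=3, seed=5)
        ft = FineTuneConfig(phase1_iters=2, phase2_iters=2, seed=6)
        m1, hist1 = train_full(x, y, tri, grid, cfg, ft)
        m2, hist2 = train_full(x, y, tri, grid, cfg, ft)
        np.testing.assert_array_equal(m1.rbm1.W, m2.rbm1.W)
        np.testing.assert_array_equal(m1.softmax_w, m2.softmax_w)
        assert hist1.selected_arch == (2, 2)
        assert [len(h) for h in hist1.pretrain_errors] == [3, 3]

    def test_training_accuracy_beats_chance_with_margin(self):
        x, y, tri = _toy_trials(n_trials=12, rows=30, seed=3)
        grid = ArchGrid(candidates=(3,), n_folds=2)
        model, _ = train_full(
            x, y, tri, grid, CdConfig(epochs=3, seed=1),
            FineTuneConfig(seed=2),
        )
        acc = (forward(x, model).argmax(axis=1) == y).mean()
        n = len(y)
        # 3-sigma binomial band around chance
        assert acc > 0.5 + 3 * np.sqrt(0.25 / n)
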