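"""Training protocol: early stopping, checkpointing, evaluation, estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xaimri.errors import ValidationError
from xaimri.train import (
    TrainConfig,
    UNetSegmenter,
    early_stop_decision,
    evaluate,
    train,
)
from xaimri.unet import UNetConfig, build_unet, load_checkpoint, stack_modalities

TINY = UNetConfig(in_channels=2, n_classes=4, depth_levels=2, base_filters=4, dropout_rate=0.1)
FAST = dict(batch_size=2, learning_rate=3e-3, loss="weighted_cross_entropy")


@pytest.fixture(scope="module")
def phantom_samples(preprocessed_cohort):
    return [
        (stack_modalities(p, ["T2", "T1ce"]), p.mask.astype(np.int64))
        for p in preprocessed_cohort
    ]


def replay_oracle(losses, patience):
    """Step-by-step simulation of the stated early-stopping rule."""
    best = losses[0]
    best_epoch = 0
    for t in range(1, len(losses)):
        if losses[t] < best:
            best = losses[t]
            best_epoch = t
    since = len(losses) - 1 - best_epoch
    effective = patience if patience > 0 else 1
    return since >= effective, best_epoch


class TestEarlyStopDecision:
    def test_strictly_decreasing_never_stops(self):
        stop, best = early_stop_decision([1.0, 0.9, 0.8, 0.7], patience=5)
        assert not stop and best == 3

    def test_worked_sequence_stops_after_patience_exhausted(self):
        losses = [1.00, 0.90, 0.95, 0.94, 0.93, 0.92, 0.91]
        stop, best = early_stop_decision(losses, patience=5)
        assert stop and best == 1
        stop_before, _ = early_stop_decision(losses[:-1], patience=5)
        assert not stop_before

    def test_patience_not_yet_exhausted(self):
        assert early_stop_decision([1.0, 0.5, 0.6, 0.7, 0.8, 0.9], patience=5) == (False, 1)

    def test_tie_keeps_first_epoch(self):
        _, best = early_stop_decision([0.5, 0.5, 0.5], patience=5)
        assert best == 0

    def test_zero_patience_stops_on_first_non_improvement(self):
        assert early_stop_decision([1.0, 0.9], patience=0) == (False, 1)
        assert early_stop_decision([1.0, 0.9, 0.95], patience=0) == (True, 1)

    @settings(deadline=None, max_examples=1000, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 10.0, allow_nan=False), min_size=1, max_size=60),
        st.integers(0, 10),
    )
    def test_agrees_with_replay_oracle(self, losses, patience):
        assert early_stop_decision(losses, patience) == replay_oracle(losses, patience)


class TestTrainConfig:
    def test_defaults_follow_the_training_protocol(self):
        cfg = TrainConfig()
        assert (cfg.batch_size, cfg.max_epochs, cfg.learning_rate, cfg.patience) == (
            4, 40, 1e-4, 5,
        )

    @pytest.mark.parametrize(
        "kwargs", [{"batch_size": 0}, {"max_epochs": 0}, {"patience": -1},
                   {"learning_rate": 0.0}, {"loss": "hinge"}],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            TrainConfig(**kwargs)


class TestTrainLoop:
    def test_memorization_overfit_bar(self, phantom_samples):
        """Two subjects, tiny model, generous epochs: global training Dice >= 0.90."""
        from xaimri.metrics import dice_coefficient

        model = build_unet(TINY, seed=0)
        pair = phantom_samples[:2]
        train(model, pair, pair, TrainConfig(max_epochs=60, patience=60, seed=0, **FAST))
        preds = np.stack([model.forward(x[None])[0].argmax(0) for x, _ in pair])
        truths = np.stack([y for _, y in pair])
        assert dice_coefficient(preds, truths, 4, mode="global") >= 0.90

    def test_history_and_best_checkpoint_consistency(self, phantom_samples, tmp_path):
        model = build_unet(TINY, seed=1)
        result = train(
            model, phantom_samples[:3], phantom_samples[3:],
            TrainConfig(max_epochs=4, patience=2, seed=1, **FAST),
            checkpoint_path=tmp_path / "best.npz",
            checkpoint_meta={"modalities": ["T2", "T1ce"]},
        )
        assert len(result.history) <= 4
        losses = result.val_losses
        assert result.best_epoch == int(np.argmin(losses))
        # reloading the checkpoint reproduces the best validation loss
        reloaded, sidecar = load_checkpoint(result.best_checkpoint)
        from xaimri.train import _dataset_loss, _resolve_loss

        loss_fn = _resolve_loss("weighted_cross_entropy", phantom_samples[:3], 4)
        val_loss, _ = _dataset_loss(reloaded, phantom_samples[3:], loss_fn)
        assert val_loss == pytest.approx(losses[result.best_epoch], abs=1e-6)
        assert sidecar["modalities"] == ["T2", "T1ce"]

    def test_identical_seeds_reproduce_history(self, phantom_samples):
        def run():
            model = build_unet(TINY, seed=5)
            return train(model, phantom_samples[:3], phantom_samples[3:],
                         TrainConfig(max_epochs=3, seed=5, **FAST)).history

        assert run() == run()

    def test_early_stop_bookkeeping(self, phantom_samples):
        model = build_unet(TINY, seed=2)
        result = train(model, phantom_samples[:3], phantom_samples[3:],
                       TrainConfig(max_epochs=40, patience=1, seed=2, **FAST))
        if result.stopped_early:
            assert len(result.history) - 1 - result.best_epoch == 1
        assert len(result.history) <= 40

    def test_empty_set_and_channel_mismatch_rejected(self, phantom_samples):
        model = build_unet(TINY, seed=0)
        with pytest.raises(ValidationError, match="nonempty"):
            train(model, [], phantom_samples[3:], TrainConfig())
        bad = [(x[:1], y) for x, y in phantom_samples[:2]]
        with pytest.raises(ValidationError, match="channels"):
            train(model, bad, bad, TrainConfig())


class TestEvaluate:
    def test_perfect_predictor_limit(self, phantom_samples):
        class Oracle:
            in_channels = 2
            n_classes = 4

            def forward(self, x, train=False):
                onehot = np.eye(4)[self.truth][None]
                return np.moveaxis(onehot, -1, 1)

        oracle = Oracle()
        x, y = phantom_samples[0]
        oracle.truth = y
        report = evaluate(oracle, [(x, y)])
        assert report.dice_coef == pytest.approx(1.0)
        assert report.mean_iou == pytest.approx(1.0)
        assert report.accuracy == pytest.approx(1.0)

    def test_constant_background_predictor_accuracy_is_background_fraction(self, phantom_samples):
        class Background:
            in_channels = 2
            n_classes = 4

            def forward(self, x, train=False):
                probs = np.zeros((1, 4) + x.shape[2:], dtype=np.float32)
                probs[:, 0] = 1.0
                return probs

        x, y = phantom_samples[0]
        report = evaluate(Background(), [(x, y)])
        assert report.accuracy == pytest.approx(float((y == 0).mean()))

    def test_report_carries_exactly_the_six_metric_names(self, phantom_samples):
        x, y = phantom_samples[0]

        class Background:
            in_channels = 2
            n_classes = 4

            def forward(self, x, train=False):
                probs = np.zeros((1, 4) + x.shape[2:], dtype=np.float32)
                probs[:, 0] = 1.0
                return probs

        report = evaluate(Background(), [(x, y)])
        assert report.METRIC_NAMES == (
            "accuracy", "mean_iou", "dice_coef", "precision", "sensitivity", "specificity",
        )


class TestUNetSegmenterEstimator:
    def test_sklearn_protocol_and_fitted_attributes(self, phantom_samples):
        X = np.stack([x for x, _ in phantom_samples])
        y = np.stack([t for _, t in phantom_samples])
        est = UNetSegmenter(depth_levels=2, base_filters=4, max_epochs=2,
                            batch_size=2, learning_rate=3e-3,
                            loss="weighted_cross_entropy", random_state=0)
        params = est.get_params()
        assert params["max_epochs"] == 2
        est.set_params(max_epochs=3)
        est.fit(X, y)
        assert hasattr(est, "model_") and hasattr(est, "history_")
        assert est.n_iter_ == len(est.history_) <= 3
        pred = est.predict(X)
        assert pred.shape == y.shape
        proba = est.predict_proba(X[:1])
        assert proba.shape == (1, 4) + y.shape[1:]
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-5)
        assert 0.0 <= est.score(X, y) <= 1.0

    def test_clone_compatible(self):
        from sklearn.base import clone

        est = UNetSegmenter(max_epochs=2)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
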