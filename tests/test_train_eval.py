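"""Training harness and confusion-matrix metrics."""

import numpy as np
import pandas as pd
import pytest

from glomseg.model import NetworkSpec, build_modified_unet
from glomseg.synthdata import generate_tileset
from glomseg.train_eval import (
    SWEEP_COLUMNS,
    MetricReport,
    PixelConfusion,
    TrainConfig,
    confusion,
    dice_coefficient,
    evaluate,
    metrics,
    sweep,
    train,
)


class TestConfusion:
    def test_perfect_prediction(self, rng):
        mask = (rng.random((8, 8)) < 0.3).astype(np.uint8)
        cm = confusion(mask, mask)
        P = int(mask.sum())
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (P, 0, 0, 64 - P)

    def test_worst_case(self):
        cm = confusion(np.ones((2, 2), np.uint8), np.zeros((2, 2), np.uint8))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 4, 0, 0)

    def test_enumerated_four_pixels(self):
        cm = confusion(np.array([[1, 1, 0, 0]]), np.array([[1, 0, 1, 0]]))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 1, 1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(np.zeros((2, 2), np.uint8), np.zeros((3, 3), np.uint8))

    def test_total_is_pixel_count(self, rng):
        pred = (rng.random((5, 7)) < 0.5).astype(np.uint8)
        truth = (rng.random((5, 7)) < 0.5).astype(np.uint8)
        assert confusion(pred, truth).total == 35

    def test_additivity_over_images(self, rng):
        """Confusion of a tile collection equals the sum of per-tile
        confusions."""
        preds = [(rng.random((6, 6)) < 0.4).astype(np.uint8) for _ in range(5)]
        truths = [(rng.random((6, 6)) < 0.4).astype(np.uint8) for _ in range(5)]
        summed = PixelConfusion(0, 0, 0, 0)
        for p, t in zip(preds, truths):
            summed = summed + confusion(p, t)
        stacked = confusion(np.hstack(preds), np.hstack(truths))
        assert summed == stacked


class TestMetrics:
    def test_balanced_case(self):
        rep = metrics(PixelConfusion(tp=1, fp=1, fn=1, tn=1))
        assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 50.0

    def test_perfect_classifier(self):
        rep = metrics(PixelConfusion(tp=10, fp=0, fn=0, tn=20))
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1) == (100.0,) * 4

    def test_zero_tp_guarded(self):
        with pytest.warns(RuntimeWarning):
            rep = metrics(PixelConfusion(tp=0, fp=3, fn=2, tn=5))
        assert rep.precision == rep.recall == rep.f1 == 0.0

    def test_empty_confusion_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics(PixelConfusion(0, 0, 0, 0))

    def test_f1_is_harmonic_mean(self):
        rep = metrics(PixelConfusion(tp=6, fp=2, fn=4, tn=8))
        p, r = rep.precision, rep.recall
        assert rep.f1 == pytest.approx(2 * p * r / (p + r))

    def test_f1_equals_dice_on_random_pairs(self, rng):
        """F1 from the confusion matrix is the Dice coefficient of the two
        masks, to numerical identity, on 100 random pairs."""
        import warnings as _warnings
        for _ in range(100):
            h, w = int(rng.integers(2, 20)), int(rng.integers(2, 20))
            pred = (rng.random((h, w)) < rng.random()).astype(np.uint8)
            truth = (rng.random((h, w)) < rng.random()).astype(np.uint8)
            if not (pred.sum() + truth.sum()):
                continue
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                f1 = metrics(confusion(pred, truth)).f1 / 100.0
            assert abs(f1 - dice_coefficient(pred, truth)) < 1e-12

    def test_invariance_under_pixel_permutation(self, rng):
        pred = (rng.random((8, 8)) < 0.5).astype(np.uint8)
        truth = (rng.random((8, 8)) < 0.5).astype(np.uint8)
        perm = rng.permutation(64)
        rep_a = metrics(confusion(pred, truth))
        rep_b = metrics(confusion(pred.ravel()[perm].reshape(8, 8),
                                  truth.ravel()[perm].reshape(8, 8)))
        assert rep_a == rep_b


class TestTrainConfig:
    def test_unknown_optimizer_rejected(self):
        with pytest.raises(ValueError, match="adamw"):
            TrainConfig(optimizer="adamw")

    def test_yaml_round_trip(self, tmp_path):
        cfg = TrainConfig(optimizer="rmsprop", batch_size=16, epochs=3, seed=4)
        cfg.to_yaml(tmp_path / "run.yaml")
        assert TrainConfig.from_yaml(tmp_path / "run.yaml") == cfg


@pytest.fixture(scope="module")
def tiny_data():
    tiles = generate_tileset(12, 12, tile_size=32, seed=11)
    return tiles


@pytest.fixture(scope="module")
def tiny_spec():
    return NetworkSpec(width_scale=0.03, tile_size=32)


class TestTrain:
    def test_history_length_and_loss_decrease(self, tiny_data, tiny_spec):
        """Three epochs on separable synthetic blobs: three records, and the
        final training loss is below the first epoch's."""
        net = build_modified_unet(tiny_spec, seed=0)
        history = train(net, tiny_data, tiny_data,
                        TrainConfig(epochs=3, seed=0))
        assert len(history) == 3
        assert history.records[-1].train_loss < history.records[0].train_loss
        assert all(0 <= r.val_accuracy <= 100 for r in history)

    def test_determinism_under_seed(self, tiny_data, tiny_spec):
        runs = []
        for _ in range(2):
            net = build_modified_unet(tiny_spec, seed=0)
            history = train(net, tiny_data, tiny_data,
                            TrainConfig(epochs=2, seed=5))
            runs.append([(r.train_loss, r.val_loss) for r in history])
        assert runs[0] == runs[1]

    def test_empty_training_set_rejected(self, tiny_data, tiny_spec):
        from glomseg.tiling import TileSet
        net = build_modified_unet(tiny_spec)
        with pytest.raises(ValueError, match="empty training set"):
            train(net, TileSet(), tiny_data, TrainConfig(epochs=1))

    def test_tile_size_mismatch_rejected(self, tiny_data):
        net = build_modified_unet(NetworkSpec(width_scale=0.03, tile_size=64))
        with pytest.raises(ValueError, match="tile size"):
            train(net, tiny_data, tiny_data, TrainConfig(epochs=1))


class TestEvaluate:
    def test_per_image_table_schema(self, tiny_data, tiny_spec):
        net = build_modified_unet(tiny_spec, seed=0)
        table, agg = evaluate(net, tiny_data)
        assert list(table.columns) == ["image_id", "accuracy", "precision",
                                       "recall", "f1"]
        assert len(table) == len(tiny_data)
        assert isinstance(agg, MetricReport)
        for c in ("accuracy", "precision", "recall", "f1"):
            assert table[c].between(0, 100).all()
            assert getattr(agg, c) == pytest.approx(float(table[c].mean()))


class TestSweep:
    def test_table_schema_and_cardinality(self, tiny_data, tiny_spec):
        grid = [TrainConfig(optimizer=o, epochs=1, seed=0)
                for o in ("adam", "sgd")]
        table = sweep(grid, tiny_data, tiny_data,
                      lambda: build_modified_unet(tiny_spec, seed=0))
        assert list(table.columns) == SWEEP_COLUMNS
        assert len(table) == 2
        assert list(table["optimizer"]) == ["adam", "sgd"]

    def test_empty_grid_rejected(self, tiny_data, tiny_spec):
        with pytest.raises(ValueError, match="empty"):
            sweep([], tiny_data, tiny_data, lambda: None)


@pytest.mark.parametrize("name", ["adam", "sgd", "rmsprop", "adadelta"])
def test_every_optimizer_reduces_loss(name, tiny_data, tiny_spec):
    """Each supported optimizer makes progress on the separable fixture."""
    net = build_modified_unet(tiny_spec, seed=0)
    history = train(net, tiny_data, tiny_data,
                    TrainConfig(optimizer=name, epochs=3, seed=0))
    assert history.records[-1].train_loss < history.records[0].train_loss
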