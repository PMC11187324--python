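"""MIL bags, slide-level splits, instance sampling and training protocol."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import chisquare

from blscreen.mil import (
    Bag,
    ModelConfig,
    build_bags,
    forward_bag,
    sample_instances,
    split_slides,
    train_model,
)
from blscreen.nn import MILNet
from blscreen.qc import QCResult
from blscreen.synthetic import generate_tile
from blscreen.tiling import TileRecord


def _passing_qc():
    return QCResult(True, {s: True for s in ("background", "pen", "purple_pink", "otsu")}, {})


def _failing_qc():
    return QCResult(False, {"background": False}, {"bg_std": 0.0})


def make_record(slide_id, label, seed, x=0, y=0, mag="20x", passed=True):
    return TileRecord(
        slide_id=slide_id, x=x, y=y, magnification=mag, tile_size_px=64,
        raster=generate_tile(label, "clean", 64, seed),
        qc=_passing_qc() if passed else _failing_qc(),
    )


def make_bag(slide_id, label, n=6, seed0=0):
    return Bag(slide_id=slide_id, label=label,
               instances=[make_record(slide_id, label, seed0 + i, x=64 * i) for i in range(n)])


SMALL_CONFIG = dict(backbone="tiny-cnn", input_size_px=64, sample_size=6,
                    batch_size=4, max_epochs=12, patience=5)


@pytest.fixture(scope="module")
def small_bags():
    train = [make_bag(f"pos{i}", 1, seed0=10 * i) for i in range(6)] + [
        make_bag(f"neg{i}", 0, seed0=10 * i) for i in range(6)
    ]
    val = [make_bag("vpos", 1, seed0=100), make_bag("vneg", 0, seed0=200)]
    return train, val


@pytest.fixture(scope="module")
def trained_small(small_bags):
    train, val = small_bags
    return train_model(ModelConfig(**SMALL_CONFIG, seed=0), train, val)


class TestBuildBags:
    def test_counts_and_rejects(self):
        records = (
            [make_record("a", 1, s, x=64 * s) for s in range(5)]
            + [make_record("b", 0, s, x=64 * s) for s in range(8)]
            + [make_record("c", 1, s, x=64 * s, passed=False) for s in range(3)]
        )
        with pytest.warns(UserWarning, match="no QC-passing"):
            bags, rejects = build_bags(records, {"a": 1, "b": 0, "c": 1})
        assert sorted(b.instance_count for b in bags) == [5, 8]
        assert rejects == ["c"]

    def test_bag_label_inherits_slide_label(self):
        records = [make_record("a", 1, 0), make_record("b", 0, 1)]
        bags, _ = build_bags(records, {"a": 1, "b": 0})
        assert {b.slide_id: b.label for b in bags} == {"a": 1, "b": 0}

    def test_instance_ordering_deterministic(self):
        def build():
            recs = [make_record("a", 1, s, x=64 * (3 - s), mag=m)
                    for s in range(4) for m in ("10x", "40x")]
            bags, _ = build_bags(recs, {"a": 1})
            return [(r.magnification, r.y, r.x) for r in bags[0].instances]

        first, second = build(), build()
        assert first == second
        assert first == sorted(first, key=lambda k: (("40x", "20x", "10x", "5x").index(k[0]), k[1], k[2]))

    def test_mixed_slide_instances_rejected(self):
        with pytest.raises(ValueError, match="different slide"):
            Bag("a", 1, [make_record("b", 1, 0)])


class TestSplitSlides:
    def test_exact_division(self):
        split = split_slides([f"s{i}" for i in range(10)], seed=1)
        counts = {p: len(split.slides(p)) for p in ("train", "val", "test")}
        assert counts == {"train": 6, "val": 2, "test": 2}

    def test_cohort_scale_split(self):
        split = split_slides([f"s{i}" for i in range(160)], seed=1)
        counts = {p: len(split.slides(p)) for p in ("train", "val", "test")}
        assert counts == {"train": 96, "val": 32, "test": 32}

    def test_seed_reproducibility_and_sensitivity(self):
        ids = [f"s{i}" for i in range(10)]
        a = split_slides(ids, seed=3)
        b = split_slides(ids, seed=3)
        c = split_slides(ids, seed=4)
        assert a.assignment == b.assignment
        assert any(a.assignment[s] != c.assignment[s] for s in ids)

    def test_partitions_disjoint_and_exhaustive(self):
        ids = [f"s{i}" for i in range(37)]
        split = split_slides(ids, seed=0)
        parts = [set(split.slides(p)) for p in ("train", "val", "test")]
        assert set().union(*parts) == set(ids)
        assert sum(len(p) for p in parts) == len(ids)

    def test_stratification_keeps_both_classes_in_train(self):
        ids = [f"s{i}" for i in range(20)]
        labels = {s: (1 if i < 10 else 0) for i, s in enumerate(ids)}
        for seed in range(5):
            split = split_slides(ids, seed=seed, labels=labels)
            train_labels = {labels[s] for s in split.slides("train")}
            assert train_labels == {0, 1}

    def test_too_few_slides_rejected(self):
        with pytest.raises(ValueError):
            split_slides(["a", "b"], seed=0)


class TestSampleInstances:
    def test_subsample_is_distinct(self):
        bag = make_bag("a", 1, n=30)
        out = sample_instances(bag, 10, seed_or_rng=0)
        assert len(out) == 10
        assert len({(r.x, r.y) for r in out}) == 10

    def test_saturation_returns_all_without_duplication(self):
        bag = make_bag("a", 1, n=12)
        out = sample_instances(bag, 20, seed_or_rng=0)
        assert len(out) == 12

    def test_fixed_seed_reproducible(self):
        bag = make_bag("a", 1, n=30)
        a = [(r.x, r.y) for r in sample_instances(bag, 10, seed_or_rng=7)]
        b = [(r.x, r.y) for r in sample_instances(bag, 10, seed_or_rng=7)]
        assert a == b

    def test_empty_bag_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sample_instances(Bag("a", 1, []), 5, 0)

    def test_marginal_inclusion_uniform(self):
        """Chi-square over 2000 seeded draws of 3-of-10: inclusion counts
        are consistent with the uniform marginal (p > 0.001)."""
        bag = make_bag("a", 1, n=10)
        rng = np.random.default_rng(123)
        counts = np.zeros(10)
        for _ in range(2000):
            for rec in sample_instances(bag, 3, rng):
                counts[rec.x // 64] += 1
        _, p = chisquare(counts)
        assert p > 0.001


class TestForwardBag:
    def test_plain_identical_instances_equal_single_probability(self):
        cfg = ModelConfig(**SMALL_CONFIG, seed=1)
        net = MILNet("tiny-cnn", attention=False, seed=1)
        rec = make_record("a", 1, 0)
        p1, _ = forward_bag(net, [rec], config=cfg)
        p5, _ = forward_bag(net, [rec] * 5, config=cfg)
        assert p5 == pytest.approx(p1, abs=1e-6)

    def test_attention_weights_normalized(self):
        cfg = ModelConfig(**SMALL_CONFIG, attention=True, seed=1)
        net = MILNet("tiny-cnn", attention=True, attention_head_size=16, seed=1)
        recs = [make_record("a", 1, s, x=64 * s) for s in range(4)]
        _, alpha = forward_bag(net, recs, config=cfg)
        assert alpha.shape == (4,)
        assert alpha.sum() == pytest.approx(1.0, abs=1e-6)

    def test_single_instance_bag_reduces_to_instance_probability(self):
        rec = make_record("a", 1, 0)
        for attention in (False, True):
            cfg = ModelConfig(**SMALL_CONFIG, attention=attention, seed=2)
            net = MILNet("tiny-cnn", attention=attention, seed=2)
            p, alpha = forward_bag(net, [rec], config=cfg)
            assert 0.0 <= p <= 1.0
            if attention:
                assert alpha == pytest.approx([1.0])

    def test_empty_instances_rejected(self):
        net = MILNet("tiny-cnn", seed=0)
        with pytest.raises(ValueError):
            forward_bag(net, [], config=ModelConfig(**SMALL_CONFIG))


class TestTrainModel:
    def test_history_bounded_and_best_epoch_is_min(self, trained_small):
        tm = trained_small
        assert len(tm.history) <= tm.config.max_epochs
        losses = [h["val_loss"] for h in tm.history]
        assert tm.history[tm.best_epoch - 1]["val_loss"] == min(losses)

    def test_learns_above_majority_baseline(self, trained_small):
        # balanced validation set: majority baseline is 0.5
        best = trained_small.history[trained_small.best_epoch - 1]
        assert best["val_acc"] > 0.5

    def test_single_class_training_rejected(self, small_bags):
        train, val = small_bags
        pos_only = [b for b in train if b.label == 1]
        with pytest.raises(ValueError, match="both classes"):
            train_model(ModelConfig(**SMALL_CONFIG, seed=0), pos_only, val)

    def test_reproducible_given_seed(self, small_bags, trained_small):
        train, val = small_bags
        again = train_model(ModelConfig(**SMALL_CONFIG, seed=0), train, val)
        assert again.history == trained_small.history
        assert all(np.array_equal(again.parameters[k], trained_small.parameters[k])
                   for k in again.parameters)

    def test_checkpoint_roundtrip(self, trained_small, tmp_path):
        from blscreen.mil import TrainedModel

        path = tmp_path / "m.npz"
        trained_small.save(path)
        loaded = TrainedModel.load(path)
        assert loaded.config == trained_small.config
        assert loaded.best_epoch == trained_small.best_epoch
        rec = make_record("a", 1, 99)
        assert forward_bag(loaded, [rec])[0] == pytest.approx(
            forward_bag(trained_small, [rec])[0], abs=1e-7
        )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="patience"):
            ModelConfig(max_epochs=5, patience=5)
        with pytest.raises(ValueError, match="backbone"):
            ModelConfig(backbone="vgg-like")
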