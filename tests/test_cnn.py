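"""Architecture constants, training dynamics, freeze contract, inference."""

import numpy as np
import pytest

from imgsurv import (
    CNNSurvival,
    IntervalGrid,
    ModelSpec,
    SurvivalRecord,
    TrainConfig,
    build_model,
)
from imgsurv.cnn import (
    batch_loss,
    extract_features,
    finetune,
    predict_hazards,
    pretrain,
    samples_to_batch,
)
from imgsurv.imaging import ImageSample
from imgsurv.survival import discrete_survival_loss, encode_targets

SIDE = 32  # small input for fast tests; pool chain 32 -> 16 -> 5 -> 1


def toy_samples(rng, n, side=SIDE, prefix="s"):
    out = []
    for i in range(n):
        mk = np.zeros((side, side), np.uint8)
        mk[4:-4, 4:-4] = 1
        px = rng.integers(0, 256, (side, side)).astype(np.float32) * mk
        out.append(ImageSample(px, mk, f"{prefix}{i}", 0))
    return out


def toy_records(rng, n, prefix="s"):
    times = rng.exponential(300, n)
    events = rng.random(n) < 0.75
    return [
        SurvivalRecord(f"{prefix}{i}", float(max(t, 1.0)), int(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


@pytest.fixture
def spec():
    return ModelSpec(n_intervals=4, input_side=SIDE)


class TestArchitecture:
    def test_feature_layer_width_and_parameters(self):
        net = build_model(ModelSpec(n_intervals=12))
        assert net["feature_dense"].n_parameters == 627
        assert net["feature_dense"].out_features == 19

    def test_feature_vectors_have_width_19(self, spec, rng):
        net = build_model(spec, seed=0)
        samples = toy_samples(rng, 3)
        feats = extract_features(net, samples, spec)
        assert feats.shape == (3, 19 + 2)  # id + slice_index + 19 features

    def test_single_interval_head(self):
        net = build_model(ModelSpec(n_intervals=1))
        assert net["hazard_head"].n_parameters == 20

    def test_six_convolutions_and_pool_chain(self, spec):
        net = build_model(spec)
        conv_names = [n for n, _ in net.layers if n.startswith("conv")]
        assert conv_names == [f"conv{i}" for i in range(1, 7)]
        pools = [layer.pool for n, layer in net.layers if n.startswith("pool")]
        assert pools == [2, 3, 3]

    def test_input_too_small_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(n_intervals=3, input_side=10)


class TestTrainingDynamics:
    def test_loss_decreases_on_small_sample(self, rng):
        samples = toy_samples(rng, 50)
        records = toy_records(rng, 50)
        model = CNNSurvival(
            samples, records, n_intervals=3,
            spec=None, config=TrainConfig(learning_rate=1e-2, seed=3),
        )
        model.spec = ModelSpec(n_intervals=model.grid.n_intervals,
                               input_side=SIDE, dropout_rate=0.0)
        res = model.fit(epochs=5)
        assert len(res.loss_history) == 5
        assert res.loss_history[-1] <= res.loss_history[0]

    def test_zero_epochs_is_a_noop(self, spec, rng):
        net = build_model(spec, seed=1)
        before = net.param_hash()
        samples = toy_samples(rng, 8)
        targets = encode_targets(toy_records(rng, 8),
                                 IntervalGrid([0, 100, 200, 400, 800]))
        history = pretrain(net, samples, targets, TrainConfig(seed=0), spec,
                           epochs=0)
        assert history == []
        assert net.param_hash() == before

    def test_zero_learning_rate_freezes_dynamics(self, rng):
        # full-batch, no dropout: with lr 0 every epoch sees the same loss
        samples = toy_samples(rng, 10)
        records = toy_records(rng, 10)
        grid = IntervalGrid([0, 100, 300, 800])
        spec = ModelSpec(n_intervals=3, input_side=SIDE, dropout_rate=0.0)
        net = build_model(spec, seed=2)
        targets = encode_targets(records, grid)
        cfg = TrainConfig(learning_rate=0.0, batch_size=100, seed=0)
        history = pretrain(net, samples, targets, cfg, spec, epochs=4)
        assert np.ptp(history) == pytest.approx(0.0, abs=1e-9)

    def test_training_loop_loss_equals_survival_loss(self, spec, rng):
        net = build_model(spec, seed=4)
        samples = toy_samples(rng, 6)
        targets = encode_targets(toy_records(rng, 6),
                                 IntervalGrid([0, 100, 200, 400, 800]))
        x = samples_to_batch(samples, spec.input_side)
        from imgsurv.cnn import _sigmoid

        h = _sigmoid(net.forward(x, train=True))
        expected = discrete_survival_loss(h, targets)
        # same forward state: train-mode BN with identical batch, dropout off
        spec_nodrop = ModelSpec(n_intervals=4, input_side=SIDE, dropout_rate=0.0)
        net2 = build_model(spec_nodrop, seed=4)
        h2 = _sigmoid(net2.forward(x, train=True))
        assert batch_loss(net2, x, targets) == pytest.approx(
            discrete_survival_loss(h2, targets), abs=1e-5
        )
        assert expected > 0

    def test_non_finite_loss_aborts(self, spec, rng):
        net = build_model(spec, seed=0)
        net["hazard_head"].params["weight"][:] = np.nan
        samples = toy_samples(rng, 4)
        targets = encode_targets(toy_records(rng, 4),
                                 IntervalGrid([0, 100, 200, 400, 800]))
        with pytest.raises(RuntimeError, match="non-finite"):
            pretrain(net, samples, targets, TrainConfig(seed=0), spec, epochs=1)


class TestFreezeContract:
    BACKBONE = {f"conv{i}" for i in range(1, 7)} | {f"bn{i}" for i in range(1, 7)}

    def _pretrained(self, rng, spec):
        net = build_model(spec, seed=5)
        samples = toy_samples(rng, 12)
        records = toy_records(rng, 12)
        grid = IntervalGrid([0, 100, 300, 600, 1200])
        targets = encode_targets(records, grid)
        pretrain(net, samples, targets, TrainConfig(seed=1), spec, epochs=1)
        return net, grid

    def test_backbone_bit_identical_after_finetune(self, spec, rng):
        net, grid = self._pretrained(rng, spec)
        backbone_before = net.param_hash(self.BACKBONE)
        feature_before = net.param_hash({"feature_dense"})
        samples = toy_samples(rng, 10, prefix="t")
        targets = encode_targets(toy_records(rng, 10, prefix="t"), grid)
        finetune(net, samples, targets, TrainConfig(seed=2), spec, epochs=3)
        assert net.param_hash(self.BACKBONE) == backbone_before
        assert net.param_hash({"feature_dense"}) != feature_before

    def test_trainable_set_under_policies(self, spec, rng):
        net, grid = self._pretrained(rng, spec)
        samples = toy_samples(rng, 6, prefix="t")
        targets = encode_targets(toy_records(rng, 6, prefix="t"), grid)
        finetune(net, samples, targets, TrainConfig(seed=0), spec, epochs=0)
        head = net["hazard_head"].n_parameters
        assert net.n_parameters(trainable_only=True) == 627 + head

        finetune(net, samples, targets,
                 TrainConfig(seed=0, freeze_policy="features_only"), spec,
                 epochs=0)
        assert net.n_parameters(trainable_only=True) == 627

    def test_head_frozen_under_strict_policy(self, spec, rng):
        net, grid = self._pretrained(rng, spec)
        head_before = net.param_hash({"hazard_head"})
        samples = toy_samples(rng, 8, prefix="t")
        targets = encode_targets(toy_records(rng, 8, prefix="t"), grid)
        finetune(net, samples, targets,
                 TrainConfig(seed=3, freeze_policy="features_only"), spec,
                 epochs=2)
        assert net.param_hash({"hazard_head"}) == head_before


class TestInference:
    def test_hazards_in_unit_interval(self, spec, rng):
        net = build_model(spec, seed=6)
        h = predict_hazards(net, toy_samples(rng, 5), spec)
        assert h.shape == (5, 4)
        assert np.all((h > 0) & (h < 1))

    def test_duplicated_inputs_identical_outputs(self, spec, rng):
        net = build_model(spec, seed=7)
        s = toy_samples(rng, 1)[0]
        twin = ImageSample(s.pixels.copy(), s.mask.copy(), "s0", 1)
        h = predict_hazards(net, [s, twin], spec)
        np.testing.assert_array_equal(h[0], h[1])
        f = extract_features(net, [s, twin], spec)
        np.testing.assert_array_equal(f.iloc[0, 2:].values, f.iloc[1, 2:].values)

    def test_repeated_calls_deterministic(self, spec, rng):
        net = build_model(spec, seed=8)
        samples = toy_samples(rng, 3)
        np.testing.assert_array_equal(
            predict_hazards(net, samples, spec), predict_hazards(net, samples, spec)
        )

    def test_curves_from_hazards_are_monotone(self, spec, rng):
        from imgsurv import hazards_to_survival

        net = build_model(spec, seed=9)
        h = predict_hazards(net, toy_samples(rng, 4), spec)
        grid = IntervalGrid([0, 100, 200, 400, 800])
        for curve in hazards_to_survival(h, grid):
            assert np.all(np.diff(curve.probabilities) <= 0)

    def test_wrong_input_shape_rejected(self, spec, rng):
        net = build_model(spec, seed=10)
        bad = toy_samples(rng, 1, side=64)
        with pytest.raises(ValueError, match="standardize"):
            predict_hazards(net, bad, spec)


class TestResultsObject:
    def test_fit_save_load_predict_roundtrip(self, rng, tmp_path):
        samples = toy_samples(rng, 15)
        records = toy_records(rng, 15)
        model = CNNSurvival(samples, records, n_intervals=3,
                            config=TrainConfig(seed=11))
        res = model.fit(epochs=1)
        h_before = res.predict_hazards(samples[:3])
        res.save(tmp_path / "model")
        from imgsurv import CNNSurvivalResults

        loaded = CNNSurvivalResults.load(tmp_path / "model")
        np.testing.assert_allclose(loaded.predict_hazards(samples[:3]), h_before,
                                   atol=1e-7)
        assert loaded.stage == "pretrained"
        assert "feature" in loaded.summary()

    def test_finetune_does_not_mutate_parent(self, rng):
        samples = toy_samples(rng, 12)
        records = toy_records(rng, 12)
        model = CNNSurvival(samples, records, n_intervals=2,
                            config=TrainConfig(seed=12))
        res = model.fit(epochs=1)
        hash_before = res.net.param_hash()
        tuned = res.finetune(samples, records, epochs=1)
        assert res.net.param_hash() == hash_before
        assert tuned.stage == "finetuned"

    def test_reproducible_under_seed(self, rng):
        samples = toy_samples(rng, 10)
        records = toy_records(rng, 10)
        h = []
        for _ in range(2):
            model = CNNSurvival(samples, records, n_intervals=2,
                                config=TrainConfig(seed=13))
            res = model.fit(epochs=2)
            h.append(res.predict_hazards(samples[:2]))
        np.testing.assert_array_equal(h[0], h[1])
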