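"""Model construction, class weights, training protocol, embeddings."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oodhar as oh
from oodhar import models as M
from oodhar.synthgen import ConfigurationError


def _toy_data(rng, n=60, n_classes=5):
    labels = np.array([oh.CANONICAL_ACTIVITIES[i % n_classes] for i in range(n)],
                      dtype=object)
    return {"windows": rng.normal(size=(n, 4, 250)),
            "features": rng.normal(size=(n, 192)), "labels": labels}


class TestClassWeights:
    def test_inverse_frequency(self):
        labels = ["walk"] * 80 + ["run"] * 20
        classes, w = M.class_weights(labels, classes=("walk", "run"))
        assert classes == ("walk", "run")
        assert np.allclose(w, [0.625, 2.5])

    def test_paper_literal(self):
        labels = ["walk"] * 80 + ["run"] * 20
        _, w = M.class_weights(labels, classes=("walk", "run"),
                               mode="paper-literal")
        assert np.allclose(w, [0.8, 0.2])

    def test_balanced_counts_equal_weights(self):
        labels = ["walk"] * 30 + ["run"] * 30
        for mode in ("inverse-frequency", "paper-literal"):
            _, w = M.class_weights(labels, classes=("walk", "run"), mode=mode)
            assert w[0] == w[1]

    def test_absent_class_excluded(self):
        classes, w = M.class_weights(["walk"] * 10 + ["run"] * 10)
        assert classes == ("walk", "run") and len(w) == 2


class TestBuildModel:
    def test_logit_shapes(self, rng):
        for family in oh.FAMILIES:
            net = M.build_model(M.default_spec(family), seed=0)
            data = _toy_data(rng, n=4)
            logits, _ = net.forward(
                data["windows"] if net.backbone else None,
                data["features"] if (net.hybrid or not net.backbone) else None)
            assert logits.shape == (4, 5)

    def test_lr_parameter_count(self):
        net = M.build_model(M.default_spec("LR"), seed=0)
        assert sum(p.size for p in net.parameters) == 5 * 192 + 5

    def test_hybrid_fusion_input_width(self):
        net = M.build_model(M.default_spec("CNN-base-hybrid"), seed=0)
        fusion = net.trunk[0]
        assert fusion.W.shape[0] == net._flat_width + 192

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            M.ModelSpec("MLP", mlp_hidden=64)
        with pytest.raises(ConfigurationError):
            M.ModelSpec("ResNet-hybrid", fusion_width=128)
        with pytest.raises(ConfigurationError):
            M.ModelSpec("GRU")

    @pytest.mark.parametrize("family,width", [
        ("MLP", 128), ("CNN-base", 128), ("ResNet", 128),
        ("CNN-simple-hybrid", 128), ("CNN-base-hybrid", 128),
        ("ResNet-hybrid", 256), ("LR", 192),
    ])
    def test_embedding_widths(self, rng, family, width):
        data = _toy_data(rng, n=30)
        net = M.build_model(M.default_spec(family), seed=0)
        trained = M.train(net, data, M.TrainConfig(max_epochs=1, batch_size=16))
        emb = M.embed(trained, data)
        assert emb.values.shape == (30, width)
        assert emb.source == "embedding"

    def test_lr_embedding_is_its_input(self, rng):
        data = _toy_data(rng, n=20)
        net = M.build_model(M.default_spec("LR"), seed=0)
        trained = M.train(net, data, M.TrainConfig(max_epochs=1, batch_size=8))
        emb = M.embed(trained, data)
        assert np.array_equal(emb.values, data["features"])


class TestGradients:
    def test_conv_backward_matches_finite_differences(self, rng):
        x = rng.normal(size=(2, 3, 12))
        conv = M.Conv1d(3, 2, 5, rng)
        out = conv.forward(x)
        g = rng.normal(size=out.shape)
        conv.backward(g)
        eps = 1e-6
        for p, grad in zip(conv.params, conv.grads):
            idx = tuple(0 for _ in p.shape)
            p[idx] += eps
            up = (conv.forward(x) * g).sum()
            p[idx] -= 2 * eps
            down = (conv.forward(x) * g).sum()
            p[idx] += eps
            assert (up - down) / (2 * eps) == pytest.approx(grad[idx], rel=1e-4)

    def test_maxpool_backward_routes_to_argmax(self, rng):
        x = rng.normal(size=(1, 1, 6))
        pool = M.MaxPool1d(2, stride=2)
        out = pool.forward(x)
        gx = pool.backward(np.ones_like(out))
        assert gx.sum() == out.size
        assert np.all((gx == 0) | (gx == 1))


class TestEarlyStopping:
    def test_cap_at_140(self):
        losses = list(np.linspace(1.0, 0.1, 200))
        stop, ckpt = M.early_stopping_trace(losses)
        assert (stop, ckpt) == (140, 140)

    def test_patience_arithmetic(self):
        losses = [1.0, 0.9, 0.8, 0.7, 0.5] + [0.6] * 100
        stop, ckpt = M.early_stopping_trace(losses)
        assert (stop, ckpt) == (35, 5)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=200))
    def test_stop_bound_property(self, losses):
        stop, ckpt = M.early_stopping_trace(losses)
        assert stop <= min(140, ckpt + 30)
        assert 1 <= ckpt <= stop

    def test_trained_model_respects_bound(self, rng):
        data = _toy_data(rng, n=40)
        net = M.build_model(M.default_spec("MLP"), seed=1)
        cfg = M.TrainConfig(max_epochs=25, patience=5, batch_size=16, seed=2)
        tr = M.train(net, data, cfg)
        assert tr.stop_epoch <= min(cfg.max_epochs, tr.checkpoint_epoch + cfg.patience)
        assert tr.checkpoint_epoch == 1 + int(np.argmin(tr.history["val_loss"]))


class TestTrain:
    def test_deterministic_history(self, rng):
        data = _toy_data(rng, n=50)
        cfg = M.TrainConfig(max_epochs=5, batch_size=16, seed=9)
        h1 = M.train(M.build_model(M.default_spec("MLP"), seed=3), data, cfg).history
        h2 = M.train(M.build_model(M.default_spec("MLP"), seed=3), data, cfg).history
        assert h1 == h2

    def test_lr_solves_separable_two_class_problem(self, rng):
        n = 100
        feats = 0.1 * rng.normal(size=(n, 192))  # low-variance nuisance dims
        labels = np.where(rng.normal(size=n) > 0, "walk", "run").astype(object)
        feats[:, 0] = np.where(labels == "walk", 2.0, -2.0) + 0.2 * rng.normal(size=n)
        data = {"features": feats, "labels": labels}
        net = M.build_model(M.default_spec("LR"), n_classes=2, seed=0)
        tr = M.train(net, data, M.TrainConfig(batch_size=32, seed=0))
        pred = M.predict(tr, data)
        assert np.mean(pred == labels) == 1.0
        assert tr.stop_epoch <= 140

    def test_empty_validation_split_rejected(self, rng):
        data = _toy_data(rng, n=5)
        net = M.build_model(M.default_spec("MLP"), seed=0)
        with pytest.raises(ValueError):
            M.train(net, data, M.TrainConfig(validation_fraction=0.0))

    def test_checkpoint_restored(self, rng):
        data = _toy_data(rng, n=40)
        net = M.build_model(M.default_spec("MLP"), seed=1)
        tr = M.train(net, data, M.TrainConfig(max_epochs=10, batch_size=16, seed=4))
        # forward loss with restored parameters equals the checkpointed minimum
        assert min(tr.history["val_loss"]) == tr.history["val_loss"][tr.checkpoint_epoch - 1]


class TestPredict:
    def test_tie_breaks_to_lowest_class_index(self, rng):
        data = _toy_data(rng, n=10)
        net = M.build_model(M.default_spec("LR"), seed=0)
        trained = M.train(net, data, M.TrainConfig(max_epochs=1, batch_size=8))
        net.classifier.W[...] = 0.0
        net.classifier.b[...] = 0.0
        pred = M.predict(trained, data)
        assert set(pred) == {trained.classes[0]}

    def test_batch_length(self, rng):
        data = _toy_data(rng, n=17)
        net = M.build_model(M.default_spec("MLP"), seed=0)
        trained = M.train(net, data, M.TrainConfig(max_epochs=1, batch_size=8))
        assert len(M.predict(trained, data)) == 17

    def test_embed_untrained_rejected(self, rng):
        net = M.build_model(M.default_spec("MLP"), seed=0)
        tm = M.TrainedModel(net, net.spec, M.TrainConfig(), oh.CANONICAL_ACTIVITIES)
        with pytest.raises(ValueError):
            M.embed(tm, _toy_data(rng, n=2))


class TestGrid:
    def test_nine_distinct_runs(self):
        cfgs = M.grid_configs(base_seed=100)
        assert len(cfgs) == 9
        assert len({(c.learning_rate, c.batch_size) for c in cfgs}) == 9
        assert len({c.seed for c in cfgs}) == 9
        assert {c.learning_rate for c in cfgs} == set(M.GRID_LEARNING_RATES)
        assert {c.batch_size for c in cfgs} == set(M.GRID_BATCH_SIZES)

    def test_window_norm_round_trip(self, rng):
        w = rng.normal(loc=3.0, scale=2.0, size=(10, 4, 250))
        norm = M.fit_window_norm(w)
        z = M.apply_window_norm(norm, w)
        assert abs(z.mean()) < 1e-9 and abs(z.std() - 1) < 1e-9

    def test_run_manifest_written(self, rng, tmp_path):
        data = _toy_data(rng, n=30)
        net = M.build_model(M.default_spec("LR"), seed=0)
        tr = M.train(net, data, M.TrainConfig(max_epochs=2, batch_size=16))
        M.write_run_manifest(tr, tmp_path / "run.json", extra={"task": "ID/A"})
        import json
        m = json.loads((tmp_path / "run.json").read_text())
        assert m["family"] == "LR" and m["stop_epoch"] == 2 and m["task"] == "ID/A"
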