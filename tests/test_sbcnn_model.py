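"""Architecture specs, training behaviour, export and Algorithm-1 inference."""

import numpy as np
import pytest

from sbcnn.sbcnn_model import (
    SBCNN,
    ClassificationDataset,
    ExportedLayer,
    ExportedSBCNN,
    PresentationConfig,
    aggregate_presentations,
    build_alexnet,
    build_mini_sbcnn,
    sbcnn_infer,
    train,
)
from sbcnn.cost_model import count_params
from sbcnn.stochastic_input import ChannelStats, compute_channel_stats
from sbcnn.synthetic_data import make_classification_dataset


class TestBuildAlexnet:
    def test_full_two_class_parameter_count(self):
        assert sum(count_params(build_alexnet(2))) == 57_012_034

    def test_reduced_removes_hidden_fc(self):
        assert sum(count_params(build_alexnet(2, reduced=True))) == 57_012_034 - 16_781_312

    def test_output_layer_contribution(self):
        spec10 = build_alexnet(10)
        spec2 = build_alexnet(2)
        diff = sum(count_params(spec10)) - sum(count_params(spec2))
        assert diff == (4096 * 10 + 10) - (4096 * 2 + 2)

    def test_shapes_chain(self):
        shapes = build_alexnet(10).output_shapes()
        assert shapes[-1] == (10,)

    def test_rejects_single_class(self):
        with pytest.raises(ValueError):
            build_alexnet(1)


class TestPresentationConfig:
    def test_matched_requires_equal_counts(self):
        with pytest.raises(ValueError):
            PresentationConfig(n_train=8, n_infer=16, strategy="matched")

    def test_max_defaults_to_256(self):
        assert PresentationConfig.max_presentations(n_infer=8).n_train == 256

    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError):
            PresentationConfig(n_train=0, n_infer=1, strategy="matched")


class TestAggregatePresentations:
    def test_majority(self):
        assert aggregate_presentations([np.array([1]), np.array([1]), np.array([-1])])[0] == 1

    def test_tie_resolves_positive(self):
        assert aggregate_presentations([np.array([1]), np.array([-1])])[0] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_presentations([])

    def test_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k, m = int(rng.integers(1, 9)), int(rng.integers(1, 20))
            vecs = [rng.choice([-1, 1], m) for _ in range(k)]
            out = aggregate_presentations(vecs)
            for j in range(m):
                pos = sum(1 for v in vecs if v[j] == 1)
                assert out[j] == (1 if pos >= k - pos else -1)


def _tiny_dataset(seed=0, n_classes=2):
    rng = np.random.default_rng(seed)
    return make_classification_dataset(
        n_classes=n_classes, n_train_per_class=20, n_test_per_class=10,
        image_size=8, separation=6.0, noise_std=1.0, rng=rng,
    )


def _tiny_model(ds, seed=0):
    stats = compute_channel_stats(ds.train_images)
    spec = build_mini_sbcnn(ds.num_classes, input_size=8, width=8)
    return SBCNN(spec, stats, seed=seed)


class TestTraining:
    def test_zero_learning_rate_keeps_weights(self):
        ds = _tiny_dataset()
        model = _tiny_model(ds)
        before = [p.data.copy() for p in model.params()]
        train(model, ds, PresentationConfig.matched(2), {"lr": 0.0, "epochs": 1, "seed": 0})
        for p, w in zip(model.params(), before):
            assert np.array_equal(p.data, w)

    def test_seed_fixed_runs_are_identical(self):
        ds = _tiny_dataset()
        h1 = train(_tiny_model(ds, 1), ds, PresentationConfig.matched(2),
                   {"epochs": 2, "seed": 5})
        h2 = train(_tiny_model(ds, 1), ds, PresentationConfig.matched(2),
                   {"epochs": 2, "seed": 5})
        assert h1["loss"] == h2["loss"]

    def test_separable_problem_reaches_95pct(self):
        """Well-separated 2-class set trains to >= 95% within 20 epochs."""
        ds = _tiny_dataset(seed=3)
        model = _tiny_model(ds, seed=3)
        h = train(model, ds, PresentationConfig.matched(8),
                  {"epochs": 20, "lr": 5e-3, "seed": 3})
        assert max(h["train_accuracy"]) >= 0.95


class TestExportedInference:
    def setup_method(self):
        self.ds = _tiny_dataset(seed=4)
        self.model = _tiny_model(self.ds, seed=4)
        train(self.model, self.ds, PresentationConfig.matched(4),
              {"epochs": 3, "lr": 5e-3, "seed": 4})
        self.exported = self.model.export()

    def test_unfolded_model_rejected(self):
        with pytest.raises(ValueError, match="export"):
            sbcnn_infer(self.model, self.ds.test_images[0], PresentationConfig.matched(4),
                        np.random.default_rng(0))

    def test_invalid_presentation_count(self):
        with pytest.raises(ValueError):
            self.exported.infer(self.ds.test_images[:1], 0, np.random.default_rng(0))

    def test_seed_fixed_inference_reproducible(self):
        s1 = self.exported.infer(self.ds.test_images[:5], 8, np.random.default_rng(1))
        s2 = self.exported.infer(self.ds.test_images[:5], 8, np.random.default_rng(1))
        assert np.array_equal(s1, s2)

    def test_single_presentation_is_one_stochastic_pass(self):
        s = self.exported.infer(self.ds.test_images[:3], 1, np.random.default_rng(2))
        assert s.shape == (3, 2) and s.dtype == np.int64

    def test_saturated_input_equals_deterministic_bnn(self):
        """All-ones presentations reduce to the deterministic BNN for any N."""
        img = self.ds.test_images[:2]
        outs = []
        for n in (1, 4, 16):
            ones = np.ones((2 * n, 3, 8, 8))
            outs.append(self.exported.infer(img, n, None, presentations=ones))
        assert np.array_equal(outs[0], outs[1]) and np.array_equal(outs[1], outs[2])

    def test_integer_and_float_paths_agree(self):
        pm1 = self.exported.sample_inputs(self.ds.test_images, 4, np.random.default_rng(3))
        si = self.exported.infer(self.ds.test_images, 4, None, presentations=pm1)
        sf = self.exported.infer(self.ds.test_images, 4, None, presentations=pm1,
                                 float_reference=True)
        assert np.array_equal(si.astype(float), sf)

    def test_score_variance_nonincreasing_in_presentations(self):
        """Concentration: repeated-inference score variance shrinks with N."""
        img = self.ds.test_images[:1]
        variances = []
        for n in (1, 8, 64):
            scores = [
                self.exported.infer(img, n, np.random.default_rng(100 + r))[0]
                for r in range(100)
            ]
            variances.append(np.mean(np.var(scores, axis=0)))
        # 10% slack absorbs the variance-estimator noise at 100 repeats
        assert variances[1] <= 1.1 * variances[0]
        assert variances[2] <= 1.1 * variances[1]

    def test_save_load_roundtrip(self, tmp_path):
        path = tmp_path / "model.npz"
        self.exported.save(path)
        loaded = ExportedSBCNN.load(path)
        pm1 = self.exported.sample_inputs(self.ds.test_images[:6], 4, np.random.default_rng(5))
        a = self.exported.infer(self.ds.test_images[:6], 4, None, presentations=pm1)
        b = loaded.infer(self.ds.test_images[:6], 4, None, presentations=pm1)
        assert np.array_equal(a, b)


def _random_exported_fc_net(rng, sizes=(64, 32, 10)):
    """Random exported fc network with random batch-norm folds."""
    layers = []
    for i, (fin, fout) in enumerate(zip(sizes[:-1], sizes[1:])):
        W = rng.choice([-1.0, 1.0], (fout, fin))
        meta = {"kind": "fc", "in_f": fin, "out_f": fout}
        if i < len(sizes) - 2:
            layers.append(ExportedLayer.folded(
                meta, W, fin,
                gamma=rng.normal(0, 1, fout) + np.where(rng.uniform(size=fout) > 0.5, 2.0, -2.0),
                beta=rng.normal(0, 1, fout),
                mean=rng.normal(0, 3, fout),
                var=rng.uniform(0.05, 4.0, fout),
            ))
        else:
            layers.append(ExportedLayer(meta=meta, W=W, fan_in=fin))
    stats = ChannelStats(mu=np.zeros(3), sigma=np.ones(3))
    return ExportedSBCNN(stem=layers[:1], trunk=layers[1:], stats=stats,
                         dist="normal", spec_json="{}", num_classes=sizes[-1])


class TestFoldedPathEquivalence:
    def test_random_networks_rank_identically(self):
        """Folded integer path == float bn reference on random fc networks."""
        rng = np.random.default_rng(42)
        for trial in range(10):
            net = _random_exported_fc_net(rng)
            x = rng.choice([-1.0, 1.0], (2 * 100, 64))  # 100 inputs, N=2
            si = net.infer(None, 2, None, presentations=x)
            sf = net.infer(None, 2, None, presentations=x, float_reference=True)
            assert np.array_equal(si.astype(float), sf)
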