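"""Network assembly: CNN taps, band branches, fusion head, estimator API."""

import numpy as np
import pytest

from bfenet.data_model import FeatureSample
from bfenet.model import (
    BFENet,
    BFENetClassifier,
    ModelConfig,
    TINY_CONFIG,
    band_branch_forward,
    conv_stack_forward,
    full_forward,
    macro_ovr_auc,
)


@pytest.fixture
def tiny_config():
    return ModelConfig(n_channels=8, n_classes=3, **TINY_CONFIG)


@pytest.fixture
def net(tiny_config):
    return BFENet(tiny_config, T=32, rng=np.random.default_rng(7))


@pytest.fixture
def batch(rng):
    return rng.normal(size=(4, 8, 32, 5))


class TestConfig:
    def test_default_conv_time_lengths_for_seed_shape(self):
        cfg = ModelConfig(n_channels=62, n_classes=3)
        assert cfg.layer_time_lengths(265) == [130, 63, 29]

    def test_time_exhaustion_names_failing_layer(self):
        cfg = ModelConfig(n_channels=8, n_classes=3)
        with pytest.raises(ValueError, match="layer 3"):
            cfg.layer_time_lengths(32)  # kernel 5 / pool 2 exhausts depth 3

    def test_filters_length_must_match_depth(self):
        with pytest.raises(ValueError, match="conv_filters"):
            ModelConfig(n_channels=8, n_classes=3, n_layers=2)

    def test_head_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(n_channels=8, n_classes=3, d_model=30, heads=8)


class TestConvStack:
    def test_default_filter_counts(self):
        cfg = ModelConfig(n_channels=8, n_classes=3)
        assert cfg.conv_filters == (64, 128, 256)

    def test_tap_shapes_follow_arithmetic(self, net, rng):
        taps = conv_stack_forward(rng.normal(size=(8, 32)), net)
        lengths = net.config.layer_time_lengths(32)
        for tap, f, tl in zip(taps, net.config.conv_filters, lengths):
            assert tap.shape == (8, f, tl)

    def test_channel_independence(self, net, rng):
        """Zeroing EEG channel j changes only channel j's tapped features."""
        x = rng.normal(size=(8, 32))
        x2 = x.copy()
        x2[3] = 0.0
        for tap_a, tap_b in zip(conv_stack_forward(x, net), conv_stack_forward(x2, net)):
            diff = np.abs(tap_a - tap_b).sum(axis=(1, 2))
            assert diff[3] > 0
            np.testing.assert_array_equal(np.delete(diff, 3), 0.0)


class TestBandBranch:
    def test_band_vector_length(self, net, rng):
        out = band_branch_forward(rng.normal(size=(8, 32)), net)
        cfg = net.config
        assert out.band_vector.shape == (cfg.n_layers * 8 * cfg.gcn_out,)

    def test_eval_determinism(self, net, rng):
        x = rng.normal(size=(8, 32))
        a = band_branch_forward(x, net)
        b = band_branch_forward(x, net)
        np.testing.assert_array_equal(a.band_vector, b.band_vector)

    def test_adjacency_rows_have_k_nonzeros(self, net, rng):
        out = band_branch_forward(rng.normal(size=(8, 32)), net)
        for sp in out.per_layer_adjacency:
            assert sp.k == net.config.k
            assert np.all((sp.matrix != 0).sum(axis=1) == min(net.config.k, 8))


class TestFullForward:
    def test_softmax_output_contract(self, net, batch):
        probs = net.predict_proba(batch)
        assert probs.shape == (4, 3)
        assert np.all(probs > 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_band_count_mismatch_rejected(self, net, rng):
        x = rng.normal(size=(2, 8, 32, 4))
        with pytest.raises(ValueError, match="expected"):
            net.forward(x)

    def test_single_sample_wrapper(self, net, rng):
        feats = rng.normal(size=(8, 32, 5))
        s = FeatureSample(subject_id="s01", session_id="1", trial_id="t1",
                         label=0, features=feats, native_length=32)
        p = full_forward(s, net)
        np.testing.assert_allclose(p, net.predict_proba(feats[None])[0], atol=1e-12)

    def test_band_permutation_consistency(self, tiny_config, batch):
        """Permuting band order together with branch parameters and FC blocks
        leaves the output unchanged."""
        net = BFENet(tiny_config, T=32, rng=np.random.default_rng(3))
        perm = [4, 2, 0, 1, 3]
        net2 = BFENet(tiny_config, T=32, rng=np.random.default_rng(3))
        for new_b, old_b in enumerate(perm):
            for name in list(net.params):
                if name.startswith(f"band{old_b}_"):
                    suffix = name.split("_", 1)[1]
                    net2.params[f"band{new_b}_{suffix}"].data = net.params[name].data.copy()
            net2.encoders = {  # rebind encoder views onto the copied tensors
                key: net2.encoders[key] for key in net2.encoders
            }
        # rebuild encoder parameter objects from the flat dict
        for (b, l), enc in net2.encoders.items():
            for tname in enc.tensors():
                setattr(enc, tname, net2.params[f"band{b}_enc{l}_{tname}"])
        # permute FC input blocks to match
        block = net.params["fc_W"].data.shape[0] // 5
        fc = net.params["fc_W"].data.reshape(5, block, -1)
        net2.params["fc_W"].data = fc[perm].reshape(-1, fc.shape[-1]).copy()
        net2.params["fc_b"].data = net.params["fc_b"].data.copy()
        a = net.predict_proba(batch)
        b = net2.predict_proba(batch[:, :, :, perm])
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_channel_permutation_equivariance_of_adjacency(self, net, batch, rng):
        """Shared conv weights + no positional encoding: permuting channels
        permutes every exported adjacency consistently."""
        perm = rng.permutation(8)
        _, aux = net.forward(batch)
        _, aux_p = net.forward(batch[:, perm])
        for key in aux["adjacency"]:
            a = aux["adjacency"][key][:, np.ix_(perm, perm)[0], np.ix_(perm, perm)[1]]
            np.testing.assert_allclose(aux_p["adjacency"][key], a, atol=1e-8)


class TestGradients:
    def test_backprop_matches_finite_differences_everywhere(self, rng):
        """Loss gradient at random coordinates of every parameter family."""
        cfg = ModelConfig(n_channels=4, n_classes=2, n_layers=2, conv_filters=(2, 3),
                          kernel_time=3, d_model=8, heads=2, k=2, gcn_out=2)
        net = BFENet(cfg, T=12, rng=np.random.default_rng(0))
        X = rng.normal(size=(3, 4, 12, 5))
        y = np.array([0, 1, 0])

        loss = net.loss(X, y, training=False)
        for p in net.params.values():
            p.zero_grad()
        loss = net.loss(X, y, training=False)
        loss.backward()
        families = ["band0_conv0_W", "band1_proj1_W", "band2_tokln0_gamma",
                    "band3_enc1_WQ", "band4_gcn0_Theta", "fc_W"]
        for name in families:
            p = net.params[name]
            for flat_idx in rng.choice(p.data.size, size=min(3, p.data.size),
                                       replace=False):
                idx = np.unravel_index(flat_idx, p.data.shape)
                eps = 1e-6
                orig = p.data[idx]
                p.data[idx] = orig + eps
                fp = net.loss(X, y, training=False).data.item()
                p.data[idx] = orig - eps
                fm = net.loss(X, y, training=False).data.item()
                p.data[idx] = orig
                num = (fp - fm) / (2 * eps)
                assert p.grad[idx] == pytest.approx(num, rel=1e-3, abs=1e-9), name

    def test_parameter_count_reported_and_scales(self):
        small = BFENet(ModelConfig(n_channels=4, n_classes=3, **TINY_CONFIG), T=32,
                       rng=np.random.default_rng(0))
        big = BFENet(ModelConfig(n_channels=62, n_classes=3, **TINY_CONFIG), T=32,
                     rng=np.random.default_rng(0))
        assert 0 < small.n_parameters < big.n_parameters


class TestClassifierEstimator:
    def test_sklearn_param_interface(self):
        clf = BFENetClassifier(k=5)
        assert clf.get_params()["k"] == 5
        clf.set_params(k=7)
        assert clf.k == 7
        from sklearn.base import clone

        assert clone(clf).k == 7

    def test_fit_predict_shapes_and_determinism(self, rng):
        X = rng.normal(size=(12, 6, 24, 5))
        y = np.array([0, 1, 2] * 4)
        kwargs = dict(TINY_CONFIG, kernel_time=3, max_epochs=2, random_state=5)
        a = BFENetClassifier(**kwargs).fit(X, y)
        b = BFENetClassifier(**kwargs).fit(X, y)
        assert a.predict(X).shape == (12,)
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))
        assert set(a.predict(X)) <= {0, 1, 2}
        assert a.stop_epoch_ <= 2 and len(a.loss_history_) == len(a.auc_history_)

    def test_invalid_auc_stop_rejected(self, rng):
        X = rng.normal(size=(6, 6, 24, 5))
        y = np.array([0, 1] * 3)
        with pytest.raises(ValueError, match="auc_stop"):
            BFENetClassifier(auc_stop=1.01).fit(X, y)

    def test_noop_on_nonfinite_input(self, rng):
        X = rng.normal(size=(6, 6, 24, 5))
        X[0, 0, 0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            BFENetClassifier().fit(X, np.zeros(6))


class TestAUCMonitor:
    def test_perfect_scores_give_unit_auc(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        scores = np.eye(3)[y]
        assert macro_ovr_auc(y, scores) == 1.0

    def test_null_scores_near_half(self, rng):
        y = rng.integers(0, 3, size=2000)
        scores = rng.random((2000, 3))
        assert 0.47 < macro_ovr_auc(y, scores) < 0.53

    def test_minimal_two_sample_case(self):
        assert macro_ovr_auc(np.array([0, 1]), np.array([[0.9, 0.1], [0.2, 0.8]])) == 1.0

    def test_absent_class_skipped_with_warning(self):
        y = np.array([0, 1, 0, 1])
        scores = np.tile([0.2, 0.5, 0.3], (4, 1))
        with pytest.warns(UserWarning, match="absent"):
            macro_ovr_auc(y, scores)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            macro_ovr_auc(np.zeros(4, dtype=int), np.random.rand(4, 2))
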