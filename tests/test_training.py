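"""LOSO harness, early stopping, ablation adjacency providers."""

import numpy as np
import pytest

from bfenet.connectivity import make_synthetic_montage
from bfenet.data_model import normalize_per_subject
from bfenet.model import TINY_CONFIG, BFENetClassifier
from bfenet.synthetic import PlantedModel, generate_corpus
from bfenet.training import (
    AdjacencyProvider,
    EvalReport,
    TrainConfig,
    ablation_adjacency,
    distance_adjacency,
    plv_matrix,
    run_loso,
    train_fold,
)
from conftest import build_registry


SMALL_KWARGS = dict(TINY_CONFIG)


@pytest.fixture(scope="module")
def small_registry():
    return normalize_per_subject(build_registry(n_subjects=3, n_sessions=1, trials=6))


class TestTrainConfig:
    def test_invalid_auc_stop(self):
        with pytest.raises(ValueError, match="auc_stop"):
            TrainConfig(auc_stop=1.01)

    def test_invalid_mode(self):
        with pytest.raises(ValueError, match="adjacency_mode"):
            TrainConfig(adjacency_mode="spatial")


class TestTrainFold:
    def test_loss_decreases_on_separable_corpus(self, small_registry):
        from bfenet.data_model import loso_splits

        fold = loso_splits(small_registry)[0]
        clf, stop = train_fold(
            fold, small_registry, SMALL_KWARGS, TrainConfig(seed=1, max_epochs=5)
        )
        assert clf.loss_history_[-1] < clf.loss_history_[0]
        assert 1 <= stop <= 5

    def test_early_stop_on_linearly_separable_toy(self, rng):
        """A label-revealing mean offset makes the toy trivially separable:
        training macro-AUC reaches 0.99 and halts well before 100 epochs."""
        model = PlantedModel(n_channels=6, n_classes=2, coupling_strength=0.0,
                             subject_offset_scale=0.0, seed=0)
        reg = generate_corpus(model, 2, 1, 8, T=24)
        X = reg.features()
        y = reg.labels()
        X = X + 2.0 * y[:, None, None, None]  # plant an unmissable signal
        clf = BFENetClassifier(**dict(TINY_CONFIG, kernel_time=3), max_epochs=100,
                               random_state=0)
        clf.fit(X, y)
        assert clf.stop_epoch_ < 100
        assert clf.auc_history_[-1] >= 0.99

    def test_oracle_feature_gives_perfect_loso(self):
        """Upper-bound sanity: with the label written into the features, every
        fold reaches accuracy 1 and std 0."""
        reg = build_registry(n_subjects=3, n_sessions=1, trials=6)
        patt_rng = np.random.default_rng(99)
        patterns = patt_rng.normal(size=(3, 8, 32, 5))  # fixed pattern per class
        for i, s in enumerate(reg.samples):
            reg.samples[i] = type(s)(
                subject_id=s.subject_id, session_id=s.session_id, trial_id=s.trial_id,
                label=s.label, features=5.0 * patterns[s.label],
                native_length=s.native_length,
            )
        report = run_loso(reg, SMALL_KWARGS, TrainConfig(seed=0, max_epochs=30))
        assert report.mean_accuracy == 1.0
        assert report.std_accuracy == 0.0


class TestRunLoso:
    def test_fold_count_and_report_consistency(self, small_registry):
        report = run_loso(small_registry, SMALL_KWARGS,
                          TrainConfig(seed=2, max_epochs=2))
        assert len(report.per_subject_accuracy) == 3
        accs = np.array(list(report.per_subject_accuracy.values()))
        assert report.mean_accuracy == pytest.approx(accs.mean())
        assert report.std_accuracy == pytest.approx(accs.std())
        # pooled confusion rows sum to the per-class test counts
        conf = np.array(report.confusion)
        labels = small_registry.labels()
        for c in range(3):
            assert conf[c].sum() == (labels == c).sum()

    def test_reproducibility_byte_identical(self, small_registry):
        tc = TrainConfig(seed=3, max_epochs=2)
        a = run_loso(small_registry, SMALL_KWARGS, tc)
        b = run_loso(small_registry, SMALL_KWARGS, tc)
        assert a.to_json() == b.to_json()
        assert EvalReport.from_json(a.to_json()).mean_accuracy == a.mean_accuracy


class TestDistanceAdjacency:
    def test_inverse_distance_ratio(self):
        import pandas as pd

        montage = pd.DataFrame({
            "name": ["a", "b", "c"],
            "x": [0.0, 1.0, 2.0], "y": [0.0, 0.0, 0.0], "z": [0.0, 0.0, 0.0],
        })
        # electrodes at distance 1 and 2 from "a": weights 1 and 0.5 -> ratio 2:1
        pos = montage[["x", "y", "z"]].to_numpy()
        d = np.linalg.norm(pos[0] - pos[1]), np.linalg.norm(pos[0] - pos[2])
        assert d[1] / d[0] == 2.0
        A = distance_adjacency(montage, k=2)
        assert A[0, 1] / A[0, 2] == pytest.approx(2.0)

    def test_missing_montage_rejected(self):
        with pytest.raises(ValueError, match="montage"):
            ablation_adjacency("distance", montage=None)

    def test_topk_applied(self):
        montage = make_synthetic_montage(8)
        A = distance_adjacency(montage, k=3)
        assert np.all((A != 0).sum(axis=1) == 3)


class TestPLV:
    def test_identical_sinusoids_lock_to_one(self):
        fs = 200.0
        t = np.arange(0, 5, 1 / fs)
        x = np.sin(2 * np.pi * 10 * t)
        plv = plv_matrix(np.stack([x, x]), fs, band="alpha")
        assert plv[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_constant_phase_offset_locks_to_one(self):
        fs = 200.0
        t = np.arange(0, 5, 1 / fs)
        a = np.sin(2 * np.pi * 10 * t)
        b = np.sin(2 * np.pi * 10 * t + 1.1)
        plv = plv_matrix(np.stack([a, b]), fs, band="alpha")
        assert plv[0, 1] == pytest.approx(1.0, abs=5e-3)

    def test_independent_noise_has_low_plv(self, rng):
        x = rng.standard_normal((2, 10_000))
        plv = plv_matrix(x, fs=200.0, band="alpha")
        assert plv[0, 1] < 0.1

    def test_missing_signals_rejected(self):
        with pytest.raises(ValueError, match="signals"):
            ablation_adjacency("plv", signals=None, fs=200.0)


class TestNoSelfMatrix:
    def test_exported_adjacency_is_softmax_of_attention(self, rng):
        """In no_self_matrix mode the graph is row-softmax(A) with the Gram
        term removed — verified against a manual recomputation."""
        from bfenet._autograd import Tensor
        from bfenet.encoder import encoder_forward, layer_norm, topk_mask
        from bfenet.model import BFENet, ModelConfig

        cfg = ModelConfig(n_channels=6, n_classes=3, adjacency_mode="no_self_matrix",
                          **{**TINY_CONFIG, "k": 6})
        net = BFENet(cfg, T=32, rng=np.random.default_rng(0))
        X = rng.normal(size=(2, 6, 32, 5))
        _, aux = net.forward(X)
        b, l = 2, 1
        h = Tensor(X[:, :, :, b].reshape(12, 1, 32))
        for ll in range(l + 1):
            h = h.conv1d(net.params[f"band{b}_conv{ll}_W"],
                         net.params[f"band{b}_conv{ll}_b"]).maxpool1d(2)
        tap = h.reshape(2, 6, -1)
        tok = tap @ net.params[f"band{b}_proj{l}_W"] + net.params[f"band{b}_proj{l}_b"]
        tok = layer_norm(tok, net.params[f"band{b}_tokln{l}_gamma"],
                         net.params[f"band{b}_tokln{l}_beta"])
        state = encoder_forward(tok, net.encoders[(b, l)])
        expected = state.A.softmax(axis=-1).data
        np.testing.assert_array_equal(aux["adjacency"][(b, l)], expected)


class TestAdaptiveVsFixedModes:
    def test_fixed_mode_reuses_one_graph(self, small_registry):
        montage = make_synthetic_montage(8)
        tc = TrainConfig(seed=0, max_epochs=1, adjacency_mode="distance")
        report = run_loso(small_registry, SMALL_KWARGS, tc, montage=montage)
        assert report.adjacency_mode == "distance"
        assert len(report.per_subject_accuracy) == 3

    def test_provider_modes(self):
        assert ablation_adjacency("no_self_matrix").matrix is None
        assert ablation_adjacency("adaptive").mode == "adaptive"
        with pytest.raises(ValueError, match="unknown"):
            ablation_adjacency("plv2")
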