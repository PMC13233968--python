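"""Network construction, folds, lead selection and desk-scale training."""

import numpy as np
import pytest

from pedqtc import qtnet as qn
from pedqtc.synthcohort import LEADS


def tiny_config(**kw):
    base = dict(n_blocks=2, kernel_size=5, base_channels=4, stem_stride=5,
                dropout_rate=0.1, input_leads=("II",), input_length=250,
                epochs=3, batch_size=16, learning_rate=3e-3)
    base.update(kw)
    return qn.NetConfig(**base)


class TestBuildRegressor:
    def test_full_architecture_shapes(self):
        cfg = qn.NetConfig()  # 16 blocks, 11 leads, 5000 samples
        net = qn.build_regressor(cfg)
        x = np.zeros((2, 11, 5000), dtype=np.float32)
        out = net.forward(x)
        assert out.shape == (2,)

    @pytest.mark.parametrize("cfg", [
        qn.NetConfig(),
        qn.desk_config(("II",)),
        qn.NetConfig(n_blocks=5, base_channels=8, kernel_size=7,
                     stem_stride=4, input_leads=("I", "II")),
    ], ids=["full16", "desk4", "odd5"])
    def test_parameter_count_closed_form(self, cfg):
        net = qn.build_regressor(cfg)
        assert net.n_parameters() == qn.count_parameters(cfg)

    def test_zeroed_network_outputs_head_bias(self):
        cfg = tiny_config(n_blocks=1, dropout_rate=0.0)
        net = qn.build_regressor(cfg)
        for owner, name in net.parameters():
            setattr(owner, name, np.zeros_like(getattr(owner, name)))
        net.head.b = np.array([3.25], dtype=np.float32)
        out = net.forward(np.zeros((4, 1, 250), dtype=np.float32))
        np.testing.assert_allclose(out, 3.25, atol=1e-6)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            qn.NetConfig(n_blocks=0)
        with pytest.raises(ValueError):
            qn.NetConfig(input_leads=("II", "nope"))
        with pytest.raises(ValueError):
            qn.NetConfig(dropout_rate=1.0)

    def test_gradients_match_finite_differences(self):
        cfg = tiny_config(dropout_rate=0.0, input_length=60, stem_stride=4)
        net = qn.build_regressor(cfg)
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (3, 1, 60)).astype(np.float32)
        y = rng.normal(0, 1, 3).astype(np.float32)
        out = net.forward(x, train=True)
        net.backward(((2.0 / 3) * (out - y)).astype(np.float32))

        def loss():
            return float(np.mean((net.forward(x, train=True) - y) ** 2))

        checked = 0
        for owner, name in net.parameters():
            arr = getattr(owner, name).reshape(-1)
            grad = getattr(owner, "d" + name).reshape(-1)
            i = int(rng.integers(arr.size))
            eps = 3e-2
            orig = float(arr[i])
            arr[i] = orig + eps
            lp = loss()
            arr[i] = orig - eps
            lm = loss()
            arr[i] = orig
            num = (lp - lm) / (2 * eps)
            if abs(num) > 1e-3:
                assert grad[i] == pytest.approx(num, rel=0.05, abs=5e-3)
                checked += 1
        assert checked >= 5


class TestFolds:
    def test_one_patient_per_fold(self):
        folds = qn.patient_grouped_kfold([f"P{i}" for i in range(10)], k=10)
        assert sorted(folds.fold_sizes()) == [1] * 10

    def test_pigeonhole_sizes(self):
        folds = qn.patient_grouped_kfold([f"P{i}" for i in range(101)], k=10)
        assert sorted(set(folds.fold_sizes())) == [10, 11]

    def test_records_follow_patient(self):
        ids = ["A", "A", "B", "A", "C", "B"] + [f"P{i}" for i in range(20)]
        folds = qn.patient_grouped_kfold(ids, k=5, seed=3)
        rec = folds.record_folds(ids)
        assert rec[0] == rec[1] == rec[3]
        assert rec[2] == rec[5]

    def test_split_hygiene(self):
        rng = np.random.default_rng(0)
        ids = rng.choice([f"P{i:04d}" for i in range(300)], size=1000)
        folds = qn.patient_grouped_kfold(ids, k=10, seed=1)
        rec = folds.record_folds(ids)
        for f in range(10):
            train_p = set(ids[rec != f])
            test_p = set(ids[rec == f])
            assert not train_p & test_p

    def test_deterministic_and_errors(self):
        ids = [f"P{i}" for i in range(25)]
        a = qn.patient_grouped_kfold(ids, k=5, seed=7)
        b = qn.patient_grouped_kfold(ids, k=5, seed=7)
        assert a.assignment == b.assignment
        with pytest.raises(ValueError):
            qn.patient_grouped_kfold(ids[:3], k=5)


class TestSelectLeads:
    def test_named_subsets(self):
        w = np.arange(5000 * 11).reshape(5000, 11)
        tele = qn.select_leads(w, "telemetry3")
        assert tele.shape == (5000, 3)
        np.testing.assert_array_equal(tele[:, 2], w[:, LEADS.index("V1")])
        np.testing.assert_array_equal(qn.select_leads(w, "all11"), w)

    def test_single_lead(self):
        w = np.zeros((5000, 11))
        assert qn.select_leads(w, ["II"]).shape == (5000, 1)

    def test_unknown_lead_rejected(self):
        with pytest.raises(KeyError):
            qn.select_leads(np.zeros((10, 11)), ["V99"])


class TestTraining:
    def _toy_data(self, n=96, length=250, seed=0):
        """Waveforms whose mean amplitude encodes the label."""
        rng = np.random.default_rng(seed)
        y = rng.uniform(380, 480, n)
        x = np.zeros((n, length, 11), dtype=np.float32)
        base = rng.normal(0, 0.2, (n, length))
        x[:, :, :] = (base + (y[:, None] - 424.0) / 50.0)[:, :, None]
        return x, y

    def test_constant_labels_converge(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (80, 250, 11)).astype(np.float32)
        y = np.full(80, 424.0)
        cfg = tiny_config(epochs=100, dropout_rate=0.0, learning_rate=1e-2,
                          patience=100)
        net = qn.build_regressor(cfg)
        net, norm, _ = qn.train(net, x[:64], y[:64], cfg, seed=2)
        preds = qn.predict(net, norm, x[64:])
        np.testing.assert_allclose(preds, 424.0, atol=1.0)

    def test_seeded_training_reproducible(self):
        x, y = self._toy_data()
        cfg = tiny_config()
        n1 = qn.build_regressor(cfg)
        n1, norm1, _ = qn.train(n1, x[:80], y[:80], cfg, seed=5)
        n2 = qn.build_regressor(cfg)
        n2, norm2, _ = qn.train(n2, x[:80], y[:80], cfg, seed=5)
        p1 = qn.predict(n1, norm1, x[80:])
        p2 = qn.predict(n2, norm2, x[80:])
        np.testing.assert_allclose(p1, p2, atol=1e-4)

    def test_learns_amplitude_coded_labels(self):
        x, y = self._toy_data(n=160)
        cfg = tiny_config(epochs=6)
        net = qn.build_regressor(cfg)
        net, norm, _ = qn.train(net, x[:128], y[:128], cfg, seed=3)
        preds = qn.predict(net, norm, x[128:])
        mae = np.mean(np.abs(preds - y[128:]))
        baseline = np.mean(np.abs(y[128:] - y[:128].mean()))
        assert mae < baseline

    def test_divergence_raises(self):
        x, y = self._toy_data(n=48)
        cfg = tiny_config(learning_rate=1e6, epochs=2)
        net = qn.build_regressor(cfg)
        with np.errstate(over="ignore"), pytest.raises(qn.TrainingDivergedError):
            qn.train(net, x, y * 1e12, cfg, seed=0)

    def test_cross_validate_prediction_set(self):
        x, y = self._toy_data(n=60)
        ids = np.repeat([f"P{i}" for i in range(30)], 2)
        cfg = tiny_config(epochs=1, val_fraction=0.0)
        pset = qn.cross_validate(x, y, ids, cfg, k=3, seed=0)
        assert len(pset) == 60
        assert np.all(np.isfinite(pset.raw))
        # records of one patient share a fold
        f = pset.frame
        assert (f.groupby("patient_id")["fold"].nunique() == 1).all()


class TestCheckpoints:
    def test_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (40, 250, 11)).astype(np.float32)
        y = rng.uniform(380, 480, 40)
        cfg = tiny_config(epochs=2)
        net = qn.build_regressor(cfg)
        net, norm, _ = qn.train(net, x[:32], y[:32], cfg, seed=1)
        before = qn.predict(net, norm, x[32:])
        path = tmp_path / "model.npz"
        qn.save_checkpoint(path, net, norm)
        net2, norm2 = qn.load_checkpoint(path)
        after = qn.predict(net2, norm2, x[32:])
        np.testing.assert_allclose(after, before, atol=1e-5)
        assert net2.config == cfg


class TestPredictionSet:
    def test_required_columns_enforced(self):
        import pandas as pd

        with pytest.raises(ValueError):
            qn.PredictionSet(pd.DataFrame({"patient_id": ["a"]}))

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        frame = pd.DataFrame({
            "patient_id": ["a", "b"], "fold": [0, 1],
            "true_qtc_ms": [420.0, 470.0],
            "raw_pred_qtc_ms": [425.0, 462.0],
        })
        pset = qn.PredictionSet(frame).with_calibrated([425.0, 470.0])
        path = tmp_path / "preds.csv"
        pset.to_csv(path)
        loaded = qn.PredictionSet.from_csv(path)
        np.testing.assert_allclose(loaded.calibrated, [425.0, 470.0])
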