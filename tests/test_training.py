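import numpy as np
import pytest

from _oracles import auroc_oracle, aupr_oracle
from epintlm import (EPINTLM, SeqGenDataset, TrainConfig, aupr, auroc,
                     evaluate, predict, train, training_schedule)
from conftest import random_table, tiny_config


class TestSchedule:
    @pytest.mark.parametrize("epoch,trainable,lr", [
        (1, False, 1e-3),
        (2, False, 1e-3),   # boundary: still frozen
        (3, True, 1e-4),    # unfreeze + rate drop coincide
        (10, True, 1e-4),
    ])
    def test_freeze_unfreeze_and_rate(self, epoch, trainable, lr):
        cfg = TrainConfig()
        assert training_schedule(epoch, cfg) == (trainable, lr)

    def test_epoch_below_one_errors(self):
        with pytest.raises(ValueError):
            training_schedule(0, TrainConfig())

    def test_rate_ordering_enforced(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_initial=1e-4, lr_after_unfreeze=1e-3)


class TestMetrics:
    def test_auroc_hand_example(self):
        # 4 pos-neg pairs, 3 concordant -> 0.75
        assert auroc([0.9, 0.8, 0.7, 0.3], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_auroc_perfect_and_ties(self):
        assert auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert auroc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == pytest.approx(0.5)

    def test_aupr_hand_example(self):
        # precision 1 at recall 1/2, 2/3 at recall 1 -> 5/6
        assert aupr([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(5 / 6)

    def test_aupr_perfect(self):
        assert aupr([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_null_aupr_near_prevalence(self, rng):
        n = 10000
        labels = (rng.random(n) < 0.05).astype(int)
        scores = rng.random(n)
        assert aupr(scores, labels) == pytest.approx(0.05, abs=0.02)

    @pytest.mark.parametrize("case", range(5))
    def test_metrics_match_first_principles_oracles(self, case):
        rng = np.random.default_rng(case)
        n = 40
        labels = rng.integers(0, 2, n)
        labels[0], labels[1] = 0, 1
        scores = np.round(rng.random(n), 2)   # induce some ties
        assert auroc(scores, labels) == pytest.approx(
            auroc_oracle(scores, labels), abs=1e-12)
        assert aupr(scores, labels) == pytest.approx(
            aupr_oracle(scores, labels), abs=1e-9)

    def test_monotone_transform_invariance(self, rng):
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        scores = rng.normal(size=30)
        warped = np.exp(3 * scores)  # strictly monotone
        assert auroc(scores, labels) == pytest.approx(auroc(warped, labels))
        assert aupr(scores, labels) == pytest.approx(aupr(warped, labels))

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError):
            aupr([0.1, 0.2], [0, 0])


def make_dataset(rng, n, n_pos, pair_prefix=""):
    """Tiny token-level dataset with a separable signal: positives carry
    token 7 everywhere, negatives never do."""
    cfg = tiny_config()
    I_E = rng.integers(8, 4097, (n, 60)).astype(np.int32)
    I_P = rng.integers(8, 4097, (n, 40)).astype(np.int32)
    y = np.zeros(n, dtype=np.int8)
    y[:n_pos] = 1
    I_E[:n_pos, ::3] = 7
    I_P[:n_pos, ::3] = 7
    G = np.zeros((n, cfg.genomic_dim), dtype=np.float32)
    ids = np.array([f"{pair_prefix}{i}" for i in range(n)])
    return SeqGenDataset(I_E=I_E, I_P=I_P, G=G, y=y, pair_ids=ids)


class TestTrainLoop:
    def _model(self, seed=0):
        cfg = tiny_config(dropout=0.1)
        rng = np.random.default_rng(42)
        return EPINTLM(cfg, random_table(rng, dim=cfg.embed_dim), seed=seed)

    def _config(self, **kw):
        base = dict(batch_size=16, max_epochs=4, seed=5, early_stop_patience=4)
        base.update(kw)
        return TrainConfig(**base)

    def test_loss_decreases_on_separable_data(self, rng):
        fit = make_dataset(rng, 64, 24, "f")
        val = make_dataset(rng, 32, 12, "v")
        model = self._model()
        hist = train(model, fit, val,
                     self._config(max_epochs=10, early_stop_patience=10))
        assert hist.epochs[-1]["train_loss"] < hist.epochs[0]["train_loss"]
        assert max(r["val_auroc"] for r in hist.epochs) > 0.8

    def test_history_records_schedule(self, rng):
        fit = make_dataset(rng, 48, 16, "f")
        val = make_dataset(rng, 24, 8, "v")
        hist = train(self._model(), fit, val, self._config())
        flags = [r["embedding_trainable"] for r in hist.epochs]
        lrs = [r["lr"] for r in hist.epochs]
        assert flags[:2] == [False, False] and all(flags[2:])
        assert lrs[:2] == [1e-3, 1e-3] and all(lr == 1e-4 for lr in lrs[2:])

    def test_same_seed_reproduces_first_epoch_loss(self, rng):
        fit = make_dataset(rng, 48, 16, "f")
        val = make_dataset(rng, 24, 8, "v")
        h1 = train(self._model(seed=3), fit, val, self._config(max_epochs=1))
        h2 = train(self._model(seed=3), fit, val, self._config(max_epochs=1))
        assert h1.epochs[0]["train_loss"] == pytest.approx(
            h2.epochs[0]["train_loss"], abs=1e-6)

    def test_pair_id_leakage_rejected(self, rng):
        fit = make_dataset(rng, 48, 16, "same")
        val = make_dataset(rng, 24, 8, "same")
        with pytest.raises(ValueError, match="leak"):
            train(self._model(), fit, val, self._config())

    def test_empty_split_rejected(self, rng):
        fit = make_dataset(rng, 48, 16, "f")
        empty = SeqGenDataset(I_E=np.empty((0, 60), dtype=np.int32),
                              I_P=np.empty((0, 40), dtype=np.int32),
                              G=np.empty((0, 10), dtype=np.float32),
                              y=np.empty(0, dtype=np.int8),
                              pair_ids=np.empty(0, dtype="U4"))
        with pytest.raises(ValueError):
            train(self._model(), fit, empty, self._config())

    def test_evaluate_reports_counts(self, rng):
        ds = make_dataset(rng, 40, 4, "t")
        rep = evaluate(self._model(), ds, batch_size=16)
        assert rep["n_pos"] == 4 and rep["n_neg"] == 36
        assert 0.0 <= rep["auroc"] <= 1.0 and 0.0 <= rep["aupr"] <= 1.0

    def test_predict_is_deterministic_in_eval_mode(self, rng):
        ds = make_dataset(rng, 20, 4, "t")
        model = self._model()
        assert np.array_equal(predict(model, ds), predict(model, ds))
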