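"""Joint loss, schedule, early stopping, fold construction, and the fit loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgmtl.autodiff import Tensor
from ecgmtl.model import ModelConfig
from ecgmtl.synthetic import SyntheticSpec, make_dataset
from ecgmtl.training import (TrainingConfig, early_stop, encode_labels,
                             joint_loss, lr_at_epoch, make_folds, train)


class TestJointLoss:
    def test_lambda_one_equals_main_loss(self, rng):
        ms = Tensor(rng.normal(size=(4, 3)))
        as_ = Tensor(rng.normal(size=(4, 2)))
        ym = (rng.random((4, 3)) < 0.5).astype(float)
        ya = (rng.random((4, 2)) < 0.5).astype(float)
        total = joint_loss(ms, ym, as_, ya, 1.0)
        from ecgmtl.autodiff import bce_with_logits
        assert float(total.data) == pytest.approx(
            float(bce_with_logits(ms, ym).data))

    def test_weighted_arithmetic(self):
        # engineered scores giving known per-task losses, then Eq arithmetic
        from ecgmtl.autodiff import bce_with_logits
        ms, ym = Tensor([[0.0]]), np.array([[1.0]])
        as_, ya = Tensor([[0.0]]), np.array([[0.0]])
        l = joint_loss(ms, ym, as_, ya, 0.5)
        # both halves are log 2, so any lambda gives log 2
        assert float(l.data) == pytest.approx(np.log(2.0))

    def test_single_record_hand_computed_cross_entropy(self):
        # p = sigmoid(1) for a positive, sigmoid(-0.5) for a negative
        s = Tensor([[1.0, -0.5]])
        y = np.array([[1.0, 0.0]])
        expected = -0.5 * (np.log(1 / (1 + np.exp(-1.0)))
                           + np.log(1 - 1 / (1 + np.exp(0.5))))
        assert float(joint_loss(s, y, s, y, 1.0).data) == pytest.approx(expected)

    def test_rejects_lambda_outside_unit_interval(self, rng):
        s = Tensor(rng.normal(size=(1, 2)))
        y = np.zeros((1, 2))
        with pytest.raises(ValueError):
            joint_loss(s, y, s, y, 1.5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(lam=st.floats(min_value=0.0, max_value=1.0))
    def test_linear_in_lambda(self, lam):
        rng = np.random.default_rng(5)
        ms, as_ = Tensor(rng.normal(size=(3, 2))), Tensor(rng.normal(size=(3, 4)))
        ym = (rng.random((3, 2)) < 0.5).astype(float)
        ya = (rng.random((3, 4)) < 0.5).astype(float)
        l0 = float(joint_loss(ms, ym, as_, ya, 0.0).data)
        l1 = float(joint_loss(ms, ym, as_, ya, 1.0).data)
        lmid = float(joint_loss(ms, ym, as_, ya, lam).data)
        assert lmid == pytest.approx(lam * l1 + (1 - lam) * l0, abs=1e-12)


class TestSchedule:
    def test_initial_rate(self):
        assert lr_at_epoch(0, TrainingConfig()) == pytest.approx(0.0005)

    def test_before_first_decay(self):
        assert lr_at_epoch(9, TrainingConfig()) == pytest.approx(0.0005)

    def test_one_decade_decay(self):
        assert lr_at_epoch(10, TrainingConfig()) == pytest.approx(0.00005)

    def test_rejects_negative_epoch(self):
        with pytest.raises(ValueError):
            lr_at_epoch(-1, TrainingConfig())


class TestEarlyStop:
    def test_strictly_decreasing_never_stops(self):
        for n in range(1, 30):
            assert not early_stop(list(np.linspace(1.0, 0.1, n)), 10)

    def test_triggers_exactly_after_patience_plateau(self):
        history = [0.5, 0.3] + [0.35] * 9
        assert not early_stop(history, 10)
        history.append(0.36)  # 10th non-improving epoch after the best
        assert early_stop(history, 10)

    def test_improvement_resets_the_window(self):
        history = [0.5] + [0.6] * 9 + [0.4]
        assert not early_stop(history, 10)

    def test_ties_do_not_count_as_improvement(self):
        assert early_stop([0.4] * 11, 10)


class TestMakeFolds:
    def test_recommended_split_by_fold_tag(self, tiny_dataset):
        records, _ = tiny_dataset
        tr, va, te = make_folds(records, "ptbxl_recommended")
        n = len(records)
        assert len(tr) + len(va) + len(te) == n
        assert all(records[i].fold <= 8 for i in tr)
        assert all(records[i].fold == 9 for i in va)
        assert all(records[i].fold == 10 for i in te)

    def test_recommended_requires_fold_metadata(self, tiny_dataset):
        records, _ = tiny_dataset
        import copy
        orphan = [copy.copy(r) for r in records[:5]]
        for r in orphan:
            r.fold = None
        with pytest.raises(ValueError, match="fold"):
            make_folds(orphan, "ptbxl_recommended")

    def test_stratified_deterministic(self, tiny_dataset):
        records, _ = tiny_dataset
        a = make_folds(records, "stratified_10fold", seed=3)
        b = make_folds(records, "stratified_10fold", seed=3)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_stratified_balance_two_classes(self):
        from ecgmtl.preprocessing import EcgRecord
        records = []
        for i in range(100):
            r = EcgRecord(f"r{i}", np.zeros((1, 4)), 100.0,
                          main_labels={"A" if i < 50 else "B"})
            records.append(r)
        tr, va, te = make_folds(records, "stratified_10fold", seed=0)
        for idx in (va, te):
            labels = [min(records[i].main_labels) for i in idx]
            assert abs(labels.count("A") - labels.count("B")) <= 1

    def test_unknown_scheme_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="scheme"):
            make_folds(tiny_dataset[0], "bogus")


def fast_cfgs(seed=0, epochs=2):
    mcfg = ModelConfig(in_leads=12, n_main_classes=9, n_aux_classes=5,
                       block_channels=(4,), block_strides=(4,),
                       se_reduction=2, gru_hidden=4)
    tcfg = TrainingConfig(lr0=5e-3, max_epochs=epochs, seed=seed)
    return mcfg, tcfg


class TestTrainLoop:
    def test_loss_decreases_on_easy_data(self, cpsc):
        spec = SyntheticSpec(hierarchy=cpsc,
                             frequencies={c: 7 for c in cpsc.fine_classes},
                             rate=100.0, duration=4.0, noise_sd=0.02,
                             multilabel_rate=0.0, seed=2)
        records, _ = make_dataset(spec)
        mcfg, tcfg = fast_cfgs(epochs=5)
        _, log, _ = train(records, mcfg, tcfg, cpsc.fine_classes,
                          cpsc.coarse_classes)
        assert log.train_loss_total.iloc[-1] < log.train_loss_total.iloc[0]

    def test_lambda_one_leaves_aux_head_untouched(self, tiny_dataset, cpsc):
        records, _ = tiny_dataset
        mcfg, tcfg = fast_cfgs(epochs=1)
        tcfg.lambda_weight = 1.0
        model, _, _ = train(records, mcfg, tcfg, cpsc.fine_classes,
                            cpsc.coarse_classes)
        fresh = type(model)(mcfg, seed=tcfg.seed)
        assert np.array_equal(model.aux_head.weight.data,
                              fresh.aux_head.weight.data)
        assert not np.array_equal(model.main_head.weight.data,
                                  fresh.main_head.weight.data)

    def test_same_seed_reproduces_epoch_losses(self, tiny_dataset, cpsc):
        records, _ = tiny_dataset
        logs = []
        for _ in range(2):
            mcfg, tcfg = fast_cfgs(seed=11, epochs=1)
            _, log, _ = train(records, mcfg, tcfg, cpsc.fine_classes,
                              cpsc.coarse_classes)
            logs.append(log.train_loss_total.iloc[0])
        assert logs[0] == logs[1]

    def test_rejects_empty_training_set(self, cpsc):
        mcfg, tcfg = fast_cfgs()
        with pytest.raises(ValueError):
            train([], mcfg, tcfg, cpsc.fine_classes, cpsc.coarse_classes)

    def test_rejects_nonuniform_shapes(self, tiny_dataset, cpsc):
        import copy
        records = [copy.copy(r) for r in tiny_dataset[0][:6]]
        records[0].signal = records[0].signal[:, :100]
        mcfg, tcfg = fast_cfgs()
        with pytest.raises(ValueError, match="uniform"):
            train(records, mcfg, tcfg, cpsc.fine_classes, cpsc.coarse_classes)


def test_encode_labels_multi_hot(cpsc, tiny_dataset):
    records, _ = tiny_dataset
    y = encode_labels(records, cpsc.fine_classes)
    assert y.shape == (len(records), 9)
    assert np.array_equal(y.sum(axis=1),
                          [len(r.main_labels) for r in records])
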