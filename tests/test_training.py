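import numpy as np
import pytest

from eegmind.containers import Window, WindowedDataset
from eegmind.experiments import benchmark_model_config
from eegmind.model import EEGMindModel
from eegmind.training import (AugmentConfig, TrainConfig, augment,
                              cosine_warm_restart_lr, early_stop_trace,
                              evaluate, noise_robustness_suite,
                              report_from_confusion, stratified_kfold,
                              stratified_split, train)


def _balanced_dataset(rng, n=100, k=2, c=2, w=16):
    wins = [Window(rng.standard_normal((c, w)), f"w{i}", 0) for i in range(n)]
    labels = np.repeat(np.arange(1, k + 1), n // k)
    return WindowedDataset(wins, labels, K=k)


class TestStratifiedSplit:
    def test_80_10_10_counts_per_class(self, rng):
        ds = _balanced_dataset(rng, n=100)
        tr, va, te = stratified_split(ds, (0.8, 0.1, 0.1), seed=0)
        assert (len(tr), len(va), len(te)) == (80, 10, 10)
        for sub, n_expected in [(tr, 40), (va, 5), (te, 5)]:
            for k in (1, 2):
                assert (sub.labels == k).sum() == n_expected

    def test_deterministic(self, rng):
        ds = _balanced_dataset(rng)
        a = stratified_split(ds, seed=3)
        b = stratified_split(ds, seed=3)
        for sa, sb in zip(a, b):
            assert [w.source_recording for w in sa.windows] == \
                   [w.source_recording for w in sb.windows]

    def test_all_in_train(self, rng):
        ds = _balanced_dataset(rng, n=20)
        tr, va, te = stratified_split(ds, (1.0, 0.0, 0.0), seed=0)
        assert len(tr) == 20 and len(va) == 0 and len(te) == 0

    def test_small_class_rejected(self, rng):
        wins = [Window(rng.standard_normal((2, 8)), "w", 0) for _ in range(5)]
        ds = WindowedDataset(wins, [1, 1, 1, 2, 2], K=2)
        with pytest.raises(ValueError, match="class 2"):
            stratified_split(ds, seed=0)

    def test_disjoint(self, rng):
        ds = _balanced_dataset(rng)
        tr, va, te = stratified_split(ds, seed=1)
        ids = [w.source_recording for s in (tr, va, te) for w in s.windows]
        assert len(ids) == len(set(ids)) == len(ds)


class TestStratifiedKfold:
    def test_fold_sizes_balanced(self, rng):
        ds = _balanced_dataset(rng, n=100)
        folds = stratified_kfold(ds, k=5, seed=0)
        for train_idx, val_idx in folds:
            assert len(val_idx) == 20
            assert (ds.labels[val_idx] == 1).sum() == 10

    def test_exact_partition(self, rng):
        ds = _balanced_dataset(rng, n=90)
        folds = stratified_kfold(ds, k=5, seed=2)
        all_val = np.concatenate([v for _, v in folds])
        assert sorted(all_val) == list(range(90))
        for tr_idx, v_idx in folds:
            assert set(tr_idx).isdisjoint(v_idx)
            assert len(tr_idx) + len(v_idx) == 90

    def test_stratification_within_one_window(self, rng):
        wins = [Window(rng.standard_normal((2, 8)), f"w{i}", 0)
                for i in range(47)]
        labels = np.array([1] * 30 + [2] * 17)
        ds = WindowedDataset(wins, labels, K=2)
        for _, val_idx in stratified_kfold(ds, k=5, seed=0):
            for k, n_k in [(1, 30), (2, 17)]:
                got = (ds.labels[val_idx] == k).sum()
                assert abs(got - n_k / 5) <= 1

    def test_k_one_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 2"):
            stratified_kfold(_balanced_dataset(rng), k=1)

    def test_class_smaller_than_k_rejected(self, rng):
        wins = [Window(rng.standard_normal((2, 8)), "w", 0) for _ in range(8)]
        ds = WindowedDataset(wins, [1] * 5 + [2] * 3, K=2)
        with pytest.raises(ValueError, match="class 2"):
            stratified_kfold(ds, k=5)


class TestAugment:
    def test_all_probabilities_zero_identity(self, rng):
        x = rng.standard_normal((4, 3, 32))
        out = augment(x, AugmentConfig(), seed=0)
        assert np.array_equal(out, x)

    def test_jitter_invertible(self, rng):
        x = rng.standard_normal((3, 64))
        shifted = np.roll(x, 5, axis=-1)
        assert np.allclose(np.roll(shifted, -5, axis=-1), x)
        cfg = AugmentConfig(p_jitter=1.0, max_jitter=8)
        out = augment(x, cfg, seed=1)
        # a circular shift preserves the sample multiset per channel
        assert np.allclose(np.sort(out, axis=-1), np.sort(x, axis=-1))

    def test_noise_at_requested_snr(self, rng):
        x = rng.standard_normal((6, 4, 64)) * 10
        cfg = AugmentConfig(p_noise=1.0, noise_snr_db=20.0)
        out = augment(x, cfg, seed=2)
        for xi, oi in zip(x, out):
            realized = 10 * np.log10(
                np.mean(xi**2) / np.mean((oi - xi) ** 2))
            assert abs(realized - 20.0) < 0.5

    def test_crop_longer_than_window_rejected(self, rng):
        with pytest.raises(ValueError, match="crop"):
            augment(rng.standard_normal((1, 2, 16)),
                    AugmentConfig(p_crop=1.0, crop_fraction=1.5), seed=0)

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal((4, 2, 32))
        cfg = AugmentConfig(p_crop=0.5, p_noise=0.5, p_jitter=0.5, p_warp=0.5)
        assert np.array_equal(augment(x, cfg, seed=9), augment(x, cfg, seed=9))


class TestSchedule:
    def test_restart_resets_to_peak(self):
        lr0 = 1e-3
        assert cosine_warm_restart_lr(0, lr0, period=10) == lr0
        assert cosine_warm_restart_lr(10, lr0, period=10) == lr0  # restart
        # within a period the lr decays
        assert cosine_warm_restart_lr(9, lr0, period=10) < lr0 * 0.05

    def test_period_doubles(self):
        lr0 = 1.0
        # second cycle spans epochs 10..30; its midpoint is epoch 20
        assert abs(cosine_warm_restart_lr(20, lr0, 10, 2) - 0.5) < 1e-12


class TestEarlyStopping:
    def test_patience_rule_on_constructed_sequence(self):
        # improves at 0,1,2 then flat: stops after patience=3 flat epochs
        losses = [1.0, 0.8, 0.6, 0.6, 0.6, 0.6, 0.5, 0.4]
        assert early_stop_trace(losses, patience=3) == 6

    def test_patience_one_with_constant_loss_stops_at_second_epoch(self):
        assert early_stop_trace([0.5, 0.5, 0.5, 0.5], patience=1) == 2

    def test_never_triggered_runs_full_schedule(self):
        assert early_stop_trace([0.5, 0.4, 0.3], patience=2) == 3


class TestTrain:
    def test_lr_zero_leaves_parameters_unchanged(self, tiny_dataset):
        ds, _ = tiny_dataset
        tr, va, _ = stratified_split(ds, seed=0)
        m = EEGMindModel(benchmark_model_config(seed=0, d_model=16,
                                                fusion_width=16))
        before = m.get_state()
        m, _ = train(m, tr, va, TrainConfig(lr=0.0, max_epochs=1, seed=0))
        after = m.get_state()
        for k in before:
            assert np.array_equal(before[k], after[k])

    def test_checkpoint_is_best_validation(self, tiny_dataset):
        ds, _ = tiny_dataset
        tr, va, _ = stratified_split(ds, seed=0)
        m = EEGMindModel(benchmark_model_config(seed=0, d_model=16,
                                                fusion_width=16))
        m, hist = train(m, tr, va, TrainConfig(lr=1e-2, max_epochs=8, seed=0))
        final_val = float(m.loss(va.stack(), va.labels).data)
        assert final_val <= hist.val_loss.min() + 1e-9


class TestEvaluate:
    def test_perfect_predictions(self):
        rep = report_from_confusion(np.array([[10, 0], [0, 10]]), auc=1.0)
        assert rep.accuracy == rep.recall == rep.f1 == 1.0
        assert rep.confusion[0, 1] == rep.confusion[1, 0] == 0

    def test_stated_binary_confusion(self):
        # positives = class 2: sensitivity 45/50, specificity 40/50
        rep = report_from_confusion(np.array([[40, 10], [5, 45]]))
        assert abs(rep.accuracy - 0.85) < 1e-12
        assert abs(rep.sensitivity - 0.9) < 1e-12
        assert abs(rep.specificity - 0.8) < 1e-12

    def test_macro_f1_matches_per_class_oracle(self, rng):
        cm = rng.integers(0, 30, (3, 3))
        cm += np.eye(3, dtype=int)  # ensure nonzero diagonals
        rep = report_from_confusion(cm)
        f1s = []
        for c in range(3):
            tp = cm[c, c]
            prec = tp / cm[:, c].sum()
            rec = tp / cm[c].sum()
            f1s.append(0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec))
        assert abs(rep.f1 - np.mean(f1s)) < 1e-12

    def test_constant_classifier_auc_half(self, tiny_dataset):
        ds, _ = tiny_dataset
        m = EEGMindModel(benchmark_model_config(seed=0, d_model=16,
                                                fusion_width=16))
        # zero output layer -> identical probabilities for every window
        m.params["w_o"].data[:] = 0.0
        m.params["b_o"].data[:] = 0.0
        rep = evaluate(m, ds)
        assert abs(rep.auc - 0.5) < 1e-9

    def test_single_class_set_has_no_auc(self, tiny_dataset):
        ds, _ = tiny_dataset
        sub = ds.subset(np.where(ds.labels == 1)[0])
        m = EEGMindModel(benchmark_model_config(seed=0, d_model=16,
                                                fusion_width=16))
        rep = evaluate(m, sub)
        assert rep.auc is None


class TestRobustnessSuite:
    def test_one_row_per_tier_plus_clean(self, tiny_dataset):
        ds, _ = tiny_dataset
        m = EEGMindModel(benchmark_model_config(seed=0, d_model=16,
                                                fusion_width=16))
        table = noise_robustness_suite(m, ds, tiers=[20.0, 10.0], seed=0)
        assert list(table.scenario) == ["clean", "snr_20dB", "snr_10dB"]

    def test_clean_row_equals_plain_evaluate(self, tiny_dataset):
        ds, _ = tiny_dataset
        m = EEGMindModel(benchmark_model_config(seed=0, d_model=16,
                                                fusion_width=16))
        table = noise_robustness_suite(m, ds, tiers=[5.0], seed=0)
        rep = evaluate(m, ds)
        assert table.accuracy.iloc[0] == rep.accuracy
        assert table.f1.iloc[0] == rep.f1
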