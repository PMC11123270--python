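"""Schedule, loss, early stopping, splitting, and the freezing contract."""

import numpy as np
import pytest

import protonshift as ps
from protonshift.gnn import GraphConfig, ModelParams
from protonshift.training import (TrainConfig, TrainHistory, _dataset_loss,
                                  build_training_set, early_stop_check,
                                  finetune, frozen_layers_unchanged,
                                  lr_schedule, masked_mae_loss, split_dataset,
                                  train)


class TestLrSchedule:
    def test_initial_rate(self):
        assert lr_schedule(0, TrainConfig()) == pytest.approx(5e-4)

    def test_flat_before_first_decay(self):
        cfg = TrainConfig()
        assert lr_schedule(69, cfg) == pytest.approx(5e-4)

    def test_two_decay_steps(self):
        assert lr_schedule(140, TrainConfig()) == pytest.approx(5e-4 * 0.96**2)

    def test_non_increasing_piecewise_constant(self):
        cfg = TrainConfig()
        lrs = [lr_schedule(e, cfg) for e in range(300)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        # constant inside each 70-epoch block
        for block in range(4):
            vals = set(lrs[block * 70:(block + 1) * 70])
            assert len(vals) == 1

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(-1, TrainConfig())


class TestMaskedMae:
    def test_zero_when_exact(self):
        pred = np.array([1.0, 2.0, 3.0])
        assert masked_mae_loss(pred, pred, np.ones(3, bool)) == 0.0

    def test_arithmetic(self):
        assert masked_mae_loss([1.0, 3.0], [1.5, 2.5], [True, True]) == pytest.approx(0.5)

    def test_unmasked_nodes_ignored(self):
        pred = np.array([1.0, 100.0])
        tgt = np.array([1.5, np.nan])
        mask = np.array([True, False])
        assert masked_mae_loss(pred, tgt, mask) == pytest.approx(0.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            masked_mae_loss([1.0], [1.0], [False])


class TestEarlyStop:
    def _hist(self, vals):
        h = TrainHistory()
        h.checkpoints = [(10 * (i + 1) - 1, v) for i, v in enumerate(vals)]
        return h

    def test_small_rise_continues(self):
        assert early_stop_check(self._hist([0.20, 0.21]), TrainConfig()) == "continue"

    def test_large_rise_stops(self):
        assert early_stop_check(self._hist([0.20, 0.23]), TrainConfig()) == "stop"

    def test_boundary_exact_ten_percent_continues(self):
        assert early_stop_check(self._hist([0.20, 0.22]), TrainConfig()) == "continue"

    def test_monotone_decreasing_never_stops(self):
        vals = list(np.linspace(1.0, 0.1, 30))
        for k in range(2, len(vals) + 1):
            assert early_stop_check(self._hist(vals[:k]), TrainConfig()) == "continue"

    def test_first_checkpoint_continues(self):
        assert early_stop_check(self._hist([0.5]), TrainConfig()) == "continue"


class TestSplitDataset:
    def test_sizes(self):
        train_part, val_part = split_dataset(list(range(10)), 0.2, seed=0)
        assert len(train_part) == 8 and len(val_part) == 2

    def test_deterministic_and_partitioning(self):
        items = list(range(17))
        a = split_dataset(items, 0.3, seed=4)
        b = split_dataset(items, 0.3, seed=4)
        assert a[0] == b[0] and a[1] == b[1]
        assert sorted(a[0] + a[1]) == items

    def test_too_few_molecules_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1], 0.2, seed=0)


@pytest.fixture(scope="module")
def tiny_trained():
    """A very small scratch run shared by the wiring tests."""
    cfg = GraphConfig(n_rbf=8, dim=16, readout_widths=(16, 12, 8))
    molecules, records = ps.make_dataset(6, ps.OracleParams(), 0.0, seed=21)
    dataset = build_training_set(molecules, records, cfg)
    tc = TrainConfig.reduced_scratch(max_epochs=40, seed=0)
    params, history = train(ModelParams(cfg, seed=0), dataset, tc)
    return cfg, dataset, tc, params, history


class TestTrain:
    def test_history_lr_matches_schedule(self, tiny_trained):
        _, _, tc, _, history = tiny_trained
        expect = [lr_schedule(e, tc) for e in range(len(history.lr))]
        assert history.lr == expect

    def test_loss_decreases(self, tiny_trained):
        _, _, _, _, history = tiny_trained
        assert history.train_loss[-1] < history.train_loss[0]

    def test_best_checkpoint_is_minimum(self, tiny_trained):
        _, _, _, _, history = tiny_trained
        best = dict(history.checkpoints)[history.best_checkpoint_epoch]
        assert best == min(v for _, v in history.checkpoints)

    def test_empty_dataset_rejected(self):
        cfg = GraphConfig(n_rbf=8, dim=16, readout_widths=(16, 12, 8))
        with pytest.raises(ValueError):
            train(ModelParams(cfg), [], TrainConfig())

    def test_wrong_mode_rejected(self, tiny_trained):
        cfg, dataset, _, params, _ = tiny_trained
        with pytest.raises(ValueError):
            train(ModelParams(cfg), dataset, TrainConfig(mode="finetune"))
        with pytest.raises(ValueError):
            finetune(params, dataset, TrainConfig(mode="scratch"))


class TestFinetuneFreezing:
    def test_exactly_six_trainable_and_frozen_bitwise(self, tiny_trained):
        cfg, _, _, pretrained, _ = tiny_trained
        molecules, records = ps.make_dataset(
            5, ps.perturb_oracle(ps.OracleParams(), ps.transfer_gap_spec()),
            0.0, seed=33)
        dataset = build_training_set(molecules, records, cfg)
        ft_cfg = TrainConfig.reduced_finetune(max_epochs=30, seed=1)
        result, _ = finetune(pretrained, dataset, ft_cfg)
        assert result.n_trainable_layers() == 6
        assert frozen_layers_unchanged(pretrained, result)
        # the trainable layers actually moved
        moved = any(
            not np.array_equal(pretrained.weights[n], result.weights[n])
            for n in result.weights
            if result.trainable_flags[result.layer_of(n)])
        assert moved
        # target scaling inherited, not refit
        assert result.target_mean == pretrained.target_mean
        assert result.target_std == pretrained.target_std


class TestConfigValidation:
    def test_defaults_are_published_protocol(self):
        cfg = TrainConfig()
        assert cfg.lr0 == 5e-4
        assert cfg.decay_fraction == 0.04
        assert cfg.decay_interval_epochs == 70
        assert cfg.max_epochs == 1200
        assert cfg.batch_size == 32
        assert cfg.val_check_interval_epochs == 10
        assert cfg.early_stop_rise_fraction == 0.10

    @pytest.mark.parametrize("bad", [dict(lr0=-1), dict(val_fraction=0.0),
                                     dict(val_fraction=0.9), dict(mode="x"),
                                     dict(max_epochs=0)])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            TrainConfig(**bad)
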