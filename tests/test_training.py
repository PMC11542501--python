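"""Training regimes: smoke runs, reproducibility, CPS and Mean Teacher wiring."""

from dataclasses import replace

import numpy as np
import pytest

from octseg.errors import DataError
from octseg.losses import ema_update
from octseg.segmenters import SegmenterConfig
from octseg.synthetic import make_benchmark_dataset
from octseg.training import (
    TrainConfig,
    TrainedModel,
    run_ablation,
    subsample_unlabeled,
    train_cps,
    train_mean_teacher,
    train_supervised,
)


def tiny_cfg(**kw) -> TrainConfig:
    base = dict(
        segmenter=SegmenterConfig(architecture="unet", width=4, depth=2),
        loss="ce",
        epochs=2,
        batch_labeled=2,
        batch_unlabeled=2,
        lr=2e-3,
        seed=0,
        crop_size=16,
    )
    base.update(kw)
    return TrainConfig(**base)


class TestSupervised:
    def test_smoke_one_epoch(self, tiny_dataset):
        model = train_supervised(tiny_cfg(epochs=1), tiny_dataset)
        assert len(model.history) == 1
        assert "train_loss" in model.history[0]
        assert "val_mean_iou" in model.history[0]

    def test_loss_decreases_when_overfitting(self, tiny_dataset):
        model = train_supervised(tiny_cfg(epochs=20), tiny_dataset)
        losses = [h["train_loss"] for h in model.history]
        assert losses[-1] < losses[0]

    def test_seed_reproducibility(self, tiny_dataset):
        a = train_supervised(tiny_cfg(epochs=1, seed=5), tiny_dataset)
        b = train_supervised(tiny_cfg(epochs=1, seed=5), tiny_dataset)
        assert a.history[0]["train_loss"] == pytest.approx(
            b.history[0]["train_loss"], abs=1e-5
        )

    def test_no_labeled_data_rejected(self, small_params, tmp_path):
        man = make_benchmark_dataset(
            small_params, seed=0, out_dir=tmp_path,
            n_labeled_patients=1, n_unlabeled_patients=1,
            n_val_patients=1, n_test_patients=1,
        )
        for r in man.records:  # strip the labeled flag
            if r.split == "train":
                r.labeled = False
                r.mask_path = r.boundaries_path = None
        with pytest.raises(DataError):
            train_supervised(tiny_cfg(), man)

    @pytest.mark.parametrize("loss", ["wce", "ce_dice"])
    def test_alternate_losses_run(self, tiny_dataset, loss):
        model = train_supervised(tiny_cfg(epochs=1, loss=loss), tiny_dataset)
        assert np.isfinite(model.history[0]["train_loss"])

    def test_double_unet_trains(self, tiny_dataset):
        cfg = tiny_cfg(
            epochs=1,
            segmenter=SegmenterConfig(architecture="double_unet", width=4, depth=1),
        )
        model = train_supervised(cfg, tiny_dataset)
        assert np.isfinite(model.history[0]["train_loss"])


class TestCps:
    def test_fraction_zero_is_pure_supervised_pair(self, tiny_dataset):
        model = train_cps(tiny_cfg(unlabeled_fraction=0.0), tiny_dataset)
        assert model.predictor == "cps_1"
        assert all("unlabeled_loss" not in h for h in model.history)

    def test_history_tracks_both_loss_components(self, tiny_dataset):
        model = train_cps(tiny_cfg(unlabeled_fraction=1.0), tiny_dataset)
        h = model.history[0]
        assert {"labeled_loss", "unlabeled_loss", "total_loss"} <= set(h)
        assert h["total_loss"] == pytest.approx(
            h["labeled_loss"] + h["unlabeled_loss"], abs=1e-9
        )

    def test_unlabeled_subsample_size_and_reproducibility(self, tiny_dataset):
        records = tiny_dataset.select(split="train", labeled=False)
        for frac in (0.25, 0.5, 1.0):
            sub1 = subsample_unlabeled(records, frac, seed=9)
            sub2 = subsample_unlabeled(records, frac, seed=9)
            assert len(sub1) == round(frac * len(records))
            assert [r.scan_id for r in sub1] == [r.scan_id for r in sub2]

    def test_pair_uses_distinct_seeds(self, tiny_dataset):
        model = train_cps(tiny_cfg(epochs=1, seed=3), tiny_dataset)
        seg2 = model.extras["cps_2"]
        assert model.segmenter.cfg.seed == 3
        assert seg2.cfg.seed == 4

    def test_fraction_without_unlabeled_data_rejected(self, small_params, tmp_path):
        man = make_benchmark_dataset(
            small_params, seed=1, out_dir=tmp_path,
            n_labeled_patients=2, n_unlabeled_patients=1,
            n_val_patients=1, n_test_patients=1,
        )
        man.records = [r for r in man.records if r.labeled]
        with pytest.raises(DataError):
            train_cps(tiny_cfg(unlabeled_fraction=1.0), man)


class TestMeanTeacher:
    def test_decay_zero_teacher_tracks_student(self, tiny_dataset):
        model = train_mean_teacher(
            tiny_cfg(epochs=1, ema_decay=0.0, patience=None), tiny_dataset
        )
        student = model.extras["student"]
        # with decay 0 the teacher equals the student after every step; the
        # returned teacher carries best-validation weights of the same path
        tw = model.segmenter.module.get_weights()
        sw = student.module.get_weights()
        assert all(np.allclose(a, b, atol=1e-6) for a, b in zip(tw, sw))

    def test_history_length_equals_epochs(self, tiny_dataset):
        model = train_mean_teacher(tiny_cfg(epochs=3), tiny_dataset)
        assert len(model.history) == 3
        assert model.predictor == "teacher"

    def test_two_step_ema_matches_hand_unrolled_recursion(self):
        """Teacher update on a one-parameter toy model: two EMA steps equal
        the unrolled recursion t2 = d*(d*t0 + (1-d)*s1) + (1-d)*s2."""
        decay = 0.7
        t = 5.0
        for s in (1.0, 2.0):
            t = ema_update(s, t, decay)
        expected = decay * (decay * 5.0 + 0.3 * 1.0) + 0.3 * 2.0
        assert t == pytest.approx(expected, abs=1e-12)


class TestIsolationAndCheckpoints:
    def test_training_never_reads_test_split(self, small_params, tmp_path):
        man = make_benchmark_dataset(
            small_params, seed=2, out_dir=tmp_path,
            n_labeled_patients=2, n_unlabeled_patients=4,
            n_val_patients=1, n_test_patients=2,
        )
        man.access_log.clear()
        train_cps(tiny_cfg(epochs=1), man)
        test_ids = {r.scan_id for r in man.select(split="test")}
        assert not (set(man.access_log) & test_ids)

    def test_checkpoint_roundtrip_bit_identical_config(self, tiny_dataset, tmp_path):
        model = train_supervised(tiny_cfg(epochs=1, seed=2), tiny_dataset)
        model.save(tmp_path / "run")
        loaded = TrainedModel.load(tmp_path / "run")
        assert loaded.config == model.config
        assert loaded.history == model.history
        img = np.random.default_rng(0).random((16, 16))
        assert np.array_equal(
            loaded.predict(img).scores, model.predict(img).scores
        )


class TestAblation:
    def test_report_shape_and_spearman(self, tiny_dataset):
        report = run_ablation(
            tiny_cfg(epochs=1), tiny_dataset, fractions=[0.0, 1.0], seeds=[0, 1]
        )
        assert len(report.table) == 4
        assert set(report.table["fraction"]) == {0.0, 1.0}
        assert set(report.spearman_by_seed.index) == {0, 1}
        assert np.isfinite(report.median_spearman) or np.isnan(
            report.median_spearman
        )

    def test_single_fraction_reduces_to_supervised_arm(self, tiny_dataset):
        report = run_ablation(
            tiny_cfg(epochs=1), tiny_dataset, fractions=[0.0], seeds=[0]
        )
        assert len(report.table) == 1
        assert np.isnan(report.spearman_by_seed[0])


class TestCpsLabeledLossSwitch:
    def test_weighted_labeled_term_changes_loss(self, tiny_dataset):
        plain = train_cps(tiny_cfg(epochs=1, unlabeled_fraction=0.0), tiny_dataset)
        weighted = train_cps(
            tiny_cfg(epochs=1, unlabeled_fraction=0.0, cps_labeled_loss="wce"),
            tiny_dataset,
        )
        assert plain.history[0]["labeled_loss"] != pytest.approx(
            weighted.history[0]["labeled_loss"], abs=1e-9
        )

    def test_unknown_flavour_rejected(self, tiny_dataset):
        from octseg.errors import ConfigError

        with pytest.raises(ConfigError):
            train_cps(tiny_cfg(cps_labeled_loss="dice"), tiny_dataset)
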