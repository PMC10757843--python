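import numpy as np
import pytest

from cpseg.losses import lambda_warmup, pseudo_label, soft_dice_loss
from cpseg.models import SegmenterConfig, build_segmenter
from cpseg.sampling import CropBatch, select_labeled_slices
from cpseg.synthdata import degrade_to_sparse
from cpseg.training import (TrainConfig, _mixed_pseudo, init_cps_state,
                            predict_volume, train_cps, train_supervised)
from cpseg.volume_io import ImageVolume, MaskVolume

TINY_MODEL = SegmenterConfig(architecture="resunet", depth=2, base_channels=4)


@pytest.fixture()
def sparse_setup(small_synth, tiny_plan):
    _, image, _, nucleoli = small_synth
    labeled = select_labeled_slices(64, 3)
    sparse = degrade_to_sparse(nucleoli, labeled)
    unlabeled = [z for z in range(64) if z not in labeled]
    return image, sparse, unlabeled, tiny_plan


def _tc(plan, seed=0, **kw):
    defaults = dict(epochs=2, steps_per_epoch=2, batch_size=4, crop_plan=plan,
                    seed=seed)
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestSupervised:
    def test_learnability_loss_decreases(self, sparse_setup):
        image, sparse, _, plan = sparse_setup
        cfg = _tc(plan, epochs=12, steps_per_epoch=4, batch_size=8, lr=1e-2)
        model = build_segmenter(TINY_MODEL, 1)
        model, log = train_supervised(model, (image, sparse), 12, cfg)
        first, last = log.records[0]["L_s"], log.records[-1]["L_s"]
        assert last < first

    def test_seeded_rerun_reproduces_loss_trajectory(self, sparse_setup):
        image, sparse, _, plan = sparse_setup
        runs = []
        for _ in range(2):
            cfg = _tc(plan, seed=7)
            model = build_segmenter(TINY_MODEL, 15)
            _, log = train_supervised(model, (image, sparse), 2, cfg)
            runs.append([r["L_s"] for r in log.records])
        assert runs[0] == pytest.approx(runs[1], rel=1e-12)

    def test_collapse_warning_on_quota_free_ultra_sparse_training(self, tiny_plan):
        # <0.1% foreground and no quota: the model drifts to all-background
        # predictions and the trainer must flag it
        rng = np.random.default_rng(0)
        voxels = rng.uniform(0.3, 0.7, size=(8, 128, 128))
        labels = np.zeros((8, 128, 128), dtype=np.uint8)
        labels[4, 60:62, 60:62] = 1  # 4 voxels of 2**17
        image = ImageVolume(voxels)
        sparse = MaskVolume(labels, annotated_slices=tuple(range(8)))
        cfg = _tc(tiny_plan, epochs=6, steps_per_epoch=8, batch_size=4,
                  fg_quota=0.0, lr=3e-2)
        model = build_segmenter(TINY_MODEL, 3)
        with pytest.warns(RuntimeWarning, match="all-background"):
            train_supervised(model, (image, sparse), 6, cfg)


class TestCps:
    def test_lambda_zero_reduces_to_supervised(self, sparse_setup):
        # with the CPS weight forced to zero, model1's parameter trajectory is
        # identical to plain supervised training on the same seeded batches
        image, sparse, unlabeled, plan = sparse_setup
        cfg = _tc(plan, seed=5, lambda_max=0.0)
        sup = build_segmenter(TINY_MODEL, cfg.seed * 2 + 1)
        sup, _ = train_supervised(sup, (image, sparse), 2, cfg)
        state = init_cps_state(TINY_MODEL, cfg)
        state, _ = train_cps(state, (image, sparse), (image, unlabeled), 2,
                             use_cutmix=False, cfg=cfg)
        for p_sup, p_cps in zip(sup.parameters(), state.model1.parameters()):
            assert np.array_equal(p_sup.data, p_cps.data)

    def test_log_lambda_column_matches_warmup(self, sparse_setup):
        image, sparse, unlabeled, plan = sparse_setup
        cfg = _tc(plan, epochs=8, steps_per_epoch=1, batch_size=2)
        state = init_cps_state(TINY_MODEL, cfg)
        state, log = train_cps(state, (image, sparse), (image, unlabeled), 8,
                               use_cutmix=False, cfg=cfg)
        for rec in log.records:
            assert rec["lam"] == lambda_warmup(rec["epoch"])

    def test_pools_must_be_disjoint(self, sparse_setup):
        image, sparse, unlabeled, plan = sparse_setup
        cfg = _tc(plan)
        state = init_cps_state(TINY_MODEL, cfg)
        bad_pool = unlabeled + [sparse.annotated_slices[0]]
        with pytest.raises(ValueError, match="overlap"):
            train_cps(state, (image, sparse), (image, bad_pool), 1, False, cfg)

    def test_empty_unlabeled_pool_degrades_with_warning(self, sparse_setup):
        image, sparse, _, plan = sparse_setup
        cfg = _tc(plan, epochs=1)
        state = init_cps_state(TINY_MODEL, cfg)
        with pytest.warns(RuntimeWarning, match="degrades to supervised"):
            train_cps(state, (image, sparse), (image, []), 1, False, cfg)

    def test_stop_gradient_between_networks(self, sparse_setup, rng):
        # optimizing model1 against model2's pseudo-labels must leave model2
        # without any gradient
        image, sparse, unlabeled, plan = sparse_setup
        m1 = build_segmenter(TINY_MODEL, 1)
        m2 = build_segmenter(TINY_MODEL, 2)
        x = rng.uniform(size=(2, 32, 32))
        p1, p2 = m1.forward(x), m2.forward(x)
        loss = soft_dice_loss(pseudo_label(p2).labels, p1)
        loss.backward()
        assert all(p.grad is not None for p in m1.parameters())
        assert all(p.grad is None for p in m2.parameters())

    def test_cutmix_pseudo_labels_use_identical_boxes(self, sparse_setup, rng):
        # pixel-exact: outside the box the mixed pseudo-label equals the
        # pseudo-label of batch A, inside it equals that of batch B
        image, sparse, unlabeled, plan = sparse_setup
        model = build_segmenter(TINY_MODEL, 4)
        imgs_a = rng.uniform(size=(3, 32, 32))
        imgs_b = rng.uniform(size=(3, 32, 32))
        batch_a = CropBatch(images=imgs_a, masks=None,
                            contains_fg=np.zeros(3, bool),
                            source_slices=np.zeros(3, int))
        batch_b = CropBatch(images=imgs_b, masks=None,
                            contains_fg=np.zeros(3, bool),
                            source_slices=np.zeros(3, int))
        regions = np.zeros((3, 32, 32), dtype=bool)
        regions[0, :16, :], regions[1, 5:20, 7:30] = True, True
        mixed = _mixed_pseudo(model, batch_a, batch_b, regions, derived_from=1)[:, 0]
        pl_a = pseudo_label(model.predict(imgs_a)[:, 0]).labels
        pl_b = pseudo_label(model.predict(imgs_b)[:, 0]).labels
        assert np.array_equal(mixed[regions], pl_b[regions])
        assert np.array_equal(mixed[~regions], pl_a[~regions])


class _ConstantModel:
    def __init__(self, value):
        self.value = value

    def predict(self, images):
        arr = np.asarray(images)
        return np.full((arr.shape[0], 1) + arr.shape[1:], self.value)


class TestPredictVolume:
    def test_constant_one_model_fills_volume(self, small_synth, tiny_plan):
        _, image, _, _ = small_synth
        mask = predict_volume(_ConstantModel(1.0), image, tiny_plan, slices=[0, 5])
        assert mask.labels[0].all() and mask.labels[5].all()
        assert not mask.labels[1].any()  # unrequested slices stay empty

    def test_threshold_above_one_gives_all_background(self, small_synth, tiny_plan):
        _, image, _, _ = small_synth
        mask = predict_volume(_ConstantModel(1.0), image, tiny_plan,
                              threshold=1.1, slices=[0])
        assert not mask.labels.any()

    def test_real_model_output_is_binary_over_full_slices(self, small_synth, tiny_plan):
        _, image, _, _ = small_synth
        model = build_segmenter(TINY_MODEL, 0)
        mask = predict_volume(model, image, tiny_plan, slices=[3])
        assert set(np.unique(mask.labels[3])) <= {0, 1}
        assert mask.labels[3].shape == image.voxels[3].shape
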