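"""Split logic, CNN training dynamics, prediction contracts."""

import numpy as np
import pytest

from phonocell import ClassLabel
from phonocell.cnn import (
    LeNet,
    ModelConfig,
    SplitPlan,
    load_model,
    make_split,
    predict,
    predict_proba,
    save_model,
    train,
)
from phonocell.dataset import GasfDataset


def _toy_cells(n_per_group, n_batches=1):
    cells = []
    i = 0
    for cls in (ClassLabel.NORMAL, ClassLabel.ABNORMAL):
        for b in range(1, n_batches + 1):
            for _ in range(n_per_group):
                cells.append((f"c{i:03d}", cls, b))
                i += 1
    return cells


def _toy_dataset(n_cells_per_class=6, imgs_per_cell=30, side=16, seed=0):
    """Linearly separable three-class toy images tagged by cell."""
    rng = np.random.default_rng(seed)
    images, labels, cids, bids = [], [], [], []
    cells = []
    i = 0
    for cls in (ClassLabel.NORMAL, ClassLabel.ABNORMAL):
        for _ in range(n_cells_per_class):
            cid = f"c{i:03d}"
            cells.append((cid, cls, 1))
            for _ in range(imgs_per_cell):
                # class signature: mean offset pattern + noise
                base = {ClassLabel.NORMAL: 0.5, ClassLabel.ABNORMAL: -0.5}[cls]
                img = base * np.outer(np.linspace(-1, 1, side),
                                      np.linspace(-1, 1, side))
                images.append(img + 0.1 * rng.standard_normal((side, side)))
                labels.append(int(cls))
                cids.append(cid)
                bids.append(1)
                # every cell also contributes background images
                images.append(0.1 * rng.standard_normal((side, side)))
                labels.append(int(ClassLabel.BACKGROUND))
                cids.append(cid)
                bids.append(1)
            i += 1
    n = len(images)
    ds = GasfDataset(np.asarray(images, dtype=np.float32),
                     np.asarray(labels, dtype=np.int8),
                     np.asarray(cids, dtype=object),
                     np.asarray(bids), np.zeros((n, 2), dtype=int))
    return ds, cells


class TestMakeSplit:
    def test_80_cells_at_70_percent(self):
        plan = make_split(_toy_cells(10, n_batches=4), 0.7, rng_seed=0)
        assert len(plan.train_cell_ids) == 56
        assert len(plan.test_cell_ids) == 24

    def test_10_cells_at_80_percent(self):
        plan = make_split(_toy_cells(5), 0.8, rng_seed=0)
        assert len(plan.train_cell_ids) == 8
        assert len(plan.test_cell_ids) == 2

    def test_determinism(self):
        cells = _toy_cells(10, n_batches=2)
        a = make_split(cells, 0.7, rng_seed=3)
        b = make_split(cells, 0.7, rng_seed=3)
        assert a.train_cell_ids == b.train_cell_ids
        assert a.test_cell_ids == b.test_cell_ids

    def test_unbalanced_groups_rejected(self):
        cells = _toy_cells(5) + [("extra", ClassLabel.NORMAL, 1)]
        with pytest.raises(ValueError, match="balance"):
            make_split(cells, 0.7)

    def test_overlapping_plan_rejected(self):
        with pytest.raises(ValueError):
            SplitPlan(["a", "b"], ["b", "c"])


class TestModelConfig:
    def test_exactly_two_conv_blocks(self):
        with pytest.raises(ValueError):
            ModelConfig(conv_blocks=((6, 5, 2),))

    def test_exactly_three_classes(self):
        with pytest.raises(ValueError):
            ModelConfig(n_classes=4)


class TestTraining:
    @pytest.fixture(scope="class")
    def toy(self):
        ds, cells = _toy_dataset()
        split = make_split(cells, 0.7, rng_seed=1)
        return ds, split

    def test_loss_decreases_on_smoke_run(self, toy):
        ds, split = toy
        cfg = ModelConfig(epochs=2, batch_size=32, rng_seed=0, patience=5)
        _, log = train(ds, split, cfg)
        assert log[1]["train_loss"] < log[0]["train_loss"]

    def test_learns_separable_classes(self, toy):
        ds, split = toy
        cfg = ModelConfig(epochs=6, batch_size=32, rng_seed=0, patience=5)
        model, _ = train(ds, split, cfg)
        test = ds.for_cells(split.test_cell_ids)
        acc = float(np.mean(predict_proba(model, test.images).argmax(axis=1)
                            == test.labels))
        assert acc > 0.9

    def test_test_cells_do_not_influence_training(self, toy):
        # corrupting every test-cell label must leave training untouched
        ds, split = toy
        cfg = ModelConfig(epochs=2, batch_size=32, rng_seed=0, patience=5)
        _, log_a = train(ds, split, cfg)
        corrupted = GasfDataset(ds.images, ds.labels.copy(), ds.cell_ids,
                                ds.batch_ids, ds.pixels)
        test_rows = np.isin(corrupted.cell_ids, split.test_cell_ids)
        corrupted.labels[test_rows] = (corrupted.labels[test_rows] + 1) % 3
        _, log_b = train(corrupted, split, cfg)
        assert log_a == log_b

    def test_missing_class_rejected(self):
        ds, cells = _toy_dataset(n_cells_per_class=3)
        keep = ds.labels != int(ClassLabel.BACKGROUND)
        ds2 = ds.subset(keep)
        # drop backgrounds entirely: training must refuse
        split = make_split(cells, 0.7, rng_seed=0)
        with pytest.raises(ValueError, match="class"):
            train(ds2, split, ModelConfig(epochs=1, rng_seed=0))

    def test_unknown_cell_in_split_rejected(self, toy):
        ds, split = toy
        bad = SplitPlan(list(split.train_cell_ids) + ["ghost"],
                        list(split.test_cell_ids))
        with pytest.raises(ValueError, match="ghost"):
            train(ds, bad, ModelConfig(epochs=1, rng_seed=0))


class TestPredict:
    @pytest.fixture(scope="class")
    def model(self):
        return LeNet(ModelConfig(rng_seed=0), input_side=16)

    def test_softmax_simplex(self, model):
        imgs = np.random.default_rng(0).uniform(-1, 1, (5, 16, 16))
        probs = predict_proba(model, imgs)
        assert probs.shape == (5, 3)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicate_images_identical_predictions(self, model):
        img = np.random.default_rng(1).uniform(-1, 1, (16, 16))
        probs = predict_proba(model, np.stack([img, img]))
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_prediction_count_and_sources(self, model):
        imgs = np.random.default_rng(2).uniform(-1, 1, (4, 16, 16))
        preds = predict(model, imgs, sources=[("c", r, 0) for r in range(4)])
        assert len(preds) == 4
        assert preds[2].source == ("c", 2, 0)

    def test_save_load_round_trip(self, model, tmp_path):
        path = tmp_path / "model.npz"
        save_model(model, path)
        clone = load_model(path)
        imgs = np.random.default_rng(3).uniform(-1, 1, (3, 16, 16))
        np.testing.assert_allclose(predict_proba(model, imgs),
                                   predict_proba(clone, imgs), atol=1e-6)


class TestWaveformInformation:
    def test_cnn_beats_single_feature_thresholds(self, e2e):
        """The CNN must beat the best single-feature (nu or alpha0)
        threshold rule on the same held-out pixels: it sees the whole
        waveform, not just one fitted parameter.  The threshold rule is
        given the fair-but-favourable treatment of choosing its two cuts
        on training-cell pixels."""
        from phonocell.processing import fit_trace

        scans = {s.cell_id: s for s in e2e["scans"]}

        def fitted_features(dataset, indices):
            feats, labels = [], []
            for i in indices:
                scan = scans[dataset.cell_ids[i]]
                r, c = dataset.pixels[i]
                fit = fit_trace(scan.trace_at(r, c), scan.acquisition)
                feats.append((fit.sound_velocity, fit.attenuation))
                labels.append(int(dataset.labels[i]))
            return np.asarray(feats), np.asarray(labels)

        rng = np.random.default_rng(99)
        ds, pred = e2e["eval_ds"], e2e["eval_pred"]
        test_idx = rng.choice(len(ds), size=700, replace=False)
        test_feats, test_labels = fitted_features(ds, test_idx)
        cnn_acc = float(np.mean(pred[test_idx] == ds.labels[test_idx]))

        train_ds = e2e["dataset"].for_cells(e2e["split"].train_cell_ids)
        train_idx = rng.choice(len(train_ds), size=700, replace=False)
        train_feats, train_labels = fitted_features(train_ds, train_idx)

        def best_single_feature_acc(col):
            # two-cut banding fitted on train pixels, scored on test pixels
            x_tr, x_te = train_feats[:, col], test_feats[:, col]
            cuts = np.quantile(x_tr, np.linspace(0.02, 0.98, 33))
            orders = [(2, 1, 0), (0, 1, 2), (2, 0, 1), (1, 0, 2)]
            best_rule, best_train = None, -1.0
            for a_i, lo in enumerate(cuts):
                for hi in cuts[a_i:]:
                    band = (x_tr >= lo).astype(int) + (x_tr > hi).astype(int)
                    for order in orders:
                        acc = float(np.mean(np.take(order, band) == train_labels))
                        if acc > best_train:
                            best_train, best_rule = acc, (lo, hi, order)
            lo, hi, order = best_rule
            band = (x_te >= lo).astype(int) + (x_te > hi).astype(int)
            return float(np.mean(np.take(order, band) == test_labels))

        single = max(best_single_feature_acc(0), best_single_feature_acc(1))
        assert cnn_acc > single
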