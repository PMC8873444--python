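import itertools

import numpy as np
import pytest

from ki67pi import classifier as clf
from ki67pi import fragments as fr
from ki67pi import io_annotations as io
from ki67pi import synthetic as syn


class TestTrainingConfig:
    def test_unknown_architecture(self):
        with pytest.raises(ValueError, match="architecture"):
            clf.TrainingConfig(architecture="resnet50")

    def test_valid_fraction_bounds(self):
        with pytest.raises(ValueError):
            clf.TrainingConfig(valid_fraction=1.0)


class TestTrainModel:
    def test_single_class_pool_rejected(self, toy_pool):
        x, y = toy_pool
        with pytest.raises(ValueError, match="both classes"):
            clf.train_model(x[y == 0], y[y == 0], clf.TrainingConfig(epochs=1))

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            clf.train_model(
                np.empty((0, 24, 24, 3), np.uint8), [], clf.TrainingConfig(epochs=1)
            )

    def test_training_is_deterministic(self, toy_pool):
        x, y = toy_pool
        cfg = clf.TrainingConfig(epochs=2, batch_size=16, seed=9)
        a = clf.train_model(x, y, cfg)
        b = clf.train_model(x, y, cfg)
        assert a.log[0]["train_loss"] == b.log[0]["train_loss"]
        for key in a.params:
            np.testing.assert_array_equal(a.params[key], b.params[key])

    def test_log_and_checkpoint_contract(self, toy_model):
        assert len(toy_model.log) <= toy_model.config.epochs
        assert sum(e["checkpointed"] for e in toy_model.log) <= toy_model.config.epochs
        # checkpoint discipline: the kept weights are the validation-loss minimum
        assert toy_model.best_val_loss == min(e["val_loss"] for e in toy_model.log)

    def test_artifact_round_trip(self, tmp_path, toy_model, toy_pool):
        path = tmp_path / "model.npz"
        toy_model.save(path)
        back = clf.ModelArtifact.load(path)
        assert back.config == toy_model.config
        assert back.input_size == toy_model.input_size
        assert back.best_val_loss == toy_model.best_val_loss
        x, _ = toy_pool
        img = io.SlideImage("t", x[0])
        grid = fr.build_grid(24, 24, 24, 24)
        np.testing.assert_allclose(
            clf.predict(back, img, grid).scores,
            clf.predict(toy_model, img, grid).scores,
        )


class TestPredict:
    def test_window_mismatch_rejected(self, toy_model):
        img = io.SlideImage("t", np.zeros((48, 48, 3), np.uint8))
        grid = fr.build_grid(48, 48, 48, 48)
        with pytest.raises(ValueError, match="input size"):
            clf.predict(toy_model, img, grid)

    def test_scores_within_unit_interval(self, toy_model):
        rng = np.random.default_rng(0)
        img = io.SlideImage("t", rng.integers(0, 256, (72, 72, 3), dtype=np.uint8))
        grid = fr.build_grid(72, 72, 24, 24)
        pred = clf.predict(toy_model, img, grid)
        assert (pred.scores >= 0).all() and (pred.scores <= 1).all()
        np.testing.assert_array_equal(pred.labels, pred.scores >= 0.5)

    def test_blank_white_image_is_all_negative(self, separable_model):
        img = io.SlideImage("white", np.full((96, 96, 3), 255, np.uint8))
        grid = fr.build_grid(96, 96, 48, 16)
        pred = clf.predict(separable_model, img, grid)
        assert not pred.labels.any()


class TestHeuristicClassify:
    def test_blank_fragment_negative_and_stained_fragment_positive(self):
        blank = syn.render_from_stain_densities(np.zeros((96, 96)), np.zeros((96, 96)))
        full = syn.render_from_stain_densities(
            np.full((96, 96), 0.1), np.zeros((96, 96))
        )
        grid = fr.build_grid(96, 96, 96, 96)
        assert clf.heuristic_classify(blank, grid).labels.tolist() == [0]
        assert clf.heuristic_classify(full, grid).labels.tolist() == [1]

    def test_agrees_with_annotation_labels_on_clean_slides(self):
        # with the sensitivity-oriented cut (roughly one nucleus per window)
        # the stained-fraction rule approximates "at least one relevant cell"
        slide = syn.generate_slide(
            syn.SynthesisConfig(seed=12, target_pi=0.3, artifact_count=0, lymphocyte_count=0)
        )
        grid = fr.build_grid(slide.image.height, slide.image.width, 96, 16)
        pred = clf.heuristic_classify(slide.image, grid, min_stained_fraction=0.01)
        truth = fr.label_fragments(grid, slide.annotations)
        assert (pred.labels == truth.labels).mean() >= 0.90

    def test_parameter_validation(self, default_slide):
        grid = fr.build_grid(default_slide.image.height, default_slide.image.width, 96, 16)
        with pytest.raises(ValueError):
            clf.heuristic_classify(default_slide.image, grid, min_stained_fraction=0.0)


class TestEnsembleVote:
    def _map(self, grid, labels):
        labels = np.asarray(labels, dtype=float)
        return clf.PredictionMap(grid=grid, scores=labels, labels=labels.astype(int))

    def test_majority_on_all_vote_combinations(self):
        grid = fr.build_grid(48, 48 * 8, 48, 48)  # 8 fragments: one per combination
        combos = np.array(list(itertools.product([0, 1], repeat=3)))  # (8, 3)
        maps = [self._map(grid, combos[:, m]) for m in range(3)]
        voted = clf.ensemble_vote(maps)
        expected = (combos.sum(axis=1) >= 2).astype(int)
        np.testing.assert_array_equal(voted.labels, expected)

    def test_idempotent_on_identical_maps(self):
        grid = fr.build_grid(48, 96, 48, 48)
        m = self._map(grid, [1, 0])
        voted = clf.ensemble_vote([m, m, m])
        np.testing.assert_array_equal(voted.labels, m.labels)

    def test_symmetric_under_permutation(self):
        rng = np.random.default_rng(1)
        grid = fr.build_grid(48, 48 * 5, 48, 48)
        maps = [self._map(grid, rng.integers(0, 2, 5)) for _ in range(3)]
        base = clf.ensemble_vote(maps)
        for perm in itertools.permutations(maps):
            np.testing.assert_array_equal(clf.ensemble_vote(list(perm)).labels, base.labels)

    def test_scores_are_component_means(self):
        grid = fr.build_grid(48, 96, 48, 48)
        maps = [
            clf.PredictionMap(grid=grid, scores=np.array(s))
            for s in ([0.2, 0.9], [0.4, 0.8], [0.9, 0.1])
        ]
        voted = clf.ensemble_vote(maps)
        np.testing.assert_allclose(voted.scores, [0.5, 0.6])

    def test_wrong_count_rejected(self):
        grid = fr.build_grid(48, 48, 48, 48)
        m = self._map(grid, [1])
        with pytest.raises(ValueError, match="exactly 3"):
            clf.ensemble_vote([m, m])

    def test_grid_mismatch_rejected(self):
        m1 = self._map(fr.build_grid(48, 48, 48, 48), [1])
        m2 = self._map(fr.build_grid(48, 96, 48, 48), [1, 0])
        with pytest.raises(ValueError, match="grid"):
            clf.ensemble_vote([m1, m1, m2])


def test_prediction_map_invariants():
    grid = fr.build_grid(48, 96, 48, 48)
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        clf.PredictionMap(grid=grid, scores=np.array([1.2, 0.1]))
    pm = clf.PredictionMap(grid=grid, scores=np.array([0.7, 0.2]))
    np.testing.assert_array_equal(pm.labels, [1, 0])


def test_prediction_map_csv(tmp_path):
    grid = fr.build_grid(48, 96, 48, 48)
    pm = clf.PredictionMap(grid=grid, scores=np.array([0.7, 0.2]))
    pm.to_csv(tmp_path / "pred.csv")
    lines = (tmp_path / "pred.csv").read_text().strip().splitlines()
    assert lines[0] == "origin_row,origin_col,score,label"
    assert len(lines) == 3
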