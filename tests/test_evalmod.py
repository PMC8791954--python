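import numpy as np
import pytest
from sklearn import metrics as skm
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from lossdiff.evalmod import (
    BACKGROUND_CELL,
    accuracy,
    confusion_matrix,
    evaluate,
    mcnemar,
    render_heatmap,
    roc_auc,
    slide_heatmap,
    tsne_export,
)


class TestAccuracy:
    def test_percent_scale(self):
        preds = np.zeros(100, dtype=int)
        truths = np.zeros(100, dtype=int)
        truths[:5] = 1
        assert accuracy(preds, truths) == pytest.approx(95.0)

    def test_all_correct(self):
        assert accuracy([1, 2, 3], [1, 2, 3]) == 100.0

    def test_two_thirds(self):
        assert accuracy([0, 1, 1], [0, 0, 1]) == pytest.approx(100 * 2 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy([], [])


class TestConfusionMatrix:
    def test_perfect_is_diagonal(self):
        y = [0, 1, 2, 2]
        cm = confusion_matrix(y, y, 3)
        assert np.all(cm == np.diag([1, 1, 2]))

    def test_brute_force_tally(self):
        preds = [0, 1, 2, 0, 1, 2]
        truths = [0, 0, 1, 1, 2, 2]
        cm = confusion_matrix(preds, truths, 3)
        for i in range(3):
            for j in range(3):
                expected = sum(1 for p, t in zip(preds, truths) if t == i and p == j)
                assert cm[i, j] == expected
        assert cm.sum() == 6

    def test_out_of_range_label(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_matrix([0, 3], [0, 1], 3)

    def test_accuracy_equals_trace_over_total(self):
        rng = np.random.default_rng(0)
        preds = rng.integers(0, 4, 200)
        truths = rng.integers(0, 4, 200)
        cm = confusion_matrix(preds, truths, 4)
        assert accuracy(preds, truths) == pytest.approx(100 * np.trace(cm) / cm.sum())


class TestRocAuc:
    def test_perfect_ranking(self):
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
        truths = [0, 0, 1, 1]
        assert roc_auc(scores, truths, "micro") == pytest.approx(1.0)
        assert roc_auc(scores, truths, "macro") == pytest.approx(1.0)

    def test_constant_scores_are_chance(self):
        scores = np.full((10, 2), 0.5)
        truths = [0, 1] * 5
        assert roc_auc(scores, truths, "micro") == pytest.approx(0.5)
        assert roc_auc(scores, truths, "macro") == pytest.approx(0.5)

    def test_pairwise_enumeration_binary(self):
        pos_scores = [0.9, 0.8]
        neg_scores = [0.3, 0.2]
        scores = np.array([[1 - s, s] for s in pos_scores + neg_scores])
        truths = [1, 1, 0, 0]
        assert roc_auc(scores, truths, "per_class")[1] == pytest.approx(1.0)
        # swap one positive/negative score pair: 3 of 4 pairs still ordered
        scores2 = np.array([[1 - s, s] for s in [0.9, 0.3, 0.8, 0.2]])
        assert roc_auc(scores2, truths, "per_class")[1] == pytest.approx(0.75)

    def test_binary_micro_equals_single_class_auc(self):
        rng = np.random.default_rng(1)
        s1 = rng.random(50)
        scores = np.column_stack([1 - s1, s1])
        truths = rng.integers(0, 2, 50)
        assert roc_auc(scores, truths, "micro") == pytest.approx(
            roc_auc(scores, truths, "per_class")[1], abs=1e-12
        )

    def test_absent_class_skipped_with_warning(self):
        scores = np.array([[0.5, 0.3, 0.2], [0.2, 0.6, 0.2], [0.3, 0.3, 0.4]])
        truths = [0, 1, 0]
        with pytest.warns(UserWarning, match="class 2"):
            macro = roc_auc(scores, truths, "macro")
        assert 0.0 <= macro <= 1.0


class TestMcNemar:
    def _preds(self, b, c, n_both_right=30):
        """Build prediction vectors with given discordant counts."""
        truths = np.zeros(b + c + n_both_right, dtype=int)
        a = np.zeros_like(truths)
        bb = np.zeros_like(truths)
        a[:b] = 0
        bb[:b] = 1  # a right, b wrong
        a[b : b + c] = 1
        bb[b : b + c] = 0  # a wrong, b right
        return a, bb, truths

    def test_closed_form_continuity_correction(self):
        a, b, t = self._preds(15, 5)
        out = mcnemar(a, b, t, variant="chi2")
        assert out["b"] == 15 and out["c"] == 5
        assert out["statistic"] == pytest.approx(81 / 20)

    def test_symmetric_discordance_gives_p_one(self):
        a, b, t = self._preds(6, 6)
        out = mcnemar(a, b, t)
        assert out["method"] == "exact_binomial"
        assert out["p_value"] == pytest.approx(1.0)

    def test_swapping_classifiers_is_symmetric(self):
        a, b, t = self._preds(18, 9)
        x = mcnemar(a, b, t)
        y = mcnemar(b, a, t)
        assert x["statistic"] == y["statistic"]
        assert x["p_value"] == pytest.approx(y["p_value"])

    def test_degenerate_no_discordance(self):
        a, b, t = self._preds(0, 0)
        out = mcnemar(a, b, t)
        assert out["p_value"] == 1.0 and out["method"] == "degenerate"

    @pytest.mark.parametrize("b,c", [(15, 5), (40, 20), (3, 1), (25, 0)])
    def test_matches_reference_implementation(self, b, c):
        a, bb, t = self._preds(b, c)
        table = [[0, b], [c, 0]]
        ours = mcnemar(a, bb, t)
        if b + c >= 25:
            ref = sm_mcnemar(table, exact=False, correction=True)
        else:
            ref = sm_mcnemar(table, exact=True)
        assert ours["p_value"] == pytest.approx(float(ref.pvalue), abs=1e-9)


class TestReferenceAgreement:
    """Accuracy / confusion / AUC agree with scikit-learn on random data."""

    def test_thousand_random_instances(self):
        rng = np.random.default_rng(42)
        n, K = 1000, 4
        truths = rng.integers(0, K, n)
        raw = rng.random((n, K))
        scores = raw / raw.sum(axis=1, keepdims=True)
        preds = scores.argmax(axis=1)

        assert accuracy(preds, truths) == pytest.approx(
            100 * skm.accuracy_score(truths, preds), abs=1e-9
        )
        np.testing.assert_array_equal(
            confusion_matrix(preds, truths, K), skm.confusion_matrix(truths, preds)
        )
        onehot = np.eye(K)[truths]
        assert roc_auc(scores, truths, "micro") == pytest.approx(
            skm.roc_auc_score(onehot.ravel(), scores.ravel()), abs=1e-9
        )
        assert roc_auc(scores, truths, "macro") == pytest.approx(
            skm.roc_auc_score(truths, scores, multi_class="ovr", average="macro"),
            abs=1e-9,
        )
        per_class = roc_auc(scores, truths, "per_class")
        for c in range(K):
            assert per_class[c] == pytest.approx(
                skm.roc_auc_score(onehot[:, c], scores[:, c]), abs=1e-9
            )


class TestEvaluateReport:
    def test_report_consistency(self):
        rng = np.random.default_rng(7)
        truths = rng.integers(0, 3, 300)
        raw = rng.random((300, 3)) + np.eye(3)[truths]  # informative scores
        scores = raw / raw.sum(axis=1, keepdims=True)
        report = evaluate(scores, truths)
        assert report.accuracy == pytest.approx(
            100 * np.trace(report.confusion) / report.confusion.sum()
        )
        assert report.confusion.sum(axis=1).tolist() == [
            int((truths == c).sum()) for c in range(3)
        ]
        assert 0.5 < report.micro_auc <= 1.0


class TestSlideHeatmap:
    def test_placement(self):
        grid = slide_heatmap([1, 0], [(0, 0), (256, 0)], (512, 512), 256)
        assert grid.shape == (2, 2)
        assert grid[0, 0] == 1 and grid[0, 1] == 0
        assert grid[1, 0] == BACKGROUND_CELL

    def test_empty_predictions(self):
        grid = slide_heatmap([], [], (512, 256), 128)
        assert grid.shape == (2, 4)
        assert np.all(grid == BACKGROUND_CELL)

    def test_duplicate_cell_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            slide_heatmap([0, 1], [(0, 0), (0, 0)], (512, 512), 256)

    def test_misaligned_patch_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            slide_heatmap([0], [(10, 0)], (512, 512), 256)

    def test_round_trip_against_region_map(self):
        from lossdiff.patchio import assign_label, tile_image, tissue_filter
        from lossdiff.synthgen import (
            SlideLayout,
            annotation_noise_rate,
            generate_synthetic_slide,
            make_recipes,
        )

        layout = SlideLayout(
            width=256, height=256,
            regions=[
                (0, ((0, 0), (256, 0), (256, 256), (0, 256))),
                (1, ((64, 64), (192, 64), (192, 192), (64, 192))),
            ],
        )
        slide = generate_synthetic_slide(layout, make_recipes(2, 0.2, 0), seed=0)
        coords, preds = [], []
        for x, y in tile_image(slide.image, 64):
            tile_truth = slide.region_map[y : y + 64, x : x + 64]
            coords.append((x, y))
            preds.append(int(np.bincount(tile_truth[tile_truth >= 0]).argmax()))
        grid = slide_heatmap(preds, coords, (256, 256), 64)
        # interior malignant cell and a benign corner cell
        assert grid[1, 1] == 1 and grid[0, 0] == 0
        img = render_heatmap(grid)
        assert img.shape == (grid.shape[0] * 8, grid.shape[1] * 8, 3)


class TestTsne:
    def test_row_count_and_determinism(self):
        rng = np.random.default_rng(0)
        feats = rng.normal(size=(40, 8))
        a = tsne_export(feats, seed=1)
        b = tsne_export(feats, seed=1)
        assert a.shape == (40, 2)
        np.testing.assert_array_equal(a, b)

    def test_small_sample_reduces_perplexity_with_warning(self):
        rng = np.random.default_rng(1)
        feats = rng.normal(size=(12, 5))
        with pytest.warns(UserWarning, match="perplexity"):
            emb = tsne_export(feats, seed=0)
        assert emb.shape == (12, 2)

    def test_separated_clouds_stay_separated(self):
        rng = np.random.default_rng(3)
        cloud_a = rng.normal(0, 0.3, size=(30, 10))
        cloud_b = rng.normal(5, 0.3, size=(30, 10))
        feats = np.vstack([cloud_a, cloud_b])
        emb = tsne_export(feats, seed=0)
        labels = np.array([0] * 30 + [1] * 30)
        intra = np.mean(
            [np.linalg.norm(emb[labels == c] - emb[labels == c].mean(0), axis=1).mean()
             for c in (0, 1)]
        )
        inter = np.linalg.norm(emb[labels == 0].mean(0) - emb[labels == 1].mean(0))
        assert inter > intra

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            tsne_export(np.zeros((3, 4)))
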