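"""Corpus clustering, barcode construction, and the boosted-tree stage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scalestack.barcode import (
    Barcode,
    BarcodeClassifier,
    ClusterModel,
    assign_clusters,
    class_prevalence_weights,
    compute_barcode,
    concat_barcodes,
    filter_min_tiles,
    fit_corpus_clusters,
    monte_carlo_cv,
    t_confidence_interval,
)


class TestFitClusters:
    def test_two_planted_blobs_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        mu = np.zeros(8)
        mu2 = np.full(8, 10.0)
        X = np.vstack([mu + rng.normal(size=(200, 8)),
                       mu2 + rng.normal(size=(200, 8))])
        truth = np.repeat([0, 1], 200)
        model = fit_corpus_clusters(X, mag=20, k=2, seed=0)
        labels = assign_clusters(model, X)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k1_everything_one_cluster(self, rng):
        X = rng.normal(size=(50, 4))
        model = fit_corpus_clusters(X, mag=10, k=1, seed=0)
        assert compute_barcode(assign_clusters(model, X), 1) == pytest.approx([1.0])

    def test_default_k_is_150(self, rng):
        X = rng.normal(size=(400, 8))
        model = fit_corpus_clusters(X, mag=5, seed=0)
        assert model.k == 150
        assert model.to_metadata()["K"] == 150

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="insufficient tiles"):
            fit_corpus_clusters(rng.normal(size=(10, 4)), mag=5, k=20)


class TestAssignClusters:
    def test_centroid_row_maps_to_itself(self, rng):
        C = rng.normal(size=(5, 6))
        model = ClusterModel(mag=20, centroids=C)
        assert assign_clusters(model, C[3:4])[0] == 3

    def test_equidistant_tie_lowest_index(self):
        C = np.zeros((6, 2))
        C[2] = [1.0, 0.0]
        C[5] = [-1.0, 0.0]
        C[0] = [0.0, 9.0]
        C[1] = [0.0, -9.0]
        C[3] = [0.0, 7.0]
        C[4] = [0.0, -7.0]
        model = ClusterModel(mag=20, centroids=C)
        # origin is equidistant from centroids 2 and 5 -> lowest wins
        assert assign_clusters(model, np.zeros((1, 2)))[0] == 2

    def test_matches_exhaustive_scan(self, rng):
        C = rng.normal(size=(12, 5))
        X = rng.normal(size=(80, 5))
        model = ClusterModel(mag=20, centroids=C)
        got = assign_clusters(model, X)
        brute = np.array([
            int(np.argmin([np.sum((x - c) ** 2) for c in C])) for x in X])
        np.testing.assert_array_equal(got, brute)

    def test_dim_mismatch(self, rng):
        model = ClusterModel(mag=20, centroids=rng.normal(size=(3, 4)))
        with pytest.raises(ValueError, match="dimension mismatch"):
            assign_clusters(model, rng.normal(size=(2, 7)))

    def test_assignment_never_mutates_centroids(self, rng):
        """Leakage guard: scoring held-out tiles must not refit clusters."""
        X = rng.normal(size=(100, 4))
        model = fit_corpus_clusters(X, mag=20, k=5, seed=0)
        before = model.centroids.copy()
        assign_clusters(model, rng.normal(size=(500, 4)))
        np.testing.assert_array_equal(model.centroids, before)


class TestComputeBarcode:
    def test_proportions_by_definition(self):
        assert compute_barcode([0, 0, 1, 3], 4) == pytest.approx(
            [0.5, 0.25, 0.0, 0.25])

    def test_all_tiles_one_cluster_one_hot_150(self):
        block = compute_barcode([2] * 40, 150)
        assert len(block) == 150
        assert block[2] == 1.0
        assert block.sum() == 1.0

    def test_single_tile_one_hot(self):
        block = compute_barcode([4], 6)
        assert block.tolist() == [0, 0, 0, 0, 1, 0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no tiles"):
            compute_barcode([], 4)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 9), min_size=1, max_size=200))
    def test_normalization_property(self, assignments):
        block = compute_barcode(assignments, 10)
        assert block.sum() == pytest.approx(1.0, abs=1e-9)
        assert ((block >= 0) & (block <= 1)).all()


class TestMinTileFilter:
    def _counts(self, rows):
        return pd.DataFrame(rows).set_index("slide_id")

    def test_boundary_64_retained(self):
        counts = self._counts([{"slide_id": "a", 5: 64, 10: 64, 20: 64}])
        assert filter_min_tiles(counts, (5, 10, 20)) == ["a"]

    def test_any_magnification_below_discards(self):
        counts = self._counts([{"slide_id": "a", 5: 100, 10: 63, 20: 400}])
        assert filter_min_tiles(counts, (5, 10, 20)) == []

    def test_empty_cohort(self):
        counts = pd.DataFrame(columns=["slide_id", 5]).set_index("slide_id")
        assert filter_min_tiles(counts, (5,)) == []

    def test_only_selected_mags_considered(self):
        counts = self._counts([{"slide_id": "a", 5: 1, 10: 80, 20: 400}])
        assert filter_min_tiles(counts, (10, 20)) == ["a"]

    def test_monotone_in_threshold(self, rng):
        counts = self._counts(
            [{"slide_id": f"s{i}", 5: int(rng.integers(0, 200)),
              20: int(rng.integers(0, 200))} for i in range(40)])
        sizes = [len(filter_min_tiles(counts, (5, 20), t))
                 for t in (0, 16, 64, 128)]
        assert sizes == sorted(sizes, reverse=True)


class TestConcatBarcodes:
    def test_three_blocks_of_150(self, rng):
        blocks = {m: rng.dirichlet(np.ones(150)) for m in (5, 10, 20)}
        bc = concat_barcodes(blocks, "s1", (5, 10, 20))
        assert len(bc.vector) == 450
        assert bc.mags == (20, 10, 5)  # descending order fixed

    def test_single_mag_unchanged(self, rng):
        block = rng.dirichlet(np.ones(10))
        bc = concat_barcodes({10: block}, "s1")
        np.testing.assert_array_equal(bc.vector, block)

    def test_slicing_recovers_blocks_bit_exactly(self, rng):
        blocks = {m: rng.dirichlet(np.ones(7)) for m in (5, 10, 20)}
        bc = concat_barcodes(blocks, "s1", (5, 10, 20))
        for m in (5, 10, 20):
            np.testing.assert_array_equal(bc.block(m), blocks[m])

    def test_missing_block_rejected(self, rng):
        with pytest.raises(ValueError, match="lacks barcode"):
            concat_barcodes({10: rng.dirichlet(np.ones(4))}, "s1", (5, 10))


class TestPrevalenceWeights:
    def test_balanced_unit_weights(self):
        w = class_prevalence_weights([0, 0, 1, 1, 2, 2])
        assert w == pytest.approx([1.0] * 6)

    def test_three_to_one_oracle(self):
        w = class_prevalence_weights(["A", "A", "A", "B"])
        assert w == pytest.approx([2 / 3, 2 / 3, 2 / 3, 2.0])

    def test_single_class_all_ones(self):
        assert class_prevalence_weights([5, 5, 5]) == pytest.approx([1, 1, 1])

    def test_mean_weight_one(self, rng):
        labels = rng.integers(0, 4, 100)
        assert class_prevalence_weights(labels).mean() == pytest.approx(1.0)


def _barcode_cohort(rng, n_classes=3, per_class=30, k=8, informative_block=0,
                    n_mags=2):
    """Synthetic barcodes: classes differ only in one magnification block."""
    X, y = [], []
    for c in range(n_classes):
        base = rng.dirichlet(np.ones(k), size=1)[0]
        for _ in range(per_class):
            blocks = []
            for b in range(n_mags):
                if b == informative_block:
                    alpha = np.ones(k)
                    alpha[c % k] = 40.0
                    blocks.append(rng.dirichlet(alpha))
                else:
                    blocks.append(rng.dirichlet(np.ones(k) * 50))
            X.append(np.concatenate(blocks))
            y.append(c)
    return np.asarray(X), np.asarray(y)


class TestBarcodeClassifier:
    def test_separable_barcodes_high_macro_f1(self, rng):
        from scalestack.evaluation import confusion_and_f1

        X, y = _barcode_cohort(rng, per_class=40)
        order = rng.permutation(len(y))
        X, y = X[order], y[order]
        model = BarcodeClassifier(X[:90], y[:90])
        res = model.fit(n_draws=0, n_estimators=100, seed=0)
        _, _, macro, _ = confusion_and_f1(y[90:], res.predict(X[90:]), 3)
        assert macro >= 0.95

    def test_importance_concentrates_in_informative_block(self, rng):
        X, y = _barcode_cohort(rng, per_class=100, informative_block=0)
        names = [f"20x_c{j}" for j in range(8)] + [f"10x_c{j}" for j in range(8)]
        model = BarcodeClassifier(X, y, feature_names=names)
        res = model.fit(n_draws=0, n_estimators=100, seed=0)
        imp = res.feature_importance()
        frac = imp.loc[imp["mag"] == "20x", "importance"].sum() / imp["importance"].sum()
        assert frac >= 0.8

    def test_constant_barcodes_chance_level(self, rng):
        from scalestack.evaluation import confusion_and_f1

        X = np.tile(np.full(8, 1 / 8), (120, 1))
        y = np.repeat(np.arange(4), 30)
        model = BarcodeClassifier(X[:100], y[:100])
        res = model.fit(n_draws=0, n_estimators=20, seed=0)
        _, _, macro, _ = confusion_and_f1(y[100:], res.predict(X[100:]), 4)
        assert macro <= 0.3  # no information -> no skill

    def test_random_search_reports_tuned_params(self, rng):
        X, y = _barcode_cohort(rng, per_class=20)
        model = BarcodeClassifier(X, y)
        res = model.fit(n_draws=3, n_estimators=20, seed=0)
        assert set(res.best_params) == {
            "learning_rate", "max_depth", "subsample", "colsample_bytree",
            "reg_lambda"}
        assert "tuned params" in res.summary()

    def test_degenerate_labels_rejected(self, rng):
        with pytest.raises(ValueError, match="degenerate"):
            BarcodeClassifier(rng.random((5, 4)), np.zeros(5, dtype=int))


class TestMonteCarloCV:
    def test_t_interval_hand_oracle(self):
        mean, hw = t_confidence_interval([0.6, 0.7, 0.8, 0.7, 0.7])
        assert mean == pytest.approx(0.70)
        assert hw == pytest.approx(0.0878, abs=2e-4)

    def test_constant_metric_zero_width(self, rng):
        X = rng.random((40, 4))
        y = np.repeat([0, 1], 20)
        res = monte_carlo_cv(
            X, y, patients=np.arange(40),
            fit_predict=lambda Xtr, ytr, Xv, s: np.zeros(len(Xv), dtype=int),
            metric=lambda a, b: 0.5, n_folds=5, holdout_frac=0.2, seed=0)
        assert res.ci_half_width == 0.0
        assert res.ci == (0.5, 0.5)

    def test_five_folds_by_default(self, rng):
        X, y = _barcode_cohort(rng, n_classes=2, per_class=25)
        res = monte_carlo_cv(
            X, y, patients=np.arange(len(y)),
            fit_predict=lambda Xtr, ytr, Xv, s: np.ones(len(Xv), dtype=int),
            holdout_frac=0.2, seed=0)
        assert len(res.fold_scores) == 5

    def test_patient_wise_holdout(self, rng):
        """All slides of a held-out patient leave the training fold."""
        X = rng.random((30, 3))
        y = np.repeat([0, 1], 15)
        patients = np.repeat(np.arange(10), 3)
        seen = []

        def fit_predict(Xtr, ytr, Xv, s):
            seen.append((len(Xtr), len(Xv)))
            return np.zeros(len(Xv), dtype=int)

        monte_carlo_cv(X, y, patients, fit_predict, n_folds=3,
                       holdout_frac=0.2, seed=1)
        for ntr, nv in seen:
            assert nv % 3 == 0  # whole patients (3 slides each) held out

    def test_bad_fold_count(self, rng):
        with pytest.raises(ValueError):
            monte_carlo_cv(rng.random((4, 2)), np.array([0, 1, 0, 1]),
                           np.arange(4), lambda *a: None, n_folds=1)
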