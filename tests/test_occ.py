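"""One-class classifiers: scores, threshold calibration and selection."""

import numpy as np
import pandas as pd
import pytest

from milkscreen.occ import (
    KNNOneClass,
    SIMCAOneClass,
    SVMOneClass,
    _holdout_size,
    evaluate,
    knn_grid,
    select_model,
    specificity,
)
from milkscreen.schema import FEATURES


@pytest.fixture(scope="module")
def X(control_features):
    return control_features


@pytest.fixture(scope="module")
def knn(X):
    return KNNOneClass(k=3, random_state=1).fit(X)


def brute_knn_score(train, z, k):
    """Exhaustive nearest-neighbour search oracle (autoscaled space)."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    T = (train - mu) / sd
    q = (z - mu) / sd
    d = np.sort(np.linalg.norm(T - q, axis=1))
    return d[:k].mean()


class TestKNNScore:
    def test_training_vector_scores_zero_at_k1(self, X):
        m = KNNOneClass(k=1, random_state=0).fit(X)
        assert m.raw_scores(X.iloc[[0]])[0] == pytest.approx(0.0, abs=1e-12)

    def test_feature_permutation_leaves_scores_unchanged(self, X, knn):
        permuted = X[list(reversed(FEATURES))]
        np.testing.assert_allclose(knn.raw_scores(permuted), knn.raw_scores(X), atol=1e-12)

    def test_matches_exhaustive_search_oracle(self, X, knn):
        rng = np.random.default_rng(9)
        M = X.to_numpy(dtype=float)
        # canonical row order used internally; the oracle sorts the same way
        M = M[np.lexsort(M.T[::-1])]
        for _ in range(10):
            z = M[rng.integers(len(M))] + rng.normal(0, 0.5, M.shape[1])
            got = knn.raw_scores(pd.DataFrame([z], columns=list(FEATURES)))[0]
            assert got == pytest.approx(brute_knn_score(M, z, k=3), abs=1e-9)

    def test_duplicating_a_training_point_never_raises_scores(self, X, knn):
        # neighbour improvement is a property of the distances themselves,
        # so compare within one fixed autoscaled space
        Z = ((X - knn.mean_) / knn.scale_).to_numpy()
        probe = Z + 0.3
        base = knn._score_inner(knn._fit_inner(Z), probe)
        dup = knn._score_inner(knn._fit_inner(np.vstack([Z, Z[4]])), probe)
        assert (dup <= base + 1e-12).all()

    def test_k_larger_than_training_fold_rejected(self, X):
        with pytest.raises(ValueError, match="k="):
            KNNOneClass(k=12, random_state=0).fit(X)


class TestSIMCAScore:
    def test_training_mean_has_zero_score_distance(self, X):
        m = SIMCAOneClass(n_factors=3, random_state=0).fit(X)
        center = pd.DataFrame([X.mean(axis=0)])
        od, sd = m.score_components(center)
        assert sd[0] == pytest.approx(0.0, abs=1e-9)

    def test_full_rank_reconstruction_has_zero_residual(self, X):
        m = SIMCAOneClass(n_factors=7, random_state=0).fit(X)
        od, _ = m.score_components(X)
        np.testing.assert_allclose(od, 0.0, atol=1e-9)

    def test_residual_matches_eigendecomposition_oracle(self, X):
        m = SIMCAOneClass(n_factors=3, random_state=0).fit(X)
        od, _ = m.score_components(X)
        # independent oracle: eigendecomposition of the covariance of the
        # autoscaled training data, residual = projection on trailing PCs
        Z = ((X - m.mean_) / m.scale_).to_numpy()
        Zc = Z - Z.mean(axis=0)
        w, V = np.linalg.eigh(np.cov(Zc, rowvar=False))
        trailing = V[:, np.argsort(w)[::-1][3:]]
        oracle = np.linalg.norm(Zc @ trailing, axis=1)
        got = np.sort(od)
        np.testing.assert_allclose(got, np.sort(oracle), atol=1e-9)

    def test_factors_beyond_rank_rejected(self, X):
        with pytest.raises(ValueError):
            SIMCAOneClass(n_factors=8, random_state=0).fit(X)


class TestSVMScore:
    def test_training_set_mostly_inside_at_small_nu(self, X):
        m = SVMOneClass(gamma=0.1, random_state=0).fit(X)
        assert evaluate(m, X) >= 90.0

    def test_tiny_gamma_flattens_the_decision_surface(self, X):
        m = SVMOneClass(gamma=1e-9, random_state=0).fit(X)
        scores = m.raw_scores(X)
        assert np.ptp(scores) < 1e-3  # near-degenerate single global region

    def test_duplicated_training_set_classifies_identically(self, X):
        m1 = SVMOneClass(gamma=0.1, random_state=0).fit(X)
        dup = pd.concat([X, X], ignore_index=True)
        m2 = SVMOneClass(gamma=0.1, random_state=0).fit(dup)
        probe = X * 1.05
        np.testing.assert_array_equal(m1.predict(probe), m2.predict(probe))

    def test_invalid_gamma_rejected(self, X):
        with pytest.raises(ValueError, match="gamma"):
            SVMOneClass(gamma=-1.0, random_state=0).fit(X)


class TestThresholdCalibration:
    def test_pooled_cv_coverage_at_least_99_percent(self, X):
        for cls in (KNNOneClass, SIMCAOneClass, SVMOneClass):
            m = cls(random_state=2).fit(X)
            inside = np.mean(m.cv_scores_ <= m.threshold_)
            assert inside >= 0.99, cls.__name__

    def test_same_seed_gives_identical_threshold(self, X):
        a = KNNOneClass(k=3, random_state=7).fit(X)
        b = KNNOneClass(k=3, random_state=7).fit(X)
        assert a.threshold_ == b.threshold_

    def test_holdout_rounding_half_up(self):
        assert _holdout_size(15, 0.30) == 5
        assert _holdout_size(10, 0.25) == 3  # 2.5 rounds up

    def test_smaller_alpha_gives_more_permissive_threshold(self, X):
        strict = KNNOneClass(k=3, alpha=0.10, random_state=3).fit(X)
        loose = KNNOneClass(k=3, alpha=0.01, random_state=3).fit(X)
        assert loose.threshold_ >= strict.threshold_

    def test_row_order_invariance(self, X):
        a = KNNOneClass(k=3, random_state=5).fit(X)
        b = KNNOneClass(k=3, random_state=5).fit(X.sample(frac=1.0, random_state=99))
        assert a.threshold_ == pytest.approx(b.threshold_, abs=1e-12)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_zero_repetitions_rejected(self, X):
        with pytest.raises(ValueError):
            KNNOneClass(repetitions=0, random_state=0).fit(X)


class TestEvaluation:
    def test_training_copies_are_fully_inside(self, X, knn):
        copies = pd.concat([X.iloc[:5]] * 3, ignore_index=True)
        assert evaluate(knn, copies) == pytest.approx(100.0)

    def test_empty_test_set_rejected(self, X, knn):
        with pytest.raises(ValueError):
            evaluate(knn, X.iloc[:0])

    def test_strong_water_dilutions_mostly_flagged(self, knn, adulterant_set):
        level4 = adulterant_set[(adulterant_set["category"] == "water")
                                & (adulterant_set["level"] == 4)]
        assert specificity(knn, level4) > 50.0


class TestModelSelection:
    def test_single_candidate_grid_returns_it(self, X, adulterant_set):
        best, res = select_model([KNNOneClass(k=4, random_state=1)], X, adulterant_set)
        assert best.k == 4 and len(res) == 1

    def test_tie_breaks_to_smaller_hyperparameter(self, X, adulterant_set):
        res = pd.DataFrame()
        a = KNNOneClass(k=2, random_state=1)
        b = KNNOneClass(k=3, random_state=1)
        best, res = select_model([b, a], X, adulterant_set)
        tied = res.loc[res["overall"] == res["overall"].max(), "param"]
        assert best.k == tied.min()

    def test_overall_performance_is_mean_of_cv_and_adulterant(self, X, adulterant_set):
        _, res = select_model([KNNOneClass(k=3, random_state=1)], X, adulterant_set)
        row = res.iloc[0]
        assert row["overall"] == pytest.approx(
            (row["cv_accuracy"] + row["adulterant_rejection"]) / 2
        )

    def test_empty_grid_rejected(self, X, adulterant_set):
        with pytest.raises(ValueError):
            select_model([], X, adulterant_set)


class TestParameterRecovery:
    """Selected models must separate strong adulterations from genuine milk."""

    @pytest.mark.parametrize("cls", [KNNOneClass, SIMCAOneClass, SVMOneClass])
    def test_level4_dilution_and_carbs_flagged_genuine_retained(
        self, cls, pools, stats, adulterant_set
    ):
        import milkscreen as ms

        train = ms.generate_controls(pools, stats, n=15, seed=101)[list(FEATURES)]
        held = ms.generate_controls(pools, stats, n=30, seed=202)[list(FEATURES)]
        m = cls(random_state=11).fit(train)
        strong = adulterant_set[
            (adulterant_set["level"] == 4)
            & adulterant_set["category"].isin(["water", "carbohydrate"])
        ]
        assert specificity(m, strong) > 80.0, cls.__name__
        assert evaluate(m, held) >= 90.0, cls.__name__
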