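import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from fieldqsar import (contour_grid, field_fraction, fit_pls,
                       fit_with_selection, loo_q2, model_search,
                       search_table, select_components)
from fieldqsar.fields import FieldConfig, assemble_fields, column_filter

RNG = np.random.default_rng(42)

# a fixed 6x4 "hand" dataset for oracle comparisons
X_HAND = np.array([
    [0.2, 1.1, -0.5, 0.7],
    [1.4, -0.3, 0.9, -1.2],
    [-0.7, 0.8, 1.3, 0.4],
    [0.9, -1.5, -0.2, 1.1],
    [-1.3, 0.6, 0.5, -0.8],
    [0.5, 0.2, -1.1, 0.3],
])
Y_HAND = np.array([5.1, 6.3, 4.8, 5.9, 4.2, 5.5])


def brute_force_loo_q2(X, y, ncomp):
    """Independent explicit leave-one-out loop, straight from the q2 formula."""
    n = len(y)
    preds = []
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        m = PLSRegression(n_components=ncomp, scale=False)
        m.fit(X[mask], y[mask])
        preds.append(m.predict(X[i:i + 1]).ravel()[0])
    preds = np.asarray(preds)
    return 1 - np.sum((y - preds) ** 2) / np.sum((y - y.mean()) ** 2), preds


class TestFitPLS:
    def test_exact_fit_on_rank_one_response(self):
        # y exactly linear in the single retained column: one component
        # captures everything
        X = RNG.normal(size=(10, 1))
        y = 2.0 * X[:, 0] + 1.0
        fit = fit_pls(X, y, 1)
        assert fit.r2_ncv >= 0.999

    def test_full_rank_equals_ols(self):
        ncomp = X_HAND.shape[1]
        fit = fit_pls(X_HAND, Y_HAND, ncomp)
        Xc = np.column_stack([np.ones(len(Y_HAND)), X_HAND])
        beta, *_ = np.linalg.lstsq(Xc, Y_HAND, rcond=None)
        ols_pred = Xc @ beta
        pls_pred = fit.predict_matrix(X_HAND)
        assert np.allclose(pls_pred, ols_pred, atol=1e-6)

    def test_scores_orthogonal(self):
        fit = fit_pls(X_HAND, Y_HAND, 3)
        T = fit.x_scores()
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8

    def test_bad_component_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_pls(X_HAND, Y_HAND, 0)
        with pytest.raises(ValueError):
            fit_pls(X_HAND, Y_HAND, 6)  # > n-1

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError):
            fit_pls(X_HAND, np.ones(6), 1)

    def test_see_convention(self):
        fit = fit_pls(X_HAND, Y_HAND, 2)
        rss = np.sum((Y_HAND - fit.predict_matrix(X_HAND)) ** 2)
        assert fit.see == pytest.approx(np.sqrt(rss / (6 - 2 - 1)))


class TestLOO:
    @pytest.mark.parametrize("ncomp", [1, 2, 3])
    def test_matches_brute_force_oracle(self, ncomp):
        res = loo_q2(X_HAND, Y_HAND, ncomp)
        q2_ref, preds_ref = brute_force_loo_q2(X_HAND, Y_HAND, ncomp)
        assert res.q2 == pytest.approx(q2_ref, abs=1e-10)
        assert np.allclose(res.predictions, preds_ref, atol=1e-10)

    def test_q2_equals_formula_on_stored_predictions(self):
        res = loo_q2(X_HAND, Y_HAND, 2)
        q2 = 1 - np.sum((Y_HAND - res.predictions) ** 2) \
            / np.sum((Y_HAND - Y_HAND.mean()) ** 2)
        assert res.q2 == q2

    def test_noiseless_linear_data_near_perfect(self):
        # adequate component count on noiseless linear data: LOO refits
        # reach the exact relation, so held-out predictions are near-perfect
        X = RNG.normal(size=(15, 6))
        y = X @ np.array([1.0, -0.5, 0, 0, 0.8, 0]) + 5
        assert loo_q2(X, y, 6).q2 >= 0.99

    def test_permuted_y_fails_under_null(self):
        X = RNG.normal(size=(12, 8))
        y = X[:, 0] * 2 + RNG.normal(size=12) * 0.1
        rng = np.random.default_rng(0)
        bad = sum(loo_q2(X, rng.permutation(y), 2).q2 < 0.5 for _ in range(50))
        assert bad >= 48  # >= 95% of 50 scrambles

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError):
            loo_q2(X_HAND, np.ones(6), 1)


class TestSelectComponents:
    def test_two_factor_recovery(self):
        rng = np.random.default_rng(3)
        T = rng.normal(size=(30, 2))
        P = rng.normal(size=(2, 10))
        X = T @ P + rng.normal(size=(30, 10)) * 0.05
        y = T @ np.array([1.0, -1.5]) + rng.normal(size=30) * 0.05
        n_star, profile = select_components(X, y, max_n=5)
        assert abs(n_star - 2) <= 1
        assert len(profile) == 5

    def test_max_n_one(self):
        n_star, _ = select_components(X_HAND, Y_HAND, max_n=1)
        assert n_star == 1

    def test_pure_noise_reported_not_raised(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        n_star, profile = select_components(X, y, max_n=3)
        assert 1 <= n_star <= 3
        assert np.isfinite(profile["q2"]).all()


class TestModelSearch:
    def test_comfa_two_fields_three_combos(self, small_xy):
        fm, y = small_xy
        results = model_search(fm, y, max_n=3)
        assert sorted(r.label for r in results) == ["E", "S", "SE"]

    def test_rank_order_non_increasing(self, small_xy):
        fm, y = small_xy
        results = model_search(fm, y, max_n=3)
        q2s = [r.fit.q2 for r in results]
        assert q2s == sorted(q2s, reverse=True)
        assert [r.rank for r in results] == [1, 2, 3]

    def test_comsia_five_fields_31_combos(self, small_set):
        mols, acts, truth = small_set
        y = np.array([a.pic50 for a in acts])
        cfg = FieldConfig(fields_enabled=("S", "E", "H", "D", "A"))
        fm = column_filter(
            assemble_fields(mols, truth.lattice, cfg, "comsia"), 0.05)
        results = model_search(fm, y, max_n=2)
        assert len(results) == 31
        table = search_table(results)
        assert set(table.columns) >= {"fields", "q2", "N", "SEE", "r2_ncv"}

    def test_row_permutation_invariance(self, small_xy):
        fm, y = small_xy
        fit = fit_with_selection(fm, y, max_n=3)
        perm = np.random.default_rng(1).permutation(len(y))
        from dataclasses import replace
        fm_p = replace(fm, values=fm.values[perm],
                       compound_ids=[fm.compound_ids[i] for i in perm])
        fit_p = fit_with_selection(fm_p, y[perm], max_n=3)
        assert fit_p.q2 == pytest.approx(fit.q2, abs=1e-8)
        assert fit_p.r2_ncv == pytest.approx(fit.r2_ncv, abs=1e-8)
        assert np.allclose(fit_p.coefficients, fit.coefficients, atol=1e-8)


class TestFieldFraction:
    def test_single_block_is_100(self, small_xy):
        fm, y = small_xy
        fit = fit_pls(fm.subset_fields(["S"]), y, 2)
        frac = field_fraction(fit)
        assert frac["comfa:S"] == pytest.approx(100.0)

    def test_duplicated_block_splits_evenly(self, small_xy):
        from dataclasses import replace
        fm, y = small_xy
        sub = fm.subset_fields(["S"])
        dup = replace(
            sub,
            values=np.hstack([sub.values, sub.values]),
            field_labels=np.concatenate(
                [sub.field_labels,
                 np.array(["comfa:E"] * sub.values.shape[1])]),
            point_indices=np.concatenate([sub.point_indices, sub.point_indices]),
            block_scale={**sub.block_scale,
                         "comfa:E": sub.block_scale["comfa:S"]},
            column_mask=np.concatenate([sub.column_mask, sub.column_mask]))
        fit = fit_pls(dup, y, 2)
        frac = field_fraction(fit)
        assert frac["comfa:S"] == pytest.approx(50.0, abs=0.1)
        assert frac["comfa:E"] == pytest.approx(50.0, abs=0.1)

    def test_fractions_sum_to_100(self, small_xy):
        fm, y = small_xy
        fit = fit_pls(fm, y, 2)
        assert sum(field_fraction(fit).values()) == pytest.approx(100.0, abs=0.01)


class TestContours:
    def test_percentile_counts_on_distinct_values(self):
        # 80/20 thresholds on 100 distinct values select exactly 20 + 20
        from fieldqsar.pls import threshold_points
        v = np.random.default_rng(0).permutation(100).astype(float)
        fav, dis = threshold_points(v, 80, 20)
        assert fav.sum() == 20
        assert dis.sum() == 20
        assert not np.any(fav & dis)

    def test_negating_y_swaps_favored_disfavored(self, small_xy):
        fm, y = small_xy
        fit = fit_pls(fm, y, 2)
        fit_neg = fit_pls(fm, -y, 2)
        cs = contour_grid(fit)
        cs_neg = contour_grid(fit_neg)
        for letter in cs:
            assert set(cs[letter].favored_points) \
                == set(cs_neg[letter].disfavored_points)
            assert set(cs[letter].disfavored_points) \
                == set(cs_neg[letter].favored_points)

    def test_planted_region_recovered(self, small_set, small_xy):
        _, _, truth = small_set
        fm, y = small_xy
        fit = fit_with_selection(fm.subset_fields(["S"]), y, max_n=3)
        cs = contour_grid(fit)["S"]
        retained = set(int(p) for p in cs.point_indices)
        planted = set(int(p) for p in truth.positive_points) & retained
        fav = set(int(p) for p in cs.favored_points)
        jac = len(fav & planted) / len(fav | planted)
        assert jac >= 0.5


def test_masked_column_never_changes_statistics(small_xy):
    fm, y = small_xy
    from dataclasses import replace
    # append a wild column that the mask excludes
    wild = np.linspace(-100, 100, fm.values.shape[0])[:, None]
    fm2 = replace(fm, values=np.hstack([fm.values, wild]),
                  field_labels=np.concatenate([fm.field_labels,
                                               [fm.field_labels[0]]]),
                  point_indices=np.concatenate([fm.point_indices, [0]]),
                  column_mask=np.concatenate([fm.column_mask, [False]]))
    f1 = fit_with_selection(fm, y, max_n=2)
    f2 = fit_with_selection(fm2, y, max_n=2)
    assert f2.q2 == pytest.approx(f1.q2, abs=1e-12)
    assert f2.r2_ncv == pytest.approx(f1.r2_ncv, abs=1e-12)
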