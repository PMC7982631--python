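import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, spearmanr
from sklearn.base import clone

from careindex.errors import (CoverageError, DegenerateDataError,
                              InsufficientDataError)
from careindex.indices import INDEX_COLUMNS, index_table
from careindex.qci import (AGGREGATION_LEVELS, QualityOfCareIndex,
                           aggregate_qci, fit_qci, fit_qci_from_panels,
                           score_qci)


def brute_force_pca(X):
    """Independent correlation-matrix eigendecomposition: standardize by
    explicit column means/sds, form the correlation matrix elementwise, and
    take the eigenvector of the largest eigenvalue via numpy's general
    (non-symmetric) eigensolver."""
    X = np.asarray(X, float)
    n, p = X.shape
    Z = np.empty_like(X)
    for j in range(p):
        Z[:, j] = (X[:, j] - X[:, j].mean()) / X[:, j].std(ddof=1)
    corr = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            corr[i, j] = np.sum(Z[:, i] * Z[:, j]) / (n - 1)
    eigvals, eigvecs = np.linalg.eig(corr)
    k = int(np.argmax(eigvals.real))
    return eigvecs[:, k].real, eigvals[k].real / p


def random_matrix(rng, n=None):
    n = n if n is not None else int(rng.integers(3, 21))
    X = rng.lognormal(0.0, 1.0, size=(n, 4))
    while np.any(X.std(axis=0, ddof=1) == 0):  # pragma: no cover
        X = rng.lognormal(0.0, 1.0, size=(n, 4))
    return X


class TestFit:
    def test_matches_brute_force_eigendecomposition(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            X = random_matrix(rng)
            model = fit_qci(X)
            ref_vec, ref_var = brute_force_pca(X)
            dot = abs(float(model.loadings_ @ ref_vec))
            assert dot == pytest.approx(1.0, abs=1e-8)
            assert model.variance_explained_ == pytest.approx(ref_var, abs=1e-8)

    def test_two_distinct_rows_explain_everything(self):
        X = np.array([[0.1, 0.5, 8.0, 7.0], [0.3, 0.9, 5.0, 9.0]])
        model = fit_qci(X)
        assert model.variance_explained_ == pytest.approx(1.0, abs=1e-12)

    def test_constant_column_raises_naming_the_index(self):
        X = np.array([[0.1, 0.5, 8.0, 7.0],
                      [0.1, 0.9, 5.0, 9.0],
                      [0.1, 0.7, 6.0, 8.0]])
        with pytest.raises(DegenerateDataError, match="mir"):
            fit_qci(X)

    def test_single_row_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fit_qci(np.array([[0.1, 0.5, 8.0, 7.0]]))

    def test_loadings_unit_norm_and_anti_mir_orientation(self, fitted):
        model, vectors = fitted
        assert np.linalg.norm(model.loadings_) == pytest.approx(1.0, abs=1e-12)
        scores, _ = score_qci(model, vectors)
        r = pearsonr(scores["raw_score"], vectors.loc[vectors["valid"], "mir"])[0]
        assert r <= 0
        assert model.orientation_ * model.loadings_[0] <= 0


class TestScore:
    def test_fitting_set_attains_both_endpoints(self, fitted):
        model, vectors = fitted
        scores, _ = score_qci(model, vectors)
        assert scores["qci"].max() == pytest.approx(100.0, abs=1e-12)
        assert scores["qci"].min() == pytest.approx(0.0, abs=1e-12)
        assert not scores["clipped"].any()

    def test_refit_scoring_reproduces_fit_scores_exactly(self, fitted):
        model, vectors = fitted
        a, _ = score_qci(model, vectors)
        b, _ = score_qci(model, vectors.copy())
        assert (a["raw_score"].to_numpy() == b["raw_score"].to_numpy()).all()

    def test_out_of_range_vector_clips_to_100(self, fitted):
        model, vectors = fitted
        best = vectors[vectors["valid"]].copy().head(1)
        best["mir"] = 0.0            # no deaths at all: better than anything fit
        best["yll_yld"] = 0.0
        best["prev_inc"] = vectors["prev_inc"].max() * 10
        scores, _ = score_qci(model, best)
        assert scores.iloc[0]["qci"] == 100.0
        assert bool(scores.iloc[0]["clipped"])

    def test_invalid_vectors_skipped_with_audit(self, fitted):
        model, vectors = fitted
        vectors = vectors.copy()
        vectors.loc[vectors.index[:3], "valid"] = False
        vectors.loc[vectors.index[:3], "reason"] = "undefined ratio(s): mir"
        scores, audit = score_qci(model, vectors)
        assert len(audit) == 3 and len(scores) == len(vectors) - 3
        assert (audit["reason"] == "undefined ratio(s): mir").all()

    def test_rescale_is_affine(self, fitted):
        model, vectors = fitted
        scores, _ = score_qci(model, vectors)
        un = scores[~scores["clipped"]]
        assert pearsonr(un["raw_score"], un["qci"])[0] == pytest.approx(1.0, abs=1e-12)

    def test_increasing_mir_never_raises_qci(self, fitted):
        model, vectors = fitted
        row = vectors[vectors["valid"]].head(1).copy()
        base = score_qci(model, row)[0].iloc[0]["qci"]
        for bump in (1.5, 3.0, 10.0):
            worse = row.copy()
            worse["mir"] = row["mir"] * bump
            assert score_qci(model, worse)[0].iloc[0]["qci"] <= base + 1e-12


class TestRecovery:
    def test_noiseless_panel_recovers_latent_quality_exactly(self, noiseless_run):
        _, _, truth, panels = noiseless_run
        model, _ = fit_qci_from_panels(panels)
        agg = aggregate_qci(model, panels, "location")
        q = pd.Series(truth.quality)
        rho = spearmanr(q, agg.set_index("location")["qci"].reindex(q.index)).statistic
        assert rho == 1.0


class TestSerialization:
    def test_text_round_trip_is_exact(self, fitted):
        model, vectors = fitted
        back = QualityOfCareIndex.from_text(model.to_text())
        np.testing.assert_array_equal(back.loadings_, model.loadings_)
        np.testing.assert_array_equal(back.means_, model.means_)
        np.testing.assert_array_equal(back.sds_, model.sds_)
        assert (back.orientation_, back.score_min_, back.score_max_, back.fit_n_) == \
            (model.orientation_, model.score_min_, model.score_max_, model.fit_n_)
        X = vectors.loc[vectors["valid"], list(INDEX_COLUMNS)].to_numpy(float)
        np.testing.assert_array_equal(back.raw_score(X), model.raw_score(X))


class TestSklearnApi:
    def test_params_clone_and_transform_shape(self):
        rng = np.random.default_rng(0)
        X = random_matrix(rng, n=12)
        model = QualityOfCareIndex(clip=False)
        assert model.get_params() == {"clip": False}
        cloned = clone(model).set_params(clip=True)
        out = cloned.fit_transform(X)
        assert out.shape == (12, 1)
        assert cloned.get_feature_names_out().tolist() == ["qci"]

    def test_works_in_a_pipeline(self):
        from sklearn.pipeline import Pipeline
        rng = np.random.default_rng(1)
        X = random_matrix(rng, n=15)
        pipe = Pipeline([("qci", QualityOfCareIndex())])
        assert pipe.fit_transform(X).shape == (15, 1)


class TestAggregate:
    def test_single_stratum_aggregate_is_identity(self, fitted, noiseless_run):
        model, vectors = fitted
        panels = noiseless_run[3]
        one = panels.head(1)
        agg = aggregate_qci(model, one, "all_age", check_coverage=False)
        direct, _ = score_qci(model, index_table(one))
        assert agg.iloc[0]["qci"] == pytest.approx(direct.iloc[0]["qci"], abs=1e-12)

    def test_homogeneous_strata_aggregate_to_same_score(self, fitted):
        model, _ = fitted
        rows = pd.DataFrame([
            {"location": "X", "year": 2017, "sex": "female", "age_group": a,
             "incidence": 10.0, "prevalence": 80.0, "deaths": 1.6,
             "dalys": 42.0, "ylls": 37.0, "ylds": 5.0}
            for a in ("50 to 54", "55 to 59")
        ])
        agg = aggregate_qci(model, rows, "all_age", check_coverage=False)
        direct, _ = score_qci(model, index_table(rows.head(1)))
        assert agg.iloc[0]["qci"] == pytest.approx(direct.iloc[0]["qci"], rel=1e-12)

    def test_three_stratum_hand_summed_oracle(self, fitted, noiseless_run):
        model, _ = fitted
        panels = noiseless_run[3]
        grp = panels[(panels.location == "Location 001")
                     & (panels.year == 2017) & (panels.sex == "female")].head(3)
        agg = aggregate_qci(model, grp, "all_age", check_coverage=False)
        summed = grp[["incidence", "prevalence", "deaths",
                      "dalys", "ylls", "ylds"]].sum()
        hand = pd.DataFrame([{"location": "Location 001", "year": 2017,
                              "sex": "female", "age_group": "All Ages",
                              **summed.to_dict()}])
        direct, _ = score_qci(model, index_table(hand))
        assert agg.iloc[0]["qci"] == pytest.approx(direct.iloc[0]["qci"], rel=1e-12)

    def test_aggregate_never_averages_scores(self, fitted, noiseless_run):
        """Count-weighted recomputation differs from the mean of scores."""
        model, vectors = fitted
        panels = noiseless_run[3]
        agg = aggregate_qci(model, panels, "location")
        scores, _ = score_qci(model, vectors)
        means = scores.groupby("location")["qci"].mean()
        merged = agg.set_index("location")["qci"]
        assert not np.allclose(merged.to_numpy(), means.reindex(merged.index))

    def test_missing_constituent_raises_coverage_error(self, fitted, noiseless_run):
        model, _ = fitted
        panels = noiseless_run[3]
        holed = panels[~((panels.location == "Location 001")
                         & (panels.age_group == "0 to 4"))]
        with pytest.raises(CoverageError, match="Location 001"):
            aggregate_qci(model, holed, "all_age")

    def test_levels_cover_documented_grid(self, fitted, noiseless_run):
        model, _ = fitted
        panels = noiseless_run[3]
        for level, cols in AGGREGATION_LEVELS.items():
            agg = aggregate_qci(model, panels, level)
            assert list(agg.columns[:len(cols)]) == cols
            assert len(agg) == panels.groupby(cols).ngroups
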