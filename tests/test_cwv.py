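"""Community-weighted mean/variance and the functional-variance PCA."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA as SKPCA

from funcvar.cwv import (
    convergence_half_life, correlate_pc1_dispersion, cwm, cwm_matrix, cwv,
    cwv_matrix, functional_variance_pc1, pca, pca_of_cwv, theil_sen_slope,
)
from funcvar.diversity import CommunityMatrix, relative_abundance
from funcvar.traits import FUZZY, QUANTITATIVE, TraitMeta, expand_and_scale
from funcvar.synthetic import SyntheticConfig, generate_species_pool, generate_survey
from conftest import make_community, make_trait_table, random_trait_table
from oracles import cwm_loop, cwv_loop


class TestScalarCwmCwv:
    def test_single_species_returns_its_row_and_zero_variance(self):
        X = np.array([[1.5, -2.0, 0.3]])
        p = np.array([1.0])
        np.testing.assert_allclose(cwm(p, X), X[0])
        np.testing.assert_allclose(cwv(p, X), np.zeros(3))

    def test_even_binary_trait(self):
        p = np.array([0.5, 0.5])
        X = np.array([[0.0], [1.0]])
        assert cwm(p, X)[0] == pytest.approx(0.5)
        assert cwv(p, X)[0] == pytest.approx(0.25)

    def test_skewed_binary_trait(self):
        p = np.array([0.9, 0.1])
        X = np.array([[0.0], [1.0]])
        assert cwv(p, X)[0] == pytest.approx(0.09, abs=1e-12)

    def test_matches_loop_oracles(self, rng):
        for _ in range(50):
            n, t = int(rng.integers(1, 9)), int(rng.integers(1, 6))
            a = rng.uniform(0.01, 1, n)
            p = a / a.sum()
            X = rng.normal(0, 3, (n, t))
            np.testing.assert_allclose(cwm(p, X), cwm_loop(p, X), atol=1e-12)
            np.testing.assert_allclose(cwv(p, X), cwv_loop(p, X), atol=1e-12)

    def test_two_pass_and_moment_forms_agree(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 10))
            a = rng.uniform(0.01, 1, n)
            p = a / a.sum()
            X = rng.normal(0, 5, (n, 4))
            moment = p @ X**2 - (p @ X) ** 2
            np.testing.assert_allclose(cwv(p, X), moment, atol=1e-10)

    def test_nonnegative_and_zero_iff_shared_value(self, rng):
        p = np.array([0.3, 0.7])
        X = np.array([[2.0, 1.0], [2.0, 3.0]])
        v = cwv(p, X)
        assert v[0] == 0.0
        assert v[1] > 0
        for _ in range(20):
            n = int(rng.integers(2, 8))
            a = rng.uniform(0.01, 1, n)
            assert np.all(cwv(a / a.sum(), rng.normal(size=(n, 3))) >= 0)

    def test_crisp_fuzzy_column_gives_bernoulli_variance(self):
        # memberships in {0,1}: CWV = q(1-q), q the weighted category frequency
        tt = make_trait_table(
            {"diet.b": [1.0, 0.0, 1.0], "diet.f": [0.0, 1.0, 0.0]},
            [TraitMeta(name="diet", type=FUZZY, categories=["b", "f"])],
        )
        X = expand_and_scale(tt)
        ab = np.array([[2.0, 1.0, 1.0]])
        cm = make_community(ab, tt.species_ids)
        V = cwv_matrix(cm, X)
        q = 0.75  # weighted frequency of category b
        assert V.iloc[0]["diet.b"] == pytest.approx(q * (1 - q), abs=1e-12)
        assert V.iloc[0]["diet.f"] == pytest.approx(q * (1 - q), abs=1e-12)


class TestCwvMatrix:
    def test_monodominant_station_is_zero_row(self, rng):
        tt = random_trait_table(rng, 4)
        X = expand_and_scale(tt)
        ab = np.array([[0.0, 3.0, 0.0, 0.0]])
        V = cwv_matrix(make_community(ab, tt.species_ids), X)
        np.testing.assert_allclose(V.to_numpy(), 0.0, atol=1e-15)

    def test_identical_stations_identical_rows(self, rng):
        tt = random_trait_table(rng, 5)
        X = expand_and_scale(tt)
        row = rng.uniform(0, 2, 5)
        V = cwv_matrix(make_community(np.tile(row, (2, 1)), tt.species_ids), X)
        np.testing.assert_allclose(V.iloc[0], V.iloc[1], atol=0)

    def test_every_cell_matches_scalar_oracle(self, rng):
        tt = random_trait_table(rng, 6)
        X = expand_and_scale(tt)
        ab = rng.uniform(0, 2, (8, 6))
        ab[ab < 0.4] = 0.0
        ab[:, 0] += 0.1  # keep every station occupied
        cm = make_community(ab, tt.species_ids)
        V = cwv_matrix(cm, X)
        M = cwm_matrix(cm, X)
        Xv = X.values.to_numpy()
        for k in range(ab.shape[0]):
            p, present = relative_abundance(ab[k])
            np.testing.assert_allclose(V.iloc[k], cwv_loop(p, Xv[present]), atol=1e-12)
            np.testing.assert_allclose(M.iloc[k], cwm_loop(p, Xv[present]), atol=1e-12)

    def test_cwm_bounded_by_present_species_values(self, rng):
        tt = random_trait_table(rng, 6)
        X = expand_and_scale(tt)
        ab = rng.uniform(0.1, 2, (5, 6))
        M = cwm_matrix(make_community(ab, tt.species_ids), X)
        Xv = X.values.to_numpy()
        assert np.all(M.to_numpy() <= Xv.max(axis=0) + 1e-12)
        assert np.all(M.to_numpy() >= Xv.min(axis=0) - 1e-12)


class TestPCA:
    def test_single_varying_column_concentrates_pc1(self):
        M = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": 1.0, "c": -2.0})
        res = pca(M)
        assert res.explained[0] == pytest.approx(1.0)
        assert abs(res.loadings.loc["a", "PC1"]) == pytest.approx(1.0)

    def test_two_perfectly_correlated_columns(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        M = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = pca(M)
        assert res.explained[0] == pytest.approx(1.0)
        l1 = res.loadings["PC1"].abs()
        # loadings proportional to column sds (1 : 2 here)
        assert l1["b"] / l1["a"] == pytest.approx(2.0, abs=1e-10)

    def test_reconstruction_and_explained_sum(self, rng):
        M = pd.DataFrame(rng.normal(0, 2, (20, 6)))
        res = pca(M)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T + res.center
        np.testing.assert_allclose(recon, M.to_numpy(), atol=1e-10)
        assert res.explained.sum() == pytest.approx(1.0, abs=1e-10)
        # loadings orthonormal, scores uncorrelated across components
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(6), atol=1e-10)
        S = res.scores.to_numpy()
        corr = np.corrcoef(S, rowvar=False)
        assert np.all(np.abs(corr - np.eye(6)) < 1e-8)

    def test_agrees_with_sklearn(self, rng):
        M = pd.DataFrame(rng.normal(0, 1, (30, 5)))
        res = pca(M)
        sk = SKPCA(n_components=5).fit(M.to_numpy())
        np.testing.assert_allclose(
            res.explained, sk.explained_variance_ratio_, atol=1e-10
        )
        # scores agree up to per-component sign
        sk_scores = sk.transform(M.to_numpy())
        for k in range(5):
            ours = res.scores.iloc[:, k].to_numpy()
            sign = np.sign(np.dot(ours, sk_scores[:, k]))
            np.testing.assert_allclose(ours, sign * sk_scores[:, k], atol=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pca(pd.DataFrame({"a": [1.0]}))
        with pytest.raises(ValueError, match="no variance"):
            pca(pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]}))

    def test_scale_columns_changes_decomposition_but_not_sum(self, rng):
        M = pd.DataFrame(rng.normal(0, 1, (25, 4)) * np.array([1, 10, 0.1, 5]))
        r1, r2 = pca(M), pca(M, scale_columns=True)
        assert not np.allclose(r1.explained, r2.explained)
        assert r2.explained.sum() == pytest.approx(1.0, abs=1e-10)

    def test_pc1_sign_oriented_against_dispersion(self, rng):
        M = pd.DataFrame(rng.normal(0, 2, (30, 4)))
        base = pca(M)
        q = pd.Series(-base.scores["PC1"].to_numpy(), index=M.index)  # anti-aligned
        res = pca_of_cwv(M, rao_q_values=q)
        s = res.scores["PC1"].to_numpy()
        assert np.corrcoef(s, q.to_numpy())[0, 1] >= 0
        assert res.sign_convention == "corr(PC1, RaoQ) >= 0"


class TestCorrelation:
    def test_identical_vectors_give_one(self):
        x = pd.Series([1.0, 2.0, 5.0])
        assert correlate_pc1_dispersion(x, x) == pytest.approx(1.0)

    def test_orthogonal_residual_gives_zero(self, rng):
        x = rng.normal(0, 1, 50)
        y = rng.normal(0, 1, 50)
        resid = y - np.polyval(np.polyfit(x, y, 1), x)
        r2 = correlate_pc1_dispersion(pd.Series(x), pd.Series(resid))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_covariance_formula(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        r2 = correlate_pc1_dispersion(pd.Series(x), pd.Series(y))
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = (cov / (x.std() * y.std())) ** 2
        assert r2 == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate_pc1_dispersion(pd.Series([1.0, 1.0]), pd.Series([1.0, 2.0]))


class TestFunctionalVariancePipeline:
    def test_identical_stations_degenerate(self, rng):
        tt = random_trait_table(rng, 5)
        row = rng.uniform(0.5, 2, 5)
        cm = make_community(np.tile(row, (4, 1)), tt.species_ids)
        with pytest.raises(ValueError, match="no variance"):
            functional_variance_pc1(cm, tt)

    def test_borealization_survey_arctic_trend_positive(self):
        cfg = SyntheticConfig(seed=11)
        tt, pools = generate_species_pool(cfg)
        cm = generate_survey(cfg, pools)
        fv = functional_variance_pc1(cm, tt)
        reg = fv.regional_means
        arctic = reg[reg.region == "arctic"].set_index("year")["PC1"]
        assert theil_sen_slope(arctic.to_numpy()) > 0
        assert fv.r2_with_dispersion > 0.5
        # trait ranking covers every expanded column, sorted by |loading|
        assert len(fv.trait_ranking) == fv.pca_result.loadings.shape[0]
        mags = fv.trait_ranking["loading"].abs().to_numpy()
        assert all(a >= b for a, b in zip(mags, mags[1:]))

    def test_pipeline_invariant_to_station_and_species_order(self, rng):
        cfg = SyntheticConfig(seed=5, n_stations_per_region_year=4, last_year=2008)
        tt, pools = generate_species_pool(cfg)
        cm = generate_survey(cfg, pools)
        fv1 = functional_variance_pc1(cm, tt)
        sp_perm = list(rng.permutation(tt.species_ids))
        st_perm = list(rng.permutation(cm.station_ids))
        from funcvar.traits import TraitTable
        tt2 = TraitTable(
            species_ids=sp_perm, values=tt.values.loc[sp_perm],
            trait_meta=tt.trait_meta,
        )
        cm2 = CommunityMatrix(
            abundance=cm.abundance.loc[st_perm, sp_perm],
            station_meta=cm.station_meta.loc[st_perm],
        )
        fv2 = functional_variance_pc1(cm2, tt2)
        s1 = fv1.per_station.loc[st_perm, "PC1"]
        s2 = fv2.per_station["PC1"]
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-8)


class TestTrendHelpers:
    def test_theil_sen_recovers_linear_slope(self):
        y = 2.5 * np.arange(10) + 1.0
        assert theil_sen_slope(y) == pytest.approx(2.5)

    def test_half_life_on_geometric_gap(self):
        years = list(range(2004, 2010))
        a = pd.Series([0.0] * 6, index=years)
        b = pd.Series([8.0, 6.0, 4.0, 3.0, 2.0, 1.0], index=years)
        assert convergence_half_life(a, b) == 2006
        assert convergence_half_life(a, a) == 2004
        c = pd.Series([8.0] * 6, index=years)
        assert convergence_half_life(a, c) is None
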