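"""Reliability screening, isometric size, shape PCA, ratio spectrum, tests."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chemotaxa import morpho, synthetic
from chemotaxa.synthetic import ScenarioConfig


def _long(values: np.ndarray, repeats: int = 1, labels=None) -> morpho.MorphTable:
    n, p = values.shape
    rows = []
    for i in range(n):
        for r in range(1, repeats + 1):
            for j in range(p):
                rows.append({
                    "individual": f"i{i}", "repeat": r, "variable": f"v{j}",
                    "value": values[i, j],
                    "species": (labels[i] if labels is not None else "A"),
                    "location": "L1",
                })
    return morpho.MorphTable(pd.DataFrame(rows))


class TestIcc:
    def test_identical_repeats_give_one(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 2, size=(10, 3))
        mt = _long(vals, repeats=2)
        report, _ = morpho.icc_reliability(mt)
        assert np.allclose(report["icc"], 1.0)

    def test_pure_noise_repeats_dropped(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(40):
            for r in (1, 2):
                rows.append({"individual": f"i{i}", "repeat": r, "variable": "v0",
                             "value": 10.0 + rng.normal(0, 1.0)})
        report, kept = morpho.icc_reliability(morpho.MorphTable(pd.DataFrame(rows)))
        assert report["icc"].iloc[0] < 0.85
        assert not report["keep"].iloc[0]

    def test_matches_pingouin_icc1(self):
        import pingouin as pg

        rng = np.random.default_rng(2)
        mu = rng.normal(10, 3, size=25)
        vals = mu[:, None] + rng.normal(0, 1, size=(25, 2)) + 30
        rows = []
        for i in range(25):
            for r in (1, 2):
                rows.append({"individual": i, "repeat": r, "variable": "v0",
                             "value": vals[i, r - 1]})
        df = pd.DataFrame(rows)
        report, _ = morpho.icc_reliability(morpho.MorphTable(df))
        ref = pg.intraclass_corr(data=df, targets="individual", raters="repeat",
                                 ratings="value")
        icc1 = ref.loc[ref["Type"] == "ICC(1,1)", "ICC"].iloc[0]
        assert report["icc"].iloc[0] == pytest.approx(icc1, abs=1e-9)

    def test_simulated_variance_ratio_recovers_closed_form(self):
        # between-individual var 9, within var 1, k=2 -> ICC = 9/10
        iccs = []
        for s in range(30):
            rng = np.random.default_rng(s)
            mu = rng.normal(0, 3, size=200)
            vals = mu[:, None] + rng.normal(0, 1, size=(200, 2)) + 50
            rows = [{"individual": i, "repeat": r + 1, "variable": "v",
                     "value": vals[i, r]} for i in range(200) for r in (0, 1)]
            rep, _ = morpho.icc_reliability(morpho.MorphTable(pd.DataFrame(rows)))
            iccs.append(rep["icc"].iloc[0])
        assert np.mean(iccs) == pytest.approx(0.9, abs=0.05)


class TestSizeAndShape:
    def test_geometric_mean_examples(self):
        vals = pd.DataFrame([[2.0, 8.0], [3.0, 3.0]], columns=["a", "b"])
        g = morpho.isometric_size(vals)
        assert g.iloc[0] == pytest.approx(4.0)
        assert g.iloc[1] == pytest.approx(3.0)

    def test_gm_below_arithmetic_mean(self):
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(rng.uniform(0.5, 5, size=(20, 6)))
        assert (morpho.isometric_size(vals) <= vals.mean(axis=1) + 1e-12).all()

    def test_isometric_rescaling_leaves_shape_scores(self):
        rng = np.random.default_rng(4)
        vals = pd.DataFrame(np.exp(rng.normal(5, 0.3, size=(15, 6))))
        shape1 = morpho.shape_pca(vals)
        scaled = vals.copy()
        scaled.iloc[0] *= 10.0
        shape2 = morpho.shape_pca(scaled)
        assert np.allclose(shape1.shape_scores.values, shape2.shape_scores.values,
                           atol=1e-9)

    def test_pure_isometric_data_has_no_shape_variance(self):
        template = np.array([1.0, 2.0, 4.0, 0.5])
        scales = np.linspace(0.5, 3.0, 10)
        vals = pd.DataFrame(np.outer(scales, template))
        shape = morpho.shape_pca(vals)
        total_var = shape.shape_scores.values.var(axis=0).sum()
        assert total_var == pytest.approx(0.0, abs=1e-18)

    def test_log_data_reconstructs_from_size_and_shape(self):
        rng = np.random.default_rng(5)
        vals = pd.DataFrame(np.exp(rng.normal(5, 0.3, size=(12, 5))))
        shape = morpho.shape_pca(vals)
        p = vals.shape[1]
        u = np.ones(p) / np.sqrt(p)
        iso_part = np.outer(shape.log_iso.values * np.sqrt(p), u)
        shape_part = (shape.shape_scores.values @ shape.shape_loadings.values.T
                      + shape.mean_log_projected.values)
        assert np.allclose(iso_part + shape_part, np.log(vals.values), atol=1e-9)

    def test_loadings_orthogonal_to_isometry(self):
        rng = np.random.default_rng(6)
        vals = pd.DataFrame(np.exp(rng.normal(5, 0.3, size=(30, 6))))
        shape = morpho.shape_pca(vals)
        p = vals.shape[1]
        u = np.ones(p) / np.sqrt(p)
        # axes with non-zero variance must be orthogonal to u
        keep = shape.eigen_pct > 1e-8
        dots = shape.shape_loadings.values[:, keep].T @ u
        assert np.allclose(dots, 0.0, atol=1e-8)


class TestRatioSpectrum:
    def _fit(self, seed=7, n=40):
        rng = np.random.default_rng(seed)
        logs = rng.normal(0, 0.05, size=(n, 5)) + rng.normal(0, 0.2, size=(n, 1))
        logs[:, 0] += np.linspace(-0.5, 0.5, n)  # dominant contrast on v0
        vals = pd.DataFrame(np.exp(logs), columns=[f"v{j}" for j in range(5)])
        return vals, morpho.shape_pca(vals)

    def test_variables_ordered_by_loading(self):
        vals, shape = self._fit()
        spec = morpho.pca_ratio_spectrum(shape, vals, axis=0, n_boot=0)
        assert list(spec["loading"]) == sorted(spec["loading"], reverse=True)

    def test_extreme_pair_identifies_contrast(self):
        vals, shape = self._fit()
        spec = morpho.pca_ratio_spectrum(shape, vals, axis=0, n_boot=0)
        assert "v0" in (spec.index[0], spec.index[-1])

    def test_no_bootstrap_means_no_ci_columns(self):
        vals, shape = self._fit()
        spec = morpho.pca_ratio_spectrum(shape, vals, axis=0, n_boot=0)
        assert "ci_low" not in spec.columns

    def test_bootstrap_ci_separates_dominant_variable(self):
        hits = 0
        for seed in range(10):
            vals, shape = self._fit(seed=100 + seed)
            spec = morpho.pca_ratio_spectrum(shape, vals, axis=0, n_boot=100,
                                             seed=seed)
            extreme = "v0"
            middle = [v for v in spec.index if v != extreme][1:-1]
            lo, hi = spec.loc[extreme, ["ci_low", "ci_high"]]
            mid_loadings = spec.loc[middle, "loading"]
            hits += ((mid_loadings < lo) | (mid_loadings > hi)).all()
        assert hits >= 9

    def test_axis_out_of_range(self):
        vals, shape = self._fit()
        with pytest.raises(ValueError, match="out of range"):
            morpho.pca_ratio_spectrum(shape, vals, axis=99, n_boot=0)


class TestManova:
    def test_matches_statsmodels_single_factor_pillai(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(8)
        Y = pd.DataFrame(rng.normal(size=(30, 2)), columns=["y1", "y2"])
        species = pd.Series(["A"] * 15 + ["B"] * 15)
        mine = morpho.two_group_manova(Y, species)
        df = Y.copy()
        df["species"] = species.values
        ref = MANOVA.from_formula("y1 + y2 ~ species", data=df).mv_test()
        tab = ref.results["species"]["stat"].loc["Pillai's trace"]
        assert mine.loc["species", "pillai"] == pytest.approx(tab["Value"], abs=1e-9)
        assert mine.loc["species", "p"] == pytest.approx(tab["Pr > F"], abs=1e-9)

    def test_single_response_reduces_to_sequential_anova(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(9)
        y = rng.normal(size=40)
        species = pd.Series(["A"] * 20 + ["B"] * 20)
        loc = pd.Series(list("wxyz") * 10)
        mine = morpho.two_group_manova(pd.DataFrame({"y": y}), species, loc)
        ref = anova_lm(
            smf.ols("y ~ species + loc",
                    data=pd.DataFrame({"y": y, "species": species, "loc": loc})).fit(),
            typ=1,
        )
        assert mine.loc["species", "p"] == pytest.approx(ref.loc["species", "PR(>F)"],
                                                         abs=1e-9)
        assert mine.loc["location", "p"] == pytest.approx(ref.loc["loc", "PR(>F)"],
                                                          abs=1e-9)

    def test_perfect_separation_gives_tiny_p(self):
        Y = pd.DataFrame(np.vstack([np.random.default_rng(10).normal(0, 0.01, (15, 2)),
                                    np.random.default_rng(11).normal(5, 0.01, (15, 2))]))
        species = pd.Series(["A"] * 15 + ["B"] * 15)
        res = morpho.two_group_manova(Y, species)
        assert res.loc["species", "p"] < 1e-6

    def test_shape_difference_detected_at_generator_defaults(self):
        rejections = 0
        for seed in range(100):
            cfg = ScenarioConfig(seed=seed, n_individuals_morpho=20,
                                 n_variables_morpho=10)
            mt = synthetic.gen_morphometrics(cfg)
            shape = morpho.shape_pca(mt.values())
            res = morpho.two_group_manova(shape.shape_scores.iloc[:, :2],
                                          mt.labels("species"))
            rejections += res.loc["species", "p"] <= 0.05
        assert rejections >= 90


class TestWelch:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        t, df, p = morpho.welch_t(x, x)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_equal_variance_equals_student_t(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=20), rng.normal(size=20)
        t_w, df_w, p_w = morpho.welch_t(x, y)
        t_s, p_s = stats.ttest_ind(x, y, equal_var=True)
        assert t_w == pytest.approx(t_s, rel=1e-6)
        assert df_w <= len(x) + len(y) - 2
        assert p_w == pytest.approx(p_s, abs=1e-2)

    def test_zero_variance_both_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            morpho.welch_t([1.0, 1.0], [2.0, 2.0])
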