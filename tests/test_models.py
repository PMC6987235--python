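"""Soil PCA and the status-contrast mixed model."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from treesilience import ResilienceLMM, soil_fertility_pc1
from treesilience.synthetic import generate_soil_table, simulate_record_table


class TestSoilPca:
    def test_latent_factor_dominates_and_matches_eigen_oracle(self):
        rng = np.random.default_rng(0)
        soil = generate_soil_table(60, rng)
        scores, loadings, varfrac = soil_fertility_pc1(soil)
        assert varfrac > 0.2                     # far above 1/10
        # oracle: eigendecomposition of the correlation matrix
        num = soil.drop(columns="site")
        z = (num - num.mean()) / num.std(ddof=0)
        evals = np.linalg.eigvalsh(np.cov(z.to_numpy().T, ddof=0))
        assert varfrac == pytest.approx(evals[-1] / evals.sum(), abs=1e-8)
        assert np.linalg.norm(loadings.to_numpy()) == pytest.approx(1.0)

    def test_orientation_positive_on_nitrogen(self):
        rng = np.random.default_rng(1)
        soil = generate_soil_table(50, rng)
        scores, loadings, _ = soil_fertility_pc1(soil)
        assert loadings["total_nitrogen"] > 0
        assert np.corrcoef(scores, soil["total_nitrogen"])[0, 1] > 0
        # flipping all inputs leaves the oriented scores' structure intact
        flipped = soil.copy()
        num_cols = flipped.columns.drop("site")
        flipped[num_cols] = -flipped[num_cols]
        s2, l2, _ = soil_fertility_pc1(flipped)
        assert abs(np.corrcoef(scores, s2)[0, 1]) == pytest.approx(1.0)

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        soil = generate_soil_table(30, rng)
        soil["ph"] = 6.0
        with pytest.warns(UserWarning, match="constant soil columns"):
            _, loadings, _ = soil_fertility_pc1(soil)
        assert "ph" not in loadings.index


@pytest.fixture(scope="module")
def records():
    rec = simulate_record_table(n_sites=40, trees_per_site=20,
                                status_effect=-0.10, seed=8)
    rng = np.random.default_rng(9)
    # add tree- and site-level covariates so the full design is exercised
    rec["dbh_i"] = rng.normal(30, 5, len(rec))
    rec["delta_time"] = rng.integers(10, 41, len(rec)).astype(float)
    site_cov = {s: rng.normal() for s in rec["site"].unique()}
    for name in ("spei_i", "speidiff_resil", "aridity", "soil_pc1"):
        rec[name] = rec["site"].map({s: rng.normal() for s in site_cov})
    rec["resistance"] = rec["resilience"]
    rec["recovery"] = rec["resilience"]
    return rec


def test_design_rules(records):
    m_resil = ResilienceLMM(records, response="resilience")
    assert "speidiff_resil" in m_resil.fixed
    assert "surviving" in m_resil.fixed
    m_resist = ResilienceLMM(records, response="resistance")
    assert "speidiff_resil" not in m_resist.fixed
    assert "spei_i" in m_resist.fixed
    # continuous predictors standardised to unit variance
    for c in ("dbh_i", "spei_i", "aridity"):
        assert m_resil.frame[c].std(ddof=1) == pytest.approx(1.0)
    # interactions respect status as the common factor
    inters = [t for t in m_resil.fixed if "_x_" in t]
    assert all(t.startswith("surviving_x_") for t in inters)


def test_status_reference_is_now_dead(records):
    m = ResilienceLMM(records, fixed=["surviving"], random=None)
    fit = m.fit()
    # intercept = mean log response of now-dead trees (reference level)
    dead_mean = np.log(records.loc[records.status == "now-dead",
                                   "resilience"]).mean()
    assert fit.params["Intercept"] == pytest.approx(dead_mean, abs=1e-10)


def test_ols_limit_matches_statsmodels_oracle(records):
    terms = ["surviving", "dbh_i", "spei_i"]
    m = ResilienceLMM(records, fixed=terms, random=None)
    fit = m.fit()
    X = m._design(terms)
    oracle = sm.OLS(np.log(records["resilience"].to_numpy()), X).fit()
    np.testing.assert_allclose(fit.params.to_numpy(),
                               oracle.params.to_numpy(), atol=1e-6)


def test_single_dataset_parameter_recovery(records):
    fit = ResilienceLMM(records, fixed=["surviving"]).fit()
    b = fit.coef_table().loc["surviving"]
    assert b["std_beta"] == pytest.approx(-0.10, abs=0.05)
    assert fit.delta_aic_status > 2
    r2m, r2c = fit.r2_marginal_conditional()
    assert 0 <= r2m <= r2c <= 1


def test_variance_components_recovered_loosely():
    rec = simulate_record_table(n_sites=120, trees_per_site=20,
                                sd_site=0.2, sd_resid=0.3, seed=10)
    fit = ResilienceLMM(rec, fixed=["surviving"]).fit()
    vc = fit.variance_components
    assert vc["site"] == pytest.approx(0.04, abs=0.02)
    assert vc["residual"] == pytest.approx(0.09, abs=0.01)


def test_zero_random_variance_r2m_equals_r2c(records):
    fit = ResilienceLMM(records, fixed=["surviving"], random=None).fit()
    r2m, r2c = fit.r2_marginal_conditional()
    assert r2m == pytest.approx(r2c)


def test_reduction_drops_null_covariate_first_and_lowers_aic(records):
    rec = records.copy()
    rng = np.random.default_rng(11)
    rec["noise_cov"] = rng.normal(size=len(rec))
    m = ResilienceLMM(rec, fixed=["surviving", "dbh_i"], random=None)
    # append a pure-noise covariate through the public fixed-terms interface
    m.frame["noise_cov"] = (rec["noise_cov"] - rec["noise_cov"].mean()) \
        / rec["noise_cov"].std(ddof=1)
    m.fixed = ["surviving", "dbh_i", "noise_cov"]
    full = m.fit()
    red = full.reduce()
    assert red.aic <= full.aic
    if red.reduction_trail:
        assert red.reduction_trail[0]["dropped"] in ("noise_cov", "dbh_i")
        assert "surviving" in red.terms


def test_reduction_respects_marginality(records):
    m = ResilienceLMM(records,
                      fixed=["surviving", "dbh_i", "surviving_x_dbh_i"],
                      random=None)
    full = m.fit()
    red = full.reduce()
    # a main effect may only disappear after its interaction has gone
    if "surviving_x_dbh_i" in red.terms:
        assert {"surviving", "dbh_i"} <= set(red.terms)


def test_adjusted_means_balanced_closed_form(records):
    fit = ResilienceLMM(records, fixed=["surviving"], random=None).fit()
    am = fit.adjusted_means(by=("status",))
    logs = np.log(records.set_index("status")["resilience"])
    for status in ("surviving", "now-dead"):
        expected = np.exp(logs.loc[status].mean())
        got = am.loc[am.status == status, "mean"].iloc[0]
        assert got == pytest.approx(expected, rel=1e-10)
    contrast = am[am.status == "surviving - now-dead"].iloc[0]
    assert contrast["mean"] < 1          # planted deficit in surviving? no:
    # status_effect = -0.10 on surviving, so surviving mean is lower
    assert contrast["p"] < 0.05


def test_adjusted_means_split_rule(records):
    fit = ResilienceLMM(records, fixed=["surviving"], random=None).fit()
    am = fit.adjusted_means()
    assert set(am["group"]) == {None}    # no status x group term: one panel


def test_plot_adjusted_means_smoke(records, tmp_path):
    import matplotlib
    matplotlib.use("Agg")
    fit = ResilienceLMM(records, fixed=["surviving"], random=None).fit()
    ax = fit.plot_adjusted_means()
    assert ax.get_ylabel()
    ax.figure.savefig(tmp_path / "means.png")


def test_rank_deficiency_reported_and_droppable(records):
    rec = records.copy()
    rec["dup"] = rec["dbh_i"]
    m = ResilienceLMM(rec, fixed=["surviving", "dbh_i"], random=None)
    m.frame["dup"] = m.frame["dbh_i"]
    with pytest.raises(ValueError, match="aliased"):
        m._check_rank(["surviving", "dbh_i", "dup"])


def test_too_few_genera_rejected(records):
    rec = records.copy()
    rec["genus"] = "only_one"
    with pytest.raises(ValueError, match="genus"):
        ResilienceLMM(rec, fixed=["surviving"])
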