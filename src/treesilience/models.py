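"""Status-contrast linear mixed models and the soil-fertility PCA.

The central object is :class:`ResilienceLMM`, a statsmodels-style model
for the question "were trees that later died during drought less
resilient to an earlier drought than coexisting survivors?".  The
response is a log-transformed Lloret index (resilience, resistance or
recovery, on TRW or BAI); fixed effects are tree status (reference:
now-dead), taxonomic group (reference: angiosperm), DBH in the event
year, drought intensity (SPEI_i and, for resilience, SPEIdiff_resil),
the time from event to last ring (delta_time), site aridity, soil
fertility (PC1) and all status interactions; random intercepts are
nested site-within-species-within-genus.  ``fit()`` returns a
:class:`ResilienceLMMResults` carrying standardised coefficients, Wald
confidence intervals and p-values, Nakagawa-Schielzeth marginal and
conditional R^2, the AIC increment of dropping status, backward AIC
reduction and back-transformed adjusted means.

Continuous predictors are standardised (centred, unit variance) so the
reported betas are standardised effects; the intercept is left on the
response scale.  AICs for model comparison are computed from maximum
likelihood refits because the compared models differ in their fixed
parts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["soil_fertility_pc1", "ResilienceLMM", "ResilienceLMMResults",
           "r2_marginal_conditional"]

CONTINUOUS_TERMS = ["dbh_i", "spei_i", "speidiff_resil", "delta_time",
                    "aridity", "soil_pc1"]


def soil_fertility_pc1(soil_table, nitrogen_col="total_nitrogen"):
    """First principal component of the standardised soil table.

    Columns are centred and scaled to unit variance; constant columns are
    dropped with a warning.  The component sign is oriented so that the
    nitrogen loading is positive, making higher scores mean more fertile
    soil.

    Returns ``(scores, loadings, variance_fraction)`` where ``scores``
    is a site-indexed Series.
    """
    tab = soil_table.set_index("site") if "site" in soil_table.columns \
        else soil_table
    num = tab.select_dtypes("number")
    if num.isna().any().any():
        raise ValueError("soil table contains missing values")
    const = [c for c in num.columns if num[c].nunique() == 1]
    if const:
        warnings.warn(f"constant soil columns dropped: {const}", stacklevel=2)
        num = num.drop(columns=const)
    if len(num) < 3:
        raise ValueError("need at least 3 sites for a PCA")
    z = StandardScaler().fit_transform(num.to_numpy())
    pca = PCA()
    scores_all = pca.fit_transform(z)
    load = pca.components_[0]
    if nitrogen_col in num.columns and load[list(num.columns).index(nitrogen_col)] < 0:
        load = -load
        scores_all[:, 0] = -scores_all[:, 0]
    scores = pd.Series(scores_all[:, 0], index=num.index, name="soil_pc1")
    loadings = pd.Series(load, index=num.columns, name="pc1_loading")
    return scores, loadings, float(pca.explained_variance_ratio_[0])


def _interaction_col(a, b):
    return f"{a}_x_{b}"


@dataclass
class ResilienceLMMResults:
    """Fitted status-contrast model (see module docstring)."""

    model: "ResilienceLMM"
    terms: list
    reml_result: object                 # statsmodels MixedLMResults or OLS
    ml_result: object
    reduction_trail: list = field(default_factory=list)

    # -- coefficient table ------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return self.reml_result.params[:len(self.terms) + 1]

    def coef_table(self) -> pd.DataFrame:
        res = self.reml_result
        names = ["Intercept"] + self.terms
        est = res.params[names]
        se = res.bse[names]
        ci = res.conf_int().loc[names]
        stat = est / se
        p = 2 * stats.norm.sf(np.abs(stat))
        return pd.DataFrame({
            "std_beta": est, "ci_lo": ci[0], "ci_hi": ci[1],
            "statistic": stat, "p": p,
        })

    # -- information criteria --------------------------------------------
    @property
    def aic(self) -> float:
        """Gaussian ML AIC (fixed + covariance parameters + residual)."""
        return _ml_aic(self.ml_result)

    @property
    def delta_aic_status(self) -> float:
        """AIC(no-status model) - AIC(this model), both under ML."""
        no_status = [t for t in self.terms
                     if "surviving" not in t.split("_x_") and t != "surviving"]
        ml0 = self.model._fit_ml(no_status)
        return _ml_aic(ml0) - self.aic

    # -- variance decomposition ------------------------------------------
    def r2_marginal_conditional(self):
        return r2_marginal_conditional(self)

    @property
    def variance_components(self) -> dict:
        res = self.reml_result
        if self.model.random is None:
            return {"residual": float(res.scale)}
        out = {"genus": float(np.asarray(res.cov_re)[0, 0])}
        if len(res.vcomp):
            for name, v in zip(res.model.exog_vc.names, res.vcomp):
                out[name] = float(v)
        out["residual"] = float(res.scale)
        return out

    # -- model reduction --------------------------------------------------
    def reduce(self):
        """Backward AIC elimination respecting marginality.

        At each step the least significant droppable term (one not
        involved in any remaining interaction) is removed if that lowers
        the ML AIC; the procedure stops otherwise.  Returns a new
        results object with the reduction trail attached.
        """
        terms = list(self.terms)
        trail = []
        current = self
        while True:
            tab = current.coef_table().drop(index="Intercept")
            in_inter = set()
            for t in terms:
                if "_x_" in t:
                    in_inter.update(t.split("_x_"))
            droppable = [t for t in terms if "_x_" in t or t not in in_inter]
            if not droppable:
                break
            worst = max(droppable, key=lambda t: tab.loc[t, "p"])
            cand_terms = [t for t in terms if t != worst]
            cand = self.model._fit_terms(cand_terms)
            if cand.aic < current.aic:
                trail.append({"dropped": worst, "p": float(tab.loc[worst, "p"]),
                              "aic_before": current.aic, "aic_after": cand.aic})
                current, terms = cand, cand_terms
            else:
                break
        current.reduction_trail = trail
        return current

    # -- adjusted means ---------------------------------------------------
    def adjusted_means(self, by=None):
        """Back-transformed least-square means with 95% CI and contrasts.

        Continuous covariates are held at their (centred) means; the
        non-focal factor is averaged over its two levels.  ``by``
        defaults to ("status", "group") when a status x group interaction
        survived in the model, else ("status",).  Returns a DataFrame on
        the index-ratio scale (exponentiated) plus the pairwise
        now-dead vs surviving contrast per panel.
        """
        if by is None:
            by = ("status", "group") if _interaction_col("surviving", "gymnosperm") \
                in self.terms else ("status",)
        for f in by:
            if f not in ("status", "group"):
                raise ValueError(f"unknown factor {f!r}")
        if "group" in by and "gymnosperm" not in self.model.frame.columns:
            raise ValueError("group factor absent from the model frame")
        names = ["Intercept"] + self.terms
        est = self.reml_result.params[names].to_numpy()
        cov = self.reml_result.cov_params().loc[names, names].to_numpy()

        def design_row(surviving, gymnosperm):
            vals = {"Intercept": 1.0, "surviving": surviving,
                    "gymnosperm": gymnosperm}
            row = []
            for t in names:
                if t in vals:
                    row.append(vals[t])
                elif "_x_" in t:
                    a, b = t.split("_x_")
                    row.append(vals.get(a, 0.0) * vals.get(b, 0.0))
                else:
                    row.append(0.0)          # continuous terms centred at 0
            return np.array(row)

        panels = [("gymnosperm", 1.0), ("angiosperm", 0.0)] \
            if "group" in by else [(None, 0.5)]
        z = stats.norm.ppf(0.975)
        rows = []
        for gname, gval in panels:
            xs = {"surviving": design_row(1.0, gval),
                  "now-dead": design_row(0.0, gval)}
            for status, x in xs.items():
                mu = float(x @ est)
                se = float(np.sqrt(x @ cov @ x))
                rows.append({"group": gname, "status": status,
                             "mean": np.exp(mu),
                             "ci_lo": np.exp(mu - z * se),
                             "ci_hi": np.exp(mu + z * se)})
            dx = xs["surviving"] - xs["now-dead"]
            diff = float(dx @ est)
            se_d = float(np.sqrt(dx @ cov @ dx))
            stat = diff / se_d
            rows.append({"group": gname, "status": "surviving - now-dead",
                         "mean": np.exp(diff),
                         "ci_lo": np.exp(diff - z * se_d),
                         "ci_hi": np.exp(diff + z * se_d),
                         "statistic": stat,
                         "p": 2 * stats.norm.sf(abs(stat))})
        return pd.DataFrame(rows)

    def plot_adjusted_means(self, ax=None, **kwargs):
        """Point-and-interval plot of the back-transformed adjusted means."""
        from .plotting import plot_adjusted_means
        return plot_adjusted_means(self.adjusted_means(), ax=ax, **kwargs)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        r2m, r2c = self.r2_marginal_conditional()
        tab = self.coef_table()
        lines = [
            f"Status-contrast LMM: log {self.model.response} "
            f"({self.model.metric})",
            f"N = {len(self.model.frame)} trees",
            "",
            f"{'term':<28}{'std beta':>10}{'CI 95%':>22}{'stat':>8}{'p':>9}",
        ]
        for name, row in tab.iterrows():
            ci = f"[{row.ci_lo: .3f},{row.ci_hi: .3f}]"
            lines.append(f"{name:<28}{row.std_beta:>10.3f}{ci:>22}"
                         f"{row.statistic:>8.2f}{row.p:>9.3g}")
        lines.append("")
        vc = self.variance_components
        lines.append("Random-effect variances: "
                     + ", ".join(f"{k}={v:.4g}" for k, v in vc.items()))
        lines.append(f"R2m = {r2m:.3f}  R2c = {r2c:.3f}  "
                     f"AIC(ML) = {self.aic:.1f}  "
                     f"dAIC(no status) = {self.delta_aic_status:.1f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        r2m, r2c = self.r2_marginal_conditional()
        return {
            "response": self.model.response, "metric": self.model.metric,
            "terms": self.terms,
            "coefficients": self.coef_table().to_dict(orient="index"),
            "variance_components": self.variance_components,
            "r2m": r2m, "r2c": r2c, "aic_ml": self.aic,
            "delta_aic_status": self.delta_aic_status,
            "reduction_trail": self.reduction_trail,
            "n": int(len(self.model.frame)),
        }


def _ml_aic(res):
    if hasattr(res, "vcomp"):
        m = res.model
        k = m.k_fe + m.k_re2 + m.k_vc + 1       # + residual variance
        return float(-2 * res.llf + 2 * k)
    return float(res.aic)      # OLS


def r2_marginal_conditional(results):
    """Nakagawa-Schielzeth R^2 for a Gaussian identity-link mixed model.

    r2m = var_fixed / (var_fixed + var_random + var_residual);
    r2c adds the random-intercept variance to the numerator.
    """
    res = results.reml_result
    model = results.model
    names = ["Intercept"] + results.terms
    X = model._design(results.terms)
    var_f = float(np.var(X.to_numpy() @ res.params[names].to_numpy()))
    if model.random is None:
        var_r = 0.0
    else:
        var_r = sum(v for k, v in results.variance_components.items()
                    if k != "residual")
    var_e = float(res.scale)
    tot = var_f + var_r + var_e
    return var_f / tot, (var_f + var_r) / tot


class ResilienceLMM:
    """Linear mixed model contrasting now-dead and surviving trees.

    Parameters
    ----------
    records : DataFrame
        Per-tree record table (one row per tree for one metric) with the
        index columns produced by :func:`resilience.build_records`.
    response : {"resilience", "resistance", "recovery"}
    metric : {"TRW", "BAI"}
        Used to subset ``records`` when a ``metric`` column is present.
    fixed : list of term names or None
        Defaults to the full fixed structure: status, group, continuous
        covariates and all status interactions.  SPEIdiff terms other
        than the one matching the response are excluded; because SPEI_i
        is nearly collinear with SPEIdiff_resist and SPEIdiff_recov,
        only the resilience model carries a SPEIdiff term at all.
    random : {"nested", None}
        "nested" fits random intercepts for genus, species-in-genus and
        site-in-species; None fits ordinary least squares (all random
        variances fixed at zero).
    """

    def __init__(self, records, response="resilience", metric="TRW",
                 fixed=None, random="nested", drop_aliased=False):
        if response not in ("resilience", "resistance", "recovery"):
            raise ValueError(f"unknown response {response!r}")
        self.response = response
        self.metric = metric
        self.random = random
        df = records
        if "metric" in df.columns:
            df = df[df["metric"] == metric]
        df = df.reset_index(drop=True)
        if df.empty:
            raise ValueError("no records for the requested response/metric")
        self.frame, self.scales_ = self._build_frame(df)
        self.fixed = fixed if fixed is not None else self._default_terms()
        if drop_aliased:
            aliased = self._aliased_terms(self.fixed)
            while aliased:
                # drop aliased mains together with their interactions
                drop = set(aliased)
                for t in self.fixed:
                    if "_x_" in t and drop & set(t.split("_x_")):
                        drop.add(t)
                warnings.warn(f"dropping aliased terms {sorted(drop)} "
                              "(too few sites to identify them)", stacklevel=2)
                self.fixed = [t for t in self.fixed if t not in drop]
                aliased = self._aliased_terms(self.fixed)
        self._check_rank(self.fixed)
        if random == "nested":
            if self.frame["genus"].nunique() < 2:
                raise ValueError(
                    "grouping factor 'genus' needs >= 2 levels for the "
                    "nested random structure; use random=None")
            # a nesting level is only an identifiable variance component
            # when it has more levels than its parent
            self._vc = {}
            n_g = self.frame["genus"].nunique()
            n_sp = self.frame["species"].nunique()
            n_si = self.frame["site"].nunique()
            if n_sp > n_g:
                self._vc["species"] = "0 + C(species)"
            if n_si > max(n_sp, n_g):
                self._vc["site"] = "0 + C(site)"

    @classmethod
    def from_records(cls, records, **kwargs):
        return cls(records, **kwargs)

    # -- frame construction ------------------------------------------------
    def _build_frame(self, df):
        frame = pd.DataFrame({
            "y": np.log(df[self.response].to_numpy(dtype=float)),
            "surviving": (df["status"] == "surviving").astype(float),
            "genus": df.get("genus", pd.Series("g", index=df.index)),
            "species": df.get("species", pd.Series("s", index=df.index)),
            "site": df["site"],
        })
        if "group" in df.columns and df["group"].nunique() > 1:
            frame["gymnosperm"] = (df["group"] == "gymnosperm").astype(float)
        scales = {}
        for c in CONTINUOUS_TERMS:
            if c in df.columns and df[c].notna().all():
                sd = float(df[c].std(ddof=1))
                if sd > 0:
                    frame[c] = (df[c] - df[c].mean()) / sd
                    scales[c] = sd
        if not np.isfinite(frame["y"]).all():
            raise ValueError("log response is not finite for all records")
        return frame, scales

    def _default_terms(self):
        cont = [c for c in CONTINUOUS_TERMS if c in self.frame.columns]
        if self.response != "resilience":
            cont = [c for c in cont if c != "speidiff_resil"]
        main = (["surviving"]
                + (["gymnosperm"] if "gymnosperm" in self.frame.columns else [])
                + cont)
        inters = [_interaction_col("surviving", t) for t in main
                  if t != "surviving"]
        return main + inters

    def _design(self, terms):
        X = pd.DataFrame({"Intercept": np.ones(len(self.frame))},
                         index=self.frame.index)
        for t in terms:
            if "_x_" in t:
                a, b = t.split("_x_")
                X[t] = self.frame[a] * self.frame[b]
            else:
                X[t] = self.frame[t]
        return X

    def _aliased_terms(self, terms):
        """Greedy scan: terms whose columns add no rank to the design."""
        X = self._design(terms).to_numpy()
        kept_idx, aliased = [0], []
        rank = 1
        for j in range(1, X.shape[1]):
            r = np.linalg.matrix_rank(X[:, kept_idx + [j]])
            if r > rank:
                kept_idx.append(j)
                rank = r
            else:
                aliased.append(terms[j - 1])
        return aliased

    def _check_rank(self, terms):
        aliased = self._aliased_terms(terms)
        if aliased:
            raise ValueError(
                f"design matrix rank deficient; aliased terms: {aliased}")

    # -- fitting -----------------------------------------------------------
    def _fit_mixedlm(self, terms, reml):
        data = self.frame.copy()
        X = self._design(terms)
        for c in X.columns:
            if c != "Intercept":
                data[c] = X[c]
        rhs = " + ".join(terms) if terms else "1"
        from statsmodels.tools.sm_exceptions import ConvergenceWarning
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*[Ss]ingular.*")
            warnings.filterwarnings("ignore", category=RuntimeWarning)
            # boundary/retry chatter; genuine failure raises below
            warnings.filterwarnings("ignore", category=ConvergenceWarning)
            model = smf.mixedlm(
                f"y ~ {rhs}", data, groups=data["genus"], re_formula="1",
                vc_formula=self._vc or None)
            res = model.fit(reml=reml)
            if not res.converged:
                res = model.fit(reml=reml, method="powell")
        if not res.converged:
            raise RuntimeError(
                f"mixed model did not converge (terms={terms}); "
                f"llf={res.llf:.3f}")
        return res

    def _fit_ols(self, terms):
        X = self._design(terms)
        return sm.OLS(self.frame["y"].to_numpy(), X).fit()

    def _fit_ml(self, terms):
        if self.random is None:
            return self._fit_ols(terms)
        return self._fit_mixedlm(terms, reml=False)

    def _fit_terms(self, terms, ml_refit=True):
        if self.random is None:
            res = self._fit_ols(terms)
            return ResilienceLMMResults(model=self, terms=list(terms),
                                        reml_result=res, ml_result=res)
        reml = self._fit_mixedlm(terms, reml=True)
        ml = self._fit_mixedlm(terms, reml=False) if ml_refit else None
        return ResilienceLMMResults(model=self, terms=list(terms),
                                    reml_result=reml, ml_result=ml)

    def fit(self, ml_refit=True):
        """Fit by restricted maximum likelihood.

        ``ml_refit=True`` (default) also fits the model by plain maximum
        likelihood so AIC comparisons across fixed structures are valid;
        pass False to skip it when only coefficients are needed.
        """
        return self._fit_terms(self.fixed, ml_refit=ml_refit)
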