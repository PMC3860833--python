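"""Mixed-effects models of incubation quality and amount.

Five responses are modelled per-bout: median z-scored incubation
temperature, arcsine-square-root incubation constancy, bout length in
minutes, the probability of a detectable exchange gap (binomial), and the
log duration of detectable gaps.  All models share the same structure:
sex in interaction with day of incubation, confounders (disturbance,
radio tag, body mass, culmen, start of incubation within the season),
a nest random intercept, and a random slope on z-scored day of
incubation.  Every predictor except sex is mean centred; mass and culmen
are centred within sex.  P values can be adjusted for simultaneous
inference with a single-step max-|z| correction.

Gaussian models are fitted by maximum likelihood with
:class:`statsmodels.regression.mixed_linear_model.MixedLM`; the binomial
model uses the variational Bayes approximation of
:class:`statsmodels.genmod.bayes_mixed_glm.BinomialBayesMixedGLM`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

from .filters import retained

log = logging.getLogger(__name__)


class DesignError(ValueError):
    """Rank-deficient or otherwise unusable model design."""


# ---------------------------------------------------------------------------
# covariate preparation
# ---------------------------------------------------------------------------

def arcsine_sqrt(p):
    """Variance-stabilising transform for proportions: arcsin(sqrt(p))."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    return np.arcsin(np.sqrt(p))


def center(x):
    x = np.asarray(x, dtype=float)
    return x - np.nanmean(x)


def center_within(x, group):
    """Centre ``x`` within the levels of ``group`` (e.g. within sex)."""
    s = pd.Series(np.asarray(x, dtype=float))
    return (s - s.groupby(np.asarray(group)).transform("mean")).to_numpy()


def zscore(x):
    x = np.asarray(x, dtype=float)
    sd = np.nanstd(x)
    if sd == 0:
        return np.zeros_like(x)
    return (x - np.nanmean(x)) / sd


def prepare_covariates(table: pd.DataFrame, metadata: pd.DataFrame,
                       drop_missing_morphometrics: bool = True) -> pd.DataFrame:
    """Model-ready per-bout records from the retained bout table.

    Applies the transform/centering plan: arcsine-sqrt for constancy,
    grand-mean centering for day of incubation, season start, disturbance
    and radio tag, within-sex centering for mass and culmen, z-scored day
    for the random slope, and the previous bout length centred at its
    grand mean.  Bouts of birds lacking morphometrics are dropped.
    """
    kept = retained(table).copy()
    if kept.empty:
        raise DesignError("no retained bouts")
    meta = metadata.set_index("nest_id")
    sex = kept["sex"].to_numpy()
    nid = kept["nest_id"].to_numpy()
    f = sex == "F"
    kept["mass"] = np.where(f, meta.loc[nid, "mass_female"],
                            meta.loc[nid, "mass_male"])
    kept["culmen"] = np.where(f, meta.loc[nid, "culmen_female"],
                              meta.loc[nid, "culmen_male"])
    kept["radio"] = np.where(f, meta.loc[nid, "radio_female"],
                             meta.loc[nid, "radio_male"]).astype(float)
    kept["season_start"] = meta.loc[nid, "incubation_start_day"].to_numpy(float)
    kept["probe_type"] = meta.loc[nid, "probe_type"].to_numpy(float)
    if drop_missing_morphometrics:
        kept = kept[kept["mass"].notna() & kept["culmen"].notna()]
    out = pd.DataFrame({
        "nest_id": kept["nest_id"],
        "sex": pd.Categorical(kept["sex"], categories=["F", "M"]),
        "male": (kept["sex"] == "M").astype(float),
        "bout_length": kept["length_min"].astype(float),
        "constancy": kept["constancy"].astype(float),
        "median_z_temp": kept.get("median_z_temp", np.nan),
        "day_c": center(kept["day_of_incubation"]),
        "z_day": zscore(kept["day_of_incubation"]),
        "season_c": center(kept["season_start"]),
        "disturbance_c": center(kept["disturbance"]),
        "radio_c": center(kept["radio"]),
        "probe_type_c": center(kept["probe_type"]),
        "mass_c": center_within(kept["mass"], kept["sex"]),
        "culmen_c": center_within(kept["culmen"], kept["sex"]),
    }, index=kept.index)
    c = out["constancy"].to_numpy(float)
    valid = ~np.isnan(c)
    if np.any((c[valid] < 0) | (c[valid] > 1)):
        raise ValueError("constancy outside [0, 1]")
    out["asin_constancy"] = np.where(valid, np.arcsin(np.sqrt(np.clip(c, 0, 1))),
                                     np.nan)
    prev = kept.get("previous_bout_length")
    if prev is not None:
        out["prev_c"] = prev - np.nanmean(prev)
    return out.reset_index(drop=True)


def prepare_gap_covariates(gaps: pd.DataFrame,
                           metadata: pd.DataFrame) -> pd.DataFrame:
    """Model-ready exchange-gap records (occurrence and log duration)."""
    if gaps.empty:
        raise DesignError("no exchange gaps")
    meta = metadata.set_index("nest_id")
    g = gaps.copy()
    nid = g["nest_id"].to_numpy()
    f = g["incoming_sex"].to_numpy() == "F"
    g["mass"] = np.where(f, meta.loc[nid, "mass_female"],
                         meta.loc[nid, "mass_male"])
    g["culmen"] = np.where(f, meta.loc[nid, "culmen_female"],
                           meta.loc[nid, "culmen_male"])
    g["radio"] = np.where(f, meta.loc[nid, "radio_female"],
                          meta.loc[nid, "radio_male"]).astype(float)
    g["season_start"] = meta.loc[nid, "incubation_start_day"].to_numpy(float)
    out = pd.DataFrame({
        "nest_id": g["nest_id"],
        "male": (g["incoming_sex"] == "M").astype(float),
        "detectable": g["detectable"].astype(float),
        "log_duration": np.where(g["duration_s"] > 0,
                                 np.log(g["duration_s"].clip(lower=1e-9)),
                                 np.nan),
        "day_c": center(g["day_of_incubation"]),
        "z_day": zscore(g["day_of_incubation"]),
        "season_c": center(g["season_start"]),
        "mass_c": center_within(g["mass"], g["incoming_sex"]),
        "culmen_c": center_within(g["culmen"], g["incoming_sex"]),
        "radio_c": center(g["radio"]),
    })
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# model specification and fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one per-bout model."""

    name: str
    response: str
    fixed: str                       # patsy right-hand side
    family: str = "gaussian"         # or "binomial"
    groups: str = "nest_id"
    random_slope: str = "z_day"      # random slope term, or ""


_CONFOUNDERS = "disturbance_c + radio_c + culmen_c + mass_c + season_c"

BOUT_LENGTH = ModelSpec(
    "bout_length", "bout_length",
    f"male + day_c + prev_c + male:prev_c + male:day_c + season_c:day_c + "
    f"{_CONFOUNDERS}")
CONSTANCY = ModelSpec(
    "constancy", "asin_constancy",
    f"male + day_c + male:day_c + season_c:day_c + probe_type_c + {_CONFOUNDERS}")
Z_TEMP = ModelSpec(
    "median_z_temp", "median_z_temp",
    f"male + day_c + male:day_c + season_c:day_c + {_CONFOUNDERS}")
GAP_PROBABILITY = ModelSpec(
    "gap_probability", "detectable",
    f"male + day_c + male:day_c + season_c:day_c + {_CONFOUNDERS}",
    family="binomial")
GAP_DURATION = ModelSpec(
    "gap_duration", "log_duration",
    f"male + day_c + male:day_c + season_c:day_c + {_CONFOUNDERS}")


@dataclass
class ModelFit:
    """Coefficients, intervals, and random-effect variances of one fit."""

    spec: ModelSpec
    params: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p_raw: pd.Series
    cov: pd.DataFrame | None
    re_var: dict
    nobs: int
    ngroups: int
    converged: bool
    p_adjusted: pd.Series | None = None

    def table(self) -> pd.DataFrame:
        """Result table mirroring the usual GLMM report layout."""
        df = pd.DataFrame({
            "estimate": self.params,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p_raw,
        })
        if self.p_adjusted is not None:
            df["p_adjusted"] = self.p_adjusted
        return df


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Fit one bout-level mixed model by ML (gaussian) or VB (binomial)."""
    cols = [spec.response, spec.groups]
    data = data.dropna(subset=[c for c in cols if c in data.columns])
    if data[spec.groups].nunique() < 2:
        raise DesignError("need at least two nests")
    formula = f"{spec.response} ~ {spec.fixed}"
    X = smf.ols(formula, data=data).exog  # noqa: N806 - rank check only
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("fixed-effect design is rank deficient")
    if spec.family == "gaussian":
        return _fit_gaussian(spec, formula, data)
    if spec.family == "binomial":
        return _fit_binomial(spec, formula, data)
    raise DesignError(f"unknown family {spec.family!r}")


def _fit_gaussian(spec, formula, data) -> ModelFit:
    """ML mixed fit with graceful degradation at the variance boundary.

    A mixed fit whose likelihood falls below the nested ordinary
    least-squares fit has collapsed at the boundary (statsmodels can
    return degenerate fixed effects there); in that case the random
    structure is simplified, ultimately to OLS with the variances pinned
    at zero.
    """
    ols = smf.ols(formula, data=data).fit()
    re_formulas = ["~1"] if not spec.random_slope else \
        [f"~{spec.random_slope}", "~1"]
    for re_formula in re_formulas:
        model = smf.mixedlm(formula, data, groups=data[spec.groups],
                            re_formula=re_formula)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=False, maxiter=300)
            except (np.linalg.LinAlgError, ValueError):
                continue
        fe = res.fe_params
        ok = (np.isfinite(fe.to_numpy()).all()
              and np.isfinite(res.llf)
              and res.llf >= ols.llf - 1e-6)
        if not ok:
            continue
        names = list(fe.index)
        ci = res.conf_int().loc[names]
        re_cov = res.cov_re
        re_var = {"nest_intercept": float(re_cov.iloc[0, 0])}
        if re_cov.shape[0] > 1:
            re_var["z_day_slope"] = float(re_cov.iloc[1, 1])
        elif spec.random_slope:
            re_var["z_day_slope"] = 0.0
        re_var["residual"] = float(res.scale)
        if min(re_var.values()) < 1e-8:
            log.warning("%s: a variance component is pinned at ~0", spec.name)
        return ModelFit(spec, fe, res.bse.loc[names], ci[0], ci[1],
                        res.pvalues.loc[names],
                        res.cov_params().loc[names, names], re_var,
                        int(res.nobs), data[spec.groups].nunique(),
                        bool(getattr(res, "converged", True)))
    # all mixed fits degenerate: variances pinned at zero
    log.warning("%s: random-effect variances pinned at 0 (OLS fallback)",
                spec.name)
    names = list(ols.params.index)
    ci = ols.conf_int()
    re_var = {"nest_intercept": 0.0, "residual": float(ols.scale)}
    if spec.random_slope:
        re_var["z_day_slope"] = 0.0
    return ModelFit(spec, ols.params, ols.bse, ci[0], ci[1], ols.pvalues,
                    ols.cov_params(), re_var, int(ols.nobs),
                    data[spec.groups].nunique(), True)


def _fit_binomial(spec, formula, data) -> ModelFit:
    y = data[spec.response]
    if y.nunique() < 2:
        raise DesignError("binomial response is constant (separation)")
    vc = {"nest": f"0 + C({spec.groups})"}
    if spec.random_slope:
        vc["nest_slope"] = f"0 + C({spec.groups}):{spec.random_slope}"
    model = BinomialBayesMixedGLM.from_formula(formula, vc, data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit_vb()
    k = model.k_fep
    names = model.fep_names
    params = pd.Series(res.fe_mean, index=names)
    se = pd.Series(res.fe_sd, index=names)
    z = params / se
    p = pd.Series(2 * scipy.stats.norm.sf(np.abs(z)), index=names)
    ci_low = params - 1.96 * se
    ci_high = params + 1.96 * se
    # VB posterior is factorised: only a diagonal covariance is available
    cov = pd.DataFrame(np.diag(se.to_numpy() ** 2), index=names, columns=names)
    vcp = pd.Series(res.vcp_mean, index=model.vcp_names)
    re_var = {name: float(np.exp(2 * val)) for name, val in vcp.items()}
    return ModelFit(spec, params, se, ci_low, ci_high, p, cov, re_var,
                    len(data), data[spec.groups].nunique(), True)


# ---------------------------------------------------------------------------
# simultaneous inference
# ---------------------------------------------------------------------------

def adjust_pvalues(fit: ModelFit, n_draws: int = 100_000,
                   seed: int = 0) -> ModelFit:
    """Single-step max-|z| adjustment over all fixed-effect coefficients.

    The adjusted p value of coefficient j is P(max_k |Z_k| >= |z_j|) under
    the joint normal with the fit's estimated correlation, evaluated by
    Monte Carlo.  With one coefficient this reduces to the raw p value;
    with independent coefficients it approaches the Sidak correction.
    """
    z = (fit.params / fit.se).to_numpy()
    k = z.size
    if k == 1 or fit.cov is None:
        fit.p_adjusted = fit.p_raw.copy()
        return fit
    sd = np.sqrt(np.diag(fit.cov.to_numpy()))
    corr = fit.cov.to_numpy() / np.outer(sd, sd)
    corr = (corr + corr.T) / 2
    try:
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(k))
    except np.linalg.LinAlgError:
        warnings.warn("coefficient covariance not positive definite; "
                      "skipping p-value adjustment", stacklevel=2)
        fit.p_adjusted = None
        return fit
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_draws, k)) @ chol.T
    max_abs = np.abs(draws).max(axis=1)
    adj = np.array([np.mean(max_abs >= abs(zj)) for zj in z])
    adj = np.maximum(adj, fit.p_raw.to_numpy())  # adjusted >= raw
    fit.p_adjusted = pd.Series(np.minimum(adj, 1.0), index=fit.params.index)
    return fit


def fit_all_models(bout_cov: pd.DataFrame, gap_cov: pd.DataFrame | None = None,
                   adjust: bool = True, seed: int = 0) -> dict:
    """Fit the full per-bout model battery; returns {name: ModelFit}."""
    fits = {}
    bl = bout_cov.dropna(subset=["prev_c"]) if "prev_c" in bout_cov else bout_cov
    for spec, frame in ((BOUT_LENGTH, bl), (CONSTANCY, bout_cov),
                        (Z_TEMP, bout_cov)):
        try:
            fits[spec.name] = fit_model(spec, frame)
        except DesignError as err:
            log.warning("%s not fitted: %s", spec.name, err)
    if gap_cov is not None and not gap_cov.empty:
        try:
            fits[GAP_PROBABILITY.name] = fit_model(GAP_PROBABILITY, gap_cov)
        except DesignError as err:
            log.warning("gap probability not fitted: %s", err)
        det = gap_cov[gap_cov["detectable"] == 1]
        if det["nest_id"].nunique() >= 2:
            try:
                fits[GAP_DURATION.name] = fit_model(GAP_DURATION, det)
            except DesignError as err:
                log.warning("gap duration not fitted: %s", err)
    if adjust:
        for fit in fits.values():
            adjust_pvalues(fit, seed=seed)
    return fits
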