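"""Regression models linking treatment, social associations and song outcomes.

Four analyses are supported, all with a family random intercept (sons are
nested in families):

1. binomial GLMM — was the father the primary song tutor (1/0) ~ CORT;
2. LMM — father-son song dissimilarity ~ CORT + father-son association +
   father gregariousness + son gregariousness + number of fledglings
   (or, in a paired variant, number of male offspring — the two covariates
   are strongly correlated and never co-included);
3. LMM — father-son association ~ CORT;
4. LMM — dissimilarity between a juvenile and his first-ranked tutor ~ CORT.

The estimation backends are established routines (statsmodels MixedLM with
REML for linear models; the Laplace/MAP fit of statsmodels'
BinomialBayesMixedGLM for the binomial model; plain GLM for fixed-effects
logistic fits). This module contributes the model-table construction, the
contracts (validation, error reporting) and the unified :class:`FitResult`
reporting, including variance decompositions in percent of total.

Network predictors can enter at day-level resolution (default: one row per
son and day, the response repeated across days) or aggregated to per-son
means across days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from ._util import require_columns

__all__ = [
    "FitResult",
    "fit_lmm",
    "fit_glmm_binomial",
    "fit_logistic",
    "build_dissimilarity_table",
    "build_tutor_choice_table",
    "build_association_table",
    "build_accuracy_table",
]

#: latent-scale residual variance of a logistic model, used for variance
#: percentages in binomial GLMMs
LOGISTIC_RESIDUAL_VAR = float(np.pi**2 / 3.0)


@dataclass
class FitResult:
    """Slopes, uncertainties and variance decomposition of one model fit."""

    fixed: pd.DataFrame  # index: term; columns: slope, se, stat
    random_variance: float
    residual_variance: float
    variance_pct: dict
    method: str
    n_obs: int
    n_groups: int
    converged: bool = True
    separation: bool = False

    def slope(self, term: str) -> float:
        return float(self.fixed.loc[term, "slope"])

    def se(self, term: str) -> float:
        return float(self.fixed.loc[term, "se"])

    def stat(self, term: str) -> float:
        return float(self.fixed.loc[term, "stat"])

    def to_frame(self) -> pd.DataFrame:
        out = self.fixed.copy()
        out["method"] = self.method
        return out


def _validate_table(table, response, fixed_effects, group):
    require_columns(table, [response, *fixed_effects, group], "model table")
    used = table[[response, *fixed_effects, group]]
    if used.isna().any().any():
        bad = used.columns[used.isna().any()].tolist()
        raise ValueError(f"model table has missing values in columns {bad}")
    for col in fixed_effects:
        if np.ptp(np.asarray(table[col], dtype=float)) == 0.0:
            raise ValueError(f"singular design: constant predictor column {col!r}")
    if table[group].nunique() < 2:
        raise ValueError("need at least 2 groups for a random intercept")


def _design(table, fixed_effects):
    X = np.column_stack(
        [np.ones(len(table))] + [np.asarray(table[c], dtype=float) for c in fixed_effects]
    )
    return X, ["intercept", *fixed_effects]


def fit_lmm(
    table: pd.DataFrame,
    response: str,
    fixed_effects: list,
    group: str = "family_id",
    reml: bool = True,
) -> FitResult:
    """Linear mixed model with a single random intercept, fitted by REML.

    Falls back through a small set of optimizers until convergence; the fit
    is deterministic given the data. Raises on constant predictors (singular
    design) naming the offending column.
    """
    _validate_table(table, response, fixed_effects, group)
    y = np.asarray(table[response], dtype=float)
    X, names = _design(table, fixed_effects)
    groups = np.asarray(table[group])

    model = sm.MixedLM(y, X, groups=groups)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in ("lbfgs", "powell", "cg"):
            try:
                cand = model.fit(reml=reml, method=method)
            except Exception:
                continue
            # optimizers can report convergence at a degenerate point
            # (infinite restricted likelihood); keep the best finite fit
            if not np.isfinite(cand.llf):
                continue
            better = (
                res is None
                or (cand.converged and not res.converged)
                or (cand.converged == res.converged and cand.llf > res.llf + 1e-10)
            )
            if better:
                res = cand
    if res is None:
        # degenerate designs (e.g. one observation per group) make the
        # random intercept unidentifiable; the model collapses to ordinary
        # least squares with the random variance forced to zero
        ols = sm.OLS(y, X).fit()
        fixed = pd.DataFrame(
            {"slope": ols.params, "se": ols.bse, "stat": ols.tvalues}, index=names
        )
        return FitResult(
            fixed=fixed, random_variance=0.0,
            residual_variance=float(ols.scale),
            variance_pct={"family": 0.0, "residual": 100.0},
            method="lmm-ols-collapse", n_obs=len(y),
            n_groups=int(pd.unique(groups).size),
        )

    k = X.shape[1]
    fe = np.asarray(res.fe_params, dtype=float)
    se = np.asarray(res.bse[:k], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, fe / se, np.nan)
    fixed = pd.DataFrame({"slope": fe, "se": se, "stat": stat}, index=names)
    re_var = float(np.asarray(res.cov_re)[0, 0])
    resid = float(res.scale)
    total = re_var + resid
    pct = {
        "family": 100.0 * re_var / total if total > 0 else 0.0,
        "residual": 100.0 * resid / total if total > 0 else 0.0,
    }
    return FitResult(
        fixed=fixed, random_variance=re_var, residual_variance=resid,
        variance_pct=pct, method="lmm-reml" if reml else "lmm-ml",
        n_obs=len(y), n_groups=int(pd.unique(groups).size),
        converged=bool(res.converged),
    )


def fit_glmm_binomial(
    table: pd.DataFrame,
    response: str,
    fixed_effects: list,
    group: str = "family_id",
    fe_prior_sd: float = 5.0,
    vcp_prior_sd: float = 2.0,
) -> FitResult:
    """Binomial (logit) GLMM with a family random intercept, Laplace/MAP fit.

    Complete separation is flagged (``separation=True``) rather than silently
    reported: implausibly large slopes or standard errors on the logit scale
    indicate that a fixed effect perfectly predicts the response.
    """
    _validate_table(table, response, fixed_effects, group)
    y = np.asarray(table[response], dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binomial response must be binary 0/1")
    X, names = _design(table, fixed_effects)
    codes, levels = pd.factorize(table[group])
    exog_vc = np.zeros((len(y), len(levels)))
    exog_vc[np.arange(len(y)), codes] = 1.0
    ident = np.zeros(len(levels), dtype=int)

    model = BinomialBayesMixedGLM(
        y, X, exog_vc, ident, vcp_p=vcp_prior_sd, fe_p=fe_prior_sd,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit_map()

    k = X.shape[1]
    fe = np.asarray(res.fe_mean, dtype=float)
    se = np.asarray(res.fe_sd, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, fe / se, np.nan)
    fixed = pd.DataFrame({"slope": fe, "se": se, "stat": stat}, index=names)
    re_var = float(np.exp(2.0 * np.asarray(res.vcp_mean, dtype=float)[0]))
    total = re_var + LOGISTIC_RESIDUAL_VAR
    pct = {
        "family": 100.0 * re_var / total,
        "residual": 100.0 * LOGISTIC_RESIDUAL_VAR / total,
    }
    # separation heuristic: the fit classifies every observation correctly
    # with extreme probabilities, or slopes/ses blow up on the logit scale
    from scipy.special import expit

    prob = expit(X @ fe + exog_vc @ np.asarray(res.vc_mean, dtype=float))
    classified = bool(np.all((prob > 0.5) == (y == 1.0)))
    separation = bool(
        (classified and float(np.mean(np.abs(prob - 0.5))) > 0.4)
        or np.any(np.abs(fe[1:]) > 8.0)
        or np.any(se > 20.0)
    )
    return FitResult(
        fixed=fixed, random_variance=re_var,
        residual_variance=LOGISTIC_RESIDUAL_VAR, variance_pct=pct,
        method="glmm-binomial-map", n_obs=len(y), n_groups=len(levels),
        separation=separation,
    )


def fit_logistic(
    table: pd.DataFrame,
    response: str,
    fixed_effects: list,
    freq_weights=None,
) -> FitResult:
    """Fixed-effects-only logistic regression (GLM, binomial family)."""
    require_columns(table, [response, *fixed_effects], "model table")
    y = np.asarray(table[response], dtype=float)
    X, names = _design(table, fixed_effects)
    res = sm.GLM(
        y, X, family=sm.families.Binomial(), freq_weights=freq_weights
    ).fit()
    fixed = pd.DataFrame(
        {"slope": res.params, "se": res.bse, "stat": res.tvalues}, index=names
    )
    return FitResult(
        fixed=fixed, random_variance=0.0, residual_variance=LOGISTIC_RESIDUAL_VAR,
        variance_pct={"family": 0.0, "residual": 100.0},
        method="logistic-glm", n_obs=len(y), n_groups=0,
    )


# --------------------------------------------------------------------------- #
# model-table builders
# --------------------------------------------------------------------------- #

def _son_covariates(birds: pd.DataFrame, family_sizes: pd.DataFrame) -> pd.DataFrame:
    sons = birds[birds["role"] == "son"][
        ["bird_id", "family_id", "aviary_id", "treatment"]
    ].rename(columns={"bird_id": "son_id"})
    sons["cort_treatment"] = (sons["treatment"] == "CORT").astype(int)
    return sons.merge(family_sizes, on="family_id", how="left")


def _merge_sons(tab: pd.DataFrame, sons: pd.DataFrame) -> pd.DataFrame:
    dup = [c for c in sons.columns if c != "son_id" and c in tab.columns]
    return tab.merge(sons.drop(columns=dup), on="son_id", how="inner")


def build_dissimilarity_table(
    metrics: pd.DataFrame,
    birds: pd.DataFrame,
    family_sizes: pd.DataFrame,
    dissimilarity: dict,
    aggregate: str = "day",
) -> pd.DataFrame:
    """Model table for the father-son song-dissimilarity LMM.

    ``dissimilarity`` maps son_id -> father-son song dissimilarity score.
    ``aggregate='day'`` keeps one row per son and day (the response repeated
    across the son's days); ``'mean'`` averages the network predictors across
    days to one row per son.
    """
    if aggregate not in ("day", "mean"):
        raise ValueError("aggregate must be 'day' or 'mean'")
    require_columns(metrics, [
        "aviary_id", "day", "son_id", "father_son_strength",
        "father_gregariousness", "son_gregariousness",
    ], "metrics")
    tab = metrics.rename(columns={"father_son_strength": "father_son_association"})
    if aggregate == "mean":
        tab = tab.groupby("son_id", as_index=False)[
            ["father_son_association", "father_gregariousness", "son_gregariousness"]
        ].mean()
    tab = _merge_sons(tab, _son_covariates(birds, family_sizes))
    tab["response"] = tab["son_id"].map(dissimilarity)
    if tab["response"].isna().any():
        missing = sorted(tab.loc[tab["response"].isna(), "son_id"].unique())
        raise ValueError(f"no dissimilarity score for sons {missing}")
    return tab


def build_tutor_choice_table(tutor_table: pd.DataFrame, birds: pd.DataFrame,
                             family_sizes: pd.DataFrame) -> pd.DataFrame:
    """One row per juvenile male: father_is_tutor (0/1) and treatment."""
    require_columns(tutor_table, ["son_id", "father_rank"], "tutor table")
    tab = tutor_table[["son_id", "father_rank"]].copy()
    tab["response"] = (tab["father_rank"] == 1).astype(int)
    return _merge_sons(tab, _son_covariates(birds, family_sizes))


def build_association_table(metrics: pd.DataFrame, birds: pd.DataFrame,
                            family_sizes: pd.DataFrame,
                            aggregate: str = "day") -> pd.DataFrame:
    """Model table for father-son association ~ CORT (day-level by default)."""
    tab = metrics.rename(columns={"father_son_strength": "response"})
    if aggregate == "mean":
        tab = tab.groupby("son_id", as_index=False)["response"].mean()
    return _merge_sons(tab, _son_covariates(birds, family_sizes))


def build_accuracy_table(tutor_table: pd.DataFrame, birds: pd.DataFrame,
                         family_sizes: pd.DataFrame) -> pd.DataFrame:
    """Model table for juvenile-vs-first-ranked-tutor dissimilarity ~ CORT."""
    require_columns(tutor_table, ["son_id", "primary_dissimilarity"], "tutor table")
    tab = tutor_table[["son_id", "primary_dissimilarity"]].rename(
        columns={"primary_dissimilarity": "response"}
    )
    return _merge_sons(tab, _son_covariates(birds, family_sizes))
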