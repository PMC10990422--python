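"""Parental-age regression models for STR de novo mutation counts.

The workhorse is the Poisson GLM with an identity link, which models the
expected number of phased DNMs per child as a *linear* function of the
relevant parent's age at the child's birth::

    E[n_dnms] = beta0 + beta1 * age

rather than the exponential relationship implied by the canonical log link.
The log link reappears in two places: as the "exponential model" in AIC
comparisons against the linear model, and whenever an offset of
log(number of loci) is needed to compare mutation rates between locus
classes of different panel sizes (AT-only vs GC-containing, non-B DNA
classes, constrained vs neutral).

The paternal fraction alpha is modeled with a quasi-binomial identity-link
GLM (binomial variance with a Pearson-estimated scale), and overdispersion
of Poisson fits is assessed with the Cameron-Trivedi auxiliary regression
plus the Pearson chi-square dispersion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import DomainWarning, PerfectSeparationError

from .errors import FitError, StrDenovoError


@dataclass
class Coefficient:
    estimate: float
    se: float
    p_value: float

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = scipy.stats.norm.ppf(0.5 + level / 2)
        return self.estimate - z * self.se, self.estimate + z * self.se


@dataclass
class AgeModelFit:
    """A fitted GLM: coefficients, fit statistics, and the raw result.

    ``aic`` is ``None`` for quasi-likelihood families, where AIC is not
    defined.  ``dispersion`` is the Pearson chi-square divided by residual
    degrees of freedom.
    """

    formula: str
    link: str
    family: str
    coefficients: dict[str, Coefficient]
    aic: float | None
    dispersion: float
    n_obs: int
    result: object = field(repr=False, default=None)
    n_dropped: int = 0

    def coef(self, name: str) -> Coefficient:
        return self.coefficients[name]


def _wrap_result(result, names: list[str], formula: str, link: str,
                 family: str, quasi: bool) -> AgeModelFit:
    coefs = {
        name: Coefficient(float(result.params[k]), float(result.bse[k]),
                          float(result.pvalues[k]))
        for k, name in enumerate(names)
    }
    df_resid = max(result.df_resid, 1)
    dispersion = float(result.pearson_chi2) / df_resid
    return AgeModelFit(
        formula=formula,
        link=link,
        family=family,
        coefficients=coefs,
        aic=None if quasi else float(result.aic),
        dispersion=dispersion,
        n_obs=int(result.nobs),
        result=result,
    )


def _identity_start_params(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares start values, nudged so all initial means are positive."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    mu = X @ beta
    if mu.min() <= 0:
        beta = beta.copy()
        beta[0] += 1e-3 - mu.min()
    return beta


class _ConstrainedIdentityResult:
    """Minimal GLM-result facade for the constrained identity-link fallback."""

    def __init__(self, y: np.ndarray, X: np.ndarray, params: np.ndarray,
                 offset: np.ndarray | None):
        class _Model:
            pass

        self.params = params
        mu = X @ params + (offset if offset is not None else 0.0)
        self.mu = mu
        self.model = _Model()
        self.model.endog = y
        self.nobs = y.size
        self.df_resid = y.size - X.shape[1]
        self.pearson_chi2 = float(np.sum((y - mu) ** 2 / mu))
        with np.errstate(divide="ignore"):
            ll_terms = y * np.log(mu) - mu - scipy.special.gammaln(y + 1)
        self.llf = float(np.sum(ll_terms))
        self.aic = 2 * X.shape[1] - 2 * self.llf
        # observed Fisher information for Poisson/identity: X' diag(y/mu^2) X
        # (expected form uses 1/mu; use expected for stability)
        info = X.T @ (X / mu[:, None])
        cov = np.linalg.pinv(info)
        self.bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = params / self.bse
        self.pvalues = 2 * scipy.stats.norm.sf(np.abs(z))


def _fit_identity_constrained(y: np.ndarray, X: np.ndarray,
                              offset: np.ndarray | None) -> _ConstrainedIdentityResult:
    """Direct likelihood maximization with a positivity barrier on the means.

    Used when IRLS leaves the feasible region, which happens when the true
    mean curve is strongly convex in age (the identity link's weakness)."""
    off = offset if offset is not None else 0.0

    def nll(beta):
        mu = X @ beta + off
        if mu.min() <= 1e-9:
            return 1e12 * (1 + abs(float(mu.min())))
        return float(np.sum(mu - y * np.log(mu)))

    start = _identity_start_params(y, X)
    mu0 = X @ start + off
    if np.min(mu0) <= 0:
        start = start.copy()
        start[0] += 1e-3 - float(np.min(mu0))
    best = scipy.optimize.minimize(nll, start, method="Nelder-Mead",
                                   options={"maxiter": 5000, "xatol": 1e-10,
                                            "fatol": 1e-10})
    if not np.isfinite(best.fun) or best.fun >= 1e11:
        raise FitError("identity-link likelihood has no feasible optimum")
    return _ConstrainedIdentityResult(y, X, np.asarray(best.x), offset)


def fit_poisson_glm(
    counts,
    covariates: dict[str, np.ndarray],
    link: str = "identity",
    offset: np.ndarray | None = None,
    formula: str | None = None,
) -> AgeModelFit:
    """Maximum-likelihood Poisson GLM with identity or log link.

    Identity-link fits are guarded: IRLS starts from a least-squares
    solution shifted into the positive-mean region, and if the converged
    fit has nonpositive fitted means the model is refit by direct likelihood
    maximization under a positivity barrier (a boundary-respecting analogue
    of R's step-halved glm.fit).
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise FitError("need >= 2 observations")
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise FitError("counts must be nonnegative integers")
    names = ["intercept"] + list(covariates)
    X = np.column_stack([np.ones_like(y)] + [np.asarray(v, dtype=float)
                                             for v in covariates.values()])
    if link == "identity":
        link_obj = sm.families.links.Identity()
    elif link == "log":
        link_obj = sm.families.links.Log()
    else:
        raise ValueError(f"unsupported link: {link}")
    if formula is None:
        formula = "counts ~ " + " + ".join(covariates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DomainWarning)
        model = sm.GLM(y, X, family=sm.families.Poisson(link=link_obj), offset=offset)
        kwargs = {}
        if link == "identity":
            kwargs["start_params"] = _identity_start_params(y, X)
        try:
            result = model.fit(maxiter=200, **kwargs)
            if not np.all(np.isfinite(result.params)):
                raise FitError("non-finite coefficients")
            if link == "identity" and result.mu.min() <= 0:
                raise FitError("nonpositive fitted means")
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError,
                FitError) as exc:
            if link != "identity":
                raise FitError(f"Poisson GLM did not converge: {exc}",
                               diagnostics={"n_obs": y.size, "link": link}) from exc
            result = _fit_identity_constrained(y, X, offset)
    return _wrap_result(result, names, formula, link, "poisson", quasi=False)


def fit_age_model(counts, age, link: str = "identity") -> AgeModelFit:
    """Regress per-child DNM counts on one parental age.

    The identity link estimates mutations per year directly; the log link is
    the exponential alternative.  Requires >= 2 distinct ages.
    """
    age = np.asarray(age, dtype=float)
    if np.unique(age).size < 2:
        raise FitError("need >= 2 distinct ages")
    return fit_poisson_glm(counts, {"age": age}, link=link,
                           formula=f"n_dnms ~ age [poisson, {link} link]")


def fit_offset_interaction_model(
    counts,
    age,
    class_flag,
    denoms,
    interaction: bool = True,
) -> AgeModelFit:
    """Log-link Poisson rate model contrasting two locus classes.

    Each child contributes one row per class: count of DNMs in that class,
    the parent's age, a 0/1 class indicator, and the number of panel loci in
    the class (the rate denominator, entering as offset log(denom) with
    coefficient forced to 1).  With ``interaction`` an age x class term
    tests whether the age effect differs between classes.  Rows with a
    nonpositive denominator are dropped with a warning.
    """
    y = np.asarray(counts, dtype=float)
    age = np.asarray(age, dtype=float)
    flag = np.asarray(class_flag, dtype=float)
    den = np.asarray(denoms, dtype=float)
    keep = den > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} rows with zero denominator")
    y, age, flag, den = y[keep], age[keep], flag[keep], den[keep]
    covs = {"age": age, "class": flag}
    terms = "age + class"
    if interaction:
        covs["age:class"] = age * flag
        terms += " + age:class"
    fit = fit_poisson_glm(y, covs, link="log", offset=np.log(den),
                          formula=f"n_dnms ~ {terms} + offset(log(denom))")
    fit.n_dropped = n_dropped
    return fit


def fit_alpha_model(pat_counts, mat_counts, age) -> AgeModelFit:
    """Quasi-binomial identity-link regression of the paternal fraction of
    phased DNMs on paternal age.

    Children with no phased DNMs are excluded (the fraction is undefined);
    the binomial denominator enters as variance weights and the scale is
    estimated from the Pearson chi-square, which is what makes the fit
    quasi-binomial.  The slope is the per-year change in alpha.
    """
    pat = np.asarray(pat_counts, dtype=float)
    mat = np.asarray(mat_counts, dtype=float)
    age = np.asarray(age, dtype=float)
    n = pat + mat
    keep = n >= 1
    if not keep.any():
        raise FitError("no children with phased DNMs")
    pat, n, age = pat[keep], n[keep], age[keep]
    frac = pat / n
    X = np.column_stack([np.ones_like(age), age])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DomainWarning)
        model = sm.GLM(frac, X,
                       family=sm.families.Binomial(link=sm.families.links.Identity()),
                       var_weights=n)
        try:
            result = model.fit(maxiter=200,
                               start_params=_identity_start_params(frac, X))
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError) as exc:
            raise FitError(f"alpha model did not converge: {exc}") from exc
        result = model.fit(maxiter=200, start_params=result.params, scale="X2")
    mu = result.mu
    if mu.min() < 0 or mu.max() > 1:
        raise FitError("alpha fit produced fitted fractions outside [0, 1]",
                       diagnostics={"min_mu": float(mu.min()), "max_mu": float(mu.max())})
    fit = _wrap_result(result, ["intercept", "age"],
                       "alpha ~ age [quasi-binomial, identity link]",
                       "identity", "quasibinomial", quasi=True)
    fit.n_dropped = int((~keep).sum())
    return fit


@dataclass
class OverdispersionResult:
    dispersion: float  # Pearson chi2 / df
    statistic: float  # Cameron-Trivedi auxiliary t statistic
    p_value: float  # one-sided (overdispersion) p


def overdispersion_test(fit: AgeModelFit) -> OverdispersionResult:
    """Cameron-Trivedi test for overdispersion of a Poisson fit.

    Regresses ((y - mu)^2 - y) / mu on mu without intercept; a positive
    coefficient indicates variance growing faster than the mean.  Requires
    more observations than parameters.
    """
    result = fit.result
    if result is None or fit.family != "poisson":
        raise StrDenovoError("overdispersion test requires a Poisson fit with raw result")
    y = np.asarray(result.model.endog, dtype=float)
    mu = np.asarray(result.mu, dtype=float)
    if y.size < len(fit.coefficients) + 2:
        raise StrDenovoError("too few observations for an overdispersion test")
    aux = ((y - mu) ** 2 - y) / mu
    ols = sm.OLS(aux, mu[:, None]).fit()
    stat = float(ols.tvalues[0])
    p = float(scipy.stats.t.sf(stat, df=ols.df_resid))
    return OverdispersionResult(dispersion=fit.dispersion, statistic=stat, p_value=p)


def compare_models_aic(fits: dict[str, AgeModelFit]) -> pd.DataFrame:
    """Rank fits of the same response by AIC.

    Quasi-likelihood fits have no AIC and are listed with a note instead of
    a rank.  Delta AIC is relative to the best (lowest-AIC) model.
    """
    rows = []
    valid = {name: f for name, f in fits.items() if f.aic is not None}
    if not valid:
        raise StrDenovoError("no AIC-comparable fits")
    n_obs = {f.n_obs for f in valid.values()}
    if len(n_obs) > 1:
        raise StrDenovoError("fits compare different data (n_obs differ)")
    best = min(f.aic for f in valid.values())
    for name, f in fits.items():
        if f.aic is None:
            rows.append({"model": name, "aic": np.nan, "delta_aic": np.nan,
                         "note": "quasi-likelihood: AIC undefined"})
        else:
            rows.append({"model": name, "aic": f.aic, "delta_aic": f.aic - best,
                         "note": ""})
    out = pd.DataFrame(rows).sort_values("aic", na_position="last").reset_index(drop=True)
    return out


def subgroup_age_models(
    dnms: pd.DataFrame,
    ages: pd.Series,
    group_col: str,
    min_dnms: int = 20,
    link: str = "identity",
) -> pd.DataFrame:
    """Fit a separate age model per DNM subgroup with Bonferroni correction.

    ``dnms`` is a long table with one row per phased DNM (columns ``child``
    and ``group_col``); ``ages`` maps every cohort child to the relevant
    parental age (children with zero DNMs in a group enter as zero counts).
    Groups with <= ``min_dnms`` total DNMs are skipped.  Returns one row per
    tested group with the slope, its raw p, and the Bonferroni-adjusted p
    across tested groups.
    """
    children = ages.index
    tested = []
    for group, sub in dnms.groupby(group_col):
        if len(sub) <= min_dnms:
            continue
        counts = sub.groupby("child").size().reindex(children, fill_value=0)
        try:
            fit = fit_age_model(counts.to_numpy(), ages.to_numpy(), link=link)
        except FitError:
            continue
        coef = fit.coef("age")
        tested.append({"group": group, "n_dnms": len(sub),
                       "slope": coef.estimate, "se": coef.se,
                       "p_raw": coef.p_value})
    if not tested:
        return pd.DataFrame(columns=["group", "n_dnms", "slope", "se",
                                     "p_raw", "p_bonferroni"])
    out = pd.DataFrame(tested)
    out["p_bonferroni"] = np.minimum(out["p_raw"] * len(out), 1.0)
    return out


def compare_expansion_deletion(counts_a, counts_b, age,
                               labels: tuple[str, str] = ("expansion", "deletion")
                               ) -> dict[str, float]:
    """Test whether two mutation classes (e.g. expansions vs deletions)
    differ in age-model intercept or slope.

    Fits one identity-link Poisson GLM on the stacked per-child counts with
    a class indicator and an age x class interaction; the indicator's p
    tests the intercept difference and the interaction's p the slope
    difference.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    age = np.asarray(age, dtype=float)
    y = np.concatenate([a, b])
    ages2 = np.concatenate([age, age])
    flag = np.concatenate([np.zeros_like(a), np.ones_like(b)])
    fit = fit_poisson_glm(y, {"age": ages2, "class": flag, "age:class": ages2 * flag},
                          link="identity",
                          formula=f"n_dnms ~ age * class [{labels[0]} vs {labels[1]}]")
    return {
        "p_intercept_difference": fit.coef("class").p_value,
        "p_slope_difference": fit.coef("age:class").p_value,
        "fit": fit,
    }


def dfe_ks_test(s_group_a, s_group_b) -> tuple[float, float]:
    """Two-sided Kolmogorov-Smirnov test comparing the selection-coefficient
    distributions of two DNM groups (e.g. below- vs above-median parental
    age, or proband vs sibling)."""
    a = np.asarray(list(s_group_a), dtype=float)
    b = np.asarray(list(s_group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise StrDenovoError("both groups must be nonempty")
    res = scipy.stats.ks_2samp(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def constraint_interaction_model(counts, age, constrained_flag, denoms) -> AgeModelFit:
    """Poisson model of DNM counts at constrained vs neutral loci with a
    constraint x age interaction and a log locus-count offset; the
    interaction p-value asks whether parental age shifts the DFE."""
    return fit_offset_interaction_model(counts, age, constrained_flag, denoms,
                                        interaction=True)
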