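"""Statistical links of the trophic cascade.

Cranefly quartet counts are modelled as a negative-binomial log-link GLM
of the previous summer's mean water-table depth plus a region factor;
soil moisture checks the hydrology by ordinary least squares; breeding
bird counts (dunlin, golden plover, red grouse) are modelled as NB GLMs
of modelled cranefly abundance, with a spatially smoothed GAM variant as
a robustness check; square-level persistence categories are compared by
Kruskal-Wallis and pairwise Wilcoxon rank-sum tests; and fitted bird
models are projected onto future cranefly abundance.

The NB dispersion parameter theta follows the common alternating scheme:
an IRLS GLM fit at fixed theta, then a maximum-likelihood update of
theta at fixed means, iterated to convergence (as in MASS ``glm.nb``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "NBFitResult",
    "PersistenceCategory",
    "sum_quartet",
    "fit_negbin_glm",
    "deviance_explained",
    "predict_cranefly",
    "fit_moisture_regression",
    "fit_bird_glm",
    "fit_bird_gam_check",
    "year_correlation",
    "categorize_persistence",
    "kruskal_wallis",
    "pairwise_wilcoxon",
    "compact_letter_display",
    "project_birds",
    "REGIONS",
    "QUARTET_AREA_M2",
]

REGIONS = ("MidWales", "NorthYorkMoors", "SouthPennines")
# four emergence traps of ~0.11 m2 each per quartet
QUARTET_AREA_M2 = 4 * 0.11

PERSISTENCE_CATEGORIES = ("empty", "extinct", "colonised", "occupied")
PersistenceCategory = str


def sum_quartet(trap_counts: Sequence[int]) -> int:
    """Total adult count across the four traps of a quartet."""
    counts = list(trap_counts)
    if any(c < 0 for c in counts):
        raise ValueError("trap counts must be non-negative")
    return int(sum(counts))


# --------------------------------------------------------------------------
# negative-binomial GLM
# --------------------------------------------------------------------------

@dataclass
class NBFitResult:
    """Coefficients and fit statistics of an NB log-link GLM."""

    coef: pd.DataFrame          # index: term; columns: estimate, se, z, p
    theta: float
    null_deviance: float
    residual_deviance: float
    n: int
    loglik: float
    converged: bool
    fitted_mean: np.ndarray = field(repr=False, default=None)
    factor_levels: dict = field(default_factory=dict)

    @property
    def params(self) -> pd.Series:
        return self.coef["estimate"]


def _nb_loglik_theta(theta: float, y: np.ndarray, mu: np.ndarray) -> float:
    """NB2 log-likelihood as a function of theta at fixed means."""
    return float(np.sum(
        special.gammaln(y + theta) - special.gammaln(theta)
        - special.gammaln(y + 1.0)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))))


def _ml_theta(y: np.ndarray, mu: np.ndarray, start: float) -> float:
    """Profile-maximise the NB likelihood over theta (on log scale)."""
    def nll(log_t):
        return -_nb_loglik_theta(math.exp(log_t), y, mu)

    res = optimize.minimize_scalar(
        nll, bracket=(math.log(start) - 1.0, math.log(start) + 1.0),
        method="brent", options={"xtol": 1e-10})
    return float(np.clip(math.exp(res.x), 1e-4, 1e7))


def _moment_theta(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments starting value for theta."""
    num = np.sum(mu**2)
    den = np.sum((y - mu) ** 2 - mu)
    if den <= 0:
        return 100.0  # under-dispersed: start near Poisson
    return float(np.clip(num / den, 1e-3, 1e6))


def build_design(predictors: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Design matrix with intercept; categoricals get treatment coding
    with the alphabetically first level as reference.

    Returns the matrix and a ``{factor: [levels...]}`` map (reference
    level first).
    """
    cols = [pd.Series(1.0, index=predictors.index, name="(Intercept)")]
    levels_map: dict = {}
    for name in predictors.columns:
        col = predictors[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(col.astype(str)))
            levels_map[name] = levels
            for lev in levels[1:]:
                cols.append(pd.Series((col.astype(str) == lev).astype(float),
                                      index=predictors.index,
                                      name=f"{name}[{lev}]"))
        else:
            cols.append(col.astype(float))
    return pd.concat(cols, axis=1), levels_map


def fit_negbin_glm(response: Sequence[int], design: pd.DataFrame,
                   tol: float = 1e-8, max_iter: int = 100) -> NBFitResult:
    """NB log-link GLM with theta estimated by alternating profiling.

    ``design`` holds raw predictors (numeric and/or string-valued factor
    columns); an intercept is added and factors are treatment-coded with
    the alphabetically first level as reference.
    """
    y = np.asarray(response, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("response must be non-negative integer counts")
    X, levels_map = build_design(design)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than parameters")
    if np.linalg.matrix_rank(X.to_numpy()) < p:
        raise ValueError("design matrix is rank deficient")

    # initial means from a Poisson fit
    pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    mu = np.asarray(pois.mu)
    theta = _moment_theta(y, mu)
    converged = False
    res = None
    for _ in range(max_iter):
        fam = sm.families.NegativeBinomial(alpha=1.0 / theta)
        res = sm.GLM(y, X, family=fam).fit(start_params=res.params if res is not None else None)
        mu = np.asarray(res.mu)
        theta_new = _ml_theta(y, mu, theta)
        if abs(theta_new - theta) / (abs(theta) + 1e-12) < tol:
            theta = theta_new
            converged = True
            break
        theta = theta_new
    if not converged:
        logger.warning("theta alternation did not converge in %d iterations", max_iter)
    fam = sm.families.NegativeBinomial(alpha=1.0 / theta)
    res = sm.GLM(y, X, family=fam).fit(start_params=res.params)
    mu = np.asarray(res.mu)

    # null deviance at the SAME theta so deviance explained is well defined
    null = sm.GLM(y, np.ones((n, 1)), family=fam).fit()
    zvals = res.params / res.bse
    coef = pd.DataFrame({
        "estimate": res.params, "se": res.bse, "z": zvals,
        "p": 2.0 * stats.norm.sf(np.abs(zvals)),
    })
    ll = _nb_loglik_theta(theta, y, mu)
    return NBFitResult(coef=coef, theta=float(theta),
                       null_deviance=float(null.deviance),
                       residual_deviance=float(res.deviance),
                       n=n, loglik=ll, converged=converged, fitted_mean=mu,
                       factor_levels=levels_map)


def deviance_explained(fit: NBFitResult) -> float:
    """(null - residual) / null deviance, both at the fitted theta."""
    if fit.null_deviance <= 0:
        raise ValueError("null deviance is zero; fraction undefined")
    return (fit.null_deviance - fit.residual_deviance) / fit.null_deviance


def predict_cranefly(wtd_cm, fit: NBFitResult, region: str | None = None):
    """Expected quartet count at ``wtd_cm`` from a fitted cranefly model.

    ``region=None`` predicts for the reference region (zero factor
    effect).  Works elementwise on arrays.
    """
    params = fit.params
    eta = params["(Intercept)"] + params.get("wtd_cm", 0.0) * np.asarray(wtd_cm, float)
    if region is not None:
        levels = fit.factor_levels.get("region", [])
        if levels and region not in levels:
            raise ValueError(f"unknown region level: {region}")
        key = f"region[{region}]"
        if key in params.index:
            eta = eta + params[key]
    return np.exp(eta)


# --------------------------------------------------------------------------
# ordinary least squares links
# --------------------------------------------------------------------------

@dataclass
class OLSFitResult:
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    t_intercept: float
    t_slope: float
    r_squared: float
    f_stat: float
    f_pvalue: float
    n: int


def fit_moisture_regression(moisture: Sequence[float],
                            wtd_cm: Sequence[float]) -> OLSFitResult:
    """OLS of volumetric soil moisture on modelled WTD."""
    m = np.asarray(moisture, float)
    w = np.asarray(wtd_cm, float)
    if len(m) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(w) == 0:
        raise ValueError("constant predictor")
    X = sm.add_constant(w)
    res = sm.OLS(m, X).fit()
    return OLSFitResult(
        intercept=float(res.params[0]), slope=float(res.params[1]),
        se_intercept=float(res.bse[0]), se_slope=float(res.bse[1]),
        t_intercept=float(res.tvalues[0]), t_slope=float(res.tvalues[1]),
        r_squared=float(res.rsquared), f_stat=float(res.fvalue),
        f_pvalue=float(res.f_pvalue), n=int(res.nobs))


# --------------------------------------------------------------------------
# bird models
# --------------------------------------------------------------------------

def fit_bird_glm(birds: pd.DataFrame, species: str,
                 scope: str = "pooled") -> NBFitResult:
    """NB GLM of bird counts on modelled cranefly abundance.

    ``birds`` columns: species, count_1990, count_2004, cranefly_1990,
    cranefly_2004 (cranefly abundance of the year preceding each
    survey).  ``scope``: "1990", "2004", or "pooled" (stacks both years
    in one model, no year term).
    """
    sub = birds[birds["species"] == species]
    if sub.empty:
        raise ValueError(f"no rows for species {species!r}")
    if scope in ("1990", "2004"):
        y = sub[f"count_{scope}"].to_numpy()
        x = sub[f"cranefly_{scope}"].to_numpy(float)
    elif scope == "pooled":
        y = np.concatenate([sub["count_1990"].to_numpy(),
                            sub["count_2004"].to_numpy()])
        x = np.concatenate([sub["cranefly_1990"].to_numpy(float),
                            sub["cranefly_2004"].to_numpy(float)])
    else:
        raise ValueError("scope must be '1990', '2004' or 'pooled'")
    design = pd.DataFrame({"cranefly": x})
    return fit_negbin_glm(y, design)


def fit_bird_gam_check(counts: Sequence[int], cranefly: Sequence[float],
                       xy: np.ndarray, df_smooth: int = 8,
                       alpha_penalty: float = 1.0) -> dict:
    """Spatial-robustness check: NB GAM with a linear cranefly term plus
    penalised spline smooths of the x and y coordinates.

    Returns the cranefly coefficient and standard error from both the
    GAM and a plain GLM, so spatial confounding of the food-abundance
    effect can be judged (coefficients of similar magnitude indicate no
    strong confounding).  Theta is fixed at the plain GLM's estimate.
    """
    from statsmodels.gam.api import BSplines, GLMGam

    y = np.asarray(counts, float)
    cf = np.asarray(cranefly, float)
    xy = np.asarray(xy, float)
    if len(y) < 30:
        raise ValueError("need at least 30 observations for the smooth")
    glm = fit_negbin_glm(y.astype(int), pd.DataFrame({"cranefly": cf}))
    out = {
        "glm_coef": float(glm.params["cranefly"]),
        "glm_se": float(glm.coef.loc["cranefly", "se"]),
        "theta": glm.theta,
    }
    try:
        smoother = BSplines(xy, df=[df_smooth, df_smooth], degree=[3, 3])
        Xlin = sm.add_constant(pd.DataFrame({"cranefly": cf}))
        fam = sm.families.NegativeBinomial(alpha=1.0 / glm.theta)
        gam = GLMGam(y, Xlin, smoother=smoother,
                     alpha=[alpha_penalty, alpha_penalty], family=fam).fit()
        out["gam_coef"] = float(gam.params["cranefly"])
        out["gam_se"] = float(gam.bse.iloc[Xlin.columns.get_loc("cranefly")])
        out["gam_ok"] = True
    except Exception:
        logger.exception("spatial smooth failed; reporting GLM only")
        out["gam_ok"] = False
    return out


# --------------------------------------------------------------------------
# persistence and rank tests
# --------------------------------------------------------------------------

def year_correlation(counts_1990: Sequence[int],
                     counts_2004: Sequence[int]) -> float:
    """Spearman rank correlation between the two survey years."""
    a = np.asarray(counts_1990, float)
    b = np.asarray(counts_2004, float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance; rank correlation undefined")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


def categorize_persistence(count_1990: int, count_2004: int) -> PersistenceCategory:
    """empty / extinct / colonised / occupied from presence in each year."""
    if count_1990 < 0 or count_2004 < 0:
        raise ValueError("counts must be non-negative")
    if count_1990 == 0 and count_2004 == 0:
        return "empty"
    if count_1990 > 0 and count_2004 == 0:
        return "extinct"
    if count_1990 == 0 and count_2004 > 0:
        return "colonised"
    return "occupied"


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H, degrees of freedom and p value."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need total n >= 3")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise ValueError("all observations identical; H undefined under "
                         "tie correction")
    h, p = stats.kruskal(*groups)
    return float(h), len(groups) - 1, float(p)


def pairwise_wilcoxon(groups: Mapping[str, Sequence[float]],
                      alpha: float = 0.05,
                      adjust: str | None = None) -> tuple[pd.DataFrame, dict]:
    """Two-sided rank-sum tests for every pair of groups.

    Exact distribution when the smaller group has <= 25 observations and
    there are no ties; otherwise normal approximation with continuity
    correction.  p values are unadjusted by default (``adjust='holm'``
    or ``'bonferroni'`` available).  Returns the symmetric p-value matrix
    and a compact-letter display at ``alpha``.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size == 0:
            raise ValueError(f"group {k!r} is empty")
    pmat = pd.DataFrame(np.ones((len(names), len(names))), index=names,
                        columns=names)
    raw = {}
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            a, b = arrays[gi], arrays[gj]
            ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
            method = "exact" if (min(len(a), len(b)) <= 25 and not ties) else "asymptotic"
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method=method).pvalue)
            raw[(gi, gj)] = p
    pvals = raw
    if adjust is not None:
        from statsmodels.stats.multitest import multipletests

        keys = list(raw)
        _, adj, _, _ = multipletests([raw[k] for k in keys], method=adjust)
        pvals = dict(zip(keys, adj))
    for (gi, gj), p in pvals.items():
        pmat.loc[gi, gj] = pmat.loc[gj, gi] = p
    letters = compact_letter_display(pmat, {k: float(np.median(v))
                                            for k, v in arrays.items()}, alpha)
    return pmat, letters


def compact_letter_display(pmat: pd.DataFrame, order_stat: Mapping[str, float],
                           alpha: float = 0.05) -> dict:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``.
    Groups are lettered in increasing order of ``order_stat`` (e.g. the
    median), so 'a' marks the lowest-valued cluster.
    """
    names = sorted(pmat.index, key=lambda g: order_stat[g])
    # start with one letter-set containing all groups, then split on each
    # significant pair (insert), and absorb redundant subsets
    sets: list[set] = [set(names)]
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            if pmat.loc[gi, gj] < alpha:
                new_sets = []
                for s in sets:
                    if gi in s and gj in s:
                        new_sets.extend([s - {gi}, s - {gj}])
                    else:
                        new_sets.append(s)
                # absorb: drop sets contained in another
                sets = [s for s in new_sets
                        if s and not any(s < t for t in new_sets if t is not s)]
                # dedupe
                uniq = []
                for s in sets:
                    if s not in uniq:
                        uniq.append(s)
                sets = uniq
    sets.sort(key=lambda s: min(names.index(g) for g in s))
    labels = {g: "" for g in names}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", sets):
        for g in names:
            if g in s:
                labels[g] += letter
    return labels


# --------------------------------------------------------------------------
# projection
# --------------------------------------------------------------------------

def project_birds(fit: NBFitResult, baseline_cranefly: float,
                  future_cranefly: float) -> tuple[float, float, float]:
    """Bird abundance at baseline vs future cranefly abundance.

    Returns (baseline abundance, future abundance, percent change), with
    percent change = 100 * (baseline - future) / baseline, i.e. positive
    numbers are declines.
    """
    params = fit.params
    slope = params.get("cranefly", params.iloc[-1])
    base = math.exp(params["(Intercept)"] + slope * baseline_cranefly)
    fut = math.exp(params["(Intercept)"] + slope * future_cranefly)
    if base <= 0:
        raise ValueError("non-positive baseline abundance")
    return base, fut, 100.0 * (base - fut) / base
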