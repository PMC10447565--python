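"""Multi-model inference for soil organic carbon.

The SOC model stage takes a per-site table of twelve predictors spanning four
categories — climate (growing-season precipitation and temperature), soil
properties (pH, N/P ratio, available P, water content), microbial carbon
pools (biomass C, necromass C) and microbial community properties (bacterial
and fungal Shannon diversity, network complexity PC1/PC2) — and asks which
combination best predicts SOC:

1. Z-score every predictor and the response (ddof=1).
2. Fit every subset of the predictor roster by OLS (Gaussian maximum
   likelihood) and rank by AICc.
3. Average coefficients over the confidence set (ΔAICc < 2) with Akaike
   weights, substituting zero where a predictor is absent from a model
   ("full" averaging), with unconditional standard errors.
4. Express each averaged coefficient as a relative-importance percentage,
   |β̂ⱼ| / Σ|β̂ₖ| × 100, also summed by category.
5. Compare four nested predictor suites (#1 all twelve; #2 without the
   community properties; #3 without the carbon pools; #4 climate + soil
   only) by their best AICc.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# the twelve-predictor roster, by category
PREDICTOR_GROUPS: dict[str, tuple[str, ...]] = {
    "climate": ("mgp", "mgt"),
    "soil": ("ph", "np_ratio", "ap", "swc"),
    "microbial_c_pools": ("mbc", "mnc"),
    "community": ("bacterial_shannon", "fungal_shannon", "net_pc1", "net_pc2"),
}
PREDICTOR_NAMES: tuple[str, ...] = tuple(
    name for names in PREDICTOR_GROUPS.values() for name in names
)

# suite rosters: #2 drops community properties, #3 drops C pools, #4 drops both
SUITE_ROSTERS: dict[int, tuple[str, ...]] = {
    1: PREDICTOR_NAMES,
    2: PREDICTOR_GROUPS["climate"] + PREDICTOR_GROUPS["soil"] + PREDICTOR_GROUPS["microbial_c_pools"],
    3: PREDICTOR_GROUPS["climate"] + PREDICTOR_GROUPS["soil"] + PREDICTOR_GROUPS["community"],
    4: PREDICTOR_GROUPS["climate"] + PREDICTOR_GROUPS["soil"],
}

_Z975 = stats.norm.ppf(0.975)


def z_standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score each column; returns (standardized table, mean/sd parameters).

    SD uses denominator n-1.  The parameter frame (columns ``mean``, ``sd``)
    inverts the transform: ``x = z * sd + mean``.
    """
    means = table.mean()
    sds = table.std(ddof=1)
    constant = sds[(sds == 0) | ~np.isfinite(sds)]
    if len(constant):
        raise ValueError(f"constant column(s) cannot be standardized: {list(constant.index)}")
    z = (table - means) / sds
    params = pd.DataFrame({"mean": means, "sd": sds})
    return z, params


@dataclass
class FittedModel:
    """One OLS/ML fit: a predictor subset with its information-criterion bookkeeping."""

    predictors: tuple[str, ...]
    coefficients: np.ndarray  # intercept first
    log_likelihood: float
    k: int  # intercept + slopes + error variance
    aicc: float
    r_squared: float
    delta: float = math.nan
    weight: float = math.nan
    # filled on demand (confidence-set models only)
    coef_se: np.ndarray | None = None


# floor on the ML error variance so a perfect fit yields a finite (capped)
# log-likelihood instead of +inf; documented degenerate-case guard
_VARIANCE_FLOOR = 1e-30


def _loglik_from_rss(rss: float, n: int) -> float:
    sigma2 = max(rss / n, _VARIANCE_FLOOR)
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


def _aicc(loglik: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        raise ValueError(f"sample size {n} too small for k={k} parameters with AICc")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_ols_ml(y: np.ndarray, X: pd.DataFrame, *, ic: str = "aicc") -> FittedModel:
    """OLS fit with Gaussian ML log-likelihood and AICc (or AIC).

    ``k`` counts the intercept, the slopes and the error variance.  The
    design must be full rank and n > k.
    """
    y = np.asarray(y, float)
    names = tuple(X.columns)
    A = np.column_stack([np.ones(len(y)), X.to_numpy(float)])
    n, p = A.shape
    k = p + 1
    if n <= k:
        raise ValueError(f"n={n} too small for {p} coefficients")
    beta, rss_, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < p:
        raise ValueError("rank-deficient design matrix")
    resid = y - A @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    ll = _loglik_from_rss(rss, n)
    crit = _aicc(ll, k, n) if ic == "aicc" else -2.0 * ll + 2.0 * k
    model = FittedModel(names, beta, ll, k, crit, r2)
    # unbiased-variance OLS standard errors for downstream averaging
    if n > p:
        sigma2 = rss / (n - p)
        cov = sigma2 * np.linalg.inv(A.T @ A)
        model.coef_se = np.sqrt(np.diag(cov))
    return model


@dataclass
class ModelSet:
    """All fitted subsets, sorted by the information criterion."""

    models: list[FittedModel]
    predictor_names: tuple[str, ...]
    n: int
    ic: str = "aicc"

    @property
    def best(self) -> FittedModel:
        return self.models[0]

    def confidence_set(self, delta_max: float = 2.0) -> list[FittedModel]:
        return [m for m in self.models if m.delta < delta_max]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictors": ["+".join(m.predictors) if m.predictors else "(intercept)" for m in self.models],
                "k": [m.k for m in self.models],
                self.ic: [m.aicc for m in self.models],
                "delta": [m.delta for m in self.models],
                "weight": [m.weight for m in self.models],
                "r_squared": [m.r_squared for m in self.models],
            }
        )


def all_subsets(
    y: np.ndarray,
    predictors: pd.DataFrame,
    *,
    max_terms: int = 16,
    ic: str = "aicc",
) -> ModelSet:
    """Fit every predictor subset (2^p models, intercept-only included).

    Uses Gram-matrix updates for speed; coefficient SEs for the confidence
    set are filled in by :func:`average_models`.  ``p`` is capped at
    ``max_terms`` (default 16) because enumeration is exponential.
    """
    names = tuple(predictors.columns)
    p = len(names)
    if p > max_terms:
        raise ValueError(
            f"{p} predictors would need 2^{p} fits; pass max_terms>{p} explicitly to force"
        )
    y = np.asarray(y, float)
    n = len(y)
    A = np.column_stack([np.ones(n), predictors.to_numpy(float)])
    G = A.T @ A
    Aty = A.T @ y
    yty = float(y @ y)
    tss = float(np.sum((y - y.mean()) ** 2))

    models: list[FittedModel] = []
    for r in range(p + 1):
        for combo in itertools.combinations(range(p), r):
            idx = np.array((0,) + tuple(c + 1 for c in combo))
            Gi = G[np.ix_(idx, idx)]
            try:
                beta = np.linalg.solve(Gi, Aty[idx])
            except np.linalg.LinAlgError as exc:
                raise ValueError(f"rank-deficient subset {combo}") from exc
            rss = max(yty - float(beta @ Aty[idx]), 0.0)
            k = len(idx) + 1
            if n - k - 1 <= 0:
                continue
            ll = _loglik_from_rss(rss, n)
            crit = _aicc(ll, k, n) if ic == "aicc" else -2.0 * ll + 2.0 * k
            r2 = 1.0 - rss / tss if tss > 0 else 0.0
            models.append(FittedModel(tuple(names[c] for c in combo), beta, ll, k, crit, r2))

    best = min(m.aicc for m in models)
    rel = np.array([m.aicc - best for m in models])
    w = np.exp(-0.5 * rel)
    w /= w.sum()
    for m, d, wi in zip(models, rel, w):
        m.delta = float(d)
        m.weight = float(wi)
    models.sort(key=lambda m: m.aicc)
    return ModelSet(models, names, n, ic)


@dataclass
class AveragedModel:
    """Model-averaged standardized coefficients over the ΔIC < 2 confidence set."""

    table: pd.DataFrame  # index predictor; estimate, se, ci_lo, ci_hi, p_value
    n_models: int
    delta_max: float
    method: str

    @property
    def estimates(self) -> pd.Series:
        return self.table["estimate"]


def average_models(
    ms: ModelSet,
    delta_max: float = 2.0,
    *,
    y: np.ndarray | None = None,
    predictors: pd.DataFrame | None = None,
    method: str = "full",
) -> AveragedModel:
    """Akaike-weighted averaging over models with ΔIC < ``delta_max``.

    "full" averaging substitutes β=0 (SE 0) where a model omits a predictor;
    "conditional" averages only over the models containing it.  Unconditional
    SEs follow Burnham–Anderson: SE = Σ wᵢ·sqrt(seᵢ² + (βᵢ − β̄)²).  Wald
    95% CIs and normal-approximation p-values derive from that SE.

    Pass ``y`` and ``predictors`` (the standardized data used for
    :func:`all_subsets`) so per-model coefficient SEs can be computed for
    the confidence set; without them the Gram path has no SEs stored.
    """
    if method not in ("full", "conditional"):
        raise ValueError(f"unknown averaging method {method!r}")
    cset = ms.confidence_set(delta_max)
    if not cset:
        raise ValueError("empty confidence set (the best model always has delta 0)")
    wsum = sum(m.weight for m in cset)
    weights = [m.weight / wsum for m in cset]

    for m in cset:
        if m.coef_se is None:
            if y is None or predictors is None:
                raise ValueError("pass y and predictors so confidence-set SEs can be computed")
            refit = fit_ols_ml(y, predictors[list(m.predictors)], ic=ms.ic)
            m.coef_se = refit.coef_se
            m.coefficients = refit.coefficients

    rows = {}
    for name in ms.predictor_names:
        betas, ses, ws = [], [], []
        for m, w in zip(cset, weights):
            if name in m.predictors:
                j = m.predictors.index(name) + 1  # intercept first
                betas.append(m.coefficients[j])
                ses.append(m.coef_se[j])
                ws.append(w)
            elif method == "full":
                betas.append(0.0)
                ses.append(0.0)
                ws.append(w)
        if not ws:
            rows[name] = (0.0, math.nan, math.nan, math.nan, math.nan)
            continue
        betas = np.asarray(betas)
        ses = np.asarray(ses)
        ws = np.asarray(ws)
        if method == "conditional":
            ws = ws / ws.sum()
        est = float(ws @ betas)
        se = float(ws @ np.sqrt(ses**2 + (betas - est) ** 2))
        if se > 0:
            pval = 2.0 * stats.norm.sf(abs(est) / se)
            lo, hi = est - _Z975 * se, est + _Z975 * se
        else:
            pval, lo, hi = (math.nan, est, est)
        rows[name] = (est, se, lo, hi, pval)

    table = pd.DataFrame(
        rows, index=["estimate", "se", "ci_lo", "ci_hi", "p_value"]
    ).T
    return AveragedModel(table, len(cset), delta_max, method)


def relative_importance(avg: AveragedModel) -> tuple[pd.Series, pd.Series]:
    """Relative effect of each predictor as a percentage.

    100·|β̂ⱼ| / Σ|β̂ₖ| over the averaged estimates (absolute values, so mixed
    signs cannot push a share above 100%), plus sums over the four predictor
    categories.  Returns ``(per_predictor, per_group)``.
    """
    est = avg.estimates.abs()
    total = est.sum()
    if total == 0:
        raise ValueError("all averaged estimates are zero")
    per = 100.0 * est / total
    groups = {}
    for group, names in PREDICTOR_GROUPS.items():
        groups[group] = float(per.reindex(names).fillna(0.0).sum())
    return per, pd.Series(groups)


@dataclass
class SuiteComparison:
    """Best-model AICc and R² for predictor suites #1-#4, ranked by AICc."""

    table: pd.DataFrame  # index suite number; roster, aicc, r_squared, rank
    averaged: dict[int, AveragedModel] = field(default_factory=dict)

    def delta_vs_best_suite(self) -> pd.Series:
        return self.table["aicc"] - self.table["aicc"].min()


def compare_suites(
    y: np.ndarray,
    predictors: pd.DataFrame,
    *,
    ic: str = "aicc",
    delta_max: float = 2.0,
) -> SuiteComparison:
    """Run the all-subsets → averaging pipeline inside each of the four suites.

    Suite #1 holds all twelve predictors; #2 drops the community properties;
    #3 drops the microbial carbon pools; #4 keeps climate + soil only.  Each
    suite reports the best subset's AICc and R²; ranking is by AICc (lower
    is better).
    """
    missing = set(PREDICTOR_NAMES) - set(predictors.columns)
    if missing:
        raise ValueError(f"predictor table is missing: {sorted(missing)}")
    rows = []
    averaged = {}
    for suite, roster in SUITE_ROSTERS.items():
        ms = all_subsets(y, predictors[list(roster)], ic=ic)
        avg = average_models(ms, delta_max, y=y, predictors=predictors[list(roster)])
        averaged[suite] = avg
        rows.append(
            {
                "suite": suite,
                "roster": "+".join(roster),
                "n_predictors": len(roster),
                "aicc": ms.best.aicc,
                "r_squared": ms.best.r_squared,
            }
        )
    table = pd.DataFrame(rows).set_index("suite")
    table["rank"] = table["aicc"].rank(method="min").astype(int)
    return SuiteComparison(table, averaged)
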