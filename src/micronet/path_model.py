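"""Recursive path analysis (SEM) linking microbial properties to SOC.

SOC is first residualized on the climate and soil-property covariates by
multiple regression; the residual then enters a recursive path model with
the microbial variables (diversity, network complexity, biomass C,
necromass C).  All variables are observed, so the model is a system of
linear structural equations

    y = B y + ζ,        Cov(ζ) = Ψ,

with B strictly triangular under a topological order of the acyclic path
graph and Ψ carrying exogenous variances/covariances and endogenous
residual variances.  The implied covariance Σ(θ) = (I−B)⁻¹ Ψ (I−B)⁻ᵀ is
fitted to the sample covariance S by minimizing the ML discrepancy

    F_ML(θ) = ln|Σ| − ln|S| + tr(S Σ⁻¹) − p,

and χ² = (n−1)·F̂ with df = p(p+1)/2 − (number of free parameters).
Fit indices: RMSEA, CFI against the independence baseline, and GFI.
Standardized coefficients use model-implied SDs; total effects follow
Wright's rules (direct edge plus all products of coefficients along
directed paths).

Two editable path-topology configs (maize and rice) ship as JSON under
``micronet/path_specs/``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class PathSpecification:
    """Variables, directed edges and exogenous covariances of an acyclic path model."""

    variables: list[str]
    edges: list[tuple[str, str]]
    covariances: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        vars_ = set(self.variables)
        for a, b in list(self.edges) + list(self.covariances):
            if a not in vars_ or b not in vars_:
                raise ValueError(f"undeclared variable in ({a}, {b})")
        g = nx.DiGraph(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("path graph must be acyclic")
        self.edges = [tuple(e) for e in self.edges]
        self.covariances = [tuple(c) for c in self.covariances]
        endo = {b for _, b in self.edges}
        for a, b in self.covariances:
            if a in endo or b in endo:
                raise ValueError(f"covariance ({a}, {b}) touches an endogenous variable")

    @property
    def endogenous(self) -> list[str]:
        endo = {b for _, b in self.edges}
        return [v for v in self.variables if v in endo]

    @property
    def exogenous(self) -> list[str]:
        endo = {b for _, b in self.edges}
        return [v for v in self.variables if v not in endo]

    @classmethod
    def from_json(cls, path: str | Path) -> "PathSpecification":
        payload = json.loads(Path(path).read_text())
        return cls(
            variables=payload["variables"],
            edges=[tuple(e) for e in payload["edges"]],
            covariances=[tuple(c) for c in payload.get("covariances", [])],
        )


def load_builtin_spec(crop: str) -> PathSpecification:
    """Load the shipped maize or rice path topology."""
    ref = resources.files("micronet").joinpath(f"path_specs/{crop}.json")
    payload = json.loads(ref.read_text())
    return PathSpecification(
        variables=payload["variables"],
        edges=[tuple(e) for e in payload["edges"]],
        covariances=[tuple(c) for c in payload.get("covariances", [])],
    )


def residualize(soc: np.ndarray, controls: pd.DataFrame) -> tuple[np.ndarray, float]:
    """OLS residuals of SOC on the control covariates.

    Returns ``(residuals, share)`` where ``share`` is the residual variance
    as a fraction of the original SOC variance (the part of SOC left for
    the microbial path model to explain).
    """
    y = np.asarray(soc, float)
    n = len(y)
    if n <= controls.shape[1] + 1:
        raise ValueError("not enough sites to residualize on these controls")
    A = np.column_stack([np.ones(n), controls.to_numpy(float)])
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        raise ValueError("rank-deficient control matrix")
    resid = y - A @ beta
    var_y = float(np.var(y, ddof=1))
    share = float(np.var(resid, ddof=1) / var_y) if var_y > 0 else 0.0
    return resid, share


@dataclass
class PathFit:
    """ML path-model estimates with fit statistics."""

    spec: PathSpecification
    estimates: pd.DataFrame          # per edge: estimate, se, standardized
    covariance_estimates: pd.DataFrame
    variances: pd.Series             # exogenous variances / endogenous residual variances
    sigma_hat: pd.DataFrame          # model-implied covariance
    chi_square: float
    df: int
    p_value: float
    gfi: float
    cfi: float
    rmsea: float
    r_squared: pd.Series
    n: int
    converged: bool
    f_min: float
    sample_sds: pd.Series = None

    @property
    def standardized(self) -> pd.Series:
        return self.estimates.set_index(["source", "target"])["standardized"]


def _implied_sigma(theta, spec, order, idx, p):
    nb = len(spec.edges)
    nc = len(spec.covariances)
    B = np.zeros((p, p))
    for k, (a, b) in enumerate(spec.edges):
        B[idx[b], idx[a]] = theta[k]
    Psi = np.zeros((p, p))
    for k, (a, b) in enumerate(spec.covariances):
        Psi[idx[a], idx[b]] = Psi[idx[b], idx[a]] = theta[nb + k]
    Psi[np.diag_indices(p)] = np.exp(theta[nb + nc:])
    inv = np.linalg.inv(np.eye(p) - B)
    return inv @ Psi @ inv.T, B, Psi


def _f_ml(sigma, S, logdet_S, p):
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e10  # large finite penalty keeps quasi-Newton steps well-defined
    try:
        tr = float(np.trace(np.linalg.solve(sigma, S)))
    except np.linalg.LinAlgError:
        return 1e10
    val = logdet - logdet_S + tr - p
    return val if np.isfinite(val) else 1e10


def fit_path_model(
    spec: PathSpecification,
    data: pd.DataFrame,
    *,
    n_starts: int = 5,
    seed: int = 0,
) -> PathFit:
    """Fit a recursive path model to observed data by maximum likelihood.

    Minimizes F_ML over edge coefficients, declared exogenous covariances,
    and (log-parameterized) variances; starts from the equation-wise OLS
    solution plus jittered restarts.  Standard errors come from the inverse
    numerical Hessian of (n−1)/2 · F_ML.  Never fails silently: a fit that
    does not converge is returned with ``converged=False``.
    """
    missing = set(spec.variables) - set(data.columns)
    if missing:
        raise ValueError(f"data is missing path variables: {sorted(missing)}")
    X = data[spec.variables].to_numpy(float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than variables")
    S = np.cov(X, rowvar=False, ddof=1)
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance matrix is not positive definite")
    order = spec.variables
    idx = {v: i for i, v in enumerate(order)}
    nb, nc = len(spec.edges), len(spec.covariances)
    n_free = nb + nc + p
    df = p * (p + 1) // 2 - n_free
    if df < 0:
        raise ValueError(f"model has {n_free} free parameters but only {p*(p+1)//2} moments")

    # equation-wise OLS start (exact ML for saturated recursive structures)
    theta0 = np.zeros(n_free)
    resid_var = {}
    for v in spec.variables:
        parents = [a for a, b in spec.edges if b == v]
        if parents:
            A = np.column_stack([X[:, idx[a]] for a in parents])
            y = X[:, idx[v]]
            beta, _, _, _ = np.linalg.lstsq(A, y - y.mean(), rcond=None)
            Ac = A - A.mean(axis=0)
            r = (y - y.mean()) - Ac @ beta
            for a, b_ in zip(parents, beta):
                theta0[spec.edges.index((a, v))] = b_
            resid_var[v] = max(float(np.var(r, ddof=1)), 1e-8)
        else:
            resid_var[v] = max(float(S[idx[v], idx[v]]), 1e-8)
    for k, (a, b) in enumerate(spec.covariances):
        theta0[nb + k] = S[idx[a], idx[b]]
    for v in spec.variables:
        theta0[nb + nc + idx[v]] = math.log(resid_var[v])

    def objective(theta):
        sigma, _, _ = _implied_sigma(theta, spec, order, idx, p)
        return _f_ml(sigma, S, logdet_S, p)

    rng = np.random.default_rng(seed)
    best = None
    for start in range(n_starts):
        t0 = theta0 if start == 0 else theta0 + rng.normal(0.0, 0.1, n_free)
        res = optimize.minimize(objective, t0, method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    f_min = max(float(best.fun), 0.0)
    converged = bool(np.isfinite(f_min))

    sigma_hat, B, Psi = _implied_sigma(theta, spec, order, idx, p)
    chi2 = (n - 1) * f_min
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    rmsea = math.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))) if df > 0 else 0.0
    # independence baseline
    f_base = float(np.sum(np.log(np.diag(S))) - logdet_S)
    chi2_base = (n - 1) * f_base
    df_base = p * (p - 1) // 2
    denom = max(chi2_base - df_base, chi2 - df, 0.0)
    cfi = 1.0 - max(chi2 - df, 0.0) / denom if denom > 0 else 1.0
    cfi = min(max(cfi, 0.0), 1.0)
    sigma_inv = np.linalg.inv(sigma_hat)
    resid_m = sigma_inv @ (S - sigma_hat)
    gfi = 1.0 - np.trace(resid_m @ resid_m) / np.trace((sigma_inv @ S) @ (sigma_inv @ S))
    gfi = float(min(max(gfi, 0.0), 1.0))

    # standard errors from the numerical Hessian of (n-1)/2 * F_ML
    H = _numerical_hessian(objective, theta)
    se = np.full(n_free, np.nan)
    try:
        cov_theta = np.linalg.inv(0.5 * (n - 1) * H)
        d = np.diag(cov_theta)
        se[d > 0] = np.sqrt(d[d > 0])
    except np.linalg.LinAlgError:
        converged = False

    sds = np.sqrt(np.diag(sigma_hat))
    rows = []
    for k, (a, b) in enumerate(spec.edges):
        est = theta[k]
        rows.append(
            {
                "source": a, "target": b, "estimate": est, "se": se[k],
                "standardized": est * sds[idx[a]] / sds[idx[b]],
            }
        )
    estimates = pd.DataFrame(rows, columns=["source", "target", "estimate", "se", "standardized"])
    cov_rows = [
        {"a": a, "b": b, "estimate": theta[nb + k], "se": se[nb + k]}
        for k, (a, b) in enumerate(spec.covariances)
    ]
    variances = pd.Series(
        {v: float(np.exp(theta[nb + nc + idx[v]])) for v in spec.variables}
    )
    r2 = pd.Series(
        {
            v: 1.0 - variances[v] / sigma_hat[idx[v], idx[v]]
            for v in spec.endogenous
        }
    )
    return PathFit(
        spec=spec,
        estimates=estimates,
        covariance_estimates=pd.DataFrame(cov_rows, columns=["a", "b", "estimate", "se"]),
        variances=variances,
        sigma_hat=pd.DataFrame(sigma_hat, index=order, columns=order),
        chi_square=float(chi2),
        df=int(df),
        p_value=p_value,
        gfi=gfi,
        cfi=float(cfi),
        rmsea=float(rmsea),
        r_squared=r2,
        n=n,
        converged=converged,
        f_min=f_min,
        sample_sds=pd.Series(np.sqrt(np.diag(S)), index=order),
    )


def _numerical_hessian(f, x, eps: float = 1e-5) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4.0 * eps**2)
    return H


@dataclass
class TotalEffects:
    """Standardized direct, indirect and total effects on one outcome."""

    outcome: str
    table: pd.DataFrame  # index source; direct, indirect, total


def total_effects(fit: PathFit, outcome: str) -> TotalEffects:
    """Wright's-rules effects of every variable on ``outcome``.

    direct = the standardized edge coefficient (0 if absent); indirect =
    the sum over all directed paths of products of standardized
    coefficients; total = direct + indirect.  Computed in closed form as
    (I − B_std)⁻¹ − I.
    """
    spec = fit.spec
    if outcome not in spec.variables:
        raise ValueError(f"{outcome!r} is not a model variable")
    if not fit.converged:
        raise ValueError("cannot compute effects from a non-converged fit")
    p = len(spec.variables)
    idx = {v: i for i, v in enumerate(spec.variables)}
    B = np.zeros((p, p))
    for _, row in fit.estimates.iterrows():
        B[idx[row["target"]], idx[row["source"]]] = row["standardized"]
    total = np.linalg.inv(np.eye(p) - B) - np.eye(p)
    rows = {}
    for v in spec.variables:
        if v == outcome:
            continue
        direct = B[idx[outcome], idx[v]]
        tot = total[idx[outcome], idx[v]]
        rows[v] = {"direct": direct, "indirect": tot - direct, "total": tot}
    return TotalEffects(outcome, pd.DataFrame(rows).T[["direct", "indirect", "total"]])
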