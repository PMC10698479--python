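"""Statistical comparison of network metrics across sampling methods.

Local metrics (per-individual degree, eigenvector, betweenness) from the two
protocols are related by beta regression with a logit link: the ABS value of
an individual is the outcome, the FAS value and species are predictors, and
group identity enters as a random intercept integrated out by adaptive
Gauss-Hermite quadrature. Candidate models (null / main effects / FAS x
species interaction) are compared by AIC with a parsimony tie-break. Because
network metrics are not independent across individuals, a node-swap
permutation null (shuffling node identities within each group's network) is
available for the selected model's FAS slope. Global metrics (density,
modularity, centralization), one value per group, are compared by Pearson's
correlation test.

Outcomes exactly at 0 or 1 are compressed into the open interval with the
Smithson-Verkuilen transformation before beta fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess1

from ._util import as_seedseq

__all__ = [
    "CorrelationResult",
    "BetaRegressionResult",
    "ModelComparison",
    "PermutationResult",
    "pearson_test",
    "correlation_pvalue",
    "squeeze_unit_interval",
    "build_design",
    "fit_beta_regression",
    "compare_models",
    "node_swap_test",
    "global_comparison",
]


# ---------------------------------------------------------------------------
# Pearson correlation tests
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    n: int
    df: int
    t: float
    p: float

    def __str__(self):
        return f"r({self.df}) = {self.r:.2f}, p = {self.p:.3g}"


def correlation_pvalue(r: float, n: int) -> float:
    """Two-tailed p for a Pearson coefficient r with n pairs.

    Uses the exact t transform t = r * sqrt((n-2)/(1-r^2)) with n-2 degrees
    of freedom; |r| >= 1 returns p = 0.
    """
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if abs(r) >= 1.0:
        return 0.0
    df = n - 2
    t = abs(r) * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df))


def pearson_test(x, y) -> CorrelationResult:
    """Pearson's correlation test between two equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation is undefined when a sample has zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        return CorrelationResult(r=r, n=n, df=df, t=np.inf if r > 0 else -np.inf, p=0.0)
    t = r * np.sqrt(df / (1.0 - r * r))
    return CorrelationResult(r=r, n=n, df=df, t=float(t), p=correlation_pvalue(r, n))


# ---------------------------------------------------------------------------
# Beta regression (fixed and mixed)
# ---------------------------------------------------------------------------

def squeeze_unit_interval(y, N: int | None = None) -> np.ndarray:
    """Compress [0, 1] data into (0, 1): y' = (y (N-1) + 1/2) / N."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("values must lie in [0, 1]")
    if N is None:
        N = y.size
    return (y * (N - 1) + 0.5) / N


@dataclass
class BetaRegressionResult:
    names: list[str]
    params: np.ndarray          # fixed-effect coefficients (logit scale)
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    conf_int: np.ndarray        # 95% Wald intervals, shape (k, 2)
    phi: float                  # beta precision
    sigma2_group: float         # random-intercept variance (0 for fixed fits)
    loglik: float
    aic: float
    nobs: int
    nparams: int
    random_intercept: bool
    converged: bool
    outcome_checksum: tuple = field(default=(), repr=False)

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.se,
             "ci_low": self.conf_int[:, 0], "ci_high": self.conf_int[:, 1],
             "z": self.z, "p": self.p},
            index=self.names,
        )


def _beta_loglik_terms(y, mu, phi):
    return (
        special.gammaln(phi)
        - special.gammaln(mu * phi)
        - special.gammaln((1 - mu) * phi)
        + (mu * phi - 1) * np.log(y)
        + ((1 - mu) * phi - 1) * np.log1p(-y)
    )


_MU_EPS = 1e-10


def _mu(eta):
    return np.clip(special.expit(eta), _MU_EPS, 1 - _MU_EPS)


def _fixed_nll_grad(theta, y, X, ystar, log_y, log_1my):
    """Negative log-likelihood and analytic gradient, theta = [beta, log phi]."""
    beta, logphi = theta[:-1], theta[-1]
    phi = np.exp(logphi)
    mu = _mu(X @ beta)
    nll = -np.sum(_beta_loglik_terms(y, mu, phi))
    mustar = special.digamma(mu * phi) - special.digamma((1 - mu) * phi)
    score_eta = phi * (ystar - mustar) * mu * (1 - mu)
    g_beta = -(X.T @ score_eta)
    dphi = (
        special.digamma(phi)
        - mu * special.digamma(mu * phi)
        - (1 - mu) * special.digamma((1 - mu) * phi)
        + mu * log_y
        + (1 - mu) * log_1my
    )
    g_logphi = -phi * np.sum(dphi)
    return nll, np.append(g_beta, g_logphi)


def _group_mode(y, X, beta, phi, sigma2, ystar):
    """Newton search for the mode of the random-intercept integrand (1-d)."""
    eta0 = X @ beta
    u = 0.0
    for _ in range(50):
        mu = _mu(eta0 + u)
        mustar = special.digamma(mu * phi) - special.digamma((1 - mu) * phi)
        m = mu * (1 - mu)
        h1 = phi * np.sum((ystar - mustar) * m) - u / sigma2
        trig = special.polygamma(1, mu * phi) + special.polygamma(1, (1 - mu) * phi)
        h2 = phi * np.sum(-phi * trig * m**2 + (ystar - mustar) * (1 - 2 * mu) * m) - 1.0 / sigma2
        if h2 >= 0:  # pathological curvature: fall back to prior curvature
            h2 = -1.0 / sigma2
        step = h1 / h2
        u_new = u - step
        if abs(u_new - u) < 1e-12:
            u = u_new
            break
        u = u_new
    mu = _mu(eta0 + u)
    mustar = special.digamma(mu * phi) - special.digamma((1 - mu) * phi)
    m = mu * (1 - mu)
    trig = special.polygamma(1, mu * phi) + special.polygamma(1, (1 - mu) * phi)
    h2 = phi * np.sum(-phi * trig * m**2 + (ystar - mustar) * (1 - 2 * mu) * m) - 1.0 / sigma2
    if h2 >= 0:
        h2 = -1.0 / sigma2
    return u, h2


def _mixed_nll(theta, y_groups, X_groups, ystar_groups, gh_x, gh_w):
    """Marginal negative log-likelihood, theta = [beta, log phi, log sigma].

    The group-level intercept is integrated out by adaptive Gauss-Hermite
    quadrature centred at each group's conditional mode (Laplace mode and
    curvature supply the adaptation)."""
    beta, logphi, logsigma = theta[:-2], theta[-2], theta[-1]
    phi = np.exp(logphi)
    sigma = np.exp(logsigma)
    sigma2 = sigma**2
    total = 0.0
    log_norm = -0.5 * np.log(2 * np.pi * sigma2)
    for y, X, ystar in zip(y_groups, X_groups, ystar_groups):
        u_hat, h2 = _group_mode(y, X, beta, phi, sigma2, ystar)
        tau = 1.0 / np.sqrt(-h2)
        nodes = u_hat + np.sqrt(2.0) * tau * gh_x
        eta = X @ beta
        h_vals = np.array(
            [np.sum(_beta_loglik_terms(y, _mu(eta + u), phi)) - u**2 / (2 * sigma2) + log_norm
             for u in nodes]
        )
        log_terms = np.log(gh_w) + gh_x**2 + h_vals
        total += np.log(np.sqrt(2.0) * tau) + special.logsumexp(log_terms)
    return -total


def build_design(
    data: pd.DataFrame,
    predictor: str,
    species: str | None = None,
    interaction: bool = False,
    include_predictor: bool = True,
):
    """Design matrix: intercept, predictor, species dummies, and optionally
    predictor x species interaction terms. Returns (X, names)."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["intercept"]
    x = data[predictor].to_numpy(dtype=float) if include_predictor else None
    if include_predictor:
        cols.append(x)
        names.append(predictor)
    if species is not None:
        levels = sorted(data[species].astype(str).unique())
        for lev in levels[1:]:
            d = (data[species].astype(str) == lev).to_numpy(dtype=float)
            cols.append(d)
            names.append(f"{species}[{lev}]")
            if interaction and include_predictor:
                cols.append(x * d)
                names.append(f"{predictor}:{species}[{lev}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names


def fit_beta_regression(
    y,
    X,
    groups=None,
    random_intercept: bool = False,
    names: list[str] | None = None,
    n_quad: int = 15,
    start: np.ndarray | None = None,
    compute_se: bool = True,
) -> BetaRegressionResult:
    """Maximum-likelihood logit-link beta regression (mean-precision form).

    With ``random_intercept`` a group-level normal intercept is integrated
    out by adaptive Gauss-Hermite quadrature (``n_quad`` nodes, mode-centred;
    the Laplace approximation is the 1-node special case). Outcomes must lie
    strictly inside (0, 1) — apply :func:`squeeze_unit_interval` first.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("X and y have incompatible shapes")
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("outcomes must lie strictly in (0, 1); squeeze them first")
    p = X.shape[1]
    if names is None:
        names = [f"x{k}" for k in range(p)]
    ystar = np.log(y) - np.log1p(-y)
    log_y, log_1my = np.log(y), np.log1p(-y)

    # moment-style start: linear fit on the logit scale
    if start is None:
        beta0, *_ = np.linalg.lstsq(X, ystar, rcond=None)
        start_fixed = np.append(beta0, np.log(10.0))
    else:
        start_fixed = np.asarray(start, dtype=float)

    if not random_intercept or groups is None:
        bounds = [(None, None)] * p + [(np.log(1e-3), np.log(1e6))]
        res = optimize.minimize(
            _fixed_nll_grad, start_fixed, args=(y, X, ystar, log_y, log_1my),
            jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        theta = res.x
        loglik = -res.fun
        nparams = p + 1
        sigma2 = 0.0
        nll_for_hess = lambda th: _fixed_nll_grad(th, y, X, ystar, log_y, log_1my)[0]
    else:
        groups = np.asarray(groups)
        gh_x, gh_w = np.polynomial.hermite.hermgauss(max(int(n_quad), 1))
        uniq = pd.unique(groups)
        y_g = [y[groups == g] for g in uniq]
        X_g = [X[groups == g] for g in uniq]
        ys_g = [ystar[groups == g] for g in uniq]
        start_mixed = np.concatenate([start_fixed, [np.log(0.3)]]) if start is None else start_fixed
        if start_mixed.size != p + 2:
            start_mixed = np.concatenate([start_mixed[: p + 1], [np.log(0.3)]])
        bounds = [(None, None)] * p + [(np.log(1e-3), np.log(1e4)), (np.log(1e-4), np.log(1e2))]
        res = optimize.minimize(
            _mixed_nll, start_mixed, args=(y_g, X_g, ys_g, gh_x, gh_w),
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-11},
        )
        theta = res.x
        loglik = -res.fun
        nparams = p + 2
        sigma2 = float(np.exp(theta[-1]) ** 2)
        nll_for_hess = lambda th: _mixed_nll(th, y_g, X_g, ys_g, gh_x, gh_w)

    beta = theta[:p]
    phi = float(np.exp(theta[p]))
    if compute_se:
        H = approx_hess1(theta, nll_for_hess)
        try:
            cov = np.linalg.inv(H)
            se_all = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        except np.linalg.LinAlgError:
            se_all = np.full(theta.size, np.nan)
        se = se_all[:p]
    else:
        se = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    ci = np.column_stack([beta - 1.959963984540054 * se, beta + 1.959963984540054 * se])
    return BetaRegressionResult(
        names=list(names), params=beta, se=se, z=z, p=pvals, conf_int=ci,
        phi=phi, sigma2_group=sigma2, loglik=float(loglik),
        aic=float(2 * nparams - 2 * loglik), nobs=y.size, nparams=nparams,
        random_intercept=bool(random_intercept and groups is not None),
        converged=bool(res.success), outcome_checksum=(y.size, float(y.sum()), float((y**2).sum())),
    )


@dataclass
class ModelComparison:
    table: pd.DataFrame          # model, nparams, loglik, AIC, dAIC
    selected: str
    results: dict

    def __str__(self):
        return f"selected: {self.selected}\n{self.table}"


def compare_models(**fits: BetaRegressionResult) -> ModelComparison:
    """AIC comparison with a parsimony rule: among models within 2 AIC of
    the minimum, the one with the fewest parameters is selected."""
    if len(fits) < 2:
        raise ValueError("need at least two fitted models")
    checks = {f.outcome_checksum for f in fits.values()}
    if len(checks) > 1:
        raise ValueError("models were fitted to different outcomes")
    table = pd.DataFrame(
        {
            "model": list(fits),
            "nparams": [f.nparams for f in fits.values()],
            "loglik": [f.loglik for f in fits.values()],
            "AIC": [f.aic for f in fits.values()],
        }
    )
    table["dAIC"] = table["AIC"] - table["AIC"].min()
    candidates = table[table["dAIC"] < 2.0]
    selected = candidates.sort_values(["nparams", "AIC"]).iloc[0]["model"]
    return ModelComparison(table=table, selected=str(selected), results=dict(fits))


# ---------------------------------------------------------------------------
# Node-swap permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p: float                     # one-tailed, add-one estimator: (1+b)/(1+B)
    B: int
    n_failed: int = 0


def node_swap_test(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    groups: str,
    species: str | None = None,
    interaction: bool = False,
    random_intercept: bool = True,
    B: int = 1000,
    seed=None,
    permute_fn=None,
    n_quad: int = 9,
) -> PermutationResult:
    """Node-swap permutation p-value for the predictor's slope.

    Each replicate shuffles node identities within every group's outcome
    network — implemented as a within-group permutation of the outcome
    metric's assignment to individuals — refits the model, and collects the
    slope estimate. One-tailed p = (1 + #{beta* >= beta_hat}) / (B + 1);
    replicate-level seeds are spawned from ``seed`` so enlarging B leaves
    earlier replicates unchanged. ``random_intercept=False`` is the fast
    fixed-effects refit mode. Replicates whose refit fails are dropped and
    counted in ``n_failed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X, names = build_design(data, predictor, species=species, interaction=interaction)
    y = data[outcome].to_numpy(dtype=float)
    g = data[groups].to_numpy()
    obs = fit_beta_regression(
        y, X, groups=g, random_intercept=random_intercept, names=names,
        n_quad=n_quad, compute_se=False,
    )
    beta_hat = obs.coef(predictor)
    warm = np.append(obs.params, np.log(obs.phi))
    if obs.random_intercept:
        warm = np.append(warm, 0.5 * np.log(max(obs.sigma2_group, 1e-6)))
    group_index = {lab: np.nonzero(g == lab)[0] for lab in pd.unique(g)}
    seeds = as_seedseq(seed).spawn(B)
    null = []
    n_failed = 0
    for b in range(B):
        rng = np.random.default_rng(seeds[b])
        y_perm = y.copy()
        for lab, idx in group_index.items():
            if permute_fn is not None:
                perm = permute_fn(len(idx))
            else:
                perm = rng.permutation(len(idx))
            y_perm[idx] = y[idx][perm]
        try:
            fit = fit_beta_regression(
                y_perm, X, groups=g, random_intercept=random_intercept,
                names=names, n_quad=n_quad, start=warm, compute_se=False,
            )
            null.append(fit.coef(predictor))
        except Exception:
            n_failed += 1
    null = np.array(null)
    b_ge = int(np.sum(null >= beta_hat))
    p = (1.0 + b_ge) / (1.0 + len(null))
    return PermutationResult(observed=float(beta_hat), null=null, p=float(p),
                             B=B, n_failed=n_failed)


# ---------------------------------------------------------------------------
# Global-metric comparison
# ---------------------------------------------------------------------------

def global_comparison(
    fas: pd.DataFrame,
    abs_: pd.DataFrame,
    exclusions: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """One Pearson test per column (behaviour x global metric), with and
    without the listed group exclusions.

    ``fas`` and ``abs_`` are indexed by group with matching columns; NaN
    groups (e.g. a behaviour not analysed for a species) are dropped
    pairwise. Requires >= 3 groups per test.
    """
    if not fas.index.equals(abs_.index) or list(fas.columns) != list(abs_.columns):
        raise ValueError("FAS and ABS tables must share index (groups) and columns")
    exclusions = exclusions or {}
    rows = []
    for col in fas.columns:
        x = fas[col].astype(float)
        y = abs_[col].astype(float)
        ok = x.notna() & y.notna()
        if ok.sum() < 3:
            raise ValueError(f"{col}: fewer than 3 groups with data")
        res = pearson_test(x[ok], y[ok])
        row = {"metric": col, "n_groups": res.n, "r": res.r, "df": res.df,
               "t": res.t, "p": res.p, "excluded": ""}
        rows.append(row)
        excl = exclusions.get(col)
        if excl:
            keep = ok & ~fas.index.isin(excl)
            if keep.sum() < 3:
                raise ValueError(f"{col}: fewer than 3 groups after exclusion")
            res_x = pearson_test(x[keep], y[keep])
            rows.append({"metric": col, "n_groups": res_x.n, "r": res_x.r,
                         "df": res_x.df, "t": res_x.t, "p": res_x.p,
                         "excluded": ";".join(excl)})
    return pd.DataFrame(rows)
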