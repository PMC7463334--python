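"""Genotype-environment association by per-genotype logistic regression.

Each biallelic SNP contributes three candidate models, one per genotype
class (hom-ref, het, hom-alt): the binary presence of the class is
regressed on one environmental variable, optionally with a population-
structure covariate.  Model support is measured by the likelihood-ratio
G-score, G = 2 (ll_full - ll_null) where the null keeps the covariates but
drops the environment, and the scalar Wald score W = (beta / se(beta))^2;
both are referred to a chi-square with one degree of freedom.  p-values
are corrected to Storey q-values per environmental variable, and a model
is a significant genotype-environment association (SGEA) when both
q-values fall below the threshold (default 0.01); a SNP keeps only its
best (highest-G) significant model.

Fitting is iteratively reweighted least squares, vectorised across models
sharing a design matrix so that whole-matrix scans of hundreds of
thousands of candidate models run in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from reefscape.genotypes import MISSING, GenotypeMatrix

GENOTYPE_CLASSES = ("hom_ref", "het", "hom_alt")

MAX_ITER = 100
LL_TOL = 1e-8
SEPARATION_BETA = 50.0  # on standardized predictors


@dataclass
class AssociationModel:
    """One genotype-class x environment logistic fit."""

    snp: str
    genotype: str
    env_var: str
    intercept: float
    beta_env: float
    beta_cov: np.ndarray
    g_score: float
    wald: float
    p_g: float
    p_w: float
    n_used: int
    status: str = "ok"  # ok | degenerate_response | degenerate_predictor | separation | not_converged | untestable
    q_g: float = np.nan
    q_w: float = np.nan


def encode_genotypes(snp_column: np.ndarray) -> dict[str, np.ndarray]:
    """Indicator of each genotype class; missing entries stay NaN.

    The three indicators partition every non-missing entry (they sum to 1).
    Classes absent from the data yield all-zero vectors, which downstream
    fits flag as degenerate responses.
    """
    col = np.asarray(snp_column)
    out = {}
    for code, name in enumerate(GENOTYPE_CLASSES):
        v = np.where(col == code, 1.0, 0.0)
        v[col == MISSING] = np.nan
        out[name] = v
    return out


def count_models(n_env: int, n_snps: int) -> int:
    """Number of candidate association models: n_env x 3 genotypes x n_snps."""
    if n_env <= 0 or n_snps <= 0:
        raise ValueError("n_env and n_snps must be positive")
    return n_env * 3 * n_snps


# ------------------------------------------------------------------ IRLS
def _sigmoid(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def _loglik(Y: np.ndarray, mu: np.ndarray, mask: np.ndarray) -> np.ndarray:
    eps = 1e-12
    ll = Y * np.log(mu + eps) + (1 - Y) * np.log(1 - mu + eps)
    return np.where(mask, ll, 0.0).sum(axis=-1)


def _irls_batch(Y: np.ndarray, X: np.ndarray, mask: np.ndarray):
    """Batched logistic IRLS.

    Y: (M, n) responses in {0,1} (arbitrary where mask is False);
    X: (n, k) shared design (first column = intercept), predictors assumed
    standardized; mask: (M, n) True where the row enters model m.

    Returns beta (M, k), ll (M,), se (M, k), status (M,) int codes
    0=ok, 1=not_converged, 2=separation.
    """
    M, n = Y.shape
    k = X.shape[1]
    beta = np.zeros((M, k))
    ll_old = np.full(M, -np.inf)
    active = np.ones(M, bool)
    status = np.zeros(M, np.int8)
    Ym = np.where(mask, Y, 0.0)
    for _ in range(MAX_ITER):
        if not active.any():
            break
        eta = beta[active] @ X.T  # (Ma, n)
        mu = _sigmoid(eta)
        w = mu * (1 - mu)
        w = np.where(mask[active], np.maximum(w, 1e-10), 0.0)
        z = eta + (Ym[active] - mu) / np.maximum(mu * (1 - mu), 1e-10)
        xtwx = np.einsum("mn,nk,nl->mkl", w, X, X, optimize=True)
        xtwz = np.einsum("mn,nk->mk", w * z, X, optimize=True)
        try:
            new_beta = np.linalg.solve(xtwx + 1e-10 * np.eye(k), xtwz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new_beta = np.stack(
                [np.linalg.lstsq(A, v, rcond=None)[0] for A, v in zip(xtwx, xtwz)]
            )
        beta[active] = new_beta
        mu_new = _sigmoid(new_beta @ X.T)
        ll_new = _loglik(Ym[active], mu_new, mask[active])
        sep = np.abs(new_beta).max(axis=1) > SEPARATION_BETA
        conv = np.abs(ll_new - ll_old[active]) < LL_TOL
        ll_old[active] = ll_new
        idx = np.flatnonzero(active)
        status[idx[sep]] = 2
        still = ~(conv | sep)
        active[idx] = still
    status[active & (status == 0)] = 1  # hit MAX_ITER without converging
    # standard errors from the observed information at the final estimate
    eta = beta @ X.T
    mu = _sigmoid(eta)
    w = np.where(mask, np.maximum(mu * (1 - mu), 1e-10), 0.0)
    xtwx = np.einsum("mn,nk,nl->mkl", w, X, X, optimize=True)
    try:
        cov = np.linalg.inv(xtwx + 1e-10 * np.eye(k))
        se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    except np.linalg.LinAlgError:
        se = np.full((M, k), np.nan)
    return beta, ll_old, se, status


def _standardize(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu = float(np.nanmean(x))
    sd = float(np.nanstd(x))
    if sd == 0:
        raise ValueError("degenerate predictor: zero variance")
    return (x - mu) / sd, mu, sd


def fit_logistic(
    y: np.ndarray,
    env: np.ndarray,
    covariates: np.ndarray | None = None,
    snp: str = "snp",
    genotype: str = "geno",
    env_var: str = "env",
    min_class_count: int = 1,
) -> AssociationModel:
    """Fit one genotype-class ~ environment logistic model.

    Rows with missing response, environment or covariate are dropped
    listwise.  Predictors are standardized internally for stability;
    coefficients are reported on the original scale.  Raises ValueError on
    a constant environment; a one-class response or perfect separation is
    reported in ``status`` with no p-values.
    """
    y = np.asarray(y, float)
    env = np.asarray(env, float)
    cov = None if covariates is None else np.atleast_2d(np.asarray(covariates, float).T).T
    ok = ~np.isnan(y) & ~np.isnan(env)
    if cov is not None:
        ok &= ~np.isnan(cov).any(axis=1)
    yv, ev = y[ok], env[ok]
    n_used = int(ok.sum())
    n1 = int(yv.sum())
    if n1 == 0 or n1 == len(yv):
        return AssociationModel(snp, genotype, env_var, np.nan, np.nan, np.array([]),
                                np.nan, np.nan, np.nan, np.nan, n_used, "degenerate_response")
    if np.nanstd(ev) == 0:
        raise ValueError("degenerate predictor: environment has zero variance")
    if min(n1, len(yv) - n1) < min_class_count:
        return AssociationModel(snp, genotype, env_var, np.nan, np.nan, np.array([]),
                                np.nan, np.nan, np.nan, np.nan, n_used, "untestable")

    ev_s, e_mu, e_sd = _standardize(ev)
    cols = [np.ones(len(yv)), ev_s]
    c_mu, c_sd = [], []
    if cov is not None:
        for j in range(cov.shape[1]):
            cs, m, s = _standardize(cov[ok, j])
            cols.append(cs)
            c_mu.append(m)
            c_sd.append(s)
    X = np.column_stack(cols)
    X_null = np.delete(X, 1, axis=1)
    mask = np.ones((1, len(yv)), bool)
    beta, ll, se, st = _irls_batch(yv[None, :], X, mask)
    beta0, ll0, _, _ = _irls_batch(yv[None, :], X_null, mask)
    status = {0: "ok", 1: "not_converged", 2: "separation"}[int(st[0])]
    g = max(0.0, 2.0 * float(ll[0] - ll0[0]))
    if status != "ok":
        return AssociationModel(snp, genotype, env_var, np.nan, np.nan, np.array([]),
                                np.nan, np.nan, np.nan, np.nan, n_used, status)
    wald = float((beta[0, 1] / se[0, 1]) ** 2) if se[0, 1] > 0 else np.nan
    p_g = float(stats.chi2.sf(g, df=1))
    p_w = float(stats.chi2.sf(wald, df=1))
    # back to the original predictor scale
    beta_env = float(beta[0, 1] / e_sd)
    beta_cov = np.array([beta[0, 2 + j] / c_sd[j] for j in range(len(c_sd))])
    intercept = float(
        beta[0, 0] - beta[0, 1] * e_mu / e_sd - sum(beta[0, 2 + j] * c_mu[j] / c_sd[j]
                                                    for j in range(len(c_sd)))
    )
    return AssociationModel(snp, genotype, env_var, intercept, beta_env, beta_cov,
                            g, wald, p_g, p_w, n_used, "ok")


def scan_associations(
    matrix: GenotypeMatrix,
    env_table: pd.DataFrame,
    covariates: np.ndarray | None = None,
    env_vars: list[str] | None = None,
    min_class_count: int = 10,
) -> pd.DataFrame:
    """Fit every genotype-class x environment model over a genotype matrix.

    ``env_table`` holds one row per individual (aligned with the matrix) and
    one column per environmental variable.  Models whose genotype class has
    fewer than ``min_class_count`` carriers or non-carriers among complete
    cases are reported with status ``untestable`` and no statistics — the
    df=1 chi-square reference is unreliable below that.  Returns one row per
    model with coefficients on the original scale.
    """
    if env_vars is None:
        env_vars = [c for c in env_table.columns]
    if len(env_table) != matrix.n_individuals:
        raise ValueError("env_table must have one row per individual")
    cov = None if covariates is None else np.atleast_2d(np.asarray(covariates, float).T).T
    snp_ids = matrix.snp_ids()
    records = []
    for env_var in env_vars:
        env = env_table[env_var].to_numpy(float)
        base_ok = ~np.isnan(env)
        if cov is not None:
            base_ok &= ~np.isnan(cov).any(axis=1)
        if np.nanstd(env[base_ok]) == 0:
            raise ValueError(f"degenerate predictor: {env_var!r} has zero variance")
        records.append(_scan_one_env(matrix, env, cov, base_ok, env_var, snp_ids,
                                     min_class_count))
    return pd.concat(records, ignore_index=True)


def _scan_one_env(matrix, env, cov, base_ok, env_var, snp_ids, min_class_count):
    n = matrix.n_individuals
    ev_s, e_mu, e_sd = _standardize(np.where(base_ok, env, np.nan))
    cols = [np.ones(n), np.where(base_ok, ev_s, 0.0)]
    c_mu, c_sd = [], []
    if cov is not None:
        for j in range(cov.shape[1]):
            cs, m, s = _standardize(np.where(base_ok, cov[:, j], np.nan))
            cols.append(np.where(base_ok, cs, 0.0))
            c_mu.append(m)
            c_sd.append(s)
    X = np.column_stack(cols)
    X_null = np.delete(X, 1, axis=1)

    # build the response block: 3 genotype classes per SNP
    codes = matrix.codes  # (n, L)
    L = codes.shape[1]
    Y = np.empty((3 * L, n))
    mask = np.empty((3 * L, n), bool)
    for g in range(3):
        Y[g::3] = (codes.T == g).astype(float)
        mask[g::3] = (codes.T != MISSING) & base_ok[None, :]
    n_used = mask.sum(axis=1)
    n1 = np.where(mask, Y, 0).sum(axis=1)
    n0 = n_used - n1
    testable = (np.minimum(n1, n0) >= min_class_count)
    degenerate = (n1 == 0) | (n0 == 0)

    beta = np.full((3 * L, X.shape[1]), np.nan)
    ll = np.full(3 * L, np.nan)
    se = np.full((3 * L, X.shape[1]), np.nan)
    st = np.zeros(3 * L, np.int8)
    idx = np.flatnonzero(testable)
    if idx.size:
        b, l, s, c = _irls_batch(Y[idx], X, mask[idx])
        b0, l0, _, _ = _irls_batch(Y[idx], X_null, mask[idx])
        beta[idx], ll[idx], se[idx], st[idx] = b, l, s, c
        g_score = np.maximum(0.0, 2.0 * (l - l0))
    g_all = np.full(3 * L, np.nan)
    wald = np.full(3 * L, np.nan)
    if idx.size:
        g_all[idx] = g_score
        with np.errstate(invalid="ignore", divide="ignore"):
            wald[idx] = (beta[idx, 1] / se[idx, 1]) ** 2
    fitted = testable & (st == 0)
    p_g = np.where(fitted, stats.chi2.sf(g_all, df=1), np.nan)
    p_w = np.where(fitted, stats.chi2.sf(wald, df=1), np.nan)

    status = np.where(degenerate, "degenerate_response",
                      np.where(~testable, "untestable",
                               np.where(st == 2, "separation",
                                        np.where(st == 1, "not_converged", "ok"))))
    out = pd.DataFrame({
        "snp": np.repeat(snp_ids, 3),
        "genotype": np.tile(GENOTYPE_CLASSES, L),
        "env_var": env_var,
        "intercept": beta[:, 0] - beta[:, 1] * e_mu / e_sd
        - sum(beta[:, 2 + j] * c_mu[j] / c_sd[j] for j in range(len(c_sd))),
        "beta_env": beta[:, 1] / e_sd,
        "g_score": g_all,
        "wald": wald,
        "p_g": p_g,
        "p_w": p_w,
        "n_used": n_used.astype(int),
        "status": status,
    })
    for j in range(len(c_sd)):
        out[f"beta_cov{j + 1}"] = beta[:, 2 + j] / c_sd[j]
    return out


# ---------------------------------------------------------------- q-values
def qvalues(
    p: np.ndarray,
    method: str = "storey",
    lambdas: np.ndarray | None = None,
    pi0: float | None = None,
) -> np.ndarray:
    """False-discovery-rate q-values.

    ``method='storey'`` estimates the null proportion pi0 on a lambda grid
    (default 0.05..0.95 step 0.05) with a cubic smoother evaluated at the
    largest lambda, then sets q_(i) = min_{j: p_j >= p_i} pi0 * m * p_j /
    rank(p_j).  ``method='bh'`` fixes pi0 = 1, reducing to Benjamini-
    Hochberg adjusted p-values.  NaN entries are passed through as NaN and
    excluded from the batch.
    """
    p = np.asarray(p, float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if pv.size == 0:
        return out
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        if method == "bh":
            pi0 = 1.0
        elif method == "storey":
            pi0 = estimate_pi0(pv, lambdas)
        else:
            raise ValueError(f"unknown method {method!r}")
    m = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * pv[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    out[ok] = q
    return out


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the grid, smoothed by
    a cubic polynomial fit and evaluated at max(lambda); clipped to (0, 1].
    """
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    p = np.asarray(p, float)
    m = p.size
    pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polyval(coeffs, lambdas.max()))
    return min(max(pi0, 1.0 / m), 1.0)


def add_qvalues(models: pd.DataFrame, method: str = "storey",
                batch: str = "per_env") -> pd.DataFrame:
    """Attach q_g and q_w columns; correction batches are per environmental
    variable by default (``batch='global'`` pools all models)."""
    models = models.copy()
    if batch == "per_env":
        groups = models.groupby("env_var").groups
    elif batch == "global":
        groups = {"all": models.index}
    else:
        raise ValueError(f"unknown batch {batch!r}")
    models["q_g"] = np.nan
    models["q_w"] = np.nan
    for _, idx in groups.items():
        models.loc[idx, "q_g"] = qvalues(models.loc[idx, "p_g"].to_numpy(), method)
        models.loc[idx, "q_w"] = qvalues(models.loc[idx, "p_w"].to_numpy(), method)
    return models


def select_sgea(models: pd.DataFrame, q_threshold: float = 0.01) -> pd.DataFrame:
    """Significant genotype-environment associations.

    Keeps models with both q_g and q_w below the threshold; when a SNP is
    significant with several environmental variables or genotype classes,
    only the best model by G-score survives (ties broken by lower p_w, then
    env-variable name, deterministically).
    """
    sig = models[(models["q_g"] < q_threshold) & (models["q_w"] < q_threshold)].copy()
    if sig.empty:
        return sig
    sig = sig.sort_values(
        ["snp", "g_score", "p_w", "env_var"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return sig.groupby("snp", as_index=False, sort=True).first()
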