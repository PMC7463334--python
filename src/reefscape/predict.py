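"""Adaptive-genotype probability surfaces.

Each SGEA carries the parameters of a logistic regression linking the
presence of one adaptive genotype to one environmental variable; applied
to the environmental value of any reef cell it yields the probability of
occurrence of that genotype there.  For SGEAs tied to the same pressure
(e.g. heat stress via BAF) the per-genotype probabilities are combined by
arithmetic mean into PA, the probability of carrying adapted genotypes.

The population-structure covariate has no defined value at unsampled
reefs; prediction fixes it at a constant (default its sample mean, 0
after centering).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def inverse_logit(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-np.asarray(x, float)))


def genotype_probability(
    intercept: float,
    beta_env: float,
    env_value: np.ndarray,
    beta_cov: np.ndarray | None = None,
    covariate_value: float | np.ndarray = 0.0,
) -> np.ndarray:
    """P(adaptive genotype) = inv-logit(alpha + beta*env [+ gamma*cov]).

    Missing environmental values propagate to missing probabilities.
    """
    env_value = np.asarray(env_value, float)
    eta = intercept + beta_env * env_value
    if beta_cov is not None and np.size(beta_cov):
        eta = eta + np.dot(np.atleast_1d(beta_cov), np.atleast_1d(covariate_value))
    return np.where(np.isnan(env_value), np.nan, inverse_logit(eta))


def compute_pa(
    sgea: pd.DataFrame,
    env_table: pd.DataFrame,
    tags: list[str] | None = None,
    covariate_value: float = 0.0,
) -> pd.DataFrame:
    """Average adaptive-genotype probability per reef cell (PA).

    ``sgea`` rows need snp, env_var, intercept, beta_env (and optional
    beta_cov1...); ``env_table`` one row per cell with the environmental
    columns.  ``tags`` restricts to SGEAs of those environmental variables
    (the heat-stress subset uses the BAF-related SGEAs).  Returns a frame
    with PA and one probability column per contributing SGEA; PA is their
    arithmetic mean and is invariant to SGEA order.
    """
    if tags is not None:
        sgea = sgea[sgea["env_var"].isin(tags)]
    if len(sgea) == 0:
        raise ValueError("empty SGEA set")
    cov_cols = [c for c in sgea.columns if c.startswith("beta_cov")]
    probs = {}
    for row in sgea.itertuples():
        if row.env_var not in env_table.columns:
            raise ValueError(f"environment variable {row.env_var!r} not in table")
        beta_cov = np.array([getattr(row, c) for c in cov_cols]) if cov_cols else None
        if beta_cov is not None and np.isnan(beta_cov).any():
            beta_cov = None
        probs[f"p_{row.snp}_{row.genotype}"] = genotype_probability(
            row.intercept, row.beta_env, env_table[row.env_var].to_numpy(float),
            beta_cov, covariate_value,
        )
    out = pd.DataFrame(probs, index=env_table.index)
    out.insert(0, "PA", out.mean(axis=1))
    return out
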