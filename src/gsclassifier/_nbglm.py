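"""Vectorized negative-binomial GLM machinery.

Per-gene NB regressions with a log link, shared across genes through a common
design matrix, used for (a) gene-wise dispersion estimation when building the
seed reference and (b) Wald differential-expression tests with trend-anchored
dispersions.  All genes are fit simultaneously with batched IRLS; the
per-gene cost is a p x p solve (p = number of design columns).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

_MIN_DISP = 1e-8
_MAX_DISP = 20.0


class DesignError(ValueError):
    """Raised for rank-deficient or incomplete design matrices."""


def design_matrix(clinical: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Build an intercept + covariates design from a clinical table.

    Categorical/boolean columns are dummy-coded (first level dropped);
    numeric columns enter as-is.  Raises :class:`DesignError` on missing
    values or collinear columns (named in the message).
    """
    cols = {"intercept": np.ones(len(clinical))}
    for cov in covariates:
        if cov not in clinical.columns:
            raise DesignError(f"design covariate {cov!r} missing from clinical table")
        col = clinical[cov]
        if col.isna().any():
            bad = list(clinical.index[col.isna()])[:5]
            raise DesignError(f"design covariate {cov!r} has missing values (e.g. {bad})")
        if pd.api.types.is_numeric_dtype(col):
            cols[cov] = col.to_numpy(dtype=float)
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                cols[f"{cov}[{lev}]"] = (col.astype(str) == lev).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=clinical.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns involved in the collinearity
        keep, bad = [], []
        for j in range(X.shape[1]):
            trial = X.iloc[:, keep + [j]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
            else:
                bad.append(X.columns[j])
        raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")
    return X


def _poisson_irls(
    Y: np.ndarray, X: np.ndarray, offset: np.ndarray, n_iter: int = 8
) -> np.ndarray:
    """Batched Poisson IRLS mean fit (log link); returns beta (G x p)."""
    G, n = Y.shape
    p = X.shape[1]
    # initialize from a working log-linear regression
    z0 = np.log((Y + 0.5)) - offset[None, :]
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # G x p
    for _ in range(n_iter):
        eta = beta @ X.T + offset[None, :]
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        W = mu  # Poisson working weights
        z = eta - offset[None, :] + (Y - mu) / np.maximum(mu, 1e-12)
        XtWX = np.einsum("np,gn,nq->gpq", X, W, X)
        XtWz = np.einsum("np,gn,gn->gp", X, W, z)
        XtWX += 1e-10 * np.eye(p)[None, :, :]
        beta = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]
    return beta


def nb_loglik(y: np.ndarray, mu: np.ndarray, disp: float) -> float:
    """NB log-likelihood with Var = mu + disp * mu^2."""
    r = 1.0 / disp
    mu = np.maximum(mu, 1e-12)
    return float(
        np.sum(
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def estimate_dispersions(
    counts: np.ndarray, X: np.ndarray, offset: np.ndarray
) -> np.ndarray:
    """Per-gene dispersion MLE at the Poisson-IRLS fitted means.

    Method-of-moments start, refined by a bounded 1-d likelihood
    maximization over log dispersion.  Estimates at the lower bound signal
    (near-)Poisson genes.
    """
    Y = np.asarray(counts, dtype=float)
    beta = _poisson_irls(Y, X, offset)
    mu = np.exp(np.clip(beta @ X.T + offset[None, :], -30, 30))
    G, n = Y.shape
    p = X.shape[1]
    resid_df = max(n - p, 1)
    disp = np.empty(G)
    for g in range(G):
        y, m = Y[g], mu[g]
        mom = np.sum((y - m) ** 2 - m) / max(np.sum(m**2), 1e-12) * n / resid_df
        if not np.isfinite(mom) or mom <= 0:
            mom = _MIN_DISP
        lo, hi = np.log(_MIN_DISP), np.log(_MAX_DISP)
        x0 = float(np.clip(np.log(mom), lo, hi))
        res = minimize_scalar(
            lambda ld: -nb_loglik(y, m, float(np.exp(ld))),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 0.01, "maxiter": 50},
        )
        disp[g] = float(np.exp(res.x)) if res.success else float(np.exp(x0))
    return np.clip(disp, _MIN_DISP, _MAX_DISP)


def fit_nb_glm(
    counts: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    dispersions: np.ndarray,
    n_iter: int = 15,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched NB IRLS with fixed per-gene dispersion.

    Returns (beta, se): both G x p, with Wald standard errors from the
    observed Fisher information (X' W X)^-1.
    """
    Y = np.asarray(counts, dtype=float)
    G, n = Y.shape
    p = X.shape[1]
    disp = np.asarray(dispersions, dtype=float)[:, None]
    beta = _poisson_irls(Y, X, offset)
    for _ in range(n_iter):
        eta = np.clip(beta @ X.T + offset[None, :], -30, 30)
        mu = np.exp(eta)
        W = mu / (1.0 + disp * mu)  # NB working weights, log link
        z = eta - offset[None, :] + (Y - mu) / np.maximum(mu, 1e-12)
        XtWX = np.einsum("np,gn,nq->gpq", X, W, X)
        XtWz = np.einsum("np,gn,gn->gp", X, W, z)
        XtWX += 1e-10 * np.eye(p)[None, :, :]
        new = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new
    eta = np.clip(beta @ X.T + offset[None, :], -30, 30)
    mu = np.exp(eta)
    W = mu / (1.0 + disp * mu)
    XtWX = np.einsum("np,gn,nq->gpq", X, W, X) + 1e-10 * np.eye(p)[None, :, :]
    cov = np.linalg.inv(XtWX)
    se = np.sqrt(np.maximum(np.einsum("gpp->gp", cov), 0.0))
    return beta, se
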