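"""Parametric empirical-Bayes ComBat harmonization.

Removes additive and multiplicative acquisition-site (batch) effects from a
features x subjects table while preserving modeled biological covariates
(age, sex, and optionally diagnostic group).  The model for feature g of
subject j in batch i is

    y_ijg = alpha_g + X_j beta_g + gamma_ig + delta_ig * eps_ijg

Per-batch location gamma_ig and scale delta_ig are shrunk across features by
empirical Bayes: a normal prior on gamma (mean gamma_bar_i, variance tau_i^2)
and an inverse-gamma prior on delta^2 (shape lambda_i, scale theta_i), with
hyperparameters estimated by method of moments and posteriors solved by
iterated conditional modes.  The harmonized value is

    y*_ijg = sigma_g * (z_ijg - gamma*_ig) / delta*_ig + alpha_g + X_j beta_g

where z is the standardized residual and sigma_g the pooled feature scale.
This follows the standard reference implementations used for multi-site
neuroimaging feature tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConfoundedBatchError(ValueError):
    """A covariate column is perfectly confounded with batch."""


@dataclass
class CombatModel:
    """Fitted ComBat parameters (features x batches unless noted)."""

    batch_levels: list
    n_per_batch: np.ndarray
    feature_names: list[str]
    covariate_names: list[str]
    grand_mean: np.ndarray          # per feature
    beta: np.ndarray                # covariates x features
    var_pooled: np.ndarray          # per feature
    gamma_hat: np.ndarray           # batches x features
    delta_hat_sq: np.ndarray        # batches x features
    gamma_bar: np.ndarray           # per batch
    tau_sq: np.ndarray              # per batch
    a_prior: np.ndarray             # per batch (inverse-gamma shape)
    b_prior: np.ndarray             # per batch (inverse-gamma scale)
    gamma_star: np.ndarray          # batches x features
    delta_star_sq: np.ndarray       # batches x features
    n_iter: int = 0


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum_sq, n, a, b):
    return (0.5 * sum_sq + b) / (n / 2.0 + a - 1.0)


def _aprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m**2) / s2


def _bprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_solve(z_batch, g_hat, d_hat_sq, g_bar, t2, a, b, tol, max_iter):
    """Iterated conditional posterior updates for one batch."""
    n = z_batch.shape[1]
    g_old, d_old = g_hat.copy(), d_hat_sq.copy()
    count = 0
    change = 1.0
    while change > tol and count < max_iter:
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum_sq = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum_sq, n, a, b)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_g = np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-300)
            rel_d = np.abs(d_new - d_old) / d_old
        change = max(rel_g.max(), rel_d.max())
        g_old, d_old = g_new, d_new
        count += 1
    return g_old, d_old, count


def combat_fit_transform(
    features: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[pd.DataFrame, CombatModel]:
    """Harmonize a features x subjects table across batches.

    Parameters
    ----------
    features
        Features in rows, subjects in columns; no missing values.
    batch
        Batch (site) label per subject, indexed like the columns.
    covariates
        Numeric biological covariates to preserve (subjects x covariates),
        e.g. age, a 0/1 sex indicator, and group dummies.  May be ``None``.
    tol, max_iter
        Convergence tolerance and iteration cap for the EB posterior solve.

    Returns
    -------
    A new harmonized table (input untouched) and the fitted model.
    """
    subjects = list(features.columns)
    y = features.to_numpy(dtype=float)  # G x n
    if np.isnan(y).any():
        raise ValueError("feature table contains missing values")
    batch = batch.reindex(subjects)
    if batch.isna().any():
        raise ValueError("batch labels missing for some subjects")
    levels = sorted(batch.unique().tolist())
    if len(levels) < 2:
        raise ValueError("ComBat needs at least 2 batches")
    n = len(subjects)
    batch_onehot = np.column_stack([(batch == lv).to_numpy(float) for lv in levels])
    n_per_batch = batch_onehot.sum(axis=0)
    if (n_per_batch < 2).any():
        small = [lv for lv, c in zip(levels, n_per_batch) if c < 2]
        raise ValueError(f"each batch needs >= 2 subjects; too small: {small}")

    cov_names: list[str] = []
    x_cov = np.empty((n, 0))
    if covariates is not None and covariates.shape[1] > 0:
        covariates = covariates.reindex(subjects)
        cov_names = list(covariates.columns)
        x_cov = covariates.to_numpy(dtype=float)
        # a covariate lying in the span of the batch indicators is
        # inseparable from the site effect
        for k, name in enumerate(cov_names):
            coef, res, *_ = np.linalg.lstsq(batch_onehot, x_cov[:, k], rcond=None)
            fitted = batch_onehot @ coef
            ss = ((x_cov[:, k] - fitted) ** 2).sum()
            if ss < 1e-10 * max(1.0, (x_cov[:, k] ** 2).sum()):
                raise ConfoundedBatchError(
                    f"covariate {name!r} is confounded with batch"
                )

    design = np.hstack([batch_onehot, x_cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")

    b_hat, *_ = np.linalg.lstsq(design, y.T, rcond=None)  # p x G
    n_batch = len(levels)
    grand_mean = (n_per_batch / n) @ b_hat[:n_batch]  # per feature
    resid = y - (design @ b_hat).T
    var_pooled = (resid**2).mean(axis=1)
    if (var_pooled <= 0).any():
        raise ValueError("zero pooled variance for some feature")

    stand_mean = grand_mean[:, None] + (x_cov @ b_hat[n_batch:]).T
    sigma = np.sqrt(var_pooled)[:, None]
    z = (y - stand_mean) / sigma

    members = [batch_onehot[:, i].astype(bool) for i in range(n_batch)]
    gamma_hat = np.vstack([z[:, m].mean(axis=1) for m in members])
    delta_hat_sq = np.vstack([z[:, m].var(axis=1, ddof=1) for m in members])
    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq = gamma_hat.var(axis=1, ddof=1)
    a_prior = np.array([_aprior(d) for d in delta_hat_sq])
    b_prior = np.array([_bprior(d) for d in delta_hat_sq])

    gamma_star = np.empty_like(gamma_hat)
    delta_star_sq = np.empty_like(delta_hat_sq)
    iters = 0
    for i in range(n_batch):
        gamma_star[i], delta_star_sq[i], it = _it_solve(
            z[:, members[i]], gamma_hat[i], delta_hat_sq[i],
            gamma_bar[i], tau_sq[i], a_prior[i], b_prior[i], tol, max_iter,
        )
        iters = max(iters, it)

    adjusted = z.copy()
    for i in range(n_batch):
        adjusted[:, members[i]] = (
            z[:, members[i]] - gamma_star[i][:, None]
        ) / np.sqrt(delta_star_sq[i])[:, None]
    harmonized = adjusted * sigma + stand_mean

    model = CombatModel(
        batch_levels=levels,
        n_per_batch=n_per_batch,
        feature_names=list(features.index),
        covariate_names=cov_names,
        grand_mean=grand_mean,
        beta=b_hat[n_batch:],
        var_pooled=var_pooled,
        gamma_hat=gamma_hat,
        delta_hat_sq=delta_hat_sq,
        gamma_bar=gamma_bar,
        tau_sq=tau_sq,
        a_prior=a_prior,
        b_prior=b_prior,
        gamma_star=gamma_star,
        delta_star_sq=delta_star_sq,
        n_iter=iters,
    )
    out = pd.DataFrame(harmonized, index=features.index, columns=features.columns)
    return out, model


def harmonization_report(
    model: CombatModel, scale_flag_range: tuple[float, float] = (0.25, 4.0)
) -> pd.DataFrame:
    """Per feature x batch location/scale estimates as a tidy table.

    Rows: n_features x n_batches.  ``flag_extreme_scale`` marks features
    whose posterior scale factor falls outside ``scale_flag_range``.
    """
    if not isinstance(model, CombatModel):
        raise TypeError("harmonization_report expects a fitted CombatModel")
    rows = []
    for i, lv in enumerate(model.batch_levels):
        for g, feat in enumerate(model.feature_names):
            delta_star = float(np.sqrt(model.delta_star_sq[i, g]))
            rows.append(
                {
                    "feature": feat,
                    "batch": lv,
                    "n": int(model.n_per_batch[i]),
                    "gamma_hat": float(model.gamma_hat[i, g]),
                    "gamma_star": float(model.gamma_star[i, g]),
                    "delta_hat": float(np.sqrt(model.delta_hat_sq[i, g])),
                    "delta_star": delta_star,
                    "flag_extreme_scale": not (
                        scale_flag_range[0] <= delta_star <= scale_flag_range[1]
                    ),
                }
            )
    return pd.DataFrame(rows)
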