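"""Empirical-Bayes location/scale batch-effect adjustment (ComBat-style).

Per feature, a linear model with biological covariates (age, sex) plus batch
indicators is fit; residual data are standardized by the feature grand mean
and pooled variance; per-batch additive (gamma) and multiplicative (delta)
effects are estimated and shrunk toward parametric priors (normal for gamma,
inverse-gamma for delta) by method of moments; the shrunken effects are
removed and the covariate effects and grand mean restored.  Age and sex are
thereby preserved by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .signal import SampleMeta, SignalMatrix

__all__ = ["BatchModel", "fit_adjust", "batch_diagnostics"]

logger = logging.getLogger(__name__)

MIN_BATCH_SIZE = 2
EB_TOL = 1e-4
EB_MAX_ITER = 100


@dataclass
class BatchModel:
    """Fitted batch-adjustment parameters (one gamma*/delta* pair per
    (batch, feature))."""

    batches: list[str]
    design: np.ndarray  # samples x (batch indicators + covariates)
    gamma_hat: np.ndarray  # batches x features, raw additive effects
    gamma_star: np.ndarray  # batches x features, EB-shrunk
    delta_hat: np.ndarray  # batches x features, raw variance scales
    delta_star: np.ndarray  # batches x features, EB-shrunk (> 0)
    gamma_prior_mean: np.ndarray  # per batch
    gamma_prior_var: np.ndarray
    delta_prior_shape: np.ndarray  # inverse-gamma a per batch
    delta_prior_scale: np.ndarray  # inverse-gamma b per batch
    grand_mean: np.ndarray  # per feature
    pooled_var: np.ndarray  # per feature
    n_iterations: list[int] = field(default_factory=list)


def _design_matrix(samples: list[SampleMeta], batches: list[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Batch one-hot block followed by covariate block (age, sex indicator)."""
    batch_idx = {b: i for i, b in enumerate(batches)}
    n = len(samples)
    B = np.zeros((n, len(batches)))
    for j, s in enumerate(samples):
        B[j, batch_idx[s.batch]] = 1.0
    ages = np.array([s.age for s in samples], dtype=float)
    cov_cols = [ages - ages.mean()]
    cov_names = ["age"]
    sexes = [s.sex for s in samples]
    if len(set(sexes)) > 1:
        # indicator per non-reference sex level
        levels = sorted(set(sexes))
        for lev in levels[1:]:
            cov_cols.append(np.array([1.0 if s == lev else 0.0 for s in sexes]))
            cov_names.append(f"sex_{lev}")
    C = np.column_stack(cov_cols)
    return B, C, cov_names


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum_sq, n, a, b):
    return (0.5 * sum_sq + b) / (n / 2.0 + a - 1.0)


def fit_adjust(
    x: SignalMatrix, batch_labels: list[str] | None = None
) -> tuple[SignalMatrix, BatchModel | None]:
    """Adjust a log-scale signal matrix for batch effects, preserving age/sex.

    ``batch_labels`` defaults to each sample's ``batch`` field.  With a single
    batch the input is returned unchanged (with a warning).  Batches smaller
    than two samples are pooled into a pseudo-batch ``"small"``.
    """
    if batch_labels is None:
        batch_labels = [s.batch for s in x.samples]
    if len(batch_labels) != x.n_samples:
        raise ValueError("batch_labels length must match number of samples")
    labels = list(batch_labels)
    counts: dict[str, int] = {}
    for b in labels:
        counts[b] = counts.get(b, 0) + 1
    small = [b for b, c in counts.items() if c < MIN_BATCH_SIZE]
    if small:
        logger.warning("pooling undersized batches %s into pseudo-batch 'small'", small)
        labels = ["small" if b in small else b for b in labels]
    batches = sorted(set(labels))
    if len(batches) < 2:
        warnings.warn("single batch: nothing to correct, returning input unchanged")
        return x.with_values(x.values.copy(), "batch_corrected"), None

    relabeled = [
        SampleMeta(s.sample_id, s.age, s.sex, lab, s.tissue, s.mark,
                   s.replicate_group, s.condition)
        for s, lab in zip(x.samples, labels)
    ]
    B, C, cov_names = _design_matrix(relabeled, batches)
    X = np.hstack([B, C])
    n_samples = X.shape[0]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "design matrix is rank deficient: a covariate "
            f"({cov_names}) is confounded with batch"
        )

    Y = x.values  # features x samples
    # per-feature OLS: beta (features x p)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    n_per_batch = B.sum(axis=0)
    # grand mean = batch-size-weighted mean of the batch intercepts
    grand_mean = (n_per_batch / n_samples) @ beta[: len(batches), :]
    resid = Y.T - X @ beta  # samples x features
    pooled_var = (resid**2).sum(axis=0) / n_samples
    pooled_var = np.where(pooled_var <= 0, 1e-12, pooled_var)

    cov_effect = (C @ beta[len(batches):, :]).T  # features x samples
    stand_mean = grand_mean[:, None] + cov_effect
    Z = (Y - stand_mean) / np.sqrt(pooled_var)[:, None]  # standardized data

    n_b = len(batches)
    n_feat = Y.shape[0]
    gamma_hat = np.zeros((n_b, n_feat))
    delta_hat = np.zeros((n_b, n_feat))
    members = [np.where(B[:, i] == 1)[0] for i in range(n_b)]
    for i, idx in enumerate(members):
        Zb = Z[:, idx]
        gamma_hat[i] = Zb.mean(axis=1)
        delta_hat[i] = Zb.var(axis=1, ddof=1)
    delta_hat = np.where(delta_hat <= 0, 1e-12, delta_hat)

    # parametric EB priors by method of moments
    g_bar = gamma_hat.mean(axis=1)
    t2 = gamma_hat.var(axis=1, ddof=1)
    m = delta_hat.mean(axis=1)
    s2 = delta_hat.var(axis=1, ddof=1)
    s2 = np.where(s2 <= 0, 1e-12, s2)
    a_prior = (2 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    iters: list[int] = []
    for i, idx in enumerate(members):
        n = len(idx)
        Zb = Z[:, idx]
        g_new = gamma_hat[i].copy()
        d_new = delta_hat[i].copy()
        it = 0
        for it in range(1, EB_MAX_ITER + 1):
            g_old, d_old = g_new, d_new
            g_new = _postmean(gamma_hat[i], g_bar[i], n, d_old, t2[i])
            sum_sq = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = _postvar(sum_sq, n, a_prior[i], b_prior[i])
            change = max(
                np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max()
            )
            if change < EB_TOL:
                break
        iters.append(it)
        gamma_star[i] = g_new
        delta_star[i] = np.where(d_new <= 0, 1e-12, d_new)

    Z_adj = Z.copy()
    for i, idx in enumerate(members):
        Z_adj[:, idx] = (Z[:, idx] - gamma_star[i][:, None]) / np.sqrt(
            delta_star[i]
        )[:, None]
    corrected = Z_adj * np.sqrt(pooled_var)[:, None] + stand_mean

    model = BatchModel(
        batches=batches,
        design=X,
        gamma_hat=gamma_hat,
        gamma_star=gamma_star,
        delta_hat=delta_hat,
        delta_star=delta_star,
        gamma_prior_mean=g_bar,
        gamma_prior_var=t2,
        delta_prior_shape=a_prior,
        delta_prior_scale=b_prior,
        grand_mean=grand_mean,
        pooled_var=pooled_var,
        n_iterations=iters,
    )
    return x.with_values(corrected, "batch_corrected"), model


def _batch_f_statistics(values: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """One-way ANOVA F per feature across batch groups; NaN for features
    with zero within-group variance everywhere (constant features)."""
    n_feat = values.shape[0]
    out = np.full(n_feat, np.nan)
    arrays = [values[:, idx] for idx in groups]
    k = len(arrays)
    n_tot = sum(a.shape[1] for a in arrays)
    overall = values[:, np.concatenate(groups)].mean(axis=1)
    ss_between = sum(
        a.shape[1] * (a.mean(axis=1) - overall) ** 2 for a in arrays
    )
    ss_within = sum(((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for a in arrays)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / (k - 1)) / (ss_within / (n_tot - k))
    ok = ss_within > 0
    out[ok] = f[ok]
    return out


def batch_diagnostics(
    before: SignalMatrix, after: SignalMatrix, batch_labels: list[str] | None = None
) -> dict:
    """Mean per-feature batch F-statistic and PC1-2 batch-variance fraction,
    before and after correction.  Constant features get F = NaN and are
    excluded from the mean."""
    if before.values.shape != after.values.shape:
        raise ValueError("before/after shapes must match")
    if batch_labels is None:
        batch_labels = [s.batch for s in before.samples]
    batches = sorted(set(batch_labels))
    groups = [
        np.where(np.array(batch_labels) == b)[0] for b in batches
    ]
    report: dict = {}
    for tag, mat in (("before", before), ("after", after)):
        f = _batch_f_statistics(mat.values, groups)
        report[f"mean_batch_f_{tag}"] = float(np.nanmean(f))
        report[f"batch_f_{tag}"] = f
        # PCA over samples; fraction of PC1-2 score variance explained by batch
        centered = mat.values - mat.values.mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(centered.T, full_matrices=False)
        scores = centered.T @ vt[:2].T  # samples x 2
        r2 = []
        for c in range(2):
            y = scores[:, c]
            ss_tot = ((y - y.mean()) ** 2).sum()
            if ss_tot == 0:
                r2.append(0.0)
                continue
            ss_b = sum(len(idx) * (y[idx].mean() - y.mean()) ** 2 for idx in groups)
            r2.append(ss_b / ss_tot)
        report[f"pc_batch_r2_{tag}"] = float(np.mean(r2))
    return report
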