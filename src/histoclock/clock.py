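"""Elastic-net epigenetic age clocks.

The model minimizes (1/2n)||y - Xw - b||^2 + lambda (alpha ||w||_1 +
(1-alpha)/2 ||w||^2) on standardized features, with the intercept
unpenalized.  Hyperparameters are chosen by leave-one-group-out
cross-validation over age-stratified sample groups: each fold holds out one
whole age group, re-estimates the feature standardization on the remaining
samples only (no leakage), and the (alpha, lambda) pair minimizing the pooled
cross-validated RMSE wins, ties broken toward the larger lambda (sparser
model).  The final model is refit on all samples with the winning pair.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import ElasticNet, Ridge

from .signal import SignalMatrix, standardize_features

__all__ = [
    "ClockModel",
    "CVResult",
    "make_age_groups",
    "fit_elastic_net",
    "logo_cv_train",
    "predict_age",
    "accuracy_metrics",
    "age_gap",
    "default_alpha_grid",
    "default_lambda_path",
]

logger = logging.getLogger(__name__)

CD_TOL = 1e-7
CD_MAX_ITER = 100_000
DEFAULT_N_GROUPS = 11


@dataclass
class ClockModel:
    """A sparse linear age predictor over standardized peak features.

    Only nonzero-coefficient features are stored; ``means``/``sds`` are the
    training standardization parameters for those features.
    """

    features: list[str]
    coefficients: np.ndarray
    intercept: float
    mixing: float  # L1 fraction alpha
    penalty: float  # lambda
    means: np.ndarray
    sds: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (len(self.features) == len(self.coefficients) == len(self.means) == len(self.sds)):
            raise ValueError("features/coefficients/means/sds must align")
        if (self.coefficients == 0).any():
            raise ValueError("zero coefficients must be dropped before storage")
        if (self.sds <= 0).any():
            raise ValueError("retained features must have positive training sd")

    @property
    def n_features(self) -> int:
        return len(self.features)

    def to_json(self, path=None) -> str:
        payload = {
            "features": self.features,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "mixing": self.mixing,
            "penalty": self.penalty,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "ClockModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            features=list(payload["features"]),
            coefficients=np.array(payload["coefficients"]),
            intercept=float(payload["intercept"]),
            mixing=float(payload["mixing"]),
            penalty=float(payload["penalty"]),
            means=np.array(payload["means"]),
            sds=np.array(payload["sds"]),
            provenance=dict(payload.get("provenance", {})),
        )


@dataclass
class CVResult:
    """Pooled leave-one-group-out predictions and metrics at the winning
    hyperparameters.  Every sample is predicted exactly once."""

    groups: np.ndarray
    predictions: np.ndarray
    ages: np.ndarray
    rmse: float
    mae: float
    pearson_r: float
    alpha: float
    lam: float


def make_age_groups(
    ages: np.ndarray, n_groups: int = DEFAULT_N_GROUPS, mode: str = "equal_width"
) -> np.ndarray:
    """Partition samples into age strata.

    ``equal_width`` splits [min age, max age] into equal-width bins (empty
    bins merged with the nearest nonempty neighbor, so the final group count
    may be smaller; relabeled 0..k-1 in age order).  ``quantile`` uses
    equal-count quantile bins instead.
    """
    ages = np.asarray(ages, dtype=float)
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    lo, hi = ages.min(), ages.max()
    if lo == hi:
        raise ValueError("all ages are equal; cannot stratify")
    if mode == "equal_width":
        edges = np.linspace(lo, hi, n_groups + 1)
        raw = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0, n_groups - 1)
    elif mode == "quantile":
        qs = np.quantile(ages, np.linspace(0, 1, n_groups + 1))
        raw = np.clip(np.searchsorted(qs, ages, side="right") - 1, 0, n_groups - 1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    occupied = np.unique(raw)
    if len(occupied) < n_groups:
        logger.info(
            "merged %d empty age bins; %d groups remain", n_groups - len(occupied), len(occupied)
        )
    relabel = {g: i for i, g in enumerate(occupied)}
    return np.array([relabel[g] for g in raw], dtype=int)


def fit_elastic_net(
    x: np.ndarray, y: np.ndarray, mixing: float, penalty: float,
    feature_ids: list[str] | None = None,
    means: np.ndarray | None = None, sds: np.ndarray | None = None,
    provenance: dict | None = None,
) -> ClockModel:
    """Fit one elastic net at fixed (alpha, lambda) on pre-standardized
    features.

    ``x`` must already be standardized; ``means``/``sds`` record the
    standardization so the model can be applied to raw matrices (defaults:
    0/1, i.e. the model expects standardized input).  The pure-ridge limit
    (alpha = 0) is solved in closed form as (X'X + n lambda I)^-1 X'y on
    centered data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0.0 <= mixing <= 1.0:
        raise ValueError(f"mixing alpha must be in [0, 1], got {mixing}")
    if penalty < 0:
        raise ValueError(f"penalty lambda must be >= 0, got {penalty}")
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if mixing == 0.0:
        est = Ridge(alpha=n * penalty, fit_intercept=True, solver="cholesky")
    else:
        est = ElasticNet(
            alpha=max(penalty, np.finfo(float).tiny),
            l1_ratio=mixing,
            fit_intercept=True,
            tol=CD_TOL,
            max_iter=CD_MAX_ITER,
        )
    est.fit(x, y)
    coef = np.asarray(est.coef_, dtype=float)
    nz = np.abs(coef) > 0
    feature_ids = feature_ids if feature_ids is not None else [f"f{i}" for i in range(p)]
    means = means if means is not None else np.zeros(p)
    sds = sds if sds is not None else np.ones(p)
    return ClockModel(
        features=[feature_ids[i] for i in np.where(nz)[0]],
        coefficients=coef[nz],
        intercept=float(est.intercept_),
        mixing=mixing,
        penalty=penalty,
        means=np.asarray(means)[nz],
        sds=np.asarray(sds)[nz],
        provenance=provenance or {},
    )


def default_alpha_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 1.01, 0.1), 10)


def default_lambda_path(
    x: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int = 100,
    ratio: float = 1e-4,
) -> np.ndarray:
    """Log-spaced lambda path from the smallest lambda zeroing every
    coefficient (at the given alpha) down to ``ratio`` times it."""
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    lam_max = np.abs(xc.T @ yc).max() / (n * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-8)
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _fit_enet_path(xs, y, alpha, lambdas):
    """Coefficients along a decreasing lambda path with warm starts.
    Returns (coefs [n_lambda x p], intercepts)."""
    n, p = xs.shape
    coefs = np.zeros((len(lambdas), p))
    icepts = np.zeros(len(lambdas))
    if alpha == 0.0:
        for i, lam in enumerate(lambdas):
            est = Ridge(alpha=n * lam, fit_intercept=True, solver="cholesky")
            est.fit(xs, y)
            coefs[i] = est.coef_
            icepts[i] = est.intercept_
        return coefs, icepts
    est = ElasticNet(
        alpha=lambdas[0], l1_ratio=alpha, fit_intercept=True,
        tol=CD_TOL, max_iter=CD_MAX_ITER, warm_start=True,
    )
    # near the unpenalized end of the path coordinate descent may stop at
    # max_iter without meeting the duality gap; those fits are still accurate
    # enough for model selection, so the solver's warning is noise here
    import warnings as _warnings

    from sklearn.exceptions import ConvergenceWarning

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        for i, lam in enumerate(lambdas):
            est.set_params(alpha=max(lam, np.finfo(float).tiny))
            est.fit(xs, y)
            coefs[i] = est.coef_
            icepts[i] = est.intercept_
    return coefs, icepts


def logo_cv_train(
    x: SignalMatrix,
    ages: np.ndarray | None = None,
    groups: np.ndarray | None = None,
    alpha_grid: np.ndarray | None = None,
    n_lambda: int = 100,
    n_groups: int = DEFAULT_N_GROUPS,
) -> tuple[ClockModel, CVResult]:
    """Leave-one-group-out hyperparameter search and final refit.

    The lambda path for each alpha is computed once on the full data (so the
    grid is common across folds); standardization is re-estimated inside each
    fold on the training samples only.
    """
    y = x.ages if ages is None else np.asarray(ages, dtype=float)
    if groups is None:
        groups = make_age_groups(y, n_groups=n_groups)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups for leave-one-group-out CV")
    if any((groups == g).all() for g in uniq):
        raise ValueError("a group contains all samples")
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    alpha_grid = np.asarray(alpha_grid, dtype=float)

    n = x.n_samples
    feature_ids = x.peak_ids
    # common lambda path per alpha, from the full standardized matrix
    full_std, _, _, _ = standardize_features(x)
    paths = {
        float(a): default_lambda_path(full_std.values.T, y, float(a), n_lambda)
        for a in alpha_grid
    }

    # pooled CV predictions per (alpha, lambda-index)
    preds = {
        float(a): np.zeros((n_lambda, n)) for a in alpha_grid
    }
    for g in uniq:
        test = np.where(groups == g)[0]
        train = np.where(groups != g)[0]
        std_train, mu, sd, const = standardize_features(x, fit_columns=train)
        xs_train = std_train.values[:, train].T  # samples x features
        xs_test = std_train.values[:, test].T
        for a in alpha_grid:
            coefs, icepts = _fit_enet_path(xs_train, y[train], float(a), paths[float(a)])
            preds[float(a)][:, test] = coefs @ xs_test.T + icepts[:, None]

    best = None  # (rmse, -lam, alpha, lam_idx)
    for a in alpha_grid:
        lams = paths[float(a)]
        err = preds[float(a)] - y[None, :]
        rmse = np.sqrt((err**2).mean(axis=1))
        for i, lam in enumerate(lams):
            key = (round(float(rmse[i]), 12), -lam)
            if best is None or key < best[0]:
                best = (key, float(a), i)
    assert best is not None
    _, alpha_best, lam_idx = best
    lam_best = float(paths[alpha_best][lam_idx])
    pooled = preds[alpha_best][lam_idx]
    rmse, mae, r = accuracy_metrics(y, pooled)
    cv = CVResult(
        groups=groups, predictions=pooled, ages=y,
        rmse=rmse, mae=mae, pearson_r=r, alpha=alpha_best, lam=lam_best,
    )
    # final refit on all samples
    std_all, mu, sd, const = standardize_features(x)
    model = fit_elastic_net(
        std_all.values.T, y, alpha_best, lam_best,
        feature_ids=feature_ids, means=mu, sds=np.where(sd == 0, 1.0, sd),
        provenance={
            "n_samples": int(n),
            "tissues": sorted({s.tissue for s in x.samples}),
            "marks": sorted({s.mark for s in x.samples}),
            "training_samples": x.sample_ids,
        },
    )
    return model, cv


def predict_age(model: ClockModel, x: SignalMatrix) -> np.ndarray:
    """Predicted age per sample: intercept + sum_f w_f (x_f - mu_f) / sd_f.

    Every model feature must be present in ``x`` (matched by peak id)."""
    index = {pid: i for i, pid in enumerate(x.peak_ids)}
    missing = [f for f in model.features if f not in index]
    if missing:
        raise KeyError(f"matrix lacks {len(missing)} model features: {missing[:5]}...")
    rows = [index[f] for f in model.features]
    z = (x.values[rows, :] - model.means[:, None]) / model.sds[:, None]
    return model.intercept + model.coefficients @ z


def accuracy_metrics(y: np.ndarray, y_hat: np.ndarray) -> tuple[float, float, float]:
    """(RMSE, MAE, Pearson r); r is NaN when either vector is constant."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if len(y) < 2:
        raise ValueError("need >= 2 observations")
    err = y - y_hat
    rmse = float(np.sqrt((err**2).mean()))
    mae = float(np.abs(err).mean())
    if np.ptp(y) == 0 or np.ptp(y_hat) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(y, y_hat)[0])
    return rmse, mae, r


def age_gap(
    model: ClockModel,
    x: SignalMatrix,
    paired: bool = False,
    scaled: bool = True,
) -> dict:
    """Per-sample age gap (predicted minus chronological age) and, in paired
    mode, the scaled age gap over (pre, post) treatment pairs.

    Pairs are matched on ``replicate_group``; each pair id must occur exactly
    once per condition.  The scaled gap of a pair is
    (yhat_post - yhat_pre) / yhat_pre (or the absolute difference when
    ``scaled=False``) and is tested against zero with a one-sample two-sided
    Student t-test.
    """
    y_hat = predict_age(model, x)
    ages = x.ages
    out: dict = {
        "sample_ids": x.sample_ids,
        "predicted": y_hat,
        "gap": y_hat - ages,
    }
    if not paired:
        return out
    pre: dict[str, float] = {}
    post: dict[str, float] = {}
    for j, s in enumerate(x.samples):
        store = pre if s.condition == "pre_treatment" else (
            post if s.condition == "post_treatment" else None
        )
        if store is None:
            continue
        if s.replicate_group in store:
            raise ValueError(
                f"pair id {s.replicate_group!r} occurs twice in one condition"
            )
        store[s.replicate_group] = y_hat[j]
    if set(pre) != set(post):
        odd = set(pre) ^ set(post)
        raise ValueError(f"unpaired pair ids: {sorted(odd)}")
    pair_ids = sorted(pre)
    if scaled:
        gaps = np.array([(post[k] - pre[k]) / pre[k] for k in pair_ids])
    else:
        gaps = np.array([post[k] - pre[k] for k in pair_ids])
    out["pair_ids"] = pair_ids
    out["scaled_gap"] = gaps
    out["mean_scaled_gap"] = float(gaps.mean())
    if len(gaps) >= 2 and np.ptp(gaps) > 0:
        t, p = stats.ttest_1samp(gaps, 0.0)
        out["t"] = float(t)
        out["p"] = float(p)
    else:
        out["t"] = float("nan")
        out["p"] = float("nan")
    return out
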