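"""Clock evaluation protocols: Gaussian-noise robustness, quantile-rank
benchmarking against a reference RMSE distribution, and sample-size
saturation analysis via paired independently trained models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .clock import ClockModel, accuracy_metrics, logo_cv_train, make_age_groups, predict_age
from .signal import SignalMatrix

__all__ = [
    "RobustnessCurve",
    "SaturationCurve",
    "DEFAULT_SIGMA_GRID",
    "noise_robustness",
    "compare_curves",
    "quantile_rank",
    "saturation_analysis",
]

# noise SDs in standardized-feature units
DEFAULT_SIGMA_GRID = np.arange(0.0, 1.51, 0.3)


@dataclass
class RobustnessCurve:
    sigma_grid: np.ndarray
    rmse_mean: np.ndarray
    rmse_sem: np.ndarray
    relative_rmse: np.ndarray  # rmse(sigma)/rmse(0)
    rmse_reps: np.ndarray  # len(sigma_grid) x n_reps
    n_reps: int
    seed: int


@dataclass
class SaturationCurve:
    n_grid: np.ndarray
    r_mean: np.ndarray
    r_sd: np.ndarray
    r_reps: np.ndarray  # len(n_grid) x n_reps
    mode: str  # "observed" or "estimated"
    n_reps: int
    seed: int


def noise_robustness(
    model: ClockModel,
    x: SignalMatrix,
    ages: np.ndarray | None = None,
    sigma_grid: np.ndarray | None = None,
    n_reps: int = 20,
    seed: int = 0,
) -> RobustnessCurve:
    """Prediction RMSE under i.i.d. Gaussian noise added to the standardized
    feature values of the evaluation samples, with the trained model held
    fixed.

    Noise SD sigma is in standardized-feature units, so sigma = 1 perturbs
    each feature by one training SD.  sigma = 0 reproduces the noise-free
    baseline bit-exactly and the curve is reported both absolutely and
    relative to that baseline.
    """
    y = x.ages if ages is None else np.asarray(ages, dtype=float)
    if sigma_grid is None:
        sigma_grid = DEFAULT_SIGMA_GRID.copy()
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if (sigma_grid < 0).any():
        raise ValueError("noise SDs must be non-negative")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    baseline_pred = predict_age(model, x)
    baseline_rmse = accuracy_metrics(y, baseline_pred)[0]
    index = {pid: i for i, pid in enumerate(x.peak_ids)}
    rows = [index[f] for f in model.features]
    z = (x.values[rows, :] - model.means[:, None]) / model.sds[:, None]
    rmses = np.zeros((len(sigma_grid), n_reps))
    for i, sig in enumerate(sigma_grid):
        for rep in range(n_reps):
            if sig == 0.0:
                pred = baseline_pred
            else:
                noise = rng.normal(0.0, sig, size=z.shape)
                pred = model.intercept + model.coefficients @ (z + noise)
            rmses[i, rep] = accuracy_metrics(y, pred)[0]
    mean = rmses.mean(axis=1)
    sem = rmses.std(axis=1, ddof=1) / np.sqrt(n_reps) if n_reps > 1 else np.zeros_like(mean)
    return RobustnessCurve(
        sigma_grid=sigma_grid,
        rmse_mean=mean,
        rmse_sem=sem,
        relative_rmse=mean / baseline_rmse if baseline_rmse > 0 else mean,
        rmse_reps=rmses,
        n_reps=n_reps,
        seed=seed,
    )


def compare_curves(curve_a: RobustnessCurve, curve_b: RobustnessCurve) -> np.ndarray:
    """Two-sided Mann-Whitney U p-value at each noise level, comparing the
    per-repetition RMSE samples of two robustness curves.

    Exact enumeration when both samples have <= 20 observations and no ties;
    normal approximation with tie correction otherwise.
    """
    if not np.array_equal(curve_a.sigma_grid, curve_b.sigma_grid):
        raise ValueError("sigma grids differ between curves")
    ps = np.zeros(len(curve_a.sigma_grid))
    for i in range(len(ps)):
        a = curve_a.rmse_reps[i]
        b = curve_b.rmse_reps[i]
        small = len(a) <= 20 and len(b) <= 20
        no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        method = "exact" if (small and no_ties) else "asymptotic"
        ps[i] = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        )
    return ps


def quantile_rank(clock_rmse: float, reference_rmses) -> float:
    """Midrank quantile of the clock's RMSE within a reference distribution:
    (#{ref < clock} + 0.5 #{ref == clock}) / |ref|.  Lower is better."""
    ref = np.asarray(list(reference_rmses), dtype=float)
    if ref.size == 0:
        raise ValueError("reference RMSE list is empty")
    below = (ref < clock_rmse).sum()
    equal = (ref == clock_rmse).sum()
    return float((below + 0.5 * equal) / ref.size)


def saturation_analysis(
    x: SignalMatrix,
    ages: np.ndarray | None = None,
    n_grid: np.ndarray | None = None,
    n_reps: int = 5,
    test_fraction: float = 0.2,
    doubled: bool = False,
    seed: int = 0,
    alpha_grid: np.ndarray | None = None,
    n_lambda: int = 20,
    cv_groups: int = 4,
) -> SaturationCurve:
    """Model-stability saturation curve.

    Per repetition: hold out a random test set (``test_fraction``); split the
    remaining samples into disjoint halves A and B; for each training size n
    train one clock on n samples of A and one on n samples of B (each with
    its own leave-one-group-out hyperparameter search) and record the Pearson
    correlation between the two models' predictions on the common test set.
    ``doubled=True`` first duplicates every sample (exact copies), the
    convention for estimating the stability attainable at larger effective
    sample size.
    """
    y = x.ages if ages is None else np.asarray(ages, dtype=float)
    if doubled:
        idx = list(range(x.n_samples)) * 2
        from .signal import SampleMeta

        samples = []
        for k, i in enumerate(idx):
            s = x.samples[i]
            samples.append(
                SampleMeta(f"{s.sample_id}__dup{k}", s.age, s.sex, s.batch,
                           s.tissue, s.mark, s.replicate_group, s.condition)
            )
        x = SignalMatrix(x.values[:, idx], x.peaks, samples, x.stage)
        y = np.concatenate([y, y])
    n_samples = x.n_samples
    n_test = max(2, int(round(test_fraction * n_samples)))
    half = (n_samples - n_test) // 2
    if n_grid is None:
        n_grid = np.unique(np.geomspace(10, half, 6).round().astype(int))
    n_grid = np.asarray(n_grid, dtype=int)
    if (np.diff(n_grid) <= 0).any():
        raise ValueError("n_grid must be strictly increasing")
    if n_grid.max() > half:
        raise ValueError(
            f"largest training size {n_grid.max()} exceeds available half-size {half}"
        )
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    rs = np.zeros((len(n_grid), n_reps))
    for rep in range(n_reps):
        perm = rng.permutation(n_samples)
        test = perm[:n_test]
        a_pool = perm[n_test : n_test + half]
        b_pool = perm[n_test + half : n_test + 2 * half]
        x_test = x.subset_samples(test)
        for i, n in enumerate(n_grid):
            preds = []
            for pool in (a_pool, b_pool):
                train = pool[:n]
                x_tr = x.subset_samples(train)
                model, _ = logo_cv_train(
                    x_tr, y[train],
                    groups=make_age_groups(y[train], n_groups=min(cv_groups, max(2, n // 3))),
                    alpha_grid=alpha_grid, n_lambda=n_lambda,
                )
                preds.append(predict_age(model, x_test))
            pa, pb = preds
            if np.ptp(pa) == 0 or np.ptp(pb) == 0:
                rs[i, rep] = 0.0
            else:
                rs[i, rep] = float(stats.pearsonr(pa, pb)[0])
    return SaturationCurve(
        n_grid=n_grid,
        r_mean=rs.mean(axis=1),
        r_sd=rs.std(axis=1, ddof=1) if n_reps > 1 else np.zeros(len(n_grid)),
        r_reps=rs,
        mode="estimated" if doubled else "observed",
        n_reps=n_reps,
        seed=seed,
    )
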