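"""Age-association screening: per-peak Spearman correlation with age,
Benjamini-Hochberg adjustment, the joint |rho|/p candidate filter, a PC1-age
summary, and Fisher exact annotation-enrichment tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .signal import SignalMatrix

__all__ = [
    "AgeAssociationTable",
    "spearman_screen",
    "bh_adjust",
    "candidate_filter",
    "pc1_age_correlation",
    "fisher_enrichment",
]

DEFAULT_R_MIN = 0.5
DEFAULT_P_MAX = 0.05


@dataclass
class AgeAssociationTable:
    """Per-peak Spearman age association with BH-adjusted p-values and the
    candidate flag (|rho| >= r_min and p <= p_max, inclusive)."""

    peak_ids: list[str]
    rho: np.ndarray
    p: np.ndarray
    p_adj: np.ndarray
    direction: np.ndarray  # "positive" / "negative" / "none"
    is_candidate: np.ndarray
    r_min: float | None = None
    p_max: float | None = None

    def to_dataframe(self) -> pd.DataFrame:
        coords = [pid.split(":") for pid in self.peak_ids]
        chrom = [c[0] for c in coords]
        spans = [c[1].split("-") for c in coords]
        return pd.DataFrame(
            {
                "chrom": chrom,
                "start": [int(s[0]) for s in spans],
                "end": [int(s[1]) for s in spans],
                "rho": self.rho,
                "p": self.p,
                "p_adj": self.p_adj,
                "direction": self.direction,
                "is_candidate": self.is_candidate,
            }
        )


def _spearman_rho_p(values: np.ndarray, ages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Spearman rho (mid-ranks) with two-sided t-approximation
    p-values on n-2 df; constant features get NaN."""
    n = values.shape[1]
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    age_ranks = stats.rankdata(ages)
    rx = ranks - ranks.mean(axis=1, keepdims=True)
    ry = age_ranks - age_ranks.mean()
    num = rx @ ry
    den = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = num / den
    rho[den == 0] = np.nan
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0  # |rho| == 1
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p[np.isnan(rho)] = np.nan
    return rho, p


def spearman_screen(
    x: SignalMatrix, ages: np.ndarray | None = None, exact: bool = False
) -> AgeAssociationTable:
    """Screen every peak for monotone association with age.

    ``exact=True`` computes permutation-exact p-values by full enumeration
    (only feasible for n <= 8; intended for validation at tiny n).
    """
    ages = x.ages if ages is None else np.asarray(ages, dtype=float)
    n = len(ages)
    if n < 4:
        raise ValueError(f"spearman_screen needs >= 4 samples, got {n}")
    if np.ptp(ages) == 0:
        raise ValueError("ages are all identical")
    rho, p = _spearman_rho_p(x.values, ages)
    if exact:
        if n > 8:
            raise ValueError("exact permutation p-values limited to n <= 8")
        from itertools import permutations

        age_ranks = stats.rankdata(ages)
        for g in range(x.n_peaks):
            if np.isnan(rho[g]):
                continue
            r_obs = abs(rho[g])
            row = x.values[g]
            count = total = 0
            for perm in permutations(age_ranks):
                r_perm, _ = stats.spearmanr(row, perm)
                total += 1
                if abs(r_perm) >= r_obs - 1e-12:
                    count += 1
            p[g] = count / total
    valid = ~np.isnan(p)
    p_adj = np.full_like(p, np.nan)
    if valid.any():
        p_adj[valid] = bh_adjust(p[valid])
    n_peaks = x.n_peaks
    return AgeAssociationTable(
        peak_ids=x.peak_ids,
        rho=rho,
        p=p,
        p_adj=p_adj,
        direction=np.array(["none"] * n_peaks, dtype=object),
        is_candidate=np.zeros(n_peaks, dtype=bool),
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, mapped back to input
    order: adj_(i) = min_{k >= i} p_(k) * m / k, capped at 1."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def candidate_filter(
    table: AgeAssociationTable,
    r_min: float = DEFAULT_R_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> AgeAssociationTable:
    """Joint effect-size and nominal-p filter (inclusive on both thresholds);
    direction is the sign of rho for candidates."""
    with np.errstate(invalid="ignore"):
        cand = (np.abs(table.rho) >= r_min) & (table.p <= p_max)
    cand = np.where(np.isnan(table.rho), False, cand).astype(bool)
    direction = np.array(
        [
            ("positive" if r > 0 else "negative") if c else "none"
            for r, c in zip(table.rho, cand)
        ],
        dtype=object,
    )
    return AgeAssociationTable(
        peak_ids=table.peak_ids,
        rho=table.rho,
        p=table.p,
        p_adj=table.p_adj,
        direction=direction,
        is_candidate=cand,
        r_min=r_min,
        p_max=p_max,
    )


def pc1_age_correlation(
    x: SignalMatrix, ages: np.ndarray | None = None
) -> tuple[np.ndarray, float, float]:
    """PC1 sample scores of the feature-centered matrix and their Pearson
    correlation with age.

    Sign convention: the PC1 loading vector is oriented so its
    largest-magnitude component is positive, which makes the reported signed
    r deterministic; its magnitude is what is interpretable.
    """
    ages = x.ages if ages is None else np.asarray(ages, dtype=float)
    if x.n_samples < 3:
        raise ValueError("pc1_age_correlation needs >= 3 samples")
    centered = x.values - x.values.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    loading = vt[0]
    flip = np.sign(loading[np.argmax(np.abs(loading))]) or 1.0
    scores = u[:, 0] * s[0] * flip
    if np.ptp(scores) == 0 or np.ptp(ages) == 0:
        return scores, float("nan"), float("nan")
    r, p = stats.pearsonr(scores, ages)
    return scores, float(r), float(p)


def fisher_enrichment(
    candidates_in: int, candidates_out: int, background_in: int, background_out: int
) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 table
    [[candidates_in, candidates_out], [background_in, background_out]].

    Two-sidedness uses the classical "probability mass <= observed" rule.
    Odds ratio is the cross-product ad/bc (NaN on a zero denominator).
    """
    a, b, c, d = candidates_in, candidates_out, background_in, background_out
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("both margins of the 2x2 table must be positive")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)
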