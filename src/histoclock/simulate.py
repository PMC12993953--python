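"""Synthetic age-structured ChIP-seq data with known ground truth.

The generator emits everything the pipeline consumes — a peak set on a toy
two-chromosome genome, a raw count (or infinite-depth density) matrix, a
sample sheet, and replicated per-age-group peak calls — from a latent
log2-density model:

    x[g, j] = b_g + effect_g(age_j) + sex + gamma[g, batch_j]
              + eps[g, j] * scale[batch_j]

with baseline b_g ~ N(3, 1), planted linear effects (slope spanning
``effect_size`` log2 units over the age range), planted nonlinear
effects (a logistic step at a breakpoint age), per-feature additive batch
shifts, batch-wise noise scaling, and i.i.d. Gaussian noise.  Counts are
Poisson with mean depth * 2^x * length_kb; ``exact_mode`` skips counting and
returns the latent densities directly.  An enhancer-cluster regime places
tight constituent clusters whose interior members lose signal with age,
fragmenting stitched domains.

Everything is a pure function of the config (including its seed); the same
config reproduces bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet
from .signal import SampleMeta, SignalMatrix

__all__ = ["SimulationConfig", "GroundTruth", "SimulationResult",
           "generate", "generate_paired_treatment"]

_CHROMS = ("chrS1", "chrS2")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the standard synthetic
    regime used throughout the test protocols."""

    n_peaks: int = 2000
    n_samples: int = 60
    age_range: tuple[float, float] = (5.0, 75.0)
    fraction_linear: float = 0.1
    fraction_nonlinear: float = 0.0
    breakpoint_ages: tuple[float, ...] = (40.0, 60.0)
    breakpoint_width: float = 3.0  # logistic step steepness, years
    # planted total log2 change across the full age range; 1.75 at the
    # default noise_sd of 0.5 puts the true Spearman correlation of a linear
    # peak near 0.7 under uniform ages
    effect_size: float = 1.75
    n_batches: int = 1
    batch_shift: float = 0.0  # additive log2 shift on batches >= 1
    batch_scale: float = 1.0  # noise-SD multiplier on batches >= 1
    noise_sd: float = 0.5
    sex_effect: float = 0.0
    replicate_groups: int = 3  # replicate peak calls per age group
    n_age_groups: int = 5
    sequencing_depth: float = 20.0  # expected reads per density unit per kb
    exact_mode: bool = False  # infinite depth: return densities directly
    peak_length: int = 1000
    peak_spacing: int = 50_000
    call_threshold: float = 0.5  # latent log2 density needed for a peak call
    call_jitter_sd: float = 0.5
    coord_jitter: int = 50  # bp jitter of replicate call boundaries
    # enhancer-cluster regime
    n_clusters: int = 0
    constituents_per_cluster: int = 8
    intra_cluster_spacing: int = 6000
    cluster_signal: float = 6.0  # baseline log2 density of constituents
    fragmentation_rate: float = 0.0  # log2 density lost per year (interior)
    n_pairs: int = 10  # (pre, post) pairs for the treatment generator
    target_ages: tuple[float, ...] | None = None  # histogram-matching mode
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_linear", "fraction_nonlinear"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fraction_linear + self.fraction_nonlinear > 1.0:
            raise ValueError("planted fractions must sum to <= 1")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be positive")
        if self.age_range[1] <= self.age_range[0]:
            raise ValueError("age_range must be increasing")


@dataclass
class GroundTruth:
    """Everything needed to score recovery without re-simulation."""

    labels: np.ndarray  # per peak: null / linear+ / linear- / nonlinear / cluster
    slopes: np.ndarray  # per peak, log2 units per year (0 where N/A)
    breakpoints: np.ndarray  # per peak, NaN where N/A
    batch_labels: list[str]  # per sample
    gamma: np.ndarray  # peaks x batches planted additive shifts
    noise_scale: np.ndarray  # per batch
    cluster_id: np.ndarray  # per peak, -1 outside clusters
    interior: np.ndarray  # per peak, True for interior cluster constituents
    decay_rate: np.ndarray  # per peak, log2/year signal loss
    latent_clean: np.ndarray  # peaks x samples, effects only (no noise/batch)
    latent: np.ndarray  # peaks x samples, full latent log2 densities

    @property
    def informative(self) -> np.ndarray:
        return np.isin(self.labels, ("linear+", "linear-", "nonlinear"))


@dataclass
class SimulationResult:
    config: SimulationConfig
    peaks: PeakSet
    matrix: SignalMatrix  # raw_counts, or density in exact mode
    samples: list[SampleMeta]
    truth: GroundTruth
    replicate_calls: list[tuple[str, PeakSet]]  # (age-group id, calls)
    group_ages: dict = field(default_factory=dict)  # group id -> median age

    def sample_sheet(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "age": [s.age for s in self.samples],
                "sex": [s.sex for s in self.samples],
                "batch": [s.batch for s in self.samples],
                "tissue": [s.tissue for s in self.samples],
                "mark": [s.mark for s in self.samples],
                "replicate_group": [s.replicate_group for s in self.samples],
                "condition": [s.condition for s in self.samples],
            }
        )

    def group_members(self, group: str) -> np.ndarray:
        gidx = int(group.split("_")[-1])
        edges = _group_edges(self.config)
        ages = np.array([s.age for s in self.samples])
        raw = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0, len(edges) - 2)
        return np.where(raw == gidx)[0]

    def group_signal_peaks(self, group: str) -> PeakSet:
        """Peaks whose group-mean clean latent signal clears the call
        threshold, scored by the group-mean linear-scale density — the
        per-age-group enhancer landscape used for stitching analyses."""
        members = self.group_members(group)
        if members.size == 0:
            return PeakSet([], label=group)
        mean_latent = self.truth.latent_clean[:, members].mean(axis=1)
        keep = mean_latent >= self.config.call_threshold
        ivs = [
            GenomicInterval(iv.chrom, iv.start, iv.end, iv.name, float(2.0 ** m))
            for iv, m, k in zip(self.peaks, mean_latent, keep)
            if k
        ]
        return PeakSet(ivs, label=group)


def _group_edges(cfg: SimulationConfig) -> np.ndarray:
    return np.linspace(cfg.age_range[0], cfg.age_range[1], cfg.n_age_groups + 1)


def _place_peaks(cfg: SimulationConfig) -> tuple[PeakSet, np.ndarray, np.ndarray, np.ndarray]:
    """Non-overlapping peak placement: background peaks spaced widely on two
    chromosomes, cluster constituents packed tightly at the start of chrS1."""
    n_cluster_peaks = cfg.n_clusters * cfg.constituents_per_cluster
    n_background = cfg.n_peaks - n_cluster_peaks
    if n_background < 0:
        raise ValueError("cluster peaks exceed n_peaks")
    ivs: list[GenomicInterval] = []
    cluster_id = np.full(cfg.n_peaks, -1, dtype=int)
    interior = np.zeros(cfg.n_peaks, dtype=bool)
    k = 0
    pos = 10_000
    for c in range(cfg.n_clusters):
        for j in range(cfg.constituents_per_cluster):
            ivs.append(GenomicInterval(_CHROMS[0], pos, pos + cfg.peak_length,
                                       name=f"peak_{k:05d}"))
            cluster_id[k] = c
            interior[k] = 0 < j < cfg.constituents_per_cluster - 1
            pos += cfg.peak_length + cfg.intra_cluster_spacing
            k += 1
        pos += 200_000  # isolate clusters from each other
    per_chrom = int(np.ceil(n_background / len(_CHROMS)))
    genome_len = per_chrom * cfg.peak_spacing + pos + cfg.peak_spacing
    if genome_len > 500_000_000:
        raise ValueError("infeasible placement: peaks x spacing exceed the toy genome")
    for i in range(n_background):
        chrom = _CHROMS[1] if i >= per_chrom else _CHROMS[0]
        offset = (i % per_chrom) * cfg.peak_spacing + (pos if chrom == _CHROMS[0] else 10_000)
        ivs.append(GenomicInterval(chrom, offset, offset + cfg.peak_length,
                                   name=f"peak_{k:05d}"))
        k += 1
    order = np.argsort([(iv.chrom, iv.start) for iv in ivs], axis=0)
    peaks = PeakSet(ivs)
    # map sorted order back to generation order via names
    name_to_gen = {iv.name: g for g, iv in enumerate(ivs)}
    gen_index = np.array([name_to_gen[iv.name] for iv in peaks])
    return peaks, cluster_id[gen_index], interior[gen_index], gen_index


def _draw_ages(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.target_ages is not None:
        target = np.asarray(cfg.target_ages, dtype=float)
        return np.sort(rng.choice(target, size=n, replace=True))
    return np.sort(rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n))


def _effects(cfg: SimulationConfig, truth_arrays, ages: np.ndarray) -> np.ndarray:
    """Clean latent matrix (baseline + planted effects; no batch, no noise)."""
    b, labels, slopes, breakpoints, decay = truth_arrays
    lo, hi = cfg.age_range
    mid = 0.5 * (lo + hi)
    width = hi - lo
    x = np.tile(b[:, None], (1, len(ages)))
    lin = np.isin(labels, ("linear+", "linear-"))
    x[lin] += slopes[lin][:, None] * (ages[None, :] - mid)
    nl = labels == "nonlinear"
    if nl.any():
        amp = cfg.effect_size
        signs = np.sign(slopes[nl])
        bp = breakpoints[nl]
        step = 1.0 / (1.0 + np.exp(-(ages[None, :] - bp[:, None]) / cfg.breakpoint_width))
        x[nl] += signs[:, None] * amp * (step - 0.5)
    cl = decay > 0
    if cl.any():
        x[cl] -= decay[cl][:, None] * (ages[None, :] - lo)
    return x


def _assign_truth(cfg: SimulationConfig, rng: np.random.Generator,
                  cluster_id: np.ndarray, interior: np.ndarray):
    n = cfg.n_peaks
    b = rng.normal(3.0, 1.0, size=n)
    labels = np.array(["null"] * n, dtype=object)
    slopes = np.zeros(n)
    breakpoints = np.full(n, np.nan)
    decay = np.zeros(n)
    is_cluster = cluster_id >= 0
    b[is_cluster] = cfg.cluster_signal
    labels[is_cluster] = "cluster"
    if cfg.fragmentation_rate > 0:
        idx = np.where(is_cluster & interior)[0]
        decay[idx] = cfg.fragmentation_rate * rng.uniform(0.5, 1.5, size=idx.size)
    free = np.where(~is_cluster)[0]
    rng.shuffle(free)
    n_lin = int(round(cfg.fraction_linear * n))
    n_nl = int(round(cfg.fraction_nonlinear * n))
    if n_lin + n_nl > free.size:
        raise ValueError("not enough non-cluster peaks for the planted fractions")
    lin_idx = free[:n_lin]
    nl_idx = free[n_lin : n_lin + n_nl]
    signs = rng.choice([-1.0, 1.0], size=n_lin)
    width = cfg.age_range[1] - cfg.age_range[0]
    slopes[lin_idx] = signs * cfg.effect_size / width
    labels[lin_idx] = np.where(signs > 0, "linear+", "linear-")
    if n_nl:
        nl_signs = rng.choice([-1.0, 1.0], size=n_nl)
        slopes[nl_idx] = nl_signs  # stores the sign for nonlinear peaks
        labels[nl_idx] = "nonlinear"
        breakpoints[nl_idx] = rng.choice(np.asarray(cfg.breakpoint_ages), size=n_nl)
    return b, labels, slopes, breakpoints, decay


def _build(cfg: SimulationConfig, ages: np.ndarray, sexes: list[str],
           conditions: list[str], replicate_group: list[str],
           effective_ages: np.ndarray, rng: np.random.Generator) -> SimulationResult:
    peaks, cluster_id, interior, _ = _place_peaks(cfg)
    truth_arrays = _assign_truth(cfg, rng, cluster_id, interior)
    b, labels, slopes, breakpoints, decay = truth_arrays

    n = len(ages)
    clean = _effects(cfg, truth_arrays, effective_ages)
    if cfg.sex_effect:
        female = np.array([s == "female" for s in sexes])
        clean = clean + cfg.sex_effect * female[None, :].astype(float)

    batch_labels = [f"batch{rng.integers(0, cfg.n_batches)}" for _ in range(n)]
    if cfg.n_batches > 1:
        # guarantee every batch has >= 2 members
        for bi in range(cfg.n_batches):
            need = 2 - sum(l == f"batch{bi}" for l in batch_labels)
            for _ in range(max(0, need)):
                batch_labels[int(rng.integers(0, n))] = f"batch{bi}"
    # per-feature batch shifts of magnitude ~batch_shift with random sign:
    # sign symmetry keeps the per-sample median near 0, so median centering
    # in the log2 background step preserves the full nominal shift magnitude
    # (a feature-uniform shift would be annihilated there)
    gamma = np.zeros((cfg.n_peaks, cfg.n_batches))
    for bi in range(1, cfg.n_batches):
        signs = rng.choice([-1.0, 1.0], size=cfg.n_peaks)
        gamma[:, bi] = signs * rng.normal(
            cfg.batch_shift, 0.25 * abs(cfg.batch_shift), size=cfg.n_peaks
        )
    noise_scale = np.ones(cfg.n_batches)
    noise_scale[1:] = cfg.batch_scale
    bidx = np.array([int(l[5:]) for l in batch_labels])
    eps = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_peaks, n))
    latent = clean + gamma[:, bidx] + eps * noise_scale[bidx][None, :]

    dens = 2.0**latent
    lengths_kb = np.array([iv.length for iv in peaks]) / 1000.0
    if cfg.exact_mode:
        values, stage = dens, "density"
    else:
        lam = cfg.sequencing_depth * dens * lengths_kb[:, None]
        values = rng.poisson(lam).astype(float)
        stage = "raw_counts"

    samples = [
        SampleMeta(
            sample_id=f"s{j:03d}", age=float(ages[j]), sex=sexes[j],
            batch=batch_labels[j], tissue="simulated", mark="H3K27ac",
            replicate_group=replicate_group[j], condition=conditions[j],
        )
        for j in range(n)
    ]
    matrix = SignalMatrix(values, peaks, samples, stage)

    # replicated per-age-group peak calls
    edges = _group_edges(cfg)
    raw_groups = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0,
                         cfg.n_age_groups - 1)
    replicate_calls: list[tuple[str, PeakSet]] = []
    group_ages: dict[str, float] = {}
    for gi in range(cfg.n_age_groups):
        members = np.where(raw_groups == gi)[0]
        if members.size == 0:
            continue
        gname = f"agegroup_{gi}"
        group_ages[gname] = float(np.median(ages[members]))
        mean_latent = clean[:, members].mean(axis=1)
        for r in range(cfg.replicate_groups):
            observed = mean_latent + rng.normal(0.0, cfg.call_jitter_sd,
                                                size=cfg.n_peaks)
            called = observed >= cfg.call_threshold
            ivs = []
            for g in np.where(called)[0]:
                iv = peaks[g]
                js = int(rng.integers(-cfg.coord_jitter, cfg.coord_jitter + 1))
                je = int(rng.integers(-cfg.coord_jitter, cfg.coord_jitter + 1))
                start = max(0, iv.start + js)
                end = max(start + 1, iv.end + je)
                ivs.append(GenomicInterval(iv.chrom, start, end, iv.name,
                                           float(observed[g])))
            replicate_calls.append((gname, PeakSet(ivs, label=f"{gname}_rep{r}")))

    truth = GroundTruth(
        labels=labels, slopes=slopes, breakpoints=breakpoints,
        batch_labels=batch_labels, gamma=gamma, noise_scale=noise_scale,
        cluster_id=cluster_id, interior=interior, decay_rate=decay,
        latent_clean=clean, latent=latent,
    )
    return SimulationResult(
        config=cfg, peaks=peaks, matrix=matrix, samples=samples, truth=truth,
        replicate_calls=replicate_calls, group_ages=group_ages,
    )


def generate(config: SimulationConfig) -> SimulationResult:
    """Generate one synthetic dataset; same config (incl. seed) gives
    bit-identical outputs."""
    rng = np.random.default_rng(config.seed)
    ages = _draw_ages(config, config.n_samples, rng)
    sexes = ["female" if j % 2 else "male" for j in range(config.n_samples)]
    conditions = ["healthy"] * config.n_samples
    rep_groups = [""] * config.n_samples
    return _build(config, ages, sexes, conditions, rep_groups, ages, rng)


def generate_paired_treatment(
    config: SimulationConfig, rejuvenation_factor: float
) -> SimulationResult:
    """Healthy training samples plus (pre, post) treatment pairs in which the
    post sample's signal follows an attenuated effective age =
    rejuvenation_factor x chronological age (clamped to the minimum age, with
    a warning, when the factor drives it below the modeled range)."""
    if not 0.0 <= rejuvenation_factor <= 1.0:
        raise ValueError("rejuvenation_factor must be in (0, 1]; 0 clamps")
    rng = np.random.default_rng(config.seed)
    n_healthy = config.n_samples
    ages_h = _draw_ages(config, n_healthy, rng)
    pair_ages = rng.uniform(
        0.5 * (config.age_range[0] + config.age_range[1]),
        config.age_range[1], size=config.n_pairs,
    )
    eff_post = rejuvenation_factor * pair_ages
    lo = config.age_range[0]
    if (eff_post < lo).any():
        warnings.warn("effective post-treatment ages clamped to the minimum age")
        eff_post = np.maximum(eff_post, lo)
    ages = np.concatenate([ages_h, pair_ages, pair_ages])
    effective = np.concatenate([ages_h, pair_ages, eff_post])
    n_total = n_healthy + 2 * config.n_pairs
    sexes = ["female" if j % 2 else "male" for j in range(n_total)]
    conditions = (
        ["healthy"] * n_healthy
        + ["pre_treatment"] * config.n_pairs
        + ["post_treatment"] * config.n_pairs
    )
    rep_groups = (
        [""] * n_healthy
        + [f"pair{i:02d}" for i in range(config.n_pairs)] * 2
    )
    cfg = replace(config, n_samples=n_total)
    return _build(cfg, ages, sexes, conditions, rep_groups, effective, rng)
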