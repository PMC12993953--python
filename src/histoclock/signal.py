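"""Per-peak signal quantification: counts -> densities -> log2 background-
subtracted signal -> standardized features.

The density of peak *g* in sample *j* is the raw count divided by the peak
length in kilobases and by that sample's reads-in-peaks total in millions
(RPKM-style, with reads-in-peaks as the library size).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet

__all__ = [
    "SampleMeta",
    "SignalMatrix",
    "read_sample_sheet",
    "read_count_matrix",
    "write_matrix",
    "quantify_density",
    "log2_background_subtract",
    "standardize_features",
]

STAGES = ("raw_counts", "density", "log2bg", "standardized", "batch_corrected")

_SEXES = {"male", "female", "unknown"}
_CONDITIONS = {"healthy", "disease", "pre_treatment", "post_treatment"}


@dataclass
class SampleMeta:
    """Metadata for one ChIP-seq sample (one column of the signal matrix)."""

    sample_id: str
    age: float
    sex: str = "unknown"
    batch: str = "batch0"
    tissue: str = "tissue"
    mark: str = "mark"
    replicate_group: str = ""
    condition: str = "healthy"

    def __post_init__(self) -> None:
        if not np.isfinite(self.age):
            raise ValueError(f"sample {self.sample_id}: age must be finite")
        if self.sex not in _SEXES:
            raise ValueError(f"sample {self.sample_id}: sex must be one of {_SEXES}")
        if self.condition not in _CONDITIONS:
            raise ValueError(
                f"sample {self.sample_id}: condition must be one of {_CONDITIONS}"
            )


@dataclass
class SignalMatrix:
    """A peaks x samples matrix bound to peak coordinates and sample metadata.

    ``stage`` tags the processing state; raw counts must be non-negative and
    all later stages must be finite everywhere.
    """

    values: np.ndarray
    peaks: PeakSet
    samples: list[SampleMeta]
    stage: str = "raw_counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D peaks x samples array")
        if self.values.shape[0] != len(self.peaks):
            raise ValueError(
                f"row count {self.values.shape[0]} != number of peaks {len(self.peaks)}"
            )
        if self.values.shape[1] != len(self.samples):
            raise ValueError(
                f"column count {self.values.shape[1]} != number of samples {len(self.samples)}"
            )
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        if self.stage == "raw_counts":
            if (self.values < 0).any():
                raise ValueError("raw counts must be non-negative")
        elif not np.isfinite(self.values).all():
            raise ValueError(f"stage {self.stage}: all values must be finite")

    @property
    def n_peaks(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.samples], dtype=float)

    @property
    def peak_ids(self) -> list[str]:
        return self.peaks.peak_ids()

    def with_values(self, values: np.ndarray, stage: str) -> "SignalMatrix":
        return SignalMatrix(values, self.peaks, self.samples, stage)

    def subset_samples(self, idx: Sequence[int]) -> "SignalMatrix":
        idx = list(idx)
        return SignalMatrix(
            self.values[:, idx], self.peaks, [self.samples[i] for i in idx], self.stage
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.sample_ids)
        df.insert(0, "chrom", [iv.chrom for iv in self.peaks])
        df.insert(1, "start", [iv.start for iv in self.peaks])
        df.insert(2, "end", [iv.end for iv in self.peaks])
        return df


def read_sample_sheet(path) -> list[SampleMeta]:
    """Read a TSV/CSV sample sheet with the SampleMeta columns.

    Required columns: sample_id, age.  Missing optional columns take their
    defaults.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    for col in ("sample_id", "age"):
        if col not in df.columns:
            raise ValueError(f"sample sheet missing required column {col!r}")
    metas = []
    for _, row in df.iterrows():
        kwargs = {"sample_id": str(row["sample_id"]), "age": float(row["age"])}
        for col in ("sex", "batch", "tissue", "mark", "replicate_group", "condition"):
            if col in df.columns and not pd.isna(row[col]):
                kwargs[col] = str(row[col])
        metas.append(SampleMeta(**kwargs))
    return metas


def read_count_matrix(path, samples: list[SampleMeta], stage: str = "raw_counts") -> SignalMatrix:
    """Read a TSV whose first three columns are chrom/start/end and whose
    remaining header names are sample ids (any order; reordered to match
    ``samples``)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:3]) != ["chrom", "start", "end"]:
        raise ValueError("count matrix must start with chrom/start/end columns")
    ids = [s.sample_id for s in samples]
    missing = [i for i in ids if i not in df.columns]
    if missing:
        raise ValueError(f"count matrix missing sample columns: {missing}")
    df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    peaks = PeakSet(
        [
            GenomicInterval(str(c), int(s), int(e))
            for c, s, e in zip(df["chrom"], df["start"], df["end"])
        ]
    )
    return SignalMatrix(df[ids].to_numpy(dtype=float), peaks, list(samples), stage)


def write_matrix(matrix: SignalMatrix, path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")


def quantify_density(counts: SignalMatrix) -> SignalMatrix:
    """Raw counts -> read densities.

    d[g, j] = c[g, j] / (L_g / 1000) / (R_j / 1e6) with R_j the sample's total
    reads in peaks.  Scale-invariant per sample: multiplying one column of
    counts by k leaves its densities unchanged.
    """
    if counts.stage != "raw_counts":
        raise ValueError(f"expected stage raw_counts, got {counts.stage}")
    lengths_kb = np.array([iv.length for iv in counts.peaks], dtype=float) / 1000.0
    if (lengths_kb <= 0).any():
        raise ValueError("every peak length must be positive")
    rip = counts.values.sum(axis=0)  # reads in peaks per sample
    zero = np.where(rip == 0)[0]
    if zero.size:
        bad = [counts.samples[j].sample_id for j in zero]
        raise ValueError(f"samples with zero reads-in-peaks: {bad}")
    dens = counts.values / lengths_kb[:, None] / (rip[None, :] / 1e6)
    return counts.with_values(dens, "density")


def log2_background_subtract(
    density: SignalMatrix,
    input_density: SignalMatrix | None = None,
    pseudocount: float = 1.0,
) -> SignalMatrix:
    """log2-transform densities and subtract background.

    With a matched input-control density matrix the background is subtracted
    per cell on the log2 scale (log2 IP/input ratio); without one, each
    sample's column median of the log2 signal is subtracted, so every column
    median is exactly 0.
    """
    if density.stage != "density":
        raise ValueError(f"expected stage density, got {density.stage}")
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    x = np.log2(density.values + pseudocount)
    if input_density is not None:
        if input_density.values.shape != density.values.shape:
            raise ValueError("input_density must be aligned to the same peaks/samples")
        x = x - np.log2(input_density.values + pseudocount)
    else:
        x = x - np.median(x, axis=0, keepdims=True)
    return density.with_values(x, "log2bg")


def standardize_features(
    x: SignalMatrix, fit_columns: Sequence[int] | None = None
) -> tuple[SignalMatrix, np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature z-scoring with parameters estimated on ``fit_columns`` only.

    Returns ``(standardized matrix, mean, sd, constant_flags)``.  The sd uses
    the unbiased (n-1) denominator.  Features constant on the fit columns are
    mapped to 0 everywhere and flagged.  Estimating on training folds only is
    what prevents leakage in cross-validation.
    """
    if fit_columns is None:
        fit_columns = list(range(x.n_samples))
    fit_columns = list(fit_columns)
    if not fit_columns:
        raise ValueError("fit_columns must be nonempty")
    sub = x.values[:, fit_columns]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1) if len(fit_columns) > 1 else np.zeros(x.n_peaks)
    constant = sd == 0
    safe_sd = np.where(constant, 1.0, sd)
    z = (x.values - mean[:, None]) / safe_sd[:, None]
    z[constant, :] = 0.0
    return x.with_values(z, "standardized"), mean, sd, constant
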