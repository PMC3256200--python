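"""Descriptive density statistics of features along a chromosome.

Counts features in non-overlapping 1 Mb windows (by 5' start) and summarizes
the per-window counts by mean, standard deviation (n-1 denominator) and the
sample skewness g1 = m3 / m2^(3/2). Also provides the per-Mb-assayed density
and Spearman rank correlations between chromosome-level summaries.

A reference summary table of Takai-Jones CpG-island densities on the GRCh37
human assembly (22 autosomes + X and Y) ships with the package for worked
examples and regression tests; see :func:`load_grch37_summary`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome_io import FeatureSet, MaskSet

__all__ = [
    "ChromosomeStats",
    "window_counts",
    "density_summary",
    "assayed_density",
    "spearman_rho",
    "chromosome_stats",
    "load_grch37_summary",
]

MB = 1_000_000


@dataclass(frozen=True)
class ChromosomeStats:
    """One summary row: chromosome-level density statistics (lengths in Mb)."""

    chrom: str
    total_length: float
    missing: float
    n_features: int
    density_assayed: float
    mean_density: float
    sd_density: float
    skew_density: float


def window_counts(features: FeatureSet, window: int = MB,
                  drop_partial: bool = False) -> np.ndarray:
    """Feature counts per non-overlapping window, assigned by 5' start.

    The trailing partial window (when the chromosome length is not a multiple
    of ``window``) is kept and counted as a full window unless
    ``drop_partial``. Counts always sum to N (minus features in a dropped
    partial window).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    k = math.ceil(features.chrom_length / window)
    counts = np.bincount(features.starts // window, minlength=k).astype(np.int64) \
        if len(features) else np.zeros(k, dtype=np.int64)
    if drop_partial and features.chrom_length % window:
        counts = counts[:-1]
    return counts


def density_summary(counts: np.ndarray) -> tuple[float, float, float]:
    """Mean, sample SD (n-1) and sample skewness g1 of per-window counts.

    Skewness is NaN when the counts are constant (zero variance).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 3:
        raise ValueError("need at least 3 windows for skewness")
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1))
    skew = float(sps.skew(counts, bias=True)) if sd > 0 else float("nan")
    return mean, sd, skew


def assayed_density(n_features: int, total_length: float, missing: float) -> float:
    """Features per Mb of assayed sequence: N / (total - missing), lengths in Mb."""
    if missing >= total_length:
        raise ValueError("missing length must be smaller than total length")
    return n_features / (total_length - missing)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns (rho, two-sided p) via the t approximation; rho is NaN when
    either argument has zero rank variance.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan"), float("nan")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def chromosome_stats(features: FeatureSet, mask: MaskSet | None = None,
                     window: int = MB) -> ChromosomeStats:
    """Full summary row for one chromosome (lengths reported in Mb)."""
    total_mb = features.chrom_length / MB
    missing_mb = (mask.total_length / MB) if mask is not None else 0.0
    mean, sd, skew = density_summary(window_counts(features, window))
    return ChromosomeStats(
        chrom=features.chrom,
        total_length=total_mb,
        missing=missing_mb,
        n_features=features.n,
        density_assayed=assayed_density(features.n, total_mb, missing_mb),
        mean_density=mean,
        sd_density=sd,
        skew_density=skew,
    )


def load_grch37_summary() -> pd.DataFrame:
    """Packaged per-chromosome CpG-island density summary for GRCh37."""
    ref = resources.files("chromocorr").joinpath("data/grch37_cgi_summary.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"chrom": str})
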