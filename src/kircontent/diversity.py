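"""Genotype-diversity statistics on presence/absence panels.

Two resampling procedures support the human-vs-chimpanzee comparison of
gene-content diversity:

* rarefaction of the distinct-genotype count to a common sample size
  (default n = 26, the size of the unrelated chimpanzee subset), with
  mean, SD and a percentile 95% CI over replicates;
* a column bootstrap of the mean pairwise gene-content difference, where
  each locus is treated as a single biallelic marker and loci columns are
  resampled with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import GenotypePanel

__all__ = [
    "ResampleSummary",
    "PairwiseDiffSummary",
    "count_distinct_genotypes",
    "resample_genotype_count",
    "bootstrap_pairwise_difference",
]


@dataclass(frozen=True)
class ResampleSummary:
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    reps: int
    n: int

    def __post_init__(self):
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError("CI does not bracket the mean")
        if self.sd < 0:
            raise ValueError("negative sd")


@dataclass(frozen=True)
class PairwiseDiffSummary:
    mean: float  # in loci units
    se: float
    reps: int

    def __post_init__(self):
        if self.mean < 0 or self.se < 0:
            raise ValueError("mean and se must be nonnegative")


def _distinct_count(matrix: np.ndarray) -> int:
    return len({row.tobytes() for row in np.ascontiguousarray(matrix)})


def count_distinct_genotypes(panel: GenotypePanel, unrelated_only: bool = False) -> int:
    """Number of unique presence/absence vectors among selected individuals."""
    matrix = panel.select(unrelated_only)
    if matrix.shape[0] == 0:
        raise ValueError("empty panel")
    return _distinct_count(matrix)


def resample_genotype_count(
    panel: GenotypePanel,
    n: int = 26,
    reps: int = 5000,
    seed: int = 0,
    unrelated_only: bool = False,
    with_replacement: bool = False,
) -> ResampleSummary:
    """Rarefy the distinct-genotype count to sample size ``n``.

    Each replicate draws ``n`` individuals without replacement (rarefaction;
    a with-replacement bootstrap is available behind ``with_replacement``)
    and counts distinct genotypes. The summary gives the replicate mean, SD
    and percentile (2.5-97.5) 95% CI. ``n`` may not exceed the panel —
    rarefaction only, never extrapolation.
    """
    matrix = panel.select(unrelated_only)
    size = matrix.shape[0]
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > size:
        raise ValueError(f"n={n} exceeds the {size}-individual panel (rarefaction only)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.empty(reps, dtype=int)
    for r in range(reps):
        idx = rng.choice(size, size=n, replace=with_replacement)
        counts[r] = _distinct_count(matrix[idx])
    lo, hi = np.percentile(counts, [2.5, 97.5])
    return ResampleSummary(
        mean=float(counts.mean()),
        sd=float(counts.std(ddof=1)) if reps > 1 else 0.0,
        ci_low=float(lo),
        ci_high=float(hi),
        reps=reps,
        n=n,
    )


def _mean_pairwise_hamming(matrix: np.ndarray) -> float:
    """Mean Hamming distance over all unordered distinct pairs of rows."""
    n = matrix.shape[0]
    x = matrix.astype(np.int64)
    # sum over pairs of |xi - xj| per column: for a 0/1 column with k ones,
    # pairs differing = k (n - k)
    k = x.sum(axis=0)
    diff_pairs = (k * (n - k)).sum()
    return float(diff_pairs) / (n * (n - 1) / 2)


def bootstrap_pairwise_difference(
    panel: GenotypePanel,
    reps: int = 10000,
    seed: int = 0,
    unrelated_only: bool = False,
) -> PairwiseDiffSummary:
    """Mean pairwise gene-content difference with a column bootstrap SE.

    The point estimate is the mean Hamming distance (in loci units) over
    all unordered pairs of individuals on the original loci. Each locus is
    treated as one biallelic marker: replicates resample loci columns with
    replacement and recompute the mean pairwise distance; the SE is the SD
    of the replicate means.
    """
    matrix = panel.select(unrelated_only)
    n, n_loci = matrix.shape
    if n < 2:
        raise ValueError("pairwise difference needs at least 2 individuals")
    if reps < 2:
        raise ValueError("reps must be >= 2")
    point = _mean_pairwise_hamming(matrix)
    rng = np.random.default_rng(seed)
    means = np.empty(reps)
    for r in range(reps):
        cols = rng.integers(0, n_loci, size=n_loci)
        means[r] = _mean_pairwise_hamming(matrix[:, cols])
    return PairwiseDiffSummary(mean=point, se=float(means.std(ddof=1)), reps=reps)
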