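"""Cross-model comparison of tRNAomes and codon occupancies.

Pairwise per-codon occupancy differences with Tukey-fence outliers, a
recurrence tally of which codons are extreme in many model pairs, Pearson
correlation of isoacceptor fractions, and per-codon dispersion across
models.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .codon_abundance import TRNAFractions
from .ribotempo import OccupancyVector

__all__ = [
    "PairwiseCodonDiff",
    "RecurrenceTable",
    "pairwise_codon_diff",
    "all_pairwise_diffs",
    "recurrence",
    "fraction_correlation",
    "per_codon_sd",
]


@dataclass(frozen=True)
class PairwiseCodonDiff:
    """Signed occupancy differences for one model pair, with outlier codons."""

    model_a: str
    model_b: str
    diff: dict[str, float]
    outliers: frozenset[str]
    fences: tuple[float, float]


@dataclass(frozen=True)
class RecurrenceTable:
    """How many model pairs flagged each codon as an outlier."""

    counts: dict[str, int]
    n_pairs: int

    def recurrent(self, threshold: int = 10) -> list[str]:
        """Codons flagged in more than ``threshold`` pairs, sorted by count."""
        hits = [(c, n) for c, n in self.counts.items() if n > threshold]
        return [c for c, _ in sorted(hits, key=lambda x: (-x[1], x[0]))]


def pairwise_codon_diff(
    a: OccupancyVector,
    b: OccupancyVector,
    fence_factor: float = 1.5,
) -> PairwiseCodonDiff:
    """occupancy(a) - occupancy(b) per codon, outliers by Tukey fences.

    A codon is an outlier when its difference lies strictly outside
    [Q1 - k*IQR, Q3 + k*IQR] of this pair's difference distribution
    (k = ``fence_factor``, the boxplot convention). The fences are symmetric
    in the pair up to sign, so the outlier set is swap-invariant.
    """
    if set(a.occupancy) != set(b.occupancy):
        raise ValueError("occupancy vectors cover different codon sets")
    diff = {c: a.occupancy[c] - b.occupancy[c] for c in a.occupancy}
    vals = np.array(list(diff.values()))
    q1, q3 = np.percentile(vals, [25.0, 75.0], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - fence_factor * iqr, q3 + fence_factor * iqr
    outliers = frozenset(c for c, d in diff.items() if d < lo or d > hi)
    return PairwiseCodonDiff(
        model_a=a.model_id,
        model_b=b.model_id,
        diff=diff,
        outliers=outliers,
        fences=(float(lo), float(hi)),
    )


def all_pairwise_diffs(
    occupancies: list[OccupancyVector], fence_factor: float = 1.5
) -> list[PairwiseCodonDiff]:
    """All unordered model pairs, in input order."""
    return [
        pairwise_codon_diff(a, b, fence_factor=fence_factor)
        for a, b in combinations(occupancies, 2)
    ]


def recurrence(all_pairs: list[PairwiseCodonDiff]) -> RecurrenceTable:
    """Tally, per codon, the number of pairs in which it was an outlier."""
    if not all_pairs:
        raise ValueError("need at least one model pair")
    codons = set(all_pairs[0].diff)
    counts = {c: sum(1 for p in all_pairs if c in p.outliers) for c in sorted(codons)}
    return RecurrenceTable(counts=counts, n_pairs=len(all_pairs))


def fraction_correlation(models: list[TRNAFractions]) -> tuple[list[str], np.ndarray]:
    """Pairwise Pearson r of isoacceptor (probe-level) fraction vectors.

    Returns (model ids, symmetric correlation matrix with unit diagonal).
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    probe_ids = sorted(models[0].fractions)
    for m in models[1:]:
        if sorted(m.fractions) != probe_ids:
            raise ValueError("models cover different probe sets")
    mat = np.array([[m.fractions[p] for p in probe_ids] for m in models])
    if np.any(np.std(mat, axis=1) == 0):
        raise ValueError("zero-variance fraction vector")
    r = np.corrcoef(mat)
    # exact symmetry and unit diagonal, free of rounding fuzz
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return [m.model_id for m in models], r


def per_codon_sd(models: list[OccupancyVector]) -> dict[str, float]:
    """Sample standard deviation (n-1) of occupancy across models, per codon."""
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    codons = set(models[0].occupancy)
    for m in models[1:]:
        if set(m.occupancy) != codons:
            raise ValueError("occupancy vectors cover different codon sets")
    return {
        c: float(np.std([m.occupancy[c] for m in models], ddof=1)) for c in sorted(codons)
    }
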