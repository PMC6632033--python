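"""Codon-resolved translation-velocity profiles.

The elongation rate at a codon is taken proportional to the cellular
concentration of its cognate tRNA, so ribosome occupancy (relative dwell
time) is the reciprocal of the codon's tRNA fraction. The velocity profile
along a coding sequence smooths single-codon fractions with their harmonic
mean inside a sliding window the size of the mRNA stretch covered by a
translating ribosome (30 codons by default): time across a window adds, so
the window speed is window length over summed dwell times.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .codon_abundance import CodonFractions
from .genetic_code import CODON_TO_AA, STOP_CODONS, to_rna

__all__ = [
    "CodingSequence",
    "OccupancyVector",
    "VelocityProfile",
    "occupancy",
    "velocity_profile",
    "percentile_band",
    "slow_fast_regions",
    "plot_profile",
]

DEFAULT_WINDOW = 30


@dataclass(frozen=True)
class CodingSequence:
    """An ORF as an ordered list of sense codons (stop removed).

    Codon index 1 is the initiator AUG. ``annotations`` are optional named
    domain intervals (name, start_codon, end_codon), 1-based inclusive, used
    only for plotting.
    """

    transcript_id: str
    codons: tuple[str, ...]
    annotations: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        codons = tuple(to_rna(c) for c in self.codons)
        for i, c in enumerate(codons, start=1):
            if c in STOP_CODONS:
                raise ValueError(f"internal stop codon {c} at codon {i}")
            if c not in CODON_TO_AA:
                raise ValueError(f"invalid codon {c!r} at codon {i}")
        object.__setattr__(self, "codons", codons)

    def __len__(self) -> int:
        return len(self.codons)

    @property
    def nucleotides(self) -> str:
        return "".join(self.codons)

    @classmethod
    def from_nucleotides(
        cls,
        transcript_id: str,
        seq: str,
        annotations: tuple[tuple[str, int, int], ...] = (),
    ) -> "CodingSequence":
        """Build from a CDS string (RNA or DNA); a trailing stop is trimmed."""
        seq = re.sub(r"\s", "", to_rna(seq))
        if len(seq) % 3:
            raise ValueError("CDS length is not a multiple of 3")
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        return cls(transcript_id=transcript_id, codons=tuple(codons), annotations=annotations)

    def substitute(self, codon_index: int, codon: str) -> "CodingSequence":
        """Copy with the codon at 1-based ``codon_index`` replaced."""
        if not 1 <= codon_index <= len(self.codons):
            raise IndexError(f"codon index {codon_index} out of range")
        codons = list(self.codons)
        codons[codon_index - 1] = to_rna(codon)
        return CodingSequence(self.transcript_id, tuple(codons), self.annotations)


@dataclass(frozen=True)
class OccupancyVector:
    """Relative ribosome dwell time per codon: 1 / tRNA fraction."""

    model_id: str
    occupancy: dict[str, float]

    def __getitem__(self, codon: str) -> float:
        return self.occupancy[codon]


@dataclass(frozen=True)
class VelocityProfile:
    """Windowed relative translation speed along one CDS.

    ``values[k]`` is the harmonic mean of the per-codon fractions in the
    full window centered at codon ``centers[k]`` (1-based). Truncated edge
    windows are not reported. ``band`` is the (10th, 90th) percentile of the
    values unless other percentiles were requested.
    """

    transcript_id: str
    model_id: str
    window: int
    centers: np.ndarray
    values: np.ndarray
    band: tuple[float, float]
    band_percentiles: tuple[float, float] = (10.0, 90.0)

    def __len__(self) -> int:
        return len(self.values)


def _fraction_map(codon_fractions) -> tuple[dict[str, float], str]:
    """Accept a CodonFractions or any plain codon -> fraction mapping."""
    if isinstance(codon_fractions, CodonFractions):
        return codon_fractions.per_codon, codon_fractions.model_id
    return dict(codon_fractions), ""


def occupancy(codon_fractions) -> OccupancyVector:
    """Ribosome occupancy as the reciprocal of each codon's tRNA fraction."""
    per_codon, model_id = _fraction_map(codon_fractions)
    occ = {}
    for codon, f in per_codon.items():
        if f <= 0:
            raise ValueError(f"non-positive fraction for codon {codon}")
        occ[codon] = 1.0 / f
    return OccupancyVector(model_id=model_id, occupancy=occ)


def velocity_profile(
    seq: CodingSequence,
    codon_fractions,
    window: int = DEFAULT_WINDOW,
    band_percentiles: tuple[float, float] = (10.0, 90.0),
) -> VelocityProfile:
    """Harmonic-mean sliding-window speed profile.

    For each full window of ``window`` consecutive codons the value is
    window / sum of per-codon occupancies (the harmonic mean of the codon
    fractions), assigned to the window's center codon (start + window // 2).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    per_codon, model_id = _fraction_map(codon_fractions)
    n = len(seq)
    if n < window:
        raise ValueError(f"sequence of {n} codons is shorter than window {window}")
    unknown = sorted({c for c in seq.codons if c not in per_codon})
    if unknown:
        raise ValueError(f"codons missing from fractions: {unknown}")
    frac = np.array([per_codon[c] for c in seq.codons], dtype=float)
    if np.any(frac <= 0):
        raise ValueError("non-positive codon fraction in sequence")
    occ = 1.0 / frac
    # each window summed independently (not via a running cumsum), so a codon
    # change provably cannot perturb windows that do not contain it
    window_occ = np.convolve(occ, np.ones(window), mode="valid")
    values = window / window_occ
    starts = np.arange(1, n - window + 2)
    centers = starts + window // 2
    band = percentile_band(values, *band_percentiles)
    return VelocityProfile(
        transcript_id=seq.transcript_id,
        model_id=model_id,
        window=window,
        centers=centers,
        values=values,
        band=band,
        band_percentiles=band_percentiles,
    )


def percentile_band(values, lo: float = 10.0, hi: float = 90.0) -> tuple[float, float]:
    """(lo-th, hi-th) percentile with linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty value vector")
    p_lo, p_hi = np.percentile(values, [lo, hi], method="linear")
    return float(p_lo), float(p_hi)


def slow_fast_regions(profile: VelocityProfile) -> list[tuple[int, int, str]]:
    """Maximal runs of window centers below P10 (slow) or above P90 (fast).

    Returned as sorted, non-overlapping (start_codon, end_codon, class)
    intervals, 1-based inclusive, in center-codon coordinates.
    """
    p_lo, p_hi = profile.band
    labels = np.where(
        profile.values < p_lo, "slow", np.where(profile.values > p_hi, "fast", "")
    )
    regions: list[tuple[int, int, str]] = []
    run_start = None
    run_label = ""
    prev_center = None
    for center, label in zip(profile.centers, labels):
        contiguous = prev_center is not None and center == prev_center + 1
        if label != run_label or not contiguous:
            if run_label:
                regions.append((run_start, prev_center, run_label))
            run_start, run_label = (int(center), label) if label else (None, "")
        prev_center = int(center)
    if run_label:
        regions.append((run_start, prev_center, run_label))
    return regions


def plot_profile(profile: VelocityProfile, seq: CodingSequence | None = None, path=None):
    """Profile line with the percentile band; optional domain bars on top."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(profile.centers, profile.values, lw=0.8, color="black")
    ax.axhspan(profile.band[0], profile.band[1], color="0.85", zorder=0)
    ax.set_xlabel("codon")
    ax.set_ylabel("relative speed")
    title = f"{profile.transcript_id} / {profile.model_id} (window {profile.window})"
    ax.set_title(title, fontsize=9)
    if seq is not None and seq.annotations:
        y = ax.get_ylim()[1]
        for name, start, end in seq.annotations:
            ax.hlines(y, start, end, lw=4)
            ax.text((start + end) / 2, y, name, ha="center", va="bottom", fontsize=6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
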