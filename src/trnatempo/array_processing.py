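"""Comparative tRNA-microarray signal processing.

Two tRNA pools (sample and reference) are hybridized on one chip and read
out in two fluorescence channels; in-vitro transcribed spike-in tRNAs added
to both pools at equal amounts anchor the channel ratio at 1. This module
turns raw per-spot two-channel intensities into spike-normalized per-probe
ratios and provides replicate QC: per-probe coefficient of variation and a
two-sample Kolmogorov–Smirnov similarity test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import median

from scipy import stats

__all__ = [
    "Probe",
    "ProbePanel",
    "ArrayExperiment",
    "NormalizedRatios",
    "median_ratio",
    "normalize_to_spikes",
    "process_experiment",
    "replicate_cv",
    "ks_similarity",
    "select_representative",
]


@dataclass(frozen=True)
class Probe:
    """One tDNA probe on the array.

    A probe reports one isoacceptor, or one ambiguity group of isoacceptors
    whose sequences differ by fewer than 8 nt and cannot be resolved.
    """

    probe_id: str
    anticodons: tuple[str, ...] = ()
    amino_acid: str = ""  # one-letter code, or "Meti" for initiator Met
    decoded_codons: tuple[str, ...] = ()
    ambiguity_group: str | None = None
    is_spike: bool = False


@dataclass(frozen=True)
class ProbePanel:
    """Annotation of all probes on the chip (tRNA probes plus spike-ins)."""

    probes: tuple[Probe, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "probes", tuple(self.probes))
        ids = [p.probe_id for p in self.probes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate probe ids in panel")
        if not any(p.is_spike for p in self.probes):
            raise ValueError("panel must contain at least one spike probe")
        for p in self.probes:
            if p.is_spike and p.decoded_codons:
                raise ValueError(f"spike probe {p.probe_id} must not decode codons")
            if not p.is_spike and not p.decoded_codons:
                raise ValueError(f"probe {p.probe_id} decodes no codons")
            if len(p.decoded_codons) != len(set(p.decoded_codons)):
                raise ValueError(f"probe {p.probe_id} lists a codon twice")

    def __iter__(self):
        return iter(self.probes)

    def __len__(self) -> int:
        return len(self.probes)

    def by_id(self, probe_id: str) -> Probe:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p
        raise KeyError(probe_id)

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    @property
    def spike_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes if p.is_spike]

    @property
    def trna_ids(self) -> list[str]:
        """Non-spike probe ids, in panel order."""
        return [p.probe_id for p in self.probes if not p.is_spike]

    def family(self, amino_acid: str) -> list[Probe]:
        """All probes of one isoacceptor family (same amino acid)."""
        hits = [p for p in self.probes if p.amino_acid == amino_acid]
        if not hits:
            raise KeyError(f"no probes for amino acid {amino_acid!r}")
        return hits


@dataclass
class ArrayExperiment:
    """Raw two-channel signals for one biological replicate of one model.

    ``signals`` maps probe_id to the per-technical-replicate (spot) list of
    (sample_channel, reference_channel) intensity pairs, arbitrary
    fluorescence units.
    """

    model_id: str
    bio_replicate: int
    signals: dict[str, list[tuple[float, float]]]

    def __post_init__(self) -> None:
        for pid, spots in self.signals.items():
            for s, r in spots:
                if s < 0 or r < 0:
                    raise ValueError(f"negative intensity on probe {pid}")


@dataclass
class NormalizedRatios:
    """Spike-normalized median sample/reference ratio per probe."""

    model_id: str
    bio_replicate: int
    ratio: dict[str, float]
    dropped_spots: dict[str, int] = field(default_factory=dict)


def median_ratio(
    experiment: ArrayExperiment,
    panel: ProbePanel,
    drop_log: dict[str, int] | None = None,
) -> dict[str, float]:
    """Per-probe median of per-spot sample/reference ratios.

    Spots with a zero reference channel are scan artifacts: they are dropped
    and counted in ``drop_log`` (probe_id -> number dropped). A probe left
    with no usable spot is an error.
    """
    out: dict[str, float] = {}
    for pid in panel.probe_ids:
        spots = experiment.signals.get(pid)
        if spots is None:
            raise ValueError(f"probe {pid} missing from experiment")
        ratios = [s / r for s, r in spots if r > 0]
        n_dropped = len(spots) - len(ratios)
        if n_dropped and drop_log is not None:
            drop_log[pid] = drop_log.get(pid, 0) + n_dropped
        if not ratios:
            raise ValueError(f"probe {pid} has no spot with positive reference signal")
        out[pid] = median(ratios)
    return out


def normalize_to_spikes(
    raw: dict[str, float],
    panel: ProbePanel,
    model_id: str = "",
    bio_replicate: int = 0,
    dropped_spots: dict[str, int] | None = None,
) -> NormalizedRatios:
    """Divide every raw ratio by the median of the spike probes' ratios.

    The median across spikes (rather than the mean) keeps one misbehaving
    spike from shifting the whole array. After division the spike median is
    exactly 1, which makes the operation idempotent.
    """
    spike_ratios = [raw[pid] for pid in panel.spike_ids if pid in raw]
    spike_ratios = [r for r in spike_ratios if r > 0]
    if not spike_ratios:
        raise ValueError("no spike probe with a positive raw ratio")
    anchor = median(spike_ratios)
    ratio = {pid: r / anchor for pid, r in raw.items()}
    return NormalizedRatios(
        model_id=model_id,
        bio_replicate=bio_replicate,
        ratio=ratio,
        dropped_spots=dict(dropped_spots or {}),
    )


def process_experiment(experiment: ArrayExperiment, panel: ProbePanel) -> NormalizedRatios:
    """median_ratio followed by spike normalization, carrying QC metadata."""
    drops: dict[str, int] = {}
    raw = median_ratio(experiment, panel, drop_log=drops)
    return normalize_to_spikes(
        raw,
        panel,
        model_id=experiment.model_id,
        bio_replicate=experiment.bio_replicate,
        dropped_spots=drops,
    )


def replicate_cv(rep_a: NormalizedRatios, rep_b: NormalizedRatios) -> dict[str, float]:
    """Per-probe coefficient of variation between two replicates.

    CV = sample standard deviation (n-1 denominator; with n = 2 this is
    |a-b|/sqrt(2)) divided by the mean of the two ratios.
    """
    if set(rep_a.ratio) != set(rep_b.ratio):
        raise ValueError("replicates cover different probe sets")
    out: dict[str, float] = {}
    for pid, a in rep_a.ratio.items():
        b = rep_b.ratio[pid]
        mean = (a + b) / 2.0
        if mean <= 0:
            raise ValueError(f"non-positive mean ratio for probe {pid}")
        sd = abs(a - b) / math.sqrt(2.0)
        out[pid] = sd / mean
    return out


def ks_similarity(
    rep_a: NormalizedRatios,
    rep_b: NormalizedRatios,
    panel: ProbePanel,
) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov–Smirnov test on tRNA-probe ratios.

    Spike probes are excluded: they are anchored at ratio 1 by construction
    and carry no biology. Returns (D, p); the exact null distribution is used
    for small samples (scipy's default for n below its asymptotic cutover).
    """
    ids = [pid for pid in panel.trna_ids if pid in rep_a.ratio and pid in rep_b.ratio]
    if len(ids) < 2:
        raise ValueError("need at least 2 non-spike probes for a KS test")
    a = [rep_a.ratio[pid] for pid in ids]
    b = [rep_b.ratio[pid] for pid in ids]
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def select_representative(replicates: list[NormalizedRatios]) -> int:
    """Index of the replicate with the lowest internal variation.

    Internal variation of replicate i is the mean, over the other replicates
    j and over probes, of CV(i, j). Ties resolve to the lowest index; a
    single replicate is trivially representative.
    """
    if not replicates:
        raise ValueError("empty replicate list")
    if len(replicates) == 1:
        return 0
    scores = []
    for i, rep in enumerate(replicates):
        cvs: list[float] = []
        for j, other in enumerate(replicates):
            if i == j:
                continue
            cvs.extend(replicate_cv(rep, other).values())
        scores.append(sum(cvs) / len(cvs))
    best = min(range(len(scores)), key=lambda i: (scores[i], i))
    return best
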