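"""From comparative ratios to absolute tRNA fractions and per-codon availability.

Comparative arrays only measure each probe's abundance relative to a shared
reference pool. Anchoring them to a baseline tRNAome measured in absolute
units (fractions of total tRNA) converts every model to the same absolute
scale. Isoacceptor abundance is then allocated onto the sense codons each
probe decodes, weighted by genomic codon usage, and the per-codon vector is
renormalized to a proper distribution over the 61 sense codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .array_processing import NormalizedRatios, ProbePanel
from .codon_usage import CodonUsageTable
from .genetic_code import SENSE_CODONS

__all__ = [
    "BaselineTRNAome",
    "TRNAFractions",
    "CodonFractions",
    "FamilyView",
    "calibrate_absolute",
    "allocate_to_codons",
    "split_family_view",
]

_SUM_TOL = 1e-9

#: initiator Met does not participate in elongation; internal AUG codons are
#: served by the elongator Met isoacceptor only.
INITIATOR_AA = "Meti"


def _check_fractions(fractions: dict[str, float]) -> None:
    if any(v <= 0 for v in fractions.values()):
        raise ValueError("all fractions must be strictly positive")
    total = sum(fractions.values())
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"fractions sum to {total}, expected 1")


@dataclass(frozen=True)
class BaselineTRNAome:
    """Absolute tRNA abundances (fractions of total tRNA) for the anchor model."""

    model_id: str
    absolute: dict[str, float]

    def __post_init__(self) -> None:
        _check_fractions(self.absolute)


@dataclass(frozen=True)
class TRNAFractions:
    """Per-probe abundance as fraction of total tRNA for one model."""

    model_id: str
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        _check_fractions(self.fractions)


@dataclass(frozen=True)
class CodonFractions:
    """tRNA availability per sense codon; sums to 1 over the 61 codons.

    ``ambiguous_codons`` marks codons whose only contributing probes sit in
    an ambiguity group: their values are reported but a variant call touching
    them cannot be resolved.
    """

    model_id: str
    per_codon: dict[str, float]
    contributing_probes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    ambiguous_codons: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        missing = set(SENSE_CODONS) - set(self.per_codon)
        if missing:
            raise ValueError(f"missing sense codons: {sorted(missing)}")
        _check_fractions(self.per_codon)
        object.__setattr__(self, "ambiguous_codons", frozenset(self.ambiguous_codons))

    def __getitem__(self, codon: str) -> float:
        return self.per_codon[codon]


@dataclass(frozen=True)
class FamilyView:
    """One isoacceptor family: absolute fractions and within-family shares."""

    amino_acid: str
    fractions: dict[str, float]
    shares: dict[str, float]


def calibrate_absolute(
    sample_vs_ref: NormalizedRatios,
    baseline_vs_ref: NormalizedRatios,
    baseline: BaselineTRNAome,
    panel: ProbePanel,
) -> TRNAFractions:
    """Convert comparative ratios to absolute fractions via the baseline set.

    Per probe: (sample/reference) / (baseline/reference) x baseline absolute
    fraction. The reference pool cancels, leaving sample-vs-baseline on the
    baseline's absolute scale; renormalizing the non-spike probes to sum 1
    gives fractions of total tRNA.
    """
    raw: dict[str, float] = {}
    for pid in panel.trna_ids:
        if pid not in sample_vs_ref.ratio:
            raise ValueError(f"probe {pid} missing from sample ratios")
        if pid not in baseline_vs_ref.ratio:
            raise ValueError(f"probe {pid} missing from baseline ratios")
        if pid not in baseline.absolute:
            raise ValueError(f"probe {pid} missing from baseline tRNAome")
        b_ratio = baseline_vs_ref.ratio[pid]
        if b_ratio <= 0:
            raise ValueError(f"non-positive baseline ratio for probe {pid}")
        raw[pid] = sample_vs_ref.ratio[pid] / b_ratio * baseline.absolute[pid]
    total = sum(raw.values())
    return TRNAFractions(
        model_id=sample_vs_ref.model_id,
        fractions={pid: v / total for pid, v in raw.items()},
    )


def allocate_to_codons(
    fractions: TRNAFractions,
    panel: ProbePanel,
    usage: CodonUsageTable,
) -> CodonFractions:
    """Distribute probe abundances onto sense codons.

    Each probe's fraction is split across its decoded codons proportionally
    to genomic usage; contributions from probes reading the same codon are
    summed; the resulting 61-codon vector is renormalized to sum 1. The
    initiator Met probe is excluded (it does not elongate). Codons decoded
    only by ambiguity-grouped probes are flagged ambiguous.
    """
    alloc: dict[str, float] = {c: 0.0 for c in SENSE_CODONS}
    contributors: dict[str, list[str]] = {c: [] for c in SENSE_CODONS}
    for probe in panel:
        if probe.is_spike or probe.amino_acid == INITIATOR_AA:
            continue
        if probe.probe_id not in fractions.fractions:
            raise ValueError(f"probe {probe.probe_id} missing from fractions")
        weight_total = sum(usage[c] for c in probe.decoded_codons)
        if weight_total <= 0:
            raise ValueError(
                f"probe {probe.probe_id}: all decoded codons have zero usage"
            )
        f = fractions.fractions[probe.probe_id]
        for codon in probe.decoded_codons:
            alloc[codon] += f * usage[codon] / weight_total
            contributors[codon].append(probe.probe_id)
    orphans = [c for c in SENSE_CODONS if not contributors[c]]
    if orphans:
        raise ValueError(f"sense codons decoded by no probe: {orphans}")
    total = sum(alloc.values())
    per_codon = {c: v / total for c, v in alloc.items()}
    ambiguous = frozenset(
        c
        for c in SENSE_CODONS
        if all(panel.by_id(pid).ambiguity_group is not None for pid in contributors[c])
    )
    return CodonFractions(
        model_id=fractions.model_id,
        per_codon=per_codon,
        contributing_probes={c: tuple(v) for c, v in contributors.items()},
        ambiguous_codons=ambiguous,
    )


def split_family_view(
    fractions: TRNAFractions,
    panel: ProbePanel,
    amino_acid: str,
) -> FamilyView:
    """Fractions of one isoacceptor family plus each probe's family share."""
    probes = panel.family(amino_acid)
    sub = {p.probe_id: fractions.fractions[p.probe_id] for p in probes}
    family_total = sum(sub.values())
    shares = {pid: v / family_total for pid, v in sub.items()}
    return FamilyView(amino_acid=amino_acid, fractions=sub, shares=shares)
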