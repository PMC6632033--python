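"""Cross-model effect prediction for synonymous single-nucleotide variants.

A synonymous variant swaps a codon for another codon of the same amino
acid. If the variant codon is served by a scarcer tRNA than the wild-type
codon, local elongation slows; the speed ratio R = f_wt / f_mut (codon-level
tRNA fractions) quantifies this, and comparing R across cell models against
a reference model predicts whether the variant's effect should be the same,
stronger, weaker, absent, or reverted in each model — or unresolvable when
the relevant codons are served only by probes the array cannot distinguish.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .codon_abundance import CodonFractions
from .genetic_code import to_rna, translate_codon
from .ribotempo import CodingSequence, velocity_profile

__all__ = [
    "SynonymousVariant",
    "SNVEffectCall",
    "HGVSError",
    "PositionOutOfRange",
    "ReferenceMismatch",
    "NonSynonymousVariant",
    "parse_hgvs",
    "codon_speed_ratio",
    "classify_across_models",
    "local_profile_delta",
    "EFFECT_CLASSES",
]

EFFECT_CLASSES = ("same", "stronger", "weaker", "reverted", "no_effect", "unresolvable")

DEFAULT_TOLERANCE = 0.2


class HGVSError(ValueError):
    """A coding-variant string that cannot be applied to the CDS."""


class PositionOutOfRange(HGVSError):
    pass


class ReferenceMismatch(HGVSError):
    pass


class NonSynonymousVariant(HGVSError):
    pass


@dataclass(frozen=True)
class SynonymousVariant:
    """A synonymous substitution located on a CDS.

    ``hgvs_c`` uses coding coordinates (position 1 = first nucleotide of the
    start codon); the codon index is ceil(position / 3).
    """

    transcript_id: str
    hgvs_c: str
    position: int
    codon_index: int
    wt_codon: str
    mut_codon: str
    amino_acid: str


@dataclass(frozen=True)
class SNVEffectCall:
    """Per-model speed ratios and effect classes relative to a reference model."""

    variant: SynonymousVariant
    reference_model: str
    per_model: dict[str, tuple[float | None, str]]
    tolerance: float

    @property
    def reference_ratio(self) -> float:
        return self.per_model[self.reference_model][0]


_HGVS_RE = re.compile(
    r"^c\.\s*(\d+)\s*([ACGTUacgtu])\s*>\s*([ACGTUacgtu])$"
)


def parse_hgvs(hgvs_c: str, cds: CodingSequence) -> SynonymousVariant:
    """Resolve a ``c.<pos><ref>><alt>`` substitution against a CDS.

    Checks that the CDS carries the stated reference nucleotide at the
    coding position and that the substitution is synonymous; the three
    failure modes (position out of range, reference mismatch, amino-acid
    change) raise distinct exceptions.
    """
    m = _HGVS_RE.match(hgvs_c.strip())
    if not m:
        raise HGVSError(f"cannot parse variant {hgvs_c!r}; expected c.<pos><ref>><alt>")
    pos = int(m.group(1))
    ref, alt = to_rna(m.group(2)), to_rna(m.group(3))
    if ref == alt:
        raise HGVSError(f"{hgvs_c!r}: reference and alternate nucleotides are equal")
    n_nt = 3 * len(cds)
    if not 1 <= pos <= n_nt:
        raise PositionOutOfRange(
            f"{hgvs_c!r}: position {pos} outside CDS of {n_nt} nt"
        )
    codon_index = (pos + 2) // 3  # ceil(pos / 3)
    offset = (pos - 1) % 3
    wt_codon = cds.codons[codon_index - 1]
    if wt_codon[offset] != ref:
        raise ReferenceMismatch(
            f"{hgvs_c!r}: CDS has {wt_codon[offset]} at c.{pos}, not {ref}"
        )
    mut_codon = wt_codon[:offset] + alt + wt_codon[offset + 1 :]
    aa_wt, aa_mut = translate_codon(wt_codon), translate_codon(mut_codon)
    if aa_wt != aa_mut:
        raise NonSynonymousVariant(
            f"{hgvs_c!r}: not synonymous ({wt_codon}/{aa_wt} -> {mut_codon}/{aa_mut})"
        )
    return SynonymousVariant(
        transcript_id=cds.transcript_id,
        hgvs_c=hgvs_c.strip(),
        position=pos,
        codon_index=codon_index,
        wt_codon=wt_codon,
        mut_codon=mut_codon,
        amino_acid=aa_wt,
    )


def codon_speed_ratio(
    variant: SynonymousVariant, codon_fractions: CodonFractions
) -> float | None:
    """f_wt / f_mut, or None when either codon is array-ambiguous.

    R > 1 predicts a local slowdown introduced by the variant.
    """
    for codon in (variant.wt_codon, variant.mut_codon):
        if codon not in codon_fractions.per_codon:
            raise ValueError(f"codon {codon} missing from fractions")
    if (
        variant.wt_codon in codon_fractions.ambiguous_codons
        or variant.mut_codon in codon_fractions.ambiguous_codons
    ):
        return None
    return codon_fractions[variant.wt_codon] / codon_fractions[variant.mut_codon]


def _classify_one(r_m: float, r_ref: float, tol: float) -> str:
    # reverted is checked before no_effect: a reverted ratio also satisfies
    # the no_effect bound, and the more specific call must win
    if r_ref > 1 + tol and r_m <= 1 / (1 + tol):
        return "reverted"
    if r_m <= 1 + tol:
        return "no_effect"
    if abs(math.log2(r_m) - math.log2(r_ref)) <= math.log2(1 + tol):
        return "same"
    if r_m > r_ref * (1 + tol):
        return "stronger"
    return "weaker"


def classify_across_models(
    variant: SynonymousVariant,
    models: dict[str, CodonFractions],
    reference_model: str,
    tolerance: float = DEFAULT_TOLERANCE,
) -> SNVEffectCall:
    """Classify the variant's predicted velocity effect in every model.

    The reference model anchors the comparison and is labelled ``same`` by
    construction. For every other model the speed ratio R_m is compared to
    R_ref with a single relative tolerance on the ratio scale.
    """
    if reference_model not in models:
        raise ValueError(f"reference model {reference_model!r} not supplied")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    r_ref = codon_speed_ratio(variant, models[reference_model])
    if r_ref is None:
        raise ValueError(
            f"reference model {reference_model!r} is unresolvable for this variant"
        )
    per_model: dict[str, tuple[float | None, str]] = {}
    for model_id, fractions in models.items():
        r_m = codon_speed_ratio(variant, fractions)
        if r_m is None:
            per_model[model_id] = (None, "unresolvable")
        elif model_id == reference_model:
            per_model[model_id] = (r_m, "same")
        else:
            per_model[model_id] = (r_m, _classify_one(r_m, r_ref, tolerance))
    return SNVEffectCall(
        variant=variant,
        reference_model=reference_model,
        per_model=per_model,
        tolerance=tolerance,
    )


def local_profile_delta(
    variant: SynonymousVariant,
    seq: CodingSequence,
    codon_fractions: CodonFractions,
    window: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Velocity-profile segments around the variant, wild-type vs mutant.

    Recomputes the profile on the codon-substituted sequence and returns the
    values of every full window containing the variant codon (exactly
    ``window`` windows), for the wild-type and the mutant sequence. Only
    these windows can differ.
    """
    ci = variant.codon_index
    n = len(seq)
    if ci < window or ci > n - window + 1:
        raise ValueError(
            f"variant at codon {ci} too close to the CDS ends for a full "
            f"{window}-codon window"
        )
    if seq.codons[ci - 1] != variant.wt_codon:
        raise ValueError(
            f"CDS codon {ci} is {seq.codons[ci - 1]}, variant expects {variant.wt_codon}"
        )
    mut_seq = seq.substitute(ci, variant.mut_codon)
    wt_prof = velocity_profile(seq, codon_fractions, window=window)
    mut_prof = velocity_profile(mut_seq, codon_fractions, window=window)
    # windows with start in [ci - window + 1, ci] contain the variant codon
    starts = np.arange(1, n - window + 2)
    mask = (starts >= ci - window + 1) & (starts <= ci)
    return wt_prof.values[mask], mut_prof.values[mask]
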