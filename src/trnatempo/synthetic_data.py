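"""Synthetic study data: tRNAomes, noisy arrays, transcripts, SNV scenarios.

Every downstream stage of the pipeline is testable without wet-lab data:
this module draws ground-truth tRNA fraction vectors per cell model,
emits two-channel array signals with multiplicative log-normal noise,
spike-in probes and arbitrary per-channel scale factors, samples toy coding
sequences, and constructs codon-fraction configurations with a known
expected synonymous-variant classification.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .array_processing import ArrayExperiment, Probe, ProbePanel
from .codon_abundance import CodonFractions
from .genetic_code import SENSE_CODONS, STOP_CODONS, to_rna
from .ribotempo import CodingSequence
from .snv_effect import SynonymousVariant

__all__ = [
    "GroundTruthTRNAome",
    "NoiseModel",
    "default_panel",
    "generic_panel",
    "gen_truth",
    "gen_truth_for_panel",
    "gen_array",
    "gen_transcript",
    "gen_snv_scenario",
    "cftr_like_cds",
    "SPIKE_PREFIX",
    "STUDY_MODELS",
]

SPIKE_PREFIX = "spike_"

#: cell and tissue models of the study design (reference channel is HEK293;
#: absolute anchor is HeLa)
STUDY_MODELS = (
    "CFBE41o-",
    "HEK293",
    "HeLa",
    "FRT",
    "HBE",
    "HNE",
    "organoids",
    "iPSC_d0",
)

# Human-like isoacceptor panel derived from standard wobble rules: an
# inosine-34 anticodon reads U/C(/A)-ending codons, a dedicated isoacceptor
# claims its own codon where one exists (Thr-AGU therefore does not read
# ACG, which has its own isoacceptor), and the Pro isoacceptors differ by
# fewer than 8 nt and are reported as a single ambiguity-grouped probe.
# This is a synthetic panel: it mirrors the shape of a real tDNA chip
# (one probe per resolvable isoacceptor, all 61 sense codons covered), not
# the exact probe set of any published array.
_PANEL_TABLE: list[tuple[str, tuple[str, ...], tuple[str, ...], str | None]] = [
    ("F", ("GAA",), ("UUU", "UUC"), None),
    ("L", ("UAA",), ("UUA", "UUG"), None),
    ("L", ("CAA",), ("UUG",), None),
    ("L", ("AAG",), ("CUU", "CUC", "CUA"), None),
    ("L", ("CAG",), ("CUG",), None),
    ("I", ("AAU",), ("AUU", "AUC", "AUA"), None),
    ("I", ("UAU",), ("AUA",), None),
    ("M", ("CAU",), ("AUG",), None),
    ("Meti", ("CAU",), ("AUG",), None),
    ("V", ("AAC",), ("GUU", "GUC"), None),
    ("V", ("UAC",), ("GUA",), None),
    ("V", ("CAC",), ("GUG",), None),
    ("S", ("AGA",), ("UCU", "UCC"), None),
    ("S", ("UGA",), ("UCA",), None),
    ("S", ("CGA",), ("UCG",), None),
    ("S", ("GCU",), ("AGU", "AGC"), None),
    ("P", ("AGG", "UGG", "CGG"), ("CCU", "CCC", "CCA", "CCG"), "Pro"),
    ("T", ("AGU",), ("ACU", "ACC"), None),
    ("T", ("UGU",), ("ACA",), None),
    ("T", ("CGU",), ("ACG",), None),
    ("A", ("AGC",), ("GCU", "GCC", "GCA"), None),
    ("A", ("CGC",), ("GCG",), None),
    ("Y", ("GUA",), ("UAU", "UAC"), None),
    ("H", ("GUG",), ("CAU", "CAC"), None),
    ("Q", ("UUG",), ("CAA",), None),
    ("Q", ("CUG",), ("CAG",), None),
    ("N", ("GUU",), ("AAU", "AAC"), None),
    ("K", ("UUU",), ("AAA",), None),
    ("K", ("CUU",), ("AAG",), None),
    ("D", ("GUC",), ("GAU", "GAC"), None),
    ("E", ("UUC",), ("GAA", "GAG"), None),
    ("E", ("CUC",), ("GAG",), None),
    ("C", ("GCA",), ("UGU", "UGC"), None),
    ("W", ("CCA",), ("UGG",), None),
    ("R", ("ACG",), ("CGU", "CGC", "CGA"), None),
    ("R", ("CCG",), ("CGG",), None),
    ("R", ("UCU",), ("AGA",), None),
    ("R", ("CCU",), ("AGG",), None),
    ("G", ("GCC",), ("GGU", "GGC"), None),
    ("G", ("UCC",), ("GGA",), None),
    ("G", ("CCC",), ("GGG",), None),
]


@dataclass(frozen=True)
class GroundTruthTRNAome:
    """The true tRNA fraction vector behind a simulated model."""

    model_id: str
    fractions: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.fractions.values()):
            raise ValueError("truth fractions must be strictly positive")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"truth fractions sum to {total}, expected 1")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal signal noise and replicate structure.

    ``sigma_log`` is the standard deviation of the per-spot noise on the
    natural-log scale (0.1 corresponds to roughly a 10% coefficient of
    variation, a typical fluorescence-replicate spread). Each probe is
    spotted as 24 technical replicates; three spike-in tRNAs are added at
    equal amounts to both channels.
    """

    sigma_log: float = 0.1
    n_bio_replicates: int = 3
    n_tech_replicates: int = 24
    spike_count: int = 3

    def __post_init__(self) -> None:
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")
        if self.n_tech_replicates < 1:
            raise ValueError("need at least one technical replicate")
        if self.n_bio_replicates < 1:
            raise ValueError("need at least one biological replicate")
        if self.spike_count not in (3, 4):
            raise ValueError("spike_count must be 3 or 4")


def default_panel(spike_count: int = 3) -> ProbePanel:
    """The synthetic human-like probe panel (41 tRNA probes + spikes)."""
    probes = [
        Probe(
            probe_id=f"{aa}-{anticodons[0]}" if group is None else f"{aa}-{group}",
            anticodons=anticodons,
            amino_acid=aa,
            decoded_codons=codons,
            ambiguity_group=group,
        )
        for aa, anticodons, codons, group in _PANEL_TABLE
    ]
    probes += [
        Probe(probe_id=f"{SPIKE_PREFIX}{i + 1}", is_spike=True)
        for i in range(spike_count)
    ]
    return ProbePanel(tuple(probes))


def generic_panel(probe_ids: list[str], spike_count: int = 3) -> ProbePanel:
    """A minimal panel over arbitrary probe ids, for probe-level pipelines.

    Decoded codons are assigned round-robin and carry no meaning; use
    :func:`default_panel` whenever codon-level output is needed.
    """
    probes = [
        Probe(
            probe_id=pid,
            amino_acid="X",
            decoded_codons=(SENSE_CODONS[i % len(SENSE_CODONS)],),
        )
        for i, pid in enumerate(probe_ids)
    ]
    probes += [
        Probe(probe_id=f"{SPIKE_PREFIX}{i + 1}", is_spike=True)
        for i in range(spike_count)
    ]
    return ProbePanel(tuple(probes))


def gen_truth(
    n_probes: int,
    model_ids: list[str],
    seed: int,
    probe_ids: list[str] | None = None,
) -> list[GroundTruthTRNAome]:
    """One ground-truth tRNAome per model.

    Fractions are drawn i.i.d. log-normal(mu=0, sigma=1) per probe and
    normalized to sum 1, reproducing the roughly order-of-magnitude spread
    of measured tRNA abundances.
    """
    if n_probes < 2:
        raise ValueError("need at least 2 probes")
    if probe_ids is None:
        probe_ids = [f"tRNA_{i + 1:02d}" for i in range(n_probes)]
    if len(probe_ids) != n_probes:
        raise ValueError("probe_ids length does not match n_probes")
    truths = []
    for k, model_id in enumerate(model_ids):
        rng = np.random.default_rng([seed, k])
        draws = rng.lognormal(mean=0.0, sigma=1.0, size=n_probes)
        fractions = draws / draws.sum()
        truths.append(
            GroundTruthTRNAome(
                model_id=model_id,
                fractions=dict(zip(probe_ids, fractions)),
                seed=seed,
            )
        )
    return truths


def gen_truth_for_panel(
    panel: ProbePanel, model_ids: list[str], seed: int
) -> list[GroundTruthTRNAome]:
    """Ground truths over a panel's tRNA probes (spikes excluded)."""
    ids = panel.trna_ids
    return gen_truth(len(ids), model_ids, seed, probe_ids=ids)


# effective concentration at which spikes enter both channels; arbitrary, the
# pipeline only uses that it is equal in both pools
_SPIKE_LEVEL = 0.025
# fluorescence units are arbitrary; channel scales are drawn per replicate so
# spike normalization is actually exercised
_CHANNEL_SCALE = 1.0e4


def gen_array(
    truth: GroundTruthTRNAome,
    reference: GroundTruthTRNAome,
    noise: NoiseModel,
    seed: int,
) -> list[ArrayExperiment]:
    """Simulate comparative arrays: one ArrayExperiment per biological replicate.

    Sample-channel signal per spot is proportional to the truth fraction
    times exp(N(0, sigma_log)); the reference channel likewise from the
    reference tRNAome. Spike probes enter both channels at the same
    effective concentration, so their pre-scaling ratio is 1. Each replicate
    and channel gets an arbitrary global scale factor.
    """
    if set(truth.fractions) != set(reference.fractions):
        raise ValueError("truth and reference cover different probe sets")
    probe_ids = sorted(truth.fractions)
    spikes = [f"{SPIKE_PREFIX}{i + 1}" for i in range(noise.spike_count)]
    experiments = []
    for b in range(noise.n_bio_replicates):
        rng = np.random.default_rng([seed, b])
        scale_s = _CHANNEL_SCALE * rng.uniform(0.5, 2.0)
        scale_r = _CHANNEL_SCALE * rng.uniform(0.5, 2.0)
        signals: dict[str, list[tuple[float, float]]] = {}
        for pid in probe_ids + spikes:
            conc_s = truth.fractions.get(pid, _SPIKE_LEVEL)
            conc_r = reference.fractions.get(pid, _SPIKE_LEVEL)
            eps = rng.normal(0.0, noise.sigma_log, size=(noise.n_tech_replicates, 2))
            spots = [
                (
                    float(scale_s * conc_s * np.exp(e_s)),
                    float(scale_r * conc_r * np.exp(e_r)),
                )
                for e_s, e_r in eps
            ]
            signals[pid] = spots
        experiments.append(
            ArrayExperiment(model_id=truth.model_id, bio_replicate=b + 1, signals=signals)
        )
    return experiments


def gen_transcript(
    n_codons: int, codon_weights: dict[str, float], seed: int
) -> str:
    """Random coding sequence: 3*n_codons nucleotides plus one stop codon.

    Codons are sampled i.i.d. proportionally to ``codon_weights`` (sense
    codons only); the stop appended is UAA.
    """
    if n_codons < 1:
        raise ValueError("need at least one codon")
    weights = {to_rna(c): float(w) for c, w in codon_weights.items()}
    stops = set(weights) & STOP_CODONS
    if stops:
        raise ValueError(f"stop codons in weights: {sorted(stops)}")
    bad = [c for c in weights if c not in SENSE_CODONS]
    if bad:
        raise ValueError(f"not sense codons: {bad}")
    codons = sorted(c for c, w in weights.items() if w > 0)
    if not codons:
        raise ValueError("no codon with positive weight")
    p = np.array([weights[c] for c in codons])
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(codons), size=n_codons, p=p)
    return "".join(codons[i] for i in picks) + "UAA"


def _jittered_codon_fractions(
    model_id: str,
    rng: np.random.Generator,
    overrides: dict[str, float],
    ambiguous: frozenset[str] = frozenset(),
) -> CodonFractions:
    base = {c: (1.0 / 61.0) * float(rng.lognormal(0.0, 0.02)) for c in SENSE_CODONS}
    base.update(overrides)
    total = sum(base.values())
    return CodonFractions(
        model_id=model_id,
        per_codon={c: v / total for c, v in base.items()},
        ambiguous_codons=ambiguous,
    )


def gen_snv_scenario(
    kind: str, seed: int, tolerance: float = 0.2
) -> tuple[dict[str, CodonFractions], SynonymousVariant, str]:
    """Engineer codon fractions so the classifier must return ``kind``.

    The variant is a Thr ACU->ACG swap (third-position U>G). The reference
    model "REF" carries a clear slowdown (speed ratio R_ref = 4); the test
    model "ALT" gets a ratio placed well inside the target class band, with
    margin to every class boundary of at least the classifier tolerance
    (the `same` and `no_effect` bands are only 1 tolerance wide on each side
    of their centers, which bounds the achievable margin).

    Returns (models, variant, expected class for "ALT").
    """
    targets = {
        "same": 4.0,
        "stronger": 16.0,
        "weaker": 2.0,
        "no_effect": 1.0,
        "reverted": 0.25,
        "unresolvable": 4.0,
    }
    if kind not in targets:
        raise ValueError(f"unknown scenario kind {kind!r}")
    kind_index = sorted(targets).index(kind)  # str hash is process-salted
    rng = np.random.default_rng([seed, kind_index])
    f_wt = 0.04
    r_ref = 4.0
    ref = _jittered_codon_fractions(
        "REF", rng, {"ACU": f_wt, "ACG": f_wt / r_ref}
    )
    ambiguous = frozenset({"ACG"}) if kind == "unresolvable" else frozenset()
    alt = _jittered_codon_fractions(
        "ALT", rng, {"ACU": f_wt, "ACG": f_wt / targets[kind]}, ambiguous=ambiguous
    )
    variant = SynonymousVariant(
        transcript_id="toy",
        hgvs_c="c.6U>G",
        position=6,
        codon_index=2,
        wt_codon="ACU",
        mut_codon="ACG",
        amino_acid="T",
    )
    return {"REF": ref, "ALT": alt}, variant, kind


# domain intervals (codon coordinates) used purely as plotting metadata,
# mirroring the canonical domain layout of the CFTR channel
_CFTR_DOMAINS = (
    ("MSD1", 81, 365),
    ("NBD1", 389, 646),
    ("R", 654, 838),
    ("MSD2", 859, 1155),
    ("NBD2", 1210, 1443),
)

_CFTR_LIKE_N_CODONS = 1480


def cftr_like_cds(seed: int = 0) -> CodingSequence:
    """A synthetic CFTR-like coding sequence (1480 codons).

    Synthetic stand-in for the real CFTR CDS, which is external data: codons
    are drawn from human codon usage, with the start codon and the three
    variant-site codons of interest pinned at their real coordinates —
    codon 528 = GAG (c.1584G>A site), codon 854 = ACU (c.2562T>G site),
    codon 1290 = CCA (c.3870A>G site) — so HGVS mapping and the variant
    analyses land on the documented residue numbers.
    """
    from .codon_usage import CodonUsageTable

    usage = CodonUsageTable.human().usage
    seq = gen_transcript(_CFTR_LIKE_N_CODONS, usage, seed=seed)
    codons = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3)]
    codons[0] = "AUG"
    codons[527] = "GAG"
    codons[853] = "ACU"
    codons[1289] = "CCA"
    return CodingSequence(
        transcript_id="CFTR_like_synthetic",
        codons=tuple(codons),
        annotations=_CFTR_DOMAINS,
    )
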