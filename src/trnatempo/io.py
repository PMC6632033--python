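"""Delimited-text and FASTA I/O.

All tabular formats are plain TSV so that simulated fixtures are
bit-compatible with what the processing CLI reads. Codon keys are written
in the RNA alphabet; DNA input (T) is accepted everywhere and converted.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .array_processing import ArrayExperiment, NormalizedRatios, Probe, ProbePanel
from .codon_abundance import BaselineTRNAome, CodonFractions, TRNAFractions
from .codon_usage import CodonUsageTable
from .genetic_code import to_rna
from .ribotempo import CodingSequence, VelocityProfile

__all__ = [
    "read_panel", "write_panel",
    "read_signals", "write_signals",
    "read_ratios", "write_ratios",
    "read_fractions", "write_fractions",
    "read_baseline", "read_codon_fractions", "write_codon_fractions",
    "read_usage", "write_usage",
    "read_cds_fasta", "write_cds_fasta",
    "write_profile",
]


def write_panel(panel: ProbePanel, path) -> None:
    rows = [
        {
            "probe_id": p.probe_id,
            "anticodons": ",".join(p.anticodons),
            "amino_acid": p.amino_acid,
            "decoded_codons": ",".join(p.decoded_codons),
            "ambiguity_group": p.ambiguity_group or "",
            "is_spike": int(p.is_spike),
        }
        for p in panel
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_panel(path) -> ProbePanel:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    probes = []
    for row in df.itertuples(index=False):
        probes.append(
            Probe(
                probe_id=row.probe_id,
                anticodons=tuple(to_rna(a) for a in row.anticodons.split(",") if a),
                amino_acid=row.amino_acid,
                decoded_codons=tuple(
                    to_rna(c) for c in row.decoded_codons.split(",") if c
                ),
                ambiguity_group=row.ambiguity_group or None,
                is_spike=bool(int(row.is_spike)),
            )
        )
    return ProbePanel(tuple(probes))


def write_signals(experiments: list[ArrayExperiment], path) -> None:
    """One row per spot: model_id, bio_replicate, probe_id, spot, signals."""
    rows = []
    for exp in experiments:
        for pid, spots in exp.signals.items():
            for k, (s, r) in enumerate(spots, start=1):
                rows.append(
                    {
                        "model_id": exp.model_id,
                        "bio_replicate": exp.bio_replicate,
                        "probe_id": pid,
                        "spot": k,
                        "sample_signal": s,
                        "reference_signal": r,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_signals(path) -> list[ArrayExperiment]:
    df = pd.read_csv(path, sep="\t")
    experiments = []
    for (model_id, bio_rep), grp in df.groupby(["model_id", "bio_replicate"], sort=True):
        signals: dict[str, list[tuple[float, float]]] = {}
        for row in grp.sort_values(["probe_id", "spot"]).itertuples(index=False):
            signals.setdefault(row.probe_id, []).append(
                (float(row.sample_signal), float(row.reference_signal))
            )
        experiments.append(
            ArrayExperiment(
                model_id=str(model_id), bio_replicate=int(bio_rep), signals=signals
            )
        )
    return experiments


def write_ratios(ratios: NormalizedRatios, path) -> None:
    df = pd.DataFrame(
        {
            "probe_id": list(ratios.ratio),
            "ratio": list(ratios.ratio.values()),
        }
    )
    df.insert(0, "model_id", ratios.model_id)
    df.insert(1, "bio_replicate", ratios.bio_replicate)
    df.to_csv(path, sep="\t", index=False)


def read_ratios(path) -> NormalizedRatios:
    df = pd.read_csv(path, sep="\t")
    return NormalizedRatios(
        model_id=str(df["model_id"].iloc[0]),
        bio_replicate=int(df["bio_replicate"].iloc[0]),
        ratio=dict(zip(df["probe_id"], df["ratio"].astype(float))),
    )


def write_fractions(fractions: TRNAFractions, path) -> None:
    pd.DataFrame(
        {
            "probe_id": list(fractions.fractions),
            "fraction": list(fractions.fractions.values()),
        }
    ).assign(model_id=fractions.model_id).to_csv(path, sep="\t", index=False)


def read_fractions(path) -> TRNAFractions:
    df = pd.read_csv(path, sep="\t")
    return TRNAFractions(
        model_id=str(df["model_id"].iloc[0]),
        fractions=dict(zip(df["probe_id"], df["fraction"].astype(float))),
    )


def read_baseline(path) -> BaselineTRNAome:
    df = pd.read_csv(path, sep="\t")
    return BaselineTRNAome(
        model_id=str(df["model_id"].iloc[0]),
        absolute=dict(zip(df["probe_id"], df["fraction"].astype(float))),
    )


def write_codon_fractions(cf: CodonFractions, path) -> None:
    pd.DataFrame(
        {
            "codon": list(cf.per_codon),
            "fraction": list(cf.per_codon.values()),
            "ambiguous": [int(c in cf.ambiguous_codons) for c in cf.per_codon],
        }
    ).assign(model_id=cf.model_id).to_csv(path, sep="\t", index=False)


def read_codon_fractions(path) -> CodonFractions:
    df = pd.read_csv(path, sep="\t")
    codons = [to_rna(c) for c in df["codon"]]
    return CodonFractions(
        model_id=str(df["model_id"].iloc[0]),
        per_codon=dict(zip(codons, df["fraction"].astype(float))),
        ambiguous_codons=frozenset(
            c for c, a in zip(codons, df["ambiguous"]) if int(a)
        ),
    )


def write_usage(usage: CodonUsageTable, path) -> None:
    pd.DataFrame(
        {"codon": list(usage.usage), "usage": list(usage.usage.values())}
    ).to_csv(path, sep="\t", index=False)


def read_usage(path) -> CodonUsageTable:
    df = pd.read_csv(path, sep="\t")
    return CodonUsageTable(dict(zip(df["codon"], df["usage"].astype(float))))


def read_cds_fasta(path, transcript_id: str | None = None) -> CodingSequence:
    """First (or named) record of a FASTA file as a CodingSequence.

    Accepts DNA or RNA; a trailing stop codon, if present, is trimmed.
    """
    for rec in SeqIO.parse(str(path), "fasta"):
        if transcript_id is None or rec.id == transcript_id:
            return CodingSequence.from_nucleotides(rec.id, str(rec.seq))
    raise ValueError(f"no record {transcript_id!r} in {path}")


def write_cds_fasta(seq: CodingSequence, path, stop: str = "UAA") -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq.transcript_id}\n")
        nt = seq.nucleotides + stop
        for i in range(0, len(nt), 60):
            fh.write(nt[i : i + 60] + "\n")


def write_profile(profile: VelocityProfile, tsv_path, json_path=None, regions=None) -> None:
    """Profile as TSV (center_codon, value) plus a JSON sidecar."""
    pd.DataFrame(
        {"center_codon": profile.centers, "value": profile.values}
    ).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        meta = {
            "transcript_id": profile.transcript_id,
            "model_id": profile.model_id,
            "window": profile.window,
            "band_percentiles": list(profile.band_percentiles),
            "band": list(profile.band),
        }
        if regions is not None:
            meta["regions"] = [
                {"start": s, "end": e, "class": c} for s, e, c in regions
            ]
        Path(json_path).write_text(json.dumps(meta, indent=2))
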