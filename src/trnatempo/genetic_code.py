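"""Standard genetic code helpers on the RNA alphabet.

All codons inside the package are RNA (ACGU), uppercase. DNA input (T) is
accepted at the I/O boundary and converted on the way in.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_rna_by_id[1]

#: codon -> one-letter amino acid, 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

NUCLEOTIDES = "ACGU"


def to_rna(seq: str) -> str:
    """Uppercase and convert T -> U."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon; '*' for a stop codon."""
    codon = to_rna(codon)
    if codon in STOP_CODONS:
        return "*"
    try:
        return CODON_TO_AA[codon]
    except KeyError:
        raise ValueError(f"not a codon: {codon!r}") from None


def is_sense(codon: str) -> bool:
    return to_rna(codon) in CODON_TO_AA
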