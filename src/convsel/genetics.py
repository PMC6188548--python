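"""Genetic-code tables shared by the codon and amino-acid machinery.

The standard (vertebrate nuclear) genetic code is taken from Biopython's
codon tables.  The state spaces used throughout the package are the 61
sense codons (stop codons are excluded from the codon models, as usual for
dN/dS work) and the 20 amino acids in one-letter alphabetical order.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD_TABLE.stop_codons))

#: the 61 sense codons in TCAG-major order (the conventional codon-model order)
SENSE_CODONS: tuple[str, ...] = tuple(
    "".join(c)
    for c in itertools.product(NUCLEOTIDES, repeat=3)
    if "".join(c) not in STOP_CODONS
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_AA = len(AMINO_ACIDS)

#: amino acid encoded by each sense codon, aligned with SENSE_CODONS
CODON_AA: tuple[str, ...] = tuple(
    _STANDARD_TABLE.forward_table[c] for c in SENSE_CODONS
)
CODON_AA_INDEX: np.ndarray = np.array([AA_INDEX[a] for a in CODON_AA], dtype=int)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

#: IUPAC nucleotide ambiguity codes mapped to their compatible base sets
IUPAC_DNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("GC"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
    "-": frozenset("ACGT"),  # gap == fully missing
}

#: IUPAC protein ambiguity codes (beyond the 20 canonical residues)
IUPAC_PROTEIN: dict[str, frozenset[str]] = {
    **{a: frozenset(a) for a in AMINO_ACIDS},
    "B": frozenset("DN"),
    "Z": frozenset("EQ"),
    "J": frozenset("IL"),
    "X": frozenset(AMINO_ACIDS),
    "-": frozenset(AMINO_ACIDS),
    "*": frozenset(AMINO_ACIDS),  # stop in translation: treated as missing
}


def is_transition(b1: str, b2: str) -> bool:
    """True if the single-nucleotide change b1->b2 is a transition."""
    return (b1 in _PURINES and b2 in _PURINES) or (
        b1 in _PYRIMIDINES and b2 in _PYRIMIDINES
    )


def _codon_change_type() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Classify all sense-codon pairs by number of nucleotide differences,
    transition vs transversion (for single changes), and synonymy."""
    n = N_CODONS
    ndiff = np.zeros((n, n), dtype=int)
    transition = np.zeros((n, n), dtype=bool)
    synonymous = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            ndiff[i, j] = len(diffs)
            if len(diffs) == 1:
                transition[i, j] = is_transition(*diffs[0])
            synonymous[i, j] = CODON_AA[i] == CODON_AA[j]
    return ndiff, transition, synonymous


CODON_NDIFF, CODON_TRANSITION, CODON_SYNONYMOUS = _codon_change_type()


def translate_codon(codon: str) -> str:
    """Translate one codon; ambiguous/gapped/stop codons give 'X'/'-'/'*'."""
    codon = codon.upper().replace("U", "T")
    if codon in CODON_INDEX:
        return CODON_AA[CODON_INDEX[codon]]
    if codon in STOP_CODONS:
        return "*"
    if set(codon) <= {"-"}:
        return "-"
    return "X"
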