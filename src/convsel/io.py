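"""FASTA and result-table input/output with strict validation.

Sequence parsing goes through Biopython's FASTA reader; this layer adds
the contracts the pipeline relies on: unique record ids, alphabet
enforcement with informative error positions, uppercase normalisation and
a fixed 60-column wrap on output.  Result tables are tab-separated with a
header row; alignment coordinates in tables are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .genetics import IUPAC_DNA, IUPAC_PROTEIN

_ALPHABETS = {
    "dna": set(IUPAC_DNA) | {"."},
    "protein": set(IUPAC_PROTEIN),
}


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: a taxon/gene identifier and its sequence."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file, validating ids and alphabet membership.

    Characters are uppercased; record order is preserved.  Duplicate ids
    and out-of-alphabet characters raise ``ValueError`` naming the record
    (and 1-based position for characters).
    """
    if alphabet not in _ALPHABETS:
        raise ValueError(f"alphabet must be one of {sorted(_ALPHABETS)}")
    allowed = _ALPHABETS[alphabet]
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            rid = title.split()[0] if title.split() else ""
            if not rid:
                raise ValueError(f"empty record id in {path}")
            if rid in seen:
                raise ValueError(f"duplicate record id {rid!r} in {path}")
            seen.add(rid)
            seq = seq.upper()
            if not seq:
                raise ValueError(f"record {rid!r} has an empty sequence")
            for pos, ch in enumerate(seq, start=1):
                if ch not in allowed:
                    raise ValueError(
                        f"illegal {alphabet} character {ch!r} in record "
                        f"{rid!r} at position {pos}"
                    )
            records.append(SequenceRecord(rid, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA with 60-column line wrapping."""
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 60):
                out.write(rec.seq[i : i + 60] + "\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV (header, no index, UTF-8)."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
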