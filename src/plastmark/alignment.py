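"""Multiple sequence alignment container shared across the toolkit.

A deliberately small, immutable-ish matrix of equal-length gapped rows keyed
by unique taxon labels.  FASTA round-tripping goes through Biopython.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"


@dataclass
class Alignment:
    """An aligned matrix of sequences.

    Parameters
    ----------
    taxa:
        Ordered, unique row labels.
    rows:
        Gapped sequences, all of equal length, parallel to ``taxa``.
    alphabet:
        ``"nt"`` or ``"aa"``; informational, used to pick ambiguity symbols.
    """

    taxa: list[str]
    rows: list[str]
    alphabet: str = "nt"

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows must be parallel")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon labels must be unique")
        if self.rows:
            n = len(self.rows[0])
            for t, r in zip(self.taxa, self.rows):
                if len(r) != n:
                    raise ValueError(
                        f"row for {t!r} has length {len(r)}, expected {n}"
                    )
        if self.alphabet not in ("nt", "aa"):
            raise ValueError("alphabet must be 'nt' or 'aa'")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def slice(self, start: int, end: int) -> "Alignment":
        """Column slice [start, end), 0-based half-open."""
        return Alignment(list(self.taxa), [r[start:end] for r in self.rows],
                         self.alphabet)

    def ungapped(self, taxon: str) -> str:
        return self.row(taxon).replace(GAP, "")

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.taxa, self.rows))

    @classmethod
    def from_fasta(cls, path: str | Path, alphabet: str = "nt") -> "Alignment":
        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append(str(rec.seq).upper())
        if not taxa:
            raise ValueError(f"no sequences in {path}")
        return cls(taxa, rows, alphabet)

    def to_fasta(self, path: str | Path) -> None:
        recs = [SeqRecord(Seq(r), id=t, description="") for t, r in self.items()]
        SeqIO.write(recs, str(path), "fasta")
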