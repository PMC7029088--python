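"""Reading annotated genomes and extracting protein-coding sequences.

GenBank flat files are parsed with Biopython; every CDS feature that carries
a ``/gene`` (or, failing that, ``/product``) qualifier becomes a
:class:`CDSFeature` with a strand-corrected nucleotide sequence.  Gene names
are canonicalized to lower case because annotation case is inconsistent
across submitters.  Translation follows the longest-open-reading-frame rule
with a configurable minimum protein length, under the bacterial/plastid
genetic code (translation table 11) by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

__all__ = [
    "CDSFeature",
    "GenomeRecord",
    "read_genbank",
    "translate_longest_orf",
    "write_cds_fasta",
    "read_cds_fasta",
]

DEFAULT_TABLE = 11  # bacterial/plastid genetic code
MIN_AA_DEFAULT = 50


def canonical_gene_name(name: str) -> str:
    """Lower-cased gene name with whitespace collapsed to underscores
    ("rbcL" == "rbcl"); keeps names safe for FASTA headers and file names."""
    return "_".join(name.strip().lower().split())


@dataclass
class CDSFeature:
    """One protein-coding feature of a genome.

    ``nt_seq`` is already strand-corrected (5'->3'); ``start``/``end`` are
    1-based inclusive coordinates on the genome; ``n_segments`` counts the
    annotated coding intervals (a ``join(..)`` location has >1).
    """

    gene_name: str
    start: int
    end: int
    strand: str
    nt_seq: str
    n_segments: int = 1
    internal_stop: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end must be >= start")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        bad = set(self.nt_seq.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"non-ACGTN characters in nt_seq: {sorted(bad)}")
        self.nt_seq = self.nt_seq.upper()


@dataclass
class GenomeRecord:
    """An annotated genome: a taxon label, an accession and its CDS set."""

    taxon_label: str
    accession: str = ""
    features: list[CDSFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.taxon_label:
            raise ValueError("taxon_label must be non-empty")


def _has_internal_stop(nt: str, table_id: int) -> bool:
    trimmed = nt[: len(nt) - len(nt) % 3]
    if len(trimmed) < 6:
        return False
    aa = str(Seq(trimmed[:-3]).translate(table=table_id))
    return "*" in aa


def read_genbank(path: str | Path,
                 table_id: int = DEFAULT_TABLE) -> list[GenomeRecord]:
    """Parse a (possibly multi-record) GenBank flat file.

    One :class:`GenomeRecord` per LOCUS.  CDS features without a ``/gene``
    or ``/product`` qualifier are skipped with a logged warning; minus-strand
    features are reverse-complemented and ``join`` locations concatenated in
    annotation order.
    """
    records: list[GenomeRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:
        raise ValueError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not parsed:
        raise ValueError(f"no GenBank records in {path}")
    for rec in parsed:
        organism = rec.annotations.get("organism", "") or rec.id
        genome = GenomeRecord(taxon_label=organism.replace(" ", "_"),
                              accession=rec.id)
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            name = (quals.get("gene") or quals.get("product") or [None])[0]
            if name is None:
                log.warning("%s: CDS at %s has no /gene or /product; skipped",
                            rec.id, feat.location)
                continue
            nt = str(feat.extract(rec.seq)).upper()
            genome.features.append(CDSFeature(
                gene_name=canonical_gene_name(name),
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
                strand="-" if feat.location.strand == -1 else "+",
                nt_seq=nt,
                n_segments=len(feat.location.parts),
                internal_stop=_has_internal_stop(nt, table_id),
            ))
        records.append(genome)
    return records


def translate_longest_orf(nt_seq: str, min_aa: int = MIN_AA_DEFAULT,
                          table_id: int = DEFAULT_TABLE
                          ) -> Optional[str]:
    """Translation of the longest open reading frame, or None if too short.

    All three forward frames are scanned; an ORF is a maximal stop-free
    codon stretch running start-to-stop or to the end of the frame.  Returns
    None when the longest ORF is shorter than ``min_aa`` residues.
    """
    if not nt_seq:
        raise ValueError("empty sequence")
    nt = nt_seq.upper()
    best = ""
    for frame in range(3):
        sub = nt[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        if not sub:
            continue
        aa = str(Seq(sub).translate(table=table_id))
        for segment in aa.split("*"):
            if len(segment) > len(best):
                best = segment
    if len(best) < min_aa:
        return None
    return best


def longest_orf_nt(nt_seq: str, min_aa: int = MIN_AA_DEFAULT,
                   table_id: int = DEFAULT_TABLE) -> Optional[str]:
    """The nucleotide segment underlying the longest ORF (stop excluded).

    Companion to :func:`translate_longest_orf`, used to keep NT and AA
    sequences of a family member in register for back-translation.
    """
    if not nt_seq:
        raise ValueError("empty sequence")
    nt = nt_seq.upper()
    best = ""
    for frame in range(3):
        sub = nt[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        if not sub:
            continue
        aa = str(Seq(sub).translate(table=table_id))
        pos = 0
        for segment in aa.split("*"):
            nt_start = frame + 3 * pos
            cand = nt[nt_start: nt_start + 3 * len(segment)]
            if len(cand) > len(best):
                best = cand
            pos += len(segment) + 1  # skip the stop codon
    if len(best) < 3 * min_aa:
        return None
    return best


def write_cds_fasta(genome: GenomeRecord, path: str | Path) -> None:
    """Write a genome's CDS set as FASTA with ``>taxon|gene`` headers."""
    recs = [
        SeqRecord(Seq(f.nt_seq), id=f"{genome.taxon_label}|{f.gene_name}",
                  description="")
        for f in genome.features
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_cds_fasta(path: str | Path) -> GenomeRecord:
    """Re-read a per-genome CDS FASTA written by :func:`write_cds_fasta`."""
    features = []
    taxon = None
    for rec in SeqIO.parse(str(path), "fasta"):
        t, _, gene = rec.id.partition("|")
        if taxon is None:
            taxon = t
        elif t != taxon:
            raise ValueError(f"mixed taxa in {path}: {taxon!r} vs {t!r}")
        seq = str(rec.seq).upper()
        features.append(CDSFeature(gene_name=gene, start=1, end=len(seq),
                                   strand="+", nt_seq=seq))
    if taxon is None:
        raise ValueError(f"no sequences in {path}")
    return GenomeRecord(taxon_label=taxon, features=features)
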