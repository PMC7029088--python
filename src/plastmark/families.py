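"""Single-copy core gene families and codon alignments.

A gene family collects, per taxon, at most one coding sequence of a given
gene across a genome panel.  The filters mirror common orthology hygiene
for organellar panels: taxa carrying multiple copies of a gene are treated
as paralogous (optionally discarding the whole family), fragmented
annotations (multi-segment CDS) are removed, members whose longest ORF is
shorter than a minimum protein length are dropped, and families present in
fewer than a minimum fraction of the panel are excluded as non-core.

Codon (NT) alignments are obtained by back-translating an amino-acid
alignment onto each member's source codons; an external aligner produces
the AA alignment for real data (synthetic data is generated pre-aligned).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio.Seq import Seq

from .alignment import Alignment
from .genome_io import (DEFAULT_TABLE, MIN_AA_DEFAULT, GenomeRecord,
                        longest_orf_nt, translate_longest_orf)

log = logging.getLogger(__name__)

__all__ = [
    "GeneFamily",
    "FamilyFilterConfig",
    "build_families",
    "back_translate",
]


@dataclass
class GeneFamily:
    """A gene's members across the panel: taxon -> (nt_seq, aa_seq)."""

    gene_name: str
    members: dict[str, tuple[str, str]] = field(default_factory=dict)
    excluded_reason: Optional[str] = None
    # one of: duplicated, fragmented, low_occupancy, short_orf, listed

    @property
    def occupancy(self) -> int:
        return len(self.members)


@dataclass
class FamilyFilterConfig:
    """Filters applied when assembling single-copy core families."""

    min_fraction: float = 0.9       # of the panel size
    min_taxa: Optional[int] = None  # overrides min_fraction when set
    min_aa: int = MIN_AA_DEFAULT
    drop_duplicated: bool = True
    drop_fragmented: bool = True
    excluded_genes: tuple[str, ...] = ()
    table_id: int = DEFAULT_TABLE

    def __post_init__(self) -> None:
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if self.min_aa < 1:
            raise ValueError("min_aa must be >= 1")

    def occupancy_threshold(self, n_genomes: int) -> int:
        if self.min_taxa is not None:
            return self.min_taxa
        import math
        return math.ceil(self.min_fraction * n_genomes)


def build_families(genomes: list[GenomeRecord], cfg: FamilyFilterConfig
                   ) -> tuple[list[GeneFamily], list[GeneFamily]]:
    """Assemble per-gene families and split them into retained / excluded.

    Returns ``(retained, excluded)``; together they partition the gene-name
    universe of the panel.  Exclusion reasons are recorded on the family.
    """
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    labels = [g.taxon_label for g in genomes]
    if len(set(labels)) != len(labels):
        raise ValueError("taxon labels must be unique across the panel")

    by_gene: dict[str, dict[str, list]] = {}
    for genome in genomes:
        for feat in genome.features:
            by_gene.setdefault(feat.gene_name, {}) \
                   .setdefault(genome.taxon_label, []).append(feat)

    excluded_names = {n.strip().lower() for n in cfg.excluded_genes}
    threshold = cfg.occupancy_threshold(len(genomes))
    retained: list[GeneFamily] = []
    excluded: list[GeneFamily] = []
    for gene in sorted(by_gene):
        fam = GeneFamily(gene_name=gene)
        taxa_feats = by_gene[gene]
        if gene in excluded_names:
            fam.excluded_reason = "listed"
            excluded.append(fam)
            continue
        any_duplicated = any(len(fs) > 1 for fs in taxa_feats.values())
        if any_duplicated and cfg.drop_duplicated:
            fam.excluded_reason = "duplicated"
            excluded.append(fam)
            continue
        n_short = 0
        for taxon, feats in sorted(taxa_feats.items()):
            if len(feats) > 1:
                log.info("gene %s: taxon %s has %d copies; member dropped",
                         gene, taxon, len(feats))
                continue
            feat = feats[0]
            if cfg.drop_fragmented and feat.n_segments > 1:
                log.info("gene %s: taxon %s fragmented (%d segments); "
                         "member dropped", gene, taxon, feat.n_segments)
                continue
            aa = translate_longest_orf(feat.nt_seq, min_aa=cfg.min_aa,
                                       table_id=cfg.table_id)
            if aa is None:
                n_short += 1
                continue
            nt = longest_orf_nt(feat.nt_seq, min_aa=cfg.min_aa,
                                table_id=cfg.table_id)
            fam.members[taxon] = (nt, aa)
        if not fam.members and n_short:
            fam.excluded_reason = "short_orf"
            excluded.append(fam)
            continue
        if fam.occupancy < threshold:
            fam.excluded_reason = "low_occupancy"
            excluded.append(fam)
            continue
        retained.append(fam)
    return retained, excluded


def back_translate(aa_msa: Alignment,
                   nt_by_taxon: dict[str, str],
                   table_id: int = DEFAULT_TABLE) -> Alignment:
    """Map an AA alignment back onto the source codons.

    Each residue column expands to its source codon and each gap to
    ``---``; a trailing stop codon on the NT source is trimmed first.  A
    length mismatch between a row's residues and its NT source raises an
    error naming the taxon.
    """
    rows = []
    for taxon, aa_row in aa_msa.items():
        if taxon not in nt_by_taxon:
            raise ValueError(f"no NT sequence for taxon {taxon}")
        nt = nt_by_taxon[taxon].upper()
        n_res = sum(1 for c in aa_row if c != "-")
        if len(nt) == 3 * n_res + 3:
            last = nt[-3:]
            if Seq(last).translate(table=table_id) == "*":
                nt = nt[:-3]
        if len(nt) != 3 * n_res:
            raise ValueError(
                f"taxon {taxon}: NT length {len(nt)} does not match "
                f"{n_res} aligned residues"
            )
        out = []
        k = 0
        for c in aa_row:
            if c == "-":
                out.append("---")
            else:
                out.append(nt[3 * k: 3 * k + 3])
                k += 1
        rows.append("".join(out))
    return Alignment(list(aa_msa.taxa), rows, "nt")
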