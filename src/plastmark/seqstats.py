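"""Per-gene divergence statistics.

Implements the sequence-level quantities used to characterise candidate
marker genes: uncorrected pairwise p-distance (pairwise deletion of gaps and
missing states), the proportion of parsimony-informative columns, pairwise
dN/dS by the Nei-Gojobori (1986) counting method with Jukes-Cantor
correction, pooled GC content, and sliding-window p-distance profiles along
an alignment.

Per-gene summaries take the median across all sequence pairs (the mean is
also reported).  NG86 is a deterministic counting estimator: synonymous site
fractions are computed per codon from the genetic code, averaged between the
two sequences, and multi-step codon differences are averaged over all
minimal mutation paths that avoid stop codons.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from statistics import median
from typing import Iterable, NamedTuple, Optional

from Bio.Data import CodonTable

from .alignment import Alignment

__all__ = [
    "GeneStats",
    "WindowProfile",
    "NG86Result",
    "p_distance_pair",
    "alignment_divergence",
    "parsimony_informative_fraction",
    "ng86_dn_ds",
    "gc_content",
    "sliding_window_profile",
    "compute_gene_stats",
]

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# p-distance


def p_distance_pair(s1: str, s2: str, missing: str = "-N?") -> float:
    """Fraction of mismatching sites among pairwise-comparable sites.

    Sites where either sequence carries a gap or a character in *missing*
    are excluded.  Returns NaN if no site is comparable.
    """
    if len(s1) != len(s2):
        raise ValueError(f"length mismatch: {len(s1)} vs {len(s2)}")
    skip = set(missing.upper())
    compared = mismatches = 0
    for a, b in zip(s1.upper(), s2.upper()):
        if a in skip or b in skip:
            continue
        compared += 1
        if a != b:
            mismatches += 1
    return mismatches / compared if compared else math.nan


def _pairwise_p(aln: Alignment, missing: str) -> list[float]:
    vals = []
    for (i, r1), (j, r2) in itertools.combinations(enumerate(aln.rows), 2):
        p = p_distance_pair(r1, r2, missing=missing)
        if not math.isnan(p):
            vals.append(p)
    return vals


def alignment_divergence(aln: Alignment) -> dict[str, float]:
    """Median, mean and max of all pairwise p-distances of an alignment."""
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 rows")
    missing = "-X?" if aln.alphabet == "aa" else "-N?"
    vals = _pairwise_p(aln, missing)
    if not vals:
        return {"median": math.nan, "mean": math.nan, "max": math.nan}
    return {
        "median": median(vals),
        "mean": sum(vals) / len(vals),
        "max": max(vals),
    }


# ---------------------------------------------------------------------------
# parsimony-informative sites


def parsimony_informative_fraction(aln: Alignment) -> float:
    """Fraction of columns with >= 2 states each present in >= 2 sequences.

    Gaps and missing symbols do not count as states.
    """
    if aln.n_taxa == 0 or aln.length == 0:
        raise ValueError("empty alignment")
    missing = set("-X?" if aln.alphabet == "aa" else "-N?")
    informative = 0
    for j in range(aln.length):
        counts: dict[str, int] = {}
        for r in aln.rows:
            c = r[j]
            if c not in missing:
                counts[c] = counts.get(c, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            informative += 1
    return informative / aln.length


# ---------------------------------------------------------------------------
# NG86 dN/dS


class NG86Result(NamedTuple):
    dn: float
    ds: float
    status: str  # ok | saturated_dn | saturated_ds | saturated_both | undefined


@lru_cache(maxsize=None)
def _codon_map(table_id: int) -> dict[str, str]:
    """codon -> amino acid, stop codons mapped to '*'."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    m = dict(table.forward_table)
    for stop in table.stop_codons:
        m[stop] = "*"
    return m


@lru_cache(maxsize=None)
def _syn_sites(codon: str, table_id: int) -> float:
    """Fractional count of synonymous sites in a codon (0..3).

    Each position contributes the fraction of its three possible single-base
    changes that are synonymous; changes to stop codons count as
    nonsynonymous.
    """
    cmap = _codon_map(table_id)
    aa = cmap[codon]
    s = 0.0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if cmap[mutant] == aa and cmap[mutant] != "*":
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def _path_counts(c1: str, c2: str, table_id: int) -> tuple[float, float]:
    """(syn, nonsyn) substitution counts between two codons, averaged over
    all minimal mutation paths that avoid stop-codon intermediates.

    Falls back to averaging over every path if all of them pass through a
    stop codon.
    """
    cmap = _codon_map(table_id)
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths: list[tuple[float, float, bool]] = []  # (syn, nonsyn, via_stop)
    for order in itertools.permutations(diffs):
        cur = c1
        syn = non = 0.0
        via_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if cmap[nxt] == "*" and nxt != c2:
                via_stop = True
            if cmap[nxt] == cmap[cur]:
                syn += 1.0
            else:
                non += 1.0
            cur = nxt
        paths.append((syn, non, via_stop))
    valid = [p for p in paths if not p[2]] or paths
    syn = sum(p[0] for p in valid) / len(valid)
    non = sum(p[1] for p in valid) / len(valid)
    return syn, non


def _jc_rate(p: float) -> float:
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0


def ng86_dn_ds(c1: str, c2: str, table_id: int = 11) -> NG86Result:
    """Pairwise dN and dS by Nei-Gojobori counting with JC correction.

    Codons containing gaps, ambiguity characters or stop codons in either
    sequence are skipped pairwise.  ``status`` flags saturation (pN or pS >=
    3/4 makes the corresponding rate infinite) and the fully-undefined case
    of no comparable codons.
    """
    if len(c1) != len(c2):
        raise ValueError("sequences must have equal length")
    if len(c1) % 3 != 0:
        raise ValueError("length must be divisible by 3")
    c1, c2 = c1.upper(), c2.upper()
    cmap = _codon_map(table_id)
    s_sites = n_sites = sd = nd = 0.0
    n_codons = 0
    for k in range(0, len(c1), 3):
        a, b = c1[k:k + 3], c2[k:k + 3]
        if any(ch not in _BASES for ch in a + b):
            continue
        if cmap[a] == "*" or cmap[b] == "*":
            continue
        n_codons += 1
        s = 0.5 * (_syn_sites(a, table_id) + _syn_sites(b, table_id))
        s_sites += s
        n_sites += 3.0 - s
        psyn, pnon = _path_counts(a, b, table_id)
        sd += psyn
        nd += pnon
    if n_codons == 0:
        return NG86Result(math.nan, math.nan, "undefined")
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    dn, ds = _jc_rate(pn), _jc_rate(ps)
    status = "ok"
    if math.isinf(dn) and math.isinf(ds):
        status = "saturated_both"
    elif math.isinf(dn):
        status = "saturated_dn"
    elif math.isinf(ds):
        status = "saturated_ds"
    return NG86Result(dn, ds, status)


# ---------------------------------------------------------------------------
# GC content


def gc_content(seqs: Iterable[str] | str) -> float:
    """Pooled (G+C)/(A+C+G+T) over one or more ungapped DNA sequences.

    Ambiguity codes and gaps are excluded from both numerator and
    denominator; NaN if no unambiguous base is present.
    """
    if isinstance(seqs, str):
        seqs = [seqs]
    gc = total = 0
    for s in seqs:
        for ch in s.upper():
            if ch in "GC":
                gc += 1
                total += 1
            elif ch in "AT":
                total += 1
    return gc / total if total else math.nan


# ---------------------------------------------------------------------------
# sliding window profile


@dataclass
class WindowProfile:
    """Mean pairwise p-distance in successive alignment windows."""

    gene_name: str
    window: int
    step: int
    aln_len: int
    values: list[tuple[int, float]] = field(default_factory=list)
    # values: (start0, mean pairwise p-distance); NaN for all-gap windows


def sliding_window_profile(aln: Alignment, window: int = 30,
                           step: int = 1,
                           gene_name: str = "") -> WindowProfile:
    """Profile of mean pairwise p-distance along the alignment.

    Windows start at 0, step, 2*step, ...; a trailing partial window is kept
    only if it spans at least half the window width.
    """
    if window > aln.length:
        raise ValueError(f"window {window} exceeds alignment length {aln.length}")
    if step < 1:
        raise ValueError("step must be >= 1")
    missing = "-X?" if aln.alphabet == "aa" else "-N?"
    values: list[tuple[int, float]] = []
    for start in range(0, aln.length, step):
        width = min(window, aln.length - start)
        if width < window and width < window / 2:
            break
        sub = aln.slice(start, start + width)
        vals = _pairwise_p(sub, missing)
        values.append((start, sum(vals) / len(vals) if vals else math.nan))
        if start + width >= aln.length:
            break
    return WindowProfile(gene_name, window, step, aln.length, values)


# ---------------------------------------------------------------------------
# per-gene summary


@dataclass
class GeneStats:
    """Summary statistics for one gene family's alignments."""

    gene_name: str
    p_distance: float       # median pairwise NT p-distance
    p_distance_mean: float
    pi_fraction: float      # parsimony-informative proportion (NT)
    dn: float               # median pairwise NG86 dN
    ds: float               # median pairwise NG86 dS
    gc: float
    aln_len_nt: int
    aln_len_aa: int
    n_taxa: int = 0
    n_saturated_pairs: int = 0


def _median_defined(vals: list[float]) -> float:
    finite = [v for v in vals if not (math.isnan(v) or math.isinf(v))]
    return median(finite) if finite else math.nan


def compute_gene_stats(gene_name: str, nt_aln: Alignment,
                       aa_aln: Optional[Alignment] = None,
                       table_id: int = 11,
                       codon_aware: bool = True) -> GeneStats:
    """Compute the per-gene statistics bundle from a codon NT alignment.

    dN/dS is computed over all sequence pairs when the alignment length is a
    codon multiple and ``codon_aware`` is set; otherwise left NaN.
    """
    div = alignment_divergence(nt_aln)
    pi = parsimony_informative_fraction(nt_aln)
    gc = gc_content(r.replace("-", "") for r in nt_aln.rows)
    dns: list[float] = []
    dss: list[float] = []
    saturated = 0
    if codon_aware and nt_aln.length % 3 == 0:
        for r1, r2 in itertools.combinations(nt_aln.rows, 2):
            res = ng86_dn_ds(r1, r2, table_id=table_id)
            if res.status.startswith("saturated"):
                saturated += 1
            dns.append(res.dn)
            dss.append(res.ds)
    return GeneStats(
        gene_name=gene_name,
        p_distance=div["median"],
        p_distance_mean=div["mean"],
        pi_fraction=pi,
        dn=_median_defined(dns),
        ds=_median_defined(dss),
        gc=gc,
        aln_len_nt=nt_aln.length,
        aln_len_aa=aa_aln.length if aa_aln is not None else nt_aln.length // 3,
        n_taxa=nt_aln.n_taxa,
        n_saturated_pairs=saturated,
    )
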