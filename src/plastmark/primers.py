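"""Degenerate PCR primer proposal from conserved alignment regions.

Conserved windows are read off a sliding-window p-distance profile; within
a window a degenerate consensus is built under a majority ("50% consensus")
rule: every base whose column frequency reaches the threshold is included,
and if none does, bases are added in descending frequency (ties broken
alphabetically) until the included set covers the threshold.  The included
set is written as its IUPAC ambiguity code.  Forward/reverse primer pairs
are proposed for window pairs whose span yields an amplicon in a
Sanger-friendly length range (500-1000 bp by default), the reverse primer
being the IUPAC-aware reverse complement of the downstream window's
consensus.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .alignment import Alignment
from .seqstats import WindowProfile

__all__ = [
    "ConservedWindow",
    "PrimerCandidate",
    "IUPAC_CODES",
    "consensus_degenerate",
    "degeneracy",
    "reverse_complement_iupac",
    "find_conserved_windows",
    "propose_primer_pairs",
]

IUPAC_CODES: dict[frozenset[str], str] = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}
IUPAC_SETS: dict[str, frozenset[str]] = {v: k for k, v in IUPAC_CODES.items()}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _complement_code(code: str) -> str:
    bases = IUPAC_SETS[code]
    return IUPAC_CODES[frozenset(_COMPLEMENT[b] for b in bases)]


def reverse_complement_iupac(s: str) -> str:
    """Reverse complement of a degenerate DNA string (all 15 IUPAC codes)."""
    return "".join(_complement_code(c) for c in reversed(s.upper()))


def degeneracy(consensus: str) -> int:
    """Product of per-position ambiguity-set sizes."""
    d = 1
    for c in consensus.upper():
        d *= len(IUPAC_SETS[c])
    return d


def consensus_degenerate(columns: Alignment | Sequence[str],
                         threshold: float = 0.5) -> str:
    """Degenerate IUPAC consensus of an alignment slice.

    Per column, every base with frequency >= ``threshold`` is included; if
    none reaches it, the most frequent bases (descending, ties alphabetical)
    are added until their cumulative frequency reaches the threshold.  Gaps
    are ignored in the frequencies; an all-gap column yields 'N'.
    """
    rows = columns.rows if isinstance(columns, Alignment) else list(columns)
    if not rows or not rows[0]:
        raise ValueError("empty alignment slice")
    length = len(rows[0])
    out = []
    for j in range(length):
        counts = {b: 0 for b in "ACGT"}
        total = 0
        for r in rows:
            c = r[j].upper()
            if c == "-":
                continue
            if c not in counts:
                raise ValueError(f"non-DNA residue {c!r} in column {j}")
            counts[c] += 1
            total += 1
        if total == 0:
            out.append("N")
            continue
        freqs = {b: n / total for b, n in counts.items() if n > 0}
        included = {b for b, f in freqs.items() if f >= threshold}
        if not included:
            cum = 0.0
            for b in sorted(freqs, key=lambda b: (-freqs[b], b)):
                included.add(b)
                cum += freqs[b]
                if cum >= threshold:
                    break
        out.append(IUPAC_CODES[frozenset(included)])
    return "".join(out)


@dataclass
class ConservedWindow:
    """A low-divergence alignment interval, 0-based half-open columns."""

    gene_name: str
    start0: int
    end0: int
    mean_p_dist: float

    @property
    def length(self) -> int:
        return self.end0 - self.start0


@dataclass
class PrimerCandidate:
    window: ConservedWindow
    orientation: str            # forward | reverse
    consensus: str              # reverse primers already reverse-complemented
    degeneracy: int
    gc_range: tuple[float, float]


def find_conserved_windows(profile: WindowProfile, max_p_dist: float,
                           min_len: int = 18) -> list[ConservedWindow]:
    """Maximal runs of profile windows with p-distance <= ``max_p_dist``.

    Runs of consecutive window starts are merged into one interval spanning
    from the first window's start to the last window's end; intervals
    shorter than ``min_len`` columns are dropped.  Sorted by mean
    p-distance, most conserved first.
    """
    if not profile.values:
        raise ValueError("empty profile")
    runs: list[list[tuple[int, float]]] = []
    current: list[tuple[int, float]] = []
    prev_start = None
    for start, p in profile.values:
        ok = not math.isnan(p) and p <= max_p_dist
        contiguous = prev_start is not None and start - prev_start <= profile.step
        if ok and (not current or contiguous):
            current.append((start, p))
        elif ok:
            runs.append(current)
            current = [(start, p)]
        elif current:
            runs.append(current)
            current = []
        prev_start = start
    if current:
        runs.append(current)
    windows = []
    for run in runs:
        start0 = run[0][0]
        end0 = min(run[-1][0] + profile.window, profile.aln_len)
        if end0 - start0 < min_len:
            continue
        mean_p = sum(p for _, p in run) / len(run)
        windows.append(ConservedWindow(profile.gene_name, start0, end0, mean_p))
    windows.sort(key=lambda w: (w.mean_p_dist, w.start0))
    return windows


def _gc_range(consensus: str) -> tuple[float, float]:
    n = len(consensus)
    lo = sum(1 for c in consensus if IUPAC_SETS[c] <= frozenset("GC"))
    hi = sum(1 for c in consensus if IUPAC_SETS[c] & frozenset("GC"))
    return lo / n, hi / n


def _make_primer(aln: Alignment, window: ConservedWindow, orientation: str,
                 primer_len: tuple[int, int],
                 threshold: float) -> PrimerCandidate:
    lo, hi = primer_len
    length = min(hi, window.length)
    if orientation == "forward":
        sl = aln.slice(window.start0, window.start0 + length)
        consensus = consensus_degenerate(sl, threshold)
    else:
        sl = aln.slice(window.end0 - length, window.end0)
        consensus = reverse_complement_iupac(consensus_degenerate(sl, threshold))
    return PrimerCandidate(
        window=window, orientation=orientation, consensus=consensus,
        degeneracy=degeneracy(consensus), gc_range=_gc_range(consensus),
    )


def propose_primer_pairs(windows: Sequence[ConservedWindow], aln: Alignment,
                         amplicon_range: tuple[int, int] = (500, 1000),
                         primer_len: tuple[int, int] = (18, 30),
                         max_degeneracy: int = 512,
                         threshold: float = 0.5
                         ) -> list[tuple[PrimerCandidate, PrimerCandidate, int]]:
    """All forward/reverse primer pairs with an in-range expected amplicon.

    The amplicon length is measured in alignment columns from the forward
    primer's 5' start (upstream window start) to the reverse primer's 5'
    start (downstream window end).  Pairs in which either primer exceeds
    ``max_degeneracy`` are dropped; the list is sorted by combined
    degeneracy, then amplicon length.
    """
    lo_len, hi_len = amplicon_range
    min_primer = primer_len[0]
    usable = [w for w in sorted(windows, key=lambda w: w.start0)
              if w.length >= min_primer]
    out = []
    for wi, wj in itertools.combinations(usable, 2):
        amplicon = wj.end0 - wi.start0
        if not lo_len <= amplicon <= hi_len:
            continue
        fwd = _make_primer(aln, wi, "forward", primer_len, threshold)
        rev = _make_primer(aln, wj, "reverse", primer_len, threshold)
        if fwd.degeneracy > max_degeneracy or rev.degeneracy > max_degeneracy:
            continue
        out.append((fwd, rev, amplicon))
    out.sort(key=lambda t: (t[0].degeneracy * t[1].degeneracy, t[2]))
    return out
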