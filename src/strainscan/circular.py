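"""Circular contig repair and pairwise comparison.

Assemblies of circular molecules (mitogenomes, plasmids) are emitted as
linear contigs; reads spanning the origin make the assembler walk around
the circle more than once, leaving a spurious copy of the start of the
contig at its end. This module detects that terminal self-overlap, trims
it to recover the single-copy circle, rotates circles to a shared gene
anchor so two strains can be compared base-for-base, and reports global
pairwise identity together with large indel intervals.

Pairwise comparison uses banded global alignment with affine gap
penalties (match +1, mismatch -1, gap open -4, gap extend -1), which
keeps long strain-specific insertions as contiguous gap runs; identity is
match columns over all alignment columns (gap columns included in the
denominator by default — the convention is configurable because
published identity figures rarely state theirs). Reported indel
coordinates are 1-based inclusive in the ungapped frame of the sequence
bearing the extra bases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from ._affine import affine_align
from .genome import revcomp

DEFAULT_MIN_OVERLAP = 50
DEFAULT_MAX_MISMATCH_RATE = 0.05
DEFAULT_MIN_REPORT_LEN = 50

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class CircularContig:
    name: str
    sequence: str
    is_trimmed: bool = False
    trimmed_bases: int = 0
    rotation_offset: int = 0

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Indel:
    """A gap run of the global alignment, attributed to the sequence that
    carries the extra bases ('a' or 'b'); start/end 1-based inclusive."""

    bearer: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PairwiseComparison:
    identity: float  # percent over alignment columns
    alignment_length: int
    matches: int
    mismatches: int
    gap_columns: int
    indels: list[Indel] = field(default_factory=list)


def interval_length(start: int, end: int) -> int:
    """Length of a 1-based inclusive coordinate interval (the convention
    used for every reported indel)."""
    if end < start:
        raise ValueError(f"end {end} before start {start}")
    return end - start + 1


# ---------------------------------------------------------------------------
# trimming


def detect_terminal_overlap(
    contig: CircularContig | str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> int:
    """Length of the longest suffix matching a prefix of the same contig
    (mismatch rate at most ``max_mismatch_rate``), or 0 if none reaches
    ``min_overlap``. This is the signature of circular over-assembly."""
    if min_overlap < 20:
        raise ValueError("min_overlap < 20 invites spurious matches")
    seq = contig.sequence if isinstance(contig, CircularContig) else contig
    n = len(seq)
    if n <= 2 * min_overlap:
        raise ValueError(f"contig of {n} bp too short for min_overlap {min_overlap}")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for m in range(n // 2, min_overlap - 1, -1):
        mism = int(np.count_nonzero(arr[:m] != arr[-m:]))
        if mism <= max_mismatch_rate * m:
            return m
    return 0


def trim_circular(contig: CircularContig | str, overlap: int) -> CircularContig:
    """Remove the duplicated suffix; idempotent (re-detection on the result
    returns 0)."""
    if isinstance(contig, str):
        contig = CircularContig("contig", contig)
    if overlap < 0 or overlap >= len(contig.sequence):
        raise ValueError(f"overlap {overlap} outside [0, {len(contig.sequence)})")
    if overlap == 0:
        return contig
    return CircularContig(
        name=contig.name,
        sequence=contig.sequence[: len(contig.sequence) - overlap],
        is_trimmed=True,
        trimmed_bases=contig.trimmed_bases + overlap,
        rotation_offset=contig.rotation_offset,
    )


# ---------------------------------------------------------------------------
# rotation


def _circular_occurrences(seq: str, probe: str) -> list[int]:
    """Start offsets (mod len(seq)) of ``probe`` in the circular sequence."""
    if len(probe) > len(seq):
        return []
    doubled = seq + seq[: len(probe) - 1]
    return [m.start() for m in re.finditer(f"(?={re.escape(probe)})", doubled)]


def rotate_to_anchor(contig: CircularContig | str, anchor: str) -> CircularContig:
    """Linearize a circular contig so it starts at the unique occurrence of
    ``anchor`` (reverse-complementing first if the hit is on the minus
    strand). Raises if the anchor occurs zero or multiple times."""
    if isinstance(contig, str):
        contig = CircularContig("contig", contig)
    seq = contig.sequence
    fwd = _circular_occurrences(seq, anchor)
    rev = _circular_occurrences(seq, revcomp(anchor))
    total = len(fwd) + len(rev)
    if total != 1:
        raise ValueError(
            f"anchor occurs {total} times in {contig.name} (need exactly 1)"
        )
    if rev:
        seq = revcomp(seq)
        fwd = _circular_occurrences(seq, anchor)
    off = fwd[0]
    return CircularContig(
        name=contig.name,
        sequence=seq[off:] + seq[:off],
        is_trimmed=contig.is_trimmed,
        trimmed_bases=contig.trimmed_bases,
        rotation_offset=off,
    )


# ---------------------------------------------------------------------------
# pairwise comparison


def _cigar_ops(cigar: str) -> Iterable[tuple[int, str]]:
    for n, op in _CIGAR_RE.findall(cigar):
        yield int(n), op


def compare_pair(
    a: CircularContig | str,
    b: CircularContig | str,
    min_report_len: int = DEFAULT_MIN_REPORT_LEN,
    count_gap_columns: bool = True,
    match: int = 1,
    mismatch: int = 1,
    gap_open: int = 4,
    gap_ext: int = 1,
) -> PairwiseComparison:
    """Global affine-gap alignment report for two sequences (each at most
    100 kb).

    identity = match columns / alignment columns * 100; with
    ``count_gap_columns=False`` gap columns are dropped from the
    denominator. Gap runs of at least ``min_report_len`` are reported as
    indels located in the ungapped frame of the sequence bearing the
    insertion (adjacent gap ops are merged first)."""
    sa = a.sequence if isinstance(a, CircularContig) else a
    sb = b.sequence if isinstance(b, CircularContig) else b
    if not sa or not sb:
        raise ValueError("empty sequence")
    if len(sa) > 100_000 or len(sb) > 100_000:
        raise ValueError("sequences longer than 100 kb are not supported")
    # 'I': bases only in a; 'D': bases only in b
    ops = affine_align(sa, sb, match=match, mismatch=mismatch,
                       gap_open=gap_open, gap_ext=gap_ext)

    matches = mismatches = gaps = 0
    pos_a = pos_b = 0  # 0-based consumed bases
    indels: list[Indel] = []
    for n, op in ops:
        if op == "=":
            matches += n
            pos_a += n
            pos_b += n
        elif op in ("X", "M"):
            mismatches += n
            pos_a += n
            pos_b += n
        elif op == "I":  # bases present only in a
            gaps += n
            if n >= min_report_len:
                indels.append(Indel("a", pos_a + 1, pos_a + n))
            pos_a += n
        elif op == "D":  # bases present only in b
            gaps += n
            if n >= min_report_len:
                indels.append(Indel("b", pos_b + 1, pos_b + n))
            pos_b += n
    columns = matches + mismatches + gaps
    denom = columns if count_gap_columns else matches + mismatches
    identity = 100.0 * matches / denom if denom else 0.0
    return PairwiseComparison(
        identity=identity,
        alignment_length=columns,
        matches=matches,
        mismatches=mismatches,
        gap_columns=gaps,
        indels=indels,
    )


def comparison_report(cmp: PairwiseComparison) -> dict:
    return {
        "identity_pct": round(cmp.identity, 4),
        "alignment_columns": cmp.alignment_length,
        "matches": cmp.matches,
        "mismatches": cmp.mismatches,
        "gap_columns": cmp.gap_columns,
        "indels": [
            {
                "bearer": iv.bearer,
                "start": iv.start,
                "end": iv.end,
                "length": iv.length,
            }
            for iv in cmp.indels
        ],
    }
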