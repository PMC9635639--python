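"""Classify discontinuities between adjacent one-to-one alignment blocks.

Each junction between reference-adjacent blocks yields exactly one
breakpoint record, so multi-junction events (inversions, relocations)
count at least twice — the tallies are a census of alignment
discontinuities, not an estimate of evolutionary event counts.

Taxonomy, applied in order at each junction (left block A, right block B
on the same reference chromosome):

* query re-uses already-covered query sequence  -> DUP_IN_REF
* query chromosome changes                      -> RELOC_DIFF
* strand changes                                -> INVERSION
* query order violates the strand expectation,
  or the query jump exceeds ``jump_threshold``  -> RELOC_SAME
* otherwise delta = qryGap - refGap:
  positive -> INS_IN_QUERY, negative -> DEL_IN_QUERY, zero -> GAP

Chromosome termini with more than ``min_end_len`` unaligned reference
sequence each contribute one OTHER breakpoint.

Reported coordinates are 1-based inclusive; internal ones 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .align import AlignmentBlock

KINDS = (
    "GAP",
    "DEL_IN_QUERY",
    "INS_IN_QUERY",
    "RELOC_SAME",
    "RELOC_DIFF",
    "INVERSION",
    "DUP_IN_REF",
    "OTHER",
)

#: human-readable row labels for the tally table
KIND_LABELS = {
    "GAP": "Alignment gap",
    "DEL_IN_QUERY": "Deletion in query",
    "INS_IN_QUERY": "Insertion in query",
    "RELOC_SAME": "Relocation (same chromosome)",
    "RELOC_DIFF": "Relocation (different chromosome)",
    "DUP_IN_REF": "Duplication in reference",
    "INVERSION": "Inversion (with possible relocation)",
    "OTHER": "Other breakpoint",
}

DEFAULT_JUMP_THRESHOLD = 100_000
DEFAULT_MIN_END_LEN = 10_000
_TOL = 50  # slack for order checks / query re-use, matches filter overlap tol


@dataclass(frozen=True)
class Breakpoint:
    ref_chrom: str
    ref_pos: int  # 0-based position of the junction (refEnd of left block)
    kind: str
    ref_gap: int | None = None
    qry_gap: int | None = None
    delta: int | None = None  # qry_gap - ref_gap; only for gap-class kinds
    left_block: int | None = None
    right_block: int | None = None


def _qry_gap(a: AlignmentBlock, b: AlignmentBlock) -> int:
    if a.strand == "+":
        return b.qry_start - a.qry_end
    return a.qry_start - b.qry_end


def classify_junctions(
    blocks: list[AlignmentBlock],
    ref_lengths: dict[str, int] | None = None,
    jump_threshold: int = DEFAULT_JUMP_THRESHOLD,
    min_end_len: int = DEFAULT_MIN_END_LEN,
) -> list[Breakpoint]:
    """One classified breakpoint per junction between reference-adjacent
    blocks; blocks must be one-to-one filtered (sorted, non-overlapping).

    ``ref_lengths`` enables the terminal OTHER breakpoints; without it
    termini are not assessed.
    """
    by_chrom: dict[str, list[tuple[int, AlignmentBlock]]] = {}
    for i, b in enumerate(blocks):
        by_chrom.setdefault(b.ref_chrom, []).append((i, b))
    for chrom, items in by_chrom.items():
        for (_, a), (_, b) in zip(items, items[1:]):
            if b.ref_start < a.ref_start:
                raise ValueError(f"blocks not sorted by reference position on {chrom}")
            if a.ref_end - b.ref_start > _TOL:
                raise ValueError(
                    f"blocks overlap on reference at {chrom}:{b.ref_start}; "
                    "run one-to-one filtering first"
                )

    seen_qry: dict[str, IntervalTree] = {}
    out: list[Breakpoint] = []
    for chrom, items in by_chrom.items():
        first = items[0][1]
        seen_qry.setdefault(first.qry_chrom, IntervalTree()).addi(
            first.qry_start, first.qry_end
        )
        for (ia, a), (ib, b) in zip(items, items[1:]):
            pos = a.ref_end
            kind = None
            tree = seen_qry.setdefault(b.qry_chrom, IntervalTree())
            reused = sum(
                min(iv.end, b.qry_end) - max(iv.begin, b.qry_start)
                for iv in tree.overlap(b.qry_start, b.qry_end)
            )
            if reused > _TOL:
                kind = "DUP_IN_REF"
            elif a.qry_chrom != b.qry_chrom:
                kind = "RELOC_DIFF"
            elif a.strand != b.strand:
                kind = "INVERSION"
            else:
                qgap = _qry_gap(a, b)
                if qgap < -_TOL or abs(qgap) > jump_threshold:
                    kind = "RELOC_SAME"
            if kind is not None:
                out.append(Breakpoint(chrom, pos, kind, left_block=ia, right_block=ib))
            else:
                rgap = b.ref_start - a.ref_end
                qgap = _qry_gap(a, b)
                delta = qgap - rgap
                if delta > 0:
                    kind = "INS_IN_QUERY"
                elif delta < 0:
                    kind = "DEL_IN_QUERY"
                else:
                    kind = "GAP"
                out.append(
                    Breakpoint(chrom, pos, kind, ref_gap=rgap, qry_gap=qgap,
                               delta=delta, left_block=ia, right_block=ib)
                )
            seen_qry.setdefault(b.qry_chrom, IntervalTree()).addi(b.qry_start, b.qry_end)

    if ref_lengths:
        for chrom, items in by_chrom.items():
            length = ref_lengths.get(chrom)
            if length is None:
                continue
            first = items[0][1]
            last = items[-1][1]
            if first.ref_start > min_end_len:
                out.append(Breakpoint(chrom, 0, "OTHER"))
            if length - last.ref_end > min_end_len:
                out.append(Breakpoint(chrom, last.ref_end, "OTHER"))
    out.sort(key=lambda bp: (bp.ref_chrom, bp.ref_pos))
    return out


# ---------------------------------------------------------------------------
# tallies


def tally(breakpoints: list[Breakpoint], chroms: list[str] | None = None) -> pd.DataFrame:
    """Count breakpoints by (kind x reference chromosome) plus a Total
    column; the Alignment-gap row is the whole gap class (deletions +
    insertions + zero-delta gaps)."""
    if chroms is None:
        chroms = sorted({bp.ref_chrom for bp in breakpoints})
    counts = {kind: {c: 0 for c in chroms} for kind in KINDS}
    for bp in breakpoints:
        if bp.ref_chrom in counts[bp.kind]:
            counts[bp.kind][bp.ref_chrom] += 1
    matrix = {
        kind: {c: counts[kind][c] for c in chroms} for kind in KINDS if kind != "GAP"
    }
    gap_row = {
        c: counts["GAP"][c] + counts["DEL_IN_QUERY"][c] + counts["INS_IN_QUERY"][c]
        for c in chroms
    }
    rows = {"GAP": gap_row, **matrix}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=chroms)
    df = df.loc[list(KINDS)]
    return aggregate_counts(df)


def aggregate_counts(per_chrom: pd.DataFrame) -> pd.DataFrame:
    """Append the Total column (row sums over chromosomes) to a per-
    chromosome breakpoint count matrix.

    Accepts any kind-by-chromosome integer matrix, so published per-
    chromosome counts can be totalled with the same code path used for
    computed breakpoints.
    """
    df = per_chrom.copy()
    if "Total" in df.columns:
        df = df.drop(columns=["Total"])
    df["Total"] = df.sum(axis=1)
    return df


def tally_to_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    labeled = df.rename(index=KIND_LABELS)
    labeled.to_csv(path, sep="\t", index_label="breakpoint_class")
    return path


def breakpoints_table(breakpoints: list[Breakpoint]) -> pd.DataFrame:
    """1-based breakpoint report."""
    return pd.DataFrame(
        [
            {
                "refChrom": bp.ref_chrom,
                "refPos": bp.ref_pos + 1,
                "kind": bp.kind,
                "refGap": bp.ref_gap if bp.ref_gap is not None else ".",
                "qryGap": bp.qry_gap if bp.qry_gap is not None else ".",
                "delta": bp.delta if bp.delta is not None else ".",
                "leftBlock": bp.left_block if bp.left_block is not None else ".",
                "rightBlock": bp.right_block if bp.right_block is not None else ".",
            }
            for bp in breakpoints
        ],
        columns=["refChrom", "refPos", "kind", "refGap", "qryGap", "delta",
                 "leftBlock", "rightBlock"],
    )


# ---------------------------------------------------------------------------
# truth recovery


#: breakpoint kinds that can legitimately flag each planted SV class
_EXPECTED_KINDS = {
    "deletion": {"DEL_IN_QUERY"},
    "insertion": {"INS_IN_QUERY"},
    "tandem_dup": {"INS_IN_QUERY"},
    "inversion": {"INVERSION"},
    "relocation_same": {"RELOC_SAME"},
    "relocation_diff": {"RELOC_DIFF"},
}


def _expected_positions(row) -> list[int]:
    kind = row.kind
    if kind in ("deletion", "insertion", "tandem_dup"):
        return [row.ref_start]
    # two junctions: both edges of the affected interval
    return [row.ref_start, row.ref_end]


def recover_sv_calls(
    breakpoints: list[Breakpoint], truth_sv: pd.DataFrame, tolerance: int = 200
) -> pd.DataFrame:
    """Match planted SVs against classified breakpoints.

    A planted event is recovered when every expected junction position has
    a breakpoint of an acceptable kind within ``tolerance`` bp on the same
    reference chromosome. Returns one row per SV class with planted,
    recovered, detected-call and precision/recall columns (NaN where
    undefined).
    """
    by_kind: dict[str, list[Breakpoint]] = {}
    for bp in breakpoints:
        by_kind.setdefault(bp.kind, []).append(bp)

    rows = []
    used: set[int] = set()
    classes = list(dict.fromkeys(truth_sv["kind"])) if len(truth_sv) else []
    for cls in classes:
        events = truth_sv[truth_sv["kind"] == cls]
        ok_kinds = _EXPECTED_KINDS[cls]
        cand = [bp for k in ok_kinds for bp in by_kind.get(k, [])]
        recovered = 0
        for row in events.itertuples(index=False):
            hits = []
            for pos in _expected_positions(row):
                match = next(
                    (
                        bp
                        for bp in cand
                        if bp.ref_chrom == row.ref_chrom and abs(bp.ref_pos - pos) <= tolerance
                    ),
                    None,
                )
                hits.append(match)
            if all(h is not None for h in hits):
                recovered += 1
                used.update(id(h) for h in hits)
        detected = sum(len(by_kind.get(k, [])) for k in ok_kinds)
        planted = len(events)
        rows.append(
            {
                "class": cls,
                "planted": planted,
                "recovered": recovered,
                "detected_breakpoints": detected,
                "recall": recovered / planted if planted else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["class", "planted", "recovered",
                                       "detected_breakpoints", "recall"])
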