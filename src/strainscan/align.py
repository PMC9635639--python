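"""Whole-genome alignment by unique exact anchors plus chaining.

The aligner follows the classic maximal-unique-match recipe: find exact
matches whose seed k-mer occurs exactly once in each genome (both strands
of the query are scanned), chain co-linear anchors into alignment blocks,
and finally filter the blocks to a one-to-one set in which every
reference base and every query base is covered at most once.

Block identity is estimated as anchor-covered bases over the larger of
the two spans — an approximation of alignment identity that is accurate
on genomes whose divergence is dominated by well-spaced point variants,
which is the regime this desk-scale aligner targets. It is not a
substitute for full dynamic-programming extension on repeat-rich real
genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeSet, revcomp, seq_to_codes

DEFAULT_K = 21
DEFAULT_MAX_GAP = 2000
DEFAULT_MAX_DRIFT = 500
DEFAULT_MIN_LEN = 10_000
DEFAULT_MIN_ID = 0.85
OVERLAP_TOL = 50

# exact one-to-one selection is used for conflict components up to this
# many blocks; larger components fall back to greedy-by-score
_EXACT_COMPONENT_LIMIT = 32
# chain DP looks at most this many sorted predecessors per anchor
_CHAIN_LOOKBACK = 200


@dataclass(frozen=True)
class Anchor:
    """Maximal exact match between the genomes.

    Coordinates are 0-based on the forward strand of each genome; for
    strand '-' the anchor sequence matches the reverse complement of the
    query interval.
    """

    ref_chrom: str
    ref_start: int
    qry_chrom: str
    qry_start: int
    length: int
    strand: str

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length

    @property
    def qry_end(self) -> int:
        return self.qry_start + self.length


@dataclass(frozen=True)
class AlignmentBlock:
    """A chained local alignment between the two genomes."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    strand: str
    identity: float
    aligned_length: int

    @property
    def score(self) -> float:
        return self.aligned_length * self.identity

    def __post_init__(self) -> None:
        if self.ref_end <= self.ref_start or self.qry_end <= self.qry_start:
            raise ValueError("degenerate block interval")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")


# ---------------------------------------------------------------------------
# anchor finding


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack each k-mer of a 2-bit coded sequence into a uint64."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    c = codes.astype(np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | c[j : j + n]
    return out


def _concat_codes(genome: GenomeSet, k: int, rc: bool = False):
    """K-mer codes of all chromosomes concatenated, with a global position
    array (gapped between chromosomes so runs cannot cross boundaries)."""
    code_arrays, pos_arrays, meta = [], [], []
    offset = 0
    for name in genome.names:
        seq = genome[name] if not rc else revcomp(genome[name])
        codes = seq_to_codes(seq)
        km = _kmer_codes(codes, k)
        code_arrays.append(km)
        pos_arrays.append(np.arange(offset, offset + len(km), dtype=np.int64))
        meta.append((name, offset, len(seq)))
        offset += len(seq) + k + 10
    if code_arrays:
        return np.concatenate(code_arrays), np.concatenate(pos_arrays), meta
    return np.empty(0, np.uint64), np.empty(0, np.int64), meta


def _unique_entries(codes: np.ndarray, pos: np.ndarray):
    """Restrict to k-mer codes occurring exactly once; returns codes sorted
    ascending with their positions."""
    order = np.argsort(codes, kind="stable")
    sc, sp = codes[order], pos[order]
    if len(sc) == 0:
        return sc, sp
    new = np.empty(len(sc), dtype=bool)
    new[0] = True
    np.not_equal(sc[1:], sc[:-1], out=new[1:])
    starts = np.flatnonzero(new)
    counts = np.diff(np.append(starts, len(sc)))
    singles = starts[counts == 1]
    return sc[singles], sp[singles]


def _locate(meta, gpos: int):
    for name, offset, length in meta:
        if offset <= gpos < offset + length:
            return name, gpos - offset
    raise ValueError(f"global position {gpos} outside genome")


def find_unique_anchors(ref: GenomeSet, qry: GenomeSet, k: int = DEFAULT_K) -> list[Anchor]:
    """All maximal exact matches seeded by a k-mer unique in both genomes.

    Query uniqueness is counted across both strands; matches on the
    reverse strand are reported with strand '-' in forward coordinates.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    if ref.total_length() == 0 or qry.total_length() == 0:
        return []

    r_codes, r_pos, r_meta = _concat_codes(ref, k)
    qf_codes, qf_pos, q_meta = _concat_codes(qry, k)
    qr_codes, qr_pos, qr_meta = _concat_codes(qry, k, rc=True)

    ru_codes, ru_pos = _unique_entries(r_codes, r_pos)
    # query uniqueness across forward + reverse strands together
    q_all = np.concatenate([qf_codes, qr_codes])
    q_pos_all = np.concatenate([qf_pos, qr_pos])
    q_isrc = np.concatenate(
        [np.zeros(len(qf_codes), dtype=bool), np.ones(len(qr_codes), dtype=bool)]
    )
    qu_codes, qu_idx = _unique_entries(q_all, np.arange(len(q_all), dtype=np.int64))
    qu_pos = q_pos_all[qu_idx]
    qu_rc = q_isrc[qu_idx]
    del q_all, q_pos_all, q_isrc

    _, ri, qi = np.intersect1d(ru_codes, qu_codes, assume_unique=True, return_indices=True)
    m_rpos = ru_pos[ri]
    m_qpos = qu_pos[qi]
    m_rc = qu_rc[qi]

    anchors: list[Anchor] = []
    ref_seqs = {n: ref[n] for n in ref.names}
    qf_seqs = {n: qry[n] for n in qry.names}
    qr_seqs = {n: revcomp(qry[n]) for n in qry.names}

    for is_rc in (False, True):
        sel = m_rc == is_rc
        rpos, qpos = m_rpos[sel], m_qpos[sel]
        if len(rpos) == 0:
            continue
        diag = rpos - qpos
        order = np.lexsort((rpos, diag))
        rpos, qpos, diag = rpos[order], qpos[order], diag[order]
        breaks = np.flatnonzero((np.diff(diag) != 0) | (np.diff(rpos) != 1))
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(rpos) - 1]])
        meta = qr_meta if is_rc else q_meta
        seqs = qr_seqs if is_rc else qf_seqs
        for s, e in zip(starts, ends):
            r0, q0 = int(rpos[s]), int(qpos[s])
            length = int(rpos[e]) - r0 + k
            rchrom, rloc = _locate(r_meta, r0)
            qchrom, qloc = _locate(meta, q0)
            rseq, qseq = ref_seqs[rchrom], seqs[qchrom]
            # maximal extension beyond the unique-seed run
            while rloc > 0 and qloc > 0 and rseq[rloc - 1] == qseq[qloc - 1]:
                rloc -= 1
                qloc -= 1
                length += 1
            while (
                rloc + length < len(rseq)
                and qloc + length < len(qseq)
                and rseq[rloc + length] == qseq[qloc + length]
            ):
                length += 1
            if is_rc:
                fwd_start = len(qry[qchrom]) - qloc - length
                anchors.append(Anchor(rchrom, rloc, qchrom, fwd_start, length, "-"))
            else:
                anchors.append(Anchor(rchrom, rloc, qchrom, qloc, length, "+"))
    # identical extended anchors can arise from several seed runs; dedupe
    anchors = sorted(set(anchors), key=lambda a: (a.ref_chrom, a.ref_start, a.strand, a.qry_start))
    return anchors


# ---------------------------------------------------------------------------
# chaining


def _chain_coords(a: Anchor):
    """(diagonal, query-frame coordinate pair) in the strand's chain frame."""
    if a.strand == "+":
        return a.ref_start - a.qry_start, a.qry_start, a.qry_end
    # '-': as ref increases, forward query coordinate decreases; chain in
    # the reverse-complement frame where colinearity is again increasing
    return a.ref_start + a.qry_end, -a.qry_end, -a.qry_start


def _compatible(prev: Anchor, nxt: Anchor, max_gap: int, max_drift: int) -> bool:
    gap_r = nxt.ref_start - prev.ref_end
    if gap_r < -OVERLAP_TOL or gap_r > max_gap:
        return False
    dp_, ps, pe = _chain_coords(prev)
    dn, ns, ne = _chain_coords(nxt)
    gap_q = ns - pe
    if gap_q < -OVERLAP_TOL or gap_q > max_gap:
        return False
    return abs(dn - dp_) <= max_drift


def chain_anchors(
    anchors: list[Anchor],
    max_gap: int = DEFAULT_MAX_GAP,
    max_diag_drift: int = DEFAULT_MAX_DRIFT,
) -> list[AlignmentBlock]:
    """Merge co-linear anchors into alignment blocks.

    Within each (ref chrom, qry chrom, strand) group, a sparse
    best-predecessor dynamic program maximizes chained anchor bases
    subject to gap and diagonal-drift bounds; chains are then peeled off
    in descending score order. Block identity = anchor-covered reference
    bases / max(ref span, qry span).
    """
    blocks: list[AlignmentBlock] = []
    groups: dict[tuple, list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.ref_chrom, a.qry_chrom, a.strand), []).append(a)

    for key in sorted(groups):
        grp = sorted(groups[key], key=lambda a: (a.ref_start, a.qry_start))
        n = len(grp)
        dp = [float(a.length) for a in grp]
        parent = [-1] * n
        starts = [a.ref_start for a in grp]
        for i in range(n):
            lo = np.searchsorted(starts, grp[i].ref_start - max_gap - 2_000_000)
            lo = max(int(lo), i - _CHAIN_LOOKBACK)
            best, bestj = 0.0, -1
            for j in range(i - 1, lo - 1, -1):
                if dp[j] > best and _compatible(grp[j], grp[i], max_gap, max_diag_drift):
                    best, bestj = dp[j], j
            if bestj >= 0:
                dp[i] += best
                parent[i] = bestj
        used = [False] * n
        for i in sorted(range(n), key=lambda i: -dp[i]):
            if used[i]:
                continue
            chain = []
            j = i
            while j >= 0 and not used[j]:
                chain.append(grp[j])
                used[j] = True
                j = parent[j]
            chain.reverse()
            blocks.append(_block_from_chain(chain))
    blocks.sort(key=lambda b: (b.ref_chrom, b.ref_start, b.qry_chrom, b.qry_start))
    return blocks


def _block_from_chain(chain: list[Anchor]) -> AlignmentBlock:
    ref_start = min(a.ref_start for a in chain)
    ref_end = max(a.ref_end for a in chain)
    qry_start = min(a.qry_start for a in chain)
    qry_end = max(a.qry_end for a in chain)
    covered = 0
    last = -1
    for a in sorted(chain, key=lambda a: a.ref_start):
        s = max(a.ref_start, last)
        if a.ref_end > s:
            covered += a.ref_end - s
            last = a.ref_end
        last = max(last, a.ref_end)
    aligned = max(ref_end - ref_start, qry_end - qry_start)
    identity = min(1.0, covered / aligned)
    a0 = chain[0]
    return AlignmentBlock(
        a0.ref_chrom, ref_start, ref_end, a0.qry_chrom, qry_start, qry_end,
        a0.strand, identity, aligned,
    )


# ---------------------------------------------------------------------------
# one-to-one filtering


def _conflict(b1: AlignmentBlock, b2: AlignmentBlock, tol: int) -> bool:
    if b1.ref_chrom == b2.ref_chrom:
        if min(b1.ref_end, b2.ref_end) - max(b1.ref_start, b2.ref_start) > tol:
            return True
    if b1.qry_chrom == b2.qry_chrom:
        if min(b1.qry_end, b2.qry_end) - max(b1.qry_start, b2.qry_start) > tol:
            return True
    return False


def _exact_mwis(weights: list[float], adj: list[int]) -> int:
    """Max-weight independent set on a small conflict graph; returns the
    chosen-vertex bitmask."""
    n = len(weights)
    memo: dict[int, tuple[float, int]] = {}

    def solve(mask: int) -> tuple[float, int]:
        if mask == 0:
            return 0.0, 0
        if mask in memo:
            return memo[mask]
        v = (mask & -mask).bit_length() - 1
        rest = mask & ~(1 << v)
        w_out, c_out = solve(rest)
        w_in, c_in = solve(rest & ~adj[v])
        w_in += weights[v]
        res = (w_in, c_in | (1 << v)) if w_in > w_out else (w_out, c_out)
        memo[mask] = res
        return res

    return solve((1 << n) - 1)[1]


def filter_one_to_one(
    blocks: list[AlignmentBlock],
    min_len: int = DEFAULT_MIN_LEN,
    min_id: float = DEFAULT_MIN_ID,
    overlap_tol: int = OVERLAP_TOL,
) -> list[AlignmentBlock]:
    """Reduce blocks to the best one-to-one set.

    Blocks must be strictly longer than ``min_len`` and have identity at
    least ``min_id`` (the length bound is exclusive, the identity bound
    inclusive). Among surviving blocks a maximum-total-score subset is
    selected such that no two retained blocks overlap by more than
    ``overlap_tol`` bases on either the reference or the query frame.
    Conflict components small enough are solved exactly; larger ones
    greedily by score (ties: longer block, then reference position).
    """
    cand = [b for b in blocks if b.aligned_length > min_len and b.identity >= min_id]
    n = len(cand)
    if n == 0:
        return []

    conflicts = [[] for _ in range(n)]
    comp = list(range(n))

    def find(i):
        while comp[i] != i:
            comp[i] = comp[comp[i]]
            i = comp[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _conflict(cand[i], cand[j], overlap_tol):
                conflicts[i].append(j)
                conflicts[j].append(i)
                ri, rj = find(i), find(j)
                if ri != rj:
                    comp[ri] = rj

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    chosen: list[AlignmentBlock] = []
    for members in groups.values():
        if len(members) == 1:
            chosen.append(cand[members[0]])
        elif len(members) <= _EXACT_COMPONENT_LIMIT:
            local = {g: l for l, g in enumerate(members)}
            adj = [0] * len(members)
            for l, g in enumerate(members):
                for nb in conflicts[g]:
                    if nb in local:
                        adj[l] |= 1 << local[nb]
            weights = [cand[g].score for g in members]
            mask = _exact_mwis(weights, adj)
            chosen.extend(cand[members[l]] for l in range(len(members)) if mask >> l & 1)
        else:
            order = sorted(
                members,
                key=lambda g: (-cand[g].score, -cand[g].aligned_length,
                               cand[g].ref_chrom, cand[g].ref_start),
            )
            kept: list[int] = []
            for g in order:
                if all(not _conflict(cand[g], cand[h], overlap_tol) for h in kept):
                    kept.append(g)
            chosen.extend(cand[g] for g in kept)
    chosen.sort(key=lambda b: (b.ref_chrom, b.ref_start))
    return chosen


# ---------------------------------------------------------------------------
# convenience + tables


def align_genomes(
    ref: GenomeSet,
    qry: GenomeSet,
    k: int = DEFAULT_K,
    max_gap: int = DEFAULT_MAX_GAP,
    max_diag_drift: int = DEFAULT_MAX_DRIFT,
) -> list[AlignmentBlock]:
    """Anchor finding + chaining in one call (no one-to-one filtering)."""
    return chain_anchors(find_unique_anchors(ref, qry, k=k), max_gap, max_diag_drift)


def dotplot_table(blocks: list[AlignmentBlock]) -> pd.DataFrame:
    """One row per block, suitable for drawing a dotplot; reverse-strand
    rows carry strand '-'."""
    return pd.DataFrame(
        [
            {
                "refChrom": b.ref_chrom,
                "refStart": b.ref_start,
                "refEnd": b.ref_end,
                "qryChrom": b.qry_chrom,
                "qryStart": b.qry_start,
                "qryEnd": b.qry_end,
                "strand": b.strand,
                "identity": round(b.identity, 6),
            }
            for b in blocks
        ],
        columns=["refChrom", "refStart", "refEnd", "qryChrom", "qryStart",
                 "qryEnd", "strand", "identity"],
    )


def write_blocks(blocks, path: str | Path, header: str = "") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip().splitlines():
                fh.write(f"# {line}\n")
        dotplot_table(blocks).to_csv(fh, sep="\t", index=False)
    return path


def read_blocks(path: str | Path) -> list[AlignmentBlock]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for row in df.itertuples(index=False):
        aligned = max(row.refEnd - row.refStart, row.qryEnd - row.qryStart)
        out.append(
            AlignmentBlock(
                row.refChrom, row.refStart, row.refEnd, row.qryChrom,
                row.qryStart, row.qryEnd, row.strand, float(row.identity), aligned,
            )
        )
    return out


def paf_table(blocks: list[AlignmentBlock], ref: GenomeSet, qry: GenomeSet) -> pd.DataFrame:
    """PAF-compatible column order (query first, matches estimated from
    identity) for interoperability with standard dotplot tools."""
    rows = []
    for b in blocks:
        rows.append(
            (
                b.qry_chrom, len(qry[b.qry_chrom]), b.qry_start, b.qry_end,
                b.strand, b.ref_chrom, len(ref[b.ref_chrom]), b.ref_start, b.ref_end,
                int(round(b.identity * b.aligned_length)), b.aligned_length, 255,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["qName", "qLen", "qStart", "qEnd", "strand", "tName", "tLen",
                 "tStart", "tEnd", "matches", "alnLen", "mapq"],
    )


def plot_dotplot(blocks, ref: GenomeSet, qry: GenomeSet, path: str | Path) -> Path:
    """Whole-genome dotplot: chromosomes concatenated on each axis, forward
    blocks in blue, reversed blocks in red."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    roff, off = {}, 0
    for n in ref.names:
        roff[n] = off
        off += len(ref[n])
    rtot = off
    qoff, off = {}, 0
    for n in qry.names:
        qoff[n] = off
        off += len(qry[n])
    qtot = off
    fig, ax = plt.subplots(figsize=(6, 6))
    for b in blocks:
        x = [roff[b.ref_chrom] + b.ref_start, roff[b.ref_chrom] + b.ref_end]
        if b.strand == "+":
            y = [qoff[b.qry_chrom] + b.qry_start, qoff[b.qry_chrom] + b.qry_end]
            ax.plot(x, y, color="navy", lw=1)
        else:
            y = [qoff[b.qry_chrom] + b.qry_end, qoff[b.qry_chrom] + b.qry_start]
            ax.plot(x, y, color="crimson", lw=1)
    for n in ref.names:
        ax.axvline(roff[n], color="0.85", lw=0.5)
    for n in qry.names:
        ax.axhline(qoff[n], color="0.85", lw=0.5)
    ax.set_xlim(0, rtot)
    ax.set_ylim(0, qtot)
    ax.set_xlabel("reference")
    ax.set_ylabel("query")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
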