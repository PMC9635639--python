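"""Banded global alignment with affine gap penalties (Gotoh).

Row-vectorized integer dynamic programming inside a diagonal band; the
band half-width is derived from the unit-cost edit distance (computed by
edlib), which upper-bounds how far the affine-optimal path can stray from
the straight diagonal in the regimes this package targets (few-percent
divergence plus a handful of long indels). The horizontal gap state is
computed with a running-maximum scan so each row costs a constant number
of numpy operations.

Scores are integers: ``match`` added per identical column, ``mismatch``
subtracted per substitution column, and a gap of length L costs
``gap_open + L * gap_ext``. Affine scoring is what keeps a long insertion
aligned as one contiguous gap run instead of being smeared into cheaper
scattered substitutions — the property the indel reporter relies on.
"""

from __future__ import annotations

import numpy as np

NEG = np.int32(-(10**9) // 2)


def _edit_distance(a: str, b: str) -> int:
    import edlib

    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def affine_align(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = 1,
    gap_open: int = 4,
    gap_ext: int = 1,
    band: int | None = None,
    max_cells: int = 400_000_000,
) -> list[tuple[int, str]]:
    """Optimal banded global alignment; returns merged CIGAR-style ops.

    Ops: '=' match, 'X' substitution, 'I' bases only in ``a``,
    'D' bases only in ``b``.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise ValueError("empty sequence")
    if band is None:
        ed = _edit_distance(a, b)
        band = min(2 * ed + 64, max(n, m))
    W = max(band, abs(n - m) + 8)
    B = 2 * W + 1
    if (n + 1) * B > max_cells // 12:
        raise ValueError(
            f"alignment band too wide ({n + 1} x {B} cells); sequences too divergent"
        )

    aa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)

    H = np.full((n + 1, B), NEG, dtype=np.int32)
    E = np.full((n + 1, B), NEG, dtype=np.int32)  # gap consuming b (horizontal)
    F = np.full((n + 1, B), NEG, dtype=np.int32)  # gap consuming a (vertical)
    los = np.empty(n + 1, dtype=np.int64)

    rel = np.arange(B, dtype=np.int64)
    # row 0: leading gap in the horizontal direction
    lo0 = -W  # row 0 band is centered on column 0
    los[0] = lo0
    j0 = lo0 + rel
    in0 = (j0 >= 0) & (j0 <= m)
    row0 = np.where(j0 == 0, 0, -gap_open - gap_ext * j0).astype(np.int32)
    H[0, in0] = row0[in0]
    E[0, in0] = np.where(j0[in0] > 0, row0[in0], NEG)

    idx_ext = rel.astype(np.int64) * gap_ext

    for i in range(1, n + 1):
        lo = (i * m) // n - W
        los[i] = lo
        shift = int(lo - los[i - 1])
        prevH = H[i - 1]
        prevF = F[i - 1]

        def shifted(arr, by):
            if by == 0:
                return arr
            out = np.full(B, NEG, dtype=np.int32)
            if by > 0:
                out[: B - by] = arr[by:]
            else:
                out[-by:] = arr[:by]
            return out

        up_H = shifted(prevH, shift)  # H[i-1][j]
        up_F = shifted(prevF, shift)
        diag_H = shifted(prevH, shift - 1)  # H[i-1][j-1]

        j = lo + rel
        inside = (j >= 0) & (j <= m)
        jpos = (j >= 1) & (j <= m)

        f_row = np.maximum(up_F - gap_ext, up_H - gap_open - gap_ext)

        s = np.full(B, NEG, dtype=np.int32)
        sel = jpos
        bidx = np.clip(j - 1, 0, m - 1)
        eq = bb[bidx] == aa[i - 1]
        s[sel] = np.where(eq[sel], match, -mismatch)
        diag = np.where(jpos, diag_H + s, NEG)

        h0 = np.maximum(diag, f_row)
        # j == 0 column: only a vertical gap can reach it
        zero_col = j == 0
        h0[zero_col] = -gap_open - gap_ext * i

        t = np.where(inside, h0 + idx_ext, NEG).astype(np.int64)
        run = np.maximum.accumulate(t)
        e_row = np.full(B, np.int64(NEG))
        e_row[1:] = run[:-1] - gap_open - idx_ext[1:]
        e_row = np.maximum(e_row, NEG).astype(np.int32)
        e_row[~jpos] = NEG

        h = np.maximum(h0, e_row)
        h[~inside] = NEG
        f_row[~inside] = NEG
        H[i] = h
        E[i] = e_row
        F[i] = f_row

    def get(mat, i, j):
        r = j - los[i]
        if 0 <= r < B:
            return int(mat[i, r])
        return int(NEG)

    # traceback
    ops: list[str] = []
    i, j = n, m
    state = "H"
    h0_only = False
    while i > 0 or j > 0:
        if i == 0:
            ops.append("D")
            j -= 1
            continue
        if j == 0:
            ops.append("I")
            i -= 1
            continue
        if state == "H":
            if h0_only:
                # cell reached by a gap-open: its value is max(diag, F),
                # not the stored H (which may include an E this path
                # cannot have used)
                h0_only = False
                sub = match if a[i - 1] == b[j - 1] else -mismatch
                if get(F, i, j) >= get(H, i - 1, j - 1) + sub:
                    state = "F"
                    continue
                ops.append("=" if a[i - 1] == b[j - 1] else "X")
                i -= 1
                j -= 1
                continue
            h = get(H, i, j)
            if h == get(E, i, j):
                state = "E"
                continue
            if h == get(F, i, j):
                state = "F"
                continue
            ops.append("=" if a[i - 1] == b[j - 1] else "X")
            i -= 1
            j -= 1
        elif state == "E":
            e = get(E, i, j)
            ops.append("D")
            if j > 1 and e == get(E, i, j - 1) - gap_ext:
                j -= 1  # extend
            else:
                j -= 1
                state = "H"
                h0_only = True  # opened from a non-E cell
        else:  # F
            f = get(F, i, j)
            ops.append("I")
            if i > 1 and f == get(F, i - 1, j) - gap_ext:
                i -= 1
            else:
                i -= 1
                state = "H"
    ops.reverse()

    merged: list[tuple[int, str]] = []
    for op in ops:
        if merged and merged[-1][1] == op:
            merged[-1] = (merged[-1][0] + 1, op)
        else:
            merged.append((1, op))
    return merged
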