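"""Seeded synthetic two-strain genome datasets with planted truth.

The generator emulates the data a two-strain comparative study produces:

* a multi-chromosome reference genome (i.i.d. uniform A/C/G/T, so unique
  k-mer anchoring is well posed on small genomes);
* a derived strain carrying planted SNPs (with regional hot/cold rate
  intervals), small indels, and large structural variants (insertions,
  deletions, inversions, intra-/inter-chromosome relocations, tandem
  duplications);
* a negative-binomial 1-kb read-depth track with a smooth regional trend
  and planted low/high outlier regions;
* a VCF of the planted ("called") variants;
* a circular mitogenome pair, one copy emitted with the spurious terminal
  duplication that over-assembly of a circular molecule produces.

SNP discovery probability scales linearly with the local depth trend by
default (``depth_coupling``), reproducing the empirical positive
correlation between raw per-window SNP counts and read depth that
motivates depth normalization downstream. With a flat trend
(``depth_trend_amplitude=0``) planted SNP counts in an interval are exact
Binomial(length, rate) draws.

Every output is a deterministic function of the :class:`SimSpec`,
including its seed: re-running emits byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeSet, revcomp
from .landscape import DepthTrack, n_bins

SV_KINDS = (
    "insertion",
    "deletion",
    "inversion",
    "relocation_same",
    "relocation_diff",
    "tandem_dup",
)
RELOCATIONS = ("relocation_same", "relocation_diff")

#: bases kept free of SNPs/small indels around every SV junction so that
#: point variation never blurs a planted breakpoint
_SV_PAD = 60


@dataclass(frozen=True)
class SvEvent:
    """One planted structural variant, in reference coordinates.

    ``start`` is 0-based. For insertions ``length`` is the number of novel
    bases inserted before ``start``; for all other kinds it is the length
    of the affected reference interval ``[start, start+length)``.
    ``destination`` (chrom, position) is required for relocations and
    forbidden otherwise.
    """

    kind: str
    chrom: str
    start: int
    length: int
    destination: tuple[str, int] | None = None

    def footprint(self) -> tuple[str, int, int]:
        if self.kind == "insertion":
            return (self.chrom, self.start, self.start + 1)
        return (self.chrom, self.start, self.start + self.length)


@dataclass
class SimSpec:
    """Full description of one synthetic dataset.

    Rates are per base; ``depth_mean`` is the expected read count per 1-kb
    bin (250 reads of 200 bp = 50x coverage); ``depth_dispersion`` is the
    negative-binomial size parameter (variance = m + m^2/size).
    """

    seed: int = 0
    chrom_lengths: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 2_000_000), ("chr2", 2_000_000)]
    )
    snp_landscape: list[tuple[str, int, int, float]] = field(default_factory=list)
    baseline_snp_rate: float = 0.002
    small_indel_rate: float = 2e-5
    max_indel_len: int = 10
    sv_events: list[SvEvent] = field(default_factory=list)
    depth_mean: float = 250.0
    depth_dispersion: float = 60.0
    depth_trend_amplitude: float = 0.15
    depth_trend_period: float = 3_000_000.0
    depth_coupling: bool = True
    depth_outliers: list[tuple[str, int, int, str]] = field(default_factory=list)
    read_len: int = 200
    mito_length: int = 16_818
    mito_terminal_dup: int = 400
    mito_ancestral_length: int = 16_634
    mito_snp_rate: float = 0.005
    mito_insertion_a: int = 184
    mito_insertion_b: int = 137
    mito_insertion_a_pos: int = 14_831
    mito_insertion_b_pos: int = 14_523

    def chrom_length(self, name: str) -> int:
        for n, length in self.chrom_lengths:
            if n == name:
                return length
        raise ValueError(f"unknown chromosome {name!r}")

    def validate(self) -> None:
        lengths = dict(self.chrom_lengths)
        if len(lengths) != len(self.chrom_lengths):
            raise ValueError("chrom_lengths: duplicate chromosome name")
        for name, length in self.chrom_lengths:
            if length <= 0:
                raise ValueError(f"chrom_lengths: {name} has non-positive length")
        for rate_name in ("baseline_snp_rate", "small_indel_rate", "mito_snp_rate"):
            r = getattr(self, rate_name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{rate_name}: {r} outside [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError(f"depth_mean: {self.depth_mean} must be > 0")
        if self.depth_dispersion <= 0:
            raise ValueError(f"depth_dispersion: {self.depth_dispersion} must be > 0")
        for chrom, s, e, r in self.snp_landscape:
            if chrom not in lengths:
                raise ValueError(f"snp_landscape: unknown chromosome {chrom!r}")
            if not (0 <= s < e <= lengths[chrom]):
                raise ValueError(f"snp_landscape: interval {chrom}:{s}-{e} out of bounds")
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"snp_landscape: rate {r} outside [0, 1]")
        for chrom, s, e, level in self.depth_outliers:
            if chrom not in lengths:
                raise ValueError(f"depth_outliers: unknown chromosome {chrom!r}")
            if not (0 <= s < e <= lengths[chrom]):
                raise ValueError(f"depth_outliers: interval {chrom}:{s}-{e} out of bounds")
            if level not in ("low", "high"):
                raise ValueError(f"depth_outliers: level {level!r} not low|high")
        self._validate_svs(lengths)

    def _validate_svs(self, lengths: dict[str, int]) -> None:
        footprints: list[tuple[str, int, int]] = []
        for ev in self.sv_events:
            if ev.kind not in SV_KINDS:
                raise ValueError(f"sv_events: unknown kind {ev.kind!r}")
            if ev.length < 1:
                raise ValueError(f"sv_events: {ev.kind} length {ev.length} < 1")
            if ev.chrom not in lengths:
                raise ValueError(f"sv_events: unknown chromosome {ev.chrom!r}")
            c, s, e = ev.footprint()
            if not (0 <= s and e <= lengths[c]):
                raise ValueError(f"sv_events: {ev.kind} at {c}:{s} extends past chromosome end")
            if (ev.destination is not None) != (ev.kind in RELOCATIONS):
                raise ValueError(
                    f"sv_events: destination must be present iff kind is a relocation ({ev.kind})"
                )
            footprints.append((c, s, e))
            if ev.destination is not None:
                dc, dp = ev.destination
                if dc not in lengths or not 0 <= dp <= lengths[dc]:
                    raise ValueError(f"sv_events: destination {dc}:{dp} out of bounds")
                if ev.kind == "relocation_same" and dc != ev.chrom:
                    raise ValueError("relocation_same destination on a different chromosome")
                if ev.kind == "relocation_diff" and dc == ev.chrom:
                    raise ValueError("relocation_diff destination on the same chromosome")
                footprints.append((dc, dp, dp + 1))
        footprints.sort()
        for (c1, s1, e1), (c2, s2, e2) in zip(footprints, footprints[1:]):
            if c1 == c2 and s2 < e1 + 2 * _SV_PAD:
                raise ValueError(
                    f"sv_events: overlapping or abutting events near {c1}:{s2} "
                    f"(require >= {2 * _SV_PAD} bp separation)"
                )


@dataclass
class TruthSet:
    """Planted features of one dataset, in both coordinate frames.

    ``variants``: chrom, pos (1-based, VCF-style anchored alleles), ref,
    alt, kind (snp|ins|del). ``sv``: one row per planted SV with reference
    coordinates (0-based half-open) and the query-frame interval the event
    occupies after application. Hot/cold windows are the landscape
    intervals whose planted rate implies a normalized density above/below
    the calling thresholds under the nominal coverage.
    """

    variants: pd.DataFrame
    sv: pd.DataFrame
    hot_windows: list[tuple[str, int, int]]
    cold_windows: list[tuple[str, int, int]]
    depth_outliers: list[tuple[str, int, int, str]]


def _rng(spec_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec_seed) & 0x7FFFFFFF, stream]))


def depth_trend(spec: SimSpec, chrom_index: int, positions: np.ndarray) -> np.ndarray:
    """Smooth multiplicative depth modulation along a chromosome.

    Emulates slow regional coverage waves (GC, mappability). Phase is
    offset per chromosome so trends are not synchronized genome-wide.
    """
    x = np.asarray(positions, dtype=float)
    return 1.0 + spec.depth_trend_amplitude * np.sin(
        2.0 * np.pi * (x / spec.depth_trend_period + 0.17 * chrom_index)
    )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode()


def simulate_reference(spec: SimSpec) -> GenomeSet:
    """Generate the reference genome: i.i.d. uniform A/C/G/T per chromosome."""
    spec.validate()
    seqs = {}
    for i, (name, length) in enumerate(spec.chrom_lengths):
        seqs[name] = _random_seq(_rng(spec.seed, 100 + i), length)
    return GenomeSet(seqs)


# ---------------------------------------------------------------------------
# strain derivation


class _Seg:
    """Piece of a query chromosome: a reference slice or a literal string."""

    __slots__ = ("ref_chrom", "start", "end", "strand", "literal", "tag")

    def __init__(self, ref_chrom=None, start=0, end=0, strand="+", literal=None, tag=None):
        self.ref_chrom = ref_chrom
        self.start = start
        self.end = end
        self.strand = strand
        self.literal = literal
        self.tag = tag

    @property
    def is_ref(self) -> bool:
        return self.literal is None


def _split_out(
    segments: dict[str, list[_Seg]], chrom: str, s: int, e: int
) -> tuple[str, int]:
    """Split the untouched '+' reference segment containing ``[s, e)`` of
    reference chromosome ``chrom``; return (query chrom, index of the
    middle segment covering exactly [s, e))."""
    for qc, segs in segments.items():
        for i, seg in enumerate(segs):
            if (
                seg.is_ref
                and seg.strand == "+"
                and seg.tag is None
                and seg.ref_chrom == chrom
                and seg.start <= s
                and e <= seg.end
            ):
                pieces = []
                if seg.start < s:
                    pieces.append(_Seg(chrom, seg.start, s))
                mid = _Seg(chrom, s, e)
                pieces.append(mid)
                if e < seg.end:
                    pieces.append(_Seg(chrom, e, seg.end))
                segs[i : i + 1] = pieces
                return qc, segs.index(mid)
    raise ValueError(f"no untouched reference segment contains {chrom}:{s}-{e}")


def _forbidden_masks(spec: SimSpec) -> dict[str, np.ndarray]:
    masks = {name: np.zeros(length, dtype=bool) for name, length in spec.chrom_lengths}
    for ev in spec.sv_events:
        c, s, e = ev.footprint()
        masks[c][max(0, s - _SV_PAD) : e + _SV_PAD] = True
        if ev.destination is not None:
            dc, dp = ev.destination
            masks[dc][max(0, dp - _SV_PAD) : dp + _SV_PAD] = True
    return masks


def _plant_point_variants(
    ref: GenomeSet, spec: SimSpec, forbidden: dict[str, np.ndarray]
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict[str, list]]:
    """Draw SNP positions/alts and small indels per chromosome.

    Returns (snp_pos, snp_alt_codes, indels) where indels maps chrom to a
    list of (pos, kind 'ins'|'del', length, inserted_seq_or_None).
    """
    snp_rng = _rng(spec.seed, 200)
    indel_rng = _rng(spec.seed, 201)
    snp_pos: dict[str, np.ndarray] = {}
    snp_alt: dict[str, np.ndarray] = {}
    indels: dict[str, list] = {}
    base_codes = {b: i for i, b in enumerate("ACGT")}
    for ci, (chrom, length) in enumerate(spec.chrom_lengths):
        rate = np.full(length, spec.baseline_snp_rate, dtype=np.float64)
        for c, s, e, r in spec.snp_landscape:
            if c == chrom:
                rate[s:e] = r
        if spec.depth_coupling and spec.depth_trend_amplitude > 0:
            rate *= depth_trend(spec, ci, np.arange(length))
            np.clip(rate, 0.0, 1.0, out=rate)
        rate[forbidden[chrom]] = 0.0
        pos = np.nonzero(snp_rng.random(length) < rate)[0]
        refc = np.fromiter(
            (base_codes[ref[chrom][p]] for p in pos), dtype=np.uint8, count=len(pos)
        )
        alts = (refc + snp_rng.integers(1, 4, size=len(pos), dtype=np.uint8)) % 4
        snp_pos[chrom] = pos
        snp_alt[chrom] = alts

        # small indels: spaced away from SNPs, SVs and each other
        cand = np.nonzero(indel_rng.random(length) < spec.small_indel_rate)[0]
        out = []
        last_end = -(10**9)
        for p in cand:
            is_del = bool(indel_rng.random() < 0.5)
            ilen = int(indel_rng.integers(1, spec.max_indel_len + 1))
            span_end = p + ilen + 1 if is_del else p + 1
            if p < 1 or span_end >= length:
                continue
            if p - last_end < 50:
                continue
            if forbidden[chrom][max(0, p - 1) : span_end + 1].any():
                continue
            lo_i = np.searchsorted(pos, p - 2)
            hi_i = np.searchsorted(pos, span_end + 2)
            if hi_i > lo_i:  # collides with a SNP
                continue
            if is_del:
                out.append((int(p), "del", ilen, None))
            else:
                out.append((int(p), "ins", ilen, _random_seq(indel_rng, ilen)))
            last_end = span_end
        indels[chrom] = out
    return snp_pos, snp_alt, indels


def expected_normalized_density(
    spec: SimSpec, rate: float, window: int = 750_000
) -> float:
    """Normalized SNP density a full window of per-base rate ``rate`` is
    expected to show under the nominal coverage (used to classify planted
    landscape intervals as hot/cold truth)."""
    coverage = spec.depth_mean * spec.read_len / 1000.0
    return rate * window / coverage


def derive_strain(
    ref: GenomeSet, spec: SimSpec, high_thr: float = 500.0, low_thr: float = 1.0
) -> tuple[GenomeSet, TruthSet]:
    """Apply the planted variation to the reference, producing the query
    strain genome and the truth set in both coordinate frames."""
    spec.validate()
    for name, length in spec.chrom_lengths:
        if name not in ref or len(ref[name]) != length:
            raise ValueError(f"reference does not match spec for {name}")

    forbidden = _forbidden_masks(spec)
    snp_pos, snp_alt, indels = _plant_point_variants(ref, spec, forbidden)
    sv_rng = _rng(spec.seed, 202)

    # --- apply SVs on the segment structure
    segments: dict[str, list[_Seg]] = {
        name: [_Seg(name, 0, length)] for name, length in spec.chrom_lengths
    }
    inserted_seqs: dict[int, str] = {}
    for idx, ev in enumerate(spec.sv_events):
        if ev.kind == "deletion":
            qc, i = _split_out(segments, ev.chrom, ev.start, ev.start + ev.length)
            segments[qc][i] = _Seg(literal="", tag=(idx, "junction"))
        elif ev.kind == "insertion":
            qc, i = _split_out(segments, ev.chrom, ev.start, ev.start)
            seq = _random_seq(sv_rng, ev.length)
            inserted_seqs[idx] = seq
            segments[qc][i] = _Seg(literal=seq, tag=(idx, "inserted"))
        elif ev.kind == "inversion":
            qc, i = _split_out(segments, ev.chrom, ev.start, ev.start + ev.length)
            seg = segments[qc][i]
            seg.strand = "-"
            seg.tag = (idx, "inverted")
        elif ev.kind == "tandem_dup":
            qc, i = _split_out(segments, ev.chrom, ev.start, ev.start + ev.length)
            copy = _Seg(
                literal=ref[ev.chrom][ev.start : ev.start + ev.length], tag=(idx, "copy")
            )
            segments[qc].insert(i + 1, copy)
        elif ev.kind in RELOCATIONS:
            qc, i = _split_out(segments, ev.chrom, ev.start, ev.start + ev.length)
            moved = segments[qc][i]
            moved.tag = (idx, "moved")
            segments[qc][i] = _Seg(literal="", tag=(idx, "source"))
            dc, dp = ev.destination
            qc2, j = _split_out(segments, dc, dp, dp)
            segments[qc2][j] = moved
        else:  # pragma: no cover - guarded by validate()
            raise AssertionError(ev.kind)

    # --- materialize query chromosomes, recording query-frame coordinates
    qseqs: dict[str, str] = {}
    sv_qry: dict[int, tuple[str, int, int]] = {}
    for qc, segs in segments.items():
        parts: list[str] = []
        offset = 0
        for seg in segs:
            if seg.is_ref:
                piece = _materialize_ref_segment(
                    ref, seg, snp_pos.get(seg.ref_chrom), snp_alt.get(seg.ref_chrom),
                    indels.get(seg.ref_chrom, []),
                )
            else:
                piece = seg.literal
            if seg.tag is not None:
                idx, role = seg.tag
                if role != "source":
                    sv_qry[idx] = (qc, offset, offset + len(piece))
                else:
                    sv_qry.setdefault(idx, (qc, offset, offset))
            parts.append(piece)
            offset += len(piece)
        qseqs[qc] = "".join(parts)
    qry = GenomeSet(qseqs)

    # --- truth tables
    var_rows = []
    for chrom, _ in spec.chrom_lengths:
        seq = ref[chrom]
        for p, a in zip(snp_pos[chrom], snp_alt[chrom]):
            var_rows.append((chrom, int(p) + 1, seq[p], "ACGT"[a], "snp"))
        for p, kind, ilen, ins in indels[chrom]:
            anchor = seq[p - 1]
            if kind == "del":
                var_rows.append((chrom, p, seq[p - 1 : p + ilen], anchor, "del"))
            else:
                var_rows.append((chrom, p, anchor, anchor + ins, "ins"))
    variants = pd.DataFrame(var_rows, columns=["chrom", "pos", "ref", "alt", "kind"])
    order = {name: i for i, (name, _) in enumerate(spec.chrom_lengths)}
    variants = variants.sort_values(
        by=["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s
    ).reset_index(drop=True)

    sv_rows = []
    for idx, ev in enumerate(spec.sv_events):
        c, s, e = ev.footprint()
        qc_, qs, qe = sv_qry[idx]
        sv_rows.append(
            {
                "kind": ev.kind,
                "ref_chrom": ev.chrom,
                "ref_start": ev.start,
                "ref_end": ev.start + (0 if ev.kind == "insertion" else ev.length),
                "length": ev.length,
                "dest_chrom": ev.destination[0] if ev.destination else "",
                "dest_pos": ev.destination[1] if ev.destination else -1,
                "qry_chrom": qc_,
                "qry_start": qs,
                "qry_end": qe,
                "inserted_seq": inserted_seqs.get(idx, ""),
            }
        )
    sv = pd.DataFrame(
        sv_rows,
        columns=[
            "kind", "ref_chrom", "ref_start", "ref_end", "length",
            "dest_chrom", "dest_pos", "qry_chrom", "qry_start", "qry_end",
            "inserted_seq",
        ],
    )

    hot, cold = [], []
    for c, s, e, r in spec.snp_landscape:
        dens = expected_normalized_density(spec, r)
        if dens > high_thr:
            hot.append((c, s, e))
        elif dens < low_thr:
            cold.append((c, s, e))
    truth = TruthSet(
        variants=variants,
        sv=sv,
        hot_windows=hot,
        cold_windows=cold,
        depth_outliers=list(spec.depth_outliers),
    )
    return qry, truth


def _materialize_ref_segment(ref, seg, pos, alt, indels) -> str:
    chrom, s, e = seg.ref_chrom, seg.start, seg.end
    if s == e:
        return ""
    raw = ref[chrom][s:e]
    if seg.strand == "-":
        return revcomp(raw)
    arr = bytearray(raw, "ascii")
    if pos is not None and len(pos):
        lo = np.searchsorted(pos, s)
        hi = np.searchsorted(pos, e)
        for p, a in zip(pos[lo:hi], alt[lo:hi]):
            arr[p - s] = ord("ACGT"[a])
    seg_indels = [iv for iv in indels if s <= iv[0] < e]
    if not seg_indels:
        return arr.decode()
    parts = []
    cur = 0
    for p, kind, ilen, ins in seg_indels:
        local = p - s
        if kind == "del":
            parts.append(arr[cur:local])
            cur = local + ilen
        else:
            parts.append(arr[cur:local])
            parts.append(ins.encode())
            cur = local
    parts.append(arr[cur:])
    return b"".join(parts).decode()


# ---------------------------------------------------------------------------
# depth track


def simulate_depth(genome: GenomeSet, spec: SimSpec) -> DepthTrack:
    """Negative-binomial 1-kb read counts over ``genome`` with the smooth
    regional trend and planted low/high outlier regions.

    Low outlier bins draw uniformly from [0, 20) and high ones from
    (350, 600], i.e. strictly outside the retained range."""
    spec.validate()
    rng = _rng(spec.seed, 300)
    counts: dict[str, np.ndarray] = {}
    for ci, chrom in enumerate(genome.names):
        length = len(genome[chrom])
        nb = n_bins(length)
        starts = np.arange(nb, dtype=np.int64) * 1000
        widths = np.minimum(starts + 1000, length) - starts
        centers = starts + widths / 2
        mean = spec.depth_mean * depth_trend(spec, ci, centers) * widths / 1000.0
        size = spec.depth_dispersion
        p = size / (size + mean)
        c = rng.negative_binomial(size, p).astype(np.int64)
        for oc, s, e, level in spec.depth_outliers:
            if oc != chrom:
                continue
            sel = (starts >= s) & (starts < e)
            n = int(sel.sum())
            if level == "low":
                c[sel] = rng.integers(0, 20, size=n)
            else:
                c[sel] = rng.integers(351, 601, size=n)
        counts[chrom] = c
    return DepthTrack(counts=counts, chrom_lengths=genome.lengths)


# ---------------------------------------------------------------------------
# mitogenome


@dataclass
class MitoSim:
    """Synthetic circular mitogenome pair.

    ``circle_a`` is the focal strain's true single-copy circle (length =
    ancestral + insertion_a); ``overassembled_a`` is the same circle
    emitted the way an assembler emits a circular molecule: linearized at
    an arbitrary origin with the first ``terminal_dup`` bases spuriously
    repeated at the end. ``circle_b`` is the comparison strain: it lacks
    the focal insertion, carries its own insertion elsewhere, plus point
    substitutions. ``anchor`` is a unique gene-start sequence both circles
    share, used to linearize them consistently.
    """

    circle_a: str
    overassembled_a: str
    circle_b: str
    anchor: str
    insertion_a: tuple[int, int]  # 0-based half-open, frame of circle_a
    insertion_b: tuple[int, int]  # frame of circle_b
    rotation: int


def simulate_mito(spec: SimSpec) -> MitoSim:
    spec.validate()
    rng = _rng(spec.seed, 400)
    anc = _random_seq(rng, spec.mito_ancestral_length)
    ins_a = _random_seq(rng, spec.mito_insertion_a)
    ins_b = _random_seq(rng, spec.mito_insertion_b)
    pa = spec.mito_insertion_a_pos
    pb = spec.mito_insertion_b_pos
    circle_a = anc[:pa] + ins_a + anc[pa:]
    # strain B: own insertion plus substitutions relative to the ancestor
    b = bytearray(anc, "ascii")
    u = rng.random(len(anc))
    u[:30] = 1.0  # the anchor gene start is conserved between strains
    subs = np.nonzero(u < spec.mito_snp_rate)[0]
    base_codes = {ord(x): i for i, x in enumerate("ACGT")}
    for p in subs:
        code = (base_codes[b[p]] + int(rng.integers(1, 4))) % 4
        b[p] = ord("ACGT"[code])
    circle_b = b[:pb].decode() + ins_b + b[pb:].decode()
    rotation = int(rng.integers(0, len(circle_a)))
    rotated = circle_a[rotation:] + circle_a[:rotation]
    over = rotated + rotated[: spec.mito_terminal_dup]
    return MitoSim(
        circle_a=circle_a,
        overassembled_a=over,
        circle_b=circle_b,
        anchor=anc[:30],
        insertion_a=(pa, pa + spec.mito_insertion_a),
        insertion_b=(pb, pb + spec.mito_insertion_b),
        rotation=rotation,
    )


# ---------------------------------------------------------------------------
# emission


def write_vcf(variants: pd.DataFrame, chrom_lengths: list[tuple[str, int]], path) -> Path:
    """Minimal VCF v4.2 of the planted variants (sorted by chrom, pos)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=strainscan-simulate\n")
        for name, length in chrom_lengths:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in variants.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\n")
    return path


def _write_bed(rows, path, cols) -> Path:
    path = Path(path)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, header=False)
    return path


def emit_dataset(out_dir: str | Path, spec: SimSpec) -> dict:
    """Run the full generator and write the dataset to ``out_dir``.

    Writes ref.fasta, query.fasta, variants.vcf, depth.tsv, truth BED
    files, the mitogenome FASTAs and a manifest JSON; returns the manifest
    as a dict. Deterministic: identical spec (including seed) reproduces
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = simulate_reference(spec)
    qry, truth = derive_strain(ref, spec)
    depth = simulate_depth(ref, spec)
    mito = simulate_mito(spec)

    paths = {}
    paths["ref"] = str(ref.to_fasta(out / "ref.fasta"))
    paths["query"] = str(qry.to_fasta(out / "query.fasta"))
    paths["variants"] = str(
        write_vcf(truth.variants.assign(alt=truth.variants["alt"]), spec.chrom_lengths,
                  out / "variants.vcf")
    )
    paths["depth"] = str(depth.to_tsv(out / "depth.tsv"))
    sv_bed = out / "truth_sv.bed"
    sv_bed.write_text(
        truth.sv.drop(columns=["inserted_seq"]).to_csv(sep="\t", index=False, header=False)
    )
    paths["truth_sv"] = str(sv_bed)
    paths["truth_hot"] = str(_write_bed(truth.hot_windows, out / "truth_hot.bed",
                                        ["chrom", "start", "end"]))
    paths["truth_cold"] = str(_write_bed(truth.cold_windows, out / "truth_cold.bed",
                                         ["chrom", "start", "end"]))
    paths["truth_depth_outliers"] = str(
        _write_bed(truth.depth_outliers, out / "truth_depth_outliers.bed",
                   ["chrom", "start", "end", "level"])
    )
    GenomeSet({"mito_true": mito.circle_a}, circular={"mito_true"}).to_fasta(
        out / "mito_true.fasta"
    )
    GenomeSet({"mito_contig": mito.overassembled_a}).to_fasta(out / "mito_overassembled.fasta")
    GenomeSet({"mito_other": mito.circle_b}, circular={"mito_other"}).to_fasta(
        out / "mito_other.fasta"
    )
    paths["mito_true"] = str(out / "mito_true.fasta")
    paths["mito_overassembled"] = str(out / "mito_overassembled.fasta")
    paths["mito_other"] = str(out / "mito_other.fasta")
    (out / "mito_anchor.txt").write_text(mito.anchor + "\n")
    paths["mito_anchor"] = str(out / "mito_anchor.txt")

    manifest = {
        "seed": spec.seed,
        "spec": _spec_summary(spec),
        "files": paths,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["manifest_path"] = str(out / "manifest.json")
    return manifest


def _spec_summary(spec: SimSpec) -> dict:
    return asdict(spec)
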