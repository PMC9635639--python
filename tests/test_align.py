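"""Aligner contracts: anchors vs brute force, chaining vs exhaustive
search, one-to-one filtering vs exhaustive subset selection."""

import itertools

import numpy as np
import pytest

from strainscan import (
    AlignmentBlock,
    Anchor,
    GenomeSet,
    SimSpec,
    SvEvent,
    chain_anchors,
    derive_strain,
    dotplot_table,
    filter_one_to_one,
    find_unique_anchors,
    align_genomes,
    revcomp,
    simulate_reference,
)


# ---------------------------------------------------------------------------
# anchors


def brute_force_anchors(ref: str, qry: str, k: int) -> set[tuple]:
    """Quadratic oracle: every k-mer match with seed unique in both
    genomes (query counted over both strands), maximally extended."""

    def kmer_counts(seq):
        counts = {}
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] = counts.get(seq[i : i + k], 0) + 1
        return counts

    rc = revcomp(qry)
    ref_counts = kmer_counts(ref)
    qry_counts = kmer_counts(qry)
    for kmer, c in kmer_counts(rc).items():
        qry_counts[kmer] = qry_counts.get(kmer, 0) + c

    out = set()
    for strand, q in (("+", qry), ("-", rc)):
        for i in range(len(ref) - k + 1):
            seed = ref[i : i + k]
            if ref_counts.get(seed) != 1 or qry_counts.get(seed) != 1:
                continue
            j = q.find(seed)
            if j < 0:
                continue
            s_r, s_q, length = i, j, k
            while s_r > 0 and s_q > 0 and ref[s_r - 1] == q[s_q - 1]:
                s_r, s_q, length = s_r - 1, s_q - 1, length + 1
            while (
                s_r + length < len(ref)
                and s_q + length < len(q)
                and ref[s_r + length] == q[s_q + length]
            ):
                length += 1
            if strand == "+":
                out.add((s_r, s_q, length, "+"))
            else:
                out.add((s_r, len(qry) - s_q - length, length, "-"))
    return out


class TestAnchors:
    def test_identical_genomes_single_full_anchor(self, make_dna):
        seq = make_dna(5000)
        g = GenomeSet({"c": seq})
        anchors = find_unique_anchors(g, GenomeSet({"c": seq}), k=21)
        plus = [a for a in anchors if a.strand == "+"]
        assert len(plus) == 1
        a = plus[0]
        assert (a.ref_start, a.qry_start, a.length) == (0, 0, 5000)

    def test_disjoint_alphabets_no_anchors(self, make_dna):
        # note reverse-complementing a GT-only sequence yields AC-only
        # k-mers, so sequences are kept short enough that chance 21-mer
        # collisions over the 2-letter alphabet cannot occur
        ref = GenomeSet({"c": make_dna(200, "AC")})
        qry = GenomeSet({"c": make_dna(200, "GT")})
        assert find_unique_anchors(ref, qry, k=21) == []

    def test_matches_quadratic_oracle_on_toys(self, rng, make_dna):
        k = 21
        for trial in range(5):
            shared = make_dna(40)
            ref = make_dna(80) + shared + make_dna(80)
            ins = shared if trial % 2 == 0 else revcomp(shared)
            qry = make_dna(60) + ins + make_dna(100)
            got = {
                (a.ref_start, a.qry_start, a.length, a.strand)
                for a in find_unique_anchors(GenomeSet({"r": ref}), GenomeSet({"q": qry}), k)
            }
            assert got == brute_force_anchors(ref, qry, k)

    def test_empty_genome(self):
        assert find_unique_anchors(GenomeSet({"c": ""}), GenomeSet({"c": "ACGT" * 10})) == []

    def test_small_k_rejected(self, make_dna):
        g = GenomeSet({"c": make_dna(100)})
        with pytest.raises(ValueError):
            find_unique_anchors(g, g, k=7)


# ---------------------------------------------------------------------------
# chaining


def A(rs, qs, length, strand="+", rc="r", qc="q"):
    return Anchor(rc, rs, qc, qs, length, strand)


def exhaustive_best_chain(anchors, max_gap, max_drift):
    """Enumerate every ordered anchor subset that forms a valid chain;
    return the best total anchor length."""
    from strainscan.align import _compatible

    srt = sorted(anchors, key=lambda a: a.ref_start)
    best = 0
    for r in range(1, len(srt) + 1):
        for combo in itertools.combinations(srt, r):
            ok = all(
                _compatible(x, y, max_gap, max_drift) for x, y in zip(combo, combo[1:])
            )
            if ok:
                best = max(best, sum(a.length for a in combo))
    return best


class TestChaining:
    def test_single_anchor_block(self):
        blocks = chain_anchors([A(0, 0, 15_000)])
        assert len(blocks) == 1
        assert blocks[0].identity == 1.0
        assert blocks[0].aligned_length == 15_000

    def test_two_anchor_gap_identity(self):
        blocks = chain_anchors([A(0, 0, 6000), A(6200, 6200, 6000)], max_gap=1000)
        assert len(blocks) == 1
        b = blocks[0]
        assert b.aligned_length == 12_200
        assert b.identity == pytest.approx(12_000 / 12_200)

    def test_off_diagonal_outlier_matches_exhaustive(self):
        anchors = [
            A(0, 0, 2000),
            A(2100, 2100, 1500),
            A(3700, 50_000, 3000),  # off-diagonal outlier
            A(3700, 3700, 1800),
        ]
        blocks = chain_anchors(anchors, max_gap=1000, max_diag_drift=500)
        best = max(b.score for b in blocks)
        oracle = exhaustive_best_chain(anchors, 1000, 500)
        assert oracle == 2000 + 1500 + 1800
        assert best == pytest.approx(oracle)

    def test_exhaustive_on_random_anchor_sets(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 9))
            anchors = []
            pos = 0
            for _ in range(n):
                pos += int(rng.integers(100, 3000))
                qoff = int(rng.choice([0, 0, 0, rng.integers(-20_000, 20_000)]))
                length = int(rng.integers(200, 2000))
                anchors.append(A(pos, pos + qoff, length))
                pos += length
            blocks = chain_anchors(anchors, max_gap=2500, max_diag_drift=400)
            assert max(b.score for b in blocks) == pytest.approx(
                exhaustive_best_chain(anchors, 2500, 400)
            )


# ---------------------------------------------------------------------------
# one-to-one filtering


def B(rs, re, qs, qe, identity=1.0, rc="r", qc="q", strand="+"):
    return AlignmentBlock(rc, rs, re, qc, qs, qe, strand, identity, max(re - rs, qe - qs))


def exhaustive_one_to_one(blocks, tol=50):
    from strainscan.align import _conflict

    best, best_score = [], -1.0
    for r in range(len(blocks) + 1):
        for combo in itertools.combinations(blocks, r):
            if any(_conflict(x, y, tol) for x, y in itertools.combinations(combo, 2)):
                continue
            score = sum(b.score for b in combo)
            if score > best_score:
                best, best_score = list(combo), score
    return sorted(best, key=lambda b: (b.ref_chrom, b.ref_start)), best_score


class TestOneToOne:
    def test_length_bound_is_strict(self):
        assert filter_one_to_one([B(0, 10_000, 0, 10_000)]) == []
        assert len(filter_one_to_one([B(0, 10_001, 0, 10_001)])) == 1

    def test_identity_bound_is_inclusive(self):
        kept = filter_one_to_one([B(0, 20_000, 0, 20_000, identity=0.85)])
        assert len(kept) == 1
        assert filter_one_to_one([B(0, 20_000, 0, 20_000, identity=0.849)]) == []

    def test_staged_overlaps_match_exhaustive(self):
        blocks = [
            B(0, 30_000, 0, 30_000, 0.99),
            B(25_000, 60_000, 25_000, 60_000, 0.95),  # conflicts with both ends
            B(55_000, 90_000, 55_000, 90_000, 0.99),
            B(100_000, 130_000, 10_000, 40_000, 0.9),  # query conflict with #1
            B(140_000, 160_000, 140_000, 160_000, 0.92),
        ]
        got = filter_one_to_one(blocks)
        want, want_score = exhaustive_one_to_one(blocks)
        assert sum(b.score for b in got) == pytest.approx(want_score)
        assert got == want

    def test_random_blocks_match_exhaustive(self, rng):
        for _ in range(10):
            blocks = []
            for _ in range(int(rng.integers(4, 13))):
                rs = int(rng.integers(0, 150_000))
                length = int(rng.integers(11_000, 40_000))
                qs = int(rng.integers(0, 150_000))
                ident = float(rng.uniform(0.86, 1.0))
                blocks.append(B(rs, rs + length, qs, qs + length, ident))
            got = filter_one_to_one(blocks)
            _, want_score = exhaustive_one_to_one(blocks)
            assert sum(b.score for b in got) == pytest.approx(want_score)

    def test_retained_blocks_cover_each_base_at_most_once(self, rng):
        blocks = []
        for _ in range(40):
            rs = int(rng.integers(0, 400_000))
            length = int(rng.integers(11_000, 30_000))
            qs = int(rng.integers(0, 400_000))
            blocks.append(B(rs, rs + length, qs, qs + length, float(rng.uniform(0.86, 1))))
        kept = filter_one_to_one(blocks)
        for x, y in itertools.combinations(kept, 2):
            ref_ov = min(x.ref_end, y.ref_end) - max(x.ref_start, y.ref_start)
            qry_ov = min(x.qry_end, y.qry_end) - max(x.qry_start, y.qry_start)
            assert ref_ov <= 50 and qry_ov <= 50


# ---------------------------------------------------------------------------
# end-to-end properties


class TestGenomeScale:
    def test_self_alignment_one_block_per_chromosome(self, make_dna):
        g = GenomeSet({"c1": make_dna(15_000), "c2": make_dna(18_000)})
        kept = filter_one_to_one(align_genomes(g, g))
        assert len(kept) == 2
        assert all(b.identity == 1.0 and b.strand == "+" for b in kept)
        assert {b.ref_chrom for b in kept} == {"c1", "c2"}

    def test_symmetry_on_snp_only_pair(self):
        spec = SimSpec(seed=4, chrom_lengths=[("chr1", 80_000)],
                       baseline_snp_rate=0.002, small_indel_rate=0.0,
                       depth_trend_amplitude=0.0)
        ref = simulate_reference(spec)
        qry, _ = derive_strain(ref, spec)
        fwd = filter_one_to_one(align_genomes(ref, qry), min_len=5000)
        rev = filter_one_to_one(align_genomes(qry, ref), min_len=5000)
        fwd_t = {(b.ref_start, b.ref_end, b.qry_start, b.qry_end) for b in fwd}
        rev_t = {(b.qry_start, b.qry_end, b.ref_start, b.ref_end) for b in rev}
        assert fwd_t == rev_t

    def test_dotplot_table_marks_inversion(self):
        spec = SimSpec(seed=6, chrom_lengths=[("chr1", 120_000)],
                       baseline_snp_rate=0.001,
                       sv_events=[SvEvent("inversion", "chr1", 50_000, 30_000)])
        ref = simulate_reference(spec)
        qry, _ = derive_strain(ref, spec)
        kept = filter_one_to_one(align_genomes(ref, qry))
        df = dotplot_table(kept)
        minus = df[df["strand"] == "-"]
        assert len(minus) == 1
        assert abs(int(minus.iloc[0]["refStart"]) - 50_000) < 100
        assert abs(int(minus.iloc[0]["refEnd"]) - 80_000) < 100

    def test_dotplot_identity_diagonal_and_empty(self, make_dna):
        assert list(dotplot_table([]).columns) == [
            "refChrom", "refStart", "refEnd", "qryChrom", "qryStart",
            "qryEnd", "strand", "identity",
        ]
        g = GenomeSet({"c": make_dna(20_000)})
        df = dotplot_table(filter_one_to_one(align_genomes(g, g)))
        assert (df["refStart"] == df["qryStart"]).all()
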