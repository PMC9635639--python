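"""Generator contracts: determinism, bookkeeping, planted-truth fidelity."""

import numpy as np
import pandas as pd
import pytest

from strainscan import (
    GenomeSet,
    SimSpec,
    SvEvent,
    VariantSet,
    derive_strain,
    emit_dataset,
    revcomp,
    simulate_depth,
    simulate_mito,
    simulate_reference,
)
from strainscan.simulate import depth_trend, write_vcf


def spec_1chrom(length=100_000, **kw):
    defaults = dict(
        seed=1,
        chrom_lengths=[("chr1", length)],
        baseline_snp_rate=0.0,
        small_indel_rate=0.0,
        depth_trend_amplitude=0.0,
    )
    defaults.update(kw)
    return SimSpec(**defaults)


class TestReference:
    def test_length_and_alphabet(self):
        ref = simulate_reference(spec_1chrom(1000))
        assert set(ref["chr1"]) <= set("ACGT")
        assert len(ref["chr1"]) == 1000

    def test_same_seed_byte_identical(self, tmp_path):
        spec = spec_1chrom(5000)
        p1 = simulate_reference(spec).to_fasta(tmp_path / "a.fa")
        p2 = simulate_reference(spec).to_fasta(tmp_path / "b.fa")
        assert p1.read_bytes() == p2.read_bytes()

    def test_seed_changes_sequence(self):
        a = simulate_reference(spec_1chrom(2000, seed=1))["chr1"]
        b = simulate_reference(spec_1chrom(2000, seed=2))["chr1"]
        assert sum(x != y for x, y in zip(a, b)) > 0

    def test_invalid_spec_names_field(self):
        with pytest.raises(ValueError, match="depth_mean"):
            simulate_reference(spec_1chrom(1000, depth_mean=-1))


class TestDeriveStrain:
    def test_deletion_length_bookkeeping(self):
        spec = spec_1chrom(sv_events=[SvEvent("deletion", "chr1", 40_000, 500)])
        ref = simulate_reference(spec)
        qry, truth = derive_strain(ref, spec)
        assert len(qry["chr1"]) == 99_500
        assert truth.sv.iloc[0]["qry_start"] == truth.sv.iloc[0]["qry_end"] == 40_000

    def test_inversion_is_reverse_complement(self):
        spec = spec_1chrom(30_000, sv_events=[SvEvent("inversion", "chr1", 10_000, 10_000)])
        ref = simulate_reference(spec)
        qry, _ = derive_strain(ref, spec)
        r, q = ref["chr1"], qry["chr1"]
        assert q[:10_000] == r[:10_000]
        assert q[20_000:] == r[20_000:]
        assert q[10_000:20_000] == revcomp(r[10_000:20_000])

    def test_vcf_matches_truth_exactly(self, tmp_path):
        spec = spec_1chrom(
            1_000_000,
            snp_landscape=[("chr1", 100_000, 850_000, 0.01)],
            small_indel_rate=1e-5,
        )
        ref = simulate_reference(spec)
        _, truth = derive_strain(ref, spec)
        path = write_vcf(truth.variants, spec.chrom_lengths, tmp_path / "v.vcf")
        vs = VariantSet.from_vcf(path)
        assert len(vs) == len(truth.variants)
        n_snps_vcf = int(vs.records["is_snp"].sum())
        assert n_snps_vcf == int((truth.variants["kind"] == "snp").sum())

    def test_hot_window_count_is_binomial(self):
        # flat depth trend => counts are exact Binomial(len, rate) draws
        rate, length = 0.01, 750_000
        spec = spec_1chrom(1_000_000, snp_landscape=[("chr1", 0, length, rate)])
        ref = simulate_reference(spec)
        _, truth = derive_strain(ref, spec)
        in_window = truth.variants[
            (truth.variants["kind"] == "snp") & (truth.variants["pos"] <= length)
        ]
        mean = rate * length
        sd = np.sqrt(length * rate * (1 - rate))
        assert abs(len(in_window) - mean) < 3 * sd

    def test_depth_coupling_scales_snp_rate_with_trend(self):
        spec = spec_1chrom(
            3_000_000,
            baseline_snp_rate=0.02,
            depth_trend_amplitude=0.15,
            depth_coupling=True,
        )
        ref = simulate_reference(spec)
        _, truth = derive_strain(ref, spec)
        pos = truth.variants["pos"].to_numpy()
        # trend peak at 750 kb, trough at 2.25 Mb (period 3 Mb, phase 0)
        peak = ((pos > 650_000) & (pos <= 850_000)).sum()
        trough = ((pos > 2_150_000) & (pos <= 2_350_000)).sum()
        assert peak > trough * 1.15

    def test_relocation_moves_sequence_between_frames(self):
        spec = SimSpec(
            seed=3,
            chrom_lengths=[("chr1", 120_000), ("chr2", 120_000)],
            baseline_snp_rate=0.0,
            small_indel_rate=0.0,
            sv_events=[
                SvEvent("relocation_diff", "chr1", 40_000, 5_000,
                        destination=("chr2", 60_000))
            ],
        )
        ref = simulate_reference(spec)
        qry, truth = derive_strain(ref, spec)
        row = truth.sv.iloc[0]
        moved = qry[row.qry_chrom][row.qry_start : row.qry_end]
        assert moved == ref["chr1"][40_000:45_000]
        assert len(qry["chr1"]) == 115_000
        assert len(qry["chr2"]) == 125_000

    def test_query_reconstructable_from_truth(self):
        """Independent right-to-left string editing of the reference using
        only the truth records must reproduce the emitted query."""
        spec = spec_1chrom(
            200_000,
            baseline_snp_rate=0.001,
            small_indel_rate=2e-5,
            sv_events=[
                SvEvent("deletion", "chr1", 30_000, 700),
                SvEvent("insertion", "chr1", 60_000, 900),
                SvEvent("inversion", "chr1", 90_000, 8_000),
                SvEvent("tandem_dup", "chr1", 130_000, 1_200),
            ],
        )
        ref = simulate_reference(spec)
        qry, truth = derive_strain(ref, spec)

        seq = ref["chr1"]
        edits = []  # (start0, end0, replacement)
        for row in truth.sv.itertuples(index=False):
            if row.kind == "deletion":
                edits.append((row.ref_start, row.ref_end, ""))
            elif row.kind == "insertion":
                edits.append((row.ref_start, row.ref_start, row.inserted_seq))
            elif row.kind == "inversion":
                edits.append((row.ref_start, row.ref_end,
                              revcomp(seq[row.ref_start:row.ref_end])))
            elif row.kind == "tandem_dup":
                edits.append((row.ref_start, row.ref_end,
                              seq[row.ref_start:row.ref_end] * 2))
        for row in truth.variants.itertuples(index=False):
            if row.kind == "snp":
                edits.append((row.pos - 1, row.pos, row.alt))
            else:  # VCF-anchored indel alleles
                edits.append((row.pos - 1, row.pos - 1 + len(row.ref), row.alt))
        for s, e, repl in sorted(edits, key=lambda t: -t[0]):
            seq = seq[:s] + repl + seq[e:]
        assert seq == qry["chr1"]

    def test_overlapping_svs_rejected(self):
        spec = spec_1chrom(sv_events=[
            SvEvent("deletion", "chr1", 10_000, 5_000),
            SvEvent("inversion", "chr1", 12_000, 5_000),
        ])
        with pytest.raises(ValueError, match="overlap"):
            simulate_reference(spec)

    def test_sv_past_chromosome_end_rejected(self):
        spec = spec_1chrom(sv_events=[SvEvent("deletion", "chr1", 99_000, 5_000)])
        with pytest.raises(ValueError, match="past chromosome end"):
            simulate_reference(spec)

    def test_destination_required_iff_relocation(self):
        with pytest.raises(ValueError, match="destination"):
            spec_1chrom(sv_events=[SvEvent("deletion", "chr1", 10_000, 100,
                                           destination=("chr1", 50_000))]).validate()


class TestDepth:
    def test_bin_count_includes_partial(self):
        spec = spec_1chrom(10_000)
        track = simulate_depth(simulate_reference(spec), spec)
        assert len(track.counts["chr1"]) == 10
        spec2 = spec_1chrom(10_500)
        track2 = simulate_depth(simulate_reference(spec2), spec2)
        assert len(track2.counts["chr1"]) == 11

    def test_planted_outliers_strictly_outside_bounds(self):
        spec = spec_1chrom(
            100_000,
            depth_outliers=[("chr1", 10_000, 20_000, "low"),
                            ("chr1", 50_000, 60_000, "high")],
        )
        track = simulate_depth(simulate_reference(spec), spec)
        c = track.counts["chr1"]
        assert (c[10:20] <= 19).all()
        assert (c[50:60] >= 351).all()

    def test_sample_mean_near_spec_mean(self):
        spec = SimSpec(seed=5, chrom_lengths=[("chr1", 10_000_000)],
                       baseline_snp_rate=0.0, depth_mean=250.0)
        track = simulate_depth(simulate_reference(spec), spec)
        m = float(track.counts["chr1"].mean())
        assert abs(m - 250.0) / 250.0 < 0.05

    def test_trend_is_smooth_and_centered(self):
        spec = spec_1chrom(depth_trend_amplitude=0.15)
        x = np.arange(0, 3_000_000, 1000)
        t = depth_trend(spec, 0, x)
        assert abs(t.mean() - 1.0) < 0.01
        assert t.min() >= 0.85 and t.max() <= 1.15


class TestMito:
    def test_overassembly_and_lengths(self):
        mito = simulate_mito(SimSpec(seed=2))
        assert len(mito.circle_a) == 16_818
        assert len(mito.overassembled_a) == 16_818 + 400
        # the spurious terminal duplication repeats the start of the contig
        assert mito.overassembled_a[:400] == mito.overassembled_a[-400:]

    def test_insertion_coordinates(self):
        mito = simulate_mito(SimSpec(seed=2))
        s, e = mito.insertion_a
        assert e - s == 184
        s2, e2 = mito.insertion_b
        assert e2 - s2 == 137


class TestEmit:
    def test_roundtrip_and_reproducibility(self, tmp_path):
        spec = SimSpec(
            seed=9,
            chrom_lengths=[("chr1", 60_000), ("chr2", 40_000)],
            baseline_snp_rate=0.002,
            sv_events=[SvEvent("deletion", "chr1", 20_000, 800),
                       SvEvent("insertion", "chr2", 20_000, 600)],
            depth_outliers=[("chr1", 5_000, 8_000, "low")],
        )
        m1 = emit_dataset(tmp_path / "run1", spec)
        assert len(m1["files"]) >= 5
        ref = GenomeSet.from_fasta(m1["files"]["ref"])
        qry = GenomeSet.from_fasta(m1["files"]["query"])
        assert ref.lengths == {"chr1": 60_000, "chr2": 40_000}
        assert len(qry["chr1"]) == 59_200
        vs = VariantSet.from_vcf(m1["files"]["variants"])
        # VCF sorted by chromosome then position
        df = vs.records
        for _, grp in df.groupby("chrom", sort=False):
            assert grp["pos"].is_monotonic_increasing
        sv_bed = pd.read_csv(m1["files"]["truth_sv"], sep="\t", header=None)
        assert len(sv_bed) == len(spec.sv_events)

        m2 = emit_dataset(tmp_path / "run2", spec)
        for key, p1 in m1["files"].items():
            p2 = m2["files"][key]
            assert open(p1, "rb").read() == open(p2, "rb").read(), key
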