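"""Depth-filtered, coverage-normalized sliding-window SNP density.

The statistic implemented here answers "where along the genome is this
strain polymorphic relative to the assembly?" for pooled resequencing
data, while guarding against artifacts of uneven coverage:

1. 1-kb depth bins with aberrant read counts (fewer than ``lo`` or more
   than ``hi`` reads, defaults 20 and 350, i.e. below 4x or above 70x for
   200-bp reads) are masked as outliers before any counting.
2. Indels are discarded; only SNPs are counted.
3. SNPs are counted in sliding windows (width 750 kb, step 250 kb) and
   divided by the window's mean fold-coverage, yielding "SNPs per bases
   mapped". Raw SNP counts track read depth (more reads, more calls);
   the normalized density does not, which is the point of the division.
4. Windows are called ``high`` (> 500) or ``low`` (< 1) polymorphism,
   both bounds strict.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

BIN_WIDTH = 1000
DEFAULT_LO = 20
DEFAULT_HI = 350
DEFAULT_WINDOW = 750_000
DEFAULT_STEP = 250_000
DEFAULT_HIGH_THR = 500.0
DEFAULT_LOW_THR = 1.0
DEFAULT_READ_LEN = 200

# floor used only when log-scaling densities for display
LOG_FLOOR = 1e-2


# ---------------------------------------------------------------------------
# containers


@dataclass
class DepthTrack:
    """Per-chromosome 1-kb binned read counts with an outlier mask.

    Bins are anchored at position 0 of each chromosome with fixed 1-kb
    width; the final bin is truncated at the chromosome end. ``mask`` is
    True for retained bins and is only ever set by
    :func:`filter_depth_outliers`.
    """

    counts: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]
    bin_width: int = BIN_WIDTH
    mask: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, arr in self.counts.items():
            expected = n_bins(self.chrom_lengths[chrom], self.bin_width)
            if len(arr) != expected:
                raise ValueError(
                    f"{chrom}: {len(arr)} bins, expected {expected} "
                    f"for length {self.chrom_lengths[chrom]}"
                )
            if (np.asarray(arr) < 0).any():
                raise ValueError(f"{chrom}: negative bin counts")
        if not self.mask:
            self.mask = {c: np.ones(len(a), dtype=bool) for c, a in self.counts.items()}

    def bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(len(self.counts[chrom]), dtype=np.int64) * self.bin_width

    def bin_ends(self, chrom: str) -> np.ndarray:
        ends = self.bin_starts(chrom) + self.bin_width
        return np.minimum(ends, self.chrom_lengths[chrom])

    def to_tsv(self, path: str | Path) -> Path:
        """Write ``chrom  binStart  binEnd  readCount`` (0-based half-open)."""
        path = Path(path)
        frames = []
        for chrom in self.counts:
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "binStart": self.bin_starts(chrom),
                        "binEnd": self.bin_ends(chrom),
                        "readCount": self.counts[chrom],
                    }
                )
            )
        pd.concat(frames).to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DepthTrack":
        df = pd.read_csv(path, sep="\t", comment="#")
        counts: dict[str, np.ndarray] = {}
        lengths: dict[str, int] = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("binStart")
            counts[chrom] = grp["readCount"].to_numpy(dtype=np.int64)
            lengths[chrom] = int(grp["binEnd"].max())
        return cls(counts=counts, chrom_lengths=lengths)


def n_bins(chrom_length: int, bin_width: int = BIN_WIDTH) -> int:
    """Number of 1-kb bins covering a chromosome (final partial bin included)."""
    return -(-chrom_length // bin_width)


@dataclass
class VariantSet:
    """Flat table of variant records (``chrom``, ``pos`` 1-based, ``ref``,
    ``alt`` comma-joined alternates, ``is_snp``), sorted within chromosome."""

    records: pd.DataFrame

    COLUMNS = ("chrom", "pos", "ref", "alt", "is_snp")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"variant table missing columns: {sorted(missing)}")
        for _, grp in self.records.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("variant positions not sorted within chromosome")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_vcf(cls, path: str | Path) -> "VariantSet":
        from cyvcf2 import VCF

        rows = []
        for rec in VCF(str(path)):
            alts = list(rec.ALT)
            is_snp = len(rec.REF) == 1 and len(alts) > 0 and all(len(a) == 1 for a in alts)
            rows.append((rec.CHROM, rec.POS, rec.REF, ",".join(alts), is_snp))
        df = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        return cls(df)


@dataclass
class WindowStat:
    """Statistics for one sliding window."""

    chrom: str
    start: int
    end: int
    snp_count: int
    mean_depth: float  # fold-coverage over retained bins; NaN if none retained
    norm_density: float  # snp_count / mean_depth, "SNPs per bases mapped"
    call: str = "mid"  # high | low | mid | no_data


# ---------------------------------------------------------------------------
# operations


def filter_depth_outliers(
    track: DepthTrack, lo: int = DEFAULT_LO, hi: int = DEFAULT_HI
) -> DepthTrack:
    """Mask 1-kb bins with aberrant read counts.

    A bin is excluded iff its count is strictly below ``lo`` or strictly
    above ``hi``; counts equal to either bound are retained.
    """
    mask = {c: (a >= lo) & (a <= hi) for c, a in track.counts.items()}
    return replace(track, mask=mask)


def drop_indels(variants: VariantSet) -> VariantSet:
    """Keep only SNP records (multi-allelic sites kept iff every alternate
    allele is a single base)."""
    df = variants.records
    return VariantSet(df[df["is_snp"]].reset_index(drop=True))


def make_windows(
    chrom_lengths: dict[str, int],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list[tuple[str, int, int]]:
    """Sliding window frames: starts at 0, step, 2*step, ... while the start
    is inside the chromosome; ends truncated at the chromosome end."""
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    out = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            out.append((chrom, start, min(start + window, length)))
            start += step
    return out


def window_stats(
    windows: Sequence[tuple[str, int, int]],
    snps: VariantSet,
    track: DepthTrack,
    read_len: int = DEFAULT_READ_LEN,
) -> list[WindowStat]:
    """Per-window SNP count, mean retained coverage, and normalized density.

    A SNP is counted if its position falls inside the window *and* inside a
    retained depth bin. Mean depth converts retained bin read counts to
    fold-coverage (count * read_len / bin_width) and averages over retained
    bins only. Windows whose bins are all masked are ``no_data``.
    """
    if read_len <= 0:
        raise ValueError("read_len must be positive")
    bw = track.bin_width

    # positions of SNPs that survive the bin mask, per chromosome
    kept_pos: dict[str, np.ndarray] = {}
    snp_df = snps.records[snps.records["is_snp"]]
    for chrom, grp in snp_df.groupby("chrom", sort=False):
        pos0 = grp["pos"].to_numpy(dtype=np.int64) - 1  # 0-based
        if chrom not in track.counts:
            kept_pos[chrom] = np.array([], dtype=np.int64)
            continue
        bins = pos0 // bw
        valid = bins < len(track.counts[chrom])
        keep = np.zeros(len(pos0), dtype=bool)
        keep[valid] = track.mask[chrom][bins[valid]]
        kept_pos[chrom] = np.sort(pos0[keep])

    out = []
    for chrom, start, end in windows:
        if chrom not in track.counts:
            out.append(WindowStat(chrom, start, end, 0, math.nan, math.nan, "no_data"))
            continue
        counts = track.counts[chrom]
        mask = track.mask[chrom]
        b0 = start // bw
        b1 = min(-(-end // bw), len(counts))
        wmask = mask[b0:b1]
        n_ret = int(wmask.sum())
        pos = kept_pos.get(chrom, np.array([], dtype=np.int64))
        snp_count = int(np.searchsorted(pos, end) - np.searchsorted(pos, start))
        if n_ret == 0:
            out.append(WindowStat(chrom, start, end, snp_count, math.nan, math.nan, "no_data"))
            continue
        mean_depth = float(counts[b0:b1][wmask].sum()) * read_len / bw / n_ret
        norm = snp_count / mean_depth
        out.append(WindowStat(chrom, start, end, snp_count, mean_depth, norm))
    return out


def call_regions(
    stats: Sequence[WindowStat],
    high_thr: float = DEFAULT_HIGH_THR,
    low_thr: float = DEFAULT_LOW_THR,
) -> tuple[list[WindowStat], pd.DataFrame]:
    """Label each window high/low/mid polymorphism (strict thresholds on both
    sides) and summarize per-chromosome window counts.

    ``no_data`` windows are never called and are excluded from the summary
    denominator.
    """
    labeled = []
    for w in stats:
        if w.call == "no_data":
            labeled.append(w)
            continue
        if w.norm_density > high_thr:
            call = "high"
        elif w.norm_density < low_thr:
            call = "low"
        else:
            call = "mid"
        labeled.append(replace(w, call=call))
    rows = []
    for chrom in dict.fromkeys(w.chrom for w in labeled):
        ws = [w for w in labeled if w.chrom == chrom]
        rows.append(
            {
                "chrom": chrom,
                "windows": sum(w.call != "no_data" for w in ws),
                "high": sum(w.call == "high" for w in ws),
                "low": sum(w.call == "low" for w in ws),
                "no_data": sum(w.call == "no_data" for w in ws),
            }
        )
    return labeled, pd.DataFrame(rows)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    return float(_scipy_stats.pearsonr(x, y)[0])


def gene_counts_per_window(
    windows: Sequence[tuple[str, int, int]], genes_bed: pd.DataFrame
) -> np.ndarray:
    """Count gene starts (BED 0-based) falling in each window; used for the
    gene-count vs SNP-density correlation."""
    starts: dict[str, np.ndarray] = {
        chrom: np.sort(grp.iloc[:, 1].to_numpy(dtype=np.int64))
        for chrom, grp in genes_bed.groupby(genes_bed.columns[0], sort=False)
    }
    out = np.zeros(len(windows), dtype=np.int64)
    for i, (chrom, s, e) in enumerate(windows):
        pos = starts.get(chrom)
        if pos is not None:
            out[i] = np.searchsorted(pos, e) - np.searchsorted(pos, s)
    return out


def stats_table(stats: Sequence[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in stats],
            "start": [w.start for w in stats],
            "end": [w.end for w in stats],
            "snpCount": [w.snp_count for w in stats],
            "meanDepth": [w.mean_depth for w in stats],
            "normDensity": [w.norm_density for w in stats],
            "call": [w.call for w in stats],
        }
    )


def write_stats(stats: Sequence[WindowStat], path: str | Path, header: str = "") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip().splitlines():
                fh.write(f"# {line}\n")
        stats_table(stats).to_csv(fh, sep="\t", index=False)
    return path


def write_summary(summary: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(summary.to_dict(orient="records"), indent=2) + "\n")
    return path


def plot_landscape(
    stats: Sequence[WindowStat],
    path: str | Path,
    high_thr: float = DEFAULT_HIGH_THR,
    low_thr: float = DEFAULT_LOW_THR,
) -> Path:
    """Per-chromosome log10 density track with threshold lines.

    Zero-density windows are drawn at a fixed floor so the log axis is
    defined; the floor never affects region calls.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(w.chrom for w in stats))
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(10, 2.2 * len(chroms)), squeeze=False, sharey=True
    )
    for ax, chrom in zip(axes[:, 0], chroms):
        ws = [w for w in stats if w.chrom == chrom and w.call != "no_data"]
        mid = [(w.start + w.end) / 2e6 for w in ws]
        dens = [max(w.norm_density, LOG_FLOOR) for w in ws]
        color = {"high": "crimson", "low": "steelblue", "mid": "gray"}
        ax.scatter(mid, dens, s=12, c=[color[w.call] for w in ws])
        ax.set_yscale("log")
        ax.axhline(high_thr, ls="--", lw=0.8, c="crimson")
        ax.axhline(low_thr, ls="--", lw=0.8, c="steelblue")
        ax.set_ylabel("SNPs / bases mapped")
        ax.set_title(chrom, fontsize=9)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
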