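"""Ready-made simulation scenarios for validating the pipeline.

Each function returns a :class:`~strainscan.simulate.SimSpec` describing
a study design at desk scale: genome sizes of a few megabases, coverage
around 50x, and planted features sized so that every downstream stage
has unambiguous truth to recover. The layouts are fixed; the seed only
drives the random draws (sequences, variant placement, depth noise).
"""

from __future__ import annotations

import numpy as np

from .simulate import SimSpec, SvEvent

#: per-base SNP rate of a high-polymorphism interval: a full 750-kb window
#: at 50x yields a normalized density of 0.045 * 750000 / 50 = 675 (> 500)
HOT_RATE = 0.045
#: background rate: 0.002 * 750000 / 50 = 30, comfortably mid-range
BASELINE_RATE = 0.002


def sv_recovery_spec(seed: int) -> SimSpec:
    """Two 2.5-Mb chromosomes with 25 planted SVs.

    10 deletions and 10 insertions of 1-5 kb, 3 inversions of 20-30 kb and
    2 inter-chromosome relocations of 30-40 kb, spaced ~100 kb apart so
    every inter-event alignment block clears the one-to-one length filter.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 77]))
    events: list[SvEvent] = []
    slots = {
        "chr1": iter(range(150_000, 2_400_000, 105_000)),
        "chr2": iter(range(150_000, 2_400_000, 105_000)),
    }
    for i in range(10):
        chrom = "chr1" if i < 5 else "chr2"
        events.append(
            SvEvent("deletion", chrom, next(slots[chrom]), int(rng.integers(1000, 5001)))
        )
    for i in range(10):
        chrom = "chr1" if i < 5 else "chr2"
        events.append(
            SvEvent("insertion", chrom, next(slots[chrom]), int(rng.integers(1000, 5001)))
        )
    for i in range(3):
        chrom = "chr1" if i < 2 else "chr2"
        events.append(
            SvEvent("inversion", chrom, next(slots[chrom]), int(rng.integers(20_000, 30_001)))
        )
    for i, (src, dst) in enumerate([("chr1", "chr2"), ("chr2", "chr1")]):
        events.append(
            SvEvent(
                "relocation_diff", src, next(slots[src]),
                int(rng.integers(30_000, 40_001)),
                destination=(dst, next(slots[dst]) + 52_500),
            )
        )
    return SimSpec(
        seed=seed,
        chrom_lengths=[("chr1", 2_500_000), ("chr2", 2_500_000)],
        baseline_snp_rate=BASELINE_RATE,
        sv_events=events,
    )


def landscape_spec(seed: int) -> SimSpec:
    """Two 5-Mb chromosomes with 3 hot and 5 cold 750-kb intervals.

    Hot/cold intervals are aligned to the 250-kb window grid and separated
    so that exactly the fully-contained sliding window of each interval
    crosses the calling threshold; partially overlapping neighbours stay
    mid-range. Depth outlier regions (planted low and high bins) sit in
    background territory.
    """
    hot = [
        ("chr1", 750_000, 1_500_000),
        ("chr1", 3_750_000, 4_500_000),
        ("chr2", 750_000, 1_500_000),
    ]
    cold = [
        ("chr1", 0, 750_000),
        ("chr1", 2_250_000, 3_000_000),
        ("chr2", 0, 750_000),
        ("chr2", 2_250_000, 3_000_000),
        ("chr2", 3_750_000, 4_500_000),
    ]
    landscape = [(c, s, e, HOT_RATE) for c, s, e in hot]
    landscape += [(c, s, e, 0.0) for c, s, e in cold]
    return SimSpec(
        seed=seed,
        chrom_lengths=[("chr1", 5_000_000), ("chr2", 5_000_000)],
        snp_landscape=landscape,
        baseline_snp_rate=BASELINE_RATE,
        depth_outliers=[
            ("chr1", 1_800_000, 1_820_000, "low"),
            ("chr1", 4_600_000, 4_610_000, "high"),
            ("chr2", 1_800_000, 1_820_000, "high"),
            ("chr2", 4_600_000, 4_610_000, "low"),
        ],
    )


def mito_spec(seed: int) -> SimSpec:
    """Default mitogenome scenario: a 16,818-bp focal circle whose strain
    pair diverges by ~0.5% substitutions plus one 184-bp and one 137-bp
    strain-specific control-region insertion, emitted over-assembled with a
    400-bp terminal duplication."""
    return SimSpec(seed=seed)
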