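"""Assembly contiguity report for any FASTA.

Writes a small assembly and prints sequence counts, total length with
and without N gap characters, N50 (largest length L such that sequences
>= L cover at least half the assembly) and the length distribution.
"""

from pathlib import Path

from strainscan import GenomeSet, summarize
from strainscan.simulate import SimSpec, simulate_reference

out = Path("example_output")
out.mkdir(exist_ok=True)
spec = SimSpec(
    seed=42,
    chrom_lengths=[("scaf1", 120_000), ("scaf2", 80_000), ("scaf3", 30_000),
                   ("scaf4", 15_000)],
)
genome = simulate_reference(spec)
# splice an N gap into one scaffold, as scaffolders do between contigs
seqs = dict(genome.sequences)
seqs["scaf2"] = seqs["scaf2"][:40_000] + "N" * 500 + seqs["scaf2"][40_000:]
fasta = GenomeSet(seqs).to_fasta(out / "assembly.fasta")

report = summarize(fasta)
print(report.to_markdown())
print("N50 here means half the assembly is in scaffolds of at least "
      f"{report.n50:,} bp; the N-free total excludes the {500} scaffold-gap Ns.")
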