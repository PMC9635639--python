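"""Whole-genome alignment of a strain pair and the one-to-one block set.

Simulates a small strain pair, finds unique-k-mer anchors, chains them
into blocks, filters to the best one-to-one set (blocks > 10 kb with
identity >= 85%, no base covered twice on either genome) and prints the
dotplot table. Reverse-strand rows mark inversions.
"""

from strainscan import align_genomes, derive_strain, dotplot_table, filter_one_to_one
from strainscan import simulate_reference
from strainscan.cli import demo_spec

spec = demo_spec(seed=42)
ref = simulate_reference(spec)
qry, truth = derive_strain(ref, spec)

blocks = align_genomes(ref, qry)
one = filter_one_to_one(blocks)
print(f"{len(blocks)} chained blocks, {len(one)} retained one-to-one\n")
print(dotplot_table(one).to_string(index=False))
print(
    "\nEach row is one alignment block; refStart == qryStart rows lie on "
    "the dotplot diagonal, strand '-' rows are inversions, and rows whose "
    "query chromosome differs are relocations."
)
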