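"""Genome container and sequence utilities.

A :class:`GenomeSet` is the coordinate frame every downstream stage works
in: an ordered mapping of chromosome (or contig) names to uppercase DNA
sequences, with an optional circularity flag per sequence. Sequences are
kept as plain Python strings; the alignment stage converts them to numeric
arrays on demand.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: mapping of A/C/G/T to 2-bit codes used by the aligner
BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    BASE_TO_CODE[_b] = _i
    BASE_TO_CODE[_b + 32] = _i  # lowercase


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes 0..3 (255 for non-ACGT)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return BASE_TO_CODE[raw]


@dataclass
class GenomeSet:
    """Ordered collection of named chromosome sequences.

    Parameters
    ----------
    sequences:
        Mapping name -> uppercase DNA string. Insertion order is the
        chromosome order used in every emitted file.
    circular:
        Names of sequences that represent circular molecules.
    """

    sequences: dict[str, str]
    circular: set[str] = field(default_factory=set)

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def to_fasta(self, path: str | Path, width: int = 80) -> Path:
        """Write the genome to FASTA with fixed line wrapping.

        The output is byte-deterministic for a given genome, which the
        simulator relies on for reproducibility checks.
        """
        path = Path(path)
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
        return path

    @classmethod
    def from_fasta(cls, path: str | Path, circular: set[str] | None = None) -> "GenomeSet":
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            seqs[rec.id] = str(rec.seq).upper()
        if not seqs:
            raise ValueError(f"no sequences found in {path}")
        return cls(seqs, circular=set(circular or ()))

    def to_records(self) -> list[SeqRecord]:
        return [SeqRecord(Seq(s), id=n, description="") for n, s in self.sequences.items()]

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        buf = io.StringIO()
        for n, s in self.sequences.items():
            buf.write(f"{n}\t{len(s)} bp\n")
        return buf.getvalue()
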