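"""Assembly summary statistics (contiguity report for any FASTA)."""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO


@dataclass
class AssemblyReport:
    n_seqs: int
    total_length: int
    total_length_no_n: int  # assembly length minus N gap characters
    n50: int
    median_length: float
    min_length: int
    max_length: int
    per_scaffold: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "n_seqs": self.n_seqs,
            "total_length": self.total_length,
            "total_length_no_n": self.total_length_no_n,
            "n50": self.n50,
            "median_length": self.median_length,
            "min_length": self.min_length,
            "max_length": self.max_length,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    def to_markdown(self) -> str:
        rows = [
            ("Number of sequences", f"{self.n_seqs:,}"),
            ("Total length (bp)", f"{self.total_length:,}"),
            ("Total length minus Ns (bp)", f"{self.total_length_no_n:,}"),
            ("N50 (bp)", f"{self.n50:,}"),
            ("Median length (bp)", f"{self.median_length:,}"),
            ("Minimum length (bp)", f"{self.min_length:,}"),
            ("Maximum length (bp)", f"{self.max_length:,}"),
        ]
        out = ["| Metric | Value |", "| --- | --- |"]
        out += [f"| {k} | {v} |" for k, v in rows]
        return "\n".join(out) + "\n"


def n50(lengths: list[int]) -> int:
    """Largest length L such that sequences of length >= L sum to at least
    half the assembly total (ceiling semantics on odd totals)."""
    if not lengths:
        raise ValueError("empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("all lengths must be positive")
    half = (sum(lengths) + 1) // 2
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if acc >= half:
            return l
    raise AssertionError("unreachable")  # pragma: no cover


def summarize(fasta_path: str | Path) -> AssemblyReport:
    """One-pass contiguity report. Lowercase and uppercase N both count as
    gap characters; other IUPAC ambiguity codes count as sequence."""
    names, lengths, n_counts = [], [], []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        s = str(rec.seq)
        names.append(rec.id)
        lengths.append(len(s))
        n_counts.append(s.count("N") + s.count("n"))
    if not names:
        raise ValueError(f"no sequences in {fasta_path}")
    per_scaffold = pd.DataFrame({"name": names, "length": lengths, "n_bases": n_counts})
    total = sum(lengths)
    return AssemblyReport(
        n_seqs=len(lengths),
        total_length=total,
        total_length_no_n=total - sum(n_counts),
        n50=n50(lengths),
        median_length=float(statistics.median(lengths)),
        min_length=min(lengths),
        max_length=max(lengths),
        per_scaffold=per_scaffold,
    )
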