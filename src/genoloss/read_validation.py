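"""Validation of candidate mutations against unassembled sequencing reads.

An assembly base call can be a sequencing or consensus error; a real
mutation should be supported by the raw reads.  The mutated allele plus
at least 50 bp of flanking assembly sequence on each side is taken as
the context, and a mutation is considered validated when at least 10
reads contain that context as an exact substring (in either
orientation — reads are unstranded).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "MutationContext",
    "extract_context",
    "count_support",
    "read_sequences",
    "MIN_SUPPORT",
    "DEFAULT_FLANK",
]

MIN_SUPPORT = 10
DEFAULT_FLANK = 50


@dataclass
class MutationContext:
    """The genomic context of one mutation in the query assembly."""

    mutation_id: str
    context: str
    revcomp: str = ""

    def __post_init__(self) -> None:
        self.context = self.context.upper()
        if not self.revcomp:
            self.revcomp = str(Seq(self.context).reverse_complement())


def extract_context(
    assembly,
    contig: str,
    position: int,
    mutation_id: str = "",
    flank: int = DEFAULT_FLANK,
    allele_length: int = 1,
) -> MutationContext:
    """Extract the mutated allele with ``flank`` bp either side.

    ``position`` is the 0-based start of the mutated allele on the
    query contig; ``allele_length`` is 1 for point substitutions, the
    insertion length for insertions and 0 for a deletion junction.
    Near a contig end the maximal available flank is used, with a
    warning.  A context overlapping an assembly N-run cannot be
    confirmed and raises.
    """
    import warnings

    seq = assembly.sequences[contig]
    start = position - flank
    end = position + allele_length + flank
    if start < 0 or end > len(seq):
        warnings.warn(
            f"context for {mutation_id or contig} truncated at contig edge"
        )
        start = max(0, start)
        end = min(len(seq), end)
    if assembly.overlaps_gap(contig, start, end):
        raise ValueError("mutation context overlaps an assembly gap")
    return MutationContext(mutation_id=mutation_id, context=seq[start:end])


def count_support(
    context: MutationContext,
    reads: Iterable[str],
    min_support: int = MIN_SUPPORT,
) -> tuple[int, bool]:
    """Count reads containing the full context verbatim.

    A read supports the mutation when the context (or its reverse
    complement) occurs in it as an exact substring; partial or
    one-mismatch hits do not count.  Validated iff the count reaches
    ``min_support``.
    """
    fwd, rev = context.context, context.revcomp
    n = 0
    for read in reads:
        r = read.upper()
        if fwd in r or rev in r:
            n += 1
    return n, n >= min_support


def read_sequences(path: str | Path) -> list[str]:
    """Load read sequences from FASTA or FASTQ (by extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
    return [str(rec.seq) for rec in SeqIO.parse(str(path), fmt)]
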