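"""Filter cascade removing artifact mutations from conserved genes.

Sequencing errors near assembly gaps, alignments to processed
pseudogenes or paralogs, suboptimal exon alignments, evolutionary
splice-site shifts and precise intron deletions, and weakly constrained
protein termini all mimic gene-inactivating mutations.  The cascade
applies, in fixed order: exon-presence/assembly-gap filtering, a
conserved-gene-order (synteny) check, a frame-aware realignment rescue,
a terminal-20% trim, and isoform selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import Align

from .io_formats import ExonAlignment, GenomeAssembly, PairwiseGeneAlignment, TranscriptModel
from .mutation_scan import (
    ACCEPTOR_CONSENSUS,
    BIG_INDEL,
    DONOR_CONSENSUS,
    FS_DEL,
    FS_INS,
    SPLICE_ACCEPTOR,
    SPLICE_DONOR,
    STOP_IN_INS,
    STOP_SUBST,
    InactivatingMutation,
    apply_compensation,
    scan_exon,
)

__all__ = [
    "FilterTrace",
    "gap_filter",
    "synteny_filter",
    "rescue_realign",
    "terminal_trim",
    "select_isoform",
    "apply_cascade",
    "FILTER_ORDER",
]

FILTER_ORDER = ("scan", "gap", "synteny", "realign", "terminal", "isoform")

_POINT_CLASSES = {FS_INS, FS_DEL, STOP_SUBST, STOP_IN_INS, SPLICE_DONOR, SPLICE_ACCEPTOR}

SPLICE_SHIFT_WINDOW = 18  # bp searched either side for a relocated splice site


@dataclass
class FilterTrace:
    """Per gene x species record of surviving-mutation counts by step."""

    gene_id: str
    species: str
    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def record(self, step: str, before: int, after: int) -> None:
        self.steps.append((step, before, after))

    def counts(self) -> list[int]:
        return [n_after for _, _, n_after in self.steps]


def _surviving(muts: Sequence[InactivatingMutation]) -> int:
    return sum(1 for m in muts if m.surviving)


def gap_filter(
    muts: Sequence[InactivatingMutation],
    assembly: Optional[GenomeAssembly],
    near: int = 1,
) -> list[InactivatingMutation]:
    """Drop point mutations within ``near`` query bp of an assembly N-run.

    Exon-level deletion/unaligned calls over gapped inter-anchor regions
    are already reclassified as missing data by the presence scan.
    """
    out = list(muts)
    if assembly is None:
        return out
    for m in out:
        if not m.surviving or m.mclass not in _POINT_CLASSES:
            continue
        if m.query_contig is None or m.query_pos is None:
            continue
        # the whole mutated allele must be clear of Ns: a codon for stop
        # substitutions, the inserted/deleted stretch for indels
        span = m.length if m.length else (3 if m.mclass in (STOP_SUBST, STOP_IN_INS) else 1)
        if assembly.overlaps_gap(m.query_contig, m.query_pos - near, m.query_pos + span + near):
            m.filtered_reason = "near_gap"
    return out


def synteny_filter(
    gene_locus: Optional[tuple[str, int, int]],
    up_neighbor: Optional[tuple[str, int, int]],
    down_neighbor: Optional[tuple[str, int, int]],
) -> bool:
    """Conserved-gene-order test for one gene x query species.

    Passes when the gene's aligned query locus lies on the same contig
    as, and strictly between, the query loci of its flanking reference
    neighbors; a jointly inverted neighborhood also passes.  Unaligned
    neighbors (or a contig end) give a pass — absence of evidence is not
    treated as failure.
    """
    if gene_locus is None:
        return True
    if up_neighbor is None and down_neighbor is None:
        return True
    contig, start, end = gene_locus
    sides = []
    for nb in (up_neighbor, down_neighbor):
        if nb is None:
            sides.append(None)
            continue
        nb_contig, nb_start, nb_end = nb
        if nb_contig != contig:
            return False
        if nb_end <= start:
            sides.append(-1)
        elif nb_start >= end:
            sides.append(+1)
        else:
            return False  # neighbor overlaps the gene locus
    known = [s for s in sides if s is not None]
    if len(known) == 2 and known[0] == known[1]:
        return False  # both neighbors on the same side: order broken
    return True


def rescue_realign(
    ealn: ExonAlignment,
    muts: Sequence[InactivatingMutation],
    assembly: Optional[GenomeAssembly],
    frame_offset: int,
    exon_index: int,
    cds_start: int,
    cds_length: int,
    next_ealn: Optional[ExonAlignment] = None,
) -> list[InactivatingMutation]:
    """Remove candidate mutations that an exon-structure-aware look
    at the query locus explains away.

    Three rescues, mirroring what a splice-aware exon realigner finds:
    (a) a disrupted splice site whose consensus dinucleotide reappears
    within +-18 bp at a frame-preserving offset (filtered_reason
    "splice_shift"); (b) a precise intron deletion — the next exon
    follows contiguously in frame on the query, so the intron's splice
    mutations are moot ("intron_deletion"); (c) a fresh frame-aware
    pairwise realignment of the exon — mutations not reproduced there
    were alignment artifacts ("realign").  Never adds mutation records.
    """
    out = list(muts)
    mine = [m for m in out if m.exon_index == exon_index and m.surviving]
    if not mine or not ealn.present:
        return out

    # (b) precise intron deletion: the next exon follows contiguously on the
    # query, so the fused exons form one larger composite exon and both
    # splice mutations of the vanished intron are moot
    if next_ealn is not None and next_ealn.present and ealn.qry_contig is not None:
        if (
            next_ealn.qry_contig == ealn.qry_contig
            and next_ealn.qry_start == ealn.qry_end
        ):
            for m in out:
                if not m.surviving:
                    continue
                if m.mclass == SPLICE_DONOR and m.exon_index == exon_index:
                    m.filtered_reason = "intron_deletion"
                if m.mclass == SPLICE_ACCEPTOR and m.exon_index == exon_index + 1:
                    m.filtered_reason = "intron_deletion"

    # (a) splice-site shift search
    for m in mine:
        if not m.surviving or m.mclass not in (SPLICE_DONOR, SPLICE_ACCEPTOR):
            continue
        if assembly is None or ealn.qry_contig is None:
            continue
        if _find_shifted_site(m.mclass, ealn, assembly):
            m.filtered_reason = "splice_shift"

    # (c) frame-aware local realignment
    candidates = [
        m for m in mine
        if m.surviving and m.mclass in (FS_INS, FS_DEL, STOP_SUBST, STOP_IN_INS, BIG_INDEL)
    ]
    if candidates:
        ref = ealn.ref_aln.replace("-", "")
        qry = ealn.qry_aln.replace("-", "")
        realn = _frame_aware_realign(ref, qry)
        if realn is not None:
            new_ref, new_qry = realn
            refound = scan_exon(
                new_ref, new_qry, frame_offset,
                exon_index=exon_index, cds_start=cds_start, cds_length=cds_length,
            )
            refound = apply_compensation(
                refound, new_ref, new_qry, frame_offset,
                cds_start=cds_start, cds_length=cds_length,
            )
            keys = {(m.mclass, m.length) for m in refound if m.surviving}
            positions = sorted(m.cds_pos for m in refound if m.surviving)
            for m in candidates:
                if (m.mclass, m.length) not in keys:
                    m.filtered_reason = "realign"
                elif positions and min(abs(p - m.cds_pos) for p in positions) > 12:
                    m.filtered_reason = "realign"
    return out


def _find_shifted_site(mclass: str, ealn: ExonAlignment, assembly: GenomeAssembly) -> bool:
    """Search +-SPLICE_SHIFT_WINDOW bp for a frame-preserving consensus site."""
    contig = ealn.qry_contig
    seq = assembly.sequences.get(contig)
    if seq is None:
        return False
    consensus = DONOR_CONSENSUS if mclass == SPLICE_DONOR else ACCEPTOR_CONSENSUS
    base = ealn.qry_end if mclass == SPLICE_DONOR else ealn.qry_start - 2
    for shift in range(-SPLICE_SHIFT_WINDOW, SPLICE_SHIFT_WINDOW + 1):
        if shift == 0 or shift % 3:
            continue  # only frame-preserving shifts rescue the exon
        pos = base + shift
        if pos < 0 or pos + 2 > len(seq):
            continue
        dinuc = seq[pos:pos + 2].upper()
        if dinuc not in consensus:
            continue
        if not _shift_introduces_stop(mclass, shift, ealn, seq):
            return True
    return False


def _shift_introduces_stop(
    mclass: str, shift: int, ealn: ExonAlignment, seq: str
) -> bool:
    """Would using the shifted site add a stop codon to the exon?"""
    from .mutation_scan import STOP_CODONS

    if mclass == SPLICE_DONOR and shift > 0:
        extra = seq[ealn.qry_end:ealn.qry_end + shift].upper()
        tail = ealn.qry_aln.replace("-", "")[-2:].upper()
        window = tail + extra
    elif mclass == SPLICE_ACCEPTOR and shift < 0:
        extra = seq[ealn.qry_start + shift:ealn.qry_start].upper()
        head = ealn.qry_aln.replace("-", "")[:2].upper()
        window = extra + head
    else:
        return False  # shift shortens the exon: cannot add a stop
    for k in range(len(window) - 2):
        if window[k:k + 3] in STOP_CODONS:
            return True
    return False


_aligner: Optional[Align.PairwiseAligner] = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 2.0
        a.mismatch_score = -1.0
        a.open_gap_score = -4.0
        a.extend_gap_score = -0.5
        _aligner = a
    return _aligner


def _frame_aware_realign(ref: str, qry: str) -> Optional[tuple[str, str]]:
    """Affine-gap global realignment of the ungapped exon pair.

    Indel-placement ambiguity between score-equal alignments is absorbed
    downstream by matching realigned mutations on class and length with
    a positional tolerance, rather than by canonicalising gap positions.
    """
    if not ref or not qry:
        return None
    if max(len(ref), len(qry)) > 20000:
        return None
    aln = _get_aligner().align(ref.upper(), qry.upper())[0]
    return str(aln[0]), str(aln[1])


def terminal_trim(
    muts: Sequence[InactivatingMutation], lo: float = 0.2, hi: float = 0.8
) -> list[InactivatingMutation]:
    """Drop mutations in the first or last 20% of the protein.

    Protein termini are weakly constrained in evolution, so events there
    are poor loss evidence.  Boundaries are strict: a mutation exactly
    at 0.2 or 0.8 is kept.
    """
    out = list(muts)
    for m in out:
        if m.surviving and (m.rel_pos < lo or m.rel_pos > hi):
            m.filtered_reason = "terminal"
    return out


def select_isoform(
    per_isoform: dict[str, list[InactivatingMutation]],
    cds_lengths: dict[str, int],
) -> Optional[str]:
    """Pick the isoform with the fewest surviving mutations.

    Ties go to the longer CDS, then the lexicographically smallest
    transcript id.  Returns None when no isoform is available.
    """
    if not per_isoform:
        return None
    return min(
        per_isoform,
        key=lambda tx: (_surviving(per_isoform[tx]), -cds_lengths.get(tx, 0), tx),
    )


def apply_cascade(
    transcript: TranscriptModel,
    gene_aln: PairwiseGeneAlignment,
    muts: Sequence[InactivatingMutation],
    assembly: Optional[GenomeAssembly],
    gene_locus: Optional[tuple[str, int, int]] = None,
    up_neighbor: Optional[tuple[str, int, int]] = None,
    down_neighbor: Optional[tuple[str, int, int]] = None,
    trace: Optional[FilterTrace] = None,
) -> tuple[list[InactivatingMutation], bool]:
    """Run the per-isoform filter steps in their fixed order.

    Returns the filtered mutation list and whether the gene passed the
    synteny check (a failure excludes the gene from loss calling for
    this species).  Isoform selection happens at the gene level, after
    this per-isoform cascade.
    """
    out = list(muts)
    if trace is not None:
        trace.record("scan", _surviving(out), _surviving(out))

    before = _surviving(out)
    out = gap_filter(out, assembly)
    if trace is not None:
        trace.record("gap", before, _surviving(out))

    before = _surviving(out)
    synteny_ok = synteny_filter(gene_locus, up_neighbor, down_neighbor)
    if not synteny_ok:
        for m in out:
            if m.surviving:
                m.filtered_reason = "synteny"
    if trace is not None:
        trace.record("synteny", before, _surviving(out))

    before = _surviving(out)
    starts = transcript.exon_cds_starts()
    frames = transcript.exon_frames()
    for idx, ealn in enumerate(gene_aln.exons):
        nxt = gene_aln.exons[idx + 1] if idx + 1 < len(gene_aln.exons) else None
        out = rescue_realign(
            ealn, out, assembly, frames[idx], idx, starts[idx],
            transcript.cds_length, next_ealn=nxt,
        )
    if trace is not None:
        trace.record("realign", before, _surviving(out))

    before = _surviving(out)
    out = terminal_trim(out)
    if trace is not None:
        trace.record("terminal", before, _surviving(out))
    return out, synteny_ok
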