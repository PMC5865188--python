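"""Detection of gene-inactivating mutations in pairwise codon alignments.

The scanner looks for the classes of mutations that abolish a reading
frame: frameshifting insertions/deletions, frame-preserving insertions
that introduce a premature stop codon, substitutions creating an
in-frame stop, disrupted splice sites (donor not GT/GC, acceptor not
AG), frame-preserving indels longer than 50 bp, and deleted or
unaligned exons.  Nearby frameshifts whose lengths cancel modulo 3
("compensated" frameshifts) restore the downstream frame and are not
treated as inactivating unless the transiently shifted stretch contains
a stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .io_formats import ExonAlignment, GenomeAssembly, TranscriptModel

__all__ = [
    "InactivatingMutation",
    "scan_exon",
    "apply_compensation",
    "check_splice_sites",
    "detect_big_indel",
    "classify_exon_presence",
    "scan_gene",
    "STOP_CODONS",
    "DONOR_CONSENSUS",
    "ACCEPTOR_CONSENSUS",
    "FS_INS",
    "FS_DEL",
    "STOP_SUBST",
    "STOP_IN_INS",
    "SPLICE_DONOR",
    "SPLICE_ACCEPTOR",
    "BIG_INDEL",
    "EXON_DELETED",
    "EXON_UNALIGNED",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
DONOR_CONSENSUS = {"GT", "GC"}
ACCEPTOR_CONSENSUS = {"AG"}
BIG_INDEL_MIN = 51  # frame-preserving indels must be LONGER than 50 bp

FS_INS = "FS_INS"
FS_DEL = "FS_DEL"
STOP_SUBST = "STOP_SUBST"
STOP_IN_INS = "STOP_IN_INS"
SPLICE_DONOR = "SPLICE_DONOR"
SPLICE_ACCEPTOR = "SPLICE_ACCEPTOR"
BIG_INDEL = "BIG_INDEL"
EXON_DELETED = "EXON_DELETED"
EXON_UNALIGNED = "EXON_UNALIGNED"

_POINT_CLASSES = {FS_INS, FS_DEL, STOP_SUBST, STOP_IN_INS}


@dataclass
class InactivatingMutation:
    """One detected event.

    ``cds_pos`` is the 0-based offset of the event on the reference CDS;
    ``rel_pos`` the same as a fraction of the coding length.  ``length``
    carries the indel length (0 for substitutions).  ``filtered_reason``
    is empty while the mutation survives the filter cascade.
    """

    mclass: str
    exon_index: int
    cds_pos: int
    rel_pos: float
    detail: str = ""
    length: int = 0
    query_contig: Optional[str] = None
    query_pos: Optional[int] = None
    filtered_reason: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.rel_pos <= 1.0:
            raise ValueError("relative CDS position outside [0, 1]")
        if self.mclass == BIG_INDEL and (self.length <= 50 or self.length % 3):
            raise ValueError("BIG_INDEL must be frame-preserving and > 50 bp")
        if self.mclass in (FS_INS, FS_DEL) and self.length % 3 == 0:
            raise ValueError("frameshift length must not be a multiple of 3")

    @property
    def surviving(self) -> bool:
        return self.filtered_reason == ""

    def key(self) -> tuple:
        """Identity used to match the same event across species."""
        return (self.mclass, self.exon_index, self.cds_pos, self.length, self.detail)


def detect_big_indel(length: int, frame_preserving: bool) -> Optional[str]:
    """Class label for a frame-preserving indel longer than 50 bp, else None.

    Frameshifting indels are classified by :func:`scan_exon` regardless
    of their length.
    """
    if length <= 0:
        raise ValueError("indel length must be positive")
    if frame_preserving and length >= BIG_INDEL_MIN:
        return BIG_INDEL
    return None


def _is_stop(codon: str) -> bool:
    return codon.upper() in STOP_CODONS


def scan_exon(
    ref_aln: str,
    qry_aln: str,
    frame_offset: int,
    exon_index: int = 0,
    cds_start: int = 0,
    cds_length: Optional[int] = None,
    qry_contig: Optional[str] = None,
    qry_start: int = 0,
) -> list[InactivatingMutation]:
    """Scan one aligned exon pair for indel and stop-codon events.

    ``frame_offset`` is the reading-frame phase (0-2) of the reference
    at the exon start; ``cds_start`` the exon's offset on the full CDS.
    The query is read in the frame implied by the reference, with
    cumulative indel tracking, so that premature stops are found in the
    frame the query would actually be translated in.
    """
    if len(ref_aln) != len(qry_aln):
        raise ValueError("aligned rows differ in length")
    if cds_length is None:
        cds_length = max(1, cds_start + sum(1 for c in ref_aln if c != "-"))
    ref_aln = ref_aln.upper()
    qry_aln = qry_aln.upper()

    muts: list[InactivatingMutation] = []
    n = len(ref_aln)
    ref_off = 0  # reference bases consumed
    qry_off = 0  # query bases consumed
    i = 0
    while i < n:
        r, q = ref_aln[i], qry_aln[i]
        if r == "-" and q == "-":
            raise ValueError("gap aligned to gap")
        if r == "-":  # insertion in query
            j = i
            while j < n and ref_aln[j] == "-":
                j += 1
            ins = qry_aln[i:j].replace("-", "")
            length = j - i
            cds_pos = cds_start + ref_off
            mut = _classify_insertion(
                ins, length, cds_pos, cds_length, exon_index,
                frame_offset, ref_aln, qry_aln, i, j,
            )
            if mut is not None:
                mut.query_contig = qry_contig
                mut.query_pos = qry_start + qry_off
                muts.append(mut)
            qry_off += length
            i = j
            continue
        if q == "-":  # deletion in query
            j = i
            while j < n and qry_aln[j] == "-" and ref_aln[j] != "-":
                j += 1
            length = j - i
            cds_pos = cds_start + ref_off
            if length % 3:
                mut = InactivatingMutation(
                    FS_DEL, exon_index, cds_pos, _rel(cds_pos, cds_length),
                    detail=f"del{length}", length=length,
                )
            elif detect_big_indel(length, True):
                mut = InactivatingMutation(
                    BIG_INDEL, exon_index, cds_pos, _rel(cds_pos, cds_length),
                    detail=f"del{length}", length=length,
                )
            else:
                mut = None
            if mut is not None:
                mut.query_contig = qry_contig
                mut.query_pos = qry_start + max(0, qry_off - 1)
                muts.append(mut)
            ref_off += length
            i = j
            continue
        ref_off += 1
        qry_off += 1
        i += 1

    muts.extend(
        _scan_ref_frame_stops(
            ref_aln, qry_aln, frame_offset, exon_index, cds_start, cds_length,
            qry_contig, qry_start,
        )
    )
    muts.sort(key=lambda m: m.cds_pos)
    return muts


def _rel(cds_pos: int, cds_length: int) -> float:
    return min(1.0, max(0.0, cds_pos / max(1, cds_length)))


def _classify_insertion(
    ins: str,
    length: int,
    cds_pos: int,
    cds_length: int,
    exon_index: int,
    frame_offset: int,
    ref_aln: str,
    qry_aln: str,
    col_start: int,
    col_end: int,
) -> Optional[InactivatingMutation]:
    rel = _rel(cds_pos, cds_length)
    if length % 3:
        return InactivatingMutation(
            FS_INS, exon_index, cds_pos, rel, detail=f"ins{length}", length=length
        )
    if detect_big_indel(length, True):
        return InactivatingMutation(
            BIG_INDEL, exon_index, cds_pos, rel, detail=f"ins{length}", length=length
        )
    # frame-preserving short insertion: a stop read in the insertion's
    # frame (phase of the interrupted codon) is inactivating
    phase = (frame_offset + _ref_bases_before(ref_aln, col_start)) % 3
    left = _query_context(qry_aln, ref_aln, col_start, phase, upstream=True)
    right = _query_context(qry_aln, ref_aln, col_end, (3 - (phase + length) % 3) % 3,
                           upstream=False)
    window = left + ins + right
    for k in range(0, len(window) - 2, 3):
        codon = window[k:k + 3]
        if _is_stop(codon):
            return InactivatingMutation(
                STOP_IN_INS, exon_index, cds_pos, rel,
                detail=f"ins{length}:{codon}", length=length,
            )
    return None


def _ref_bases_before(ref_aln: str, col: int) -> int:
    return sum(1 for c in ref_aln[:col] if c != "-")


def _query_context(qry_aln: str, ref_aln: str, col: int, want: int, upstream: bool) -> str:
    """Collect up to ``want`` query bases flanking an alignment column."""
    out: list[str] = []
    rng = range(col - 1, -1, -1) if upstream else range(col, len(qry_aln))
    for i in rng:
        if len(out) == want:
            break
        if qry_aln[i] != "-":
            out.append(qry_aln[i])
    if upstream:
        out.reverse()
    return "".join(out)


def _scan_ref_frame_stops(
    ref_aln: str,
    qry_aln: str,
    frame_offset: int,
    exon_index: int,
    cds_start: int,
    cds_length: int,
    qry_contig: Optional[str],
    qry_start: int,
) -> list[InactivatingMutation]:
    """Stops formed by substitutions, read on the reference codon grid."""
    ref_cols = [i for i, c in enumerate(ref_aln) if c != "-"]
    qry_pos_at_col: list[int] = []
    q = 0
    for c in qry_aln:
        qry_pos_at_col.append(q)
        if c != "-":
            q += 1

    muts = []
    # index of the first column starting a complete reference codon
    lead = (3 - frame_offset) % 3
    for k in range(lead, len(ref_cols) - 2, 3):
        cols = ref_cols[k:k + 3]
        ref_codon = "".join(ref_aln[c] for c in cols)
        qry_codon = "".join(qry_aln[c] for c in cols)
        if "-" in qry_codon or "N" in qry_codon:
            continue  # covered by indel events / missing data
        if _is_stop(qry_codon) and not _is_stop(ref_codon):
            cds_pos = cds_start + k
            muts.append(
                InactivatingMutation(
                    STOP_SUBST, exon_index, cds_pos, _rel(cds_pos, cds_length),
                    detail=f"{ref_codon}>{qry_codon}",
                    query_contig=qry_contig,
                    query_pos=qry_start + qry_pos_at_col[cols[0]],
                )
            )
    return muts


def apply_compensation(
    muts: Sequence[InactivatingMutation],
    ref_aln: str,
    qry_aln: str,
    frame_offset: int = 0,
    cds_start: int = 0,
    cds_length: Optional[int] = None,
) -> list[InactivatingMutation]:
    """Mark runs of frameshifts that cancel each other as compensated.

    A maximal run of consecutive frameshifts whose summed signed lengths
    are a multiple of 3 restores the downstream reading frame; if the
    transiently shifted stretch between them is free of stop codons the
    run is not inactivating (filtered_reason="compensated").  A stop
    arising in the shifted stretch is reported as an additional event
    and blocks compensation.
    """
    if cds_length is None:
        cds_length = max(1, cds_start + sum(1 for c in ref_aln if c != "-"))
    out = list(muts)
    frames = [m for m in out if m.mclass in (FS_INS, FS_DEL) and m.surviving]
    frames.sort(key=lambda m: m.cds_pos)
    if len(frames) < 2:
        return out

    shifted_stops = _shifted_frame_stops(
        ref_aln.upper(), qry_aln.upper(), frame_offset, cds_start
    )

    i = 0
    extra: list[InactivatingMutation] = []
    while i < len(frames):
        total = 0
        for j in range(i, len(frames)):
            signed = frames[j].length if frames[j].mclass == FS_INS else -frames[j].length
            total += signed
            if total % 3 == 0:
                lo, hi = frames[i].cds_pos, frames[j].cds_pos
                stops = [s for s in shifted_stops if lo <= s[0] <= hi]
                if stops:
                    for cds_pos, codon in stops:
                        extra.append(
                            InactivatingMutation(
                                STOP_SUBST,
                                frames[i].exon_index,
                                cds_pos,
                                _rel(cds_pos, cds_length),
                                detail=f"shifted:{codon}",
                            )
                        )
                else:
                    for m in frames[i:j + 1]:
                        m.filtered_reason = "compensated"
                i = j + 1
                break
        else:
            break  # tail of uncompensated frameshifts
    known = {(m.mclass, m.cds_pos, m.detail) for m in out}
    for m in extra:
        if (m.mclass, m.cds_pos, m.detail) not in known:
            out.append(m)
    out.sort(key=lambda m: m.cds_pos)
    return out


def _shifted_frame_stops(
    ref_aln: str, qry_aln: str, frame_offset: int, cds_start: int
) -> list[tuple[int, str]]:
    """Stop codons met when translating the query with cumulative shifts.

    Returns (reference CDS offset, codon) for stops read on the query
    codon grid while the cumulative indel shift is non-zero.
    """
    qseq: list[str] = []
    shift_at: list[int] = []
    refpos_at: list[int] = []
    shift = 0
    ref_off = 0
    for r, q in zip(ref_aln, qry_aln):
        if r == "-" and q != "-":
            qseq.append(q)
            shift += 1
            shift_at.append(shift % 3)
            refpos_at.append(ref_off)
        elif q == "-" and r != "-":
            shift -= 1
            ref_off += 1
        elif r != "-" and q != "-":
            qseq.append(q)
            shift_at.append(shift % 3)
            refpos_at.append(ref_off)
            ref_off += 1
    s = "".join(qseq)
    stops = []
    start = (3 - frame_offset) % 3
    for k in range(start, len(s) - 2, 3):
        codon = s[k:k + 3]
        if _is_stop(codon) and shift_at[k] != 0 and "N" not in codon:
            stops.append((cds_start + refpos_at[k], codon))
    return stops


def check_splice_sites(
    donor: Optional[str],
    acceptor: Optional[str],
    exon_index: int,
    n_exons: int,
    cds_pos_donor: int = 0,
    cds_pos_acceptor: int = 0,
    cds_length: int = 1,
) -> list[InactivatingMutation]:
    """Splice-site events for one exon's intron flanks.

    The first exon has no acceptor check and the last exon no donor
    check; single-exon transcripts are skipped entirely.  A flank of
    None (unavailable or overlapping an assembly gap) is not checked.
    """
    if n_exons <= 1:
        return []
    muts = []
    if exon_index > 0 and acceptor is not None:
        acc = acceptor.upper()
        if acc not in ACCEPTOR_CONSENSUS and "N" not in acc:
            muts.append(
                InactivatingMutation(
                    SPLICE_ACCEPTOR, exon_index, cds_pos_acceptor,
                    _rel(cds_pos_acceptor, cds_length), detail=acc,
                )
            )
    if exon_index < n_exons - 1 and donor is not None:
        don = donor.upper()
        if don not in DONOR_CONSENSUS and "N" not in don:
            muts.append(
                InactivatingMutation(
                    SPLICE_DONOR, exon_index, cds_pos_donor,
                    _rel(cds_pos_donor, cds_length), detail=don,
                )
            )
    return muts


def classify_exon_presence(
    exon_length: int,
    aln: ExonAlignment,
    assembly: Optional[GenomeAssembly],
) -> str:
    """Status of one exon: aligned, deleted, unaligned or missing data.

    An exon without aligned query sequence is judged by the query region
    between the nearest up- and downstream aligning blocks: overlap with
    an assembly gap (or absent anchors, e.g. at a contig edge) means the
    data cannot support a call; otherwise an inter-anchor region shorter
    than the exon means its sequence is absent (deleted).
    """
    if aln.present:
        return "aligned"
    if aln.anchor_up is None or aln.anchor_down is None or aln.qry_contig is None:
        return "missing_data"
    lo, hi = sorted((aln.anchor_up, aln.anchor_down))
    if assembly is not None and assembly.overlaps_gap(aln.qry_contig, lo, hi):
        return "missing_data"
    if hi - lo < exon_length:
        return EXON_DELETED
    return EXON_UNALIGNED


def scan_gene(
    transcript: TranscriptModel,
    gene_aln,
    assembly: Optional[GenomeAssembly] = None,
) -> list[InactivatingMutation]:
    """Scan every exon of one gene x query alignment.

    Combines the per-exon indel/stop scan (with frameshift compensation),
    splice-site checks, and exon-presence classification into one
    mutation list, all positioned on the reference CDS.
    """
    cds_length = transcript.cds_length
    starts = transcript.exon_cds_starts()
    frames = transcript.exon_frames()
    n_exons = transcript.n_exons
    muts: list[InactivatingMutation] = []

    for idx, (exon, ealn) in enumerate(zip(transcript.exons, gene_aln.exons)):
        exon_len = exon[1] - exon[0]
        status = classify_exon_presence(exon_len, ealn, assembly)
        if status == "aligned":
            found = scan_exon(
                ealn.ref_aln,
                ealn.qry_aln,
                frames[idx],
                exon_index=idx,
                cds_start=starts[idx],
                cds_length=cds_length,
                qry_contig=ealn.qry_contig,
                qry_start=ealn.qry_start,
            )
            found = apply_compensation(
                found, ealn.ref_aln, ealn.qry_aln, frames[idx],
                cds_start=starts[idx], cds_length=cds_length,
            )
            muts.extend(found)
            cds_end = starts[idx] + exon_len
            muts.extend(
                check_splice_sites(
                    ealn.donor, ealn.acceptor, idx, n_exons,
                    cds_pos_donor=max(0, cds_end - 1),
                    cds_pos_acceptor=starts[idx],
                    cds_length=cds_length,
                )
            )
        elif status == "missing_data":
            muts.append(
                InactivatingMutation(
                    status if status in (EXON_DELETED, EXON_UNALIGNED) else EXON_DELETED,
                    idx, starts[idx], _rel(starts[idx], cds_length),
                    detail="missing", filtered_reason="missing_data",
                )
            )
        else:  # EXON_DELETED / EXON_UNALIGNED
            muts.append(
                InactivatingMutation(
                    status, idx, starts[idx], _rel(starts[idx], cds_length),
                    detail=f"len{exon_len}",
                    query_contig=ealn.qry_contig,
                )
            )
    muts.sort(key=lambda m: (m.cds_pos, m.mclass))
    return muts
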