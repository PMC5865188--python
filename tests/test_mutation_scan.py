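"""Inactivating-mutation detection in exon alignments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genoloss.io_formats import ExonAlignment
from genoloss.mutation_scan import (
    BIG_INDEL,
    EXON_DELETED,
    EXON_UNALIGNED,
    FS_DEL,
    FS_INS,
    SPLICE_ACCEPTOR,
    SPLICE_DONOR,
    STOP_IN_INS,
    STOP_SUBST,
    apply_compensation,
    check_splice_sites,
    classify_exon_presence,
    detect_big_indel,
    scan_exon,
    scan_gene,
)
from genoloss.io_formats import GenomeAssembly

STOPS = {"TAA", "TAG", "TGA"}


def frame_oracle_has_stop(ref_aln: str, qry_aln: str, frame_offset: int) -> bool:
    """Brute force: translate the query in the reference frame with
    cumulative indel tracking; report any premature stop codon."""
    qseq = "".join(c for c in qry_aln if c != "-").upper()
    start = (3 - frame_offset) % 3
    return any(qseq[k:k + 3] in STOPS for k in range(start, len(qseq) - 2, 3))


def surviving(muts):
    return [m for m in muts if m.surviving]


class TestScanExon:
    def test_identical_rows_yield_nothing(self):
        assert scan_exon("ATGCAATCG", "ATGCAATCG", 0) == []

    def test_one_bp_deletion_is_frameshift(self):
        muts = scan_exon("ATGCAATCG", "ATG-AATCG", 0)
        assert [(m.mclass, m.length) for m in muts] == [(FS_DEL, 1)]

    def test_stop_substitution_in_frame(self):
        muts = scan_exon("ATGCAATCG", "ATGTAATCG", 0)
        assert [(m.mclass, m.detail) for m in muts] == [(STOP_SUBST, "CAA>TAA")]
        assert muts[0].cds_pos == 3

    def test_frame_preserving_insertion_with_stop(self):
        # 6-bp insertion carrying TAA in the insertion's frame
        ref = "ATGCCC" + "------" + "GGGTTT"
        qry = "ATGCCC" + "TAACCC" + "GGGTTT"
        muts = scan_exon(ref, qry, 0)
        assert [m.mclass for m in muts] == [STOP_IN_INS]

    def test_frame_preserving_insertion_without_stop_is_silent(self):
        ref = "ATGCCC" + "------" + "GGGTTT"
        qry = "ATGCCC" + "CCCCCC" + "GGGTTT"
        assert scan_exon(ref, qry, 0) == []

    def test_stop_in_insertion_spanning_junction(self):
        # insertion at codon phase 1: T(AA...) completes a stop with the
        # flanking query base
        ref = "ATGT" + "---" + "CCGGGTTT"
        qry = "ATGT" + "AAC" + "CCGGGTTT"
        muts = scan_exon(ref, qry, 0)
        assert [m.mclass for m in muts] == [STOP_IN_INS]

    def test_query_n_codon_not_called_stop(self):
        assert scan_exon("ATGCAATCG", "ATGTANTCG", 0) == []

    def test_frame_offset_respected(self):
        # with frame offset 2 the first complete codon starts at column 1
        muts = scan_exon("ACAATCGTT", "ATAATCGTT", 2)
        assert [m.mclass for m in muts] == [STOP_SUBST]
        muts = scan_exon("ACAATCGTT", "ATAATCGTT", 0)
        assert muts == []

    def test_relative_position_from_cds_offsets(self):
        muts = scan_exon("ATGCAATCG", "ATGTAATCG", 0, cds_start=300, cds_length=1000)
        assert muts[0].cds_pos == 303
        assert muts[0].rel_pos == pytest.approx(0.303)


class TestBigIndel:
    @pytest.mark.parametrize(
        "length,frame_preserving,expected",
        [(51, True, BIG_INDEL), (48, True, None), (50, True, None),
         (300, True, BIG_INDEL), (52, False, None)],
    )
    def test_threshold_strictly_greater_than_50(self, length, frame_preserving, expected):
        assert detect_big_indel(length, frame_preserving) == expected

    def test_scan_reports_big_deletion(self):
        ref = "ATG" + "CCCGGGTTT" * 6 + "AAACCCGGG"
        qry = "ATG" + "-" * 54 + "AAACCCGGG"
        muts = scan_exon(ref, qry, 0)
        assert [(m.mclass, m.length) for m in muts] == [(BIG_INDEL, 54)]


class TestCompensation:
    def _scan(self, ref, qry):
        muts = scan_exon(ref, qry, 0)
        return apply_compensation(muts, ref, qry, 0)

    def test_compensated_pair_marked(self):
        # +1 insertion then -1 deletion 12 bp later, clean shifted stretch
        ref = "ATGCCC-CCTCCTCCTCCGCAACGT"
        qry = "ATGCCCACCTCCTCCTCC-CAACGT"
        muts = self._scan(ref, qry)
        assert {m.filtered_reason for m in muts} == {"compensated"}
        assert not frame_oracle_has_stop(ref, qry, 0)

    def test_stop_in_shifted_stretch_blocks_compensation(self):
        # the shifted stretch reads TGA in the +1 frame
        ref = "ATGCCC-GATCCTCCTCCGCAACGT"
        qry = "ATGCCCTGATCCTCCTCC-CAACGT"
        muts = self._scan(ref, qry)
        surv = surviving(muts)
        assert {m.mclass for m in surv} == {FS_INS, FS_DEL, STOP_SUBST}
        assert frame_oracle_has_stop(ref, qry, 0)

    def test_single_frameshift_retained(self):
        ref = "ATGCCC-CCTCCTCC"
        qry = "ATGCCCACCTCCTCC"
        muts = self._scan(ref, qry)
        assert [(m.mclass, m.filtered_reason) for m in muts] == [(FS_INS, "")]

    def test_unbalanced_run_not_compensated(self):
        ref = "ATGCCC-CCTCCTCC-TCC"
        qry = "ATGCCCACCTCCTCCATCC"
        muts = self._scan(ref, qry)
        assert all(m.surviving for m in muts)


class TestSpliceSites:
    @pytest.mark.parametrize("donor", ["GT", "GC"])
    def test_consensus_donor_accepted(self, donor):
        assert check_splice_sites(donor, "AG", 1, 4) == []

    def test_non_consensus_flagged(self):
        muts = check_splice_sites("AT", "AG", 1, 4)
        assert [m.mclass for m in muts] == [SPLICE_DONOR]
        muts = check_splice_sites("GT", "AC", 1, 4)
        assert [m.mclass for m in muts] == [SPLICE_ACCEPTOR]

    def test_terminal_exons_skip_outer_flanks(self):
        assert check_splice_sites("AT", None, 3, 4) == []  # last exon: no donor
        assert check_splice_sites(None, "CC", 0, 4) == []  # first: no acceptor

    def test_single_exon_transcript_unchecked(self):
        assert check_splice_sites("AT", "AC", 0, 1) == []


class TestExonPresence:
    def _absent(self, up, down):
        return ExonAlignment(present=False, qry_contig="c", anchor_up=up,
                             anchor_down=down)

    def test_aligned(self):
        ealn = ExonAlignment(ref_aln="ACG", qry_aln="ACG")
        assert classify_exon_presence(3, ealn, None) == "aligned"

    def test_unaligned_with_gap_is_missing_data(self):
        asm = GenomeAssembly(name="q", sequences={"c": "ACGT" * 10 + "N" * 5 + "ACGT" * 10})
        assert classify_exon_presence(30, self._absent(35, 50), asm) == "missing_data"

    def test_clean_zero_length_region_is_deletion(self):
        asm = GenomeAssembly(name="q", sequences={"c": "ACGT" * 30})
        assert classify_exon_presence(30, self._absent(40, 40), asm) == EXON_DELETED

    def test_clean_long_region_is_unaligned(self):
        asm = GenomeAssembly(name="q", sequences={"c": "ACGT" * 30})
        assert classify_exon_presence(30, self._absent(10, 100), asm) == EXON_UNALIGNED

    def test_no_anchors_is_missing_data(self):
        assert classify_exon_presence(30, self._absent(None, 40), None) == "missing_data"


@settings(max_examples=60, derandomize=True)
@given(st.data())
def test_oracle_equivalence_on_random_exon_alignments(data):
    """No surviving stop/frameshift events iff the query translates
    without a premature stop in the reference frame (checked in the
    sound direction on random mutated alignments)."""
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    n_codons = int(rng.integers(10, 40))
    from genoloss.synthetic import random_cds

    cds = random_cds(n_codons, rng)
    ref = list(cds)
    qry = list(cds)
    # random substitutions
    for _ in range(int(rng.integers(0, 6))):
        i = int(rng.integers(0, len(qry)))
        qry[i] = "ACGT"[rng.integers(0, 4)]
    # random small indel; frame-preserving deletions are excluded because a
    # stop formed purely by a deletion junction is (faithfully) not a class
    if rng.random() < 0.5:
        i = int(rng.integers(1, len(qry) - 6))
        if rng.random() < 0.5:
            k = int(rng.choice([1, 2, 4, 5]))
            for j in range(i, i + k):
                qry[j] = "-"
        else:
            k = int(rng.integers(1, 4))
            ins = "".join("ACGT"[b] for b in rng.integers(0, 4, size=k))
            qry[i] = qry[i] + ins
    ref_aln, qry_aln = [], []
    for r, q in zip(ref, qry):
        if len(q) > 1:  # insertion after this base
            ref_aln.append(r + "-" * (len(q) - 1))
        else:
            ref_aln.append(r)
        qry_aln.append(q)
    ref_aln, qry_aln = "".join(ref_aln), "".join(qry_aln)

    muts = scan_exon(ref_aln, qry_aln, 0)
    muts = apply_compensation(muts, ref_aln, qry_aln, 0)
    surv = [m for m in surviving(muts)
            if m.mclass in (FS_INS, FS_DEL, STOP_SUBST, STOP_IN_INS)]
    if frame_oracle_has_stop(ref_aln, qry_aln, 0):
        assert len(surv) >= 1
    if not surv:
        assert not frame_oracle_has_stop(ref_aln, qry_aln, 0)


def test_reference_identical_query_has_no_mutations(clean_sim):
    """Across simulated genes, an uncorrupted close relative should carry
    essentially no inactivating mutations."""
    tr = {t.transcript_id: t for t in clean_sim.reference_transcripts()}
    total = 0
    for ga in clean_sim.alignments("sp01"):
        muts = scan_gene(tr[ga.transcript_id], ga, clean_sim.assembly("sp01"))
        total += len([m for m in muts if m.surviving])
    assert total == 0


def test_scan_gene_positions_reproducible(small_sim):
    """Every reported CDS position lies inside its exon's CDS interval."""
    tr = {t.transcript_id: t for t in small_sim.reference_transcripts()}
    checked = 0
    for ga in small_sim.alignments("sp02"):
        tx = tr[ga.transcript_id]
        starts = tx.exon_cds_starts()
        lens = [e - s for s, e in tx.exons]
        for m in scan_gene(tx, ga, small_sim.assembly("sp02")):
            lo = starts[m.exon_index]
            hi = lo + lens[m.exon_index]
            assert lo <= m.cds_pos <= hi
            assert m.rel_pos == pytest.approx(
                min(1.0, m.cds_pos / tx.cds_length), abs=1e-9
            )
            checked += 1
    assert checked > 0
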