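"""The artifact-filter cascade."""

import pytest

from genoloss.alignment_filters import (
    FILTER_ORDER,
    gap_filter,
    rescue_realign,
    select_isoform,
    synteny_filter,
    terminal_trim,
)
from genoloss.io_formats import ExonAlignment, GenomeAssembly
from genoloss.mutation_scan import (
    FS_DEL,
    SPLICE_ACCEPTOR,
    SPLICE_DONOR,
    STOP_SUBST,
    InactivatingMutation,
    scan_exon,
)


def mut(mclass=STOP_SUBST, exon=0, cds_pos=50, rel=0.5, length=0, **kw):
    return InactivatingMutation(mclass, exon, cds_pos, rel, length=length, **kw)


class TestGapFilter:
    def setup_method(self):
        seq = "ACGT" * 50 + "N" * 10 + "ACGT" * 50
        self.asm = GenomeAssembly(name="q", sequences={"c": seq})

    def test_point_mutation_next_to_n_removed(self):
        m = mut(FS_DEL, length=1, query_contig="c", query_pos=199)
        (out,) = gap_filter([m], self.asm)
        assert out.filtered_reason == "near_gap"

    def test_distant_mutation_kept(self):
        m = mut(query_contig="c", query_pos=100)
        (out,) = gap_filter([m], self.asm)
        assert out.surviving

    def test_stop_codon_span_checked(self):
        # codon start two bases before the N run still overlaps it
        m = mut(STOP_SUBST, query_contig="c", query_pos=198)
        (out,) = gap_filter([m], self.asm)
        assert out.filtered_reason == "near_gap"


class TestSynteny:
    def test_between_neighbors_passes(self):
        assert synteny_filter(("c", 3000, 5000), ("c", 500, 1000), ("c", 8000, 9000))

    def test_different_contig_fails(self):
        assert not synteny_filter(("c2", 0, 1000), ("c", 500, 1000), ("c", 8000, 9000))

    def test_jointly_inverted_neighborhood_passes(self):
        # strand flip: downstream neighbor now upstream, order reversed
        assert synteny_filter(("c", 3000, 5000), ("c", 8000, 9000), ("c", 500, 1000))

    def test_both_neighbors_on_one_side_fails(self):
        assert not synteny_filter(("c", 3000, 5000), ("c", 500, 800), ("c", 900, 1200))

    def test_unaligned_neighbors_pass(self):
        assert synteny_filter(("c", 0, 100), None, None)
        assert synteny_filter(None, ("c", 0, 10), ("c", 50, 60))


class TestRescue:
    def test_splice_shift_rescued(self):
        # broken donor AT, consensus GT three bases into the intron
        seq = "A" * 100 + "ATCGT" + "T" * 100
        asm = GenomeAssembly(name="q", sequences={"c": seq})
        ealn = ExonAlignment(ref_aln="CCCCCC", qry_aln="CCCCCC", qry_contig="c",
                             qry_start=94, qry_end=100, donor="AT")
        m = mut(SPLICE_DONOR, exon=0, cds_pos=5, rel=0.5)
        out = rescue_realign(ealn, [m], asm, 0, 0, 0, 10)
        assert out[0].filtered_reason == "splice_shift"

    def test_splice_shift_blocked_by_frameshift_offset(self):
        # GT exists only at +4: not frame-preserving, no rescue
        seq = "A" * 100 + "ATCAGTA" + "A" * 100
        asm = GenomeAssembly(name="q", sequences={"c": seq})
        ealn = ExonAlignment(ref_aln="CCCCCC", qry_aln="CCCCCC", qry_contig="c",
                             qry_start=94, qry_end=100, donor="AT")
        m = mut(SPLICE_DONOR, exon=0, cds_pos=5, rel=0.5)
        out = rescue_realign(ealn, [m], asm, 0, 0, 0, 10)
        assert out[0].surviving

    def test_precise_intron_deletion_clears_both_sites(self):
        asm = GenomeAssembly(name="q", sequences={"c": "A" * 400})
        e0 = ExonAlignment(ref_aln="CCCCCC", qry_aln="CCCCCC", qry_contig="c",
                           qry_start=100, qry_end=106, donor="CC")
        e1 = ExonAlignment(ref_aln="GGGGGG", qry_aln="GGGGGG", qry_contig="c",
                           qry_start=106, qry_end=112, acceptor="CC")
        muts = [
            mut(SPLICE_DONOR, exon=0, cds_pos=5, rel=0.45),
            mut(SPLICE_ACCEPTOR, exon=1, cds_pos=6, rel=0.55),
        ]
        out = rescue_realign(e0, muts, asm, 0, 0, 0, 12, next_ealn=e1)
        assert {m.filtered_reason for m in out} == {"intron_deletion"}

    def test_real_frameshift_survives_realignment(self):
        ref = "ATGCCCGGGTTTAAACCCGGGTTTCCC"
        qry = "ATGCCCGGGTTT-AACCCGGGTTTCCC"
        muts = scan_exon(ref, qry, 0)
        ealn = ExonAlignment(ref_aln=ref, qry_aln=qry, qry_contig="c",
                             qry_start=0, qry_end=26)
        out = rescue_realign(ealn, muts, None, 0, 0, 0, 27)
        assert any(m.mclass == FS_DEL and m.surviving for m in out)

    def test_fake_stop_from_misplaced_gap_removed(self):
        # the query carries a harmless frame-preserving CCT insertion; an
        # alignment that places the gap three columns downstream pairs
        # query TGA against reference CGA, faking a stop substitution.
        # The frame-aware realignment does not reproduce it.
        ref = "TCATATC---GAAATATCCGCGACCGC"
        qry = "TCATCCTATCGAAATATCCGCGACCGC"
        muts = scan_exon(ref, qry, 0)
        assert [(m.mclass, m.detail) for m in muts if m.surviving] \
            == [(STOP_SUBST, "CGA>TGA")]
        ealn = ExonAlignment(ref_aln=ref, qry_aln=qry, qry_contig="c",
                             qry_start=0, qry_end=27)
        out = rescue_realign(ealn, muts, None, 0, 0, 0, 24)
        assert all(not m.surviving for m in out)

    def test_rescue_never_adds_records(self):
        ref = "ATGCCCGGGTTTAAACCCGGGTTTCCC"
        qry = "ATGCCCGGGTTT-AACCCGGGTTTCCC"
        muts = scan_exon(ref, qry, 0)
        ealn = ExonAlignment(ref_aln=ref, qry_aln=qry, qry_contig="c",
                             qry_start=0, qry_end=26)
        out = rescue_realign(ealn, muts, None, 0, 0, 0, 27)
        assert len(out) == len(muts)


class TestTerminalTrim:
    @pytest.mark.parametrize(
        "rel,kept",
        [(0.10, False), (0.50, True), (0.20, True), (0.80, True), (0.81, False)],
    )
    def test_strict_boundaries(self, rel, kept):
        (out,) = terminal_trim([mut(rel=rel)])
        assert out.surviving == kept


class TestIsoformSelection:
    def test_fewest_mutations_wins(self):
        iso = {"t1": [mut(), mut(), mut()], "t2": [mut()]}
        assert select_isoform(iso, {"t1": 900, "t2": 600}) == "t2"

    def test_tie_broken_by_longer_cds(self):
        iso = {"t1": [mut(), mut()], "t2": [mut(), mut()]}
        assert select_isoform(iso, {"t1": 600, "t2": 900}) == "t2"

    def test_filtered_mutations_do_not_count(self):
        filtered = mut()
        filtered.filtered_reason = "terminal"
        iso = {"t1": [filtered], "t2": [mut()]}
        assert select_isoform(iso, {"t1": 100, "t2": 100}) == "t1"

    def test_single_isoform(self):
        assert select_isoform({"t1": []}, {"t1": 100}) == "t1"


def test_cascade_counts_monotone_on_simulated_genes(small_sim):
    """Each filter step can only remove mutations (Fig.-1b-style cascade)."""
    from genoloss.pipeline import call_species

    tr = small_sim.reference_transcripts()
    res = call_species(tr, small_sim.alignments("sp03"),
                       small_sim.assembly("sp03"), "sp03")
    assert res.traces
    for trace in res.traces.values():
        counts = [nb for _, nb, _ in trace.steps] + [trace.steps[-1][2]]
        after = [na for _, _, na in trace.steps]
        for (step, nb, na) in trace.steps:
            assert na <= nb
        # steps run in the fixed documented order
        names = [s for s, _, _ in trace.steps]
        assert names == [s for s in FILTER_ORDER if s in names]


def test_artifact_mutations_all_removed_on_conserved_genes(small_sim):
    """Splice shifts, intron deletions and near-gap errors on genes evolved
    without inactivation must not leave surviving mutations that flip the
    classification (truth labels from the simulator)."""
    from genoloss import loss_caller as lc
    from genoloss.pipeline import call_species

    loss_genes = {t.gene_id for t in small_sim.truth}
    tr = small_sim.reference_transcripts()
    for sp in ("sp01", "sp04"):
        res = call_species(tr, small_sim.alignments(sp),
                           small_sim.assembly(sp), sp)
        for gid, st in res.statuses.items():
            if gid not in loss_genes:
                assert st.classification != lc.LOSS_CANDIDATE, (
                    gid, sp, [(m.mclass, m.rel_pos) for m in st.surviving]
                )
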