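"""%intact, loss classification, ancestral presence, shared mutations."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genoloss.io_formats import SpeciesTree
from genoloss.loss_caller import (
    INTACT,
    LOSS_CANDIDATE,
    MISSING_DATA,
    build_status,
    classify,
    infer_ancestral_presence,
    percent_intact,
    shared_mutation_support,
)
from genoloss.mutation_scan import STOP_SUBST, InactivatingMutation


class TestPercentIntact:
    def test_worked_example(self):
        assert percent_intact({0.20, 0.55}) == pytest.approx(45.0)

    def test_no_mutations_is_fully_intact(self):
        assert percent_intact(set()) == 100.0

    def test_three_positions(self):
        # gaps: 0.10, 0.20, 0.60, 0.10 -> 60
        assert percent_intact({0.10, 0.30, 0.90}) == pytest.approx(60.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            percent_intact({1.2})

    @settings(max_examples=100, derandomize=True)
    @given(
        st.sets(st.floats(0, 1, allow_nan=False), max_size=12),
        st.floats(0, 1, allow_nan=False),
    )
    def test_non_increasing_under_insertion(self, positions, extra):
        before = percent_intact(positions)
        after = percent_intact(set(positions) | {extra})
        assert after <= before + 1e-12

    @settings(max_examples=100, derandomize=True)
    @given(st.sets(st.floats(0.001, 0.999, allow_nan=False), max_size=8))
    def test_equals_100_iff_empty(self, positions):
        assert (percent_intact(positions) == 100.0) == (len(positions) == 0)


class TestClassify:
    def test_paper_thresholds_multi_exon(self):
        assert classify(55.0, 10, 2, 2) == LOSS_CANDIDATE
        assert classify(55.0, 10, 1, 1) == INTACT   # <20% of exons
        assert classify(60.0, 10, 2, 2) == INTACT   # %intact not < 60
        assert classify(59.9, 10, 2, 3) == LOSS_CANDIDATE

    def test_single_exon_needs_two_mutations(self):
        assert classify(50.0, 1, 1, 1) == INTACT
        assert classify(50.0, 1, 1, 2) == LOSS_CANDIDATE

    def test_missing_data_wins(self):
        assert classify(10.0, 5, 5, 9, missing=True) == MISSING_DATA

    def test_exon_fraction_boundary_inclusive(self):
        # exactly 20% of exons mutated counts
        assert classify(50.0, 5, 1, 1) == LOSS_CANDIDATE


def _mut(rel, exon=0, cls=STOP_SUBST, cds=None, reason=""):
    m = InactivatingMutation(cls, exon, cds if cds is not None else int(rel * 1000),
                             rel, detail="x")
    m.filtered_reason = reason
    return m


def test_build_status_counts_only_surviving():
    muts = [_mut(0.5, 0), _mut(0.3, 1, reason="terminal")]
    st_ = build_status("g", "sp", "g.t1", muts, n_exons=4)
    assert st_.percent_intact == pytest.approx(50.0)
    assert st_.n_exons_with_mutation == 1
    assert st_.classification == LOSS_CANDIDATE


class TestAncestralPresence:
    TREE = "(((A:1,B:1):1,(C:1,D:1):1):1,(E:2,F:2):1);"

    def _status(self, sp, lost):
        muts = [_mut(0.4), _mut(0.6, 1)] if lost else []
        return build_status("g", sp, "g.t1", muts, n_exons=4)

    def test_intact_everywhere_gives_root(self):
        tree = SpeciesTree.from_newick(self.TREE)
        statuses = [self._status(sp, False) for sp in "BCDEF"]
        anc, eligible = infer_ancestral_presence(tree, statuses, "A")
        assert tree.leaves_under(anc) == set("ABCDEF")
        assert eligible == []

    def test_loss_outside_intact_clade_dropped(self):
        tree = SpeciesTree.from_newick(self.TREE)
        # intact only in B (and reference A); loss candidate in E
        statuses = [self._status("B", False), self._status("E", True)]
        anc, eligible = infer_ancestral_presence(tree, statuses, "A")
        assert tree.leaves_under(anc) == {"A", "B"}
        assert eligible == []
        assert statuses[1].classification == "not_ancestrally_present"

    def test_loss_inside_clade_kept(self):
        tree = SpeciesTree.from_newick(self.TREE)
        statuses = [self._status("D", False), self._status("C", True)]
        anc, eligible = infer_ancestral_presence(tree, statuses, "A")
        assert tree.leaves_under(anc) == {"A", "B", "C", "D"}
        assert [s.species for s in eligible] == ["C"]

    def test_intact_in_reference_only(self):
        tree = SpeciesTree.from_newick(self.TREE)
        statuses = [self._status(sp, True) for sp in "BCDEF"]
        anc, eligible = infer_ancestral_presence(tree, statuses, "A")
        assert tree.leaves_under(anc) == {"A"}
        assert eligible == []


class TestSharedMutations:
    def test_identical_mutation_grouped(self):
        m1 = _mut(0.5, exon=2, cds=500)
        m2 = _mut(0.5, exon=2, cds=500)
        s1 = build_status("g", "sp1", "t", [m1], 5)
        s2 = build_status("g", "sp2", "t", [m2], 5)
        shared = shared_mutation_support([s1, s2])
        assert list(shared.values()) == [{"sp1", "sp2"}]

    def test_disjoint_sets_share_nothing(self):
        s1 = build_status("g", "sp1", "t", [_mut(0.5, cds=500)], 5)
        s2 = build_status("g", "sp2", "t", [_mut(0.6, cds=600)], 5)
        assert shared_mutation_support([s1, s2]) == {}

    def test_mixed_shared_and_private(self):
        shared_mut = lambda: _mut(0.5, exon=1, cds=500)  # noqa: E731
        statuses = [
            build_status("g", f"sp{i}", "t",
                         [shared_mut(), _mut(0.3 + i / 100, cds=300 + i)], 5)
            for i in range(4)
        ]
        shared = shared_mutation_support(statuses)
        assert len(shared) == 1
        assert len(next(iter(shared.values()))) == 4


def test_injected_internal_branch_loss_shares_mutations(small_sim):
    """A loss injected on an internal branch leaves identical mutations in
    both descendant species (truth propagation through the simulator)."""
    from genoloss.pipeline import call_species

    tr = small_sim.reference_transcripts()
    internal = [t for t in small_sim.truth if len(t.descendants) == 2]
    assert internal
    statuses = {}
    for sp in ("sp02", "sp03"):
        res = call_species(tr, small_sim.alignments(sp),
                           small_sim.assembly(sp), sp)
        for t in internal:
            statuses.setdefault(t.gene_id, []).append(res.statuses[t.gene_id])
    for t in internal:
        shared = shared_mutation_support(statuses[t.gene_id])
        assert any(sp_set == {"sp02", "sp03"} for sp_set in shared.values()), t
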