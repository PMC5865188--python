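"""%intact computation, per-species gene classification, ancestral
presence inference and shared-mutation evidence.

The %intact statistic is the maximum percentage of the reading frame
left intact by the surviving inactivating mutations: mutations at
relative coding positions 0.20 and 0.55 leave intact stretches of 20%,
35% and 45%, so %intact is 45.  A gene is a loss candidate in a species
when %intact < 60 and at least 20% of its exons carry inactivating
mutations (single-exon transcripts instead require at least two
mutations).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .io_formats import SpeciesTree
from .mutation_scan import InactivatingMutation

__all__ = [
    "GeneStatus",
    "percent_intact",
    "classify",
    "build_status",
    "infer_ancestral_presence",
    "shared_mutation_support",
    "INTACT",
    "LOSS_CANDIDATE",
    "MISSING_DATA",
]

INTACT = "intact"
LOSS_CANDIDATE = "loss_candidate"
MISSING_DATA = "missing_data"

INTACT_MAX = 60.0          # %intact below this supports a loss call
EXON_FRACTION = 0.2        # >= this fraction of exons must be mutated
SINGLE_EXON_MIN_MUTS = 2   # single-exon transcripts need this many events


def percent_intact(positions: Iterable[float]) -> float:
    """Largest mutation-free fraction of the coding sequence, as a percent.

    The gaps are measured between consecutive elements of
    {0} u positions u {1}; no mutations gives 100.
    """
    pts = sorted(set(positions))
    for p in pts:
        if not 0.0 <= p <= 1.0:
            raise ValueError("relative position outside [0, 1]")
    bounds = [0.0] + pts + [1.0]
    widest = max(b - a for a, b in zip(bounds, bounds[1:]))
    return 100.0 * widest


@dataclass
class GeneStatus:
    """Classification of one gene in one query species."""

    gene_id: str
    species: str
    transcript_id: str
    mutations: list[InactivatingMutation] = field(default_factory=list)
    percent_intact: float = 100.0
    n_exons: int = 1
    n_exons_with_mutation: int = 0
    classification: str = INTACT

    @property
    def surviving(self) -> list[InactivatingMutation]:
        return [m for m in self.mutations if m.surviving]


def classify(
    pct_intact: float,
    n_exons: int,
    n_exons_with_mutation: int,
    n_mutations: int,
    missing: bool = False,
) -> str:
    """Apply the loss-candidate thresholds to one gene x species."""
    if missing:
        return MISSING_DATA
    if n_exons <= 1:
        if n_mutations >= SINGLE_EXON_MIN_MUTS and pct_intact < INTACT_MAX:
            return LOSS_CANDIDATE
        return INTACT
    if pct_intact < INTACT_MAX and n_exons_with_mutation / n_exons >= EXON_FRACTION:
        return LOSS_CANDIDATE
    return INTACT


def build_status(
    gene_id: str,
    species: str,
    transcript_id: str,
    muts: Sequence[InactivatingMutation],
    n_exons: int,
    missing: bool = False,
) -> GeneStatus:
    """Assemble a GeneStatus from a filtered mutation list."""
    surv = [m for m in muts if m.surviving]
    pct = percent_intact(m.rel_pos for m in surv)
    exons_hit = len({m.exon_index for m in surv})
    cls = classify(pct, n_exons, exons_hit, len(surv), missing=missing)
    return GeneStatus(
        gene_id=gene_id,
        species=species,
        transcript_id=transcript_id,
        mutations=list(muts),
        percent_intact=pct,
        n_exons=n_exons,
        n_exons_with_mutation=exons_hit,
        classification=cls,
    )


def infer_ancestral_presence(
    tree: SpeciesTree,
    statuses: Sequence[GeneStatus],
    reference: str,
) -> tuple[Optional[object], list[GeneStatus]]:
    """Locate the most ancient ancestor in which the gene was intact and
    keep only losses below it.

    The gene must have been present in the common ancestor of the
    reference and a query species for its loss there to be meaningful.
    That ancestor is the MRCA of the reference and every query species
    without surviving gene-inactivating mutations; loss candidates
    outside the descendant clade are reclassified (their
    ``classification`` becomes ``not_ancestrally_present``) and dropped
    from the eligible list.

    Returns (ancestor node or None, eligible loss-candidate statuses).
    """
    intact_species = {reference}
    intact_species.update(
        st.species for st in statuses
        if st.classification != MISSING_DATA and not st.surviving
    )
    leaf_set = set(tree.leaf_names())
    intact_species &= leaf_set
    ancestor = tree.mrca(sorted(intact_species))
    clade = tree.leaves_under(ancestor)
    eligible = []
    for st in statuses:
        if st.classification != LOSS_CANDIDATE:
            continue
        if st.species in clade:
            eligible.append(st)
        else:
            st.classification = "not_ancestrally_present"
    return ancestor, eligible


def shared_mutation_support(
    statuses: Sequence[GeneStatus],
) -> dict[tuple, set[str]]:
    """Group identical surviving mutations across loss species.

    Two species share a mutation when class, exon index and CDS position
    (and indel length) coincide; a shared mutation is evidence the loss
    predates their split and places it on the common ancestral branch.
    Returns {mutation key: set of species}, shared entries only.
    """
    by_key: dict[tuple, set[str]] = defaultdict(set)
    for st in statuses:
        for m in st.surviving:
            by_key[m.key()].add(st.species)
    return {k: sp for k, sp in by_key.items() if len(sp) >= 2}
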