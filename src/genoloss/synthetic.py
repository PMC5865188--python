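"""Truth-labeled synthetic evolution of genes along a species tree.

The generator emulates the inputs of a reference-anchored gene-loss
screen: a reference genome with CDS annotation, query genomes evolved
along a tree under purifying selection (target Ka/Ks = ``ks_sel``) or —
on configured loss branches past a switch point — neutrally, with
injected inactivating mutations; assembly corruption (base errors,
error clusters next to assembly gaps, N-runs); structural artifacts
(splice-site shifts, precise intron deletions); exact truth-derived
pairwise alignments (no heuristic aligner, so every detected mutation
is attributable); and uniformly sampled reads.

Alignment bookkeeping: every exon is a list of ancestral columns.  A
substitution replaces a column's base, a deletion empties it, an
insertion attaches bases before a column.  Ref-vs-query alignments are
then rendered exactly, column by column; lineage-specific insertions
never align to each other.  Natural indels are restricted to terminal
branches (injected loss indels may sit on internal branches), which
keeps the column bookkeeping exact without per-base identity tracking.
"""

from __future__ import annotations

import hashlib
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .io_formats import (
    ExonAlignment,
    GenomeAssembly,
    MafBlock,
    MafRow,
    PairwiseGeneAlignment,
    SpeciesTree,
    TranscriptModel,
    write_annotation,
    write_fasta,
    write_maf,
)

__all__ = [
    "SimulationConfig",
    "LossSpec",
    "Simulation",
    "TruthRecord",
    "evolve_codon_sequence",
    "simulate_intact_matrix",
    "random_cds",
    "demo_tree",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
_STOPS = {"TAA", "TAG", "TGA"}

_CODON_AA: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    global _CODON_AA
    if not _CODON_AA:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_AA = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_AA[stop] = "*"
    return _CODON_AA


@dataclass
class LossSpec:
    """One gene-loss event to inject.

    ``branch`` names the branch by the leaves below it (a single leaf
    name, or comma-joined leaf names whose MRCA's parent edge is the
    loss branch); ``switch`` is the fraction of the branch spent under
    selection before inactivation; ``n_genes`` how many genes lose.
    """

    branch: str
    n_genes: int = 1
    switch: float = 0.5
    with_splice: bool = False
    genes: tuple[str, ...] = ()   # explicit gene ids (for convergent losses)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the screen-scale setting: a 40-leaf tree, 2,000
    conserved genes, and 20 losses injected on three independent
    trait lineages.  Branch lengths are neutral substitutions per site.
    Rates: ``ks_sel`` is the target Ka/Ks under selection; the indel
    rate is per site relative to the substitution rate and indels in
    conserved genes are frame-preserving; assembly base errors model
    consensus (not raw-read) accuracy; reads emulate long accurate
    (HiFi-grade) sequencing.
    """

    tree: str = ""
    reference: str = "ref"
    n_genes: int = 2000
    seed: int = 0
    exon_count_range: tuple[int, int] = (1, 8)
    exon_length_range: tuple[int, int] = (90, 210)
    intron_length: int = 120
    intergenic_length: int = 200
    substitution_rate: float = 1.0          # per site per unit branch length
    kappa: float = 1.0                      # transition/transversion bias
    ks_sel: float = 0.2
    indel_rate: float = 0.03                # relative to substitutions, terminal only
    loss_events: list[LossSpec] = field(default_factory=list)
    assembly_error_rate: float = 1e-4
    gap_per_mb: float = 6.0
    gap_length: int = 300
    near_gap_errors: float = 0.5            # expected planted errors per gap edge
    splice_shift_fraction: float = 0.0      # per gene x species
    intron_deletion_fraction: float = 0.0
    read_length: int = 10000
    read_error_rate: float = 1e-4
    coverage: float = 20.0
    trait1_species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tree:
            self.tree = demo_tree(40)
        for name, val in (
            ("substitution_rate", self.substitution_rate),
            ("indel_rate", self.indel_rate),
            ("assembly_error_rate", self.assembly_error_rate),
            ("read_error_rate", self.read_error_rate),
            ("coverage", self.coverage),
        ):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")


def demo_tree(n_leaves: int = 40, depth: float = 0.12, seed: int = 7) -> str:
    """A balanced-ish rooted tree with a reference leaf, in Newick.

    Terminal and internal branch lengths are jittered around values
    giving placental-scale divergence (~0.1-0.5 substitutions per
    neutral site root-to-leaf).
    """
    rng = np.random.default_rng(seed)

    def build(labels: list[str], budget: float) -> str:
        if len(labels) == 1:
            bl = budget * rng.uniform(0.7, 1.3)
            return f"{labels[0]}:{bl:.5f}"
        mid = len(labels) // 2
        bl = budget * 0.4 * rng.uniform(0.5, 1.5)
        rest = budget - bl
        return (
            f"({build(labels[:mid], rest)},{build(labels[mid:], rest)}):{bl:.5f}"
        )

    labels = ["ref"] + [f"sp{i:02d}" for i in range(1, n_leaves)]
    inner = build(labels, depth)
    return f"({inner});" if not inner.startswith("(") else inner + ";"


# ---------------------------------------------------------------------------
# per-exon evolutionary state

class ExonState:
    """Ancestral columns of one exon: chars (''=deleted) + insertions.

    ``ins[i]`` holds bases inserted before ancestral column ``i``
    (``i == len(chars)`` appends at the exon end).
    """

    __slots__ = ("chars", "ins")

    def __init__(self, seq: str):
        self.chars: list[str] = list(seq)
        self.ins: dict[int, str] = {}

    def copy(self) -> "ExonState":
        new = ExonState.__new__(ExonState)
        new.chars = self.chars.copy()
        new.ins = self.ins.copy()
        return new

    def sequence(self) -> str:
        parts = []
        for i, c in enumerate(self.chars):
            if i in self.ins:
                parts.append(self.ins[i])
            parts.append(c)
        if len(self.chars) in self.ins:
            parts.append(self.ins[len(self.chars)])
        return "".join(parts)


class GeneState:
    """One gene's evolving parts: exon columns and splice dinucleotides."""

    __slots__ = ("exons", "donors", "acceptors", "lost", "frozen")

    def __init__(self, exons: list[ExonState], n_introns: int):
        self.exons = exons
        self.donors = ["GT"] * n_introns
        self.acceptors = ["AG"] * n_introns
        self.lost = False
        # (exon index, column) pairs pinned by an injected mutation so that
        # later drift cannot erase the truth label
        self.frozen: set[tuple[int, int]] = set()

    def copy(self) -> "GeneState":
        new = GeneState.__new__(GeneState)
        new.exons = [e.copy() for e in self.exons]
        new.donors = self.donors.copy()
        new.acceptors = self.acceptors.copy()
        new.lost = self.lost
        new.frozen = self.frozen.copy()
        return new


@dataclass
class TruthRecord:
    """Ground truth for one injected loss."""

    gene_id: str
    branch: str
    descendants: tuple[str, ...]
    switch: float
    injected: tuple[tuple[str, int], ...]  # (class, CDS position on root frame)


# ---------------------------------------------------------------------------
# codon-level evolution (also used standalone for the dating fixtures)

def evolve_codon_sequence(
    seq: str,
    t: float,
    omega: float,
    rng: np.random.Generator,
    rate: float = 1.0,
    kappa: float = 1.0,
    forbid_stops: bool = True,
) -> str:
    """Evolve an in-frame CDS for time ``t`` under dN/dS = ``omega``.

    Substitutions are proposed per site as a Poisson process (HKY-style
    proposal with transition bias ``kappa``); non-synonymous proposals
    are accepted with probability ``omega``; proposals creating a stop
    codon are rejected while ``forbid_stops``.
    """
    table = _codon_table()
    s = list(seq.upper())
    L = len(s)
    n_events = rng.poisson(rate * t * L)
    positions = rng.integers(0, L, size=n_events)
    for pos in positions:
        old = s[pos]
        new = _propose_base(old, rng, kappa)
        if new is None:
            continue
        c0 = 3 * (pos // 3)
        codon = s[c0] + s[c0 + 1] + s[c0 + 2]
        if "N" in codon:
            continue
        k = pos - c0
        new_codon = codon[:k] + new + codon[k + 1:]
        if new_codon in _STOPS:
            if forbid_stops:
                continue
            s[pos] = new
            continue
        if codon in _STOPS or table[codon] == table[new_codon]:
            s[pos] = new
        elif rng.random() < omega:
            s[pos] = new
    return "".join(s)


def _propose_base(old: str, rng: np.random.Generator, kappa: float) -> Optional[str]:
    if old not in "ACGT":
        return None
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    others = [b for b in "ACGT" if b != old]
    if kappa == 1.0:
        return others[rng.integers(0, 3)]
    w = np.array([kappa if b == transitions[old] else 1.0 for b in others])
    w /= w.sum()
    return rng.choice(others, p=w)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """A random in-frame CDS without internal stop codons."""
    out = []
    for _ in range(n_codons):
        while True:
            codon = "".join(_BASES[rng.integers(0, 4, size=3)])
            if codon not in _STOPS:
                out.append(codon)
                break
    return "".join(out)


# ---------------------------------------------------------------------------
# the simulator

class Simulation:
    """Evolve a gene complement along a tree and render all artifacts."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.tree = SpeciesTree.from_newick(config.tree)
        self.truth: list[TruthRecord] = []
        self._build_root()
        self._assign_losses()
        self._evolve_tree()
        self._renders: dict[str, "_SpeciesRender"] = {}

    # -- construction ------------------------------------------------------

    def _build_root(self) -> None:
        cfg, rng = self.config, self.rng
        self.gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
        self.root: dict[str, GeneState] = {}
        self.introns: dict[str, list[str]] = {}
        self.spacers: dict[str, str] = {}
        lo, hi = cfg.exon_count_range
        elo, ehi = cfg.exon_length_range
        for gid in self.gene_ids:
            n_exons = int(rng.integers(lo, hi + 1))
            lengths = rng.integers(elo, ehi + 1, size=n_exons)
            extra = (3 - lengths.sum() % 3) % 3
            lengths[-1] += extra
            cds = random_cds(int(lengths.sum()) // 3, rng)
            exons, off = [], 0
            for L in lengths:
                exons.append(ExonState(cds[off:off + int(L)]))
                off += int(L)
            self.root[gid] = GeneState(exons, n_exons - 1)
            interiors = []
            for _ in range(n_exons - 1):
                mid = "".join(_BASES[rng.integers(0, 4, size=cfg.intron_length - 4)])
                interiors.append(mid)
            self.introns[gid] = interiors
            self.spacers[gid] = "".join(
                _BASES[rng.integers(0, 4, size=cfg.intergenic_length)]
            )

    def _assign_losses(self) -> None:
        cfg, rng = self.config, self.rng
        self.loss_genes: dict[str, list[tuple]] = {}
        pool = list(self.gene_ids)
        for spec in cfg.loss_events:
            labels = [x.strip() for x in spec.branch.split(",")]
            node = self.tree.mrca(labels)
            descendants = tuple(sorted(self.tree.leaves_under(node)))
            if spec.genes:
                chosen = list(spec.genes)
            else:
                chosen = [pool.pop(int(rng.integers(0, len(pool))))
                          for _ in range(spec.n_genes)]
            for gid in chosen:
                self.loss_genes.setdefault(gid, []).append(
                    (id(node), descendants, spec)
                )

    # -- evolution ---------------------------------------------------------

    def _evolve_tree(self) -> None:
        self.leaf_states: dict[str, dict[str, GeneState]] = {}
        root_node = self.tree.tree.seed_node
        self._descend(root_node, self.root)

    def _descend(self, node, states: dict[str, GeneState]) -> None:
        if node.is_leaf():
            self.leaf_states[node.taxon.label] = states
            return
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            child_states = {gid: st.copy() for gid, st in states.items()}
            terminal = child.is_leaf()
            for gid, st in child_states.items():
                loss = next(
                    (ev for ev in self.loss_genes.get(gid, ())
                     if ev[0] == id(child)),
                    None,
                )
                if loss is not None:
                    spec = loss[2]
                    self._evolve_gene(gid, st, bl * spec.switch, self.config.ks_sel,
                                      terminal)
                    self._inject(gid, st, spec, loss[1])
                    st.lost = True
                    self._evolve_gene(gid, st, bl * (1 - spec.switch), 1.0, terminal)
                elif st.lost:
                    self._evolve_gene(gid, st, bl, 1.0, terminal)
                else:
                    self._evolve_gene(gid, st, bl, self.config.ks_sel, terminal)
            self._descend(child, child_states)

    def _evolve_gene(
        self, gid: str, st: GeneState, t: float, omega: float, terminal: bool
    ) -> None:
        if t <= 0:
            return
        cfg, rng = self.config, self.rng
        rate = cfg.substitution_rate
        neutral = omega >= 1.0
        # substitutions on exon columns
        for exon_idx, es in enumerate(st.exons):
            L = len(es.chars)
            n = rng.poisson(rate * t * L)
            for pos in rng.integers(0, L, size=n):
                if (exon_idx, int(pos)) in st.frozen:
                    continue
                old = es.chars[pos]
                if len(old) != 1 or old not in "ACGT":
                    continue
                new = _propose_base(old, rng, cfg.kappa)
                if new is None:
                    continue
                if neutral:
                    es.chars[pos] = new
                    continue
                codon, k = self._codon_context(st, es, pos)
                if codon is None:
                    es.chars[pos] = new
                    continue
                new_codon = codon[:k] + new + codon[k + 1:]
                if new_codon in _STOPS:
                    continue
                table = _codon_table()
                if table.get(codon) == table.get(new_codon):
                    es.chars[pos] = new
                elif rng.random() < omega:
                    es.chars[pos] = new
        # splice dinucleotides: conserved under selection, free when lost
        if neutral:
            for arr in (st.donors, st.acceptors):
                for i in range(len(arr)):
                    n = rng.poisson(rate * t * 2)
                    for _ in range(n):
                        j = int(rng.integers(0, 2))
                        new = _propose_base(arr[i][j], rng, cfg.kappa)
                        if new is not None:
                            arr[i] = arr[i][:j] + new + arr[i][j + 1:]
        # indels: terminal branches only (frame-preserving while conserved,
        # and rejected if a stop codon could arise at the junction)
        if terminal and cfg.indel_rate > 0:
            for exon_idx, es in enumerate(st.exons):
                L = len(es.chars)
                n = rng.poisson(rate * cfg.indel_rate * t * L)
                for _ in range(n):
                    pos = int(rng.integers(0, L))
                    if any((exon_idx, c) in st.frozen
                           for c in range(pos - 1, pos + 7)):
                        continue
                    size = 3 * int(rng.geometric(0.5)) if not neutral \
                        else int(rng.geometric(0.4))
                    if rng.random() < 0.5:
                        if pos + size > L:
                            continue  # truncation would break the length class
                        if not neutral and _has_stop_frameless(
                            _flank(es, pos, -2) + _flank(es, pos + size, +2)
                        ):
                            continue
                        self._delete(es, pos, size)
                    else:
                        ins = "".join(_BASES[rng.integers(0, 4, size=size)])
                        if not neutral and _has_stop_frameless(
                            _flank(es, pos, -2) + ins + _flank(es, pos, +2)
                        ):
                            continue
                        es.ins[pos] = ins + es.ins.get(pos, "")

    def _codon_context(self, st: GeneState, es: ExonState, pos: int):
        """Current codon containing ancestral column ``pos`` of ``es``.

        Uses the root codon grid: with only frame-preserving indels in
        conserved genes, the phase of an ancestral column never changes.
        Returns (codon, offset) or (None, 0) near indels/edges.
        """
        exon_idx = st.exons.index(es)
        base = sum(len(e.chars) for e in st.exons[:exon_idx])
        phase = (base + pos) % 3
        cols = []
        # collect the three ancestral columns of this codon
        start = pos - phase
        for k in range(3):
            i = start + k
            e, j = es, i
            if i < 0 or i >= len(es.chars):
                e, j = self._neighbor_column(st, exon_idx, i)
                if e is None:
                    return None, 0
            c = e.chars[j]
            if len(c) != 1 or c not in "ACGT":
                return None, 0
            cols.append(c)
        return "".join(cols), phase

    @staticmethod
    def _neighbor_column(st: GeneState, exon_idx: int, i: int):
        if i < 0 and exon_idx > 0:
            prev = st.exons[exon_idx - 1]
            j = len(prev.chars) + i
            if 0 <= j < len(prev.chars):
                return prev, j
        if i >= 0 and exon_idx + 1 < len(st.exons):
            nxt = st.exons[exon_idx + 1]
            j = i - len(st.exons[exon_idx].chars)
            if 0 <= j < len(nxt.chars):
                return nxt, j
        return None, 0

    @staticmethod
    def _delete(es: ExonState, pos: int, size: int) -> None:
        end = min(len(es.chars), pos + size)
        for i in range(pos, end):
            es.chars[i] = ""

    # -- loss injection ----------------------------------------------------

    def _inject(self, gid: str, st: GeneState, spec: LossSpec, descendants) -> None:
        """Plant inactivating mutations at mid-CDS positions.

        Positions are expressed on the root CDS frame, so descendants of
        the same branch share them exactly.  Mutations sit in the middle
        60% of the CDS (outside the terminal trim) and in distinct exons
        where possible.
        """
        rng = self.rng
        lens = [len(e.chars) for e in st.exons]
        total = sum(lens)
        starts = [int(s) for s in np.cumsum([0] + lens[:-1])]
        injected: list[tuple[str, int]] = []

        # target the middle 50% of the CDS (safely inside the terminal
        # trim) and spread mutations over distinct exons where possible
        lo, hi = int(0.25 * total), int(0.75 * total)
        middle_exons = [
            i for i in range(len(lens))
            if starts[i] < hi and starts[i] + lens[i] > lo
        ]
        kinds = ("STOP_SUBST", "FS_DEL", "FS_INS")
        fracs = (0.30, 0.52, 0.70)
        targets = []
        for k, (kind, frac) in enumerate(zip(kinds, fracs)):
            ei = middle_exons[min(k * len(middle_exons) // 3, len(middle_exons) - 1)] \
                if len(middle_exons) >= 3 else middle_exons[k % len(middle_exons)]
            c_lo = max(lo, starts[ei]) + 3
            c_hi = min(hi, starts[ei] + lens[ei]) - 6
            if c_hi <= c_lo:
                c_lo, c_hi = starts[ei] + 3, starts[ei] + lens[ei] - 6
            cds = min(max(int(frac * total), c_lo), c_hi)
            targets.append((kind, ei, cds))

        for kind, ei, cds in targets:
            es = st.exons[ei]
            off = cds - starts[ei]
            if kind == "STOP_SUBST":
                c0 = cds - cds % 3  # codon-aligned on the root frame
                off = min(max(c0 - starts[ei], 0), lens[ei] - 3)
                off += (3 - (starts[ei] + off) % 3) % 3
                if off + 2 >= lens[ei]:
                    continue
                stop = ("TAA", "TGA", "TAG")[int(rng.integers(0, 3))]
                for k in range(3):
                    if es.chars[off + k]:
                        es.chars[off + k] = stop[k]
                    st.frozen.add((ei, off + k))
                injected.append(("STOP_SUBST", starts[ei] + off))
            elif kind == "FS_DEL":
                size = int(rng.integers(1, 3))
                self._delete(es, off, size)
                for c in range(off - 1, off + size + 1):
                    st.frozen.add((ei, c))
                injected.append(("FS_DEL", starts[ei] + off))
            else:
                size = int(rng.integers(1, 3))
                ins = "".join(_BASES[rng.integers(0, 4, size=size)])
                es.ins[off] = ins + es.ins.get(off, "")
                for c in range(off - 1, off + 1):
                    st.frozen.add((ei, c))
                injected.append(("FS_INS", starts[ei] + off))

        if spec.with_splice and len(st.exons) > 2:
            intron = len(st.exons) // 2 - 1
            st.donors[intron] = "AT"
            injected.append(("SPLICE_DONOR", int(starts[intron + 1]) - 1))
            # make the dead site unambiguous: no in-frame consensus dinucleotide
            # within the splice-shift search window on either side
            interiors = self.introns[gid]
            interiors[intron] = (
                _scrub_consensus(interiors[intron][:20]) + interiors[intron][20:]
            )
            exon = st.exons[intron]
            for k in range(1, 7):
                i = len(exon.chars) - 3 * k
                if i >= 0 and len(exon.chars[i]) == 1:
                    exon.chars[i] = "C"  # C starts no GT/GC/AG and no stop codon

        self.truth.append(
            TruthRecord(
                gene_id=gid,
                branch=spec.branch,
                descendants=descendants,
                switch=spec.switch,
                injected=tuple(injected),
            )
        )

    # -- rendering ---------------------------------------------------------

    def render(self, species: str) -> "_SpeciesRender":
        if species not in self._renders:
            rnd = _SpeciesRender(self, species)
            if species != self.config.reference:
                rnd.corrupt()
            rnd.finalize()
            self._renders[species] = rnd
        return self._renders[species]

    def reference_transcripts(self) -> list[TranscriptModel]:
        return self.render(self.config.reference).transcripts()

    def assembly(self, species: str) -> GenomeAssembly:
        return self.render(species).assembly()

    def alignments(self, species: str) -> list[PairwiseGeneAlignment]:
        """Exact truth-derived alignments of every gene vs the reference."""
        return _render_alignments(self, self.render(self.config.reference),
                                  self.render(species))

    def maf_blocks(self, species: str) -> list[MafBlock]:
        ref = self.render(self.config.reference)
        qry = self.render(species)
        blocks = []
        for ga in self.alignments(species):
            for idx, ealn in enumerate(ga.exons):
                if not ealn.present:
                    continue
                ref_coords = ref.exon_coords[ga.gene_id][idx]
                blocks.append(
                    MafBlock(
                        rows=[
                            MafRow(
                                f"{self.config.reference}.chr1", ref_coords[0],
                                ref_coords[1] - ref_coords[0], "+",
                                ref.genome_length, ealn.ref_aln,
                            ),
                            MafRow(
                                f"{ga.query_species}.chr1", ealn.qry_start,
                                ealn.qry_end - ealn.qry_start, "+",
                                qry.genome_length, ealn.qry_aln,
                            ),
                        ]
                    )
                )
        return blocks

    def sample_reads(
        self, species: str, seed_offset: int = 0
    ) -> list[tuple[str, int, str]]:
        """Uniform reads from the species genome with the configured
        error rate; random orientation (reads are unstranded).

        Returns (read id, genomic start, sequence); the start position is
        simulator ground truth (a real read set would not carry it)."""
        cfg = self.config
        genome = self.render(species).genome
        G = len(genome)
        rl = min(cfg.read_length, G)
        n_reads = int(round(cfg.coverage * G / rl))
        rng = np.random.default_rng((self.config.seed * 100003 + seed_offset) % (2**31))
        reads = []
        comp = str.maketrans("ACGTN", "TGCAN")
        for i in range(n_reads):
            start = int(rng.integers(0, max(1, G - rl + 1)))
            seq = list(genome[start:start + rl])
            n_err = rng.poisson(cfg.read_error_rate * rl)
            for pos in rng.integers(0, rl, size=n_err):
                if seq[pos] in "ACGT":
                    seq[pos] = _propose_base(seq[pos], rng, 1.0)
            read = "".join(seq)
            if rng.random() < 0.5:
                read = read.translate(comp)[::-1]
            reads.append((f"{species}_read{i}", start, read))
        return reads

    # -- output directory --------------------------------------------------

    def write_dir(self, outdir: str | Path, with_reads: bool = False) -> Path:
        outdir = Path(outdir)
        (outdir / "genomes").mkdir(parents=True, exist_ok=True)
        (outdir / "alignments").mkdir(exist_ok=True)
        ref = self.config.reference
        for sp in self.tree.leaf_names():
            write_fasta(self.assembly(sp), outdir / "genomes" / f"{sp}.fa")
            if sp != ref:
                write_maf(self.maf_blocks(sp), outdir / "alignments" / f"{sp}.maf")
        write_annotation(self.reference_transcripts(), outdir / "annotation.gff3")
        with open(outdir / "tree.nwk", "w") as fh:
            fh.write(self.config.tree.strip() + "\n")
        if self.config.trait1_species:
            with open(outdir / "traits.tsv", "w") as fh:
                fh.write("species\tgroup\n")
                for sp in self.tree.leaf_names():
                    if sp == ref:
                        continue
                    grp = 1 if sp in self.config.trait1_species else 2
                    fh.write(f"{sp}\t{grp}\n")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("gene\tbranch\tdescendants\tswitch\tinjected\n")
            for t in self.truth:
                inj = ";".join(f"{c}@{p}" for c, p in t.injected)
                fh.write(
                    f"{t.gene_id}\t{t.branch}\t{','.join(t.descendants)}\t"
                    f"{t.switch}\t{inj}\n"
                )
        with open(outdir / "config.yaml", "w") as fh:
            cfg = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.config).items()
                if k != "loss_events"
            }
            cfg["loss_events"] = [vars(ev) for ev in self.config.loss_events]
            yaml.safe_dump(cfg, fh)
        if with_reads:
            (outdir / "reads").mkdir(exist_ok=True)
            for sp in self.tree.leaf_names():
                if sp == ref:
                    continue
                with open(outdir / "reads" / f"{sp}.fq", "w") as fh:
                    for rid, _start, seq in self.sample_reads(sp):
                        fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
        return outdir


def _has_stop_frameless(seq: str) -> bool:
    return any(seq[k:k + 3] in _STOPS for k in range(len(seq) - 2))


def _flank(es: ExonState, pos: int, want: int) -> str:
    """Up to |want| non-deleted bases left (want<0) or right of a column."""
    out: list[str] = []
    rng_ = range(pos - 1, -1, -1) if want < 0 else range(pos, len(es.chars))
    for i in rng_:
        if len(out) == abs(want):
            break
        c = es.chars[i]
        if len(c) == 1:
            out.append(c)
    if want < 0:
        out.reverse()
    return "".join(out)


def _scrub_consensus(seq: str) -> str:
    """Remove GT/GC/AG dinucleotides from a short window."""
    s = list(seq)
    for i in range(len(s) - 1):
        if s[i] + s[i + 1] in ("GT", "GC", "AG"):
            s[i] = "C" if s[i] != "C" else "T"
    return "".join(s)


# ---------------------------------------------------------------------------
# species rendering: layout, corruption, coordinates

class _SpeciesRender:
    """Mutable per-species view: segments -> genome + coordinates."""

    def __init__(self, sim: Simulation, species: str):
        self.sim = sim
        self.species = species
        self.states = sim.leaf_states[species]
        cfg = sim.config
        rng = np.random.default_rng(
            (cfg.seed * 7919 + _stable_hash(species)) % (2**31)
        )
        self.rng = rng
        # per gene x intron structural artifacts (conserved genes only)
        self.deleted_introns: dict[str, set[int]] = {}
        self.shifted_donors: dict[str, set[int]] = {}
        if species != cfg.reference:
            for gid in sim.gene_ids:
                st = self.states[gid]
                if st.lost or len(st.exons) < 2:
                    continue
                if cfg.intron_deletion_fraction and rng.random() < cfg.intron_deletion_fraction:
                    self.deleted_introns[gid] = {
                        int(rng.integers(0, len(st.exons) - 1))
                    }
                elif cfg.splice_shift_fraction and rng.random() < cfg.splice_shift_fraction:
                    intron = int(rng.integers(0, len(st.exons) - 1))
                    self.shifted_donors[gid] = {intron}
                    st.donors[intron] = "AT"
        self._build_segments()

    def _build_segments(self) -> None:
        sim, cfg = self.sim, self.sim.config
        self.segments: list[tuple[str, object]] = []
        for gid in sim.gene_ids:
            st = self.states[gid]
            self.segments.append(("spacer", list(sim.spacers[gid])))
            for i, es in enumerate(st.exons):
                self.segments.append(("exon", (gid, i, es)))
                if i < len(st.exons) - 1:
                    if i in self.deleted_introns.get(gid, ()):
                        continue  # precise intron deletion: no sequence at all
                    interior = sim.introns[gid][i]
                    if i in self.shifted_donors.get(gid, ()):
                        # donor moved +3 bp into the intron: broken old site,
                        # one safe spacer base, consensus GT at offset 3
                        intron_seq = st.donors[i] + "C" + "GT" + interior[3:] \
                            + st.acceptors[i]
                    else:
                        intron_seq = st.donors[i] + interior + st.acceptors[i]
                    self.segments.append(("intron", (gid, i, list(intron_seq))))
        self.segments.append(("spacer", list("ACGT" * 25)))

    def corrupt(self) -> None:
        """Assembly base errors, N-gaps, and error clusters at gap edges."""
        cfg, rng = self.sim.config, self.rng
        flat_len = self._layout_length()
        # uniform consensus errors
        if cfg.assembly_error_rate > 0:
            n_err = rng.poisson(cfg.assembly_error_rate * flat_len)
            for off in rng.integers(0, flat_len, size=n_err):
                self._substitute(int(off))
        # assembly gaps (N-runs) with error-prone edges
        n_gaps = rng.poisson(cfg.gap_per_mb * flat_len / 1e6)
        for _ in range(n_gaps):
            glen = max(10, int(rng.normal(cfg.gap_length, cfg.gap_length / 4)))
            start = int(rng.integers(0, max(1, flat_len - glen)))
            self._mask(start, start + glen)
            for edge in (start - 1, start + glen):
                n_near = rng.poisson(cfg.near_gap_errors)
                for k in range(n_near):
                    off = edge - k if edge < start else edge + k
                    if 0 <= off < flat_len:
                        self._substitute(off)

    def _layout_length(self) -> int:
        self._offsets = []
        total = 0
        for kind, payload in self.segments:
            self._offsets.append(total)
            total += self._seg_len(kind, payload)
        self._total = total
        return total

    @staticmethod
    def _seg_len(kind: str, payload) -> int:
        if kind == "exon":
            _, _, es = payload
            return sum(len(c) for c in es.chars) + sum(len(v) for v in es.ins.values())
        return len(payload[2] if kind == "intron" else payload)

    def _locate(self, off: int):
        idx = bisect_right(self._offsets, off) - 1
        return idx, off - self._offsets[idx]

    def _substitute(self, off: int) -> None:
        idx, rel = self._locate(off)
        kind, payload = self.segments[idx]
        rng = self.rng
        if kind == "exon":
            _, _, es = payload
            pos = _exon_rel_to_column(es, rel)
            if pos is not None:
                old = es.chars[pos]
                if len(old) == 1 and old in "ACGT":
                    es.chars[pos] = _propose_base(old, rng, 1.0)
        else:
            buf = payload[2] if kind == "intron" else payload
            if buf[rel] in "ACGT":
                buf[rel] = _propose_base(buf[rel], rng, 1.0)

    def _mask(self, start: int, end: int) -> None:
        for off in range(start, min(end, self._total)):
            idx, rel = self._locate(off)
            kind, payload = self.segments[idx]
            if kind == "exon":
                _, _, es = payload
                pos = _exon_rel_to_column(es, rel)
                if pos is not None:
                    es.chars[pos] = "N"
                else:
                    _mask_insertion(es, rel)
            else:
                buf = payload[2] if kind == "intron" else payload
                buf[rel] = "N"

    def finalize(self) -> None:
        """Flatten segments into the genome string and record coordinates."""
        self._layout_length()
        parts: list[str] = []
        self.exon_coords: dict[str, list[tuple[int, int]]] = {}
        pos = 0
        for kind, payload in self.segments:
            if kind == "exon":
                gid, i, es = payload
                seq = es.sequence()
                self.exon_coords.setdefault(gid, []).append((pos, pos + len(seq)))
                parts.append(seq)
                pos += len(seq)
            else:
                buf = payload[2] if kind == "intron" else payload
                parts.append("".join(buf))
                pos += len(buf)
        self.genome = "".join(parts)
        self.genome_length = len(self.genome)

    # -- exported objects --------------------------------------------------

    def assembly(self) -> GenomeAssembly:
        return GenomeAssembly(name=self.species, sequences={"chr1": self.genome})

    def transcripts(self) -> list[TranscriptModel]:
        out = []
        for gid in self.sim.gene_ids:
            exons = self.exon_coords[gid]
            out.append(
                TranscriptModel(
                    gene_id=gid,
                    transcript_id=f"{gid}.t1",
                    contig="chr1",
                    strand="+",
                    exons=list(exons),
                    priority="principal",
                )
            )
        return out


def _exon_rel_to_column(es: ExonState, rel: int) -> Optional[int]:
    """Map an offset within the rendered exon back to an ancestral column."""
    acc = 0
    for i, c in enumerate(es.chars):
        if i in es.ins:
            if rel < acc + len(es.ins[i]):
                return None  # falls inside an inserted stretch
            acc += len(es.ins[i])
        if c:
            if rel < acc + len(c):
                return i
            acc += len(c)
    return None


def _mask_insertion(es: ExonState, rel: int) -> None:
    acc = 0
    for i in sorted(list(es.ins) + [len(es.chars) + 1]):
        if i > len(es.chars):
            return
        ins = es.ins[i]
        before = sum(len(c) for c in es.chars[:i])
        # approximate: mask the whole inserted stretch
        if before <= rel < before + len(ins) + sum(len(c) for c in es.chars[i:i + 1]):
            es.ins[i] = "N" * len(ins)
            return


def _stable_hash(s: str) -> int:
    return int(hashlib.sha1(s.encode()).hexdigest()[:8], 16)


# ---------------------------------------------------------------------------
# alignment rendering

def _render_alignments(
    sim: Simulation, ref: _SpeciesRender, qry: _SpeciesRender
) -> list[PairwiseGeneAlignment]:
    out = []
    # global list of present-block query intervals for anchor lookup
    all_blocks: list[tuple[int, int]] = []
    presence: dict[tuple[str, int], bool] = {}
    for gid in sim.gene_ids:
        for i, (s, e) in enumerate(qry.exon_coords[gid]):
            qst = qry.states[gid].exons[i]
            seq = qst.sequence()
            present = bool(seq) and any(c in "ACGT" for c in seq)
            presence[(gid, i)] = present
            if present:
                all_blocks.append((s, e))
    all_blocks.sort()
    starts = [b[0] for b in all_blocks]

    for gid in sim.gene_ids:
        ref_states = ref.states[gid].exons
        qry_states = qry.states[gid].exons
        exon_alns = []
        locus_lo, locus_hi = None, None
        for i, (res, qes) in enumerate(zip(ref_states, qry_states)):
            qs, qe = qry.exon_coords[gid][i]
            if presence[(gid, i)]:
                ref_row, qry_row = _pair_rows(res, qes)
                donor, acceptor = _splice_flanks(qry, gid, i, qs, qe)
                exon_alns.append(
                    ExonAlignment(
                        ref_aln=ref_row,
                        qry_aln=qry_row,
                        qry_contig="chr1",
                        qry_start=qs,
                        qry_end=qe,
                        donor=donor,
                        acceptor=acceptor,
                        present=True,
                    )
                )
                locus_lo = qs if locus_lo is None else min(locus_lo, qs)
                locus_hi = qe if locus_hi is None else max(locus_hi, qe)
            else:
                up = _nearest_block(starts, all_blocks, qs, before=True)
                down = _nearest_block(starts, all_blocks, qe, before=False)
                exon_alns.append(
                    ExonAlignment(
                        ref_aln="",
                        qry_aln="",
                        qry_contig="chr1",
                        qry_start=qs,
                        qry_end=qe,
                        present=False,
                        anchor_up=up,
                        anchor_down=down,
                    )
                )
        locus = ("chr1", locus_lo, locus_hi) if locus_lo is not None else None
        out.append(
            PairwiseGeneAlignment(
                gene_id=gid,
                transcript_id=f"{gid}.t1",
                query_species=qry.species,
                exons=exon_alns,
                qry_locus=locus,
            )
        )
    return out


def _pair_rows(res: ExonState, qes: ExonState) -> tuple[str, str]:
    ref_row: list[str] = []
    qry_row: list[str] = []
    L = len(res.chars)
    for i in range(L + 1):
        for ch in res.ins.get(i, ""):
            ref_row.append(ch)
            qry_row.append("-")
        for ch in qes.ins.get(i, ""):
            ref_row.append("-")
            qry_row.append(ch)
        if i < L:
            rc, qc = res.chars[i], qes.chars[i]
            if rc and qc:
                ref_row.append(rc)
                qry_row.append(qc)
            elif rc:
                ref_row.append(rc)
                qry_row.append("-")
            elif qc:
                ref_row.append("-")
                qry_row.append(qc)
    return "".join(ref_row), "".join(qry_row)


def _splice_flanks(qry: _SpeciesRender, gid: str, i: int, qs: int, qe: int):
    st = qry.states[gid]
    n = len(st.exons)
    genome = qry.genome
    donor = genome[qe:qe + 2] if i < n - 1 and qe + 2 <= len(genome) else None
    acceptor = genome[qs - 2:qs] if i > 0 and qs >= 2 else None
    if donor is not None and ("N" in donor or len(donor) < 2):
        donor = None
    if acceptor is not None and ("N" in acceptor or len(acceptor) < 2):
        acceptor = None
    return donor, acceptor


def _nearest_block(starts, blocks, pos: int, before: bool) -> Optional[int]:
    idx = bisect_right(starts, pos) - 1
    if before:
        while idx >= 0:
            s, e = blocks[idx]
            if e <= pos:
                return e
            idx -= 1
        return None
    idx = bisect_right(starts, pos)
    while idx < len(blocks):
        s, e = blocks[idx]
        if s >= pos:
            return s
        idx += 1
    return None


# ---------------------------------------------------------------------------
# matrix-level fixture for the phylogenetic screen

def simulate_intact_matrix(
    tree: SpeciesTree,
    groups: dict[str, int],
    n_null: int = 1000,
    n_loss: int = 20,
    noise_sd: float = 3.0,
    seed: int = 0,
):
    """A gene x species %intact matrix with known convergent-loss genes.

    Null genes are intact everywhere with phylogeny-correlated noise
    (Brownian motion on the tree, folded below 100); loss genes draw
    %intact uniformly in [10, 50] for every trait-group-1 species.
    Returns (DataFrame, list of loss gene ids).
    """
    import pandas as pd

    from .forward_genomics import brownian_covariance

    rng = np.random.default_rng(seed)
    species = [sp for sp in tree.leaf_names() if sp in groups]
    C = brownian_covariance(tree, species).to_numpy()
    Lc = np.linalg.cholesky(C + 1e-9 * np.eye(len(species)))
    rows = {}
    loss_genes = []
    for g in range(n_null + n_loss):
        gid = f"g{g:05d}"
        eps = Lc @ rng.standard_normal(len(species))
        vals = np.clip(100.0 - np.abs(noise_sd * eps), 0.0, 100.0)
        if g >= n_null:
            loss_genes.append(gid)
            for k, sp in enumerate(species):
                if groups[sp] == 1:
                    vals[k] = rng.uniform(10.0, 50.0)
        rows[gid] = vals
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=species)
    return mat, loss_genes
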