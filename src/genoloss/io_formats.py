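"""Readers/writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open; conversion to/from the
1-based closed convention of GFF happens only at parse/write boundaries.
BED output is 0-based half-open as usual.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy

__all__ = [
    "GenomeAssembly",
    "TranscriptModel",
    "ExonAlignment",
    "PairwiseGeneAlignment",
    "SpeciesTree",
    "read_annotation",
    "write_annotation",
    "read_fasta",
    "write_fasta",
    "read_maf",
    "write_maf",
    "MafBlock",
    "MafRow",
    "read_tree",
    "write_status_table",
    "write_mutation_report",
    "read_trait_table",
]

_N_RUN = re.compile(r"[Nn]+")


@dataclass
class GenomeAssembly:
    """A query or reference assembly: named contigs plus their N-run gaps.

    ``gaps`` maps contig id to a sorted list of maximal ``[start, end)``
    intervals of ambiguous bases.  Any run of N counts as an assembly gap.
    """

    name: str
    sequences: dict[str, str]
    gaps: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gaps:
            self.gaps = {
                contig: [(m.start(), m.end()) for m in _N_RUN.finditer(seq)]
                for contig, seq in self.sequences.items()
            }

    def overlaps_gap(self, contig: str, start: int, end: int) -> bool:
        """True if [start, end) intersects any N-run on ``contig``."""
        for gs, ge in self.gaps.get(contig, ()):
            if gs < end and start < ge:
                return True
        return False

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self.sequences[contig]
        return seq[max(0, start):max(0, end)]


@dataclass
class TranscriptModel:
    """One annotated isoform: ordered CDS exons on a contig.

    ``exons`` are genomic ``[start, end)`` intervals ordered 5'->3' in
    transcript orientation (descending genomic start on the minus strand).
    ``priority`` carries the isoform tag (principal / alternative).
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    priority: str = "principal"

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_cds_starts(self) -> list[int]:
        """CDS offset at which each exon begins (transcript order)."""
        out, acc = [], 0
        for s, e in self.exons:
            out.append(acc)
            acc += e - s
        return out

    def exon_frames(self) -> list[int]:
        """Reading-frame phase (0-2) at the start of each exon."""
        return [c % 3 for c in self.exon_cds_starts()]

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)


@dataclass
class ExonAlignment:
    """Pairwise alignment of one reference CDS exon to its query locus.

    ``ref_aln``/``qry_aln`` are equal-length gapped strings; ``present``
    is False when no query sequence aligns to the exon, in which case
    ``anchor_up``/``anchor_down`` give the query coordinates of the
    nearest up-/downstream aligning blocks (the inter-anchor region).
    Splice dinucleotides are taken from the query intron flanks in
    transcript orientation; None where the flank is unavailable.
    """

    ref_aln: str = ""
    qry_aln: str = ""
    qry_contig: Optional[str] = None
    qry_start: int = 0
    qry_end: int = 0
    donor: Optional[str] = None
    acceptor: Optional[str] = None
    present: bool = True
    anchor_up: Optional[int] = None
    anchor_down: Optional[int] = None

    def __post_init__(self) -> None:
        if self.present and len(self.ref_aln) != len(self.qry_aln):
            raise ValueError("aligned exon rows differ in length")


@dataclass
class PairwiseGeneAlignment:
    """All exon alignments of one gene against one query species."""

    gene_id: str
    transcript_id: str
    query_species: str
    exons: list[ExonAlignment]
    qry_locus: Optional[tuple[str, int, int]] = None

    @property
    def n_exons(self) -> int:
        return len(self.exons)


class SpeciesTree:
    """Rooted species tree with branch lengths, wrapping a dendropy tree."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.tree.is_rooted = True
        labels = self.leaf_names()
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate leaf names in species tree")

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def mrca(self, labels: Sequence[str]) -> dendropy.Node:
        labels = list(labels)
        if len(labels) == 1:
            (leaf,) = [
                lf for lf in self.tree.leaf_node_iter() if lf.taxon.label == labels[0]
            ]
            return leaf
        return self.tree.mrca(taxon_labels=labels)

    def leaves_under(self, node: dendropy.Node) -> set[str]:
        return {lf.taxon.label for lf in node.leaf_iter()}

    def root_distances(self) -> dict[str, float]:
        """Root-to-leaf path lengths keyed by leaf label."""
        self.tree.calc_node_root_distances(return_leaf_distances_only=False)
        return {
            lf.taxon.label: lf.root_distance for lf in self.tree.leaf_node_iter()
        }

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# annotation (GFF3/GTF, CDS features only; parsed with gffutils)

def read_annotation(path: str | Path) -> list[TranscriptModel]:
    """Parse CDS features from a GFF3/GTF file into transcript models.

    Coordinates are converted from 1-based closed to 0-based half-open.
    Exons are returned ordered 5'->3' in transcript orientation.  CDS
    features lacking a transcript id are skipped with a warning; a
    malformed feature line raises a parse error naming the line.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # noqa: BLE001 - surface the offending line
        raise ValueError(f"malformed annotation {path}: {exc}") from exc

    per_tx: dict[str, dict] = {}
    for feat in db.features_of_type("CDS"):
        attrs = {k: v[0] for k, v in feat.attributes.items() if v}
        tx = attrs.get("transcript_id") or attrs.get("Parent")
        if tx is None:
            warnings.warn(f"CDS without transcript id at {feat.seqid}:{feat.start}; skipped")
            continue
        rec = per_tx.setdefault(
            tx,
            {
                "gene": attrs.get("gene_id", tx),
                "contig": feat.seqid,
                "strand": feat.strand,
                "exons": [],
                "priority": attrs.get("tag", "principal"),
            },
        )
        rec["exons"].append((feat.start - 1, feat.end))

    models = []
    for tx, rec in per_tx.items():
        exons = sorted(rec["exons"], reverse=(rec["strand"] == "-"))
        models.append(
            TranscriptModel(
                gene_id=rec["gene"],
                transcript_id=tx,
                contig=rec["contig"],
                strand=rec["strand"],
                exons=exons,
                priority=rec["priority"],
            )
        )
    models.sort(key=lambda m: (m.gene_id, m.transcript_id))
    return models


def write_annotation(models: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.gene_id, m.transcript_id)):
            for s, e in sorted(m.exons):
                attrs = (
                    f"gene_id={m.gene_id};transcript_id={m.transcript_id};"
                    f"tag={m.priority}"
                )
                fh.write(
                    f"{m.contig}\tgenoloss\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, name: Optional[str] = None) -> GenomeAssembly:
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return GenomeAssembly(name=name or Path(path).stem, sequences=seqs)


def write_fasta(assembly: GenomeAssembly, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig in sorted(assembly.sequences):
            fh.write(f">{contig}\n")
            seq = assembly.sequences[contig]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# MAF (reference-anchored pairwise blocks)

@dataclass
class MafRow:
    """One "s" line: src, start, size, strand, srcSize, gapped text."""

    src: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str


@dataclass
class MafBlock:
    rows: list[MafRow]

    def row_for(self, species: str) -> Optional[MafRow]:
        for r in self.rows:
            if r.src == species or r.src.split(".")[0] == species:
                return r
        return None


def read_maf(path: str | Path, reference: str) -> list[MafBlock]:
    """Read MAF blocks, dropping (with a warning) blocks without the reference.

    Query strand and coordinates keep MAF semantics: a "-" strand start
    counts from the reverse-complemented source sequence.
    """
    from Bio import AlignIO

    blocks: list[MafBlock] = []
    for aln in AlignIO.parse(str(path), "maf"):
        rows = [
            MafRow(
                src=rec.id,
                start=rec.annotations["start"],
                size=rec.annotations["size"],
                strand="+" if rec.annotations["strand"] == 1 else "-",
                src_size=rec.annotations["srcSize"],
                text=str(rec.seq),
            )
            for rec in aln
        ]
        blk = MafBlock(rows=rows)
        if blk.row_for(reference) is None:
            warnings.warn("MAF block without reference row dropped")
            continue
        blocks.append(blk)
    return blocks


def write_maf(blocks: Iterable[MafBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for blk in blocks:
            fh.write("a\n")
            for r in blk.rows:
                fh.write(
                    f"s {r.src} {r.start} {r.size} {r.strand} {r.src_size} {r.text}\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# tree / tables

def read_tree(path: str | Path) -> SpeciesTree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return SpeciesTree(tree)


def read_trait_table(path: str | Path, tree: Optional[SpeciesTree] = None) -> dict[str, int]:
    """Read a two-column TSV (species, group in {1, 2}).

    With a tree given, species absent from the tree are a hard error.
    """
    groups: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("species"):
                continue
            sp, grp = line.split("\t")[:2]
            groups[sp] = int(grp)
    if tree is not None:
        unknown = sorted(set(groups) - set(tree.leaf_names()))
        if unknown:
            raise ValueError(f"trait species not in tree: {', '.join(unknown)}")
    return groups


def write_status_table(statuses: Iterable, path: str | Path) -> None:
    """Write per gene x species classification rows as TSV."""
    with open(path, "w") as fh:
        fh.write(
            "gene\tspecies\ttranscript\tpercent_intact\tn_exons\t"
            "n_exons_with_mutation\tclassification\n"
        )
        for st in statuses:
            fh.write(
                f"{st.gene_id}\t{st.species}\t{st.transcript_id}\t"
                f"{st.percent_intact:.4g}\t{st.n_exons}\t"
                f"{st.n_exons_with_mutation}\t{st.classification}\n"
            )


def write_mutation_report(
    mutations: Iterable[tuple[str, str, str, object]],
    tsv_path: str | Path,
    bed_path: Optional[str | Path] = None,
) -> None:
    """Write mutation rows; ``mutations`` yields (gene, transcript, species, mut).

    The BED output (0-based half-open) locates each mutation on its query
    contig where a query position is known.
    """
    muts = list(mutations)
    with open(tsv_path, "w") as fh:
        fh.write(
            "gene\ttranscript\tspecies\texon_index\tclass\tcds_rel_pos\t"
            "detail\tfiltered_reason\n"
        )
        for gene, tx, sp, m in muts:
            fh.write(
                f"{gene}\t{tx}\t{sp}\t{m.exon_index}\t{m.mclass}\t"
                f"{m.rel_pos:.6f}\t{m.detail}\t{m.filtered_reason}\n"
            )
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for gene, tx, sp, m in muts:
                if m.query_contig is None or m.query_pos is None:
                    continue
                fh.write(
                    f"{m.query_contig}\t{m.query_pos}\t{m.query_pos + 1}\t"
                    f"{gene}|{sp}|{m.mclass}\n"
                )
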