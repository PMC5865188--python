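"""End-to-end orchestration: scan -> filter cascade -> loss calls ->
%intact matrix, from in-memory objects or from a directory of files.

Default thresholds are the published ones: loss candidates need
%intact < 60 with at least 20% of exons mutated (two mutations for
single-exon genes); frame-preserving indels longer than 50 bp count as
inactivating; mutations in the terminal 20% of the protein are
discarded; the phylogenetic screen selects p < 1e-6; read validation
requires a >= 50 bp context supported by >= 10 exact read matches.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import alignment_filters as af
from . import loss_caller as lc
from .io_formats import (
    GenomeAssembly,
    MafBlock,
    PairwiseGeneAlignment,
    ExonAlignment,
    TranscriptModel,
    read_annotation,
    read_fasta,
    read_maf,
    read_tree,
    write_mutation_report,
    write_status_table,
)
from .mutation_scan import scan_gene

__all__ = [
    "RunConfig",
    "SpeciesCallResult",
    "call_species",
    "build_intact_matrix",
    "gene_alignments_from_maf",
    "run_directory",
]


@dataclass
class RunConfig:
    """All tunable thresholds, defaulting to the published values."""

    intact_max: float = 60.0
    exon_fraction: float = 0.2
    single_exon_min_muts: int = 2
    big_indel_min: int = 51
    terminal_trim: float = 0.2
    pgls_p: float = 1e-6
    t2_intact_fraction: float = 0.9
    t2_intact_cut: float = 90.0
    t2_broken_fraction: float = 0.05
    t2_broken_cut: float = 60.0
    missing_fraction: float = 0.5
    read_flank: int = 50
    read_min_support: int = 10
    seed: int = 0

    def manifest(self) -> dict:
        d = dict(vars(self))
        d["config_hash"] = hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]
        return d


@dataclass
class SpeciesCallResult:
    """Per-species outcome: statuses, mutation lists, filter traces."""

    species: str
    statuses: dict[str, lc.GeneStatus] = field(default_factory=dict)
    traces: dict[str, af.FilterTrace] = field(default_factory=dict)


def call_species(
    transcripts: Sequence[TranscriptModel],
    gene_alignments: Sequence[PairwiseGeneAlignment],
    assembly: Optional[GenomeAssembly],
    species: str,
) -> SpeciesCallResult:
    """Scan and classify every gene of one query species.

    ``transcripts`` may contain several isoforms per gene; each isoform
    is scanned and filtered separately and the isoform with the fewest
    surviving mutations represents the gene.  Conserved-gene-order
    neighbors are derived from the reference gene order.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    aln_by_tx = {ga.transcript_id: ga for ga in gene_alignments}
    loci = _gene_loci(gene_alignments)
    order = _reference_gene_order(transcripts)

    result = SpeciesCallResult(species=species)
    for gene_id, isoforms in by_gene.items():
        per_iso_muts: dict[str, list] = {}
        per_iso_missing: dict[str, bool] = {}
        cds_lengths: dict[str, int] = {}
        synteny_ok = True
        trace = af.FilterTrace(gene_id, species)
        up, down = _neighbor_loci(gene_id, order, loci)
        for tx in isoforms:
            ga = aln_by_tx.get(tx.transcript_id)
            if ga is None:
                continue
            cds_lengths[tx.transcript_id] = tx.cds_length
            muts = scan_gene(tx, ga, assembly)
            muts, ok = af.apply_cascade(
                tx, ga, muts, assembly,
                gene_locus=loci.get(gene_id),
                up_neighbor=up,
                down_neighbor=down,
                trace=trace if tx is isoforms[0] else None,
            )
            synteny_ok = synteny_ok and ok
            per_iso_muts[tx.transcript_id] = muts
            n_missing = sum(1 for m in muts if m.filtered_reason == "missing_data")
            per_iso_missing[tx.transcript_id] = n_missing > 0.5 * tx.n_exons
        if not per_iso_muts:
            continue
        chosen = af.select_isoform(per_iso_muts, cds_lengths)
        muts = per_iso_muts[chosen]
        trace.record("isoform", len([m for m in muts if m.surviving]),
                     len([m for m in muts if m.surviving]))
        tx = next(t for t in isoforms if t.transcript_id == chosen)
        missing = per_iso_missing[chosen] or not synteny_ok
        status = lc.build_status(
            gene_id, species, chosen, muts, tx.n_exons, missing=missing
        )
        result.statuses[gene_id] = status
        result.traces[gene_id] = trace
    return result


def _gene_loci(gene_alignments) -> dict[str, Optional[tuple[str, int, int]]]:
    return {ga.gene_id: ga.qry_locus for ga in gene_alignments}


def _reference_gene_order(transcripts) -> list[str]:
    span: dict[str, tuple[str, int]] = {}
    for tx in transcripts:
        s, _ = tx.span
        cur = span.get(tx.gene_id)
        if cur is None or (tx.contig, s) < cur:
            span[tx.gene_id] = (tx.contig, s)
    return sorted(span, key=lambda g: span[g])


def _neighbor_loci(gene_id, order, loci):
    try:
        i = order.index(gene_id)
    except ValueError:
        return None, None
    up = loci.get(order[i - 1]) if i > 0 else None
    down = loci.get(order[i + 1]) if i + 1 < len(order) else None
    return up, down


def build_intact_matrix(results: Sequence[SpeciesCallResult]) -> pd.DataFrame:
    """Gene x species %intact matrix; NaN marks missing data."""
    data: dict[str, dict[str, float]] = {}
    for res in results:
        for gene_id, st in res.statuses.items():
            val = float("nan") if st.classification == lc.MISSING_DATA \
                else st.percent_intact
            data.setdefault(gene_id, {})[res.species] = val
    mat = pd.DataFrame.from_dict(data, orient="index")
    return mat.sort_index()


# ---------------------------------------------------------------------------
# file-based path (CLI): reconstruct gene alignments from MAF blocks

def gene_alignments_from_maf(
    blocks: Sequence[MafBlock],
    transcripts: Sequence[TranscriptModel],
    query_assembly: GenomeAssembly,
    reference: str,
    query: str,
) -> list[PairwiseGeneAlignment]:
    """Assemble per-gene exon alignments from reference-anchored blocks.

    Blocks are matched to annotated CDS exons by reference-interval
    overlap and sliced to the exon boundaries.  Unmatched exons get
    their flanking anchors from the nearest matched blocks; splice-site
    dinucleotides are read from the query assembly around each exon's
    query locus (forward-mapped queries).
    """
    indexed = []
    for blk in blocks:
        ref_row = blk.row_for(reference)
        qry_row = blk.row_for(query)
        if ref_row is None or qry_row is None:
            continue
        indexed.append((ref_row.start, ref_row.start + ref_row.size, ref_row, qry_row))
    indexed.sort(key=lambda x: x[0])

    out = []
    for tx in sorted(transcripts, key=lambda t: t.transcript_id):
        exon_alns = []
        locus_lo = locus_hi = None
        qry_contig = None
        n = tx.n_exons
        for idx, (es, ee) in enumerate(tx.exons):
            hit = _find_block(indexed, es, ee)
            if hit is None:
                exon_alns.append(
                    ExonAlignment(present=False, qry_contig=None)
                )
                continue
            ref_row, qry_row, ref_aln, qry_aln, qs, qe = hit
            qry_contig = _strip_species(qry_row.src)
            donor = acceptor = None
            seq = query_assembly.sequences.get(qry_contig, "")
            if idx < n - 1 and qe + 2 <= len(seq):
                donor = seq[qe:qe + 2]
            if idx > 0 and qs >= 2:
                acceptor = seq[qs - 2:qs]
            donor = None if donor and "N" in donor else donor
            acceptor = None if acceptor and "N" in acceptor else acceptor
            exon_alns.append(
                ExonAlignment(
                    ref_aln=ref_aln, qry_aln=qry_aln, qry_contig=qry_contig,
                    qry_start=qs, qry_end=qe, donor=donor, acceptor=acceptor,
                )
            )
            locus_lo = qs if locus_lo is None else min(locus_lo, qs)
            locus_hi = qe if locus_hi is None else max(locus_hi, qe)
        # anchors for absent exons from neighbouring matched exons
        for idx, ealn in enumerate(exon_alns):
            if ealn.present:
                continue
            ealn.qry_contig = qry_contig
            for j in range(idx - 1, -1, -1):
                if exon_alns[j].present:
                    ealn.anchor_up = exon_alns[j].qry_end
                    break
            for j in range(idx + 1, len(exon_alns)):
                if exon_alns[j].present:
                    ealn.anchor_down = exon_alns[j].qry_start
                    break
        locus = (qry_contig, locus_lo, locus_hi) if locus_lo is not None else None
        out.append(
            PairwiseGeneAlignment(
                gene_id=tx.gene_id,
                transcript_id=tx.transcript_id,
                query_species=query,
                exons=exon_alns,
                qry_locus=locus,
            )
        )
    return out


def _strip_species(src: str) -> str:
    return src.split(".", 1)[1] if "." in src else src


def _find_block(indexed, es: int, ee: int):
    from bisect import bisect_right

    starts = [b[0] for b in indexed]
    lo = max(0, bisect_right(starts, es) - 1)
    for bs, be, ref_row, qry_row in indexed[lo:lo + 4]:
        if bs < ee and es < be:
            ref_aln, qry_aln, qs, qe = _slice_block(ref_row, qry_row, es, ee)
            if ref_aln:
                return ref_row, qry_row, ref_aln, qry_aln, qs, qe
    return None


def _slice_block(ref_row, qry_row, es: int, ee: int):
    """Cut the columns of a block down to the reference interval [es, ee)."""
    cols_lo = cols_hi = None
    rpos = ref_row.start
    for i, c in enumerate(ref_row.text):
        if c != "-":
            if rpos == es:
                cols_lo = i
            if rpos == ee - 1:
                cols_hi = i + 1
            rpos += 1
    if cols_lo is None:
        cols_lo = 0
    if cols_hi is None:
        cols_hi = len(ref_row.text)
    ref_aln = ref_row.text[cols_lo:cols_hi]
    qry_aln = qry_row.text[cols_lo:cols_hi]
    q_before = sum(1 for c in qry_row.text[:cols_lo] if c != "-")
    q_inside = sum(1 for c in qry_aln if c != "-")
    qs = qry_row.start + q_before
    return ref_aln, qry_aln, qs, qs + q_inside


def run_directory(
    datadir: str | Path,
    outdir: str | Path,
    reference: str = "ref",
    config: Optional[RunConfig] = None,
    with_forward_genomics: bool = False,
) -> dict:
    """Run scan -> filters -> calls on a simulate-style directory.

    Expects genomes/<sp>.fa, annotation.gff3, alignments/<sp>.maf and
    tree.nwk (plus traits.tsv when the phylogenetic screen is enabled).
    Writes status and mutation tables, the %intact matrix, filter-trace
    counts, and a machine-readable run manifest.  Returns the manifest.
    """
    datadir, outdir = Path(datadir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()
    transcripts = read_annotation(datadir / "annotation.gff3")
    tree = read_tree(datadir / "tree.nwk")
    species = [sp for sp in tree.leaf_names() if sp != reference]

    results = []
    for sp in species:
        maf_path = datadir / "alignments" / f"{sp}.maf"
        if not maf_path.exists():
            continue
        assembly = read_fasta(datadir / "genomes" / f"{sp}.fa", name=sp)
        blocks = read_maf(maf_path, reference)
        gene_alns = gene_alignments_from_maf(
            blocks, transcripts, assembly, reference, sp
        )
        results.append(call_species(transcripts, gene_alns, assembly, sp))

    all_statuses = [st for res in results for st in res.statuses.values()]
    write_status_table(all_statuses, outdir / "status.tsv")
    write_mutation_report(
        (
            (st.gene_id, st.transcript_id, st.species, m)
            for st in all_statuses
            for m in st.mutations
        ),
        outdir / "mutations.tsv",
        outdir / "mutations.bed",
    )
    matrix = build_intact_matrix(results)
    matrix.to_csv(outdir / "intact_matrix.tsv", sep="\t")

    with open(outdir / "filter_trace.tsv", "w") as fh:
        fh.write("gene\tspecies\tstep\tn_before\tn_after\n")
        for res in results:
            for trace in res.traces.values():
                for step, nb, na in trace.steps:
                    fh.write(f"{trace.gene_id}\t{trace.species}\t{step}\t{nb}\t{na}\n")

    manifest = config.manifest()
    manifest["n_species"] = len(results)
    manifest["n_genes"] = int(matrix.shape[0]) if len(matrix) else 0
    manifest["step_counts"] = _aggregate_steps(results)
    manifest["n_loss_calls"] = sum(
        1 for st in all_statuses if st.classification == lc.LOSS_CANDIDATE
    )

    if with_forward_genomics and (datadir / "traits.tsv").exists():
        from .forward_genomics import screen
        from .io_formats import read_trait_table

        groups = read_trait_table(datadir / "traits.tsv", tree)
        table, selected = screen(matrix, tree, groups, p_threshold=config.pgls_p)
        table.to_csv(outdir / "pgls.tsv", sep="\t", index=False)
        manifest["n_selected"] = len(selected)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _aggregate_steps(results) -> dict[str, int]:
    agg: dict[str, int] = {}
    for res in results:
        for trace in res.traces.values():
            for step, _nb, na in trace.steps:
                agg[step] = agg.get(step, 0) + na
    return agg
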