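"""Sequential multi-source aggregation of gene annotations.

Two gene loci *overlap* when at least one exon of one shares >= 1 bp with an
exon of the other, on the same strand.  Sources are merged in priority order:
the first source is accepted wholesale; each later gene locus is accepted only
if none of its transcripts overlaps an already-accepted locus.  By default the
conflict test is restricted to the candidate's own biotype class, which keeps
genes hosted inside genes of another class (e.g. miRNAs in protein-coding
introns or exons) in the atlas; a strict all-vs-all mode is available for
sensitivity analysis.  Rejected loci are logged together with the accepted
genes they collided with, and single-collision rejections become
cross-references of the accepted gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from intervaltree import IntervalTree

from .models import AnnotationSource, GeneModel, TranscriptModel


def exons_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    """True iff some exon of ``a`` shares >= 1 bp with some exon of ``b``
    on the same chromosome and strand."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    if a.span.end < b.span.start or b.span.end < a.span.start:
        return False
    # merge-scan: both exon lists are sorted by start
    i = j = 0
    ea, eb = a.exons, b.exons
    while i < len(ea) and j < len(eb):
        if ea[i].end < eb[j].start:
            i += 1
        elif eb[j].end < ea[i].start:
            j += 1
        else:
            return True
    return False


def genes_exon_overlap(a: GeneModel, b: GeneModel) -> bool:
    return any(
        exons_overlap(ta, tb) for ta in a.transcripts for tb in b.transcripts
    )


class GeneIndex:
    """Exon-level interval index over gene models, keyed by (chrom, strand).

    Interval trees hold half-open intervals, so a 1-based inclusive exon
    [s, e] is stored as [s, e + 1); stabbing queries then return exactly the
    genes with >= 1 bp in common.
    """

    def __init__(self, genes: Iterable[GeneModel] = ()) -> None:
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            self.add(g)

    def add(self, gene: GeneModel) -> None:
        self._genes[gene.gene_id] = gene
        key = (gene.chrom, gene.strand)
        tree = self._trees.setdefault(key, IntervalTree())
        for exon in gene.exon_intervals():
            tree.addi(exon.start, exon.end + 1, gene.gene_id)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __len__(self) -> int:
        return len(self._genes)

    def genes(self) -> list[GeneModel]:
        return list(self._genes.values())

    def overlapping(self, gene: GeneModel, same_class_only: bool) -> list[str]:
        tree = self._trees.get((gene.chrom, gene.strand))
        if tree is None:
            return []
        hits: set[str] = set()
        for exon in gene.exon_intervals():
            for iv in tree.overlap(exon.start, exon.end + 1):
                hits.add(iv.data)
        if same_class_only:
            hits = {
                gid for gid in hits
                if self._genes[gid].biotype_class == gene.biotype_class
            }
        return sorted(hits)


def gene_conflicts(
    candidate: GeneModel,
    accepted: GeneIndex | Iterable[GeneModel],
    same_class_only: bool = True,
) -> list[str]:
    """Accepted gene ids whose transcripts exon-overlap the candidate.

    An empty list means the candidate is addable.  With ``same_class_only``
    the comparison is restricted to accepted genes of the candidate's class.
    """
    index = accepted if isinstance(accepted, GeneIndex) else GeneIndex(accepted)
    return index.overlapping(candidate, same_class_only)


@dataclass
class RejectionRecord:
    gene_id: str
    source: str
    conflicting_ids: list[str]


@dataclass
class MergedAtlas:
    """Result of a sequential merge: accepted genes plus provenance."""

    genes: list[GeneModel]
    order: list[str]
    rejections: list[RejectionRecord] = field(default_factory=list)
    renamed: dict[str, str] = field(default_factory=dict)

    @property
    def xref_table(self) -> dict[str, dict[str, str]]:
        return {g.gene_id: dict(g.xrefs) for g in self.genes}

    def genes_of_class(self, biotype_class: str) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype_class == biotype_class]

    def to_source(self, name: str = "atlas") -> AnnotationSource:
        return AnnotationSource(name=name, priority=1, genes=self.genes)


def merge_annotations(
    sources: list[AnnotationSource],
    same_class_only: bool = True,
) -> MergedAtlas:
    """Merge sources in priority order into a non-redundant atlas.

    The priority-1 source is included wholesale; each later gene is accepted
    iff it has no same-strand exon overlap with the growing catalog (within
    its biotype class unless ``same_class_only`` is False).  A rejected gene
    that collided with exactly one accepted gene contributes its native id as
    a cross-reference of that gene.  Gene-id collisions across sources are
    resolved by renaming to ``<id>__<source>``.
    """
    if len({s.name for s in sources}) != len(sources):
        raise ValueError("source names must be unique")
    ordered = sorted(sources, key=lambda s: s.priority)

    index = GeneIndex()
    accepted: list[GeneModel] = []
    rejections: list[RejectionRecord] = []
    renamed: dict[str, str] = {}

    for rank, src in enumerate(ordered):
        for gene in src.genes:
            conflicts = (
                index.overlapping(gene, same_class_only) if rank > 0 else []
            )
            if conflicts:
                rejections.append(
                    RejectionRecord(gene.gene_id, src.name, conflicts)
                )
                if len(conflicts) == 1:
                    # rejected purely for overlapping one accepted gene:
                    # record its native id as a cross-reference by overlap
                    winner = index._genes[conflicts[0]]
                    winner.xrefs.setdefault(src.name, gene.gene_id)
                continue
            native_id = gene.gene_id
            if gene.gene_id in index:
                new_id = f"{gene.gene_id}__{src.name}"
                renamed[gene.gene_id] = new_id
                gene = GeneModel(
                    gene_id=new_id,
                    raw_biotype=gene.raw_biotype,
                    biotype_class=gene.biotype_class,
                    transcripts=gene.transcripts,
                    xrefs=dict(gene.xrefs),
                )
            gene.xrefs.setdefault(src.name, native_id)
            index.add(gene)
            accepted.append(gene)

    return MergedAtlas(
        genes=accepted,
        order=[s.name for s in ordered],
        rejections=rejections,
        renamed=renamed,
    )


def overlap_rate(
    a: AnnotationSource, b: AnnotationSource, biotype_class: str
) -> float:
    """Fraction of class genes in ``a`` exon-overlapping >= 1 class gene in
    ``b`` (asymmetric)."""
    genes_a = a.genes_of_class(biotype_class)
    if not genes_a:
        return float("nan")
    index = GeneIndex(b.genes_of_class(biotype_class))
    hit = sum(1 for g in genes_a if index.overlapping(g, same_class_only=True))
    return hit / len(genes_a)
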