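"""Shared builders for compact gene models and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from geneatlas.models import (
    AnnotationSource,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)


def make_transcript(
    exons: list[tuple[int, int]],
    chrom: str = "chr1",
    strand: str = "+",
    transcript_id: str = "t1",
    gene_id: str = "g1",
    source: str = "S1",
) -> TranscriptModel:
    ivs = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    return TranscriptModel(transcript_id, gene_id, source, ivs)


def make_gene(
    exons: list[tuple[int, int]],
    chrom: str = "chr1",
    strand: str = "+",
    gene_id: str = "g1",
    biotype: str = "protein_coding",
    biotype_class: str = "pcg",
    source: str = "S1",
    transcripts: list[TranscriptModel] | None = None,
) -> GeneModel:
    if transcripts is None:
        transcripts = [
            make_transcript(exons, chrom, strand, f"{gene_id}.t1", gene_id, source)
        ]
    return GeneModel(gene_id, biotype, biotype_class, transcripts,
                     {source: gene_id})


def brute_force_conflicts(candidate, accepted, same_class_only=True):
    """O(n^2) all-vs-all oracle for gene_conflicts."""
    out = []
    for g in accepted:
        if same_class_only and g.biotype_class != candidate.biotype_class:
            continue
        hit = any(
            ta.chrom == tb.chrom
            and ta.strand == tb.strand
            and any(
                ea.start <= eb.end and eb.start <= ea.end
                for ea in ta.exons
                for eb in tb.exons
            )
            for ta in candidate.transcripts
            for tb in g.transcripts
        )
        if hit:
            out.append(g.gene_id)
    return sorted(out)


def brute_force_merge(sources, same_class_only=True):
    """Sequential merge oracle: exhaustive pairwise comparison in priority
    order, independent of the interval-index implementation."""
    accepted = []
    for rank, src in enumerate(sorted(sources, key=lambda s: s.priority)):
        for gene in src.genes:
            if rank == 0 or not brute_force_conflicts(
                gene, accepted, same_class_only
            ):
                accepted.append(gene)
    return [g.gene_id for g in accepted]


def random_source(
    rng: np.random.Generator,
    name: str,
    n_genes: int,
    n_chroms: int = 2,
    region: int = 200_000,
    priority: int = 1,
) -> AnnotationSource:
    """Dense random gene models with plenty of accidental overlap."""
    genes = []
    for i in range(n_genes):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(1, region))
        exons = []
        pos = start
        for _ in range(int(rng.integers(1, 4))):
            length = int(rng.integers(50, 500))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(50, 2_000))
        cls = ["pcg", "lncRNA", "miRNA"][int(rng.integers(0, 3))]
        genes.append(
            make_gene(exons, chrom, strand, f"{name}_g{i:04d}",
                      biotype_class=cls, source=name)
        )
    return AnnotationSource(name=name, priority=priority, genes=genes)


def dedupe_source(src: AnnotationSource) -> AnnotationSource:
    """Drop genes that overlap an earlier same-class gene of the same source,
    mimicking an internally consistent annotation database."""
    kept = []
    for gene in src.genes:
        if not brute_force_conflicts(gene, kept, same_class_only=True):
            kept.append(gene)
    return AnnotationSource(src.name, src.priority, kept)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240319)
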