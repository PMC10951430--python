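"""Hierarchical annotation records shared by every stage of the atlas pipeline.

All coordinates are 1-based inclusive (GTF convention); BED-style inputs are
converted on read.  A gene locus is a set of transcript models on one strand of
one chromosome; the gene *span* is the hull of all exons.  Chromosome names are
opaque strings, so unplaced scaffolds are handled like any chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field


VALID_STRANDS = ("+", "-")

#: biotype classes used throughout the pipeline
PCG = "pcg"
LNCRNA = "lncRNA"
MIRNA = "miRNA"
OTHER_SMALL_RNA = "other_small_rna"
OTHER = "other"
BIOTYPE_CLASSES = (PCG, LNCRNA, MIRNA, OTHER_SMALL_RNA, OTHER)


@dataclass(frozen=True)
class GenomicInterval:
    """A closed interval [start, end] on one strand of a chromosome.

    ``strand`` is '+' or '-'; '.' is tolerated for strand-less features such
    as CAGE peaks.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in VALID_STRANDS and self.strand != ".":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval", *, same_strand: bool = False) -> bool:
        """True iff the intervals share >= 1 bp ([1,100] and [100,200] do)."""
        if self.chrom != other.chrom:
            return False
        if same_strand and self.strand != other.strand:
            return False
        return self.start <= other.end and other.start <= self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """A transcript model: an ordered list of non-overlapping exons."""

    transcript_id: str
    gene_id: str
    source: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        chrom = self.exons[0].chrom
        strand = self.exons[0].strand
        for e in self.exons:
            if e.chrom != chrom or e.strand != strand:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon on {e.chrom}{e.strand} "
                    f"differs from transcript {chrom}{strand}"
                )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def tss(self) -> int:
        """Transcription start site: 5' end of the transcript model."""
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end

    @property
    def monoexonic(self) -> bool:
        return len(self.exons) == 1


@dataclass
class GeneModel:
    """A gene locus with >= 1 transcript model, all on one strand."""

    gene_id: str
    raw_biotype: str
    biotype_class: str
    transcripts: list[TranscriptModel]
    xrefs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id}: no transcripts")
        if self.biotype_class not in BIOTYPE_CLASSES:
            raise ValueError(
                f"gene {self.gene_id}: unknown biotype class {self.biotype_class!r}"
            )
        chrom, strand = self.transcripts[0].chrom, self.transcripts[0].strand
        for t in self.transcripts:
            if t.chrom != chrom or t.strand != strand:
                raise ValueError(
                    f"gene {self.gene_id}: transcript {t.transcript_id} on "
                    f"{t.chrom}{t.strand}, expected {chrom}{strand}"
                )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.exons[0].start for t in self.transcripts)
        end = max(t.exons[-1].end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def monoexonic(self) -> bool:
        return all(t.monoexonic for t in self.transcripts)

    @property
    def source(self) -> str:
        return self.transcripts[0].source

    def exon_intervals(self) -> list[GenomicInterval]:
        return [e for t in self.transcripts for e in t.exons]


@dataclass
class AnnotationSource:
    """One input annotation: a named, priority-ranked set of gene models."""

    name: str
    priority: int
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(
                    f"source {self.name}: duplicate gene_id {g.gene_id}"
                )
            seen.add(g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def genes_of_class(self, biotype_class: str) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype_class == biotype_class]
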