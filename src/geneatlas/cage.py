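"""CAGE peak sets and TSS support.

CAGE peaks mark experimentally observed transcription start sites.  A
transcript TSS is *supported* when it falls within a peak extended by a slop
of +/- 30 bp (default).  Peak strand is ignored for matching.  BED input uses
0-based half-open coordinates and is converted to the package-wide 1-based
inclusive convention on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .models import AnnotationSource, GenomicInterval


@dataclass
class CagePeakSet:
    peaks: list[GenomicInterval]
    slop: int = 30

    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.slop < 0:
            raise ValueError("slop must be >= 0")
        for p in self.peaks:
            lo = max(1, p.start - self.slop)
            hi = p.end + self.slop
            self._trees.setdefault(p.chrom, IntervalTree()).addi(lo, hi + 1)

    def supports(self, chrom: str, tss: int) -> bool:
        """True iff ``tss`` lies within [peak.start - slop, peak.end + slop]."""
        tree = self._trees.get(chrom)
        return bool(tree and tree.overlaps_point(tss))


def read_bed(path: str, slop: int = 30) -> CagePeakSet:
    """Read BED3+ peaks (0-based half-open) into a :class:`CagePeakSet`."""
    peaks: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            peaks.append(GenomicInterval(chrom, start0 + 1, end0, strand))
    return CagePeakSet(peaks=peaks, slop=slop)


def write_bed(peaks: CagePeakSet, path: str) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks.peaks):
            fh.write(
                f"{p.chrom}\t{p.start - 1}\t{p.end}\tpeak{i}\t0\t{p.strand}\n"
            )


def cage_support(source: AnnotationSource, peaks: CagePeakSet) -> dict[str, float]:
    """Per-biotype-class fraction of transcripts with a CAGE-supported TSS."""
    supported: dict[str, int] = {}
    total: dict[str, int] = {}
    for gene in source.genes:
        cls = gene.biotype_class
        for tx in gene.transcripts:
            total[cls] = total.get(cls, 0) + 1
            if peaks.supports(tx.chrom, tx.tss):
                supported[cls] = supported.get(cls, 0) + 1
    return {cls: supported.get(cls, 0) / n for cls, n in total.items()}
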