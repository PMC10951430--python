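"""Positional classification of genes relative to their closest partner gene.

A focal gene (typically a lncRNA or miRNA) is classified against
protein-coding genes within a window:

* genic_exonic  — >= 1 bp of focal exon overlaps a partner exon (any strand);
* genic_intronic — the spans intersect but no exons do;
* intergenic    — disjoint spans, annotated with the gap in bp and an
  orientation: on equal strands, ``same_strand_up`` when the focal gene lies
  on the 5' side of the partner's transcription direction and
  ``same_strand_down`` on the 3' side; on opposite strands, ``divergent``
  when the two 5' ends face each other across the gap (head-to-head) and
  ``convergent`` when the two 3' ends do (tail-to-tail).

Genic calls carry a sense/antisense direction instead of an orientation.
The gene-level call against multiple candidates takes the best partner under
the precedence genic_exonic > genic_intronic > intergenic, then smallest
distance, then lexicographic partner id.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .models import GeneModel, TranscriptModel
from .models import LNCRNA, MIRNA, PCG

GENIC_EXONIC = "genic_exonic"
GENIC_INTRONIC = "genic_intronic"
INTERGENIC = "intergenic"

SENSE = "sense"
ANTISENSE = "antisense"
SS_UP = "same_strand_up"
SS_DOWN = "same_strand_down"
DIVERGENT = "divergent"
CONVERGENT = "convergent"

_RELATION_RANK = {GENIC_EXONIC: 0, GENIC_INTRONIC: 1, INTERGENIC: 2}


@dataclass
class PairClassification:
    focal_id: str
    partner_id: str
    relation: str
    direction: str | None  # sense/antisense, genic only
    orientation: str | None  # SS up/down, divergent, convergent; intergenic
    distance: int
    window: int

    @property
    def configuration(self) -> str:
        return self.direction if self.relation != INTERGENIC else self.orientation

    def sort_key(self) -> tuple:
        return (_RELATION_RANK[self.relation], self.distance, self.partner_id)


def _spans_classify(
    focal_span, focal_strand: str, pcg_span, pcg_strand: str
) -> tuple[str, int]:
    """(orientation, distance) for two disjoint spans; genic if they touch."""
    if focal_span.start <= pcg_span.end and pcg_span.start <= focal_span.end:
        return ("genic", 0)
    if focal_span.end < pcg_span.start:
        distance = pcg_span.start - focal_span.end
        focal_left = True
    else:
        distance = focal_span.start - pcg_span.end
        focal_left = False
    if focal_strand == pcg_strand:
        # position relative to the partner's transcription direction
        upstream = focal_left if pcg_strand == "+" else not focal_left
        return (SS_UP if upstream else SS_DOWN, distance)
    # opposite strands: which ends face across the gap?
    left_strand = focal_strand if focal_left else pcg_strand
    # facing ends are 5' ends iff the left gene points away from the gap
    return (DIVERGENT if left_strand == "-" else CONVERGENT, distance)


def classify_transcript_pair(
    focal: TranscriptModel, pcg: TranscriptModel, window: int = 100_000
) -> PairClassification | None:
    """Classify one focal transcript against one partner transcript.

    Returns None for different chromosomes or an intergenic gap beyond the
    window.
    """
    if focal.chrom != pcg.chrom:
        return None
    orientation, distance = _spans_classify(
        focal.span, focal.strand, pcg.span, pcg.strand
    )
    if orientation == "genic":
        exonic = any(
            fe.start <= pe.end and pe.start <= fe.end
            for fe in focal.exons
            for pe in pcg.exons
        )
        relation = GENIC_EXONIC if exonic else GENIC_INTRONIC
        direction = SENSE if focal.strand == pcg.strand else ANTISENSE
        return PairClassification(
            focal.transcript_id, pcg.transcript_id, relation, direction, None,
            0, window,
        )
    if distance > window:
        return None
    return PairClassification(
        focal.transcript_id, pcg.transcript_id, INTERGENIC, None, orientation,
        distance, window,
    )


def classify_gene_pair(
    focal: GeneModel, partner: GeneModel, window: int = 100_000
) -> PairClassification | None:
    """Gene-level classification of a focal gene against one partner gene.

    Exonic status is decided over all transcript exon pairs; distance and
    orientation come from the gene spans.
    """
    if focal.chrom != partner.chrom or focal.gene_id == partner.gene_id:
        return None
    orientation, distance = _spans_classify(
        focal.span, focal.strand, partner.span, partner.strand
    )
    if orientation == "genic":
        exonic = any(
            fe.start <= pe.end and pe.start <= fe.end
            for fe in focal.exon_intervals()
            for pe in partner.exon_intervals()
        )
        relation = GENIC_EXONIC if exonic else GENIC_INTRONIC
        direction = SENSE if focal.strand == partner.strand else ANTISENSE
        return PairClassification(
            focal.gene_id, partner.gene_id, relation, direction, None, 0, window
        )
    if distance > window:
        return None
    return PairClassification(
        focal.gene_id, partner.gene_id, INTERGENIC, None, orientation,
        distance, window,
    )


class _SpanIndex:
    """Interval index over gene spans for windowed candidate lookup."""

    def __init__(self, genes: list[GeneModel]) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._genes = {g.gene_id: g for g in genes}
        for g in genes:
            span = g.span
            self._trees.setdefault(g.chrom, IntervalTree()).addi(
                span.start, span.end + 1, g.gene_id
            )

    def near(self, gene: GeneModel, window: int) -> list[GeneModel]:
        tree = self._trees.get(gene.chrom)
        if tree is None:
            return []
        span = gene.span
        lo = max(1, span.start - window)
        hi = span.end + window + 1
        return [self._genes[iv.data] for iv in tree.overlap(lo, hi)]


def classify_gene(
    focal: GeneModel,
    partners: list[GeneModel] | _SpanIndex,
    window: int = 100_000,
) -> PairClassification | None:
    """Best partner within the window, or None when there is none."""
    index = partners if isinstance(partners, _SpanIndex) else _SpanIndex(partners)
    best: PairClassification | None = None
    for partner in index.near(focal, window):
        pc = classify_gene_pair(focal, partner, window)
        if pc is not None and (best is None or pc.sort_key() < best.sort_key()):
            best = pc
    return best


def classify_genes(
    focal_genes: list[GeneModel],
    partner_genes: list[GeneModel],
    window: int = 100_000,
) -> pd.DataFrame:
    """Classify every focal gene against its best partner-class gene."""
    index = _SpanIndex(partner_genes)
    rows = []
    for gene in focal_genes:
        pc = classify_gene(gene, index, window)
        if pc is None:
            rows.append((gene.gene_id, None, "unclassified", None, None, None))
        else:
            rows.append(
                (gene.gene_id, pc.partner_id, pc.relation, pc.configuration,
                 pc.distance, window)
            )
    return pd.DataFrame(
        rows,
        columns=["focal_id", "partner_id", "relation", "configuration",
                 "distance", "window"],
    )


def pair_for_coexpression(
    atlas,
    focal_class: str = LNCRNA,
    partner_class: str = PCG,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Pair each focal-class gene with its single closest partner-class gene
    within the window (default 1 Mb), using the classification precedence."""
    focal = atlas.genes_of_class(focal_class)
    partners = atlas.genes_of_class(partner_class)
    out = classify_genes(focal, partners, window)
    out.insert(1, "pair_type", f"{focal_class}:{partner_class}")
    return out[out["partner_id"].notna()].reset_index(drop=True)


def mirna_hosts(atlas) -> pd.DataFrame:
    """Tabulate miRNA genes hosted inside a lncRNA or protein-coding gene.

    A host contains the miRNA span within its own span; the relation is
    ``exonic`` when a miRNA exon overlaps a host exon and ``intronic``
    otherwise.  When hosts of both classes contain a miRNA, the smallest
    enclosing span wins; hosts may appear on several rows.
    """
    hosts = [
        g for g in atlas.genes if g.biotype_class in (LNCRNA, PCG)
    ]
    index = _SpanIndex(hosts)
    rows = []
    for mir in atlas.genes_of_class(MIRNA):
        mir_span = mir.span
        enclosing = [
            h for h in index.near(mir, 0)
            if h.span.start <= mir_span.start and mir_span.end <= h.span.end
        ]
        if not enclosing:
            continue
        host = min(
            enclosing, key=lambda h: (h.span.length, h.gene_id)
        )
        exonic = any(
            me.start <= he.end and he.start <= me.end
            for me in mir.exon_intervals()
            for he in host.exon_intervals()
        )
        rows.append(
            (mir.gene_id, host.gene_id, host.biotype_class,
             "exonic" if exonic else "intronic")
        )
    return pd.DataFrame(
        rows, columns=["mirna_id", "host_gene_id", "host_class", "relation"]
    )
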