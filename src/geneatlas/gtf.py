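"""GTF reading and writing.

Records are parsed line-by-line with gffutils so both Ensembl- and
RefSeq-style attribute dialects are accepted (``gene_biotype`` or
``gene_type``).  Reading builds the gene -> transcript -> exon hierarchy;
transcripts that carry no exon records are synthesized as single-exon models
from their own span.  Writing emits gene/transcript/exon records sorted by
chromosome then start, and re-reading a written file reproduces the in-memory
models exactly.
"""

from __future__ import annotations

from collections import OrderedDict

from gffutils.feature import feature_from_line

from .biotype import normalize_biotype
from .models import AnnotationSource, GeneModel, GenomicInterval, TranscriptModel


class GtfParseError(ValueError):
    """Raised for malformed GTF input, carrying the offending line number."""


_GENE_TYPES = {"gene"}
_TRANSCRIPT_TYPES = {"transcript", "mRNA", "lnc_RNA", "ncRNA", "miRNA_transcript"}
_EXON_TYPES = {"exon"}


def _attr(feature, *keys: str) -> str | None:
    for key in keys:
        if key in feature.attributes:
            vals = feature.attributes[key]
            if vals:
                return vals[0]
    return None


def _attrs_all(feature, key: str) -> list[str]:
    return list(feature.attributes[key]) if key in feature.attributes else []


def read_gtf(
    path: str,
    source_name: str,
    priority: int = 1,
    biotype_table: dict[str, str] | None = None,
) -> AnnotationSource:
    """Read a GTF file into an :class:`AnnotationSource`.

    Every exon is attached to its transcript via ``transcript_id``; gene
    records are optional (genes seen only through transcript/exon lines are
    created on the fly).  Unknown biotypes normalize to ``other``.
    """
    gene_meta: dict[str, dict] = {}
    tx_meta: "OrderedDict[str, dict]" = OrderedDict()
    tx_exons: dict[str, list[GenomicInterval]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # noqa: BLE001 - rewrap with location
                raise GtfParseError(f"{path}:{lineno}: {exc}") from exc
            ftype = feat.featuretype
            gene_id = _attr(feat, "gene_id")
            if gene_id is None:
                raise GtfParseError(f"{path}:{lineno}: record lacks gene_id")

            if ftype in _GENE_TYPES:
                meta = gene_meta.setdefault(gene_id, {"biotype": None, "xrefs": {}})
                bt = _attr(feat, "gene_biotype", "gene_type")
                if bt is not None:
                    meta["biotype"] = bt
                for item in _attrs_all(feat, "xref"):
                    if "|" in item:
                        src, native = item.split("|", 1)
                        meta["xrefs"][src] = native
                continue

            transcript_id = _attr(feat, "transcript_id")
            if transcript_id is None:
                raise GtfParseError(
                    f"{path}:{lineno}: {ftype} record lacks transcript_id"
                )
            if ftype in _EXON_TYPES:
                iv = GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand)
                tx_exons.setdefault(transcript_id, []).append(iv)
                tx_meta.setdefault(
                    transcript_id,
                    {"gene_id": gene_id, "chrom": feat.seqid, "strand": feat.strand,
                     "start": feat.start, "end": feat.end, "biotype": None},
                )
            else:  # transcript-level record (any non-gene, non-exon type)
                meta = tx_meta.setdefault(
                    transcript_id,
                    {"gene_id": gene_id, "chrom": feat.seqid, "strand": feat.strand,
                     "start": feat.start, "end": feat.end, "biotype": None},
                )
                meta.update(
                    chrom=feat.seqid, strand=feat.strand,
                    start=feat.start, end=feat.end,
                )
                bt = _attr(feat, "gene_biotype", "gene_type")
                if bt is not None:
                    meta["biotype"] = bt
            g = gene_meta.setdefault(gene_id, {"biotype": None, "xrefs": {}})
            bt = _attr(feat, "gene_biotype", "gene_type")
            if bt is not None and g["biotype"] is None:
                g["biotype"] = bt

    genes_tx: dict[str, list[TranscriptModel]] = {}
    for transcript_id, meta in tx_meta.items():
        exons = tx_exons.get(transcript_id)
        if not exons:
            # transcript without exon records: synthesize one from its span
            exons = [GenomicInterval(meta["chrom"], meta["start"], meta["end"],
                                     meta["strand"])]
        for e in exons:
            if e.chrom != meta["chrom"] or e.strand != meta["strand"]:
                raise GtfParseError(
                    f"{path}: exon of transcript {transcript_id} on "
                    f"{e.chrom}{e.strand} conflicts with its transcript on "
                    f"{meta['chrom']}{meta['strand']}"
                )
        try:
            tx = TranscriptModel(transcript_id, meta["gene_id"], source_name, exons)
        except ValueError as exc:
            raise GtfParseError(f"{path}: {exc}") from exc
        genes_tx.setdefault(meta["gene_id"], []).append(tx)

    genes: list[GeneModel] = []
    for gene_id, txs in genes_tx.items():
        meta = gene_meta.get(gene_id, {"biotype": None, "xrefs": {}})
        raw = meta["biotype"]
        if raw is None:
            raw = next(
                (tx_meta[t.transcript_id]["biotype"] for t in txs
                 if tx_meta[t.transcript_id]["biotype"]),
                None,
            )
        raw = raw if raw is not None else "unknown"
        xrefs = dict(meta["xrefs"])
        xrefs.setdefault(source_name, gene_id)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                raw_biotype=raw,
                biotype_class=normalize_biotype(raw, biotype_table),
                transcripts=sorted(txs, key=lambda t: t.transcript_id),
                xrefs=xrefs,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
    return AnnotationSource(name=source_name, priority=priority, genes=genes)


def _fmt_attrs(pairs: list[tuple[str, str]]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs)


def write_gtf(source: AnnotationSource, path: str) -> None:
    """Write an :class:`AnnotationSource` as GTF, sorted by chrom then start."""
    lines: list[str] = [f"## geneatlas source={source.name}"]
    for gene in sorted(source.genes, key=lambda g: (g.chrom, g.span.start, g.gene_id)):
        span = gene.span
        gene_attrs: list[tuple[str, str]] = [
            ("gene_id", gene.gene_id),
            ("gene_biotype", gene.raw_biotype),
            ("gene_source", gene.source),
        ]
        for src, native in sorted(gene.xrefs.items()):
            gene_attrs.append(("xref", f"{src}|{native}"))
        lines.append(
            "\t".join([
                gene.chrom, source.name, "gene", str(span.start), str(span.end),
                ".", gene.strand, ".", _fmt_attrs(gene_attrs),
            ])
        )
        for tx in gene.transcripts:
            tspan = tx.span
            tx_attrs = [
                ("gene_id", gene.gene_id),
                ("transcript_id", tx.transcript_id),
                ("gene_biotype", gene.raw_biotype),
            ]
            lines.append(
                "\t".join([
                    gene.chrom, source.name, "transcript", str(tspan.start),
                    str(tspan.end), ".", gene.strand, ".", _fmt_attrs(tx_attrs),
                ])
            )
            for i, exon in enumerate(tx.exons, start=1):
                exon_attrs = tx_attrs + [("exon_number", str(i))]
                lines.append(
                    "\t".join([
                        gene.chrom, source.name, "exon", str(exon.start),
                        str(exon.end), ".", gene.strand, ".",
                        _fmt_attrs(exon_attrs),
                    ])
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
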