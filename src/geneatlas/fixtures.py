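"""Seeded synthetic fixtures: multi-source annotations and expression data.

The generator emulates the inputs of a multi-source gene atlas at desk scale:

* ``generate_annotations`` lays out non-overlapping gene loci along synthetic
  chromosomes for a priority-1 source, then builds later sources as a mix of
  *overlap copies* (jittered duplicates of already-placed genes, guaranteed
  to share exonic bases on the same strand) and *novel* loci, plus miRNA
  genes planted inside protein-coding introns and inside exons of lncRNAs or
  protein-coding genes.  A truth table records, for every generated gene,
  its role, its overlap target and its host relation, so merge behaviour can
  be checked exactly.
* ``generate_expression`` draws a raw count matrix for a sample sheet of
  tissues x projects x samples.  Planted archetypes cover uniform
  (ubiquitous) genes, mono- and poly-tissue spikes, sex-biased genes, and
  co-regulated pairs driven by a shared latent tissue factor.  A block of
  high-expression "bulk" genes absorbs the remaining transcriptional mass so
  planted values are true TPMs; counts are negative-binomial with
  log-normally varying library sizes, giving the TMM step real work to do.

Everything is driven by ``FixtureSpec.seed``: one seed, byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import SampleTable
from .models import (
    AnnotationSource,
    GeneModel,
    GenomicInterval,
    LNCRNA,
    MIRNA,
    PCG,
    TranscriptModel,
)

ARCH_UNIFORM = "uniform"
ARCH_MONO = "mono_spike"
ARCH_POLY = "poly_spike"
ARCH_SEX = "sex_biased"
ARCH_COREG = "co_regulated"
ARCH_BULK = "bulk_background"


@dataclass
class FixtureSpec:
    """Conditions under which fixtures are generated.

    Annotation side: ``n_sources`` sources with ``pcg_per_source`` +
    ``lnc_per_source`` genes each; a fraction ``overlap_fraction`` of each
    later source duplicates (with coordinate jitter) genes already placed by
    higher-priority sources; ``n_mirnas`` miRNA genes are planted inside
    hosts from the priority-1 source.

    Expression side: ``n_tissues`` tissues, each covered by
    ``n_projects_per_tissue`` projects of ``samples_per_project`` samples
    with alternating sexes.  Library sizes are log-normal around
    ``mean_library_size``; counts are negative binomial with dispersion
    ``dispersion``.  Archetype fractions partition the (non-bulk) genes.
    """

    seed: int = 0
    # annotation structure
    n_chroms: int = 2
    n_sources: int = 2
    pcg_per_source: int = 40
    lnc_per_source: int = 40
    overlap_fraction: float = 0.3
    n_mirnas: int = 10
    chrom_length: int | None = 50_000_000
    # expression design
    n_tissues: int = 47
    n_projects_per_tissue: int = 1
    samples_per_project: int = 4
    mean_library_size: float = 3e7
    library_size_log_sd: float = 0.3
    dispersion: float = 0.1
    n_bulk_genes: int = 20
    # archetype mix and parameters
    frac_mono_ts: float = 0.2
    frac_poly_ts: float = 0.1
    frac_sex_biased: float = 0.05
    frac_coregulated: float = 0.2
    background_tpm: float = 0.1
    spike_fold: float = 100.0
    poly_tissues: int = 3
    sex_log2fc: float = 2.0
    latent_sd: float = 1.0
    latent_strength: float = 1.0
    residual_sd: float = 0.2

    def source_names(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_sources)]

    def tissue_names(self) -> list[str]:
        return [f"tissue{i + 1:02d}" for i in range(self.n_tissues)]


# ---------------------------------------------------------------------------
# annotation generation
# ---------------------------------------------------------------------------

_MIN_GAP = 500
_MAX_GAP = 5_000


def _make_gene(
    rng: np.random.Generator,
    gene_id: str,
    source: str,
    chrom: str,
    start: int,
    strand: str,
    biotype_class: str,
) -> GeneModel:
    if biotype_class == PCG:
        n_exons = int(rng.integers(2, 5))
        raw = "protein_coding"
    elif biotype_class == LNCRNA:
        n_exons = 1 if rng.random() < 0.6 else 2
        raw = "lncRNA"
    else:
        n_exons = 1
        raw = "miRNA"
    exons = []
    pos = start
    for _ in range(n_exons):
        length = int(rng.integers(150, 400))
        exons.append(GenomicInterval(chrom, pos, pos + length - 1, strand))
        pos += length + int(rng.integers(300, 2_000))
    tx = TranscriptModel(f"{gene_id}.t1", gene_id, source, exons)
    return GeneModel(gene_id, raw, biotype_class, [tx], {source: gene_id})


def _jittered_copy(
    rng: np.random.Generator, target: GeneModel, gene_id: str, source: str
) -> GeneModel:
    """A same-strand duplicate whose exons are jittered by < 50 bp, so it
    still shares exonic bases with the target but with nothing else nearby."""
    exons = []
    for e in target.exon_intervals():
        ds, de = int(rng.integers(-40, 41)), int(rng.integers(-40, 41))
        start, end = e.start + ds, e.end + de
        if end < start:
            start, end = end, start
        exons.append(GenomicInterval(e.chrom, max(1, start), end, e.strand))
    tx = TranscriptModel(f"{gene_id}.t1", gene_id, source, exons)
    return GeneModel(
        gene_id, target.raw_biotype, target.biotype_class, [tx],
        {source: gene_id},
    )


def _plant_mirna(
    rng: np.random.Generator, host: GeneModel, gene_id: str, source: str,
    relation: str,
) -> GeneModel | None:
    """A 70-90 bp single-exon miRNA inside a host intron or exon, same strand."""
    length = int(rng.integers(70, 91))
    tx_host = host.transcripts[0]
    if relation == "intronic":
        introns = [
            (a.end + 1, b.start - 1)
            for a, b in zip(tx_host.exons, tx_host.exons[1:])
        ]
        introns = [iv for iv in introns if iv[1] - iv[0] + 1 >= length + 20]
        if not introns:
            return None
        lo, hi = introns[int(rng.integers(len(introns)))]
    else:
        exons = [e for e in tx_host.exons if e.length >= length + 20]
        if not exons:
            return None
        e = exons[int(rng.integers(len(exons)))]
        lo, hi = e.start, e.end
    start = int(rng.integers(lo, hi - length + 2))
    iv = GenomicInterval(host.chrom, start, start + length - 1, host.strand)
    tx = TranscriptModel(f"{gene_id}.t1", gene_id, source, [iv])
    return GeneModel(gene_id, "miRNA", MIRNA, [tx], {source: gene_id})


def generate_annotations(
    spec: FixtureSpec,
) -> tuple[list[AnnotationSource], pd.DataFrame]:
    """Generate the multi-source annotation fixture and its truth table.

    The truth table has one row per generated gene: gene_id, source,
    biotype_class, role (base / novel / overlap_copy / mirna), the overlap
    target for copies, the host gene and relation for miRNAs, and
    ``expected_accepted`` — whether a class-restricted priority merge keeps
    the gene.
    """
    rng = np.random.default_rng(spec.seed)
    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    cursors = {c: 1_000 for c in chroms}
    truth_rows: list[dict] = []
    sources: list[AnnotationSource] = []
    # genes eligible as overlap targets / hosts: guaranteed accepted
    clean: dict[str, list[GeneModel]] = {PCG: [], LNCRNA: []}

    def _advance(chrom: str, gene: GeneModel) -> None:
        cursors[chrom] = gene.span.end + int(rng.integers(_MIN_GAP, _MAX_GAP))
        if spec.chrom_length is not None and cursors[chrom] > spec.chrom_length:
            raise ValueError(
                f"infeasible packing: {chrom} exceeds {spec.chrom_length} bp"
            )

    for si, name in enumerate(spec.source_names()):
        genes: list[GeneModel] = []
        classes = [PCG] * spec.pcg_per_source + [LNCRNA] * spec.lnc_per_source
        rng.shuffle(classes)
        n_overlap = {
            PCG: int(round(spec.overlap_fraction * spec.pcg_per_source)),
            LNCRNA: int(round(spec.overlap_fraction * spec.lnc_per_source)),
        }
        made_overlap = {PCG: 0, LNCRNA: 0}
        for gi, cls in enumerate(classes):
            tag = "PCG" if cls == PCG else "LNC"
            gene_id = f"{name}_{tag}{gi:04d}"
            want_overlap = (
                si > 0
                and made_overlap[cls] < n_overlap[cls]
                and clean[cls]
            )
            if want_overlap:
                target = clean[cls][int(rng.integers(len(clean[cls])))]
                gene = _jittered_copy(rng, target, gene_id, name)
                made_overlap[cls] += 1
                truth_rows.append(dict(
                    gene_id=gene_id, source=name, biotype_class=cls,
                    role="overlap_copy", overlap_target=target.gene_id,
                    host_gene_id=None, host_relation=None,
                    expected_accepted=False,
                ))
            else:
                chrom = chroms[int(rng.integers(len(chroms)))]
                strand = "+" if rng.random() < 0.5 else "-"
                gene = _make_gene(
                    rng, gene_id, name, chrom, cursors[chrom], strand, cls
                )
                _advance(chrom, gene)
                clean[cls].append(gene)
                truth_rows.append(dict(
                    gene_id=gene_id, source=name, biotype_class=cls,
                    role="base" if si == 0 else "novel", overlap_target=None,
                    host_gene_id=None, host_relation=None,
                    expected_accepted=True,
                ))
            genes.append(gene)

        if si == min(1, spec.n_sources - 1):
            # miRNAs are planted by the second source (or the only one),
            # inside hosts from the priority-1 source
            pcg_hosts = [g for g in clean[PCG] if g.source == spec.source_names()[0]]
            lnc_hosts = [g for g in clean[LNCRNA] if g.source == spec.source_names()[0]]
            for mi in range(spec.n_mirnas):
                gene_id = f"{name}_MIR{mi:04d}"
                r = rng.random()
                if r < 0.5 and pcg_hosts:
                    host_pool, relation = pcg_hosts, "intronic"
                elif r < 0.75 and pcg_hosts:
                    host_pool, relation = pcg_hosts, "exonic"
                else:
                    host_pool, relation = lnc_hosts, "exonic"
                mir = None
                for _ in range(10):  # hosts may lack a big-enough slot
                    host = host_pool[int(rng.integers(len(host_pool)))]
                    mir = _plant_mirna(rng, host, gene_id, name, relation)
                    if mir is not None:
                        break
                if mir is None:
                    continue
                genes.append(mir)
                truth_rows.append(dict(
                    gene_id=gene_id, source=name, biotype_class=MIRNA,
                    role="mirna", overlap_target=None,
                    host_gene_id=host.gene_id, host_relation=relation,
                    expected_accepted=True,
                ))
        sources.append(AnnotationSource(name=name, priority=si + 1, genes=genes))

    truth = pd.DataFrame(truth_rows)
    return sources, truth


# ---------------------------------------------------------------------------
# expression generation
# ---------------------------------------------------------------------------


@dataclass
class ExpressionFixture:
    counts: pd.DataFrame
    lengths: pd.Series
    samples: SampleTable
    truth: pd.DataFrame
    tissue_tpm: pd.DataFrame  # planted per-tissue TPM (female baseline)

    def write(self, prefix: str) -> None:
        self.counts.to_csv(f"{prefix}_counts.tsv", sep="\t")
        self.lengths.rename("length").to_csv(f"{prefix}_lengths.tsv", sep="\t")
        self.samples.write(f"{prefix}_samples.tsv")
        self.truth.to_csv(f"{prefix}_truth.tsv", sep="\t", index=False)


def _sample_sheet(spec: FixtureSpec) -> SampleTable:
    rows = []
    for t in spec.tissue_names():
        for p in range(spec.n_projects_per_tissue):
            project = f"P_{t}_{p + 1}"
            for s in range(spec.samples_per_project):
                rows.append(dict(
                    sample_id=f"{project}_s{s + 1}",
                    tissue=t,
                    project=project,
                    sex="M" if s % 2 == 0 else "F",
                ))
    return SampleTable(pd.DataFrame(rows))


def generate_expression(
    spec: FixtureSpec,
    genes: list[GeneModel] | list[str],
    lengths: pd.Series | None = None,
) -> ExpressionFixture:
    """Draw a count matrix with planted archetypes for the given genes.

    ``genes`` may be gene models (lengths = exonic length) or bare ids with
    an explicit ``lengths`` series (log-uniform 200 bp - 20 kb if omitted).
    Bulk background genes named ``BULK_*`` are appended so that per-tissue
    TPMs sum to 1e6 and planted values are exact TPMs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 17]))
    if genes and isinstance(genes[0], GeneModel):
        ids = [g.gene_id for g in genes]  # type: ignore[union-attr]
        lens = pd.Series(
            [sum(e.length for e in g.exon_intervals()) for g in genes],
            index=ids, dtype=float,
        )
    else:
        ids = list(genes)  # type: ignore[arg-type]
        lens = (
            lengths.reindex(ids).astype(float)
            if lengths is not None
            else pd.Series(
                np.exp(rng.uniform(np.log(200), np.log(20_000), len(ids))),
                index=ids,
            ).round()
        )
    tissues = spec.tissue_names()
    n_t = len(tissues)
    samples = _sample_sheet(spec)

    # archetype assignment
    order = rng.permutation(len(ids))
    n = len(ids)
    n_mono = int(round(spec.frac_mono_ts * n))
    n_poly = int(round(spec.frac_poly_ts * n))
    n_sex = int(round(spec.frac_sex_biased * n))
    n_coreg = int(round(spec.frac_coregulated * n)) // 2 * 2
    arch = np.array([ARCH_UNIFORM] * n, dtype=object)
    pos = 0
    arch[order[pos:pos + n_mono]] = ARCH_MONO
    pos += n_mono
    arch[order[pos:pos + n_poly]] = ARCH_POLY
    pos += n_poly
    arch[order[pos:pos + n_sex]] = ARCH_SEX
    pos += n_sex
    coreg_idx = order[pos:pos + n_coreg]
    arch[coreg_idx] = ARCH_COREG

    tpm = np.zeros((n, n_t))
    truth_rows: list[dict] = []
    sex_effects: dict[int, tuple[int, float]] = {}  # gene row -> (tissue, l2fc)

    def _row(gene_i: int, **kw) -> None:
        row = dict(
            gene_id=ids[gene_i], archetype=arch[gene_i], spike_tissues="",
            fold=np.nan, partner_id="", sex_tissue="", sex_log2fc=np.nan,
        )
        row.update(kw)
        truth_rows.append(row)

    for i in range(n):
        a = arch[i]
        if a == ARCH_UNIFORM:
            level = 10.0 ** rng.normal(1.3, 0.4)
            tpm[i, :] = level
            _row(i)
        elif a == ARCH_MONO:
            t = int(rng.integers(n_t))
            tpm[i, :] = spec.background_tpm
            tpm[i, t] = spec.background_tpm * spec.spike_fold
            _row(i, spike_tissues=tissues[t], fold=spec.spike_fold)
        elif a == ARCH_POLY:
            ts = rng.choice(n_t, size=min(spec.poly_tissues, n_t), replace=False)
            tpm[i, :] = spec.background_tpm
            tpm[i, ts] = spec.background_tpm * spec.spike_fold
            _row(i, spike_tissues=";".join(tissues[t] for t in sorted(ts)),
                 fold=spec.spike_fold)
        elif a == ARCH_SEX:
            level = 10.0 ** rng.normal(1.0, 0.3)
            tpm[i, :] = level
            t = int(rng.integers(n_t))
            sex_effects[i] = (t, spec.sex_log2fc)
            _row(i, sex_tissue=tissues[t], sex_log2fc=spec.sex_log2fc)

    # co-regulated pairs: shared latent tissue factor on the log10 scale
    for a_i, b_i in zip(coreg_idx[0::2], coreg_idx[1::2]):
        latent = rng.normal(0.0, spec.latent_sd, n_t)
        for gi in (a_i, b_i):
            base = rng.uniform(1.0, 2.0)  # log10 TPM in [10, 100]
            noise = rng.normal(0.0, spec.residual_sd, n_t)
            tpm[gi, :] = 10.0 ** (base + spec.latent_strength * latent + noise)
        truth_rows.append(dict(
            gene_id=ids[a_i], archetype=ARCH_COREG, spike_tissues="",
            fold=np.nan, partner_id=ids[b_i], sex_tissue="", sex_log2fc=np.nan,
        ))
        truth_rows.append(dict(
            gene_id=ids[b_i], archetype=ARCH_COREG, spike_tissues="",
            fold=np.nan, partner_id=ids[a_i], sex_tissue="", sex_log2fc=np.nan,
        ))

    # bulk background absorbing the remaining transcriptional mass
    bulk_ids = [f"BULK_{i + 1:03d}" for i in range(spec.n_bulk_genes)]
    bulk_w = rng.dirichlet(np.full(spec.n_bulk_genes, 5.0))
    bulk_lens = pd.Series(
        np.exp(rng.uniform(np.log(500), np.log(5_000), spec.n_bulk_genes)),
        index=bulk_ids,
    ).round()
    for bid in bulk_ids:
        truth_rows.append(dict(
            gene_id=bid, archetype=ARCH_BULK, spike_tissues="", fold=np.nan,
            partner_id="", sex_tissue="", sex_log2fc=np.nan,
        ))

    # per-sample expected TPM (sex effects modify male samples)
    frame = samples.frame
    tissue_idx = {t: j for j, t in enumerate(tissues)}
    n_s = len(frame)
    tpm_samples = np.zeros((n, n_s))
    for s_i, row in frame.iterrows():
        col = tpm[:, tissue_idx[row["tissue"]]].copy()
        for gi, (t, l2fc) in sex_effects.items():
            if row["sex"] == "M" and tissue_idx[row["tissue"]] == t:
                col[gi] = col[gi] * (2.0 ** l2fc)
        tpm_samples[:, s_i] = col
    planted_sum = tpm_samples.sum(axis=0)
    if (planted_sum >= 1e6).any():
        raise ValueError("planted TPM exceeds 1e6; reduce gene count or levels")
    bulk_tpm = np.outer(bulk_w, 1e6 - planted_sum)
    full_tpm = np.vstack([tpm_samples, bulk_tpm])
    all_ids = ids + bulk_ids
    all_lens = pd.concat([lens, bulk_lens])

    # counts: library sizes log-normal, NB dispersion on the expected reads
    lib = spec.mean_library_size * np.exp(
        rng.normal(0.0, spec.library_size_log_sd, n_s)
    )
    weights = full_tpm * all_lens.to_numpy()[:, None]
    props = weights / weights.sum(axis=0, keepdims=True)
    mu = props * lib[None, :]
    if spec.dispersion > 0:
        lam = rng.gamma(1.0 / spec.dispersion, mu * spec.dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=all_ids, columns=frame["sample_id"])
    truth = pd.DataFrame(truth_rows).drop_duplicates("gene_id", keep="last")
    tissue_tpm = pd.DataFrame(
        np.vstack([tpm, np.outer(bulk_w, np.full(n_t, np.nan))]),
        index=all_ids, columns=tissues,
    )
    return ExpressionFixture(
        counts=counts_df,
        lengths=all_lens,
        samples=samples,
        truth=truth.reset_index(drop=True),
        tissue_tpm=tissue_tpm,
    )
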