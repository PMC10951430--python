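# Methods

This note documents the models and procedures implemented in `geneatlas`,
the parameters that matter, what the synthetic fixtures do and do not
emulate, and the numerical choices made where the design was open.

## Coordinate and data model

All coordinates are 1-based inclusive (GTF convention); BED inputs (CAGE
peaks) are converted on read. A transcript is an ordered list of
non-overlapping exons on one strand; its TSS is the first exon start on
`+` and the last exon end on `-`. A gene locus is ≥ 1 transcript on one
strand of one chromosome; its span is the hull of all exons. Chromosome
names are opaque strings, so unplaced scaffolds need no special handling.
Biotype labels are normalized to five classes (pcg, lncRNA, miRNA,
other_small_rna, other) through an editable table; the shipped defaults
cover the common Ensembl/RefSeq vocabulary and map unknown labels to
`other`. The table is a deliberate configuration point: source dialects
differ, and the merge semantics depend on class assignment.

## Atlas aggregation

Two loci overlap when some exon pair shares ≥ 1 bp on the same strand
([1,100] and [100,200] do). The merge is sequential by source priority:
source 1 wholesale, later loci accepted iff they conflict with nothing
accepted so far. Decisions taken here:

* **Whole-locus rejection.** If any transcript of a candidate conflicts,
  the entire locus is dropped; there is no transcript-level grafting. This
  keeps accepted gene models identical to their source of origin.
* **Class-restricted conflicts by default.** Conflicts are evaluated
  within the candidate's biotype class. This is the only mode in which
  genes hosted in exons of another class (miRNAs inside protein-coding or
  lncRNA exons) survive aggregation. Note that *intron*-hosted genes share
  no exonic base with their host and therefore survive in either mode; the
  strict all-vs-all flag only changes the fate of exon-overlapping
  cross-class loci.
* **Cross-references.** A locus rejected against exactly one accepted gene
  contributes its native id as a cross-reference of that gene — an
  id-equivalence found by overlap rather than curation. Multi-collision
  rejections are only logged.
* **Id collisions.** An accepted gene whose id is already taken is renamed
  `<id>__<source>` and the renaming recorded.
* **Index.** Conflict queries run on per-(chromosome, strand) interval
  trees over exons; the contract is exact agreement with the O(n²)
  brute-force scan, which the tests assert on fixtures up to ~500 genes.
* **CAGE matching ignores peak strand** and uses a ±30 bp slop around the
  peak. Whether strand matching would be more faithful is unresolved;
  slop and strand use are configurable.

## Expression quantification

* TPM_gs = 1e6 · (c_gs/l_g) / Σ_g (c_gs/l_g). All-zero samples stay zero
  and are flagged with a warning; zero gene lengths are an error.
* TMM follows the published trimmed-mean-of-M-values procedure exactly as
  the reference R implementation does: all-zero genes removed; reference
  library = the one whose 0.75 count-proportion quantile is closest to the
  mean; per library, genes zero in either library or reference dropped;
  M-values trimmed 30% per tail, A-values 5% per tail (rank-based, average
  ranks on ties); factor = 2^(precision-weighted trimmed mean of M);
  factors rescaled to geometric mean 1. The tests cross-check against
  edgeR's `calcNormFactors` through Rscript to 1e-6.
* Factors are computed **per project**: composition bias is a
  between-library artefact best corrected within a homogeneous dataset,
  and it matches quantifying each public project separately.
  Single-sample projects get factor 1.
* "TMM expression" = 1e9 · c_gs / (l_g · N_s · f_s), i.e. FPKM on the
  TMM-effective library size — the `calcNormFactors` → `rpkm` sequence.
* Tissue profile: median TPM across samples within (tissue, project), then
  median across projects. This weights projects equally regardless of
  sample count.
* Expressed rule: clause A (some tissue median ≥ 0.1 TPM) AND clause B
  (some (tissue, project) where ≥ 50% of samples jointly pass reads ≥ 6,
  TPM ≥ 0.1, TMM ≥ 0.1). The two clauses are existential *independently* —
  the weakest reading of the rule; a `same_tissue` flag requires both in
  the same tissue. All thresholds are keyword parameters.
* Per-sex flag (for sex-DE eligibility): ≥ 8 samples per sex required;
  a gene passes if ≥ 80% of one sex's samples pass the same triple.
* Genes present in the annotation but absent from a count matrix are
  treated as zero counts, keeping flags deterministic.

## Tissue specificity

τ = Σ(1 − x̂_t)/(T − 1) on x_t = log10(median_t + 1). The +1 pseudocount is
a deliberate choice: without it, sub-1 TPM medians give negative x_t and τ
leaves [0, 1]. With it, zero-expression tissues contribute x̂ = 0 and τ is
exactly 1 for single-tissue expression. τ is computed over all tissues
(genes, not tissues, are filtered). TS calls require τ ≥ 0.90 and a peak
tissue median ≥ 1 TPM — both configurable, and the tests assert the
direction (relaxing the expression floor never reduces the TS count)
rather than any particular rate.

Gap categories scan the descending medians for the **first** consecutive
pair with fold-change ≥ 2 (a zero denominator under a nonzero numerator
counts as a gap). First-gap rather than largest-gap gives the tightest
specific group. No gap ⇒ the residual `poly8to47_TS` category. Ties in
the sort are broken by tissue name; value-identical tissues can never
straddle a gap since their fold-change is 1.

## Positional classification

Exonic status is decided over all transcript exon pairs (any strand);
span-intersecting loci without exon contact are `genic_intronic`;
orientation and distance of intergenic calls come from the gene spans
(closest ends), which stay well-defined for multi-transcript genes where a
TSS-based distance would not. Gene-level calls take the best partner under
genic_exonic > genic_intronic > intergenic, then smallest distance, then
lexicographic partner id — the precedence is a stated decision, since the
upstream classifier's tie-breaking is not published. Classification uses a
100 kb window, co-expression pairing 1 Mb; both configurable. Antisense
exonic overlap is genic antisense, not intergenic. miRNA hosts require
span containment; among multiple enclosing hosts the smallest span wins.

## Co-expression

Kendall τ-b (tie-corrected) on the per-tissue median TPM vectors; being
rank-based it is invariant to the log-transform choice up to ties.
P-values use exact enumeration for small untied samples and the
tie-adjusted normal approximation otherwise (at n = 8 the plain normal
approximation can be off by ~0.1 in the middle of the null, which is why
small samples get the exact distribution; by n ≈ 30 the two agree within
0.02). Benjamini–Hochberg runs within each pair-type batch, matching
separately reported per-type rates. Significance = |τ| ≥ 0.55 AND
q ≤ 0.05. Constant profiles give an undefined correlation, excluded from
the batch. The summary stratifies the significant fraction by
configuration and by distance (≤ 5 kb vs > 5 kb).

## Synthetic fixtures

`generate_annotations` lays out loci linearly with 0.5–5 kb gaps, so loci
never overlap unless planted: later sources mix jittered duplicates
(guaranteed same-strand exon overlap with exactly one target) with novel
loci, and miRNAs are planted in priority-1 hosts — intron-hosted in PCGs,
exon-hosted in PCGs and lncRNAs. `generate_expression` plants archetypes
on true-TPM profiles (background 0.1 TPM, 100-fold spikes for mono/poly
specificity, 2^2 sex effects in one tissue, co-regulated pairs sharing a
latent log10 tissue factor of sd 1 with residual sd 0.2), adds a bulk
block absorbing the rest of the million so planted values are exact TPMs,
and draws negative-binomial counts (dispersion 0.1) on log-normal library
sizes (mean 3e7, log-sd 0.3) — enough depth that a 0.1 TPM gene sits at
the edge of detectability, as in real data. Default design: 47 tissues,
one 4-sample project per tissue, alternating sexes; tests vary tissue and
project counts where a design feature (median-of-medians, per-sex
eligibility) is under test.

What the fixtures do **not** emulate: real chromosome sizes and gene
density, transcript-model disagreement between sources (duplicates differ
only by small jitter), correlated expression between adjacent genes,
multi-tissue projects, batch effects, and read-level artefacts. Passing
tests therefore demonstrate correctness of the rules and calibration of
the statistics under the stated generative model, not robustness to
alignment or annotation noise in real data.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale — merges of up to ~500
loci over 2–6 sources, expression matrices of ~500 genes × 47 tissues ×
188 samples, 1,000-pair null calibrations — sizes at which the brute-force
oracles remain exact and the whole suite runs in seconds. All randomness
flows from explicit seeds; a fixed seed yields byte-identical GTFs, count
matrices and pipeline outputs.

## Known limitations

* No transcript-model reconciliation across sources; the merge keeps or
  drops whole loci.
* The expressed rule's AND-of-existentials reading and the first-gap rule
  are stated interpretations of ambiguous prose; both are configurable.
* Kendall correlation across ~47 tissue medians has limited power for
  |τ| near the 0.55 threshold; the planted-pair recovery figures hold for
  strongly co-regulated pairs.
* No batch correction, no differential-expression model fitting (only the
  expression filters that feed one), and no coding-potential assessment.
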