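"""End-to-end orchestration: build -> quantify -> tau -> classify -> coexpr.

A single config dict (usually loaded from YAML) names all inputs and stage
parameters; every threshold of the method (0.1 / 1 TPM, 6 reads, 50% / 80%
sample fractions, tau 0.90, gap fold-change 2, 100 kb / 1 Mb windows,
|tau| 0.55, FDR 0.05) is a named key with the method's default.  Outputs are
plain TSV/GTF/JSON files; reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict

import pandas as pd

from . import __version__
from .cage import cage_support, read_bed
from .coexpression import call_coexpression
from .expression import (
    SampleTable,
    compute_tpm,
    flag_expressed,
    per_project_tmm,
    tissue_medians,
)
from .fixtures import FixtureSpec, generate_annotations, generate_expression
from .gtf import read_gtf, write_gtf
from .merge import MergedAtlas, merge_annotations
from .models import LNCRNA, PCG
from .neighborhood import mirna_hosts, pair_for_coexpression
from .specificity import classify_ts_table

DEFAULT_PARAMS: dict = {
    "same_class_only": True,
    "cage_slop": 30,
    "min_expr": 0.1,
    "min_reads": 6,
    "min_frac": 0.5,
    "tau_threshold": 0.90,
    "ts_min_expr": 1.0,
    "gap_fc": 2.0,
    "classify_window": 100_000,
    "coexpr_window": 1_000_000,
    "min_abs_tau": 0.55,
    "fdr": 0.05,
}


def _params(config: dict) -> dict:
    p = dict(DEFAULT_PARAMS)
    p.update(config.get("params", {}))
    return p


def _load_inputs(config: dict, out_dir: str):
    """Resolve inputs: either explicit file paths or a fixture spec."""
    if "fixtures" in config:
        spec = FixtureSpec(**config["fixtures"])
        sources, ann_truth = generate_annotations(spec)
        ann_truth.to_csv(
            os.path.join(out_dir, "annotation_truth.tsv"), sep="\t", index=False
        )
        return spec, sources, None
    inputs = config["inputs"]
    sources = [
        read_gtf(s["path"], s["name"], s.get("priority", i + 1))
        for i, s in enumerate(inputs["sources"])
    ]
    return None, sources, inputs


def run_pipeline(config: dict, out_dir: str) -> dict:
    """Run all stages the config provides inputs for; return the manifest.

    With only annotation inputs the run stops after the build stage and the
    later columns of the annotation table are NA.
    """
    os.makedirs(out_dir, exist_ok=True)
    params = _params(config)
    spec, sources, inputs = _load_inputs(config, out_dir)

    # ------------------------------------------------------------------ build
    atlas = merge_annotations(sources, same_class_only=params["same_class_only"])
    write_gtf(atlas.to_source("atlas"), os.path.join(out_dir, "atlas.gtf"))
    pd.DataFrame(
        [
            (r.gene_id, r.source, ";".join(r.conflicting_ids))
            for r in atlas.rejections
        ],
        columns=["candidate_id", "source", "conflicting_ids"],
    ).to_csv(os.path.join(out_dir, "rejections.tsv"), sep="\t", index=False)
    xref = pd.DataFrame(
        [
            {"gene_id": gid, **refs}
            for gid, refs in atlas.xref_table.items()
        ]
    )
    xref.to_csv(os.path.join(out_dir, "xref.tsv"), sep="\t", index=False)

    cage_path = (inputs or {}).get("cage") if inputs else config.get("cage")
    cage_result = None
    if cage_path:
        peaks = read_bed(cage_path, slop=params["cage_slop"])
        cage_result = {
            s.name: cage_support(s, peaks) for s in sources
        }
        with open(os.path.join(out_dir, "cage_support.json"), "w") as fh:
            json.dump(cage_result, fh, indent=2, sort_keys=True)

    # --------------------------------------------------------------- quantify
    counts = lengths = samples = None
    if spec is not None and spec.n_tissues > 0:
        expr = generate_expression(spec, atlas.genes)
        expr.write(os.path.join(out_dir, "expression"))
        counts, lengths, samples = expr.counts, expr.lengths, expr.samples
    elif inputs and "counts" in inputs:
        counts = pd.read_csv(inputs["counts"], sep="\t", index_col=0)
        lengths = pd.read_csv(
            inputs["lengths"], sep="\t", index_col=0
        ).iloc[:, 0].astype(float)
        samples = SampleTable.read(inputs["samples"])

    stage_tables: dict[str, pd.DataFrame] = {}
    if counts is not None:
        tpm = compute_tpm(counts, lengths)
        tmm, factors = per_project_tmm(counts, lengths, samples)
        medians = tissue_medians(tpm, samples)
        flags = flag_expressed(
            medians, counts, tpm, tmm, samples,
            min_expr=params["min_expr"], min_reads=params["min_reads"],
            min_frac=params["min_frac"],
        )
        medians.to_csv(os.path.join(out_dir, "profile.tsv"), sep="\t")
        flags.to_csv(os.path.join(out_dir, "flags.tsv"), sep="\t")
        stage_tables["medians"] = medians
        stage_tables["flags"] = flags

        # ---------------------------------------------------------------- tau
        tau_table = classify_ts_table(
            medians, tau_threshold=params["tau_threshold"],
            min_expr=params["ts_min_expr"], gap_fc=params["gap_fc"],
        )
        tau_table.to_csv(os.path.join(out_dir, "tau.tsv"), sep="\t")
        stage_tables["tau"] = tau_table

    # ---------------------------------------------------------------- classify
    pairs = pair_for_coexpression(
        atlas, LNCRNA, PCG, window=params["classify_window"]
    )
    pairs.to_csv(os.path.join(out_dir, "pairs.tsv"), sep="\t", index=False)
    hosts = mirna_hosts(atlas)
    hosts.to_csv(os.path.join(out_dir, "mirna_hosts.tsv"), sep="\t", index=False)
    stage_tables["pairs"] = pairs
    stage_tables["hosts"] = hosts

    # ----------------------------------------------------------------- coexpr
    if counts is not None:
        coexpr_pairs = pd.concat(
            [
                pair_for_coexpression(atlas, LNCRNA, PCG,
                                      window=params["coexpr_window"]),
                pair_for_coexpression(atlas, PCG, PCG,
                                      window=params["coexpr_window"]),
            ],
            ignore_index=True,
        )
        expressed = stage_tables["flags"].query("expressed").index
        coexpr_pairs = coexpr_pairs[
            coexpr_pairs["focal_id"].isin(expressed)
            & coexpr_pairs["partner_id"].isin(expressed)
        ].reset_index(drop=True)
        coexpr, summary = call_coexpression(
            coexpr_pairs, stage_tables["medians"],
            min_abs_tau=params["min_abs_tau"], fdr=params["fdr"],
        )
        coexpr.to_csv(os.path.join(out_dir, "coexpr.tsv"), sep="\t", index=False)
        summary.to_csv(
            os.path.join(out_dir, "coexpr_summary.tsv"), sep="\t", index=False
        )
        stage_tables["coexpr"] = coexpr

    # ------------------------------------------------------------------ table
    table = build_annotation_table(atlas, stage_tables)
    table.to_csv(os.path.join(out_dir, "annotation_table.tsv"), sep="\t")

    manifest = {
        "version": __version__,
        "params": params,
        "seed": (asdict(spec)["seed"] if spec is not None
                 else config.get("seed")),
        "sources": [s.name for s in sources],
        "n_genes": len(atlas.genes),
        "outputs": sorted(set(os.listdir(out_dir)) | {"run_manifest.json"}),
    }
    with open(os.path.join(out_dir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def build_annotation_table(
    atlas: MergedAtlas, stage_tables: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Consolidated per-gene annotation: one row per atlas gene, functional
    columns NA where a stage did not run."""
    rows = []
    for g in atlas.genes:
        span = g.span
        rows.append(dict(
            gene_id=g.gene_id,
            biotype_class=g.biotype_class,
            chrom=g.chrom, start=span.start, end=span.end, strand=g.strand,
            n_transcripts=len(g.transcripts),
            n_exons=len(g.exon_intervals()),
            monoexonic=g.monoexonic,
            source=g.source,
            xrefs=";".join(f"{k}|{v}" for k, v in sorted(g.xrefs.items())),
        ))
    table = pd.DataFrame(rows).set_index("gene_id")
    if table.index.duplicated().any():
        raise ValueError("duplicate gene_id in atlas")

    flags = stage_tables.get("flags")
    if flags is not None:
        table = table.join(flags, how="left")
    medians = stage_tables.get("medians")
    if medians is not None:
        table = table.join(medians.add_prefix("tpm_"), how="left")
    tau = stage_tables.get("tau")
    if tau is not None:
        table = table.join(tau, how="left")
    pairs = stage_tables.get("pairs")
    if pairs is not None and len(pairs):
        closest = pairs.set_index("focal_id")[
            ["partner_id", "relation", "configuration", "distance"]
        ].rename(columns=lambda c: f"closest_pcg_{c}")
        table = table.join(closest, how="left")
    hosts = stage_tables.get("hosts")
    if hosts is not None and len(hosts):
        hosted = (
            hosts.groupby("host_gene_id")["mirna_id"]
            .apply(";".join).rename("hosted_mirnas")
        )
        table = table.join(hosted, how="left")
    coexpr = stage_tables.get("coexpr")
    if coexpr is not None and len(coexpr):
        best = (
            coexpr.sort_values("q_value")
            .drop_duplicates("focal_id")
            .set_index("focal_id")[
                ["partner_id", "kendall_tau", "q_value", "significant"]
            ].rename(columns=lambda c: f"coexpr_{c}")
        )
        table = table.join(best, how="left")
    return table
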