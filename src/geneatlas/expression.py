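"""From raw counts to per-tissue expression profiles and expressed flags.

The quantification model follows common multi-project atlas practice:

* TPM is computed per sample from counts and gene lengths.
* TMM scaling factors are computed *within each project*, since composition
  bias is a between-library effect best corrected inside a homogeneous
  dataset; "TMM expression" is FPKM on TMM-effective library sizes.
* The per-tissue profile is a median of medians: first the median TPM across
  samples within each (tissue, project), then the median of those project
  medians for tissues covered by several projects.
* A gene is *expressed* iff (a) its median TPM is >= 0.1 in at least one
  tissue, and (b) in at least one (tissue, project) at least 50% of samples
  jointly have >= 6 reads, TPM >= 0.1 and TMM expression >= 0.1.  A stricter
  reading that requires both clauses to hold in the same tissue is available
  behind ``same_tissue``.
* Expression categories follow the maximum tissue median: < 0.1 TPM in all
  tissues, in [0.1, 1) in at least one tissue, or >= 1 in at least one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tmm import tmm_expression, tmm_factors

CATEGORY_LOW = "lt_0.1"
CATEGORY_MID = "from_0.1_to_1"
CATEGORY_HIGH = "ge_1"

REQUIRED_SAMPLE_COLUMNS = ("sample_id", "tissue", "project", "sex")


@dataclass
class SampleTable:
    """Sample sheet: sample_id -> (tissue, project, sex in {M, F, unknown})."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in self.frame]
        if missing:
            raise ValueError(f"sample sheet lacks columns: {missing}")
        if self.frame["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_ids in sample sheet")
        if self.frame[["tissue", "project"]].isna().any().any():
            raise ValueError("every sample needs a tissue and a project")
        self.frame = self.frame.reset_index(drop=True)

    @classmethod
    def read(cls, path: str) -> "SampleTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write(self, path: str) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def groups(self) -> pd.core.groupby.DataFrameGroupBy:
        return self.frame.groupby(["tissue", "project"], sort=True)


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: ``1e6 * (count/length) / sum(count/length)``.

    Columns of all-zero samples stay all-zero (with a warning).
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()][:5].tolist()
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero_cols = denom == 0
    if zero_cols.any():
        warnings.warn(
            f"samples with zero total counts: {list(counts.columns[zero_cols])}",
            stacklevel=2,
        )
        denom = denom.replace(0, np.nan)
    tpm = 1e6 * rate.div(denom, axis=1)
    return tpm.fillna(0.0)


def per_project_tmm(
    counts: pd.DataFrame, lengths: pd.Series, samples: SampleTable
) -> tuple[pd.DataFrame, pd.Series]:
    """TMM expression and factors, computed project by project.

    Single-sample projects cannot be composition-corrected; they get factor 1.
    """
    tmm = pd.DataFrame(
        0.0, index=counts.index, columns=counts.columns, dtype=float
    )
    factors = pd.Series(1.0, index=counts.columns, name="tmm_factor")
    for project, sub in samples.frame.groupby("project", sort=True):
        cols = [s for s in sub["sample_id"] if s in counts.columns]
        block = counts[cols]
        if len(cols) >= 2 and (block.sum(axis=0) > 0).sum() >= 2:
            f = tmm_factors(block)
        else:
            f = pd.Series(1.0, index=cols)
        factors[cols] = f
        tmm[cols] = tmm_expression(block, lengths, f)
    return tmm, factors


def tissue_medians(tpm: pd.DataFrame, samples: SampleTable) -> pd.DataFrame:
    """Median-of-project-medians per-tissue profile (genes x tissues).

    Stage 1: median TPM across samples within each (tissue, project).
    Stage 2: median across projects of the stage-1 medians.  Tissues covered
    by a single project pass through stage 1 only.
    """
    stage1: dict[tuple[str, str], pd.Series] = {}
    for (tissue, project), sub in samples.groups():
        cols = [s for s in sub["sample_id"] if s in tpm.columns]
        if not cols:
            continue
        stage1[(tissue, project)] = tpm[cols].median(axis=1)
    if not stage1:
        raise ValueError("no sample sheet entries match the expression matrix")
    stage1_df = pd.DataFrame(stage1)
    stage2 = stage1_df.T.groupby(level=0).median().T
    stage2.columns.name = "tissue"
    return stage2.sort_index(axis=1)


def expression_category(medians: pd.DataFrame) -> pd.Series:
    """Three-way expression category from the max per-tissue median TPM."""
    peak = medians.max(axis=1)
    cat = pd.Series(CATEGORY_LOW, index=medians.index, name="category")
    cat[peak >= 0.1] = CATEGORY_MID
    cat[peak >= 1.0] = CATEGORY_HIGH
    return cat


def _sample_pass(
    counts: pd.DataFrame,
    tpm: pd.DataFrame,
    tmm: pd.DataFrame,
    min_reads: float,
    min_expr: float,
) -> pd.DataFrame:
    return (counts >= min_reads) & (tpm >= min_expr) & (tmm >= min_expr)


def flag_expressed(
    medians: pd.DataFrame,
    counts: pd.DataFrame,
    tpm: pd.DataFrame,
    tmm: pd.DataFrame,
    samples: SampleTable,
    min_expr: float = 0.1,
    min_reads: float = 6,
    min_frac: float = 0.5,
    same_tissue: bool = False,
) -> pd.DataFrame:
    """Expressed flag and expression category per gene.

    expressed <=> [some tissue median TPM >= ``min_expr``] AND [some
    (tissue, project) where >= ``min_frac`` of samples have reads >=
    ``min_reads`` and TPM and TMM expression >= ``min_expr``].  With
    ``same_tissue`` both clauses must hold for the same tissue.
    """
    passing = _sample_pass(counts, tpm, tmm, min_reads, min_expr)
    clause_b_by_tissue: dict[str, pd.Series] = {}
    for (tissue, _project), sub in samples.groups():
        cols = [s for s in sub["sample_id"] if s in counts.columns]
        if not cols:
            continue
        frac = passing[cols].mean(axis=1)
        ok = frac >= min_frac
        if tissue in clause_b_by_tissue:
            clause_b_by_tissue[tissue] |= ok
        else:
            clause_b_by_tissue[tissue] = ok
    clause_b_df = pd.DataFrame(clause_b_by_tissue)

    medians = medians.reindex(counts.index).fillna(0.0)
    if same_tissue:
        common = [t for t in medians.columns if t in clause_b_df.columns]
        expressed = (
            (medians[common] >= min_expr) & clause_b_df[common]
        ).any(axis=1)
    else:
        clause_a = (medians >= min_expr).any(axis=1)
        clause_b = clause_b_df.any(axis=1)
        expressed = clause_a & clause_b
    return pd.DataFrame(
        {"expressed": expressed, "category": expression_category(medians)}
    )


def flag_expressed_per_sex(
    counts: pd.DataFrame,
    tpm: pd.DataFrame,
    tmm: pd.DataFrame,
    samples: SampleTable,
    tissue: str,
    project: str,
    min_expr: float = 0.1,
    min_reads: float = 6,
    min_frac: float = 0.8,
    min_per_sex: int = 8,
) -> pd.Series:
    """Per-gene expressed flag for the sex-differential analysis.

    Eligible (tissue, project) groups need >= ``min_per_sex`` samples of each
    sex; a gene passes iff for at least one sex, >= ``min_frac`` of that
    sex's samples jointly meet the read/TPM/TMM thresholds.
    """
    sub = samples.frame.query("tissue == @tissue and project == @project")
    by_sex = {
        sex: [s for s in grp["sample_id"] if s in counts.columns]
        for sex, grp in sub.groupby("sex")
        if sex in ("M", "F")
    }
    if len(by_sex) < 2 or any(len(v) < min_per_sex for v in by_sex.values()):
        raise ValueError(
            f"(tissue={tissue}, project={project}) needs >= {min_per_sex} "
            "samples per sex"
        )
    passing = _sample_pass(counts, tpm, tmm, min_reads, min_expr)
    flags = pd.Series(False, index=counts.index, name="expressed_per_sex")
    for cols in by_sex.values():
        flags |= passing[cols].mean(axis=1) >= min_frac
    return flags
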