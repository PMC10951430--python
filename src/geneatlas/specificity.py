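"""Tau tissue-specificity and gap-based specificity categories.

tau is computed on transformed per-tissue median expression:

    x_t = log10(median_t + 1);  x_hat_t = x_t / max_t x_t
    tau = sum_t (1 - x_hat_t) / (T - 1)

giving 0 for a uniform profile and 1 for expression confined to one tissue.
The +1 pseudocount keeps x_t >= 0 (hence tau in [0, 1]) and lets
zero-expression tissues contribute fully to specificity; the transform choice
is configurable.

A gene with tau >= 0.90 (and a maximum tissue median >= 1 TPM) is
tissue-specific (TS).  TS genes are split by scanning their tissue medians in
descending order for the first *gap*, a >= 2-fold drop between consecutive
tissues: a gap after 1 tissue gives ``mono_TS``, after 2-7 tissues
``poly2to7_TS``, and a later or absent gap ``poly8to47_TS``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MONO_TS = "mono_TS"
POLY_2TO7_TS = "poly2to7_TS"
POLY_8PLUS_TS = "poly8to47_TS"
NOT_TS = "not_TS"


def log10p1(x: np.ndarray) -> np.ndarray:
    return np.log10(np.asarray(x, dtype=float) + 1.0)


@dataclass
class TauResult:
    tau: float
    n_tissues: int
    ts_flag: bool
    ts_category: str
    specific_tissues: list[str] = field(default_factory=list)


def compute_tau(values, transform=log10p1) -> float:
    """tau of a per-tissue expression vector (NaN for an all-zero profile)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("tau needs >= 2 tissues")
    if (x < 0).any():
        raise ValueError("tau expects non-negative expression values")
    if transform is not None:
        x = transform(x)
    top = x.max()
    if top <= 0:
        warnings.warn("all-zero expression profile: tau undefined", stacklevel=2)
        return float("nan")
    xhat = x / top
    return float((1.0 - xhat).sum() / (x.size - 1))


def _first_gap(sorted_values: np.ndarray, gap_fc: float) -> int | None:
    """1-based index of the first >= gap_fc drop between consecutive tissues
    ordered by descending expression; a zero denominator under a nonzero
    numerator counts as a gap."""
    for k in range(len(sorted_values) - 1):
        hi, lo = sorted_values[k], sorted_values[k + 1]
        if hi <= 0:
            return None
        if lo == 0 or hi / lo >= gap_fc:
            return k + 1
    return None


def classify_ts(
    medians: pd.Series,
    tau: float | None = None,
    tau_threshold: float = 0.90,
    min_expr: float = 1.0,
    gap_fc: float = 2.0,
    mono_max: int = 1,
    poly_max: int = 7,
    transform=log10p1,
) -> TauResult:
    """Assign the TS flag and category for one gene's tissue-median profile.

    ``medians`` is a Series indexed by tissue name (raw TPM scale).  Ties in
    the descending sort are broken by tissue name, which never moves a gap
    (equal values have fold-change 1).
    """
    medians = medians.astype(float)
    if tau is None:
        tau = compute_tau(medians.to_numpy(), transform=transform)
    n = len(medians)
    ts_flag = bool(np.isfinite(tau) and tau >= tau_threshold)
    if not ts_flag or medians.max() < min_expr:
        return TauResult(tau, n, ts_flag, NOT_TS, [])
    ordered = medians.sort_index().sort_values(ascending=False, kind="stable")
    k = _first_gap(ordered.to_numpy(), gap_fc)
    if k is None or k > poly_max:
        k_eff = k if k is not None else n
        return TauResult(tau, n, True, POLY_8PLUS_TS,
                         list(ordered.index[:k_eff]))
    category = MONO_TS if k <= mono_max else POLY_2TO7_TS
    return TauResult(tau, n, True, category, list(ordered.index[:k]))


def classify_ts_table(
    medians: pd.DataFrame,
    tau_threshold: float = 0.90,
    min_expr: float = 1.0,
    gap_fc: float = 2.0,
    transform=log10p1,
) -> pd.DataFrame:
    """Vector version over a genes x tissues median table.

    Returns a per-gene frame with tau, ts_flag, ts_category and the
    semicolon-joined specific tissue group.
    """
    records = []
    for gene_id, row in medians.iterrows():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = classify_ts(
                row, tau_threshold=tau_threshold, min_expr=min_expr,
                gap_fc=gap_fc, transform=transform,
            )
        records.append(
            (gene_id, res.tau, res.ts_flag, res.ts_category,
             ";".join(res.specific_tissues))
        )
    return pd.DataFrame(
        records,
        columns=["gene_id", "tau", "ts_flag", "ts_category", "specific_tissues"],
    ).set_index("gene_id")


def ts_census(
    results: pd.DataFrame, classes: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts of TS genes per (biotype class, category) and per tissue.

    A gene counts toward every tissue in its specific group.  ``classes``
    maps gene_id -> biotype class; without it all genes share one class.
    """
    res = results.copy()
    if classes is None:
        res["biotype_class"] = "all"
    else:
        res["biotype_class"] = classes.reindex(res.index).fillna("other")
    by_class = (
        res.groupby(["biotype_class", "ts_category"]).size().rename("n_genes")
        .reset_index()
    )
    rows = []
    ts = res[res["ts_category"] != NOT_TS]
    for _, row in ts.iterrows():
        for tissue in str(row["specific_tissues"]).split(";"):
            if tissue:
                rows.append((tissue, row["ts_category"]))
    per_tissue = (
        pd.DataFrame(rows, columns=["tissue", "ts_category"])
        .groupby(["tissue", "ts_category"]).size().rename("n_genes")
        .reset_index()
        if rows
        else pd.DataFrame(columns=["tissue", "ts_category", "n_genes"])
    )
    return by_class, per_tissue
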