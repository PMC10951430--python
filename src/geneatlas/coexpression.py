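"""Kendall co-expression of gene pairs across tissues with FDR control.

For each focal:partner pair the Kendall rank correlation (tau-b, tie
corrected) of the two per-tissue median TPM vectors is computed; being
rank-based, the result is invariant to any monotone transform of the
profiles.  P-values are Benjamini-Hochberg adjusted within each pair-type
batch (lncRNA:PCG and PCG:PCG separately), and a pair is called co-expressed
when |tau| >= 0.55 and the adjusted p-value is <= 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall tau-b and its p-value (exact for small untied samples, normal
    approximation with tie-adjusted variance otherwise).

    Returns (nan, nan) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("kendall_tau needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    res = stats.kendalltau(x, y)
    return (float(res.statistic), float(res.pvalue))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def call_coexpression(
    pairs: pd.DataFrame,
    profiles: pd.DataFrame,
    min_abs_tau: float = 0.55,
    fdr: float = 0.05,
    batch_col: str = "pair_type",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kendall correlation and significance call for every gene pair.

    ``pairs`` needs columns focal_id, partner_id and (optionally) pair_type,
    configuration and distance; ``profiles`` is the genes x tissues median
    TPM table.  Pairs referencing genes without a profile are skipped.
    BH adjustment runs within each ``batch_col`` batch.

    Returns (per-pair results, per-configuration/distance-stratum summary of
    the fraction of significant pairs).
    """
    pairs = pairs.copy()
    if batch_col not in pairs.columns:
        pairs[batch_col] = "all"
    have = pairs["focal_id"].isin(profiles.index) & pairs["partner_id"].isin(
        profiles.index
    )
    skipped = pairs[~have]
    pairs = pairs[have].reset_index(drop=True)

    taus = np.empty(len(pairs))
    ps = np.empty(len(pairs))
    mat = profiles.to_numpy(dtype=float)
    row_of = {g: i for i, g in enumerate(profiles.index)}
    for i, (f, p_) in enumerate(zip(pairs["focal_id"], pairs["partner_id"])):
        taus[i], ps[i] = kendall_tau(mat[row_of[f]], mat[row_of[p_]])
    pairs["kendall_tau"] = taus
    pairs["p_value"] = ps
    pairs["q_value"] = np.nan
    for _, idx in pairs.groupby(batch_col).groups.items():
        pairs.loc[idx, "q_value"] = bh_adjust(pairs.loc[idx, "p_value"])
    pairs["significant"] = (
        (pairs["kendall_tau"].abs() >= min_abs_tau)
        & (pairs["q_value"] <= fdr)
    ).fillna(False)
    if len(skipped):
        pairs.attrs["skipped_pairs"] = list(skipped["focal_id"])

    summary = _summarize(pairs, batch_col)
    return pairs, summary


def _summarize(results: pd.DataFrame, batch_col: str) -> pd.DataFrame:
    rows = []
    group_cols = [batch_col]
    if "configuration" in results.columns:
        group_cols.append("configuration")
    for keys, sub in results.groupby(group_cols, dropna=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        rows.append((*keys, "all", len(sub), float(sub["significant"].mean())))
        if "distance" in results.columns and sub["distance"].notna().any():
            near = sub[sub["distance"] <= 5_000]
            far = sub[sub["distance"] > 5_000]
            for label, part in (("le_5kb", near), ("gt_5kb", far)):
                if len(part):
                    rows.append(
                        (*keys, label, len(part),
                         float(part["significant"].mean()))
                    )
    cols = group_cols + ["distance_stratum", "n_pairs", "frac_significant"]
    return pd.DataFrame(rows, columns=cols)
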