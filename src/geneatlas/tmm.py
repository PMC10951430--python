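"""Trimmed mean of M-values (TMM) between-sample normalization.

Implements the standard TMM scaling-factor procedure for raw count matrices:
the reference library is the one whose 0.75 count-proportion quantile is
closest to the mean across libraries; for each library, genes with zero
counts in either the library or the reference are dropped, the log2 ratio of
count proportions (M) is trimmed by 30% on both ends and the average log2
proportion (A) by 5%, and the factor is 2 to the precision-weighted mean of
the surviving M-values.  Factors are rescaled to geometric mean 1, so they
are pure composition corrections on top of library-size (depth)
normalization.

"TMM expression" is per-kilobase expression on TMM-effective library sizes:
``1e9 * count / (length * library_size * factor)`` — i.e. FPKM computed with
the scaled library size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    weighted: bool = True,
) -> float:
    """TMM factor of one library against the reference library."""
    obs = obs.astype(float)
    ref = ref.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / lib_obs) / (ref / lib_ref))
        abs_e = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2.0
        v = (lib_obs - obs) / lib_obs / obs + (lib_ref - ref) / lib_ref / ref
    finite = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[finite], abs_e[finite], v[finite]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)  # average ranks for ties
    rank_e = rankdata(abs_e)
    keep = (
        (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    )
    if not keep.any():
        return 1.0
    if weighted:
        f = np.nansum(log_r[keep] / v[keep]) / np.nansum(1.0 / v[keep])
    else:
        f = np.nanmean(log_r[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample TMM scaling factors (geometric mean 1) for a genes x
    samples raw count matrix.

    Raises if fewer than two libraries have nonzero totals.
    """
    mat = counts.to_numpy(dtype=float)
    lib_sizes = mat.sum(axis=0)
    if (lib_sizes > 0).sum() < 2:
        raise ValueError("TMM needs >= 2 libraries with nonzero totals")
    mat = mat[mat.any(axis=1)]  # all-zero genes carry no information
    # reference: library whose upper-quartile count proportion is closest
    # to the mean upper-quartile
    f75 = np.quantile(mat, 0.75, axis=0) / lib_sizes
    if np.median(f75) < 1e-20:
        ref_idx = int(np.argmax(np.sqrt(mat).sum(axis=0)))
    else:
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = mat[:, ref_idx]
    lib_ref = lib_sizes[ref_idx]

    factors = np.array([
        _tmm_pair_factor(mat[:, j], ref, lib_sizes[j], lib_ref)
        for j in range(mat.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def tmm_expression(
    counts: pd.DataFrame,
    lengths: pd.Series,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Length-scaled expression on TMM-effective library sizes (FPKM-like)."""
    if factors is None:
        factors = tmm_factors(counts)
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for all genes")
    lib_sizes = counts.sum(axis=0)
    eff = lib_sizes * factors.reindex(counts.columns)
    return 1e9 * counts.div(lengths, axis=0).div(eff, axis=1)
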