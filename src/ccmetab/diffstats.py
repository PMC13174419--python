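"""Two-group differential statistics.

Per-metabolite comparisons use Welch's unequal-variance t test,
two-sided, with the Welch-Satterthwaite degrees of freedom.  P values
are reported unadjusted (a Benjamini-Hochberg column is provided for
convenience but never drives the significance flag).  Row z-scoring
and log2 fold changes support heatmap-style displays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import IntensityMatrix

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NS = "ns"


def welch_arrays(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch t statistic, Welch-Satterthwaite df and two-sided p for
    treatment sample ``y`` against reference sample ``x``.

    Degenerate inputs (both groups zero-variance) map to p = 1 when
    the means are equal and p = 0 otherwise, with t/df returned as NaN.
    Groups with fewer than two values yield all-NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        return np.nan, np.nan, np.nan
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        p = 1.0 if np.isclose(y.mean(), x.mean()) else 0.0
        return np.nan, np.nan, p
    res = stats.ttest_ind(y, x, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def welch_test(matrix: IntensityMatrix, reference: str, treatment: str,
               alpha: float = 0.05) -> pd.DataFrame:
    """Per-metabolite Welch test of treatment vs reference.

    Returns a DataFrame indexed by metabolite with columns
    ``kegg_id`` (when annotated), ``mean_ref``, ``mean_treat``,
    ``delta`` (treatment - reference), ``t``, ``df``, ``p``, ``p_bh``,
    ``significant`` (unadjusted p < alpha), ``direction``
    (up/down/ns) and ``degenerate``.

    Metabolites with fewer than two observed values in either group
    get ``p = NaN`` and direction ``ns``.
    """
    ref_samples = matrix.samples_in(reference)
    trt_samples = matrix.samples_in(treatment)

    records = []
    for met in matrix.metabolite_ids:
        x = matrix.values.loc[met, ref_samples].to_numpy(dtype=float)
        y = matrix.values.loc[met, trt_samples].to_numpy(dtype=float)
        xo = x[~np.isnan(x)]
        yo = y[~np.isnan(y)]
        mean_ref = xo.mean() if xo.size else np.nan
        mean_trt = yo.mean() if yo.size else np.nan
        t, df, p = welch_arrays(x, y)
        degenerate = bool(np.isnan(t) and not np.isnan(p))
        delta = mean_trt - mean_ref if (xo.size and yo.size) else np.nan
        significant = bool(p < alpha) if not np.isnan(p) else False
        if not significant:
            direction = DIRECTION_NS
        else:
            direction = DIRECTION_UP if delta > 0 else DIRECTION_DOWN
        records.append((met, mean_ref, mean_trt, delta, t, df, p, significant,
                        direction, degenerate))

    out = pd.DataFrame.from_records(
        records,
        columns=["metabolite", "mean_ref", "mean_treat", "delta", "t", "df",
                 "p", "significant", "direction", "degenerate"],
    ).set_index("metabolite")
    out["p_bh"] = benjamini_hochberg(out["p"].to_numpy())
    if matrix.kegg_ids is not None:
        out.insert(0, "kegg_id", matrix.kegg_ids.reindex(out.index))
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p values; NaNs pass through untouched."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = stats.false_discovery_control(p[ok], method="bh")
    return out


def row_zscore(matrix: IntensityMatrix) -> tuple[IntensityMatrix, list[str]]:
    """Z-score each metabolite row across samples ((x - mean) / sd,
    sd with n-1), as used for row-scaled heatmap displays.

    Requires a complete (imputed) matrix.  Constant rows are emitted
    as all-zero and returned in the flagged list.
    """
    if matrix.missing_mask().to_numpy().any():
        raise ValueError("row_zscore requires a complete matrix (impute first)")
    vals = matrix.values.to_numpy(dtype=float)
    means = vals.mean(axis=1, keepdims=True)
    sds = vals.std(axis=1, ddof=1, keepdims=True)
    constant = (sds[:, 0] == 0.0)
    safe_sds = np.where(sds == 0.0, 1.0, sds)
    z = (vals - means) / safe_sds
    z[constant, :] = 0.0
    flagged = [m for m, c in zip(matrix.metabolite_ids, constant) if c]
    out = matrix.with_values(
        pd.DataFrame(z, index=matrix.values.index, columns=matrix.values.columns),
        note=f"row z-score ({len(flagged)} constant rows zeroed)",
    )
    return out, flagged


def log2_fold_change(matrix_raw: IntensityMatrix, reference: str,
                     treatment: str) -> pd.Series:
    """log2 of the treatment/reference group-mean ratio on raw scale."""
    matrix_raw.require_scale("raw")
    ref = matrix_raw.values[matrix_raw.samples_in(reference)].mean(axis=1, skipna=True)
    trt = matrix_raw.values[matrix_raw.samples_in(treatment)].mean(axis=1, skipna=True)
    bad = (ref <= 0) | (trt <= 0) | ref.isna() | trt.isna()
    if bad.any():
        raise ValueError(
            f"non-positive or undefined group mean for metabolite "
            f"{bad.index[bad][0]!r}; log2 fold change undefined"
        )
    return pd.Series(np.log2(trt / ref), index=matrix_raw.values.index,
                     name="log2_fc")
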