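"""Steady-state preprocessing chain for targeted LC-MS peak areas.

The canonical order is: missingness filter -> KEGG mapping -> duplicate
resolution -> log transform -> QRILC imputation -> per-sample median
centering.  Both the imputed (pre-median) matrix, which feeds pathway
enrichment, and the median-centered matrix, used for display-oriented
relative abundance, are exposed.

QRILC (quantile regression imputation of left-censored data) treats
missing values as below a per-sample limit of detection.  For each
sample column it estimates the mean and sd of the full, uncensored
log-intensity distribution by regressing the sorted observed values on
standard-normal quantiles of their plotting positions, then draws each
missing value from that normal truncated above at the estimated
censoring point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import IntensityMatrix, LOG_SCALES

logger = logging.getLogger(__name__)

#: plotting-position margin for the quantile grid
QRILC_EPS = 1e-3
#: minimum observed fraction per sample for a stable quantile fit
QRILC_MIN_OBSERVED = 0.3


@dataclass
class QrilcModel:
    """Per-sample parameters estimated by QRILC, kept for audit.

    ``mu`` and ``sigma`` are the estimated mean/sd of the uncensored
    log-intensity distribution; ``p_obs`` the observed fraction;
    ``censor_point`` the estimated limit of detection
    mu + sigma * Phi^-1(1 - p_obs).
    """

    mu: pd.Series
    sigma: pd.Series
    p_obs: pd.Series
    censor_point: pd.Series
    tune_sigma: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mu": self.mu, "sigma": self.sigma, "p_obs": self.p_obs,
            "censor_point": self.censor_point,
        }).rename_axis("sample")


def filter_missingness(matrix: IntensityMatrix, tau: float) -> IntensityMatrix:
    """Keep a metabolite iff its missing fraction is strictly below
    ``tau`` in at least one condition.

    The inequality is strict: a metabolite missing exactly
    ``tau`` in every condition is removed.
    """
    matrix.require_scale("raw", *LOG_SCALES)
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    conditions = matrix.conditions()
    if len(conditions) < 2:
        raise ValueError("missingness filter requires >= 2 conditions")
    missing = matrix.missing_mask()
    keep = pd.Series(False, index=matrix.values.index)
    for cond in conditions:
        samples = matrix.samples_in(cond)
        if not samples:
            raise ValueError(f"condition {cond!r} has zero samples")
        frac = missing[samples].mean(axis=1)
        keep |= frac < tau
    out = matrix.with_values(matrix.values.loc[keep])
    out.log(f"missingness filter tau={tau}: removed {int((~keep).sum())} of "
            f"{matrix.n_metabolites} metabolites")
    return out


def map_kegg(matrix: IntensityMatrix, id_map: pd.Series) -> IntensityMatrix:
    """Annotate metabolites with KEGG compound IDs and drop unmapped ones.

    Several metabolites may map to the same KEGG ID at this stage;
    duplicates are resolved later by :func:`deduplicate`.
    """
    kegg = id_map.reindex(matrix.values.index)
    mapped = kegg.notna()
    if not mapped.any():
        logger.warning("no metabolites mapped to KEGG IDs; empty matrix returned")
    out = matrix.with_values(matrix.values.loc[mapped])
    out.kegg_ids = kegg[mapped]
    dup_count = int(out.kegg_ids.duplicated(keep=False).sum())
    out.log(f"KEGG mapping: kept {int(mapped.sum())} of {matrix.n_metabolites} "
            f"metabolites ({dup_count} rows share a KEGG ID)")
    return out


def deduplicate(matrix: IntensityMatrix, rule: str = "higher_mean",
                normal_condition: str = "normal") -> IntensityMatrix:
    """Resolve metabolites sharing a KEGG compound ID to a single row.

    ``higher_mean`` keeps the row with the greatest mean over all
    observed values; ``lowest_variance_in_normal`` keeps the row with
    the smallest variance over observed values in the
    ``normal_condition`` samples.
    """
    if matrix.kegg_ids is None:
        raise ValueError("deduplicate requires KEGG annotations (run map_kegg first)")
    if rule == "higher_mean":
        score = matrix.values.mean(axis=1, skipna=True)
        best = pd.Series.idxmax
    elif rule == "lowest_variance_in_normal":
        normal_samples = matrix.samples_in(normal_condition)
        score = matrix.values[normal_samples].var(axis=1, ddof=1, skipna=True)
        best = pd.Series.idxmin
    else:
        raise ValueError(f"unknown dedup rule {rule!r}")
    n_observed = matrix.values.notna().sum(axis=1)

    def pick(idx):
        group_score = score.loc[idx]
        if group_score.notna().any():
            return best(group_score.dropna())
        # score undefined for every duplicate (too few observed values):
        # keep the row observed most often; first in matrix order on ties
        return n_observed.loc[idx].idxmax()

    keep_rows: list[str] = []
    for met, kid in matrix.kegg_ids.items():
        group = matrix.kegg_ids.index[matrix.kegg_ids == kid]
        if len(group) == 1:
            keep_rows.append(met)
        elif met == pick(group):
            keep_rows.append(met)
    out = matrix.with_values(matrix.values.loc[keep_rows])
    out.log(f"deduplicate rule={rule}: {matrix.n_metabolites} -> {out.n_metabolites} rows")
    return out


def log_transform(matrix: IntensityMatrix, base: str = "e",
                  zeros_as_missing: bool = True) -> IntensityMatrix:
    """Elementwise log of the raw intensities; missing stays missing.

    Raw zeros are below-LOD in practice for SRM peak areas, so by
    default they are converted to missing before the transform (the
    count is logged); with ``zeros_as_missing=False`` an observed zero
    or negative value is a hard error naming the cell.
    """
    matrix.require_scale("raw")
    if base not in ("e", "10"):
        raise ValueError("base must be 'e' or '10'")
    vals = matrix.values.copy()
    zero_mask = vals <= 0
    n_zero = int(zero_mask.sum().sum())
    if n_zero:
        if not zeros_as_missing:
            where = np.argwhere(zero_mask.to_numpy())
            i, j = where[0]
            raise ValueError(
                f"non-positive observed value at metabolite "
                f"{vals.index[i]!r}, sample {vals.columns[j]!r}"
            )
        vals = vals.mask(zero_mask)
    logged = np.log(vals) if base == "e" else np.log10(vals)
    out = matrix.with_values(logged, scale="log" if base == "e" else "log10")
    out.log(f"log transform base={base} ({n_zero} zeros treated as missing)")
    return out


def _fit_qrilc_column(observed: np.ndarray, p_obs: float) -> tuple[float, float]:
    """Estimate (mu, sigma) of the uncensored normal from the observed
    upper tail by least squares on the quantile-quantile line.

    The sorted observed values are paired with standard-normal
    quantiles of probabilities equally spaced from (1 - p_obs) + eps to
    1 - eps, one point per observed value.
    """
    obs = np.sort(observed)
    n = obs.size
    lo = (1.0 - p_obs) + QRILC_EPS
    hi = 1.0 - QRILC_EPS
    probs = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2.0])
    q = stats.norm.ppf(probs)
    sigma, mu = np.polyfit(q, obs, 1)
    return float(mu), float(sigma)


def impute_qrilc(matrix: IntensityMatrix, tune_sigma: float = 1.0,
                 seed: int = 0) -> tuple[IntensityMatrix, QrilcModel]:
    """Impute left-censored missing values column-by-column.

    Per sample: estimate (mu, sigma) of the uncensored log-intensity
    distribution from the observed quantiles, then draw each missing
    value independently from Normal(mu, tune_sigma * sigma) truncated
    above at the estimated censoring point
    ``mu + sigma * Phi^-1(1 - p_obs)``.

    Returns the completed matrix and the per-sample model for audit.
    Samples with fewer than 4 observed values, or with observed
    fraction below :data:`QRILC_MIN_OBSERVED`, are an error (filter
    more aggressively first).
    """
    matrix.require_scale(*LOG_SCALES)
    if tune_sigma <= 0:
        raise ValueError("tune_sigma must be positive")
    rng = np.random.default_rng(seed)
    vals = matrix.values.copy()
    mu_s, sd_s, pobs_s, cens_s = {}, {}, {}, {}
    for sample in vals.columns:
        col = vals[sample].to_numpy(dtype=float)
        obs_mask = ~np.isnan(col)
        n_obs = int(obs_mask.sum())
        p_obs = n_obs / col.size
        if n_obs < 4:
            raise ValueError(f"sample {sample!r} has only {n_obs} observed values (need >= 4)")
        if p_obs < QRILC_MIN_OBSERVED:
            raise ValueError(
                f"sample {sample!r} observed fraction {p_obs:.2f} below "
                f"{QRILC_MIN_OBSERVED}; apply a stronger missingness filter first"
            )
        mu, sigma = _fit_qrilc_column(col[obs_mask], p_obs)
        if sigma <= 0:
            raise ValueError(f"sample {sample!r}: non-positive estimated sd {sigma}")
        censor = mu + sigma * stats.norm.ppf(1.0 - p_obs)
        mu_s[sample], sd_s[sample] = mu, sigma
        pobs_s[sample], cens_s[sample] = p_obs, censor
        n_miss = col.size - n_obs
        if n_miss:
            width = tune_sigma * sigma
            b = (censor - mu) / width
            draws = stats.truncnorm.rvs(-np.inf, b, loc=mu, scale=width,
                                        size=n_miss, random_state=rng)
            col[~obs_mask] = draws
            vals[sample] = col

    model = QrilcModel(
        mu=pd.Series(mu_s), sigma=pd.Series(sd_s), p_obs=pd.Series(pobs_s),
        censor_point=pd.Series(cens_s), tune_sigma=tune_sigma, seed=seed,
    )
    out = matrix.with_values(vals)
    out.log(f"QRILC imputation tune_sigma={tune_sigma} seed={seed}")
    return out, model


def median_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Center each sample at its median (post-imputation, log scale).

    Metabolites at the sample median map to 0, below-median ones to
    negative values, above-median ones to positive values.
    """
    matrix.require_scale(*LOG_SCALES)
    if matrix.missing_mask().to_numpy().any():
        raise ValueError("median_normalize requires a complete matrix (impute first)")
    centered = matrix.values - matrix.values.median(axis=0)
    out = matrix.with_values(centered, scale="median_centered",
                             note="median centered per sample")
    return out


def preprocess_pipeline(matrix: IntensityMatrix, id_map: pd.Series, *,
                        tau: float = 0.2, dedup_rule: str = "higher_mean",
                        log_base: str = "e", tune_sigma: float = 1.0,
                        seed: int = 0,
                        normal_condition: str = "normal",
                        ) -> tuple[IntensityMatrix, IntensityMatrix, QrilcModel]:
    """Run the full chain filter -> map -> dedup -> log -> impute ->
    median-center.

    Returns ``(imputed, median_centered, model)``: the imputed
    (pre-median) matrix feeds enrichment and differential testing; the
    median-centered one is for display-oriented relative abundance.
    """
    m = filter_missingness(matrix, tau)
    m = map_kegg(m, id_map)
    m = deduplicate(m, dedup_rule, normal_condition=normal_condition)
    m = log_transform(m, base=log_base)
    imputed, model = impute_qrilc(m, tune_sigma=tune_sigma, seed=seed)
    centered = median_normalize(imputed)
    return imputed, centered, model
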