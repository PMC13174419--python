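"""Cross-dataset pathway comparison.

Given a reference (e.g. fly tumor) enrichment profile and one or more
comparison studies (e.g. human cancer panels), this module computes
(1) the overlap of top-k enriched pathways, including how many of the
reference's top pathways recur in at least t of the studies for every
threshold t, and (2) direction concordance of the differential-
abundance scores on the shared pathways, with a permutation null for
the observed concordant fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SharedEnrichment:
    """Top-k overlap between a reference study and comparison studies."""

    #: per comparison study, the shared pathway names in reference rank order
    shared: dict[str, list[str]]
    #: count of reference-top pathways shared with >= t studies, for t=1..n
    count_at_threshold: dict[int, int]

    @property
    def count(self) -> int:
        """Reference-top pathways recurring in at least one study."""
        return self.count_at_threshold.get(1, 0)


def shared_enriched(ref_top: list[str],
                    study_tops: dict[str, list[str]] | list[list[str]]) -> SharedEnrichment:
    """Intersect the reference top-k pathway list with each study's.

    ``count_at_threshold[t]`` reports how many reference-top pathways
    appear in the top list of at least ``t`` studies; displays default
    to t = 1 ("recurs in at least one study").
    """
    if not ref_top:
        raise ValueError("reference top pathway list is empty")
    if not isinstance(study_tops, dict):
        study_tops = {f"study_{i + 1}": top for i, top in enumerate(study_tops)}
    shared = {
        study: [p for p in ref_top if p in set(top)]
        for study, top in study_tops.items()
    }
    n_studies = len(study_tops)
    hits = {p: sum(p in set(top) for top in study_tops.values()) for p in ref_top}
    count_at_threshold = {
        t: sum(1 for p in ref_top if hits[p] >= t) for t in range(1, n_studies + 1)
    }
    return SharedEnrichment(shared=shared, count_at_threshold=count_at_threshold)


def _signs(da: pd.DataFrame, pathways: list[str], label: str) -> pd.Series:
    missing = [p for p in pathways if p not in da.index]
    if missing:
        raise ValueError(f"shared pathway {missing[0]!r} missing from {label} DA table")
    if "defined" in da.columns:
        undef = [p for p in pathways if not bool(da.loc[p, "defined"])]
        if undef:
            raise ValueError(f"shared pathway {undef[0]!r} has undefined DA score in {label}")
    return np.sign(da.loc[pathways, "score"]).astype(int)


@dataclass
class ConcordanceResult:
    """Direction agreement of DA scores on shared pathways."""

    #: long table: study, pathway, ref_sign, study_sign, concordant, counted
    table: pd.DataFrame
    #: per-study concordant fraction (NaN when no countable pathway)
    per_study: pd.Series
    #: pooled concordant fraction over all (study, pathway) pairs
    pooled: float
    #: (study, pathway) pairs excluded because either sign is 0
    zero_sign: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_concordant(self) -> int:
        return int(self.table["concordant"].sum())

    @property
    def n_counted(self) -> int:
        return int(self.table["counted"].sum())


def concordance(ref_da: pd.DataFrame,
                study_das: dict[str, pd.DataFrame] | pd.DataFrame,
                shared: dict[str, list[str]] | list[str]) -> ConcordanceResult:
    """Fraction of shared pathways whose DA direction agrees.

    A (study, pathway) pair is concordant iff
    ``sign(S_ref) == sign(S_study) != 0``; pairs where either sign is 0
    are excluded from the denominator and listed in ``zero_sign``.
    Accepts a single study (DataFrame + name list) or a panel
    (dict study -> DA table, dict study -> shared names).
    """
    if isinstance(study_das, pd.DataFrame):
        study_das = {"study": study_das}
        shared = {"study": list(shared)}
    assert isinstance(shared, dict)

    rows = []
    zero_sign: list[tuple[str, str]] = []
    for study, da in study_das.items():
        names = shared[study]
        if not names:
            continue
        ref_signs = _signs(ref_da, names, "reference")
        st_signs = _signs(da, names, study)
        for p in names:
            rs, ss = int(ref_signs[p]), int(st_signs[p])
            counted = rs != 0 and ss != 0
            conc = counted and rs == ss
            if not counted:
                zero_sign.append((study, p))
            rows.append((study, p, rs, ss, conc, counted))

    table = pd.DataFrame(
        rows, columns=["study", "pathway", "ref_sign", "study_sign",
                       "concordant", "counted"],
    )
    if len(table):
        per_study = (
            table[table["counted"]].groupby("study")["concordant"].mean()
            .reindex(sorted(study_das))
        )
        n_counted = int(table["counted"].sum())
        pooled = float(table["concordant"].sum() / n_counted) if n_counted else np.nan
    else:
        per_study = pd.Series(dtype=float)
        pooled = np.nan
    return ConcordanceResult(table=table, per_study=per_study, pooled=pooled,
                             zero_sign=zero_sign)


def concordance_permutation_null(ref_da: pd.DataFrame, study_da: pd.DataFrame,
                                 shared: list[str], n_perm: int = 1000,
                                 seed: int = 0) -> tuple[np.ndarray, float]:
    """Permutation reference for an observed concordant fraction.

    The study's DA signs are permuted across all its (defined)
    pathways ``n_perm`` times; the empirical p is
    ``(1 + #{c_perm >= c_obs}) / (1 + n_perm)``.

    Returns (null concordant fractions, p).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    obs = concordance(ref_da, study_da, shared)
    c_obs = obs.pooled

    if "defined" in study_da.columns:
        pool_signs = np.sign(study_da.loc[study_da["defined"], "score"]).to_numpy(dtype=int)
    else:
        pool_signs = np.sign(study_da["score"]).to_numpy(dtype=int)
    ref_signs = _signs(ref_da, shared, "reference").to_numpy()

    if len(set(pool_signs)) == 1:
        logger.warning("all study DA signs identical; permutation null is degenerate, p = 1")
        return np.full(n_perm, np.nan), 1.0

    n = len(shared)
    null = np.empty(n_perm, dtype=float)
    for b in range(n_perm):
        perm = rng.permutation(pool_signs)[:n]
        counted = (ref_signs != 0) & (perm != 0)
        n_counted = int(counted.sum())
        null[b] = ((ref_signs == perm) & counted).sum() / n_counted if n_counted else np.nan
    valid = null[~np.isnan(null)]
    p = float((1 + np.sum(valid >= c_obs)) / (1 + valid.size))
    return null, p
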