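"""Pathway-level summaries of a differential result.

Two complementary views:

* over-representation analysis (ORA): a hypergeometric upper-tail test
  of whether a pathway's measured members are enriched among the
  alpha-significant metabolites, against the background of all tested,
  KEGG-mapped metabolites;

* the differential-abundance (DA) score
  ``S = (U - D) / T`` with U/D the counts of members significantly
  up/down and T the members measured, summarizing the net direction of
  metabolite changes within a pathway on the scale [-1, 1].
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import PathwaySet
from .diffstats import DIRECTION_DOWN, DIRECTION_UP

logger = logging.getLogger(__name__)


def _measured_kegg(diff: pd.DataFrame) -> pd.Series:
    if "kegg_id" not in diff.columns:
        raise ValueError("differential table lacks a kegg_id column; run map_kegg first")
    kegg = diff["kegg_id"].dropna()
    return kegg


def hypergeom_upper_tail(k: int, m: int, K: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N population, K marked, m drawn)."""
    if K == 0 or k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, m))


def ora(diff: pd.DataFrame, pathways: list[PathwaySet], alpha: float = 0.05,
        min_members: int = 2) -> pd.DataFrame:
    """Hypergeometric over-representation per pathway.

    Returns a DataFrame indexed by pathway, sorted ascending by p with
    ties broken by descending enrichment ratio then name, with columns
    ``k`` (significant measured members), ``m`` (measured members),
    ``K`` (total significant metabolites), ``N`` (background size),
    ``p`` (upper tail P[X >= k]), ``ratio`` ((k/m)/(K/N)) and
    ``rank`` (1-based).
    """
    kegg = _measured_kegg(diff)
    measured = set(kegg)
    N = len(measured)
    sig_mask = diff["significant"].reindex(kegg.index).astype(bool)
    significant = set(kegg[sig_mask])
    K = len(significant)
    if K == 0:
        logger.warning("no significant metabolites at alpha=%s; all ORA p = 1", alpha)

    rows = []
    for pw in pathways:
        members = pw.members & measured
        m = len(members)
        if m < min_members:
            continue
        k = len(members & significant)
        p = hypergeom_upper_tail(k, m, K, N)
        ratio = (k / m) / (K / N) if K > 0 else 0.0
        rows.append((pw.name, k, m, K, N, p, ratio))
    out = pd.DataFrame(rows, columns=["pathway", "k", "m", "K", "N", "p", "ratio"])
    out = out.sort_values(["p", "ratio", "pathway"],
                          ascending=[True, False, True],
                          kind="mergesort").set_index("pathway")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def da_score(diff: pd.DataFrame, pathways: list[PathwaySet],
             alpha: float | None = None) -> pd.DataFrame:
    """Differential-abundance score S = (U - D) / T per pathway.

    U and D are counted from the direction flags of the differential
    table (significance at unadjusted p < alpha); T is the number of
    pathway members measured.  Pathways with T = 0 are emitted with
    ``defined = False`` and NaN score, and are excluded from
    concordance downstream.

    ``alpha`` recomputes the flags at a different level; by default the
    flags already present in ``diff`` are used.
    """
    kegg = _measured_kegg(diff)
    measured = set(kegg)
    d = diff.loc[kegg.index]
    if alpha is not None:
        sig = d["p"] < alpha
        direction = np.where(~sig, "ns",
                             np.where(d["delta"] > 0, DIRECTION_UP, DIRECTION_DOWN))
        direction = pd.Series(direction, index=d.index)
    else:
        direction = d["direction"]
    up_ids = set(kegg[direction == DIRECTION_UP])
    down_ids = set(kegg[direction == DIRECTION_DOWN])

    rows = []
    for pw in pathways:
        members = pw.members & measured
        T = len(members)
        U = len(members & up_ids)
        D = len(members & down_ids)
        score = (U - D) / T if T > 0 else np.nan
        rows.append((pw.name, U, D, T, score, T > 0))
    return pd.DataFrame(
        rows, columns=["pathway", "n_up", "n_down", "n_measured", "score", "defined"],
    ).set_index("pathway")


def top_k_pathways(results: pd.DataFrame, k: int) -> list[str]:
    """First min(k, len) pathway names of an ORA table in rank order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = results.sort_values("rank") if "rank" in results.columns else results
    return list(ordered.index[:k])
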