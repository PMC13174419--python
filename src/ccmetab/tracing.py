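"""¹³C isotopologue distribution analysis.

From long-format protein-normalized isotopologue peak areas this
module derives, per (metabolite, sample):

* the fractional labeling vector ``f_i = area_i / sum_j area_j``;
* the labeled fraction ``L = 1 - f_0`` (share of the pool carrying any
  heavy carbon);
* the mean enrichment ``E = sum_i i * f_i / n_max`` (average fraction
  of carbon positions that are ¹³C, normalized by the metabolite's
  carbon capacity so it is comparable across metabolites);
* the total pool ``P = sum_j area_j``.

Group comparisons (Welch's two-sided t test, applied independently to
each isotopologue, unadjusted) are provided on raw pools and on
fractions, and an enrichment-discontinuity score locates the edge of
an ordered pathway chain where mean enrichment drops most — the
signature of a drain/bottleneck node whose product is markedly less
labeled than its precursor.

No natural-abundance correction is applied: analyses operate on raw
SRM isotopologue areas.  Mass shifts absent from the input are treated
as zero area (SRM transitions not monitored contribute nothing to the
pool); the count of such filled channels is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import IsotopologueTable
from .diffstats import DIRECTION_DOWN, DIRECTION_UP, welch_arrays

logger = logging.getLogger(__name__)


@dataclass
class FractionalLabeling:
    """Per-(metabolite, sample) labeling fractions and summaries.

    ``fractions``: long DataFrame (metabolite, sample, mass_shift, f).
    ``summary``: one row per (metabolite, sample) with columns
    ``labeled_fraction`` (L), ``mean_enrichment`` (E), ``pool`` (P) and
    ``defined`` (False when P = 0, in which case the record is
    excluded from tests).
    """

    fractions: pd.DataFrame
    summary: pd.DataFrame
    condition: pd.Series
    n_max: dict[str, int]

    def wide(self, metabolite: str) -> pd.DataFrame:
        """Samples x mass-shift matrix of fractions for one metabolite."""
        sub = self.fractions[self.fractions["metabolite"] == metabolite]
        if sub.empty:
            raise ValueError(f"metabolite {metabolite!r} not present")
        return sub.pivot(index="sample", columns="mass_shift", values="f")


def fractional_labeling(table: IsotopologueTable) -> FractionalLabeling:
    """Compute fractions, labeled fraction, mean enrichment and pool.

    Mass shifts 0..n_max missing from the input are filled with zero
    area before normalization.  Records with a zero total pool are
    flagged undefined rather than raising.
    """
    filled_channels = 0
    frac_rows, summary_rows = [], []
    for (met, sample), grp in table.data.groupby(["metabolite", "sample"], sort=False):
        cap = table.n_max[str(met)]
        areas = np.zeros(cap + 1, dtype=float)
        areas[grp["mass_shift"].to_numpy(dtype=int)] = grp["area"].to_numpy(dtype=float)
        filled_channels += (cap + 1) - len(grp)
        pool = areas.sum()
        if pool > 0:
            f = areas / pool
            labeled = 1.0 - f[0]
            enrich = float(np.dot(np.arange(cap + 1), f)) / cap if cap > 0 else 0.0
            defined = True
        else:
            f = np.full(cap + 1, np.nan)
            labeled = enrich = np.nan
            defined = False
        for i in range(cap + 1):
            frac_rows.append((met, sample, i, f[i]))
        summary_rows.append((met, sample, labeled, enrich, pool, defined))
    if filled_channels:
        logger.info("filled %d unmonitored isotopologue channels with zero area",
                    filled_channels)

    fractions = pd.DataFrame(frac_rows,
                             columns=["metabolite", "sample", "mass_shift", "f"])
    summary = pd.DataFrame(
        summary_rows,
        columns=["metabolite", "sample", "labeled_fraction", "mean_enrichment",
                 "pool", "defined"],
    )
    ok = summary.loc[summary["defined"]]
    if len(ok):
        sums = fractions.merge(ok[["metabolite", "sample"]], on=["metabolite", "sample"])
        total = sums.groupby(["metabolite", "sample"])["f"].sum()
        assert np.allclose(total.to_numpy(), 1.0, atol=1e-9), \
            "fraction vectors must sum to 1"
    return FractionalLabeling(fractions=fractions, summary=summary,
                              condition=table.condition, n_max=dict(table.n_max))


def _welch_row(x: np.ndarray, y: np.ndarray, alpha: float):
    t, df, p = welch_arrays(x, y)
    xo, yo = x[~np.isnan(x)], y[~np.isnan(y)]
    mean_ref = xo.mean() if xo.size else np.nan
    mean_trt = yo.mean() if yo.size else np.nan
    delta = mean_trt - mean_ref
    if np.isnan(p) or p >= alpha:
        direction = "ns"
    else:
        direction = DIRECTION_UP if delta > 0 else DIRECTION_DOWN
    return mean_ref, mean_trt, delta, t, df, p, direction


def pool_partition(table: IsotopologueTable, reference: str, treatment: str,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Compare M+0, total labeled (sum over M+n, n >= 1) and each
    individual isotopologue pool between conditions.

    One row per (metabolite, quantity) where quantity is ``M+0``,
    ``labeled`` or ``M+i``; Welch two-sided p per quantity, unadjusted.
    """
    ref_samples = table.samples_in(reference)
    trt_samples = table.samples_in(treatment)
    if len(ref_samples) < 2 or len(trt_samples) < 2:
        raise ValueError("need >= 2 replicates per condition")

    rows = []
    for met, grp in table.data.groupby("metabolite", sort=False):
        cap = table.n_max[str(met)]
        wide = grp.pivot(index="sample", columns="mass_shift", values="area")
        wide = wide.reindex(columns=range(cap + 1), fill_value=0.0).fillna(0.0)
        quantities = {"M+0": wide[0], "labeled": wide[[i for i in range(1, cap + 1)]].sum(axis=1)}
        for i in range(cap + 1):
            quantities[f"M+{i}"] = wide[i]
        for qname, series in quantities.items():
            x = series.reindex(ref_samples).to_numpy(dtype=float)
            y = series.reindex(trt_samples).to_numpy(dtype=float)
            rows.append((met, qname, *_welch_row(x, y, alpha)))
    return pd.DataFrame(
        rows, columns=["metabolite", "quantity", "mean_ref", "mean_treat",
                       "delta", "t", "df", "p", "direction"],
    )


def fraction_test(fl: FractionalLabeling, reference: str, treatment: str,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Welch tests on each labeling fraction f_i and on the labeled
    fraction L, per metabolite.

    The returned table has one row per (metabolite, quantity) with
    quantity ``f_i`` for each mass shift or ``L``, plus a per-
    metabolite ``reciprocal`` flag set when f_0 is significantly down
    while some f_{i>=1} is significantly up (the reciprocal shift from
    the unlabeled into labeled species expected under increased tracer
    incorporation).
    """
    cond = fl.condition
    ref_samples = [s for s in cond.index[cond == reference]]
    trt_samples = [s for s in cond.index[cond == treatment]]
    if not ref_samples or not trt_samples:
        missing = reference if not ref_samples else treatment
        raise ValueError(f"unknown or empty condition {missing!r}")

    defined = fl.summary[fl.summary["defined"]]
    rows = []
    for met in pd.unique(fl.summary["metabolite"]):
        ok = defined[defined["metabolite"] == met]
        ok_ref = [s for s in ref_samples if s in set(ok["sample"])]
        ok_trt = [s for s in trt_samples if s in set(ok["sample"])]
        if len(ok_ref) < 2 or len(ok_trt) < 2:
            logger.warning("metabolite %r: insufficient defined replicates; skipped", met)
            continue
        wide = fl.wide(met)
        for i in wide.columns:
            x = wide[i].reindex(ok_ref).to_numpy(dtype=float)
            y = wide[i].reindex(ok_trt).to_numpy(dtype=float)
            rows.append((met, f"f_{i}", *_welch_row(x, y, alpha)))
        lab = ok.set_index("sample")["labeled_fraction"]
        x = lab.reindex(ok_ref).to_numpy(dtype=float)
        y = lab.reindex(ok_trt).to_numpy(dtype=float)
        rows.append((met, "L", *_welch_row(x, y, alpha)))

    out = pd.DataFrame(
        rows, columns=["metabolite", "quantity", "mean_ref", "mean_treat",
                       "delta", "t", "df", "p", "direction"],
    )
    flags = {}
    for met, grp in out.groupby("metabolite", sort=False):
        f0_down = ((grp["quantity"] == "f_0") & (grp["direction"] == DIRECTION_DOWN)).any()
        fi_up = (grp["quantity"].str.startswith("f_")
                 & (grp["quantity"] != "f_0")
                 & (grp["direction"] == DIRECTION_UP)).any()
        flags[met] = bool(f0_down and fi_up)
    out["reciprocal"] = out["metabolite"].map(flags)
    return out


@dataclass
class ChainDiscontinuity:
    """Enrichment drop-offs along an ordered pathway chain."""

    chain: list[str]
    #: mean enrichment per chain metabolite (replicate average)
    enrichment: pd.Series
    #: labeled fraction per chain metabolite, for reference
    labeled_fraction: pd.Series
    #: d_j = E(m_j) - E(m_{j+1}) for each edge j (1-based), positive
    #: when the precursor is more enriched than its product
    edge_scores: pd.Series
    #: 1-based index of the maximal positive edge, or None if no d_j > 0
    argmax_edge: int | None
    #: bootstrap percentile CI (2.5%, 97.5%) for the argmax edge score
    ci: tuple[float, float] | None


def enrichment_discontinuity(fl: FractionalLabeling, chain: list[str],
                             condition: str, n_boot: int = 1000,
                             seed: int = 0) -> ChainDiscontinuity:
    """Score enrichment drops along an ordered metabolite chain.

    For consecutive chain members the edge score is
    ``d_j = E(m_j) - E(m_{j+1})`` with E averaged over the replicates
    of ``condition``; a large positive d_j marks a candidate
    discontinuity (carbon entering m_j fails to propagate into
    m_{j+1}).  A bootstrap over replicates gives a percentile CI for
    the maximal edge.
    """
    if len(chain) < 2:
        raise ValueError("chain needs >= 2 metabolites")
    cond = fl.condition
    samples = [s for s in cond.index[cond == condition]]
    if not samples:
        raise ValueError(f"unknown or empty condition {condition!r}")
    defined = fl.summary[fl.summary["defined"]]

    per_rep: dict[str, pd.Series] = {}
    for met in chain:
        sub = defined[(defined["metabolite"] == met)
                      & (defined["sample"].isin(samples))]
        if len(sub) < 2:
            raise ValueError(
                f"chain metabolite {met!r} lacks >= 2 defined replicates "
                f"in condition {condition!r}"
            )
        per_rep[met] = sub.set_index("sample")["mean_enrichment"]

    enrichment = pd.Series({m: per_rep[m].mean() for m in chain}, name="E")
    lab = {m: defined[(defined["metabolite"] == m)
                      & (defined["sample"].isin(samples))]["labeled_fraction"].mean()
           for m in chain}
    labeled = pd.Series(lab, name="L")
    d = pd.Series(
        {j + 1: enrichment.iloc[j] - enrichment.iloc[j + 1]
         for j in range(len(chain) - 1)},
        name="d",
    )
    if (d > 0).any():
        argmax = int(d.idxmax())
    else:
        argmax = None

    ci = None
    if argmax is not None and n_boot > 0:
        rng = np.random.default_rng(seed)
        a = per_rep[chain[argmax - 1]].to_numpy(dtype=float)
        b = per_rep[chain[argmax]].to_numpy(dtype=float)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            boots[i] = (rng.choice(a, size=a.size).mean()
                        - rng.choice(b, size=b.size).mean())
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    return ChainDiscontinuity(chain=list(chain), enrichment=enrichment,
                              labeled_fraction=labeled, edge_scores=d,
                              argmax_edge=argmax, ci=ci)
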