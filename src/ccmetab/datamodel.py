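"""Core in-memory containers for the pipeline.

The central object is :class:`IntensityMatrix`, a metabolites x samples
table of protein-normalized peak areas with explicit missingness (NaN),
a per-sample condition factor, optional KEGG compound annotations, a
scale state (raw / log / log10 / median_centered) and a free-text
provenance log.  Missing is always distinct from zero: a zero peak area
is a legitimate measurement, whereas NaN means below the limit of
detection (or not acquired).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

#: allowed scale states, in pipeline order (raw -> log -> median_centered)
SCALES = ("raw", "log", "log10", "median_centered")
_SCALE_RANK = {"raw": 0, "log": 1, "log10": 1, "median_centered": 2}

LOG_SCALES = ("log", "log10")


class ScaleError(ValueError):
    """An operation was applied to a matrix on the wrong scale."""


@dataclass
class IntensityMatrix:
    """Metabolite x sample abundance table with explicit missingness.

    Parameters
    ----------
    values
        DataFrame indexed by metabolite ID with sample IDs as columns.
        ``NaN`` encodes a missing (below-LOD / unobserved) cell.
    condition
        Series mapping every sample ID to its condition label (a
        two-level reference/treatment factor, possibly with extra
        levels such as ``"normal"``).
    kegg_ids
        Optional Series mapping metabolite ID to a KEGG compound ID.
        ``None`` before annotation.
    scale
        One of :data:`SCALES`.
    provenance
        Append-only list of processing-log entries.
    """

    values: pd.DataFrame
    condition: pd.Series
    kegg_ids: pd.Series | None = None
    scale: str = "raw"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ScaleError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        missing_meta = [s for s in self.values.columns if s not in self.condition.index]
        if missing_meta:
            raise ValueError(
                f"samples without a condition label: {', '.join(map(str, missing_meta))}"
            )
        self.condition = self.condition.reindex(self.values.columns)
        if self.scale == "raw":
            vals = self.values.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError("raw-scale intensities must be >= 0 or missing")
        if self.kegg_ids is not None and not self.kegg_ids.index.equals(self.values.index):
            self.kegg_ids = self.kegg_ids.reindex(self.values.index)

    # -- basic accessors -------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def conditions(self) -> list[str]:
        return list(pd.unique(self.condition))

    def samples_in(self, condition: str) -> list[str]:
        sel = self.condition[self.condition == condition]
        if sel.empty:
            raise ValueError(f"unknown condition label {condition!r}")
        return list(sel.index)

    # -- state management ------------------------------------------------

    def require_scale(self, *allowed: str) -> None:
        if self.scale not in allowed:
            raise ScaleError(
                f"operation requires scale in {allowed}, matrix is {self.scale!r}"
            )

    def with_values(self, values: pd.DataFrame, *, scale: str | None = None,
                    note: str | None = None) -> "IntensityMatrix":
        """Return a copy carrying new values (and optionally a new scale).

        Scale transitions must be monotone along the pipeline
        (raw -> log -> median_centered); going backwards is rejected.
        """
        new_scale = self.scale if scale is None else scale
        if _SCALE_RANK[new_scale] < _SCALE_RANK[self.scale]:
            raise ScaleError(
                f"scale may not move backwards ({self.scale!r} -> {new_scale!r})"
            )
        kegg = None
        if self.kegg_ids is not None:
            kegg = self.kegg_ids.reindex(values.index)
        out = IntensityMatrix(
            values=values,
            condition=self.condition.copy(),
            kegg_ids=kegg,
            scale=new_scale,
            provenance=list(self.provenance),
        )
        if note:
            out.log(note)
        return out

    def log(self, message: str) -> None:
        """Append a provenance entry."""
        self.provenance.append(message)

    def copy(self) -> "IntensityMatrix":
        return replace(
            self,
            values=self.values.copy(),
            condition=self.condition.copy(),
            kegg_ids=None if self.kegg_ids is None else self.kegg_ids.copy(),
            provenance=list(self.provenance),
        )


@dataclass(frozen=True)
class PathwaySet:
    """A named set of KEGG compound IDs."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.name!r} has no members")


@dataclass
class AnalysisConfig:
    """Tunable parameters shared across pipeline stages.

    missingness_threshold
        Fraction tau in (0, 1); a metabolite is kept iff its missing
        fraction is strictly below tau in at least one condition.
    significance_level
        Two-sided alpha for per-metabolite tests (unadjusted).
    top_k
        Number of top-ranked pathways used for cross-study overlap.
    dedup_rule
        How duplicate KEGG mappings are resolved: ``"higher_mean"``
        (keep the row with the greater mean over all observed values)
        or ``"lowest_variance_in_normal"`` (keep the row with the
        smallest variance over observed values in the normal samples).
    qrilc_tune_sigma
        Multiplier on the estimated sd when drawing imputed values.
    """

    missingness_threshold: float = 0.2
    significance_level: float = 0.05
    top_k: int = 16
    dedup_rule: str = "higher_mean"
    seed: int = 0
    qrilc_tune_sigma: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.missingness_threshold < 1.0:
            raise ValueError("missingness_threshold must be in (0, 1)")
        if not 0.0 < self.significance_level < 1.0:
            raise ValueError("significance_level must be in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.dedup_rule not in ("higher_mean", "lowest_variance_in_normal"):
            raise ValueError(f"unknown dedup_rule {self.dedup_rule!r}")
        if self.qrilc_tune_sigma <= 0:
            raise ValueError("qrilc_tune_sigma must be positive")


@dataclass
class SyntheticTruth:
    """Planted parameters of a simulated dataset; the downstream oracle.

    Attributes
    ----------
    effect
        Per-metabolite log-scale mean shift (treatment minus reference).
    pathway_assignment
        Metabolite ID -> pathway name.
    censor_quantile
        Per-sample left-censoring quantile q_c in [0, 1).
    labeling
        (metabolite, condition) -> true isotopologue probability vector
        pi_0..pi_n summing to 1.
    concordance_plan
        study name -> {pathway name -> planted direction (+1/-1)}.
    realized_concordant_fraction
        The fraction actually planted when the requested one is not
        exactly realizable with the given number of shared pathways.
    kegg_map
        Metabolite ID -> synthetic KEGG compound ID (metabolites
        deliberately left unannotated are absent).
    """

    seed: int
    effect: pd.Series | None = None
    pathway_assignment: dict[str, str] | None = None
    censor_quantile: float | None = None
    labeling: dict[tuple[str, str], np.ndarray] | None = None
    concordance_plan: dict[str, dict[str, int]] | None = None
    realized_concordant_fraction: float | None = None
    kegg_map: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.censor_quantile is not None and not 0.0 <= self.censor_quantile < 1.0:
            raise ValueError("censor_quantile must be in [0, 1)")
        if self.labeling is not None:
            for key, pi in self.labeling.items():
                pi = np.asarray(pi, dtype=float)
                if abs(pi.sum() - 1.0) > 1e-12:
                    raise ValueError(f"labeling vector for {key} does not sum to 1")
        if self.effect is not None and not np.all(np.isfinite(self.effect)):
            raise ValueError("planted effects must be finite")


@dataclass
class IsotopologueTable:
    """Long-format protein-normalized isotopologue peak areas.

    ``data`` holds one row per (metabolite, mass_shift, sample) with
    columns ``metabolite``, ``kegg_id``, ``mass_shift`` (integer M+n
    index, >= 0) and ``area`` (>= 0).  ``n_max`` gives each
    metabolite's carbon-backbone capacity; shifts beyond it are
    rejected.  ``condition`` maps sample -> condition label.
    """

    data: pd.DataFrame
    condition: pd.Series
    n_max: dict[str, int]

    REQUIRED = ("metabolite", "kegg_id", "mass_shift", "sample", "area")

    def __post_init__(self) -> None:
        missing_cols = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing_cols:
            raise ValueError(f"isotopologue table lacks columns: {missing_cols}")
        d = self.data
        if (d["area"] < 0).any():
            bad = d.loc[d["area"] < 0].iloc[0]
            raise ValueError(
                f"negative area for {bad['metabolite']} M+{bad['mass_shift']} "
                f"sample {bad['sample']}"
            )
        if (d["mass_shift"] < 0).any():
            raise ValueError("mass_shift must be >= 0")
        dup = d.duplicated(subset=["metabolite", "mass_shift", "sample"])
        if dup.any():
            bad = d.loc[dup].iloc[0]
            raise ValueError(
                f"duplicate record ({bad['metabolite']}, M+{bad['mass_shift']}, "
                f"{bad['sample']})"
            )
        for met, grp in d.groupby("metabolite", sort=False):
            cap = self.n_max.get(str(met))
            if cap is None:
                raise ValueError(f"no carbon capacity (n_max) for metabolite {met!r}")
            if int(grp["mass_shift"].max()) > cap:
                raise ValueError(
                    f"mass shift exceeds capacity n_max={cap} for metabolite {met!r}"
                )
        unknown = set(d["sample"]) - set(self.condition.index)
        if unknown:
            raise ValueError(
                f"samples without a condition label: {', '.join(sorted(map(str, unknown)))}"
            )

    @property
    def metabolites(self) -> list[str]:
        return list(pd.unique(self.data["metabolite"]))

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.data["sample"]))

    def samples_in(self, condition: str) -> list[str]:
        sel = self.condition[self.condition == condition]
        if sel.empty:
            raise ValueError(f"unknown condition label {condition!r}")
        return [s for s in sel.index if s in set(self.data["sample"])]
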