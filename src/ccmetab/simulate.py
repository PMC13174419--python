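"""Synthetic data generators with planted ground truth.

Three generators emulate the data shapes the pipeline consumes, so
every downstream stage has an oracle that requires no downloads:

* :func:`generate_steady_state` — an SRM-style peak-area matrix
  (default ~310 metabolites, mirroring a targeted polar-metabolite
  panel) with per-metabolite log-normal intensities, planted
  per-pathway condition shifts, and per-sample left censoring at a
  limit-of-detection quantile (the missingness mechanism QRILC
  assumes);
* :func:`generate_panel` — a multi-study panel (a reference study plus
  comparison "cancer panels") whose per-pathway differential
  directions realize a planted concordance plan;
* :func:`generate_tracing` — long-format isotopologue tables drawn
  from known true labeling-fraction vectors with multiplicative
  (log-normal) noise and per-replicate pool-size variation.

All generators are deterministic given their seed, and censoring is
strictly left-tailed: every censored cell's latent value lies below
every observed value in its sample.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    IntensityMatrix,
    IsotopologueTable,
    PathwaySet,
    SyntheticTruth,
)

DEFAULT_N_METABOLITES = 310
DEFAULT_PATHWAY_SIZE = 8


def _kegg_id(i: int) -> str:
    return f"C{i + 1:05d}"


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise with coefficient of
    variation ``cv`` (cv = 0 returns exact ones)."""
    if cv == 0:
        return np.ones(size)
    s = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def _assign_pathways(n_metabolites: int, pathway_names: Sequence[str],
                     pathway_size: int) -> dict[str, str]:
    """Assign metabolites met_0001.. to pathways block-wise; leftovers
    stay unassigned (measured but outside every pathway set)."""
    assignment: dict[str, str] = {}
    idx = 0
    for name in pathway_names:
        for _ in range(pathway_size):
            if idx >= n_metabolites:
                raise ValueError(
                    f"{len(pathway_names)} pathways of size {pathway_size} need "
                    f"{len(pathway_names) * pathway_size} metabolites, have {n_metabolites}"
                )
            assignment[f"met_{idx + 1:04d}"] = name
            idx += 1
    return assignment


def kegg_map_from_truth(truth: SyntheticTruth) -> pd.Series:
    if truth.kegg_map is None:
        raise ValueError("truth carries no KEGG map")
    return truth.kegg_map


def pathway_sets_from_truth(truth: SyntheticTruth) -> list[PathwaySet]:
    """Build GMT-style pathway sets (KEGG-ID members) from the planted
    metabolite -> pathway assignment."""
    if truth.pathway_assignment is None or truth.kegg_map is None:
        raise ValueError("truth lacks pathway assignment or KEGG map")
    members: dict[str, set[str]] = {}
    for met, pw in truth.pathway_assignment.items():
        kid = truth.kegg_map.get(met)
        if kid is not None and isinstance(kid, str):
            members.setdefault(pw, set()).add(kid)
    return [PathwaySet(name=n, members=frozenset(m))
            for n, m in sorted(members.items())]


def _simulate_matrix(rng: np.random.Generator, metabolite_ids: list[str],
                     effect: pd.Series, n_per_group: int, q_c: float,
                     conditions: tuple[str, str], baseline_mean: float,
                     baseline_sd: float, within_sd: float,
                     baseline_offset: pd.Series | None = None,
                     sd_scale: pd.Series | None = None) -> IntensityMatrix:
    """Core log-normal intensity model with per-sample left censoring."""
    n_met = len(metabolite_ids)
    reference, treatment = conditions
    samples = ([f"{reference}_{r + 1}" for r in range(n_per_group)]
               + [f"{treatment}_{r + 1}" for r in range(n_per_group)])
    condition = pd.Series([reference] * n_per_group + [treatment] * n_per_group,
                          index=samples, name="condition")

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_met)
    if baseline_offset is not None and len(baseline_offset):
        baseline = baseline + (baseline_offset.astype(float)
                               .reindex(metabolite_ids).fillna(0.0).to_numpy())
    met_sd = within_sd * rng.uniform(0.6, 1.4, size=n_met)
    if sd_scale is not None and len(sd_scale):
        met_sd = met_sd * (sd_scale.astype(float)
                           .reindex(metabolite_ids).fillna(1.0).to_numpy())
    shift = effect.reindex(metabolite_ids).fillna(0.0).to_numpy()

    log_vals = np.empty((n_met, 2 * n_per_group))
    for j in range(2 * n_per_group):
        mu = baseline + (shift if j >= n_per_group else 0.0)
        log_vals[:, j] = rng.normal(mu, met_sd)
    raw = np.exp(log_vals)

    if q_c > 0:
        for j in range(raw.shape[1]):
            lod = np.quantile(raw[:, j], q_c)
            raw[raw[:, j] < lod, j] = np.nan

    values = pd.DataFrame(raw, index=pd.Index(metabolite_ids, name="metabolite"),
                          columns=samples)
    return IntensityMatrix(values=values, condition=condition, scale="raw")


def generate_steady_state(
    n_metabolites: int = DEFAULT_N_METABOLITES,
    n_per_group: int = 6,
    q_c: float = 0.2,
    effect_spec: Mapping[str, float] | None = None,
    n_pathways: int | None = None,
    pathway_size: int = DEFAULT_PATHWAY_SIZE,
    conditions: tuple[str, str] = ("control", "tumor"),
    baseline_mean: float = 9.0,
    baseline_sd: float = 1.0,
    within_sd: float = 0.3,
    frac_unmapped: float = 0.03,
    n_duplicates: int = 4,
    seed: int = 0,
) -> tuple[IntensityMatrix, SyntheticTruth]:
    """Simulate a steady-state SRM peak-area matrix with planted effects.

    Per metabolite, log intensities are normal with a metabolite-
    specific baseline (mean ``baseline_mean``, spread ``baseline_sd``
    across metabolites) and within-group sd ``within_sd`` (jittered per
    metabolite); treatment samples get the planted log-scale shift of
    their pathway from ``effect_spec``.  Raw intensities are the
    exponentials; per sample, all values below that sample's ``q_c``
    quantile are censored to missing.

    Pathways (default: enough of size ``pathway_size`` to cover the
    names in ``effect_spec`` plus null fillers) partition a prefix of
    the metabolites; the rest stay outside every pathway.  A few
    metabolites are left without KEGG annotation and a few duplicate
    feature rows (same KEGG compound, lower mean, higher variance) are
    appended so that the mapping and deduplication stages have work to
    do.

    Returns the raw-scale matrix and a :class:`SyntheticTruth` holding
    the planted effects, pathway assignment, KEGG map and censoring
    quantile.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not 0.0 <= q_c < 1.0:
        raise ValueError("censoring quantile q_c must be in [0, 1)")
    rng = np.random.default_rng(seed)
    effect_spec = dict(effect_spec or {})

    if n_pathways is None:
        n_pathways = max(len(effect_spec), (n_metabolites // pathway_size) * 2 // 3)
    filler_names = [f"pathway_{i + 1:02d}" for i in range(n_pathways)]
    names = list(effect_spec) + [n for n in filler_names if n not in effect_spec]
    names = names[:max(n_pathways, len(effect_spec))]
    assignment = _assign_pathways(n_metabolites, names, pathway_size)

    metabolite_ids = [f"met_{i + 1:04d}" for i in range(n_metabolites)]
    effect = pd.Series(
        [effect_spec.get(assignment.get(m, ""), 0.0) for m in metabolite_ids],
        index=metabolite_ids, name="effect",
    )

    # KEGG map: unique compound per metabolite; a random few unmapped
    kegg = pd.Series({m: _kegg_id(i) for i, m in enumerate(metabolite_ids)},
                     name="kegg_id")
    n_unmapped = int(round(frac_unmapped * n_metabolites))
    unassigned = [m for m in metabolite_ids if m not in assignment]
    drop_pool = unassigned if len(unassigned) >= n_unmapped else metabolite_ids
    for m in rng.choice(drop_pool, size=min(n_unmapped, len(drop_pool)), replace=False):
        kegg = kegg.drop(m)

    # duplicate feature rows: same compound, dimmer and noisier, so both
    # dedup rules keep the primary row
    dup_parents = list(rng.choice([m for m in metabolite_ids if m in kegg.index],
                                  size=min(n_duplicates, n_metabolites), replace=False))
    all_ids = metabolite_ids + [f"{p}__dup" for p in dup_parents]
    if dup_parents:
        dup_effect = pd.Series({f"{p}__dup": float(effect[p]) for p in dup_parents},
                               dtype=float)
        effect = pd.concat([effect, dup_effect])
    for p in dup_parents:
        kegg[f"{p}__dup"] = kegg[p]
        if p in assignment:
            assignment[f"{p}__dup"] = assignment[p]

    # duplicates are dimmer (lower latent baseline) and noisier, so
    # "higher mean" and "lowest variance in normal" both keep the parent
    offset = pd.Series({f"{p}__dup": math.log(0.25) for p in dup_parents})
    sd_scale = pd.Series({f"{p}__dup": 2.0 for p in dup_parents})
    matrix = _simulate_matrix(rng, all_ids, effect, n_per_group, q_c, conditions,
                              baseline_mean, baseline_sd, within_sd,
                              baseline_offset=offset, sd_scale=sd_scale)
    matrix.log(f"simulated steady state: {len(all_ids)} features, q_c={q_c}, seed={seed}")

    truth = SyntheticTruth(
        seed=seed, effect=effect, pathway_assignment=assignment,
        censor_quantile=q_c, kegg_map=kegg,
    )
    return matrix, truth


def generate_panel(
    n_studies: int = 6,
    shared_pathways: Sequence[str] | None = None,
    concordant_fraction: float = 2.0 / 3.0,
    n_specific: int = 4,
    n_filler: int = 10,
    effect_size: float = 2.0,
    n_per_group: int = 6,
    q_c: float = 0.2,
    pathway_size: int = DEFAULT_PATHWAY_SIZE,
    seed: int = 0,
) -> tuple[list[IntensityMatrix], SyntheticTruth]:
    """Simulate a multi-study panel with a planted concordance plan.

    Study 0 is the reference profile; studies 1..n-1 are comparison
    panels.  All studies share one metabolite/pathway universe made of
    ``shared_pathways`` (strongly perturbed in every study),
    ``n_specific`` study-private pathways each (perturbed only in
    their own study, so each study's top-ranked list is filled by its
    own 16 = shared + specific perturbed pathways when the defaults
    are used), and ``n_filler`` null pathways.

    Directions: the reference assigns alternating +/- to the shared
    pathways; each comparison study matches the reference on
    ``round(concordant_fraction * n_shared)`` of them (the realized
    fraction is recorded in the truth when the request is not exactly
    realizable) and flips the rest.  Every study uses a
    ("normal", "tumor") condition factor so the lowest-variance
    deduplication rule is exercisable.
    """
    if n_studies < 2:
        raise ValueError("need a reference plus >= 1 comparison study")
    if not 0.0 <= concordant_fraction <= 1.0:
        raise ValueError("concordant_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    if shared_pathways is None:
        shared_pathways = [f"shared_{i + 1:02d}" for i in range(12)]
    shared = list(shared_pathways)
    n_shared = len(shared)
    n_conc = int(round(concordant_fraction * n_shared))
    realized = n_conc / n_shared

    ref_dirs = {pw: (1 if i % 2 == 0 else -1) for i, pw in enumerate(shared)}
    specific = {s: [f"study{s}_only_{i + 1}" for i in range(n_specific)]
                for s in range(n_studies)}
    fillers = [f"null_{i + 1:02d}" for i in range(n_filler)]

    plan: dict[str, dict[str, int]] = {}
    plan["study_0"] = dict(ref_dirs)
    for s in range(n_studies):
        sdirs = {pw: int(rng.choice([-1, 1])) for pw in specific[s]}
        if s == 0:
            plan["study_0"].update(sdirs)
            continue
        conc_idx = rng.choice(n_shared, size=n_conc, replace=False)
        dirs = {}
        for i, pw in enumerate(shared):
            dirs[pw] = ref_dirs[pw] if i in conc_idx else -ref_dirs[pw]
        dirs.update(sdirs)
        plan[f"study_{s}"] = dirs

    # one panel-wide metabolite universe: block-wise pathway assignment
    # and KEGG map shared by every study; only the planted effects differ
    universe = shared + [pw for s in range(n_studies) for pw in specific[s]] + fillers
    n_metabolites = len(universe) * pathway_size
    assignment = _assign_pathways(n_metabolites, universe, pathway_size)
    metabolite_ids = [f"met_{i + 1:04d}" for i in range(n_metabolites)]
    kegg = pd.Series({m: _kegg_id(i) for i, m in enumerate(metabolite_ids)},
                     name="kegg_id")
    dup_parents = list(rng.choice(metabolite_ids, size=4, replace=False))
    all_ids = metabolite_ids + [f"{p}__dup" for p in dup_parents]
    for p in dup_parents:
        kegg[f"{p}__dup"] = kegg[p]
        if p in assignment:
            assignment[f"{p}__dup"] = assignment[p]

    matrices: list[IntensityMatrix] = []
    ref_effect: pd.Series | None = None
    for s in range(n_studies):
        study_plan = plan[f"study_{s}"]
        effect = pd.Series(
            [effect_size * study_plan.get(assignment.get(m, ""), 0)
             for m in all_ids],
            index=all_ids, name="effect", dtype=float,
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        rng_s = np.random.default_rng(sub_seed)
        offset = pd.Series({f"{p}__dup": math.log(0.25) for p in dup_parents})
        sd_scale = pd.Series({f"{p}__dup": 2.0 for p in dup_parents})
        matrix = _simulate_matrix(rng_s, all_ids, effect, n_per_group, q_c,
                                  ("normal", "tumor"), baseline_mean=9.0,
                                  baseline_sd=1.0, within_sd=0.3,
                                  baseline_offset=offset, sd_scale=sd_scale)
        matrix.log(f"panel study {s} (seed {sub_seed}, q_c={q_c})")
        matrices.append(matrix)
        if s == 0:
            ref_effect = effect

    truth = SyntheticTruth(
        seed=seed,
        effect=ref_effect,
        pathway_assignment=assignment,
        censor_quantile=q_c,
        kegg_map=kegg,
        concordance_plan=plan,
        realized_concordant_fraction=realized,
    )
    return matrices, truth


def generate_tracing(
    labeling: Mapping[tuple[str, str], Sequence[float]],
    n_max: Mapping[str, int] | None = None,
    kegg_ids: Mapping[str, str] | None = None,
    n_per_group: int = 6,
    noise_cv: float = 0.1,
    pool_mean: float | Mapping[tuple[str, str], float] = 1e5,
    pool_cv: float | None = None,
    seed: int = 0,
) -> tuple[IsotopologueTable, SyntheticTruth]:
    """Simulate long-format isotopologue tables from true fractions.

    ``labeling`` maps (metabolite, condition) to the true isotopologue
    probability vector pi_0..pi_n (summing to 1).  Per replicate, the
    total pool is drawn log-normally (mean-preserving) around the
    condition mean ``pool_mean`` with coefficient of variation
    ``pool_cv`` (defaults to ``noise_cv``); each isotopologue area is
    ``pool * pi_i`` times independent mean-1 log-normal noise with
    coefficient of variation ``noise_cv``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if pool_cv is None:
        pool_cv = noise_cv
    rng = np.random.default_rng(seed)

    pis = {k: np.asarray(v, dtype=float) for k, v in labeling.items()}
    for key, pi in pis.items():
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError(f"labeling vector for {key} must sum to 1")
        if (pi < 0).any():
            raise ValueError(f"labeling vector for {key} has negative entries")

    metabolites = sorted({m for m, _ in pis})
    conditions = sorted({c for _, c in pis})
    if n_max is None:
        n_max = {m: max(len(pis[(m, c)]) for c in conditions if (m, c) in pis) - 1
                 for m in metabolites}
    if kegg_ids is None:
        kegg_ids = {m: _kegg_id(i) for i, m in enumerate(metabolites)}

    rows = []
    condition_map: dict[str, str] = {}
    for cond in conditions:
        for r in range(n_per_group):
            sample = f"{cond}_{r + 1}"
            condition_map[sample] = cond
            for met in metabolites:
                if (met, cond) not in pis:
                    continue
                pi = pis[(met, cond)]
                mean_pool = (pool_mean if isinstance(pool_mean, (int, float))
                             else pool_mean[(met, cond)])
                pool = float(mean_pool * _lognormal_factor(rng, pool_cv, ()))
                noise = _lognormal_factor(rng, noise_cv, pi.size)
                areas = pool * pi * noise
                for i, area in enumerate(areas):
                    rows.append((met, kegg_ids[met], i, sample, float(area)))

    data = pd.DataFrame(rows, columns=["metabolite", "kegg_id", "mass_shift",
                                       "sample", "area"])
    table = IsotopologueTable(
        data=data,
        condition=pd.Series(condition_map, name="condition"),
        n_max={m: int(n_max[m]) for m in metabolites},
    )
    truth = SyntheticTruth(seed=seed, labeling=pis)
    return table, truth
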