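# Methods

This note documents the statistical models, conventions and design
choices behind `ccmetab`, module by module, including what the
synthetic-data generators do and do not emulate.

## Data model and scales

An `IntensityMatrix` carries protein-normalized peak areas
(metabolites × samples) with NaN as an explicit missing marker —
distinct from zero, which is a legitimate peak area. Matrices carry a
scale state (`raw` → `log`/`log10` → `median_centered`) and
operations check it: the pipeline only moves forward along this order,
so a double log transform or a median centering of raw data is a hard
error rather than a silent corruption. Every operation appends to a
provenance log (parameters, row counts, removals).

The condition factor is a two-level reference/treatment contrast
declared in the sample metadata; extra levels (e.g. `normal` in human
panels) are carried through so that the normal-sample deduplication
rule can be applied.

## Preprocessing chain

Order: missingness filter → KEGG mapping → deduplication → log
transform → QRILC imputation → median centering. Row identity and
ordering are preserved; the row count is non-increasing through the
first three steps and constant afterwards.

* **Missingness filter.** A metabolite is retained iff its missing
  fraction is *strictly* below τ (default 0.2) in at least one
  condition. The strictness matters at the boundary: exactly 20 %
  missing in every condition removes the metabolite.
* **KEGG mapping.** The compound map is a user-supplied two-column
  table; no database lookups. Unmapped metabolites are dropped.
  Several features may map to one compound at this stage.
* **Deduplication.** One row per KEGG compound. `higher_mean` keeps
  the duplicate with the greater mean over all observed values (the
  natural choice for a tumor/control contrast); `lowest_variance_in_normal`
  keeps the one with the smallest variance over observed values in the
  normal samples (the convention for multi-cohort cancer panels with a
  normal arm). If the scoring statistic is undefined for every
  duplicate (too few observed values), the most-observed row is kept,
  ties broken by matrix order.
* **Log transform.** Base e or 10. Observed zeros are treated as
  below-LOD and converted to missing by default (SRM zeros are
  censored values in practice, and the left-censored imputer is the
  right tool for them); with `zeros_as_missing=False` a zero is a hard
  error naming the cell.
* **Median centering** subtracts each sample's median after
  imputation, mapping at-median metabolites to 0 and below-median ones
  to negative values. Both the imputed (pre-median) matrix — used for
  testing and enrichment — and the centered matrix — used for
  display-oriented relative abundance — are returned, since the two
  serve different purposes and collapsing them would force a guess.

### QRILC imputation

Missing values are modeled as left-censored draws from a per-sample
normal log-intensity distribution (the limit of detection varies by
run, hence per column, matching the reference implementation's
column-wise default). For a sample with observed fraction p_obs:

1. The sorted observed values are paired with standard-normal
   quantiles of probabilities equally spaced from (1 − p_obs) + ε to
   1 − ε, ε = 10⁻³, one point per observed value (a stable
   plotting-position convention), and μ̂, σ̂ are the intercept/slope of
   the least-squares quantile–quantile line.
2. Each missing value is drawn independently from
   𝒩(μ̂, tune_σ·σ̂) truncated above at the estimated censoring point
   Q(1 − p_obs) = μ̂ + σ̂·Φ⁻¹(1 − p_obs). `tune_sigma` defaults to 1.0.

Guards: a sample needs ≥ 4 observed values and an observed fraction of
at least 0.3 (below that the quantile fit is unreliable and the right
fix is a stronger missingness filter); σ̂ ≤ 0 is an error. On censored
standard-normal data with 5000 values per sample, μ̂ and σ̂ are
recovered to within ±0.05, and every imputed value respects the
censoring point by construction. Imputation is seeded and
reproducible.

## Differential statistics

Welch's unequal-variance t test, two-sided, sample sd with n − 1,
Welch–Satterthwaite df. Degenerate inputs (both groups zero-variance)
map to p = 1 when the means are equal and p = 0 otherwise, flagged,
with t/df as NaN — this avoids NaN propagation into downstream
counting. Metabolites with fewer than two observed values in a group
are flagged with undefined p and direction `ns`. P values are reported
unadjusted, matching the convention of reporting exact per-metabolite
p values in this kind of targeted study; a BH-adjusted column is
available for users but never drives the significance flag.

## Pathway scores

**ORA.** Hypergeometric upper tail P[X ≥ k] on the α-significant set
against the background of all tested KEGG-mapped metabolites.
Pathways with fewer than `min_members = 2` measured members are
excluded (singletons would dominate rankings). Results are sorted by
ascending p, ties broken by descending enrichment ratio
(k/m)/(K/N) and then name, which makes ranks and top-k lists
deterministic. Web-platform enrichment tools implement richer
quantitative set statistics; absolute p values from those will differ
from this first-principles ORA, but rankings on strong effects agree,
and ORA is exactly checkable against enumeration.

**DA score.** S = (U − D)/T with significance at unadjusted p < α.
This is the differential-abundance score convention used by pan-cancer
metabolomics resources; it is linear in the member direction flags, so
negating every effect negates every S exactly. T = 0 pathways are
flagged undefined and excluded from concordance.

## Cross-study concordance

Shared pathways are the intersection of top-k ORA lists. "Recurs
across multiple datasets" is ambiguous (≥ 1 study? a majority?), so
the module reports the count of reference-top pathways shared with
≥ t studies for *every* t and defaults displays to t = 1. Direction
is sign(S); a shared pathway is concordant iff the signs are equal
and nonzero. Zero-sign pathways are excluded from the denominator and
listed separately — "up- or down-regulation" presupposes a direction.
The concordant fraction is reported per study and pooled over all
(study, pathway) pairs, since a headline like "two-thirds of shared
pathways" could be either. A permutation null (study signs permuted
across its pathways, p = (1 + #{c_perm ≥ c_obs})/(1 + n_perm)) gives
the observed fraction a significance reference.

## ¹³C isotopologue analysis

Fractions are computed per replicate and then tested (the replicate is
the experimental unit), not pooled first. Mass shifts absent from the
input are filled with zero area — an unmonitored SRM transition
contributes nothing to the pool — with a logged count so users can
audit. Zero-pool records are flagged undefined and excluded from
tests. No natural-abundance correction is applied; analyses operate on
raw SRM isotopologue areas, and the long-format layout leaves room to
insert a correction-matrix step later.

Mean enrichment E = Σᵢ i·fᵢ / n_max is normalized by the metabolite's
carbon capacity so that, e.g., a 6-carbon and a 4-carbon intermediate
are on the same 0–1 scale — required for cross-metabolite chain
comparison. Where a single "fractional enrichment" number is needed
the chain score uses E by default and reports the labeled fraction
L = 1 − f₀ alongside, since the two can rank metabolites differently.

The discontinuity score on an ordered chain m₁ → … → m_n is
d_j = E(m_j) − E(m_{j+1}); the maximal positive edge is the candidate
drain/bottleneck (carbon enters the precursor but fails to propagate),
with a replicate bootstrap percentile CI. A uniform-enrichment chain
scores zero everywhere and reports no candidate.

## Synthetic-data generators

The generators define the study conditions for all validation:

* **Steady state**: 310 metabolites by default (a realistic targeted
  polar panel size), log-normal intensities with per-metabolite
  baselines (mean 9, sd 1 on the natural-log scale, i.e. peak areas
  spanning ~2 orders of magnitude) and within-group sd 0.3 (jittered
  ×0.6–1.4 per metabolite, typical of SRM replicate CVs), block-wise
  pathway assignment (8 members each), planted per-pathway log-scale
  shifts, and per-sample left censoring at the q_c = 0.2 quantile —
  matching the ~20 % missingness a LOD filter at τ = 0.2 targets. A
  few unannotated features and duplicate rows (dimmer, noisier copies
  of a parent compound) exercise the mapping and dedup stages.
* **Panels**: a reference study plus comparison studies over one shared
  universe: 12 shared pathways (strong effects, ±2 log units,
  directions per a planted plan realizing the requested concordant
  fraction — `round(fraction × n_shared)` concordant per study, the
  realized fraction recorded when not exactly realizable), 4
  study-private perturbed pathways each, and null fillers. Each study
  carries a normal arm. With the defaults each study's top-16 ORA list
  is exactly its 16 perturbed pathways, so the planted overlap (12)
  and concordance plan are recoverable exactly by the full pipeline.
* **Tracing**: per replicate, a log-normal total pool (mean-preserving)
  times the true fraction vector π times independent mean-1 log-normal
  noise (multiplicative, because peak areas are positive and
  heteroscedastic; CV 0.1 by default).

What the generators do **not** emulate: chromatographic drift, batch
effects, correlated noise between metabolites, isotope natural
abundance, and non-normal heavy-tailed intensity distributions.
Passing tests therefore demonstrate correctness of the computations
under the stated censoring/noise model, not robustness to every
artifact of real LC-MS data.

## Numerical conventions

* Report floats are serialized with 12 significant digits; matrix
  writers use shortest-round-trip representation, so write → read is
  lossless and fixed-seed runs are byte-identical.
* All randomness flows through `numpy.random.default_rng(seed)`;
  sub-seeds are drawn below 2³¹.
* Fraction vectors are asserted to sum to 1 within 10⁻⁹ after every
  tracing operation.
* Problem sizes used by the test suite and the acceptance script
  (5000-value QRILC fits, 2000-metabolite null panels, 6-study
  end-to-end runs, 100-seed detection-rate estimates) were chosen so
  the full validation completes in well under a minute on one CPU
  while keeping Monte-Carlo error far inside the asserted tolerances.

## Known limitations

* ORA treats metabolites as exchangeable; no topology or abundance
  weighting.
* The Welch degenerate-case convention (p = 1 for identical constant
  groups) is a documented choice, not an inference.
* QRILC assumes normal log intensities per sample; heavy left tails
  bias σ̂ upward.
* The concordance permutation null permutes pathway labels, ignoring
  correlation between overlapping pathways.
* Flux is out of scope: isotopologue distributions constrain but do
  not determine fluxes, and no flux fitting is attempted.
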