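# Methods

This note documents the statistical procedures, the generative model
behind the synthetic cohorts, and the numerical and design choices made
where more than one defensible option existed.

## Bivariate battery

Categorical variables are compared between women and men with Pearson's
chi-square test of homogeneity on the sex × level table,
χ² = Σ (O−E)²/E with E = row·col/N and df = (2−1)(k−1). No Yates
continuity correction is applied by default: the packaged printed tables
reproduce their published odds ratios and significance calls only with
the uncorrected statistic, and the correction is known to be
conservative at these cell sizes. It remains available via
`chi_square_test(..., correction=True)`.

Continuous variables use the two-sided Wilcoxon rank-sum
(Mann–Whitney) test: exact enumeration when both samples have ≤10
observations and no ties, otherwise the normal approximation with
mid-ranks and tie-corrected variance. The continuity correction is
applied on the asymptotic path, matching R's `wilcox.test` default (the
kind of software these analyses are usually run in). The worst-case gap
between the exact two-sided p and the corrected normal approximation at
n = 8+8 is ≈0.011 — a property of the discrete exact distribution, not
of any implementation — so agreement is asserted on the mean over seeded
permutations (< 0.01), not the maximum.

Odds ratios use the Woolf/logit interval,
exp(ln OR ± z·√(1/a+1/b+1/c+1/d)), with men as the reference
category. Zero cells are an error by default; the Haldane–Anscombe +0.5
correction must be requested explicitly (`haldane=True`) so that
printed-value reproduction is never silently perturbed. P-values are
reported unadjusted, as is conventional for descriptive cohort tables; a
Benjamini–Hochberg option (`adjust="bh"`) exists but is off by default.
Every analysis is repeated in the 65–84 and ≥85 strata. Variables that
are constant within a stratum are skipped with a logged warning rather
than failing the run.

Banding schemes: age decades 65–74 / 75–84 / 85–94 / ≥95 and the binary
65–84 / ≥85 split; Barthel 0–100 in steps of 5 into total (<20), severe
(20–35), moderate (40–55), low (60–95) dependence and independent (100);
chronic-medication counts into oligopharmacy (0–4), moderate (5–9) and
excessive (≥10) polypharmacy; Charlson scores into configurable tertiles
(default cut points 2–5 / 6–8 / 9–14).

## Co-occurrence networks

For a subcohort of N patients, each unordered condition pair (A, B)
carries the observed count O of patients with both, the expectation
under independence E = n_A·n_B/N, their ratio O/E, and the pair
prevalence O/N. Each patient contributes 0/1 per pair — co-occurrence
counts patients, not episodes.

Filter semantics, where the convention was open:

- expectations are computed **within each sex subcohort** (per-sex N and
  margins), since the networks are built per sex; a pooled-expectation
  comparison is possible by passing the pooled frame.
- the 2% prevalence filter applies to **node prevalence** in the
  subcohort; applying it to pair prevalence instead is exposed as
  `filter_on_pair_prevalence=True`.
- both thresholds are **strict** (`>`): a node at exactly 2% or an edge
  at O/E exactly 2.0 is removed.
- isolated nodes are dropped after edge filtering (configurable), and
  degrees are recomputed on the filtered graph.

Sex exclusivity of a condition is n_{sex} / (n_female + n_male) over
carriers of the condition pooled across sexes, so the two shares sum
to 1. It is undefined (NaN) for conditions nobody carries.

## ForceAtlas2 layout

The layout is implemented from scratch (it is a core deliverable, not a
wrapped dependency). Per iteration:

- repulsion between all node pairs: k_r (deg_i+1)(deg_j+1)/d, applied
  along the separation vector; exact all-pairs computation — with ≤64
  conditions a Barnes–Hut approximation would only add error;
- attraction along edges: w^δ · d in linear mode (w^δ · log(1+d) in
  LinLog mode), with edge weight w = pair prevalence by default,
  matching the figure convention that edge width encodes pair
  prevalence;
- gravity k_g (deg+1) toward the origin keeps components from drifting
  apart indefinitely;
- adaptive speed: per-node swing (force change between iterations) and
  traction (average force) are mass-weighted and combined into a global
  speed `tolerance · traction/swing`, whose growth is capped at 1.5× per
  iteration; per-node speed is damped by √swing and capped at 10/|F|.

Defaults: k_r = 2.0, k_g = 1.0, δ = 1.0, tolerance = 1.0, at most 1,000
iterations, stopping when mean displacement falls below 1e-4. Initial
positions are uniform in the unit disc from the seeded generator;
exactly coincident points (including an all-coincident degenerate start)
are separated by a small deterministic index-dependent jitter, so forces
are always finite and no exception is ever raised for coincident nodes.
Given the seed, coordinates are bit-reproducible.

Layouts are qualitative: node adjacency structure is preserved
(connected pairs end closer than non-connected ones), but no two
parameterizations produce pixel-comparable pictures.

## Prescribing-rules engine

A medication is chronic when started ≥90 days before admission ("three
months" is fixed as 90 days) and its form is systemic; creams,
ointments, healing material and OTC products are excluded before rules
run. The filter is idempotent and a start date after admission is a hard
error.

Criteria are (id, kind, predicate) entries in a registry; the three
built-ins are registered through the same interface available to
extensions:

- **STOPP D5** — any benzodiazepine (ATC N05BA/N05CD/N05CF) with ≥28
  days between start and admission ("four or more weeks" = 28 days).
- **STOPP L1** — a strong opioid (N02AB/N02AE) that is transdermal,
  indicated for mild pain, and not predated by any step-1 analgesic
  (N02BE paracetamol, M01A NSAIDs). Only this abbreviated reading is
  implemented; the full WHO-ladder context of the clinical wording is
  out of scope.
- **START H2** — a regularly scheduled opioid (N02A) with no laxative
  (A06A) anywhere in the list. "Regularly" excludes as-needed use.

ATC prefix sets are configuration (`AtcConfig`), since criteria name
drug classes, not codes. Vaccine-related omission criteria are excluded
by construction. STOPP hits are PIMs, START hits are PPOs;
`patient_flags` aggregates any-PIM/any-PPO, the chronic count and its
polypharmacy band.

## Synthetic cohorts

The generator emulates an acute-admission cohort of adults ≥65: default
sex split 394:346, per-sex decade-band age distributions concentrated
above 85 (ages uniform within bands; the open ≥95 band is capped at
105), frailty, household, Barthel, Charlson, length-of-stay (log-normal
around a median of 11 days), in-hospital death (≈9%), any-ADR (≈33%,
split into admission-only/stay-only/both at the observed 125:92:28
proportions) and nursing-home discharge among survivors. All rates are
per-sex and overridable through `CohortSpec`.

Condition structure: each targeted pair (A, B, sex, ψ) is sampled from
the exact 2×2 joint distribution whose marginals match the declared
prevalences and whose cross-product ratio equals ψ — the admissible root
of Plackett's quadratic in the both-present cell, clamped to the Fréchet
bounds. Everything untargeted is independent. Two targets sharing a
condition within the same sex are rejected at validation rather than
silently distorting marginals; a target on a degenerate marginal (0
or 1) is reported as infeasible with the pair named. Independence of
untargeted pairs is an assumption, not a reconstruction of any real
cohort's joint dependence; passing recovery tests therefore demonstrates
correctness of the sampler, not realism of the dependence structure.
Note that O/E of a pair is bounded well below its odds ratio at common
prevalences — an OR of 3 at 30% prevalence yields O/E ≈ 1.56 — so
specs intended to produce network edges need rarer conditions with
stronger associations.

The medication model draws the total count from a Poisson (default mean
10, giving ≈95% polypharmacy), includes class-specific drugs
(benzodiazepine with configurable duration, oral/transdermal strong
opioids, a laxative conditional on opioid use) with declared
probabilities, and fills the remainder with unremarkable maintenance
drugs started 90–400 days pre-admission. `p_laxative_given_opioid`
directly controls the START-H2 firing rate.

Fixture mode expands printed 2×k tables (counts by sex and level) into
one patient row per count. Only sex and the named variable are
populated; every other field keeps an explicit missing sentinel and is
never imputed, because printed tables are marginal — each expansion
supports exactly one bivariate analysis, and cross-tabulating the
expansion reproduces the input table exactly.

All sampling flows through one `numpy.random.Generator` seeded from the
spec; per-patient medication streams derive deterministically from the
spec seed, so identical specs give byte-identical cohort tables.

## Pipeline

Stages run in order cohort → rules → statistics → networks → layout;
each records row counts, wall-clock and SHA-256 checksums of emitted
files in a JSON manifest. The manifest itself is not checksummed (it
carries timings); all data outputs are deterministic under fixed
config + seed, including the forest-plot SVG (fixed hash salt, no
embedded timestamp). On `resume=True` the rules stage is skipped when
its recorded outputs are unchanged on disk and the config matches;
deeper DAG-style caching is deliberately out of scope. A stage failure
raises an error naming the stage, leaving earlier outputs intact.

Fixture mode has no patient-level joint data, so network and layout
stages are skipped and the report states zero edges.

## Problem sizes in the validation suite

The repeated-simulation checks use 200 cohorts of n = 5,000 for
pairwise-OR recovery, 2,000 replicates of n = 80 for type-I calibration,
n = 20,000 for the O/E null, and 20 seeded layouts of a 30-node random
graph — sizes at which the binomial/Monte-Carlo error bounds quoted in
the tests are comfortably discriminating.

## Known limitations

- The generator matches marginals and targeted pairwise ORs only; real
  cohorts have higher-order dependence, informative missingness and
  center effects that are not modelled.
- The rules engine implements three screening criteria; the full
  STOPP/START v2 set, dose-based checks and drug–drug interactions are
  out of scope.
- Charlson scores are consumed, never computed; frailty is a supplied
  flag, not a scale.
- Printed-table mode can only reproduce analyses whose counts were
  printed; quantities whose underlying cells were not published
  (e.g. most condition-level ORs) are covered qualitatively by the
  simulation-recovery properties instead.
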