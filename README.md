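# comorbnet

Sex-stratified multimorbidity analysis for older hospitalized cohorts:
co-occurrence networks of chronic conditions and geriatric syndromes,
a bivariate statistical battery with odds ratios, and a STOPP/START
screening-rules engine for potentially inappropriate prescribing — plus a
synthetic-cohort generator so the whole pipeline runs without any patient
data.

## Who this is for

Epidemiologists and clinical-pharmacology researchers who study
multimorbidity in geriatric inpatient cohorts and want a reproducible,
scriptable version of the standard descriptive workflow: compare every
clinical variable between women and men, quantify significant differences
as odds ratios, draw per-sex disease co-occurrence networks, and screen
chronic medication lists against explicit prescribing criteria.

## The methods in brief

**Bivariate battery.** Each categorical variable is tested with a Pearson
chi-square on the sex × level table (no Yates correction); continuous
variables (length of stay) use the Wilcoxon rank-sum test. Binary
variables reaching significance get a Woolf odds ratio with men as the
reference category:

```
OR = ad/bc,   95% CI = exp( ln OR ± z_0.975 · √(1/a + 1/b + 1/c + 1/d) )
```

with a = exposed women, b = unexposed women, c = exposed men,
d = unexposed men. Every analysis is repeated in the 65–84 and ≥85 age
strata, and significant ORs are assembled into a forest plot.

**Co-occurrence networks.** Within each sex subcohort, every condition
pair (A, B) gets an observed co-occurrence count O and an expected count
under independence E = n_A·n_B/N. Nodes are kept when condition
prevalence exceeds 2% and edges when O/E exceeds 2 (both strict);
node color intensity encodes sex exclusivity — the share of all carriers
of a condition who belong to that sex. Networks are positioned with a
from-scratch ForceAtlas2 implementation (degree-weighted repulsion,
linear attraction weighted by pair prevalence, gravity, adaptive speed)
and exported as GraphML/GEXF.

**Prescribing rules.** Medications count as chronic when prescribed at
least 90 days before admission and given systemically. Three STOPP/START
screening criteria ship as built-ins in an extensible registry:
benzodiazepines for ≥4 weeks (STOPP D5), transdermal strong opioids as
first-line therapy for mild pain (STOPP L1), and laxative omission under
regular opioids (START H2).

**Synthetic cohorts.** A `CohortSpec` declares per-sex condition
prevalences, targeted within-sex pairwise odds ratios (sampled from the
exact 2×2 joint distribution matching the marginals — Plackett's
construction), banded age distributions, outcome rates and a medication
model. A fixture mode instead expands packaged printed contingency
tables (740 patients: 394 women, 346 men) into patient rows, so
published marginal statistics are reproduced exactly.

## Worked example

Re-analysing the packaged printed tables:

```bash
comorbnet fixture --out results_fixture
```

```
# comorbnet run report

- input mode: **fixture**
- cohort: 740 patients (394 female, 346 male)
- significant variables at alpha=0.05 (all strata pooled): age_group4, alcohol, any_pim, barthel_band, frailty, household, tobacco
  - frailty=yes: OR 1.81 (95% CI 1.34-2.44)
  - any_pim=yes: OR 1.49 (95% CI 1.08-2.07)
- networks: no condition-level data in this mode (zero edges)
```

Frailty is markedly more common in women (269/394 vs 188/346; the odds
of being frail are 1.81× higher in women), and women carry at least one
potentially inappropriate medication more often (303/394 = 76.9% vs
69.1%; OR 1.49). Printed tables carry marginals only, so no
patient-level joint data exists in this mode and the network stages are
skipped.

A fully synthetic run with injected condition structure
(`examples via YAML config`):

```yaml
# cohort.yaml
input_mode: synthetic
output_dir: results_synthetic
seed: 11
n_patients: 2000
condition_prevalence:
  asthma: [0.12, 0.02]       # [female, male] prevalence
  chronic_pain: [0.30, 0.20]
  copd: [0.10, 0.30]
  gout: [0.04, 0.10]
  vertigo: [0.08, 0.04]
pair_targets:
  - [asthma, chronic_pain, female, 8.0]   # within-sex odds ratio
  - [copd, gout, male, 10.0]
medication_model:
  n_medications_mean: 10.0
  p_benzodiazepine: 0.3
  p_opioid_oral: 0.2
  p_laxative_given_opioid: 0.5
syndromes: [chronic_pain]
```

```bash
comorbnet run-all --config cohort.yaml
```

```
# comorbnet run report

- input mode: **synthetic**
- cohort: 2000 patients
- significant variables at alpha=0.05 (all strata pooled): asthma, chronic_pain, copd, frail, gout, household, vertigo
  - frail=True: OR 1.90 (95% CI 1.59-2.28)
  - asthma=1: OR 7.41 (95% CI 4.44-12.38)
  - chronic_pain=1: OR 1.61 (95% CI 1.31-1.97)
  - copd=1: OR 0.21 (95% CI 0.16-0.27)
  - gout=1: OR 0.41 (95% CI 0.29-0.60)
  - vertigo=1: OR 2.37 (95% CI 1.59-3.53)
- female network: 2 nodes, 1 edges
- male network: 2 nodes, 1 edges
- prescribing-rule hits: 763
```

The injected associations surface as expected: the asthma–chronic-pain
pair (target OR 8 in women) and the copd–gout pair (target OR 10 in men)
are the only pairs strong and rare enough to clear the O/E > 2 edge
filter, giving one edge per sex network. The output directory holds the
cohort and medication CSVs, test and odds-ratio tables, criterion hits,
GraphML networks with ForceAtlas2 coordinates, the forest plot SVG, and
a JSON manifest with SHA-256 checksums of every file (identical
config + seed ⇒ identical checksums).

The same stages are available individually (`simulate`, `fixture`,
`stats`, `network`, `layout`, `rules`) and as library functions
(`comorbnet.run_bivariate_battery`, `comorbnet.per_sex_networks`,
`comorbnet.force_atlas2`, `comorbnet.default_registry`, ...).

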