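"""Synthetic patient cohorts with controlled statistical structure.

Two input modes feed the downstream analyses:

* :func:`generate_cohort` draws a fully synthetic cohort from a
  :class:`CohortSpec` — per-sex condition prevalences, targeted pairwise
  odds ratios (so that selected condition pairs exceed an observed/expected
  ratio of 2), banded age distributions, outcome rates and a medication
  model.
* :func:`expand_printed_table` deterministically expands a printed 2×k
  contingency table (counts by sex and level) into one patient row per
  count, so published marginal tables can be re-analysed exactly.

All randomness flows through a single :class:`numpy.random.Generator`
seeded from ``CohortSpec.seed``; identical specs give byte-identical
cohort tables.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FEMALE",
    "MALE",
    "SEXES",
    "MedicationModel",
    "MedicationRecord",
    "PairTarget",
    "CohortSpec",
    "PatientRecord",
    "InfeasiblePairTarget",
    "joint_cell_probability",
    "generate_cohort",
    "generate_medications",
    "expand_printed_table",
    "crosstab_records",
    "cohort_to_frame",
    "medications_to_frame",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_medications_csv",
    "read_medications_csv",
    "medication_records_from_frame",
]

FEMALE = "female"
MALE = "male"
SEXES = (FEMALE, MALE)

#: Decade age bands used throughout: label -> (low, high) inclusive.
AGE_BANDS_4 = {
    "65-74": (65, 74),
    "75-84": (75, 84),
    "85-94": (85, 94),
    ">=95": (95, 105),
}
AGE_BAND_4_LABELS = tuple(AGE_BANDS_4)

#: Reference admission date used when none is supplied (synthetic mode only).
DEFAULT_ADMISSION_DATE = date(2017, 6, 1)

MISSING = None  # explicit "missing" sentinel for unpopulated fixture fields


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MedicationRecord:
    """One chronic prescription as seen at hospital admission.

    ``atc_code`` follows the WHO Anatomical Therapeutic Chemical
    classification; class membership checks use code prefixes.
    """

    atc_code: str
    start_date: date
    admission_date: date
    schedule: str = "regular"  # regular | as_needed
    route: str = "oral"  # oral | transdermal | other
    indication: str = "other"  # mild_pain | moderate_severe_pain | anxiety_insomnia | other
    form: str = "systemic"  # systemic | cream_ointment | healing_material | otc

    def __post_init__(self) -> None:
        if not self.atc_code:
            raise ValueError("atc_code must be nonempty")
        if self.start_date > self.admission_date:
            raise ValueError(
                f"medication start {self.start_date} is after admission "
                f"{self.admission_date}"
            )

    @property
    def duration_days(self) -> int:
        """Days between prescription start and admission."""
        return (self.admission_date - self.start_date).days


@dataclass
class PatientRecord:
    """One hospital admission of one patient.

    Any field except ``patient_id`` may be ``None``, the explicit
    "missing" sentinel used by fixture expansion (printed tables only
    populate one variable at a time and nothing is ever imputed).
    """

    patient_id: str
    sex: str | None = MISSING
    age_years: int | None = MISSING
    household: str | None = MISSING  # alone | nursing_home | relatives_other
    barthel: int | None = MISSING
    frail: bool | None = MISSING
    charlson_score: int | None = MISSING
    conditions: set[str] = field(default_factory=set)
    medications: list[MedicationRecord] = field(default_factory=list)
    los_days: int | None = MISSING
    discharge_nursing_home: bool | None = MISSING
    died_in_hospital: bool | None = MISSING
    death_cause: str | None = MISSING  # exacerbation | treatment_complication | other | not_applicable
    adr_at_admission: bool | None = MISSING
    adr_during_stay: bool | None = MISSING
    adr_worst: str | None = MISSING  # life_threatening | lengthened_stay | other_important | none
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex is not MISSING and self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age_years is not MISSING and self.age_years < 65:
            raise ValueError("cohort restricted to age >= 65")
        if self.died_in_hospital is False and self.death_cause not in (
            MISSING,
            "not_applicable",
        ):
            raise ValueError("death_cause must be not_applicable for survivors")

    @property
    def age_group2(self) -> str | None:
        if self.age_years is MISSING:
            return MISSING
        return "65-84" if self.age_years <= 84 else ">=85"

    @property
    def age_group4(self) -> str | None:
        if self.age_years is MISSING:
            return MISSING
        for label, (lo, hi) in AGE_BANDS_4.items():
            if lo <= self.age_years <= hi:
                return label
        return ">=95"

    @property
    def adr_any(self) -> bool | None:
        if self.adr_at_admission is MISSING or self.adr_during_stay is MISSING:
            return MISSING
        return bool(self.adr_at_admission or self.adr_during_stay)


@dataclass(frozen=True)
class PairTarget:
    """A targeted within-sex association between two binary conditions."""

    condition_a: str
    condition_b: str
    sex: str
    odds_ratio: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if not self.odds_ratio > 0:
            raise ValueError("target odds ratio must be strictly positive")
        if self.condition_a == self.condition_b:
            raise ValueError("pair target must name two distinct conditions")


@dataclass(frozen=True)
class MedicationModel:
    """Generative model for per-patient chronic medication lists.

    ``n_medications_mean`` is the Poisson mean of the total chronic
    medication count; class-specific drugs (benzodiazepine, strong
    opioids, laxative) are included with the given probabilities and the
    remainder of the count is filled with unremarkable maintenance drugs.
    ``p_laxative_given_opioid`` controls how often regular opioid users
    carry a laxative, hence the rate at which the laxative-omission
    screening rule fires.
    """

    n_medications_mean: float = 10.0
    p_benzodiazepine: float = 0.0
    benzodiazepine_duration_days: int = 180
    p_opioid_transdermal: float = 0.0
    p_opioid_oral: float = 0.0
    p_laxative_given_opioid: float = 0.5
    p_mild_pain_given_transdermal: float = 0.5
    p_opioid_schedule_regular: float = 0.9

    def __post_init__(self) -> None:
        for name in (
            "p_benzodiazepine",
            "p_opioid_transdermal",
            "p_opioid_oral",
            "p_laxative_given_opioid",
            "p_mild_pain_given_transdermal",
            "p_opioid_schedule_regular",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.n_medications_mean < 0:
            raise ValueError("n_medications_mean must be >= 0")


def _default_age_distribution() -> dict[str, tuple[float, ...]]:
    # Decade-band frequencies typical of an acute geriatric admission cohort
    # (over half of patients >= 85, women older than men on average).
    return {
        FEMALE: (29 / 394, 128 / 394, 212 / 394, 25 / 394),
        MALE: (52 / 346, 135 / 346, 154 / 346, 5 / 346),
    }


def _default_outcome_rates() -> dict[str, dict[str, float]]:
    # Per-sex outcome probabilities: in-hospital death, any adverse drug
    # reaction, nursing-home discharge among survivors, frailty.
    return {
        FEMALE: {
            "death": 38 / 394,
            "adr_any": 132 / 394,
            "nursing_home_discharge": 62 / 356,
            "frail": 269 / 394,
        },
        MALE: {
            "death": 28 / 346,
            "adr_any": 113 / 346,
            "nursing_home_discharge": 43 / 318,
            "frail": 188 / 346,
        },
    }


@dataclass
class CohortSpec:
    """Generative description of a synthetic cohort.

    ``condition_prevalence`` maps condition name to a ``(female, male)``
    prevalence pair.  ``pair_targets`` inject within-sex associations by
    sampling targeted pairs from the exact 2×2 joint distribution that
    matches the marginals and the requested odds ratio; all untargeted
    conditions are independent.
    """

    n_patients: int
    seed: int
    sex_fraction_female: float = 394 / 740
    condition_prevalence: dict[str, tuple[float, float]] = field(default_factory=dict)
    pair_targets: list[PairTarget] = field(default_factory=list)
    age_group_distribution: dict[str, tuple[float, ...]] = field(
        default_factory=_default_age_distribution
    )
    outcome_rates: dict[str, dict[str, float]] = field(default_factory=_default_outcome_rates)
    medication_model: MedicationModel | None = None
    admission_date: date = DEFAULT_ADMISSION_DATE

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0.0 <= self.sex_fraction_female <= 1.0:
            raise ValueError("sex_fraction_female outside [0, 1]")
        for name, prev in self.condition_prevalence.items():
            if len(prev) != 2:
                raise ValueError(f"condition {name!r}: need (female, male) prevalences")
            for p in prev:
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"condition {name!r}: prevalence {p} outside [0, 1]")
        for sex, dist in self.age_group_distribution.items():
            if sex not in SEXES:
                raise ValueError(f"unknown sex {sex!r} in age distribution")
            if len(dist) != len(AGE_BAND_4_LABELS):
                raise ValueError("age distribution needs one probability per decade band")
            if any(p < 0 for p in dist):
                raise ValueError("age distribution probabilities must be >= 0")
            if abs(sum(dist) - 1.0) > 1e-9:
                raise ValueError(f"age distribution for {sex} does not sum to 1")
        for sex, rates in self.outcome_rates.items():
            for key, p in rates.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"outcome rate {sex}/{key}={p} outside [0, 1]")
        seen: dict[tuple[str, str], str] = {}
        for t in self.pair_targets:
            for c in (t.condition_a, t.condition_b):
                if c not in self.condition_prevalence:
                    raise ValueError(f"pair target references undeclared condition {c!r}")
                key = (t.sex, c)
                if key in seen:
                    raise ValueError(
                        f"conflicting pair targets: condition {c!r} appears in more "
                        f"than one target for sex {t.sex}"
                    )
                seen[key] = c
        # fail fast on infeasible targets, before any sampling
        for t in self.pair_targets:
            col = 0 if t.sex == FEMALE else 1
            joint_cell_probability(
                self.condition_prevalence[t.condition_a][col],
                self.condition_prevalence[t.condition_b][col],
                t.odds_ratio,
                pair=(t.condition_a, t.condition_b),
            )


class InfeasiblePairTarget(ValueError):
    """Raised when a requested pairwise odds ratio is incompatible with the marginals."""


# ---------------------------------------------------------------------------
# Exact 2x2 joint distribution for a targeted pair
# ---------------------------------------------------------------------------


def joint_cell_probability(
    p_a: float, p_b: float, odds_ratio: float, pair: tuple[str, str] | None = None
) -> float:
    """Probability of the both-present cell of a 2×2 joint distribution.

    Solves for ``p11`` such that the joint distribution with marginals
    ``p_a``, ``p_b`` has cross-product ratio ``odds_ratio``:

        psi = p11 * p00 / (p10 * p01)

    For ``psi != 1`` this is the root of a quadratic in ``p11``
    (Plackett's construction); the admissible root is the one inside the
    Fréchet bounds ``[max(0, p_a + p_b - 1), min(p_a, p_b)]``.
    """
    label = f"({pair[0]}, {pair[1]})" if pair else f"(p_a={p_a}, p_b={p_b})"
    if not (0.0 <= p_a <= 1.0 and 0.0 <= p_b <= 1.0):
        raise InfeasiblePairTarget(f"pair {label}: marginals outside [0, 1]")
    if odds_ratio <= 0:
        raise InfeasiblePairTarget(f"pair {label}: odds ratio must be > 0")
    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    if not math.isclose(odds_ratio, 1.0) and (
        p_a in (0.0, 1.0) or p_b in (0.0, 1.0)
    ):
        raise InfeasiblePairTarget(
            f"pair {label}: a degenerate marginal (0 or 1) cannot carry an "
            f"odds ratio of {odds_ratio}"
        )
    if math.isclose(odds_ratio, 1.0):
        p11 = p_a * p_b
    else:
        psi = odds_ratio
        s = 1.0 + (p_a + p_b) * (psi - 1.0)
        disc = s * s - 4.0 * psi * (psi - 1.0) * p_a * p_b
        if disc < 0:
            raise InfeasiblePairTarget(
                f"pair {label}: odds ratio {odds_ratio} infeasible for marginals"
            )
        p11 = (s - math.sqrt(disc)) / (2.0 * (psi - 1.0))
    if p11 < lo - 1e-12 or p11 > hi + 1e-12:
        raise InfeasiblePairTarget(
            f"pair {label}: odds ratio {odds_ratio} incompatible with marginals "
            f"{p_a}, {p_b} (p11={p11:.6g} outside [{lo:.6g}, {hi:.6g}])"
        )
    # degenerate marginals (0 or 1) force a boundary cell regardless of psi
    return min(max(p11, lo), hi)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _sample_conditions(
    rng: np.random.Generator,
    n: int,
    sex_col: int,
    prevalence: Mapping[str, tuple[float, float]],
    targets: Sequence[PairTarget],
) -> dict[str, np.ndarray]:
    """Indicator arrays for one sex subcohort (vectorised)."""
    out: dict[str, np.ndarray] = {}
    targeted: set[str] = set()
    for t in targets:
        p_a = prevalence[t.condition_a][sex_col]
        p_b = prevalence[t.condition_b][sex_col]
        p11 = joint_cell_probability(p_a, p_b, t.odds_ratio, (t.condition_a, t.condition_b))
        probs = np.array([p11, p_a - p11, p_b - p11, 1.0 - p_a - p_b + p11])
        probs = np.clip(probs, 0.0, None)
        probs = probs / probs.sum()
        cell = rng.choice(4, size=n, p=probs)
        out[t.condition_a] = ((cell == 0) | (cell == 1)).astype(np.int8)
        out[t.condition_b] = ((cell == 0) | (cell == 2)).astype(np.int8)
        targeted.update((t.condition_a, t.condition_b))
    for name, prev in prevalence.items():
        if name not in targeted:
            out[name] = (rng.random(n) < prev[sex_col]).astype(np.int8)
    return out


# carriers of any in-hospital ADR split into admission-only / stay-only / both
_ADR_PATTERN_PROBS = (125 / 245, 92 / 245, 28 / 245)
_DEATH_CAUSE_PROBS = {"exacerbation": 55 / 63, "treatment_complication": 1 / 63, "other": 7 / 63}
_ADR_WORST_PROBS = {"life_threatening": 0.10, "lengthened_stay": 0.45, "other_important": 0.45}
_HOUSEHOLD_PROBS = {
    FEMALE: {"alone": 73 / 394, "nursing_home": 61 / 394, "relatives_other": 260 / 394},
    MALE: {"alone": 49 / 346, "nursing_home": 34 / 346, "relatives_other": 263 / 346},
}


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a synthetic cohort from ``spec``; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    if n == 0:
        return []
    is_female = rng.random(n) < spec.sex_fraction_female
    records: list[PatientRecord] = [
        PatientRecord(patient_id=f"P{i:06d}", sex=FEMALE if f else MALE)
        for i, f in enumerate(is_female)
    ]

    band_bounds = list(AGE_BANDS_4.values())
    for sex, col in ((FEMALE, 0), (MALE, 1)):
        idx = np.flatnonzero(is_female if sex == FEMALE else ~is_female)
        m = idx.size
        if m == 0:
            continue
        cond = _sample_conditions(rng, m, col, spec.condition_prevalence, [
            t for t in spec.pair_targets if t.sex == sex
        ])
        band = rng.choice(len(band_bounds), size=m, p=spec.age_group_distribution[sex])
        lows = np.array([b[0] for b in band_bounds])
        highs = np.array([b[1] for b in band_bounds])
        ages = rng.integers(lows[band], highs[band] + 1)
        rates = spec.outcome_rates[sex]
        died = rng.random(m) < rates.get("death", 0.0)
        adr_any = rng.random(m) < rates.get("adr_any", 0.0)
        adr_pattern = rng.choice(3, size=m, p=_ADR_PATTERN_PROBS)
        nh = rng.random(m) < rates.get("nursing_home_discharge", 0.0)
        frail = rng.random(m) < rates.get("frail", 0.5)
        barthel = rng.integers(0, 21, size=m) * 5
        charlson = rng.integers(2, 15, size=m)
        los = np.maximum(1, np.rint(np.exp(rng.normal(math.log(11.0), 0.55, size=m)))).astype(int)
        hh_levels = list(_HOUSEHOLD_PROBS[sex])
        hh_p = np.array([_HOUSEHOLD_PROBS[sex][k] for k in hh_levels])
        household = rng.choice(len(hh_levels), size=m, p=hh_p / hh_p.sum())
        death_cause = rng.choice(
            list(_DEATH_CAUSE_PROBS), size=m, p=list(_DEATH_CAUSE_PROBS.values())
        )
        adr_worst = rng.choice(list(_ADR_WORST_PROBS), size=m, p=list(_ADR_WORST_PROBS.values()))

        names = list(cond)
        mat = np.column_stack([cond[c] for c in names]) if names else np.zeros((m, 0), np.int8)
        for j, i in enumerate(idx):
            r = records[i]
            r.age_years = int(ages[j])
            r.conditions = {names[k] for k in np.flatnonzero(mat[j])}
            r.frail = bool(frail[j])
            r.barthel = int(barthel[j])
            r.charlson_score = int(charlson[j])
            r.household = hh_levels[int(household[j])]
            r.los_days = int(los[j])
            r.died_in_hospital = bool(died[j])
            r.death_cause = str(death_cause[j]) if died[j] else "not_applicable"
            r.discharge_nursing_home = bool(nh[j]) and not died[j]
            if adr_any[j]:
                pat = int(adr_pattern[j])
                r.adr_at_admission = pat in (0, 2)
                r.adr_during_stay = pat in (1, 2)
            else:
                r.adr_at_admission = False
                r.adr_during_stay = False
            r.adr_worst = str(adr_worst[j]) if r.adr_during_stay else "none"

    if spec.medication_model is not None:
        for i, r in enumerate(records):
            r.medications = generate_medications(
                r, spec.medication_model, seed=int((spec.seed * 1_000_003 + i) % (2**31)),
                admission_date=spec.admission_date,
            )
    return records


_FILLER_ATC = ("C09AA02", "A02BC01", "C10AA05", "B01AC06", "C07AB02", "A10BA02", "N06AB03")


def generate_medications(
    patient: PatientRecord,
    model: MedicationModel,
    seed: int,
    admission_date: date = DEFAULT_ADMISSION_DATE,
) -> list[MedicationRecord]:
    """Draw one patient's chronic medication list from ``model``."""
    rng = np.random.default_rng(seed)
    meds: list[MedicationRecord] = []

    def chronic_start() -> date:
        return admission_date - timedelta(days=int(rng.integers(90, 401)))

    if rng.random() < model.p_benzodiazepine:
        meds.append(
            MedicationRecord(
                atc_code="N05BA12",
                start_date=admission_date - timedelta(days=model.benzodiazepine_duration_days),
                admission_date=admission_date,
                indication="anxiety_insomnia",
            )
        )
    opioid = False
    if rng.random() < model.p_opioid_transdermal:
        opioid = True
        mild = rng.random() < model.p_mild_pain_given_transdermal
        meds.append(
            MedicationRecord(
                atc_code="N02AB03",
                start_date=chronic_start(),
                admission_date=admission_date,
                route="transdermal",
                indication="mild_pain" if mild else "moderate_severe_pain",
                schedule="regular"
                if rng.random() < model.p_opioid_schedule_regular
                else "as_needed",
            )
        )
    if rng.random() < model.p_opioid_oral:
        opioid = True
        meds.append(
            MedicationRecord(
                atc_code="N02AA01",
                start_date=chronic_start(),
                admission_date=admission_date,
                indication="moderate_severe_pain",
                schedule="regular"
                if rng.random() < model.p_opioid_schedule_regular
                else "as_needed",
            )
        )
    if opioid and rng.random() < model.p_laxative_given_opioid:
        meds.append(
            MedicationRecord(
                atc_code="A06AD11",
                start_date=chronic_start(),
                admission_date=admission_date,
            )
        )
    total = int(rng.poisson(model.n_medications_mean)) if model.n_medications_mean > 0 else 0
    for k in range(max(0, total - len(meds))):
        meds.append(
            MedicationRecord(
                atc_code=_FILLER_ATC[k % len(_FILLER_ATC)],
                start_date=chronic_start(),
                admission_date=admission_date,
            )
        )
    return meds


# ---------------------------------------------------------------------------
# Printed-table expansion (fixture mode)
# ---------------------------------------------------------------------------


def expand_printed_table(
    variable_name: str,
    counts_by_sex_and_level: Sequence[Sequence[int]] | np.ndarray,
    levels: Sequence[str] | None = None,
) -> list[PatientRecord]:
    """Expand a printed 2×k table (rows female, male) into patient rows.

    Only ``sex`` and the named variable are populated; every other field
    keeps the explicit missing sentinel, because a printed table carries
    marginal information for one variable only.  The expansion round-trips:
    cross-tabulating the records reproduces the input counts exactly.
    """
    counts = np.asarray(counts_by_sex_and_level, dtype=int)
    if counts.ndim != 2 or counts.shape[0] != 2:
        raise ValueError("counts must be a 2×k table with rows (female, male)")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    k = counts.shape[1]
    if levels is None:
        levels = [f"level_{j}" for j in range(k)]
    if len(levels) != k:
        raise ValueError("one level name per column required")
    records: list[PatientRecord] = []
    i = 0
    for row, sex in enumerate(SEXES):
        for col, level in enumerate(levels):
            for _ in range(int(counts[row, col])):
                rec = PatientRecord(patient_id=f"{variable_name}_{i:05d}", sex=sex)
                rec.extras[variable_name] = str(level)
                records.append(rec)
                i += 1
    return records


def crosstab_records(records: Iterable[PatientRecord], variable_name: str) -> pd.DataFrame:
    """Sex × level cross-tabulation of a fixture variable (rows female, male)."""
    rows = [(r.sex, r.extras.get(variable_name)) for r in records]
    df = pd.DataFrame(rows, columns=["sex", variable_name]).dropna()
    tab = pd.crosstab(df["sex"], df[variable_name])
    return tab.reindex(index=list(SEXES), fill_value=0)


# ---------------------------------------------------------------------------
# Tabular views and delimited-text I/O
# ---------------------------------------------------------------------------

_SCALAR_FIELDS = (
    "patient_id",
    "sex",
    "age_years",
    "household",
    "barthel",
    "frail",
    "charlson_score",
    "los_days",
    "discharge_nursing_home",
    "died_in_hospital",
    "death_cause",
    "adr_at_admission",
    "adr_during_stay",
    "adr_worst",
)


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """One row per patient; conditions become 0/1 indicator columns."""
    base = {f: [getattr(r, f) for r in records] for f in _SCALAR_FIELDS}
    df = pd.DataFrame(base)
    df["age_group2"] = [r.age_group2 for r in records]
    df["age_group4"] = [r.age_group4 for r in records]
    df["adr_any"] = [r.adr_any for r in records]
    all_conditions = sorted({c for r in records for c in r.conditions})
    for c in all_conditions:
        df[c] = np.fromiter((int(c in r.conditions) for r in records), dtype=np.int8,
                            count=len(records))
    extra_keys = sorted({k for r in records for k in r.extras})
    for k in extra_keys:
        df[k] = [r.extras.get(k) for r in records]
    return df


def medications_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Long-format medication table keyed by patient_id."""
    rows = []
    for r in records:
        for m in r.medications:
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "atc_code": m.atc_code,
                    "start_date": m.start_date.isoformat(),
                    "admission_date": m.admission_date.isoformat(),
                    "schedule": m.schedule,
                    "route": m.route,
                    "indication": m.indication,
                    "form": m.form,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "atc_code",
            "start_date",
            "admission_date",
            "schedule",
            "route",
            "indication",
            "form",
        ],
    )


def medication_records_from_frame(frame: pd.DataFrame) -> dict[str, list[MedicationRecord]]:
    """Group a long-format medication table back into per-patient record lists."""
    out: dict[str, list[MedicationRecord]] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(row.patient_id, []).append(
            MedicationRecord(
                atc_code=row.atc_code,
                start_date=date.fromisoformat(row.start_date),
                admission_date=date.fromisoformat(row.admission_date),
                schedule=row.schedule,
                route=row.route,
                indication=row.indication,
                form=row.form,
            )
        )
    return out


def write_cohort_csv(records: Sequence[PatientRecord], path) -> pd.DataFrame:
    df = cohort_to_frame(records)
    df.to_csv(path, index=False)
    return df


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_medications_csv(records: Sequence[PatientRecord], path) -> pd.DataFrame:
    df = medications_to_frame(records)
    df.to_csv(path, index=False)
    return df


def read_medications_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
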