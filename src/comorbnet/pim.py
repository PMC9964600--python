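"""Chronic-medication eligibility and a STOPP/START screening-rules engine.

Only medications prescribed at least three months (90 days) before
admission and given systemically count as chronic; creams, ointments,
healing material and over-the-counter products are excluded before any
rule runs.

Three screening criteria ship as built-ins, registered in the same table
an extension would use:

* ``STOPP_D5`` — benzodiazepines taken for four or more weeks (≥28 days);
* ``STOPP_L1`` — a transdermal strong opioid used as first-line therapy
  for mild pain (no step-1 analgesic predating it);
* ``START_H2`` — missing laxative in a patient receiving opioids on a
  regular schedule (a prescribing omission rather than an inappropriate
  drug).

Drug classes are matched by configurable ATC code prefixes; the defaults
cover the usual benzodiazepine (N05BA/N05CD/N05CF), strong opioid
(N02AB/N02AE), opioid (N02A), step-1 analgesic (N02BE/M01A) and laxative
(A06A) groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Callable, Iterable, Sequence

from .cohort import MedicationRecord
from .stats import band_variable

__all__ = [
    "AtcConfig",
    "CriterionHit",
    "Criterion",
    "CriterionRegistry",
    "default_registry",
    "chronic_filter",
    "evaluate_stopp_d5",
    "evaluate_stopp_l1",
    "evaluate_start_h2",
    "patient_flags",
]

PIM = "PIM"  # potentially inappropriate medication (STOPP)
PPO = "PPO"  # potential prescribing omission (START)

CHRONIC_DAYS = 90  # "at least 3 months before admission"
D5_MIN_DAYS = 28  # "4 or more weeks"


@dataclass(frozen=True)
class AtcConfig:
    """ATC prefix sets for the drug classes the rules reference."""

    benzodiazepines: tuple[str, ...] = ("N05BA", "N05CD", "N05CF")
    strong_opioids: tuple[str, ...] = ("N02AB", "N02AE")
    opioids: tuple[str, ...] = ("N02A",)
    step1_analgesics: tuple[str, ...] = ("N02BE", "M01A")
    laxatives: tuple[str, ...] = ("A06A",)


DEFAULT_ATC = AtcConfig()


@dataclass(frozen=True)
class CriterionHit:
    criterion_id: str
    kind: str  # PIM | PPO
    triggering_records: tuple[MedicationRecord, ...]
    rationale: str

    def __post_init__(self) -> None:
        if self.criterion_id.startswith("STOPP") and self.kind != PIM:
            raise ValueError("STOPP criteria flag PIMs")
        if self.criterion_id.startswith("START") and self.kind != PPO:
            raise ValueError("START criteria flag PPOs")


def _matches(record: MedicationRecord, prefixes: Iterable[str]) -> bool:
    return any(record.atc_code.startswith(p) for p in prefixes)


def chronic_filter(
    records: Sequence[MedicationRecord], admission_date: date | None = None
) -> list[MedicationRecord]:
    """Keep systemic medications started ≥90 days before admission.

    Idempotent.  ``admission_date`` overrides the per-record admission
    date when the records came from a source that lacks one.
    """
    out: list[MedicationRecord] = []
    for r in records:
        rec = r if admission_date is None else replace(r, admission_date=admission_date)
        if rec.start_date > rec.admission_date:
            raise ValueError(
                f"{rec.atc_code}: start {rec.start_date} after admission {rec.admission_date}"
            )
        if rec.form != "systemic":
            continue
        if rec.start_date <= rec.admission_date - timedelta(days=CHRONIC_DAYS):
            out.append(rec)
    return out


def evaluate_stopp_d5(
    records: Sequence[MedicationRecord], atc: AtcConfig = DEFAULT_ATC
) -> CriterionHit | None:
    """Benzodiazepine use for four or more weeks at admission."""
    hits = tuple(
        r
        for r in records
        if _matches(r, atc.benzodiazepines) and r.duration_days >= D5_MIN_DAYS
    )
    if not hits:
        return None
    return CriterionHit(
        criterion_id="STOPP_D5",
        kind=PIM,
        triggering_records=hits,
        rationale="benzodiazepine prescribed for >= 4 weeks",
    )


def evaluate_stopp_l1(
    records: Sequence[MedicationRecord], atc: AtcConfig = DEFAULT_ATC
) -> CriterionHit | None:
    """Transdermal strong opioid as first-line therapy for mild pain."""
    hits = []
    for r in records:
        if not _matches(r, atc.strong_opioids):
            continue
        if r.route != "transdermal" or r.indication != "mild_pain":
            continue
        predated = any(
            _matches(s, atc.step1_analgesics) and s.start_date < r.start_date
            for s in records
        )
        if not predated:
            hits.append(r)
    if not hits:
        return None
    return CriterionHit(
        criterion_id="STOPP_L1",
        kind=PIM,
        triggering_records=tuple(hits),
        rationale="transdermal strong opioid first line for mild pain",
    )


def evaluate_start_h2(
    records: Sequence[MedicationRecord], atc: AtcConfig = DEFAULT_ATC
) -> CriterionHit | None:
    """Laxative omission in a patient on regularly scheduled opioids."""
    regular_opioids = tuple(
        r for r in records if _matches(r, atc.opioids) and r.schedule == "regular"
    )
    if not regular_opioids:
        return None
    if any(_matches(r, atc.laxatives) for r in records):
        return None
    return CriterionHit(
        criterion_id="START_H2",
        kind=PPO,
        triggering_records=regular_opioids,
        rationale="regular opioid without a laxative",
    )


# ---------------------------------------------------------------------------
# Registry: the built-ins are data, not special cases
# ---------------------------------------------------------------------------

Predicate = Callable[[Sequence[MedicationRecord]], CriterionHit | None]


@dataclass(frozen=True)
class Criterion:
    criterion_id: str
    kind: str
    predicate: Predicate


@dataclass
class CriterionRegistry:
    criteria: list[Criterion] = field(default_factory=list)

    def register(self, criterion_id: str, kind: str, predicate: Predicate) -> None:
        if kind not in (PIM, PPO):
            raise ValueError("kind must be PIM or PPO")
        if any(c.criterion_id == criterion_id for c in self.criteria):
            raise ValueError(f"criterion {criterion_id!r} already registered")
        self.criteria.append(Criterion(criterion_id, kind, predicate))

    def evaluate(self, records: Sequence[MedicationRecord]) -> list[CriterionHit]:
        hits = []
        for c in self.criteria:
            hit = c.predicate(records)
            if hit is not None:
                hits.append(hit)
        return hits


def default_registry(atc: AtcConfig = DEFAULT_ATC) -> CriterionRegistry:
    reg = CriterionRegistry()
    reg.register("STOPP_D5", PIM, lambda r: evaluate_stopp_d5(r, atc))
    reg.register("STOPP_L1", PIM, lambda r: evaluate_stopp_l1(r, atc))
    reg.register("START_H2", PPO, lambda r: evaluate_start_h2(r, atc))
    return reg


def patient_flags(
    records: Sequence[MedicationRecord],
    registry: CriterionRegistry | None = None,
) -> dict:
    """Summary flags for one patient's chronic-filtered records."""
    if registry is None:
        registry = default_registry()
    hits = registry.evaluate(records)
    return {
        "any_pim": any(h.kind == PIM for h in hits),
        "any_ppo": any(h.kind == PPO for h in hits),
        "n_chronic": len(records),
        "polypharmacy_band": band_variable(len(records), "polypharmacy"),
        "hits": hits,
    }
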