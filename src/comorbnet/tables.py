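"""Packaged printed contingency counts for fixture mode.

A published cohort description usually prints, for each clinical
variable, the count of patients per level split by sex (and by age
stratum), i.e. a family of marginal 2×k tables rather than the joint
patient-level data.  This module ships such a table family for a
740-patient acute-admission cohort of older adults (394 women, 346 men)
so that every bivariate analysis can be re-run exactly from the printed
counts via :func:`comorbnet.cohort.expand_printed_table`.

Counts are stored per stratum: ``all``, ``65-84`` and ``>=85``; rows are
(female, male).  Percentages for two variables are defined over a
restricted denominator: nursing-home discharge over survivors, cause of
death over the deceased.
"""

from __future__ import annotations

from typing import Mapping, Sequence

__all__ = ["COHORT_TOTALS", "PRINTED_TABLES", "printed_table", "printed_variables"]

#: Patients per stratum, rows (female, male).
COHORT_TOTALS: Mapping[str, tuple[int, int]] = {
    "all": (394, 346),
    "65-84": (157, 187),
    ">=85": (237, 159),
}

# variable -> {"levels": [...], "counts": {stratum: ((female...), (male...))},
#              "denominator": optional note}
PRINTED_TABLES: dict[str, dict] = {
    "age_group4": {
        "levels": ["65-74", "75-84", "85-94", ">=95"],
        "counts": {"all": ((29, 128, 212, 25), (52, 135, 154, 5))},
    },
    "household": {
        "levels": ["alone", "nursing_home", "relatives_other"],
        "counts": {
            "all": ((73, 61, 260), (49, 34, 263)),
            "65-84": ((35, 12, 110), (29, 16, 142)),
            ">=85": ((38, 49, 150), (20, 18, 121)),
        },
    },
    "barthel_band": {
        "levels": [
            "total_dependence",
            "severe_dependence",
            "moderate_dependence",
            "low_dependence",
            "independent",
        ],
        "counts": {
            "all": ((59, 46, 79, 165, 45), (31, 30, 45, 129, 111)),
            "65-84": ((18, 10, 30, 66, 33), (16, 14, 22, 56, 79)),
            ">=85": ((41, 36, 49, 99, 12), (15, 16, 23, 73, 32)),
        },
    },
    "frailty": {
        "levels": ["no", "yes"],
        "counts": {
            "all": ((125, 269), (158, 188)),
            "65-84": ((59, 98), (98, 89)),
            ">=85": ((66, 171), (60, 99)),
        },
    },
    "charlson_tertile": {
        "levels": ["2-5", "6-8", "9-14"],
        "counts": {
            "all": ((86, 219, 89), (62, 192, 92)),
            "65-84": ((42, 79, 36), (44, 97, 46)),
            ">=85": ((44, 140, 53), (18, 95, 46)),
        },
    },
    "tobacco": {
        "levels": ["non_smoker", "former_smoker", "smoker", "not_available"],
        "counts": {
            "all": ((325, 19, 7, 43), (92, 197, 33, 24)),
            "65-84": ((133, 9, 5, 10), (37, 114, 25, 11)),
            ">=85": ((192, 10, 2, 33), (55, 83, 8, 13)),
        },
    },
    "alcohol": {
        "levels": ["non_drinker", "former_drinker", "heavy_drinker", "not_available"],
        "counts": {
            "all": ((338, 4, 6, 46), (197, 47, 51, 51)),
            "65-84": ((137, 2, 5, 13), (87, 35, 41, 24)),
            ">=85": ((201, 2, 1, 33), (110, 12, 10, 27)),
        },
    },
    "prior_exacerbation": {
        "levels": ["no", "yes"],
        "counts": {
            "all": ((126, 268), (99, 247)),
            "65-84": ((40, 117), (50, 137)),
            ">=85": ((86, 151), (49, 110)),
        },
    },
    "polypharmacy": {
        "levels": ["oligopharmacy", "moderate_polypharmacy", "excessive_polypharmacy"],
        "counts": {
            "all": ((28, 142, 224), (18, 117, 211)),
            "65-84": ((5, 52, 100), (9, 48, 130)),
            ">=85": ((23, 90, 124), (9, 69, 81)),
        },
    },
    "any_pim": {
        "levels": ["no", "yes"],
        "counts": {
            "all": ((91, 303), (107, 239)),
            "65-84": ((38, 119), (58, 129)),
            ">=85": ((53, 184), (49, 110)),
        },
    },
    "any_ppo": {
        "levels": ["no", "yes"],
        "counts": {
            "all": ((252, 142), (225, 121)),
            "65-84": ((104, 53), (131, 56)),
            ">=85": ((148, 89), (94, 65)),
        },
    },
    "nursing_home_discharge": {
        "levels": ["no", "yes"],
        "counts": {
            "all": ((294, 62), (275, 43)),
            "65-84": ((123, 15), (146, 24)),
            ">=85": ((171, 47), (129, 19)),
        },
        "denominator": "alive",
    },
    "in_hospital_mortality": {
        "levels": ["no", "yes"],
        "counts": {
            "all": ((356, 38), (318, 28)),
            "65-84": ((138, 19), (170, 17)),
            ">=85": ((218, 19), (148, 11)),
        },
    },
    "death_cause": {
        "levels": ["treatment_complication", "exacerbation", "other"],
        "counts": {
            "all": ((0, 32, 5), (1, 23, 2)),
            "65-84": ((0, 16, 2), (1, 13, 1)),
            ">=85": ((0, 16, 3), (0, 10, 1)),
        },
        "denominator": "deceased",
    },
    "adr_any": {
        "levels": ["no", "yes"],
        "counts": {
            "all": ((262, 132), (233, 113)),
            "65-84": ((98, 59), (122, 65)),
            ">=85": ((164, 73), (111, 48)),
        },
    },
    "adr_at_admission": {
        "levels": ["no", "yes"],
        "counts": {
            "all": ((47, 85), (45, 68)),
            "65-84": ((20, 39), (28, 37)),
            ">=85": ((27, 46), (17, 31)),
        },
        "denominator": "any_adr",
    },
    "adr_during_stay": {
        "levels": ["no", "yes"],
        "counts": {
            "all": ((69, 63), (56, 57)),
            "65-84": ((32, 27), (30, 35)),
            ">=85": ((37, 36), (26, 22)),
        },
        "denominator": "any_adr",
    },
    "adr_worst": {
        "levels": ["life_threatening", "lengthened_stay", "other_important"],
        "counts": {
            "all": ((9, 26, 28), (3, 28, 26)),
            "65-84": ((5, 13, 9), (2, 16, 17)),
            ">=85": ((4, 13, 19), (1, 12, 9)),
        },
        "denominator": "adr_during_stay",
    },
}


def printed_variables() -> list[str]:
    return list(PRINTED_TABLES)


def printed_table(
    variable: str, stratum: str = "all"
) -> tuple[Sequence[str], tuple[tuple[int, ...], tuple[int, ...]]]:
    """Levels and (female, male) counts of a packaged printed table."""
    if variable not in PRINTED_TABLES:
        raise KeyError(f"no printed table for {variable!r}")
    entry = PRINTED_TABLES[variable]
    if stratum not in entry["counts"]:
        raise KeyError(f"{variable!r} has no printed counts for stratum {stratum!r}")
    return entry["levels"], entry["counts"][stratum]
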