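"""The bivariate statistical battery.

Every variable in a cohort table is compared between women and men with a
Pearson chi-square test (categorical) or a Wilcoxon rank-sum test
(continuous), overall and within the two age strata (65–84, ≥85).  For
binary exposures reaching significance, the sex odds ratio (reference
category: men) is computed with a Woolf/logit confidence interval

    OR = ad / bc,    CI = exp( ln OR ± z_{1-α/2} · sqrt(1/a + 1/b + 1/c + 1/d) )

where a = exposed women, b = unexposed women, c = exposed men,
d = unexposed men.  Defaults follow common epidemiological reporting
practice: no Yates continuity correction, no zero-cell correction unless
explicitly requested, unadjusted p-values (a Benjamini–Hochberg option
exists but is off by default).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import FEMALE, MALE, SEXES

__all__ = [
    "ContingencyTable",
    "ORResult",
    "TestResult",
    "odds_ratio",
    "chi_square_test",
    "wilcoxon_rank_sum",
    "run_bivariate_battery",
    "assemble_forest",
    "render_forest",
    "band_variable",
    "benjamini_hochberg",
]

logger = logging.getLogger(__name__)

STRATA = ("all", "65-84", ">=85")


@dataclass(frozen=True)
class ContingencyTable:
    """A sex × level table of counts (rows female, male)."""

    variable: str
    levels: tuple[str, ...]
    counts: tuple[tuple[int, ...], tuple[int, ...]]
    stratum: str = "all"

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError("need at least two levels")
        for row in self.counts:
            if len(row) != len(self.levels):
                raise ValueError("counts shape must be 2 × len(levels)")
            if any(c < 0 for c in row):
                raise ValueError("counts must be non-negative")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, variable: str, stratum: str = "all"
    ) -> "ContingencyTable":
        sub = frame if stratum == "all" else frame[frame["age_group2"] == stratum]
        tab = pd.crosstab(sub["sex"], sub[variable]).reindex(index=list(SEXES), fill_value=0)
        levels = tuple(str(c) for c in tab.columns)
        counts = tuple(tuple(int(v) for v in tab.loc[s]) for s in SEXES)
        return cls(variable=variable, levels=levels, counts=counts, stratum=stratum)


@dataclass(frozen=True)
class ORResult:
    variable: str
    exposure_level: str
    or_point: float
    ci_low: float
    ci_high: float
    alpha: float
    cell_counts: tuple[int, int, int, int]
    stratum: str = "all"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError("confidence interval must contain the point estimate")


@dataclass(frozen=True)
class TestResult:
    variable: str
    test: str  # chi_square | wilcoxon
    statistic: float
    p_value: float
    df: int | None = None
    stratum: str = "all"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# Core tests
# ---------------------------------------------------------------------------


def odds_ratio(
    a: int,
    b: int,
    c: int,
    d: int,
    alpha: float = 0.05,
    variable: str = "",
    exposure_level: str = "",
    stratum: str = "all",
    haldane: bool = False,
) -> ORResult:
    """Woolf (logit) odds ratio for a 2×2 table.

    ``haldane=True`` opts in to the Haldane–Anscombe +0.5 correction for
    zero cells; by default any zero cell is an error so that printed-table
    reproduction is never silently perturbed.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    cells = (a, b, c, d)
    if 0 in cells:
        if not haldane:
            raise ValueError(
                "zero cell in 2×2 table; pass haldane=True for the +0.5 correction"
            )
        a, b, c, d = (x + 0.5 for x in cells)
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - alpha / 2)
    return ORResult(
        variable=variable,
        exposure_level=exposure_level,
        or_point=point,
        ci_low=point * math.exp(-z * se),
        ci_high=point * math.exp(z * se),
        alpha=alpha,
        cell_counts=cells,
        stratum=stratum,
    )


def chi_square_test(table: ContingencyTable, correction: bool = False) -> TestResult:
    """Pearson chi-square test of homogeneity on a 2×k table.

    No Yates continuity correction by default.  A zero row or column
    margin is rejected with the offending level named.
    """
    arr = table.array
    if (arr.sum(axis=1) == 0).any():
        sex = SEXES[int(np.flatnonzero(arr.sum(axis=1) == 0)[0])]
        raise ValueError(f"degenerate table for {table.variable!r}: no {sex} observations")
    col_sums = arr.sum(axis=0)
    if (col_sums == 0).any():
        lvl = table.levels[int(np.flatnonzero(col_sums == 0)[0])]
        raise ValueError(f"degenerate table for {table.variable!r}: empty level {lvl!r}")
    stat, p, dof, _ = sps.chi2_contingency(arr, correction=correction)
    return TestResult(
        variable=table.variable,
        test="chi_square",
        statistic=float(stat),
        p_value=float(p),
        df=int(dof),
        stratum=table.stratum,
    )


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    variable: str = "",
    stratum: str = "all",
    continuity: bool = True,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact enumeration when both samples have ≤10 observations and there
    are no ties; otherwise the normal approximation with mid-ranks and a
    tie-corrected variance.  The continuity correction is applied by
    default, matching R's ``wilcox.test``; pass ``continuity=False`` to
    drop it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    exact = x.size <= 10 and y.size <= 10 and not _has_ties(x, y)
    res = sps.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=continuity,
    )
    return TestResult(
        variable=variable,
        test="wilcoxon",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        df=None,
        stratum=stratum,
    )


# ---------------------------------------------------------------------------
# Variable banding
# ---------------------------------------------------------------------------

_BARTHEL_BANDS = (
    (0, 15, "total_dependence"),
    (20, 35, "severe_dependence"),
    (40, 55, "moderate_dependence"),
    (60, 95, "low_dependence"),
    (100, 100, "independent"),
)

#: Charlson tertile cut points (inclusive bands), configurable.
DEFAULT_CHARLSON_TERTILES = ((2, 5), (6, 8), (9, 14))


def band_variable(
    value: float,
    scheme: str,
    charlson_tertiles: Sequence[tuple[int, int]] = DEFAULT_CHARLSON_TERTILES,
) -> str:
    """Deterministic interval assignment for the analysis groupings.

    Schemes: ``age4`` decade bands (65–74, 75–84, 85–94, ≥95); ``age2``
    (65–84, ≥85); ``barthel`` dependence bands on the 0–100 scale in steps
    of 5; ``polypharmacy`` chronic-medication counts (0–4 oligopharmacy,
    5–9 moderate, ≥10 excessive); ``charlson_tertiles`` with configurable
    cut points.
    """
    if scheme == "age4":
        v = int(value)
        if v < 65:
            raise ValueError(f"age {v} below cohort minimum 65")
        if v <= 74:
            return "65-74"
        if v <= 84:
            return "75-84"
        if v <= 94:
            return "85-94"
        return ">=95"
    if scheme == "age2":
        v = int(value)
        if v < 65:
            raise ValueError(f"age {v} below cohort minimum 65")
        return "65-84" if v <= 84 else ">=85"
    if scheme == "barthel":
        v = int(value)
        if v % 5 != 0 or not 0 <= v <= 100:
            raise ValueError(f"Barthel score {v} not a multiple of 5 in [0, 100]")
        for lo, hi, name in _BARTHEL_BANDS:
            if lo <= v <= hi:
                return name
        raise AssertionError("unreachable")
    if scheme == "polypharmacy":
        v = int(value)
        if v < 0:
            raise ValueError("medication count must be >= 0")
        if v <= 4:
            return "oligopharmacy"
        if v <= 9:
            return "moderate_polypharmacy"
        return "excessive_polypharmacy"
    if scheme == "charlson_tertiles":
        v = int(value)
        for lo, hi in charlson_tertiles:
            if lo <= v <= hi:
                return f"{lo}-{hi}"
        raise ValueError(f"Charlson score {v} outside configured tertiles")
    raise ValueError(f"unknown banding scheme {scheme!r}")


# ---------------------------------------------------------------------------
# The battery
# ---------------------------------------------------------------------------

#: Levels treated as the exposed category of a binary variable.
_POSITIVE_LEVELS = {"yes", "true", "1", "1.0"}


def _exposure_level(levels: Sequence[str]) -> str:
    for lv in levels:
        if str(lv).strip().lower() in _POSITIVE_LEVELS:
            return str(lv)
    return str(levels[-1])


@dataclass
class BatteryResult:
    tests: list[TestResult] = field(default_factory=list)
    odds_ratios: list[ORResult] = field(default_factory=list)
    skipped: list[tuple[str, str, str]] = field(default_factory=list)  # (variable, stratum, reason)

    def tests_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(t) for t in self.tests])

    def odds_ratios_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.odds_ratios:
            a, b, c, d = r.cell_counts
            rows.append(
                {
                    "variable": r.variable,
                    "exposure_level": r.exposure_level,
                    "stratum": r.stratum,
                    "or": r.or_point,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "alpha": r.alpha,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "variable",
                "exposure_level",
                "stratum",
                "or",
                "ci_low",
                "ci_high",
                "alpha",
                "a",
                "b",
                "c",
                "d",
            ],
        )


def run_bivariate_battery(
    frame: pd.DataFrame,
    variables: Sequence[str],
    continuous: Iterable[str] = ("los_days",),
    strata: Sequence[str] = STRATA,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> BatteryResult:
    """Run the sex-difference battery over ``variables``.

    Categorical variables get a chi-square test of the sex × level table;
    variables listed in ``continuous`` get a Wilcoxon rank-sum test between
    sexes.  Binary categorical variables whose test reaches ``alpha`` also
    get a Woolf odds ratio (women vs men).  ``adjust="bh"`` applies a
    Benjamini–Hochberg correction across all computed p-values before the
    significance filter (off by default).
    """
    continuous = set(continuous)
    missing = [v for v in variables if v not in frame.columns]
    if missing:
        raise KeyError(f"unknown variable(s): {missing}")
    result = BatteryResult()
    pending_or: list[tuple[int, ContingencyTable]] = []
    for var in variables:
        for stratum in strata:
            sub = frame if stratum == "all" else frame[frame["age_group2"] == stratum]
            sub = sub[sub[var].notna()]
            if var in continuous:
                x = sub.loc[sub["sex"] == FEMALE, var].to_numpy(dtype=float)
                y = sub.loc[sub["sex"] == MALE, var].to_numpy(dtype=float)
                if x.size == 0 or y.size == 0:
                    result.skipped.append((var, stratum, "a sex has no observations"))
                    logger.warning("skipping %s in stratum %s: empty sex group", var, stratum)
                    continue
                result.tests.append(wilcoxon_rank_sum(x, y, variable=var, stratum=stratum))
                continue
            values = sub[var].astype(str)
            if values.nunique() < 2:
                result.skipped.append((var, stratum, "constant variable"))
                logger.warning("skipping %s in stratum %s: constant variable", var, stratum)
                continue
            tab = ContingencyTable.from_frame(
                sub.assign(**{var: values}), var, stratum="all"
            )
            tab = ContingencyTable(tab.variable, tab.levels, tab.counts, stratum=stratum)
            try:
                test = chi_square_test(tab)
            except ValueError as exc:
                result.skipped.append((var, stratum, str(exc)))
                logger.warning("skipping %s in stratum %s: %s", var, stratum, exc)
                continue
            result.tests.append(test)
            if len(tab.levels) == 2:
                pending_or.append((len(result.tests) - 1, tab))

    pvals = np.array([t.p_value for t in result.tests])
    effective = benjamini_hochberg(pvals) if adjust == "bh" else pvals
    for test_idx, tab in pending_or:
        if effective[test_idx] >= alpha:
            continue
        lvl = _exposure_level(tab.levels)
        j = tab.levels.index(lvl)
        a = tab.counts[0][j]
        b = tab.counts[0][1 - j]
        c = tab.counts[1][j]
        d = tab.counts[1][1 - j]
        try:
            result.odds_ratios.append(
                odds_ratio(
                    a, b, c, d, alpha=alpha, variable=tab.variable,
                    exposure_level=lvl, stratum=tab.stratum,
                )
            )
        except ValueError as exc:
            result.skipped.append((tab.variable, tab.stratum, f"OR skipped: {exc}"))
    return result


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    if n == 0:
        return p
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Forest plot
# ---------------------------------------------------------------------------


def assemble_forest(or_results: Sequence[ORResult]) -> list[dict]:
    """Forest-plot records sorted by descending odds ratio."""
    if not or_results:
        raise ValueError("no odds ratios to assemble")
    ordered = sorted(or_results, key=lambda r: r.or_point, reverse=True)
    return [
        {
            "label": f"{r.variable}={r.exposure_level}" if r.exposure_level else r.variable,
            "or": r.or_point,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "stratum": r.stratum,
        }
        for r in ordered
    ]


def render_forest(records: Sequence[dict], path) -> None:
    """Write the forest plot (log-scaled OR axis, women vs men) as SVG/PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "comorbnet"  # deterministic SVG ids
    n = len(records)
    fig, ax = plt.subplots(figsize=(6, max(2, 0.4 * n + 1)))
    ys = np.arange(n)[::-1]
    for y, rec in zip(ys, records):
        ax.plot([rec["ci_low"], rec["ci_high"]], [y, y], color="0.3", lw=1.5)
        ax.plot(rec["or"], y, "s", color="tab:blue")
    ax.axvline(1.0, color="0.6", ls="--", lw=1)
    ax.set_yticks(ys)
    ax.set_yticklabels([r["label"] for r in records])
    ax.set_xscale("log")
    ax.set_xlabel("Odds ratio (women vs men, 95% CI)")
    fig.tight_layout()
    if str(path).endswith(".svg"):
        fig.savefig(path, metadata={"Date": None})  # no embedded timestamp
    else:
        fig.savefig(path)
    plt.close(fig)
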