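"""Pipeline orchestration: cohort → rules → statistics → networks → layout.

A :class:`RunConfig` names exactly one input mode:

* ``synthetic`` — draw a cohort from a :class:`~comorbnet.cohort.CohortSpec`
  (seed mandatory);
* ``fixture`` — expand the packaged printed contingency tables and re-run
  every bivariate analysis from the printed counts (no patient-level
  joint data, so network/layout stages are skipped);
* ``file`` — read a cohort CSV (and optional long-format medication CSV)
  supplied by the user.

Every run writes a JSON manifest with the config snapshot, per-stage row
counts, wall-clock times and a SHA-256 checksum of every emitted file;
identical config + seed gives identical checksums.  On re-run with
``resume=True``, a stage is skipped when its recorded inputs and outputs
are unchanged on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    FEMALE,
    MALE,
    CohortSpec,
    MedicationModel,
    PairTarget,
    cohort_to_frame,
    expand_printed_table,
    generate_cohort,
    medication_records_from_frame,
    medications_to_frame,
)
from .layout import LayoutParams, force_atlas2
from .network import (
    ConditionCatalog,
    export_network,
    network_to_frames,
    per_sex_networks,
)
from .pim import chronic_filter, default_registry, patient_flags
from .stats import (
    ContingencyTable,
    assemble_forest,
    chi_square_test,
    odds_ratio,
    render_forest,
    run_bivariate_battery,
)
from .tables import COHORT_TOTALS, PRINTED_TABLES

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "PipelineError", "run_pipeline", "summarize"]

INPUT_MODES = ("synthetic", "fixture", "file")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    input_mode: str
    output_dir: str
    seed: int | None = None
    cohort_csv: str | None = None  # file mode
    medications_csv: str | None = None  # file mode, optional
    n_patients: int = 740
    condition_prevalence: dict[str, tuple[float, float]] = field(default_factory=dict)
    pair_targets: list[tuple[str, str, str, float]] = field(default_factory=list)
    medication_model: dict[str, float] | None = None
    syndromes: list[str] = field(default_factory=list)  # catalog kinds
    prevalence_threshold: float = 0.02
    oe_threshold: float = 2.0
    alpha: float = 0.05
    layout: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.input_mode not in INPUT_MODES:
            raise ValueError(f"input_mode must be one of {INPUT_MODES}")
        if self.input_mode == "synthetic" and self.seed is None:
            raise ValueError("synthetic mode requires a seed")
        if self.input_mode == "file" and not self.cohort_csv:
            raise ValueError("file mode requires cohort_csv")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("configuration must be a mapping")
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def cohort_spec(self) -> CohortSpec:
        med = MedicationModel(**self.medication_model) if self.medication_model else None
        return CohortSpec(
            n_patients=self.n_patients,
            seed=int(self.seed),
            condition_prevalence={
                k: tuple(v) for k, v in self.condition_prevalence.items()
            },
            pair_targets=[PairTarget(*t) for t in self.pair_targets],
            medication_model=med,
        )


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict[str, dict] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    df.to_csv(path, index=False)
    manifest.checksums[path.name] = _sha256(path)


class _Stage:
    """Context manager recording wall-clock and failures per stage."""

    def __init__(self, name: str, manifest: RunManifest):
        self.name = name
        self.manifest = manifest
        self.info: dict[str, Any] = {}

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self.info

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise PipelineError(f"stage {self.name!r} failed: {exc}") from exc
        self.info["wall_seconds"] = round(time.perf_counter() - self.t0, 4)
        self.manifest.stages[self.name] = self.info
        logger.info("stage %s: done in %.2fs", self.name, self.info["wall_seconds"])


def _stage_unchanged(name: str, old: RunManifest | None, manifest: RunManifest,
                     outdir: Path) -> bool:
    if old is None or name not in old.stages:
        return False
    files = old.stages[name].get("outputs", [])
    for f in files:
        p = outdir / f
        if not p.exists() or _sha256(p) != old.checksums.get(f):
            return False
    manifest.stages[name] = old.stages[name]
    for f in files:
        manifest.checksums[f] = old.checksums[f]
    logger.info("stage %s: outputs unchanged, skipped", name)
    return True


def run_pipeline(config: RunConfig, resume: bool = False) -> RunManifest:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_snapshot = json.loads(
        json.dumps(dataclasses.asdict(config), default=str)
    )
    manifest = RunManifest(config=config_snapshot, version=__version__)
    old: RunManifest | None = None
    manifest_path = outdir / "manifest.json"
    if resume and manifest_path.exists():
        try:
            raw = json.loads(manifest_path.read_text())
            old = RunManifest(**raw)
            if old.config != manifest.config:
                old = None
        except (TypeError, ValueError):
            old = None

    # ---- cohort stage ----------------------------------------------------
    cohort: pd.DataFrame | None = None
    meds: pd.DataFrame | None = None
    with _Stage("cohort", manifest) as info:
        if config.input_mode == "synthetic":
            records = generate_cohort(config.cohort_spec())
            cohort = cohort_to_frame(records)
            meds = medications_to_frame(records)
            _write_csv(cohort, outdir / "cohort.csv", manifest)
            _write_csv(meds, outdir / "medications.csv", manifest)
            info["outputs"] = ["cohort.csv", "medications.csv"]
        elif config.input_mode == "file":
            cohort = pd.read_csv(config.cohort_csv)
            if config.medications_csv:
                meds = pd.read_csv(config.medications_csv)
            info["outputs"] = []
        else:  # fixture: no joint patient-level data, printed tables only
            info["outputs"] = []
            info["printed_variables"] = list(PRINTED_TABLES)
        info["n_patients"] = 0 if cohort is None else int(len(cohort))

    # ---- rules stage -----------------------------------------------------
    if meds is not None and len(meds) and _stage_unchanged("rules", old, manifest, outdir):
        cohort = pd.read_csv(outdir / "cohort_flagged.csv")
    elif meds is not None and len(meds):
        with _Stage("rules", manifest) as info:
            registry = default_registry()
            by_patient = medication_records_from_frame(meds)
            hit_rows, flag_rows = [], []
            for pid in cohort["patient_id"]:
                eligible = chronic_filter(by_patient.get(pid, []))
                flags = patient_flags(eligible, registry)
                for h in flags.pop("hits"):
                    hit_rows.append(
                        {"patient_id": pid, "criterion_id": h.criterion_id, "kind": h.kind}
                    )
                flag_rows.append({"patient_id": pid, **flags})
            hits = pd.DataFrame(hit_rows, columns=["patient_id", "criterion_id", "kind"])
            flags_df = pd.DataFrame(flag_rows)
            cohort = cohort.merge(flags_df, on="patient_id", how="left")
            for col in ("any_pim", "any_ppo"):
                cohort[col] = np.where(cohort[col].fillna(False), "yes", "no")
            _write_csv(hits, outdir / "criterion_hits.csv", manifest)
            _write_csv(cohort, outdir / "cohort_flagged.csv", manifest)
            info["outputs"] = ["criterion_hits.csv", "cohort_flagged.csv"]
            info["n_hits"] = int(len(hits))

    # ---- statistics stage ------------------------------------------------
    with _Stage("stats", manifest) as info:
        if config.input_mode == "fixture":
            tests_df, ors_df = _fixture_battery(config.alpha)
        else:
            variables = [
                v
                for v in (
                    "household",
                    "frailty" if "frailty" in cohort.columns else None,
                    "frail" if "frail" in cohort.columns else None,
                    "any_pim" if "any_pim" in cohort.columns else None,
                    "any_ppo" if "any_ppo" in cohort.columns else None,
                    "died_in_hospital",
                    "adr_any",
                    "los_days",
                )
                if v is not None and v in cohort.columns
            ]
            variables += [c for c in config.condition_prevalence if c in cohort.columns]
            battery = run_bivariate_battery(
                cohort, variables, continuous=("los_days",), alpha=config.alpha
            )
            tests_df = battery.tests_frame()
            ors_df = battery.odds_ratios_frame()
        _write_csv(tests_df, outdir / "tests.csv", manifest)
        _write_csv(ors_df, outdir / "odds_ratios.csv", manifest)
        info["outputs"] = ["tests.csv", "odds_ratios.csv"]
        info["n_tests"] = int(len(tests_df))
        info["n_odds_ratios"] = int(len(ors_df))
        if len(ors_df):
            from .stats import ORResult

            recs = [
                ORResult(
                    variable=r.variable,
                    exposure_level=r.exposure_level,
                    or_point=r.or_,
                    ci_low=r.ci_low,
                    ci_high=r.ci_high,
                    alpha=r.alpha,
                    cell_counts=(r.a, r.b, r.c, r.d),
                    stratum=r.stratum,
                )
                for r in ors_df.rename(columns={"or": "or_"}).itertuples(index=False)
                if r.stratum == "all"
            ]
            if recs:
                render_forest(assemble_forest(recs), outdir / "forest.svg")
                manifest.checksums["forest.svg"] = _sha256(outdir / "forest.svg")
                info["outputs"].append("forest.svg")

    # ---- network + layout stages ----------------------------------------
    condition_cols = sorted(config.condition_prevalence) if cohort is not None else []
    if condition_cols:
        with _Stage("network", manifest) as info:
            catalog = ConditionCatalog.from_lists(
                chronic=[c for c in condition_cols if c not in config.syndromes],
                syndromes=[c for c in condition_cols if c in config.syndromes],
            )
            nets = per_sex_networks(
                cohort,
                catalog,
                prevalence_threshold=config.prevalence_threshold,
                oe_threshold=config.oe_threshold,
            )
            info["outputs"] = []
            for sex, g in nets.items():
                nodes_df, edges_df = network_to_frames(g)
                _write_csv(nodes_df, outdir / f"network_{sex}_nodes.csv", manifest)
                _write_csv(edges_df, outdir / f"network_{sex}_edges.csv", manifest)
                info["outputs"] += [f"network_{sex}_nodes.csv", f"network_{sex}_edges.csv"]
                info[f"n_nodes_{sex}"] = g.number_of_nodes()
                info[f"n_edges_{sex}"] = g.number_of_edges()

        with _Stage("layout", manifest) as info:
            params = LayoutParams(seed=int(config.seed or 0), **config.layout)
            info["outputs"] = []
            for sex, g in nets.items():
                if g.number_of_nodes() == 0:
                    continue
                pos = force_atlas2(g, params)
                coords = pd.DataFrame(
                    [{"condition": v, "x": x, "y": y} for v, (x, y) in sorted(pos.items())]
                )
                _write_csv(coords, outdir / f"layout_{sex}.csv", manifest)
                export_network(
                    g, outdir / f"network_{sex}.graphml", fmt="graphml", positions=pos
                )
                manifest.checksums[f"network_{sex}.graphml"] = _sha256(
                    outdir / f"network_{sex}.graphml"
                )
                info["outputs"] += [f"layout_{sex}.csv", f"network_{sex}.graphml"]

    # the manifest itself carries timings, so it is not checksummed
    manifest.save(manifest_path)
    return manifest


def _fixture_battery(alpha: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-run every printed-table bivariate analysis from the packaged counts."""
    test_rows, or_rows = [], []
    for var, entry in PRINTED_TABLES.items():
        levels = entry["levels"]
        for stratum, counts in entry["counts"].items():
            records = expand_printed_table(var, counts, levels=levels)
            tab = ContingencyTable(
                variable=var,
                levels=tuple(levels),
                counts=tuple(tuple(int(x) for x in row) for row in counts),
                stratum=stratum,
            )
            try:
                res = chi_square_test(tab)
            except ValueError:
                continue
            test_rows.append(
                {
                    "variable": var,
                    "test": res.test,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                    "stratum": stratum,
                    "n_records": len(records),
                }
            )
            if len(levels) == 2 and res.p_value < alpha:
                a, b = counts[0][1], counts[0][0]
                c, d = counts[1][1], counts[1][0]
                if 0 in (a, b, c, d):
                    continue
                orr = odds_ratio(
                    a, b, c, d, alpha=alpha, variable=var,
                    exposure_level=levels[1], stratum=stratum,
                )
                or_rows.append(
                    {
                        "variable": var,
                        "exposure_level": orr.exposure_level,
                        "stratum": stratum,
                        "or": orr.or_point,
                        "ci_low": orr.ci_low,
                        "ci_high": orr.ci_high,
                        "alpha": alpha,
                        "a": a, "b": b, "c": c, "d": d,
                    }
                )
    return (
        pd.DataFrame(test_rows),
        pd.DataFrame(
            or_rows,
            columns=["variable", "exposure_level", "stratum", "or", "ci_low",
                     "ci_high", "alpha", "a", "b", "c", "d"],
        ),
    )


def summarize(manifest: RunManifest, results_dir=None) -> str:
    """Human-readable markdown report of a completed run."""
    outdir = Path(results_dir or manifest.config["output_dir"])
    lines = ["# comorbnet run report", ""]
    mode = manifest.config["input_mode"]
    lines.append(f"- input mode: **{mode}**")
    if mode == "fixture":
        nf, nm = COHORT_TOTALS["all"]
        lines.append(f"- cohort: {nf + nm} patients ({nf} female, {nm} male)")
    else:
        n = manifest.stages.get("cohort", {}).get("n_patients", 0)
        lines.append(f"- cohort: {n} patients")
    tests_path = outdir / "tests.csv"
    if tests_path.exists():
        tests = pd.read_csv(tests_path)
        alpha = manifest.config.get("alpha", 0.05)
        sig = tests[(tests["stratum"] == "all") & (tests["p_value"] < alpha)]
        lines.append(
            f"- significant variables at alpha={alpha} (all strata pooled): "
            f"{', '.join(sorted(sig['variable'].unique())) or 'none'}"
        )
    ors_path = outdir / "odds_ratios.csv"
    if ors_path.exists():
        ors = pd.read_csv(ors_path)
        for _, r in ors[ors["stratum"] == "all"].iterrows():
            lines.append(
                f"  - {r['variable']}={r['exposure_level']}: OR {r['or']:.2f} "
                f"(95% CI {r['ci_low']:.2f}-{r['ci_high']:.2f})"
            )
    for sex in (FEMALE, MALE):
        key = f"n_nodes_{sex}"
        if key in manifest.stages.get("network", {}):
            info = manifest.stages["network"]
            lines.append(
                f"- {sex} network: {info[key]} nodes, {info[f'n_edges_{sex}']} edges"
            )
    if "network" not in manifest.stages:
        lines.append("- networks: no condition-level data in this mode (zero edges)")
    if "rules" in manifest.stages:
        lines.append(f"- prescribing-rule hits: {manifest.stages['rules'].get('n_hits', 0)}")
    return "\n".join(lines) + "\n"
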