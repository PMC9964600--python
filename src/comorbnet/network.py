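"""Per-sex co-occurrence networks of chronic conditions and geriatric syndromes.

For each sex subcohort, every unordered pair of conditions gets an edge
carrying the observed co-occurrence count, the count expected under
independence (``n_a * n_b / N``), their ratio O/E, and the pair
prevalence (``observed / N``).  Networks are filtered by strict
thresholds — node prevalence > 2% and pairwise O/E > 2 by default — and
exported as attribute-typed GraphML or GEXF for downstream drawing.

Node attributes include the within-subcohort prevalence and the sex
exclusivity: the share of all carriers of a condition (both sexes
pooled) who belong to this subcohort's sex, so
``exclusivity_female + exclusivity_male = 1`` for any condition carried
by at least one patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import FEMALE, MALE

__all__ = [
    "ConditionCatalog",
    "NetworkEdge",
    "pairwise_oe",
    "build_network",
    "per_sex_networks",
    "export_network",
    "import_network",
    "network_to_frames",
]

CHRONIC_CONDITION = "chronic_condition"
GERIATRIC_SYNDROME = "geriatric_syndrome"


@dataclass(frozen=True)
class ConditionCatalog:
    """Ordered list of condition identifiers with their kind."""

    names: tuple[str, ...]
    kinds: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("catalog must be nonempty")
        if len(set(self.names)) != len(self.names):
            raise ValueError("condition names must be unique")
        for n in self.names:
            if self.kinds.get(n) not in (CHRONIC_CONDITION, GERIATRIC_SYNDROME):
                raise ValueError(f"condition {n!r} lacks a valid kind")

    @classmethod
    def from_lists(
        cls, chronic: Sequence[str] = (), syndromes: Sequence[str] = ()
    ) -> "ConditionCatalog":
        kinds = {c: CHRONIC_CONDITION for c in chronic}
        kinds.update({g: GERIATRIC_SYNDROME for g in syndromes})
        return cls(names=tuple(chronic) + tuple(syndromes), kinds=kinds)


@dataclass(frozen=True)
class NetworkEdge:
    """One unordered condition pair within a subcohort (a < b lexicographically)."""

    condition_a: str
    condition_b: str
    observed: int
    expected: float
    oe_ratio: float
    pair_prevalence: float

    def __post_init__(self) -> None:
        if self.condition_a >= self.condition_b:
            raise ValueError("edge endpoints must satisfy condition_a < condition_b")
        if self.observed < 0 or self.oe_ratio < 0:
            raise ValueError("observed and O/E must be non-negative")
        if not 0.0 <= self.pair_prevalence <= 1.0:
            raise ValueError("pair prevalence outside [0, 1]")


def _indicator_matrix(frame: pd.DataFrame, catalog: ConditionCatalog) -> np.ndarray:
    missing = [c for c in catalog.names if c not in frame.columns]
    if missing:
        raise KeyError(f"condition(s) absent from cohort table: {missing}")
    return frame[list(catalog.names)].to_numpy(dtype=np.int64)


def pairwise_oe(frame: pd.DataFrame, catalog: ConditionCatalog) -> list[NetworkEdge]:
    """All-pairs observed/expected co-occurrence for one subcohort.

    ``frame`` must carry one 0/1 column per catalog condition.  For a pair
    (A, B): observed = patients with both; expected = n_A * n_B / N; edges
    are emitted for every pair with both marginals positive.
    """
    if len(frame) == 0:
        raise ValueError("subcohort is empty")
    X = _indicator_matrix(frame, catalog)
    n = len(frame)
    margins = X.sum(axis=0)
    co = X.T @ X  # co-occurrence counts; diagonal = margins
    edges: list[NetworkEdge] = []
    names = catalog.names
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if margins[i] == 0 or margins[j] == 0:
                continue
            a, b = sorted((names[i], names[j]))
            observed = int(co[i, j])
            expected = margins[i] * margins[j] / n
            edges.append(
                NetworkEdge(
                    condition_a=a,
                    condition_b=b,
                    observed=observed,
                    expected=float(expected),
                    oe_ratio=float(observed / expected),
                    pair_prevalence=float(observed / n),
                )
            )
    return edges


def build_network(
    frame: pd.DataFrame,
    catalog: ConditionCatalog,
    prevalence_threshold: float = 0.02,
    oe_threshold: float = 2.0,
    exclusivity: Mapping[str, float] | None = None,
    drop_isolated: bool = True,
    filter_on_pair_prevalence: bool = False,
) -> nx.Graph:
    """Filtered co-occurrence network for one subcohort.

    Nodes with prevalence strictly above ``prevalence_threshold`` are
    retained; edges need ``oe_ratio`` strictly above ``oe_threshold`` and
    both endpoints retained.  With ``filter_on_pair_prevalence`` the
    prevalence filter applies to the pair prevalence of each edge instead
    of to the node marginals (alternative reading of the 2% filter).
    Isolated nodes are dropped unless ``drop_isolated=False``.
    """
    if prevalence_threshold < 0 or oe_threshold < 0:
        raise ValueError("thresholds must be >= 0")
    if len(frame) == 0:
        raise ValueError("subcohort is empty")
    edges = pairwise_oe(frame, catalog)
    n = len(frame)
    X = _indicator_matrix(frame, catalog)
    prevalence = dict(zip(catalog.names, X.sum(axis=0) / n))

    g = nx.Graph()
    if filter_on_pair_prevalence:
        kept_nodes = {c for c in catalog.names if prevalence[c] > 0}
    else:
        kept_nodes = {c for c in catalog.names if prevalence[c] > prevalence_threshold}
    for c in kept_nodes:
        g.add_node(
            c,
            prevalence=float(prevalence[c]),
            kind=catalog.kinds[c],
            exclusivity=float(exclusivity.get(c, float("nan"))) if exclusivity else float("nan"),
        )
    for e in edges:
        if e.oe_ratio <= oe_threshold:
            continue
        if filter_on_pair_prevalence and e.pair_prevalence <= prevalence_threshold:
            continue
        if e.condition_a in kept_nodes and e.condition_b in kept_nodes:
            g.add_edge(
                e.condition_a,
                e.condition_b,
                observed=e.observed,
                expected=e.expected,
                oe_ratio=e.oe_ratio,
                pair_prevalence=e.pair_prevalence,
            )
    if drop_isolated:
        g.remove_nodes_from([v for v, d in dict(g.degree()).items() if d == 0])
    for v in g.nodes:
        g.nodes[v]["degree"] = int(g.degree(v))
    return g


def sex_exclusivity(frame: pd.DataFrame, catalog: ConditionCatalog) -> dict[str, dict[str, float]]:
    """Per-condition share of carriers belonging to each sex (pooled denominator)."""
    out: dict[str, dict[str, float]] = {FEMALE: {}, MALE: {}}
    for c in catalog.names:
        if c not in frame.columns:
            raise KeyError(f"condition {c!r} absent from cohort table")
        nf = int(frame.loc[frame["sex"] == FEMALE, c].sum())
        nm = int(frame.loc[frame["sex"] == MALE, c].sum())
        total = nf + nm
        if total == 0:
            continue
        out[FEMALE][c] = nf / total
        out[MALE][c] = nm / total
    return out


def per_sex_networks(
    frame: pd.DataFrame,
    catalog: ConditionCatalog,
    prevalence_threshold: float = 0.02,
    oe_threshold: float = 2.0,
    **kwargs,
) -> dict[str, nx.Graph]:
    """Independent filtered networks for the female and male subcohorts."""
    excl = sex_exclusivity(frame, catalog)
    nets: dict[str, nx.Graph] = {}
    for sex in (FEMALE, MALE):
        sub = frame[frame["sex"] == sex]
        if len(sub) == 0:
            raise ValueError(f"no {sex} patients in cohort")
        nets[sex] = build_network(
            sub,
            catalog,
            prevalence_threshold=prevalence_threshold,
            oe_threshold=oe_threshold,
            exclusivity=excl[sex],
            **kwargs,
        )
    return nets


def export_network(
    network: nx.Graph,
    path,
    fmt: str = "graphml",
    positions: Mapping[str, tuple[float, float]] | None = None,
) -> None:
    """Write the network with all node/edge attributes; optional layout coords."""
    g = network.copy()
    if positions is not None:
        missing = [v for v in g.nodes if v not in positions]
        if missing:
            raise ValueError(f"positions missing for nodes: {missing}")
        for v in g.nodes:
            g.nodes[v]["x"] = float(positions[v][0])
            g.nodes[v]["y"] = float(positions[v][1])
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "gexf":
        nx.write_gexf(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'graphml' or 'gexf')")


def import_network(path, fmt: str = "graphml") -> nx.Graph:
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "gexf":
        return nx.read_gexf(path)
    raise ValueError(f"unknown format {fmt!r}")


def network_to_frames(network: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge attribute tables for inspection / CSV dumps."""
    nodes = pd.DataFrame(
        [{"condition": v, **network.nodes[v]} for v in sorted(network.nodes)]
    )
    edge_rows = []
    for u, v, d in network.edges(data=True):
        a, b = sorted((u, v))
        edge_rows.append({"condition_a": a, "condition_b": b, **d})
    edges = pd.DataFrame(
        sorted(edge_rows, key=lambda r: (r["condition_a"], r["condition_b"]))
        if edge_rows
        else [],
        columns=["condition_a", "condition_b", "observed", "expected", "oe_ratio",
                 "pair_prevalence"],
    )
    return nodes, edges
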