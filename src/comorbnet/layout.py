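"""A from-scratch ForceAtlas2 force-directed layout.

ForceAtlas2 is a continuous graph layout with degree-weighted repulsion,
linear (or log) attraction along edges, gravity toward the origin, and an
adaptive global speed driven by the swing/traction balance:

* repulsion between every node pair: ``k_r (deg_i + 1)(deg_j + 1) / d``;
* attraction along each edge: ``w^delta * d`` in linear mode or
  ``w^delta * log(1 + d)`` in LinLog mode;
* gravity: ``k_g (deg_i + 1)`` toward the origin;
* swing of a node = magnitude of the change of its total force between
  iterations; traction = magnitude of the average; the global speed is
  ``tolerance * total_traction / total_swing`` with its growth capped at
  1.5× per iteration, and per-node speed is damped by the node's own
  swing.

Repulsion is computed exactly over all pairs (no Barnes–Hut tree): the
comorbidity networks handled here have at most a few dozen nodes, where
exactness beats asymptotic speed.  Everything is vectorised over an
(n, 2) position array and fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping

import networkx as nx
import numpy as np

__all__ = ["LayoutParams", "LayoutState", "initialize_positions", "force_atlas2"]

_KS = 0.1  # per-node speed scale, as in the reference algorithm
_KS_MAX = 10.0  # cap on per-node displacement relative to force
_SPEED_GROWTH_CAP = 1.5


@dataclass(frozen=True)
class LayoutParams:
    """Tunable layout parameters (the cited algorithm's knobs)."""

    scaling_ratio: float = 2.0  # k_r, repulsion strength
    gravity: float = 1.0  # k_g, pull toward origin
    edge_weight_influence: float = 1.0  # delta; 0 ignores weights
    tolerance: float = 1.0  # swing/speed trade-off
    max_iterations: int = 1000
    epsilon: float = 1e-4  # stop when mean displacement falls below this
    linlog_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scaling_ratio <= 0:
            raise ValueError("scaling_ratio must be > 0")
        if self.gravity < 0 or self.edge_weight_influence < 0:
            raise ValueError("gravity and edge_weight_influence must be >= 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class LayoutState:
    """Positions plus the adaptive-speed accumulators, for introspection."""

    positions: np.ndarray  # (n, 2)
    swing: np.ndarray  # per-node
    traction: np.ndarray  # per-node
    speed: float
    iteration: int
    speed_trace: list[float] = field(default_factory=list)


_MIN_DIST = 1e-9


def initialize_positions(
    network: nx.Graph, seed: int
) -> dict[Hashable, np.ndarray]:
    """Uniform random positions in the unit disc; coincident points jittered."""
    rng = np.random.default_rng(seed)
    nodes = list(network.nodes)
    n = len(nodes)
    r = np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    pos = _deterministic_jitter(pos)
    return {v: pos[i] for i, v in enumerate(nodes)}


def _deterministic_jitter(pos: np.ndarray) -> np.ndarray:
    """Separate exactly coincident points with a tiny index-dependent offset."""
    pos = pos.copy()
    n = len(pos)
    seen: dict[tuple[float, float], int] = {}
    for i in range(n):
        key = (float(pos[i, 0]), float(pos[i, 1]))
        while key in seen:
            angle = 2 * np.pi * (i + 1) / max(n, 1)
            pos[i] += 1e-6 * (i + 1) * np.array([np.cos(angle), np.sin(angle)])
            key = (float(pos[i, 0]), float(pos[i, 1]))
        seen[key] = i
    return pos


def _forces(
    pos: np.ndarray,
    mass: np.ndarray,
    edge_idx: np.ndarray,
    edge_w: np.ndarray,
    params: LayoutParams,
) -> np.ndarray:
    n = len(pos)
    force = np.zeros_like(pos)

    # exact pairwise repulsion: k_r * m_i * m_j / d along the separation
    diff = pos[:, None, :] - pos[None, :, :]  # (n, n, 2)
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, 1.0)
    dist = np.maximum(dist, _MIN_DIST)
    coef = params.scaling_ratio * np.outer(mass, mass) / (dist * dist)
    np.fill_diagonal(coef, 0.0)
    force += (coef[:, :, None] * diff).sum(axis=1)

    # linear (or linlog) attraction along edges, weighted by w^delta
    if len(edge_idx):
        i, j = edge_idx[:, 0], edge_idx[:, 1]
        d = pos[i] - pos[j]
        dn = np.maximum(np.linalg.norm(d, axis=1), _MIN_DIST)
        w = edge_w**params.edge_weight_influence
        if params.linlog_mode:
            mag = w * np.log1p(dn) / dn
        else:
            mag = w  # linear: |F| = w * d, direction d/|d|  ->  factor w
        pull = mag[:, None] * d
        np.add.at(force, i, -pull)
        np.add.at(force, j, pull)

    # gravity toward the origin: k_g * m_i
    if params.gravity > 0:
        dn = np.maximum(np.linalg.norm(pos, axis=1), _MIN_DIST)
        force -= params.gravity * mass[:, None] * pos / dn[:, None]
    return force


def force_atlas2(
    network: nx.Graph,
    params: LayoutParams | None = None,
    initial: Mapping[Hashable, np.ndarray] | None = None,
    weight: str | None = "pair_prevalence",
    return_state: bool = False,
):
    """Run the layout to convergence; returns ``{node: (x, y)}``.

    Edge weights default to the ``pair_prevalence`` attribute (the edge
    width encoding of the network figures); absent attributes count as
    weight 1.  With ``return_state=True`` a ``(positions, LayoutState)``
    pair is returned, exposing the speed trace and accumulators.
    """
    if params is None:
        params = LayoutParams()
    nodes = list(network.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("cannot lay out an empty network")
    index = {v: i for i, v in enumerate(nodes)}
    if initial is None:
        init = initialize_positions(network, params.seed)
    else:
        init = {v: np.asarray(initial[v], dtype=float) for v in nodes}
    pos = _deterministic_jitter(np.array([init[v] for v in nodes], dtype=float))

    mass = np.array([network.degree(v) + 1.0 for v in nodes])
    edge_idx = np.array(
        [[index[u], index[v]] for u, v in network.edges], dtype=int
    ).reshape(-1, 2)
    if weight is None:
        edge_w = np.ones(len(edge_idx))
    else:
        edge_w = np.array(
            [float(d.get(weight, 1.0)) for _, _, d in network.edges(data=True)]
        )

    prev_force = np.zeros_like(pos)
    speed = 1.0
    state = LayoutState(
        positions=pos, swing=np.zeros(n), traction=np.zeros(n), speed=speed, iteration=0
    )
    for it in range(1, params.max_iterations + 1):
        force = _forces(pos, mass, edge_idx, edge_w, params)
        swing = np.linalg.norm(force - prev_force, axis=1)
        traction = np.linalg.norm(force + prev_force, axis=1) / 2.0
        total_swing = float((mass * swing).sum())
        total_traction = float((mass * traction).sum())
        if total_swing > 0:
            target = params.tolerance * total_traction / total_swing
        else:
            target = speed * _SPEED_GROWTH_CAP
        speed = min(target, speed * _SPEED_GROWTH_CAP)

        fmag = np.maximum(np.linalg.norm(force, axis=1), _MIN_DIST)
        node_speed = _KS * speed / (1.0 + speed * np.sqrt(swing))
        node_speed = np.minimum(node_speed, _KS_MAX / fmag)
        displacement = node_speed[:, None] * force
        pos = pos + displacement
        if not np.isfinite(pos).all():
            raise FloatingPointError("non-finite coordinates in layout")  # pragma: no cover
        prev_force = force
        state.swing, state.traction = swing, traction
        state.speed = speed
        state.iteration = it
        state.speed_trace.append(speed)
        if float(np.linalg.norm(displacement, axis=1).mean()) < params.epsilon:
            break
    state.positions = pos
    result = {v: (float(pos[i, 0]), float(pos[i, 1])) for i, v in enumerate(nodes)}
    if return_state:
        return result, state
    return result
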