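"""Global landscape assembly: anchored potentials, ratios, rate exponents.

A landscape is a bipartite graph of stable fixed points and saddles.  Each
saddle contributes two uphill barriers (least-action values from the stable
states it connects).  Potential values are propagated over a breadth-first
spanning tree from an anchor node (the landscape is defined up to a constant);
non-tree edges measure the cycle inconsistency of the computed barriers.
Probability ratios between states follow the Boltzmann-Gibbs form
``rho(b)/rho(a) = exp(-(phi(b)-phi(a))/eps)``, valid at any noise strength,
and the transition-rate exponent from a state over a saddle is
``exp(-barrier/eps)`` (the prefactor is out of scope).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.integrate import solve_ivp

from .action import ActionResult, ode_adaptive_time, refine_action
from .fixed_points import FixedPoint, SaddleConnection, newton_find
from .systems import DynamicalSystem

__all__ = [
    "LandscapeGraph",
    "UndefinedRatioError",
    "barrier_pair",
    "assemble_landscape",
    "probability_ratio",
    "rate_exponent",
    "min_barrier",
    "potential_of_point",
]

logger = logging.getLogger(__name__)

BARRIER_RTOL = 1e-2  # relative tolerance expected of computed barriers


class UndefinedRatioError(ValueError):
    """Raised when two states are not connected through any saddle chain."""


@dataclass
class LandscapeGraph:
    """Fixed points, saddle connections and anchored potential values."""

    graph: nx.MultiGraph
    fixed_points: Dict[str, FixedPoint]
    phi: Dict[str, float]
    anchor: str
    component: Dict[str, int]
    inconsistency: float

    @property
    def stable_ids(self) -> List[str]:
        return sorted(i for i, fp in self.fixed_points.items() if fp.is_stable)

    @property
    def saddle_ids(self) -> List[str]:
        return sorted(i for i, fp in self.fixed_points.items() if fp.is_saddle)

    def barrier(self, stable: str, saddle: str) -> float:
        """Minimal uphill barrier from a stable state to an adjacent saddle."""
        if not self.graph.has_edge(stable, saddle):
            raise KeyError(f"no saddle connection between {stable!r} and {saddle!r}")
        data = self.graph.get_edge_data(stable, saddle)
        return min(d["barrier"] for d in data.values())

    def same_component(self, a: str, b: str) -> bool:
        return self.component[a] == self.component[b]

    def to_dict(self) -> dict:
        nodes = {
            i: {
                "x": fp.x.tolist(),
                "stability": fp.stability,
                "residual": fp.residual,
                "phi": self.phi[i],
                "component": self.component[i],
            }
            for i, fp in self.fixed_points.items()
        }
        edges = [
            {"stable": u if self.fixed_points[u].is_stable else v,
             "saddle": v if self.fixed_points[u].is_stable else u,
             "barrier": d["barrier"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return {"anchor": self.anchor, "inconsistency": self.inconsistency,
                "nodes": nodes, "edges": edges}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def barrier_table(self):
        """Barriers as a DataFrame (one row per stable-saddle edge)."""
        import pandas as pd
        rows = []
        for u, v, d in self.graph.edges(data=True):
            s, a = (u, v) if self.fixed_points[u].is_stable else (v, u)
            rows.append({"stable": s, "saddle": a, "barrier": d["barrier"]})
        return pd.DataFrame(rows).sort_values(["saddle", "stable"]).reset_index(drop=True)


def barrier_pair(system: DynamicalSystem, connection: SaddleConnection,
                 K: int = 100, T: Optional[float] = None,
                 refine: bool = True, rtol: float = 2e-3,
                 ) -> Tuple[Tuple[float, float], Tuple[ActionResult, ActionResult]]:
    """Uphill least-action barriers from both targets of a saddle connection.

    The time window for each side defaults to the recorded ODE descent
    duration (the uphill path is the time reverse of the adjoint descent).
    """
    if not connection.is_complete:
        raise ValueError("saddle connection is incomplete or diverged")
    barriers = []
    results = []
    for i, target in enumerate(connection.targets):
        T_i = T if T is not None else ode_adaptive_time(system, connection, i)
        if refine:
            res = refine_action(system, target.x, connection.saddle.x,
                                T=T_i, K0=K, rtol=rtol)
        else:
            from .action import minimize_action
            res = minimize_action(system, target.x, connection.saddle.x, K=K, T=T_i)
        barriers.append(max(res.action, 0.0))
        results.append(res)
    return (barriers[0], barriers[1]), (results[0], results[1])


def _node_ids(fps: Sequence[FixedPoint], labels: Optional[Dict[int, str]] = None
              ) -> List[str]:
    ids = []
    n_s = n_u = n_o = 0
    for i, fp in enumerate(fps):
        if labels and i in labels:
            ids.append(labels[i])
        elif fp.is_stable:
            n_s += 1
            ids.append(f"S{n_s}")
        elif fp.is_saddle:
            n_u += 1
            ids.append(f"U{n_u}")
        else:
            n_o += 1
            ids.append(f"O{n_o}")
    return ids


def assemble_landscape(system: DynamicalSystem, fps: Sequence[FixedPoint],
                       connections: Sequence[SaddleConnection],
                       anchor: Optional[str] = None, K: int = 100,
                       labels: Optional[Dict[int, str]] = None,
                       precomputed: Optional[Dict[int, Tuple[float, float]]] = None,
                       inconsistency_warn: float = 2 * BARRIER_RTOL,
                       ) -> LandscapeGraph:
    """Build the anchored landscape graph from fixed points and connections.

    Barriers are computed with :func:`barrier_pair` unless supplied in
    ``precomputed`` (connection index -> pair).  Potentials are propagated
    breadth-first from ``anchor`` (default: the first stable node); each
    disconnected component is anchored independently at its first stable node
    and a warning is logged, since no ratio across components is defined.
    Cycle mismatches beyond ``inconsistency_warn`` are logged as well.
    """
    fps = list(fps)
    ids = _node_ids(fps, labels)
    identity = {id(fp): i for i, fp in enumerate(fps)}

    def index_of(fp: FixedPoint) -> Optional[int]:
        i = identity.get(id(fp))
        if i is not None:
            return i
        # fall back to coordinate matching (targets may be re-polished copies)
        for j, cand in enumerate(fps):
            if np.linalg.norm(cand.x - fp.x) < 1e-6 * (1 + np.linalg.norm(fp.x)):
                return j
        return None

    fixed_points = dict(zip(ids, fps))
    G = nx.MultiGraph()
    G.add_nodes_from(ids)

    for ci, conn in enumerate(connections):
        si = index_of(conn.saddle)
        if si is None:
            raise ValueError("connection saddle not among supplied fixed points")
        if precomputed is not None and ci in precomputed:
            pair = precomputed[ci]
        else:
            pair, _ = barrier_pair(system, conn, K=K)
        for t, b in zip(conn.targets, pair):
            ti = index_of(t)
            if ti is None:
                raise ValueError("connection target not among supplied fixed points")
            if b < 0:
                raise ValueError("negative barrier")
            G.add_edge(ids[ti], ids[si], barrier=float(b))

    stable_ids = sorted(i for i, fp in fixed_points.items() if fp.is_stable)
    if anchor is None:
        if not stable_ids:
            raise ValueError("landscape has no stable fixed point to anchor")
        anchor = stable_ids[0]
    if anchor not in fixed_points:
        raise ValueError(f"anchor {anchor!r} is not a fixed point id")

    phi: Dict[str, float] = {}
    component: Dict[str, int] = {}
    inconsistency = 0.0
    comps = list(nx.connected_components(G))
    # order components so the one holding the requested anchor comes first
    comps.sort(key=lambda c: (anchor not in c, sorted(c)[0]))
    for c_idx, comp in enumerate(comps):
        comp_nodes = sorted(comp)
        if c_idx == 0 and anchor in comp:
            root = anchor
        else:
            roots = [n for n in comp_nodes if fixed_points[n].is_stable]
            root = roots[0] if roots else comp_nodes[0]
            if len(comps) > 1:
                logger.warning(
                    "landscape component %d is disconnected; anchored at %r "
                    "(no ratio across components)", c_idx, root)
        phi[root] = 0.0
        component[root] = c_idx
        tree_edges = list(nx.bfs_edges(G, root))
        seen_pairs = set()
        for u, v in tree_edges:
            data = G.get_edge_data(u, v)
            b = min(d["barrier"] for d in data.values())
            sgn = +1.0 if fixed_points[u].is_stable else -1.0
            phi[v] = phi[u] + sgn * b
            component[v] = c_idx
            seen_pairs.add(frozenset((u, v)))
        # non-tree edges (and parallel barriers) measure cycle inconsistency
        for u, v, d in G.subgraph(comp).edges(data=True):
            s, a = (u, v) if fixed_points[u].is_stable else (v, u)
            mismatch = abs(phi[a] - (phi[s] + d["barrier"]))
            if frozenset((u, v)) in seen_pairs:
                # tree edge: only parallel-edge spread counts
                data = G.get_edge_data(u, v)
                bmin = min(dd["barrier"] for dd in data.values())
                mismatch = abs(d["barrier"] - bmin)
            inconsistency = max(inconsistency, mismatch)
    for n in G.nodes:
        if n not in phi:  # isolated node
            phi[n] = 0.0
            component[n] = len(comps)
            comps.append({n})
    if inconsistency > inconsistency_warn:
        logger.warning("landscape cycle inconsistency %.3g exceeds %.3g",
                       inconsistency, inconsistency_warn)
    return LandscapeGraph(graph=G, fixed_points=fixed_points, phi=phi,
                          anchor=anchor, component=component,
                          inconsistency=float(inconsistency))


def probability_ratio(graph: LandscapeGraph, a: str, b: str, eps: float) -> float:
    """Steady-state probability ratio ``rho(b)/rho(a)`` at noise strength eps."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    if a not in graph.phi or b not in graph.phi:
        raise KeyError("unknown state id")
    if not graph.same_component(a, b):
        raise UndefinedRatioError(
            f"{a!r} and {b!r} lie in different landscape components")
    return math.exp(-(graph.phi[b] - graph.phi[a]) / eps)


def rate_exponent(graph: LandscapeGraph, from_id: str, saddle: str,
                  eps: float) -> float:
    """Exponential factor ``exp(-barrier/eps)`` of the transition rate.

    This is the asymptotic Kramers-type exponent only (proportionality; the
    prefactor is not computed), meaningful when eps is small compared with
    the barrier.  With several parallel connections the minimal barrier
    dominates.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    b = graph.barrier(from_id, saddle)
    return math.exp(-b / eps)


def min_barrier(graph: LandscapeGraph, a: str, b: str) -> Tuple[float, str]:
    """Smallest barrier from stable state ``a`` toward ``b`` over shared saddles."""
    best = None
    best_saddle = None
    for s in graph.saddle_ids:
        if graph.graph.has_edge(a, s) and graph.graph.has_edge(b, s):
            bar = graph.barrier(a, s)
            if best is None or bar < best:
                best, best_saddle = bar, s
    if best is None:
        raise UndefinedRatioError(f"no common saddle between {a!r} and {b!r}")
    return best, best_saddle


def potential_of_point(system: DynamicalSystem, graph: LandscapeGraph, x,
                       K: int = 100, descent_tol: float = 1e-8,
                       t_max: float = 1e4, bound: float = 1e6,
                       rtol: float = 2e-3) -> float:
    """Potential value of an arbitrary state within some basin of attraction.

    The ODE is integrated from ``x`` to its stable fixed point ``x*``; the
    returned value is ``phi(x*)`` plus the least-action potential difference
    from ``x*`` up to ``x``, with the descent duration as time window.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))

    def rhs(t, y):
        return system.drift(y)

    def settled(t, y):
        return np.linalg.norm(system.drift(y)) - descent_tol
    settled.terminal = True
    settled.direction = -1

    def escaped(t, y):
        return np.linalg.norm(y) - bound
    escaped.terminal = True
    escaped.direction = 1

    sol = solve_ivp(rhs, (0.0, t_max), x, events=[settled, escaped],
                    rtol=1e-10, atol=1e-12, method="LSODA")
    if len(sol.t_events[1]) > 0 or not sol.success:
        raise ValueError("descent from x diverged; point outside landscape domain")
    x_end = sol.y[:, -1]
    T_dn = max(float(sol.t[-1]), 1.0)
    target_id = None
    for i in graph.stable_ids:
        fp = graph.fixed_points[i]
        if np.linalg.norm(fp.x - x_end) < 1e-3 * (1 + np.linalg.norm(x_end)):
            target_id = i
            break
    if target_id is None:
        polished = newton_find(system, x_end)
        raise ValueError(
            "descent reached a stable state not present in the landscape"
            + ("" if polished is None else f" (near {polished.x})"))
    fp = graph.fixed_points[target_id]
    if np.linalg.norm(fp.x - x) <= descent_tol * (1 + np.linalg.norm(x)):
        return graph.phi[target_id]
    res = refine_action(system, fp.x, x, T=T_dn, K0=K, rtol=rtol)
    return graph.phi[target_id] + max(res.action, 0.0)
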