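"""Model/Results interface tying the landscape pipeline together.

:class:`LandscapeModel` holds a dynamical system plus the search
configuration (bounding box, number of Newton starts, path-discretization
defaults); :meth:`LandscapeModel.fit` runs the full protocol — fixed-point
sweep, saddle descents, least-action barriers, anchored potential assembly —
and returns a :class:`LandscapeResults` carrying the landscape graph,
diagnostic tables and a ``summary()``.  Stochastic simulation and pointwise
potential evaluation hang off these two objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import fixed_points as fp_mod
from . import landscape as ls_mod
from . import simulate as sim_mod
from .systems import DynamicalSystem, HillNetworkSpec, build_hill_system, make_fixture

__all__ = ["LandscapeModel", "LandscapeResults"]


class LandscapeModel:
    """Potential-landscape analysis of a multistable stochastic system.

    Parameters
    ----------
    system : DynamicalSystem
        The drift/diffusion model to analyse.
    bounds : array-like of shape (N, 2)
        Bounding box for fixed-point search starts.
    n_starts : int
        Number of Latin-hypercube Newton starts.
    K : int
        Base number of path segments for action minimization (refined
        adaptively).
    dedup_radius, perturb_size : float
        Fixed-point merge radius and saddle perturbation size.
    """

    def __init__(self, system: DynamicalSystem, bounds,
                 n_starts: int = 200, K: int = 100,
                 dedup_radius: float = 1e-4, perturb_size: float = 1e-3):
        self.system = system
        self.bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
        if self.bounds.shape != (system.N, 2):
            raise ValueError(f"bounds must have shape ({system.N}, 2)")
        self.n_starts = int(n_starts)
        self.K = int(K)
        self.dedup_radius = float(dedup_radius)
        self.perturb_size = float(perturb_size)

    @classmethod
    def from_fixture(cls, name: str, bounds=None, **kwargs) -> "LandscapeModel":
        fixture_params = kwargs.pop("params", {})
        system = make_fixture(name, **fixture_params)
        if bounds is None:
            bounds = np.tile([[-2.5, 2.5]], (system.N, 1))
        return cls(system, bounds, **kwargs)

    @classmethod
    def from_hill_spec(cls, spec: HillNetworkSpec, bounds, **kwargs) -> "LandscapeModel":
        return cls(build_hill_system(spec), bounds, **kwargs)

    def fit(self, seed: int = 0, extra_starts: Optional[np.ndarray] = None,
            anchor: Optional[str] = None,
            labels: Optional[Dict[int, str]] = None) -> "LandscapeResults":
        """Run the global-landscape protocol and return the results object."""
        starts = fp_mod.latin_hypercube_starts(self.bounds, self.n_starts, seed=seed)
        if extra_starts is not None:
            starts = np.vstack([starts, np.atleast_2d(extra_starts)])
        fps = fp_mod.sweep_fixed_points(self.system, starts,
                                        dedup_radius=self.dedup_radius)
        stable = [fp for fp in fps if fp.is_stable]
        saddles = [fp for fp in fps if fp.is_saddle]
        connections = []
        for s in saddles:
            conn = fp_mod.descend_from_saddle(self.system, s,
                                              perturb_size=self.perturb_size,
                                              stable_points=stable)
            if conn.is_complete:
                connections.append(conn)
        graph = ls_mod.assemble_landscape(self.system, fps, connections,
                                          anchor=anchor, K=self.K, labels=labels)
        return LandscapeResults(model=self, fixed_points_=fps,
                                connections=connections, graph=graph, seed=seed)

    def simulate(self, interpretation: str, eps: float, dt: float, steps: int,
                 replicates: int = 1, seed: int = 0, **kwargs):
        """Euler-Maruyama ensemble simulation of the system."""
        return sim_mod.simulate(self.system, interpretation, eps, dt, steps,
                                replicates=replicates, seed=seed, **kwargs)


@dataclass
class LandscapeResults:
    """Fitted landscape: fixed points, barriers, anchored potentials."""

    model: LandscapeModel
    fixed_points_: list
    connections: list
    graph: ls_mod.LandscapeGraph
    seed: int

    # -- tables ---------------------------------------------------------
    def fixed_point_table(self) -> pd.DataFrame:
        rows = []
        for node_id in sorted(self.graph.fixed_points):
            fp = self.graph.fixed_points[node_id]
            rows.append({
                "id": node_id,
                **{f"x{i+1}": fp.x[i] for i in range(fp.x.size)},
                "stability": fp.stability,
                "residual": fp.residual,
                "phi": self.graph.phi[node_id],
                "component": self.graph.component[node_id],
                "max_re_eig": float(np.max(fp.eigenvalues.real)),
            })
        return pd.DataFrame(rows)

    def barrier_table(self) -> pd.DataFrame:
        return self.graph.barrier_table()

    def ratio_table(self, epsilons: Sequence[float],
                    reference: Optional[str] = None) -> pd.DataFrame:
        """Probability of each stable state relative to ``reference``.

        One column per noise strength; rows are stable states in the
        reference's component.
        """
        ref = reference or self.graph.anchor
        ids = [i for i in self.graph.stable_ids
               if self.graph.same_component(i, ref)]
        data = {"state": ids}
        for eps in epsilons:
            data[f"eps={eps:g}"] = [
                ls_mod.probability_ratio(self.graph, ref, i, eps) for i in ids]
        return pd.DataFrame(data)

    # -- scalar queries ---------------------------------------------------
    def probability_ratio(self, a: str, b: str, eps: float) -> float:
        return ls_mod.probability_ratio(self.graph, a, b, eps)

    def rate_exponent(self, from_id: str, saddle: str, eps: float) -> float:
        return ls_mod.rate_exponent(self.graph, from_id, saddle, eps)

    def potential_at(self, x, K: Optional[int] = None) -> float:
        return ls_mod.potential_of_point(self.model.system, self.graph, x,
                                         K=K or self.model.K)

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        sys_name = self.model.system.name or "user system"
        fps = self.fixed_point_table()
        n_stable = int((fps["stability"] == "stable").sum())
        n_saddle = int((fps["stability"] == "saddle").sum())
        lines = [
            "Potential landscape summary",
            "=" * 64,
            f"system: {sys_name}   N={self.model.system.N}   seed={self.seed}",
            f"fixed points: {len(fps)} ({n_stable} stable, {n_saddle} saddle)",
            f"anchor: {self.graph.anchor}   cycle inconsistency: "
            f"{self.graph.inconsistency:.3g}",
            "",
            "Fixed points (potential relative to anchor)",
            "-" * 64,
            fps.to_string(index=False,
                          float_format=lambda v: f"{v:.6g}"),
        ]
        bt = self.barrier_table()
        if len(bt):
            lines += [
                "",
                "Barriers (uphill least-action values, stable -> saddle)",
                "-" * 64,
                bt.to_string(index=False, float_format=lambda v: f"{v:.6g}"),
            ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<LandscapeResults: {len(self.graph.stable_ids)} stable, "
                f"{len(self.graph.saddle_ids)} saddle>")
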