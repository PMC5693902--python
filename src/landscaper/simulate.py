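"""Stochastic simulation under Ito, Stratonovich and A-type interpretations.

All interpretations are integrated with the explicit Euler-Maruyama scheme;
the interpretation enters purely as a drift correction:

* ``ito``           — drift ``f``;
* ``atype``         — drift ``f + eps * Delta f`` with
  ``Delta f_i = sum_j d/dx_j (D_ij + Q_ij)`` (the exact Ito-equivalent form
  of A-type integration, which preserves the ODE fixed-point structure at
  any noise strength);
* ``stratonovich``  — drift ``f + eps * sum_jk G_kj d/dx_k G_ij`` (the
  standard Stratonovich-to-Ito conversion).

Noise convention: the white noise has covariance ``2 eps delta(t-t')``, so
each Euler step adds ``G(x) sqrt(2 eps dt) eta`` with standard-normal eta.
The factor 2 (rather than ``eps dt``) is easy to get wrong when porting:
with it, the stationary variance of ``dx/dt = -x + zeta`` is exactly eps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .systems import DynamicalSystem

__all__ = [
    "TrajectoryEnsemble",
    "EmpiricalPotential",
    "simulate",
    "empirical_potential",
    "peak_positions",
]

INTERPRETATIONS = ("ito", "stratonovich", "atype")


@dataclass
class TrajectoryEnsemble:
    """Post-burn-in samples pooled across replicate trajectories."""

    samples: np.ndarray  # (n_samples, N)
    dt: float
    steps: int
    burn_in: int
    thinning: int
    replicates: int
    seed: int
    interpretation: str
    eps: float

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    def to_dataframe(self):
        import pandas as pd
        cols = {f"x{i+1}": self.samples[:, i] for i in range(self.samples.shape[1])}
        return pd.DataFrame(cols)


@dataclass
class EmpiricalPotential:
    """``-eps ln rho_ss`` on a histogram grid, shifted so the minimum is 0.

    ``values`` is NaN on unoccupied bins (unobserved, not infinite).
    """

    edges: list              # per-axis bin edges
    values: np.ndarray       # potential per bin, NaN where unoccupied
    counts: np.ndarray
    eps: float

    @property
    def centers(self) -> list:
        return [0.5 * (e[:-1] + e[1:]) for e in self.edges]

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def to_dataframe(self, min_count: int = 1):
        """Sparse table of occupied bin centers and potential values."""
        import pandas as pd
        idx = np.argwhere(self.counts >= min_count)
        cents = self.centers
        data = {f"x{d+1}": cents[d][idx[:, d]] for d in range(len(cents))}
        data["count"] = self.counts[tuple(idx.T)]
        data["potential"] = self.values[tuple(idx.T)]
        return pd.DataFrame(data)


def _drift_function(system: DynamicalSystem, interpretation: str, eps: float):
    if interpretation == "ito":
        return system.drift_batch
    if interpretation == "atype":
        if not system.has_Q:
            raise ValueError("A-type simulation requires the antisymmetric matrix Q")
        if system.delta_f is not None:
            def drift(X):
                base = system.drift_batch(X)
                corr = np.apply_along_axis(system.delta_f, -1, X) if X.ndim > 1 \
                    else system.delta_f(X)
                return base + eps * np.asarray(corr, dtype=float)
            return drift
        if system.diffusion_is_constant and system._Q_const is not None:
            return system.drift_batch  # Delta f = 0 for constant D and Q
        def drift(X):
            base = system.drift_batch(X)
            corr = np.apply_along_axis(system.atype_correction, -1, np.atleast_2d(X))
            return base + eps * corr.reshape(base.shape)
        return drift
    if interpretation == "stratonovich":
        if system.G is None and system.diffusion_is_constant:
            return system.drift_batch  # constant G: no correction
        def strat_corr(x):
            out = np.zeros(system.N)
            h = 1e-5
            G0 = system.noise_matrix(x)
            for k in range(system.N):
                e = np.zeros(system.N)
                e[k] = h
                dG = (system.noise_matrix(x + e) - system.noise_matrix(x - e)) / (2 * h)
                out += dG @ G0[k, :]
            return out
        def drift(X):
            base = system.drift_batch(X)
            corr = np.apply_along_axis(strat_corr, -1, np.atleast_2d(X))
            return base + eps * corr.reshape(base.shape)
        return drift
    raise ValueError(f"unknown interpretation {interpretation!r}; "
                     f"choose from {INTERPRETATIONS}")


def simulate(system: DynamicalSystem, interpretation: str, eps: float,
             dt: float, steps: int, replicates: int = 1, seed: int = 0,
             burn_in: Optional[int] = None, thinning: int = 10,
             x0: Optional[np.ndarray] = None,
             x0_scale: float = 1.0) -> TrajectoryEnsemble:
    """Euler-Maruyama ensemble simulation; returns pooled thinned samples.

    ``burn_in`` defaults to the first 20% of ``steps``.  Initial states are
    ``x0`` broadcast over replicates, or i.i.d. normal with ``x0_scale``.
    With ``eps = 0`` this reduces to deterministic forward Euler.  NaN or
    overflow aborts with the offending step index.
    """
    if dt <= 0 or steps < 1 or replicates < 1:
        raise ValueError("dt, steps and replicates must be positive")
    if burn_in is None:
        burn_in = int(0.2 * steps)
    drift = _drift_function(system, interpretation, eps)
    rng = np.random.default_rng(seed)
    if x0 is not None:
        X = np.broadcast_to(np.asarray(x0, dtype=float),
                            (replicates, system.N)).copy()
    else:
        X = rng.normal(scale=x0_scale, size=(replicates, system.N))
    G_const = None
    if system.G is None and system.diffusion_is_constant:
        G_const = system.noise_matrix(np.zeros(system.N))
        if np.allclose(G_const, np.eye(system.N)):
            G_const = "identity"
    amp = np.sqrt(2.0 * eps * dt)
    out = []
    for k in range(steps):
        X = X + drift(X) * dt
        if eps > 0:
            eta = rng.standard_normal((replicates, system.N))
            if G_const is None:
                for r in range(replicates):
                    X[r] += amp * (system.noise_matrix(X[r]) @ eta[r])
            elif isinstance(G_const, str):
                X += amp * eta
            else:
                X += amp * eta @ G_const.T
        if not np.all(np.isfinite(X)):
            raise FloatingPointError(
                f"simulation produced NaN/overflow at step {k} "
                f"(dt may be too large for the local Lipschitz scale)")
        if k >= burn_in and (k - burn_in) % thinning == 0:
            out.append(X.copy())
    samples = np.concatenate(out, axis=0) if out else np.empty((0, system.N))
    return TrajectoryEnsemble(samples=samples, dt=dt, steps=steps,
                              burn_in=burn_in, thinning=thinning,
                              replicates=replicates, seed=seed,
                              interpretation=interpretation, eps=eps)


def empirical_potential(ensemble: TrajectoryEnsemble, box: Sequence[Tuple[float, float]],
                        bins: int, eps: Optional[float] = None) -> EmpiricalPotential:
    """Histogram estimate of ``-eps ln rho_ss`` over an axis-aligned box.

    The density is normalized over the box; the potential is shifted so the
    minimum over occupied bins is zero (a potential is defined only up to a
    constant).  Empty bins get NaN.
    """
    if ensemble.n == 0:
        raise ValueError("empty ensemble")
    if eps is None:
        eps = ensemble.eps
    box = np.atleast_2d(np.asarray(box, dtype=float))
    N = ensemble.samples.shape[1]
    edges = [np.linspace(box[d, 0], box[d, 1], bins + 1) for d in range(N)]
    counts, _ = np.histogramdd(ensemble.samples, bins=edges)
    total = counts.sum()
    if total == 0:
        raise ValueError("no samples fall inside the box")
    widths = np.prod([e[1] - e[0] for e in edges])
    dens = counts / (total * widths)
    pot = np.full_like(dens, np.nan)
    occ = counts > 0
    pot[occ] = -eps * np.log(dens[occ])
    pot = pot - np.nanmin(pot)
    return EmpiricalPotential(edges=edges, values=pot,
                              counts=counts.astype(int), eps=eps)


def boltzmann_bin_probabilities(system, box: Sequence[Tuple[float, float]],
                                bins: int, eps: float, subdiv: int = 8) -> np.ndarray:
    """Exact Boltzmann bin probabilities ``exp(-phi/eps)`` for 2-D systems.

    Integrates the analytic steady state over each histogram bin on a
    ``subdiv``-times finer midpoint grid and normalizes over the box — the
    correct reference for comparing a *binned* empirical potential against
    an analytic potential (comparing against the bin-center value of phi
    instead introduces an O(grad phi * bin width) bias).
    Requires ``system.phi`` and ``N = 2``.
    """
    if system.phi is None:
        raise ValueError("system has no analytic potential")
    if system.N != 2:
        raise NotImplementedError("reference integration implemented for N=2")
    box = np.atleast_2d(np.asarray(box, dtype=float))
    n1 = bins * subdiv
    g1 = np.linspace(box[0, 0], box[0, 1], n1, endpoint=False) \
        + (box[0, 1] - box[0, 0]) / n1 / 2
    g2 = np.linspace(box[1, 0], box[1, 1], n1, endpoint=False) \
        + (box[1, 1] - box[1, 0]) / n1 / 2
    X = np.stack(np.meshgrid(g1, g2, indexing="ij"), axis=-1)
    B = np.exp(-np.asarray(system.phi(X), dtype=float) / eps)
    p = B.reshape(bins, subdiv, bins, subdiv).sum(axis=(1, 3))
    return p / p.sum()


def peak_positions(potential: EmpiricalPotential, min_count: int = 1) -> np.ndarray:
    """Bin centers of strict local minima of the empirical potential.

    A bin qualifies when it is occupied (``count >= min_count``) and its
    value is strictly below every occupied neighbor (full Moore
    neighborhood).  Returns an ``(n_peaks, N)`` array sorted
    lexicographically.
    """
    mask = potential.counts >= min_count
    vals = potential.values
    shape = vals.shape
    N = len(shape)
    cents = potential.centers
    peaks = []
    offsets = [np.array(o) for o in np.ndindex(*(3,) * N)]
    offsets = [o - 1 for o in offsets if not np.all(o == 1)]
    for idx in np.argwhere(mask):
        v = vals[tuple(idx)]
        is_min = True
        for o in offsets:
            j = idx + o
            if np.any(j < 0) or np.any(j >= shape):
                continue
            tj = tuple(j)
            if mask[tj] and vals[tj] <= v:
                is_min = False
                break
        if is_min:
            peaks.append([cents[d][idx[d]] for d in range(N)])
    peaks.sort()
    return np.asarray(peaks, dtype=float).reshape(len(peaks), N)
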