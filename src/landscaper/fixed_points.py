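"""Locating and classifying fixed points of the deterministic counterpart ODE.

The global-landscape protocol needs (i) the stable fixed points and saddles of
``dx/dt = f(x)``, found here by damped Newton iteration from many start
points, and (ii) for each saddle, the pair of stable states reached by
deterministic descent from a small perturbation along its unstable direction,
together with the descent durations (which later set the time window of the
uphill least-action minimization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import qmc

from .systems import DynamicalSystem

__all__ = [
    "FixedPoint",
    "SaddleConnection",
    "newton_find",
    "sweep_fixed_points",
    "descend_from_saddle",
    "latin_hypercube_starts",
]

logger = logging.getLogger(__name__)

NEWTON_TOL = 1e-9
CLASS_TOL = 1e-6


@dataclass
class FixedPoint:
    """An equilibrium of the ODE with its linear stability data."""

    x: np.ndarray
    eigenvalues: np.ndarray
    stability: str  # "stable" | "saddle" | "unstable_other"
    residual: float

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"

    @property
    def is_saddle(self) -> bool:
        return self.stability == "saddle"

    def distance(self, other: "FixedPoint") -> float:
        return float(np.linalg.norm(self.x - other.x))


@dataclass
class SaddleConnection:
    """Stable states reached by descending from both sides of a saddle."""

    saddle: FixedPoint
    targets: List[Optional[FixedPoint]] = field(default_factory=list)
    descent_times: List[float] = field(default_factory=list)
    diverged: List[bool] = field(default_factory=list)

    @property
    def is_complete(self) -> bool:
        return (len(self.targets) == 2 and not any(self.diverged)
                and all(t is not None for t in self.targets))


def classify(eigenvalues: np.ndarray, class_tol: float = CLASS_TOL) -> str:
    """Stability class from Jacobian eigenvalues.

    Eigenvalues with real part within ``class_tol`` of zero count as
    non-positive, so marginal systems are classed on the stable side.
    """
    n_pos = int(np.sum(eigenvalues.real > class_tol))
    if n_pos == 0:
        return "stable"
    if n_pos == 1:
        return "saddle"
    return "unstable_other"


def newton_find(system: DynamicalSystem, start: Sequence[float],
                newton_tol: float = NEWTON_TOL, max_iter: int = 100,
                class_tol: float = CLASS_TOL) -> Optional[FixedPoint]:
    """Damped Newton iteration on ``f(x) = 0``; None on failure.

    Steps solve ``J dx = -f`` with a pseudo-inverse fallback for singular
    Jacobians, and are backtracked (halved, up to 40 times) until the
    residual norm decreases.  Returns None when the iteration stalls,
    diverges, or leaves the representable range.
    """
    x = np.asarray(start, dtype=float).copy()
    if not np.all(np.isfinite(x)):
        raise ValueError("start point must be finite")
    fx = system.drift(x)
    for _ in range(max_iter):
        res = np.linalg.norm(fx)
        if res <= newton_tol * (1 + np.linalg.norm(x)):
            J = system.jacobian(x)
            eig = np.linalg.eigvals(J)
            return FixedPoint(x=x, eigenvalues=eig,
                              stability=classify(eig, class_tol), residual=res)
        J = system.jacobian(x)
        try:
            step = np.linalg.solve(J, -fx)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -fx, rcond=None)[0]
        if not np.all(np.isfinite(step)):
            step = np.linalg.pinv(J) @ (-fx)
            if not np.all(np.isfinite(step)):
                return None
        lam = 1.0
        for _bt in range(40):
            x_new = x + lam * step
            f_new = system.drift(x_new)
            if np.all(np.isfinite(f_new)) and np.linalg.norm(f_new) < res:
                break
            lam *= 0.5
        else:
            return None
        x, fx = x_new, f_new
        if np.linalg.norm(x) > 1e12:
            return None
    return None


def latin_hypercube_starts(bounds: np.ndarray, n: int, seed: Optional[int] = None) -> np.ndarray:
    """Latin-hypercube sample of ``n`` start points inside a bounding box.

    ``bounds`` is an ``(N, 2)`` array of per-coordinate lower/upper limits.
    """
    bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
    sampler = qmc.LatinHypercube(d=bounds.shape[0], seed=seed)
    u = sampler.random(n)
    return qmc.scale(u, bounds[:, 0], bounds[:, 1])


def sweep_fixed_points(system: DynamicalSystem, starts: np.ndarray,
                       dedup_radius: float = 1e-4,
                       newton_tol: float = NEWTON_TOL,
                       class_tol: float = CLASS_TOL) -> List[FixedPoint]:
    """Newton search from every start point, merged within ``dedup_radius``.

    Of coincident finds the one with the smallest residual is kept; failed
    starts are dropped (their count is logged).  The result is sorted
    lexicographically by coordinates so it does not depend on start order.
    """
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    if starts.size == 0:
        raise ValueError("starts must be nonempty")
    found: List[FixedPoint] = []
    failures = 0
    for s in starts:
        fp = newton_find(system, s, newton_tol=newton_tol, class_tol=class_tol)
        if fp is None:
            failures += 1
            continue
        for existing in found:
            if existing.distance(fp) < dedup_radius:
                if fp.residual < existing.residual:
                    existing.x = fp.x
                    existing.eigenvalues = fp.eigenvalues
                    existing.stability = fp.stability
                    existing.residual = fp.residual
                break
        else:
            found.append(fp)
    if failures:
        logger.info("sweep_fixed_points: %d/%d starts failed to converge",
                    failures, len(starts))
    found.sort(key=lambda fp: tuple(fp.x))
    return found


def unstable_direction(system: DynamicalSystem, saddle: FixedPoint) -> np.ndarray:
    """Unit eigenvector of the single unstable eigenvalue of a saddle."""
    J = system.jacobian(saddle.x)
    w, V = np.linalg.eig(J)
    i = int(np.argmax(w.real))
    v = V[:, i]
    if np.max(np.abs(v.imag)) > 1e-8 * np.max(np.abs(v.real) + 1e-300):
        raise ValueError("unstable eigenvector is complex; not a 1-D unstable manifold")
    v = v.real
    return v / np.linalg.norm(v)


def descend_from_saddle(system: DynamicalSystem, saddle: FixedPoint,
                        perturb_size: float = 1e-3,
                        stable_points: Optional[List[FixedPoint]] = None,
                        descent_tol: float = 1e-8, t_max: float = 1e4,
                        bound: float = 1e6,
                        match_radius: float = 1e-3) -> SaddleConnection:
    """Integrate the ODE from both sides of a saddle's unstable direction.

    From ``saddle.x +/- perturb_size * v`` (``v`` the unit unstable
    eigenvector) the flow is integrated until ``|f| < descent_tol`` or
    ``t_max`` elapses.  Each endpoint is matched against ``stable_points``
    when given (within ``match_radius`` scaled by state size), otherwise
    polished by Newton iteration.  Trajectories leaving ``|x| > bound`` are
    flagged as diverged.
    """
    if not saddle.is_saddle:
        raise ValueError("descend_from_saddle requires a saddle point")
    v = unstable_direction(system, saddle)
    conn = SaddleConnection(saddle=saddle)

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

    for sign in (+1.0, -1.0):
        x0 = saddle.x + sign * perturb_size * v
        sol = solve_ivp(rhs, (0.0, t_max), x0, events=[settled, escaped],
                        rtol=1e-10, atol=1e-12, method="LSODA")
        diverged = len(sol.t_events[1]) > 0 or not sol.success
        x_end = sol.y[:, -1]
        t_end = float(sol.t[-1])
        target: Optional[FixedPoint] = None
        if not diverged:
            if stable_points:
                scale = 1 + np.linalg.norm(x_end)
                for fp in stable_points:
                    if np.linalg.norm(fp.x - x_end) < match_radius * scale:
                        target = fp
                        break
            if target is None:
                target = newton_find(system, x_end)
                if target is not None and not target.is_stable:
                    target = None
            diverged = target is None
        conn.targets.append(target)
        conn.descent_times.append(t_end)
        conn.diverged.append(diverged)
    return conn
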