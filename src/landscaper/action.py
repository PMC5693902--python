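"""Least-action computation of potential differences.

The potential barrier between a stable state ``x*`` and a saddle ``s*`` is the
infimum, over paths connecting them, of the Ito-form action

    S_T[x] = (1/4) * integral  (dx/dt - f)^T D^{-1}(x) (dx/dt - f) dt,

whose minimum equals the potential difference ``phi(s*) - phi(x*)`` in the
zero-noise limit.  Numerically the path is divided into ``K`` segments and the
integrand is evaluated at pre-points (the discretization consistent with
Ito's convention):

    S = (1/4) * sum_k  dt_k * r_k^T D^{-1}(x^{k-1}) r_k,
    r_k = (x^k - x^{k-1})/dt_k - f(x^{k-1}),

and minimized over the interior points with both endpoints pinned.  The
discrete minimum carries an O(dt) (on some systems O(dt^2)) bias, so barrier
computations refine by doubling ``K`` with warm-started optimization and
Richardson-extrapolate the resulting sequence (:func:`refine_action`).

Time convention: ``T`` is always the total path duration ``T2 - T1``, so the
uniform step is ``dt = T/K``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize as _scipy_minimize

from .fixed_points import SaddleConnection
from .systems import DynamicalSystem

__all__ = [
    "DiscretePath",
    "ActionResult",
    "discrete_action",
    "action_gradient",
    "minimize_action",
    "refine_action",
    "ode_adaptive_time",
    "atype_action",
]

DEFAULT_K = 100
DEFAULT_T = 20.0


@dataclass
class DiscretePath:
    """A K-segment path: ``K+1`` points with strictly increasing times."""

    points: np.ndarray  # (K+1, N)
    times: np.ndarray   # (K+1,)

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        if self.points.shape[0] != self.times.shape[0]:
            raise ValueError("points and times length mismatch")
        if self.points.shape[0] < 2:
            raise ValueError("a path needs at least one segment")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def K(self) -> int:
        return self.points.shape[0] - 1

    @property
    def N(self) -> int:
        return self.points.shape[1]

    @property
    def dt(self) -> np.ndarray:
        return np.diff(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @classmethod
    def straight_line(cls, x_from, x_to, K: int, T: float) -> "DiscretePath":
        """Uniform-time straight line from ``x_from`` to ``x_to`` over window ``T``."""
        x_from = np.atleast_1d(np.asarray(x_from, dtype=float))
        x_to = np.atleast_1d(np.asarray(x_to, dtype=float))
        pts = np.linspace(x_from, x_to, K + 1)
        times = np.linspace(-T / 2, T / 2, K + 1)
        return cls(points=pts, times=times)

    def refined(self) -> "DiscretePath":
        """The same geometric path on a grid with doubled K (midpoint insertion)."""
        t_new = np.empty(2 * self.K + 1)
        t_new[0::2] = self.times
        t_new[1::2] = 0.5 * (self.times[:-1] + self.times[1:])
        p_new = np.empty((2 * self.K + 1, self.N))
        p_new[0::2] = self.points
        p_new[1::2] = 0.5 * (self.points[:-1] + self.points[1:])
        return DiscretePath(points=p_new, times=t_new)

    def to_dataframe(self):
        import pandas as pd
        cols = {f"x{i+1}": self.points[:, i] for i in range(self.N)}
        return pd.DataFrame({"t": self.times, **cols})


@dataclass
class ActionResult:
    """Outcome of an action minimization."""

    action: float
    path: DiscretePath
    converged: bool
    iterations: int
    gradient_norm: float
    action_history: List[float] = field(default_factory=list)
    K_history: List[int] = field(default_factory=list)
    extrapolated: bool = False

    def to_dict(self) -> dict:
        return {
            "action": self.action,
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "gradient_norm": float(self.gradient_norm),
            "K": int(self.path.K),
            "duration": self.path.duration,
            "action_history": [float(a) for a in self.action_history],
            "K_history": [int(k) for k in self.K_history],
            "extrapolated": bool(self.extrapolated),
        }


# ----------------------------------------------------------------------
# Action and its gradient
# ----------------------------------------------------------------------

def _residuals(system: DynamicalSystem, pts: np.ndarray, dt: np.ndarray,
               extra_drift=None):
    """Pre-point residuals r_k and D^{-1} r_k along a path."""
    pre = pts[:-1]
    v = (pts[1:] - pre) / dt[:, None]
    drift = system.drift_batch(pre)
    if extra_drift is not None:
        drift = drift + extra_drift(pre)
    r = v - drift
    if system.diffusion_is_constant:
        cf = cho_factor(system.diffusion(pre[0]))
        Dinv_r = cho_solve(cf, r.T).T
    else:
        Dinv_r = np.empty_like(r)
        for k in range(pre.shape[0]):
            try:
                cf = cho_factor(system.diffusion(pre[k]))
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    f"D(x) not positive definite at segment k={k}") from exc
            Dinv_r[k] = cho_solve(cf, r[k])
    return r, Dinv_r


def discrete_action(system: DynamicalSystem, path: DiscretePath) -> float:
    """Pre-point discretized Ito-form action of a path (zero-noise limit)."""
    r, Dinv_r = _residuals(system, path.points, path.dt)
    return float(0.25 * np.sum(path.dt * np.einsum("ki,ki->k", r, Dinv_r)))


def action_gradient(system: DynamicalSystem, path: DiscretePath,
                    fd_step: float = 1e-6) -> np.ndarray:
    """Analytic gradient of :func:`discrete_action` w.r.t. interior points.

    Returns an ``(K-1, N)`` array.  Each interior point ``x^m`` enters the
    action twice: as the end point of segment ``m`` and as the pre-point of
    segment ``m+1`` (through the drift, and through ``D`` when the diffusion
    is state-dependent; that last term is differentiated by central finite
    differences of the quadratic form).
    """
    pts, dt = path.points, path.dt
    K = path.K
    r, Dinv_r = _residuals(system, pts, dt)
    grad = np.zeros((K - 1, path.N))
    # end-point role in segment m (pre-point x^{m-1}):  0.5 * D^{-1} r_m
    grad += 0.5 * Dinv_r[:-1]
    # pre-point role in segment m+1: -0.5 D^{-1} r - (dt/2) J^T D^{-1} r
    interior = pts[1:-1]
    J = system.jacobian_batch(interior)  # (K-1, N, N)
    JT_Dinv_r = np.einsum("mji,mj->mi", J, Dinv_r[1:])
    grad += -0.5 * Dinv_r[1:] - 0.5 * dt[1:, None] * JT_Dinv_r
    if not system.diffusion_is_constant:
        # d/dx^m of (dt/4) r^T D^{-1}(x^m) r  (r held fixed)
        for m in range(K - 1):
            x = interior[m]
            for i in range(path.N):
                h = max(fd_step, fd_step * abs(x[i]))
                e = np.zeros(path.N)
                e[i] = h
                dD = (system.diffusion(x + e) - system.diffusion(x - e)) / (2 * h)
                grad[m, i] -= 0.25 * dt[m + 1] * (Dinv_r[m + 1] @ dD @ Dinv_r[m + 1])
    return grad


def atype_action(system: DynamicalSystem, path: DiscretePath, eps: float) -> float:
    """Finite-noise action with the A-type drift ``f + eps * Delta f``.

    ``Delta f_i = sum_j d/dx_j (D_ij + Q_ij)`` requires ``Q``; the value
    coincides with :func:`discrete_action` when ``eps = 0`` or when both
    ``D`` and ``Q`` are constant.  Used to verify that the finite-noise and
    zero-noise actions agree as ``eps -> 0``.
    """
    if not system.has_Q:
        raise ValueError("atype_action requires the antisymmetric matrix Q")
    if eps == 0.0:
        return discrete_action(system, path)

    def extra(pre):
        return eps * np.stack([system.atype_correction(x) for x in pre])

    r, Dinv_r = _residuals(system, path.points, path.dt, extra_drift=extra)
    return float(0.25 * np.sum(path.dt * np.einsum("ki,ki->k", r, Dinv_r)))


# ----------------------------------------------------------------------
# Minimization
# ----------------------------------------------------------------------

def minimize_action(system: DynamicalSystem, x_from, x_to, K: int = DEFAULT_K,
                    T: float = DEFAULT_T, init: Optional[DiscretePath] = None,
                    opt_tol: Optional[float] = None,
                    maxiter: int = 100_000) -> ActionResult:
    """Minimize the discrete action between two fixed endpoints.

    The path has ``K`` uniform segments over a total time window ``T``
    (``dt = T/K``) and is initialized as the straight line between the
    endpoints unless ``init`` is given.  Optimization is quasi-Newton
    (L-BFGS-B) with the analytic gradient; ``converged`` reports whether the
    final gradient infinity-norm is below ``opt_tol`` (default ``1e-8 * K``).
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    if T <= 0:
        raise ValueError("T must be positive")
    x_from = np.atleast_1d(np.asarray(x_from, dtype=float))
    x_to = np.atleast_1d(np.asarray(x_to, dtype=float))
    if opt_tol is None:
        opt_tol = 1e-8 * K
    if init is None:
        init = DiscretePath.straight_line(x_from, x_to, K, T)
    else:
        if init.K != K or abs(init.duration - T) > 1e-12 * max(1.0, T):
            raise ValueError("init path inconsistent with requested K, T")
    times = init.times
    dt = np.diff(times)
    N = x_from.size
    pts_buf = init.points.copy()
    pts_buf[0], pts_buf[-1] = x_from, x_to

    def objective(z):
        pts_buf[1:-1] = z.reshape(K - 1, N)
        p = DiscretePath(points=pts_buf, times=times)
        S = discrete_action(system, p)
        g = action_gradient(system, p)
        if not (np.isfinite(S) and np.all(np.isfinite(g))):
            raise FloatingPointError("drift produced NaN/inf along the path")
        return S, g.ravel()

    res = _scipy_minimize(objective, pts_buf[1:-1].ravel(), jac=True,
                          method="L-BFGS-B",
                          options=dict(maxiter=maxiter, maxfun=2 * maxiter,
                                       ftol=1e-18, gtol=1e-12))
    pts_buf[1:-1] = res.x.reshape(K - 1, N)
    final = DiscretePath(points=pts_buf.copy(), times=times.copy())
    gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    return ActionResult(action=float(res.fun), path=final,
                        converged=bool(gnorm <= opt_tol),
                        iterations=int(res.nit), gradient_norm=gnorm,
                        action_history=[float(res.fun)], K_history=[K])


def refine_action(system: DynamicalSystem, x_from, x_to, T: float,
                  K0: int = 100, rtol: float = 2e-3, atol: float = 1e-8,
                  max_levels: int = 6, richardson: bool = True,
                  maxiter: int = 100_000) -> ActionResult:
    """Grid-refined action minimization with Richardson extrapolation.

    Minimizes at ``K0`` segments, then repeatedly doubles ``K`` (warm-starting
    from the previous optimum via midpoint insertion).  The discrete minima
    converge linearly (or faster) in ``dt``, so successive first-order
    extrapolants ``R = 2 S_{2K} - S_K`` are formed and the loop stops when two
    of them agree to ``rtol`` (relative, floored by ``atol``).  The reported
    ``action`` is the last extrapolant (or the finest raw minimum when
    ``richardson=False``).
    """
    result = minimize_action(system, x_from, x_to, K=K0, T=T, maxiter=maxiter)
    S_hist = [result.action]
    K_hist = [K0]
    R_prev = None
    best = result
    for _ in range(max_levels):
        init = best.path.refined()
        nxt = minimize_action(system, x_from, x_to, K=init.K, T=T,
                              init=init, maxiter=maxiter)
        S_hist.append(nxt.action)
        K_hist.append(init.K)
        best = nxt
        R = 2 * S_hist[-1] - S_hist[-2]
        if R_prev is not None and abs(R - R_prev) <= max(rtol * abs(R), atol):
            R_prev = R
            break
        R_prev = R
    value = R_prev if (richardson and R_prev is not None) else S_hist[-1]
    # the action is nonnegative by construction; extrapolation round-off can
    # dip microscopically below zero on downhill (zero-action) paths
    value = max(float(value), 0.0)
    return ActionResult(action=value, path=best.path, converged=best.converged,
                        iterations=best.iterations,
                        gradient_norm=best.gradient_norm,
                        action_history=[float(s) for s in S_hist],
                        K_history=K_hist, extrapolated=bool(richardson))


def ode_adaptive_time(system: DynamicalSystem, connection: SaddleConnection,
                      target_index: int) -> float:
    """Descent duration of a saddle connection, used as the uphill time window.

    The least-action uphill path is the time reverse of the adjoint descent,
    so its duration should match the deterministic descent time recorded by
    :func:`landscaper.fixed_points.descend_from_saddle`.
    """
    if connection.diverged[target_index]:
        raise ValueError("descent trajectory diverged; no time window available")
    return float(connection.descent_times[target_index])
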