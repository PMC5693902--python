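"""Dynamical-system definitions: drift/diffusion bundles, Hill networks, fixtures.

A :class:`DynamicalSystem` packages everything the rest of the library needs
to analyse a stochastic dynamical model

    dx/dt = f(x) + G(x) zeta(t),      <zeta(t) zeta(t')^T> = 2 eps delta(t-t'),

namely the drift ``f``, the diffusion matrix ``D = G G^T``, and optionally the
antisymmetric matrix ``Q`` and an analytic potential ``phi`` satisfying the
decomposition ``f = -(D + Q) grad phi``.  When ``phi`` is supplied it is used
for validation only — the numerical machinery never reads it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np

__all__ = [
    "DynamicalSystem",
    "HillEdge",
    "HillNetworkSpec",
    "build_hill_system",
    "make_fixture",
    "FIXTURE_NAMES",
]

ArrayLike = Union[np.ndarray, Sequence[float], float]
MatrixFn = Callable[[np.ndarray], np.ndarray]


def _as_matrix_fn(M: Union[np.ndarray, MatrixFn, None], N: int):
    """Wrap a constant matrix as a callable; return (callable, constant-or-None)."""
    if M is None:
        return None, None
    if callable(M):
        return M, None
    arr = np.atleast_2d(np.asarray(M, dtype=float))
    if arr.shape != (N, N):
        raise ValueError(f"matrix has shape {arr.shape}, expected ({N}, {N})")
    return (lambda x, _a=arr: _a), arr


@dataclass
class DynamicalSystem:
    """A drift/diffusion model with optional decomposition data.

    Parameters
    ----------
    N : int
        State-space dimension.
    f : callable
        Drift; maps a length-``N`` state to a length-``N`` vector.  If
        ``vectorized`` is true it must also accept ``(..., N)`` batches,
        acting along the last axis.
    jac : callable, optional
        Analytic Jacobian of ``f``.  Central finite differences are used
        when absent.
    D : ndarray or callable
        Symmetric positive-definite diffusion matrix (constant or
        state-dependent).  Defaults to the identity.
    G : callable, optional
        Noise matrix with ``G G^T = D``.  Defaults to the lower Cholesky
        factor of ``D`` (any such factor yields the same Fokker-Planck
        equation).
    Q : ndarray or callable, optional
        Antisymmetric matrix of the decomposition ``f = -(D+Q) grad phi``.
    phi : callable, optional
        Analytic potential, used only as a validation oracle.
    grad_phi : callable, optional
        Analytic gradient of ``phi``.
    delta_f : callable, optional
        Analytic A-type drift correction ``Delta f_i = sum_j d/dx_j (D+Q)_ij``;
        computed by finite differences when absent.
    eps : float
        Default noise strength (temperature-like, >= 0).
    """

    N: int
    f: Callable[[np.ndarray], np.ndarray]
    jac: Optional[Callable[[np.ndarray], np.ndarray]] = None
    D: Union[np.ndarray, MatrixFn, None] = None
    G: Optional[MatrixFn] = None
    Q: Union[np.ndarray, MatrixFn, None] = None
    phi: Optional[Callable[[np.ndarray], float]] = None
    grad_phi: Optional[Callable[[np.ndarray], np.ndarray]] = None
    delta_f: Optional[Callable[[np.ndarray], np.ndarray]] = None
    jac_batch: Optional[Callable[[np.ndarray], np.ndarray]] = None
    eps: float = 1.0
    vectorized: bool = False
    name: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be a positive integer")
        if self.eps < 0:
            raise ValueError("noise strength eps must be nonnegative")
        if self.D is None:
            self.D = np.eye(self.N)
        self._D_fn, self._D_const = _as_matrix_fn(self.D, self.N)
        self._Q_fn, self._Q_const = _as_matrix_fn(self.Q, self.N)
        if self._D_const is not None:
            np.linalg.cholesky(self._D_const)  # fail fast on non-SPD constants
            self._G_const = None if self.G is not None else np.linalg.cholesky(self._D_const)
        else:
            self._G_const = None

    # -- evaluation ----------------------------------------------------
    def drift(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.f(np.asarray(x, dtype=float)), dtype=float)

    def drift_batch(self, X: np.ndarray) -> np.ndarray:
        """Drift on a batch of states with shape ``(..., N)``."""
        X = np.asarray(X, dtype=float)
        if self.vectorized:
            return np.asarray(self.f(X), dtype=float)
        return np.apply_along_axis(self.drift, -1, X)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.jac is not None:
            return np.asarray(self.jac(x), dtype=float)
        return self._fd_jacobian(x)

    def jacobian_batch(self, X: np.ndarray) -> np.ndarray:
        """Jacobians at a batch of states: ``(m, N) -> (m, N, N)``.

        Uses ``jac_batch`` when supplied, otherwise central finite
        differences evaluated through the (possibly vectorized) drift,
        which costs 2N batched drift calls regardless of batch size.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.jac_batch is not None:
            return np.asarray(self.jac_batch(X), dtype=float)
        if self.jac is not None:
            return np.stack([np.asarray(self.jac(x), dtype=float) for x in X])
        m = X.shape[0]
        J = np.empty((m, self.N, self.N))
        for j in range(self.N):
            h = np.maximum(1e-6, 1e-6 * np.abs(X[:, j]))[:, None]
            E = np.zeros_like(X)
            E[:, j] = h[:, 0]
            J[:, :, j] = (self.drift_batch(X + E) - self.drift_batch(X - E)) / (2 * h)
        return J

    def _fd_jacobian(self, x: np.ndarray) -> np.ndarray:
        J = np.empty((self.N, self.N))
        for i in range(self.N):
            h = max(1e-6, 1e-6 * abs(x[i]))
            e = np.zeros(self.N)
            e[i] = h
            J[:, i] = (self.drift(x + e) - self.drift(x - e)) / (2 * h)
        return J

    def diffusion(self, x: np.ndarray) -> np.ndarray:
        if self._D_const is not None:
            return self._D_const
        return np.asarray(self._D_fn(np.asarray(x, dtype=float)), dtype=float)

    @property
    def diffusion_is_constant(self) -> bool:
        return self._D_const is not None

    def noise_matrix(self, x: np.ndarray) -> np.ndarray:
        if self.G is not None:
            return np.asarray(self.G(np.asarray(x, dtype=float)), dtype=float)
        if self._G_const is not None:
            return self._G_const
        return np.linalg.cholesky(self.diffusion(x))

    def antisym(self, x: np.ndarray) -> Optional[np.ndarray]:
        if self._Q_fn is None:
            return None
        if self._Q_const is not None:
            return self._Q_const
        return np.asarray(self._Q_fn(np.asarray(x, dtype=float)), dtype=float)

    @property
    def has_Q(self) -> bool:
        return self._Q_fn is not None

    def atype_correction(self, x: np.ndarray, fd_step: float = 1e-5) -> np.ndarray:
        """A-type drift correction ``Delta f_i = sum_j d/dx_j [D_ij + Q_ij]``.

        Uses the analytic ``delta_f`` when supplied, otherwise central finite
        differences on ``D + Q`` (requires ``Q``; detailed balance without a
        declared ``Q=0`` is ambiguous).
        """
        x = np.asarray(x, dtype=float)
        if self.delta_f is not None:
            return np.asarray(self.delta_f(x), dtype=float)
        if not self.has_Q:
            raise ValueError("A-type correction requires Q (use Q=0 for detailed balance)")
        if self._D_const is not None and self._Q_const is not None:
            return np.zeros(self.N)
        out = np.zeros(self.N)
        for j in range(self.N):
            e = np.zeros(self.N)
            e[j] = fd_step
            Mp = self.diffusion(x + e) + self.antisym(x + e)
            Mm = self.diffusion(x - e) + self.antisym(x - e)
            out += (Mp[:, j] - Mm[:, j]) / (2 * fd_step)
        return out

    def potential_gradient(self, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
        if self.phi is None:
            raise ValueError("system has no analytic potential")
        x = np.asarray(x, dtype=float)
        if self.grad_phi is not None:
            return np.asarray(self.grad_phi(x), dtype=float)
        g = np.empty(self.N)
        for i in range(self.N):
            e = np.zeros(self.N)
            e[i] = h
            g[i] = (self.phi(x + e) - self.phi(x - e)) / (2 * h)
        return g

    # -- validation ----------------------------------------------------
    def validate(self, points: Optional[np.ndarray] = None, rng=None, tol: float = 1e-8) -> None:
        """Check structural invariants at sample points; raise on violation.

        Verifies that D is SPD (Cholesky), ``G G^T = D``, antisymmetry of Q,
        the orthogonality ``(grad phi)^T Q grad phi = 0``, and — when both Q
        and phi are present — the decomposition ``f + (D+Q) grad phi = 0``.
        """
        if points is None:
            rng = np.random.default_rng(rng)
            points = rng.normal(size=(8, self.N))
        points = np.atleast_2d(points)
        for x in points:
            Dx = self.diffusion(x)
            if not np.allclose(Dx, Dx.T, atol=tol):
                raise ValueError("D(x) is not symmetric")
            np.linalg.cholesky(Dx)
            Gx = self.noise_matrix(x)
            if np.linalg.norm(Gx @ Gx.T - Dx) > max(tol, tol * np.linalg.norm(Dx)):
                raise ValueError("G(x) G(x)^T does not match D(x)")
            Qx = self.antisym(x)
            if Qx is not None:
                if np.linalg.norm(Qx + Qx.T) > tol:
                    raise ValueError("Q(x) is not antisymmetric")
                if self.phi is not None:
                    g = self.potential_gradient(x)
                    if abs(g @ Qx @ g) > max(tol, tol * (1 + g @ g)):
                        raise ValueError("(grad phi)^T Q grad phi != 0")
                    resid = self.drift(x) + (Dx + Qx) @ g
                    scale = 1 + np.linalg.norm(self.drift(x))
                    if np.linalg.norm(resid) > 1e-5 * scale:
                        raise ValueError("decomposition f = -(D+Q) grad phi violated")


# ----------------------------------------------------------------------
# Hill-equation regulatory networks
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class HillEdge:
    """A single regulatory interaction modelled by a Hill term.

    ``sign`` is ``"activation"`` (term ``a x_s^n / (k^n + x_s^n)``) or
    ``"inhibition"`` (term ``a k^n / (k^n + x_s^n)``), with strength ``a``,
    Hill exponent ``n`` and half-saturation constant ``k``; ``source`` is the
    regulating node and ``target`` the regulated one.
    """

    source: str
    target: str
    sign: str
    a: float
    n: float
    k: float


@dataclass
class HillNetworkSpec:
    """Declarative description of a gene-regulatory Hill network."""

    nodes: list
    edges: list  # of HillEdge
    degradation: Mapping[str, float]
    basal: Mapping[str, float]

    def validate(self) -> None:
        nodeset = set(self.nodes)
        if len(nodeset) != len(self.nodes):
            raise ValueError("duplicate node names")
        for e in self.edges:
            if e.source not in nodeset:
                raise ValueError(f"edge source {e.source!r} is not a declared node")
            if e.target not in nodeset:
                raise ValueError(f"edge target {e.target!r} is not a declared node")
            if e.sign not in ("activation", "inhibition"):
                raise ValueError(f"unknown edge sign {e.sign!r}")
            if not (e.a > 0 and e.n > 0 and e.k > 0):
                raise ValueError("Hill constants a, n, k must be strictly positive")
        for node in self.nodes:
            if self.degradation.get(node, 0.0) <= 0:
                raise ValueError(f"degradation rate for {node!r} must be strictly positive")
            if self.basal.get(node, 0.0) < 0:
                raise ValueError(f"basal rate for {node!r} must be nonnegative")

    # JSON round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "edges": [
                {"source": e.source, "target": e.target, "sign": e.sign,
                 "a": e.a, "n": e.n, "k": e.k}
                for e in self.edges
            ],
            "degradation": dict(self.degradation),
            "basal": dict(self.basal),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HillNetworkSpec":
        edges = [HillEdge(**e) for e in d.get("edges", [])]
        return cls(nodes=list(d["nodes"]), edges=edges,
                   degradation=dict(d.get("degradation", {})),
                   basal=dict(d.get("basal", {})))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "HillNetworkSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_hill_system(spec: HillNetworkSpec, eps: float = 1.0) -> DynamicalSystem:
    """Assemble a :class:`DynamicalSystem` from a Hill-network description.

    Each node's rate of change is the sum of a basal production rate and the
    regulatory Hill terms targeting it, minus first-order degradation.  The
    diffusion matrix defaults to the identity (additive noise).  States are
    clipped at zero inside Hill terms so the drift is defined on all of R^N
    (expression levels are physically nonnegative).
    """
    spec.validate()
    nodes = list(spec.nodes)
    N = len(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    deg = np.array([spec.degradation[n] for n in nodes])
    basal = np.array([float(spec.basal.get(n, 0.0)) for n in nodes])
    # per-edge arrays for vectorized evaluation
    e_src = np.array([idx[e.source] for e in spec.edges], dtype=int)
    e_tgt = np.array([idx[e.target] for e in spec.edges], dtype=int)
    e_act = np.array([e.sign == "activation" for e in spec.edges])
    e_a = np.array([e.a for e in spec.edges])
    e_n = np.array([e.n for e in spec.edges])
    e_k = np.array([e.k for e in spec.edges])

    def f(x):
        x = np.asarray(x, dtype=float)
        out = basal - deg * x
        if len(e_src):
            xs = np.clip(x[..., e_src], 0.0, None)
            xn = xs ** e_n
            kn = e_k ** e_n
            term = np.where(e_act, e_a * xn / (kn + xn), e_a * kn / (kn + xn))
            if x.ndim == 1:
                np.add.at(out, e_tgt, term)
            else:
                flat = out.reshape(-1, N)
                tflat = term.reshape(-1, len(e_src))
                for j, t in enumerate(e_tgt):
                    flat[:, t] += tflat[:, j]
        return out

    def jac(x):
        x = np.asarray(x, dtype=float)
        J = np.diag(-deg).astype(float).copy()
        for e_i in range(len(e_src)):
            s = e_src[e_i]
            xs = max(x[s], 0.0)
            n, k, a = e_n[e_i], e_k[e_i], e_a[e_i]
            kn = k ** n
            if xs == 0.0:
                d = 0.0 if n != 1 else a / kn * (1.0 if e_act[e_i] else -1.0)
            else:
                common = a * n * kn * xs ** (n - 1) / (kn + xs ** n) ** 2
                d = common if e_act[e_i] else -common
            if x[s] < 0:
                d = 0.0
            J[e_tgt[e_i], s] += d
        return J

    return DynamicalSystem(N=N, f=f, jac=jac, D=np.eye(N), eps=eps,
                           vectorized=True, name="hill_network",
                           params={"nodes": nodes})


# ----------------------------------------------------------------------
# Analytic fixtures
# ----------------------------------------------------------------------

FIXTURE_NAMES = (
    "double_well_1d",
    "double_well_2d",
    "rotational_ou",
    "gradient_plus_curl",
    "variable_curl",
)


def _rot(q: float) -> np.ndarray:
    return np.array([[0.0, q], [-q, 0.0]])


def make_fixture(name: str, eps: float = 1.0, **params) -> DynamicalSystem:
    """Analytic test systems with known potential, diffusion and curl.

    Every fixture carries the exact decomposition ``f = -(D+Q) grad phi`` so
    downstream computations (fixed points, least-action barriers, sampled
    steady states) have a closed-form oracle.

    ``double_well_1d(tilt=0)``
        ``phi = (x^2-1)^2/4 + tilt*x``, ``f = -phi'``, ``D = 1``, ``Q = 0``.
    ``double_well_2d``
        ``phi = (x1^2-1)^2/4 + x2^2/2``, pure gradient descent, ``D = I``.
    ``rotational_ou(q=1)``
        ``f = -(I + Q) x`` with constant curl ``Q = [[0,q],[-q,0]]`` and
        ``phi = |x|^2/2``.
    ``gradient_plus_curl(q=1)``
        Bistable ``phi`` of double_well_2d driven by ``f = -(I+Q) grad phi``
        with constant ``Q``; detailed balance is broken but the A-type drift
        correction vanishes.
    ``variable_curl(q0=1, c=1)``
        Same bistable ``phi`` with state-dependent curl ``q(x) = q0 + c*x2``,
        giving a nonzero A-type correction ``Delta f = (c, 0)`` even though
        the noise is additive.  Exhibits the displacement of probability
        peaks under Ito simulation that A-type integration removes.
    """
    if name == "double_well_1d":
        tilt = float(params.pop("tilt", 0.0))
        _check_no_extra(params)

        def phi(x):
            x0 = np.asarray(x, dtype=float)[..., 0]
            return (x0 ** 2 - 1) ** 2 / 4 + tilt * x0

        def f(x):
            x = np.asarray(x, dtype=float)
            x0 = x[..., 0]
            return np.stack([-(x0 ** 3 - x0 + tilt)], axis=-1)

        def jac_batch(X):
            return (-(3 * X[:, 0] ** 2 - 1)).reshape(-1, 1, 1)

        return DynamicalSystem(
            N=1, f=f, jac=lambda x: np.array([[-(3 * x[0] ** 2 - 1)]]),
            jac_batch=jac_batch,
            D=np.eye(1), Q=np.zeros((1, 1)),
            phi=phi, grad_phi=lambda x: np.array([x[0] ** 3 - x[0] + tilt]),
            eps=eps, vectorized=True, name=name, params={"tilt": tilt})

    if name in ("double_well_2d", "gradient_plus_curl"):
        q = float(params.pop("q", 0.0 if name == "double_well_2d" else 1.0))
        _check_no_extra(params)
        Q = _rot(q)
        A = np.eye(2) + Q  # D + Q

        def phi(x):
            x = np.asarray(x, dtype=float)
            return (x[..., 0] ** 2 - 1) ** 2 / 4 + x[..., 1] ** 2 / 2

        def gphi(x):
            x = np.asarray(x, dtype=float)
            return np.stack([x[..., 0] ** 3 - x[..., 0], x[..., 1]], axis=-1)

        def f(x):
            g = gphi(x)
            return -g @ A.T

        def jac(x):
            H = np.array([[3 * x[0] ** 2 - 1, 0.0], [0.0, 1.0]])
            return -A @ H

        def jac_batch(X):
            m = X.shape[0]
            H = np.zeros((m, 2, 2))
            H[:, 0, 0] = 3 * X[:, 0] ** 2 - 1
            H[:, 1, 1] = 1.0
            return -np.einsum("ij,mjk->mik", A, H)

        return DynamicalSystem(N=2, f=f, jac=jac, jac_batch=jac_batch,
                               D=np.eye(2), Q=Q,
                               phi=phi, grad_phi=gphi, eps=eps,
                               vectorized=True, name=name, params={"q": q})

    if name == "rotational_ou":
        q = float(params.pop("q", 1.0))
        _check_no_extra(params)
        Q = _rot(q)
        A = np.eye(2) + Q

        def f(x):
            return -np.asarray(x, dtype=float) @ A.T

        return DynamicalSystem(
            N=2, f=f, jac=lambda x: -A,
            jac_batch=lambda X: np.broadcast_to(-A, (X.shape[0], 2, 2)).copy(),
            D=np.eye(2), Q=Q,
            phi=lambda x: 0.5 * np.sum(np.asarray(x, dtype=float) ** 2, axis=-1),
            grad_phi=lambda x: np.asarray(x, dtype=float),
            eps=eps, vectorized=True, name=name, params={"q": q})

    if name == "variable_curl":
        q0 = float(params.pop("q0", 1.0))
        c = float(params.pop("c", 1.0))
        _check_no_extra(params)

        def qfun(x):
            return q0 + c * np.asarray(x, dtype=float)[..., 1]

        def phi(x):
            x = np.asarray(x, dtype=float)
            return (x[..., 0] ** 2 - 1) ** 2 / 4 + x[..., 1] ** 2 / 2

        def gphi(x):
            x = np.asarray(x, dtype=float)
            return np.stack([x[..., 0] ** 3 - x[..., 0], x[..., 1]], axis=-1)

        def f(x):
            x = np.asarray(x, dtype=float)
            g = gphi(x)
            q = qfun(x)
            return np.stack([-(g[..., 0] + q * g[..., 1]),
                             q * g[..., 0] - g[..., 1]], axis=-1)

        def jac(x):
            x = np.asarray(x, dtype=float)
            h1 = 3 * x[0] ** 2 - 1
            q = q0 + c * x[1]
            g1 = x[0] ** 3 - x[0]
            return np.array([[-h1, -(q + c * x[1])],
                             [q * h1, c * g1 - 1.0]])

        def jac_batch(X):
            m = X.shape[0]
            h1 = 3 * X[:, 0] ** 2 - 1
            q = q0 + c * X[:, 1]
            g1 = X[:, 0] ** 3 - X[:, 0]
            J = np.empty((m, 2, 2))
            J[:, 0, 0] = -h1
            J[:, 0, 1] = -(q + c * X[:, 1])
            J[:, 1, 0] = q * h1
            J[:, 1, 1] = c * g1 - 1.0
            return J

        return DynamicalSystem(
            N=2, f=f, jac=jac, jac_batch=jac_batch,
            D=np.eye(2), Q=lambda x: _rot(qfun(x)),
            phi=phi, grad_phi=gphi,
            delta_f=lambda x: np.array([c, 0.0]),
            eps=eps, vectorized=True, name=name, params={"q0": q0, "c": c})

    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def _check_no_extra(params: dict) -> None:
    if params:
        raise ValueError(f"unknown fixture parameters: {sorted(params)}")
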