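"""Quasi-potentials in the weak-noise limit b -> 0.

The stationary density is written as exp(-S0/b); the leading order S0
solves a Hamilton-Jacobi equation H(x, y, dS0/dx, dS0/dy) = 0.  For the
shot-noise PDMP the burst terms contribute the exponential-kernel
transform a*(1/(1-p) - 1) on the admissible momentum domain p < 1,
while the diffusion approximation is quadratic in the momenta.

S0 is computed with a geometric minimum-action method: paths from the
attractor are reparametrized to equal arc length, and the momentum at
each segment is recovered from the zero-Hamiltonian constraint together
with the alignment condition grad_p H || direction of travel.  Both
built-in Hamiltonians are separable in the momenta, so the alignment
system reduces to a one-dimensional root-find in the proportionality
constant lambda per segment; this avoids the Legendre transform of the
non-quadratic PDMP Hamiltonian.  (The simpler recovery p || direction
solves H = 0 on a ray; it is exact for one-species and
detailed-balance systems but only lower-bounds the geometric action
for the coupled switch, so it is kept as a fallback for Hamiltonians
that do not provide the separable inverse.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize

from .diffusion_approx import DriftDiffusion
from .model_core import ModelParams

__all__ = [
    "HamiltonianSpec",
    "ActionResult",
    "QuasiPotentialField",
    "pdmp_hamiltonian",
    "diffusion_hamiltonian",
    "minimize_action",
    "quasipotential_surface",
]

_P_GUARD = 1e-9


@dataclass(frozen=True)
class HamiltonianSpec:
    """A Hamiltonian H(x, y, px, py) with its partial derivatives.

    All callables are vectorized over numpy arrays.  ``p_bound`` is the
    supremum of each momentum component (1 for the PDMP burst kernel,
    inf for diffusion Hamiltonians).  H(x, y, 0, 0) = 0 by construction
    (the zero-momentum characteristic is the deterministic flow).
    """

    H: Callable
    dH_dp: Callable  # -> (dH/dpx, dH/dpy)
    dH_dx: Callable  # -> (dH/dx, dH/dy)
    p_bound: float
    kind: str
    params: object = None
    # optional separable inverse of grad_p H for the exact gMAM
    # alignment condition: p_from_lambda(x, y, vx, vy, lam) -> (px, py)
    # solves dH/dp_i = lam * v_i componentwise; lambda_bound gives the
    # supremum of admissible lam (may return inf).
    p_from_lambda: Callable | None = None
    lambda_bound: Callable | None = None

    def check_momentum(self, px, py):
        if np.any(px >= self.p_bound) or np.any(py >= self.p_bound):
            raise ValueError(
                f"momentum outside admissible domain (components must be "
                f"< {self.p_bound})"
            )


def _burst_rates(params: ModelParams):
    """Concentration-scale burst rates Lambda_i = b * a_i and their
    spatial derivatives.

    Uses validation-free closures (these sit in the innermost loop of
    the action minimizer); equality with b * transcription_propensity
    is asserted in the test suite.
    """
    K, b, B = params.K, params.b, params.B

    if params.regulation == "toggle":
        r0, r, n = params.r0, params.r, params.n

        def lam(x, y):
            x = np.asarray(x, float)
            y = np.asarray(y, float)
            return B * (r0 + r / (1.0 + y**n)), B * (r0 + r / (1.0 + x**n))

        def dhill(z):
            zn = z ** (n - 1.0)
            return -B * r * n * zn / (1.0 + zn * z) ** 2

        def dlam(x, y):
            x = np.asarray(x, float)
            y = np.asarray(y, float)
            zero = np.zeros(np.broadcast_shapes(x.shape, y.shape))
            return zero, dhill(y), dhill(x), zero

        return lam, dlam

    q0, r1, r2 = params.q0, params.r1, params.r2
    n1, n2, K1, K2 = params.n1, params.n2, params.K1, params.K2
    s1, s2 = K / K1, K / K2  # concentration-to-Hill-argument scales

    def one(ns, no):
        f1 = 1.0 / (1.0 + (ns * s1) ** n1)
        f2 = 1.0 / (1.0 + (no * s2) ** n2)
        return b * q0 * (1.0 + r1 * f1) * (1.0 + r2 * f2)

    def lam(x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return one(x, y), one(y, x)

    def dlam(x, y, h=1e-6):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        xp, xm = x + h, np.maximum(x - h, 0.0)
        yp, ym = y + h, np.maximum(y - h, 0.0)
        dlx_dx = (one(xp, y) - one(xm, y)) / (xp - xm)
        dly_dx = (one(y, xp) - one(y, xm)) / (xp - xm)
        dlx_dy = (one(x, yp) - one(x, ym)) / (yp - ym)
        dly_dy = (one(yp, x) - one(ym, x)) / (yp - ym)
        return dlx_dx, dlx_dy, dly_dx, dly_dy

    return lam, dlam


def pdmp_hamiltonian(params: ModelParams) -> HamiltonianSpec:
    """WKB Hamiltonian of the shot-noise PDMP.

    H = Lam_X(x,y)*(1/(1-px) - 1) + Lam_Y(x,y)*(1/(1-py) - 1)
        - gamma0*x*px - gamma0*y*py,   px, py < 1,

    where Lam_i = b*a_i is the burst rate scaled to concentration
    units.  Expanding to second order in the momenta recovers a
    diffusion Hamiltonian with burst second moment 2b^2; the cubic and
    higher terms are the bursting-noise signature.
    """
    g0 = params.gamma0
    lam, dlam = _burst_rates(params)

    def H(x, y, px, py):
        lx, ly = lam(x, y)
        return (
            lx * (px / (1.0 - px))
            + ly * (py / (1.0 - py))
            - g0 * np.asarray(x) * px
            - g0 * np.asarray(y) * py
        )

    def dH_dp(x, y, px, py):
        lx, ly = lam(x, y)
        return (
            lx / (1.0 - px) ** 2 - g0 * np.asarray(x),
            ly / (1.0 - py) ** 2 - g0 * np.asarray(y),
        )

    def dH_dx(x, y, px, py):
        dlx_dx, dlx_dy, dly_dx, dly_dy = dlam(x, y)
        fx = px / (1.0 - px)
        fy = py / (1.0 - py)
        return (
            dlx_dx * fx + dly_dx * fy - g0 * px,
            dlx_dy * fx + dly_dy * fy - g0 * py,
        )

    def p_from_lambda(x, y, vx, vy, lam):
        # invert Lam/(1-p)^2 - gamma0*x = lam*v componentwise
        lx, ly = lam_rates(x, y)
        dx_ = np.maximum(g0 * np.maximum(x, 1e-9) + lam * vx, 1e-300)
        dy_ = np.maximum(g0 * np.maximum(y, 1e-9) + lam * vy, 1e-300)
        return 1.0 - np.sqrt(lx / dx_), 1.0 - np.sqrt(ly / dy_)

    def lambda_bound(x, y, vx, vy):
        with np.errstate(divide="ignore"):
            bx = np.where(vx < 0, g0 * np.maximum(x, 1e-9) / np.maximum(-vx, 1e-300),
                          np.inf)
            by = np.where(vy < 0, g0 * np.maximum(y, 1e-9) / np.maximum(-vy, 1e-300),
                          np.inf)
        return np.minimum(bx, by) * (1.0 - 1e-9)

    lam_rates = lam
    return HamiltonianSpec(H=H, dH_dp=dH_dp, dH_dx=dH_dx, p_bound=1.0,
                           kind="pdmp", params=params,
                           p_from_lambda=p_from_lambda,
                           lambda_bound=lambda_bound)


def diffusion_hamiltonian(dd: DriftDiffusion) -> HamiltonianSpec:
    """WKB Hamiltonian of the diffusion approximation.

    With the same exp(-S0/b) ansatz as the PDMP (so that both S0
    surfaces share one scale):

        H = sum_i [ v_i p_i + (D_i / (2 b)) p_i^2 ].
    """
    params = dd.params
    b, B, g0 = params.b, params.B, params.gamma0
    lam, dlam = _burst_rates(params)
    # D/(2b) expressed through Lambda = b*a:
    #   D = a*(2B^2+B)/K^2 + g0*x/K  =>  D/(2b) = Lam*(1 + 1/(2B)) + g0*x/(2B)
    cm = 1.0 + 0.5 / B

    def H(x, y, px, py):
        lx, ly = lam(x, y)
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (
            (lx - g0 * x) * px
            + (ly - g0 * y) * py
            + (cm * lx + g0 * x / (2.0 * B)) * px**2
            + (cm * ly + g0 * y / (2.0 * B)) * py**2
        )

    def dH_dp(x, y, px, py):
        lx, ly = lam(x, y)
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (
            lx - g0 * x + 2.0 * (cm * lx + g0 * x / (2.0 * B)) * px,
            ly - g0 * y + 2.0 * (cm * ly + g0 * y / (2.0 * B)) * py,
        )

    def dH_dx(x, y, px, py):
        dlx_dx, dlx_dy, dly_dx, dly_dy = dlam(x, y)
        gx = g0 / (2.0 * B)
        return (
            dlx_dx * (px + cm * px**2) + dly_dx * (py + cm * py**2)
            - g0 * px + gx * px**2,
            dlx_dy * (px + cm * px**2) + dly_dy * (py + cm * py**2)
            - g0 * py + gx * py**2,
        )

    def p_from_lambda(x, y, vx, vy, lam_):
        # quadratic H: dH/dp = drift + 2*Q*p = lam*v
        lx, ly = lam(x, y)
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        qx = cm * lx + g0 * x / (2.0 * B)
        qy = cm * ly + g0 * y / (2.0 * B)
        return (
            (lam_ * vx - (lx - g0 * x)) / (2.0 * qx),
            (lam_ * vy - (ly - g0 * y)) / (2.0 * qy),
        )

    return HamiltonianSpec(H=H, dH_dp=dH_dp, dH_dx=dH_dx, p_bound=np.inf,
                           kind="diffusion", params=dd.params,
                           p_from_lambda=p_from_lambda)


# ---------------------------------------------------------------------------
# Geometric minimum action method
# ---------------------------------------------------------------------------


@dataclass
class ActionResult:
    value: float
    path: np.ndarray  # (n, 2)
    momenta: np.ndarray  # (n-1, 2) per segment
    converged: bool
    reachable: bool
    n_outer: int


def _segment_theta(ham: HamiltonianSpec, mid, vhat):
    """Per-segment momentum magnitude theta >= 0 solving
    H(mid, theta*vhat) = 0, with p = theta*vhat.

    Returns (theta, reachable_mask).  theta = 0 on segments moving with
    the deterministic flow.
    """
    M = len(mid)
    x, y = mid[:, 0], mid[:, 1]
    gpx, gpy = ham.dH_dp(x, y, np.zeros(M), np.zeros(M))
    gprime0 = gpx * vhat[:, 0] + gpy * vhat[:, 1]
    active = gprime0 < -1e-12
    theta = np.zeros(M)
    reachable = np.ones(M, dtype=bool)
    if not np.any(active):
        return theta, reachable
    # admissible upper bound on theta per segment
    with np.errstate(divide="ignore"):
        bx = np.where(vhat[:, 0] > 0, (ham.p_bound - _P_GUARD) / vhat[:, 0], np.inf)
        by = np.where(vhat[:, 1] > 0, (ham.p_bound - _P_GUARD) / vhat[:, 1], np.inf)
    theta_dom = np.minimum(bx, by)

    def g(th):
        return ham.H(x, y, th * vhat[:, 0], th * vhat[:, 1])

    def gprime(th):
        hpx, hpy = ham.dH_dp(x, y, th * vhat[:, 0], th * vhat[:, 1])
        return hpx * vhat[:, 0] + hpy * vhat[:, 1]

    # bracket: double hi until g(hi) > 0 (or the domain edge is hit)
    hi = np.where(np.isfinite(theta_dom), theta_dom, 1.0)
    for _ in range(60):
        val = g(hi)
        need_more = active & (val <= 0) & ~np.isfinite(theta_dom)
        if not np.any(need_more):
            break
        hi = np.where(need_more, hi * 2.0, hi)
    unreachable = active & (g(hi) <= 0)
    reachable &= ~unreachable
    theta = np.where(unreachable, hi, theta)
    solve = active & ~unreachable
    # safeguarded Newton on the positive root (g convex, g(0) = 0, g'(0) < 0)
    lo = np.zeros(M)
    hi_b = hi.copy()
    th = 0.5 * (lo + hi_b)
    for _ in range(30):
        v = g(th)
        lo = np.where(solve & (v <= 0), th, lo)
        hi_b = np.where(solve & (v > 0), th, hi_b)
        dv = gprime(th)
        with np.errstate(divide="ignore", invalid="ignore"):
            newton = th - v / dv
        bad = ~np.isfinite(newton) | (newton <= lo) | (newton >= hi_b) | (dv <= 0)
        th = np.where(bad, 0.5 * (lo + hi_b), newton)
        if np.all((hi_b - lo)[solve] < 1e-12 * (1.0 + hi_b[solve])):
            break
    theta = np.where(solve, th, theta)
    return theta, reachable


def _segment_momenta(ham: HamiltonianSpec, mid, vhat, ok):
    """Exact gMAM momentum per segment: solve H(mid, p) = 0 together
    with grad_p H = lambda * vhat (lambda > 0) via a monotone
    one-dimensional root-find in lambda.

    Returns (p, lambda, reachable)."""
    M = len(mid)
    x, y = mid[:, 0], mid[:, 1]
    vx, vy = vhat[:, 0], vhat[:, 1]
    if ham.lambda_bound is not None:
        bound = ham.lambda_bound(x, y, vx, vy)
    else:
        bound = np.full(M, np.inf)

    def g(lam):
        px, py = ham.p_from_lambda(x, y, vx, vy, lam)
        with np.errstate(over="ignore", invalid="ignore"):
            return ham.H(x, y, px, py)

    reachable = np.ones(M, dtype=bool)
    hi = np.where(np.isfinite(bound), bound, 1.0)
    for _ in range(80):
        val = g(hi)
        need_more = ok & ~(val > 0) & ~np.isfinite(bound)
        if not np.any(need_more):
            break
        hi = np.where(need_more, hi * 2.0, hi)
    reachable &= ~(ok & ~(g(hi) > 0))
    lo = np.zeros(M)
    for _ in range(60):
        lam = 0.5 * (lo + hi)
        v = g(lam)
        up = ok & (v <= 0)
        lo = np.where(up, lam, lo)
        hi = np.where(ok & ~up, lam, hi)
    lam = 0.5 * (lo + hi)
    px, py = ham.p_from_lambda(x, y, vx, vy, lam)
    p = np.column_stack([px, py])
    p[~ok] = 0.0
    return p, lam, reachable


def _action_and_grad(ham: HamiltonianSpec, phi: np.ndarray):
    """Geometric action S = sum_k <p_k, dphi_k> and its gradient with
    respect to the path nodes.

    With the exact momentum recovery the gradient follows from the
    envelope theorem: d(cost_k)/d(midpoint) = -(ell_k/lambda_k) *
    grad_x H(mid_k, p_k) and d(cost_k)/d(Delta_k) = p_k.  The ray
    fallback (p parallel to vhat) differentiates the root theta by the
    implicit-function theorem instead.
    """
    d = phi[1:] - phi[:-1]
    ell = np.hypot(d[:, 0], d[:, 1])
    ok = ell > 1e-14
    vhat = np.zeros_like(d)
    vhat[ok] = d[ok] / ell[ok, None]
    mid = 0.5 * (phi[1:] + phi[:-1])

    if ham.p_from_lambda is not None:
        p, lam, reach_mask = _segment_momenta(ham, mid, vhat, ok)
        rate = np.maximum(np.einsum("ij,ij->i", p, vhat), 0.0)
        S = float(np.sum(rate * ell))
        Hx, Hy = ham.dH_dx(mid[:, 0], mid[:, 1], p[:, 0], p[:, 1])
        gradH_x = np.column_stack([Hx, Hy])
        with np.errstate(divide="ignore", invalid="ignore"):
            mu = np.where((lam > 1e-12) & ok, ell / lam, 0.0)
        mid_term = -0.5 * mu[:, None] * gradH_x
        mid_term[~ok] = 0.0
        pterm = p * ok[:, None]
        grad = np.zeros_like(phi)
        grad[:-1] += mid_term - pterm
        grad[1:] += mid_term + pterm
        return S, grad, p, bool(np.all(reach_mask | ~ok))

    theta, reachable = _segment_theta(ham, mid, vhat)
    theta = np.where(ok, theta, 0.0)
    S = float(np.sum(theta * ell))
    px, py = theta * vhat[:, 0], theta * vhat[:, 1]
    Hpx, Hpy = ham.dH_dp(mid[:, 0], mid[:, 1], px, py)
    Hx, Hy = ham.dH_dx(mid[:, 0], mid[:, 1], px, py)
    gradH_x = np.column_stack([Hx, Hy])
    gradH_p = np.column_stack([Hpx, Hpy])
    denom = np.einsum("ij,ij->i", gradH_p, vhat)
    act = (theta > 0) & (np.abs(denom) > 1e-14)
    # P @ gradH_p with P = I - vhat vhat^T
    proj = gradH_p - vhat * np.einsum("ij,ij->i", gradH_p, vhat)[:, None]
    grad = np.zeros_like(phi)
    for side, sign in ((0, -1.0), (1, 1.0)):  # left / right endpoint of segment
        dtheta = np.zeros_like(d)
        dtheta[act] = -(
            0.5 * gradH_x[act] + sign * (theta[act] / ell[act])[:, None] * proj[act]
        ) / denom[act, None]
        contrib = ell[:, None] * dtheta + sign * theta[:, None] * vhat
        if side == 0:
            grad[:-1] += contrib
        else:
            grad[1:] += contrib
    momenta = theta[:, None] * vhat
    return S, grad, momenta, bool(np.all(reachable | ~ok))


def _redistribute(phi: np.ndarray) -> np.ndarray:
    """Equal-arc-length reparametrization (linear interpolation)."""
    seg = np.hypot(*np.diff(phi, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        return phi
    su = np.linspace(0.0, s[-1], len(phi))
    return np.column_stack([np.interp(su, s, phi[:, 0]), np.interp(su, s, phi[:, 1])])


def minimize_action(
    ham: HamiltonianSpec,
    attractor,
    endpoint,
    path_points: int = 128,
    tol: float = 1e-5,
    max_outer: int = 12,
    inner_maxiter: int = 30,
    box: float | None = None,
    init_path: np.ndarray | None = None,
) -> ActionResult:
    """Minimize the geometric action from ``attractor`` to ``endpoint``.

    Outer iterations alternate an L-BFGS descent over the interior
    nodes with an equal-arc-length reparametrization, until the action
    stagnates within ``tol``.  Deterministic given the initialization
    (default: straight line).
    """
    if path_points < 32:
        raise ValueError("path_points must be >= 32")
    a = np.asarray(attractor, float)
    e = np.asarray(endpoint, float)
    if np.linalg.norm(e - a) < 1e-12:
        path = np.tile(a, (path_points, 1))
        return ActionResult(0.0, path, np.zeros((path_points - 1, 2)), True, True, 0)
    if init_path is None:
        phi = np.linspace(0, 1, path_points)[:, None] * (e - a)[None, :] + a[None, :]
    else:
        phi = _redistribute(np.asarray(init_path, float))
    if box is None:
        box = 4.0 * max(np.max(np.abs(a)), np.max(np.abs(e)), 1.0)

    def pack(z):
        full = np.empty((path_points, 2))
        full[0], full[-1] = a, e
        full[1:-1] = z.reshape(-1, 2)
        return full

    def fun(z):
        full = pack(z)
        S, grad, *_ = _action_and_grad(ham, full)
        return S, grad[1:-1].ravel()

    bounds = [(0.0, box)] * (2 * (path_points - 2))
    S_prev = np.inf
    converged = False
    reachable = True
    n_outer = 0
    for n_outer in range(1, max_outer + 1):
        res = minimize(
            fun, phi[1:-1].ravel(), jac=True, method="L-BFGS-B",
            bounds=bounds, options={"maxiter": inner_maxiter, "ftol": 1e-12},
        )
        phi = _redistribute(pack(res.x))
        S, _, _, reachable = _action_and_grad(ham, phi)
        if abs(S - S_prev) < tol * max(1.0, abs(S)):
            converged = True
            S_prev = S
            break
        S_prev = S
    S, _, momenta, reachable = _action_and_grad(ham, phi)
    return ActionResult(float(S), phi, momenta, converged, reachable, n_outer)


@dataclass
class QuasiPotentialField:
    """Grid of quasi-potential values relative to one attractor."""

    xs: np.ndarray
    ys: np.ndarray
    S0: np.ndarray  # (len(xs), len(ys))
    attractor: np.ndarray
    converged: np.ndarray
    reachable: np.ndarray
    kind: str
    paths: dict = field(default_factory=dict)  # (i, j) -> path array

    def wkb_density(self, b: float) -> np.ndarray:
        """exp(-S0/b), normalized to sum 1 (WKB stationary estimate)."""
        w = np.exp(-(self.S0 - np.nanmin(self.S0)) / b)
        w[~np.isfinite(w)] = 0.0
        return w / w.sum()


def quasipotential_surface(
    ham: HamiltonianSpec,
    attractor,
    xs,
    ys,
    path_points: int = 48,
    tol: float = 1e-5,
    max_outer: int = 6,
    inner_maxiter: int = 25,
    keep_paths: bool = False,
) -> QuasiPotentialField:
    """S0 on a grid by repeated minimize_action, warm-started from the
    nearest already-computed grid point."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    a = np.asarray(attractor, float)
    S0 = np.full((len(xs), len(ys)), np.nan)
    conv = np.zeros(S0.shape, dtype=bool)
    reach = np.ones(S0.shape, dtype=bool)
    pts = [(i, j) for i in range(len(xs)) for j in range(len(ys))]
    pts.sort(key=lambda ij: np.hypot(xs[ij[0]] - a[0], ys[ij[1]] - a[1]))
    done: dict = {}
    field_paths: dict = {}
    for i, j in pts:
        end = np.array([xs[i], ys[j]])
        init = None
        if done:
            ni, nj = min(
                done,
                key=lambda ij: np.hypot(xs[ij[0]] - end[0], ys[ij[1]] - end[1]),
            )
            prev = done[(ni, nj)]
            s = np.linspace(0.0, 1.0, len(prev))[:, None]
            init = prev + s * (end - prev[-1])[None, :]
        res = minimize_action(
            ham, a, end, path_points=path_points, tol=tol,
            max_outer=max_outer, inner_maxiter=inner_maxiter, init_path=init,
        )
        S0[i, j] = res.value
        conv[i, j] = res.converged
        reach[i, j] = res.reachable
        done[(i, j)] = res.path
        if keep_paths:
            field_paths[(i, j)] = res.path
    return QuasiPotentialField(
        xs=xs, ys=ys, S0=S0, attractor=a, converged=conv, reachable=reach,
        kind=ham.kind, paths=field_paths,
    )
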