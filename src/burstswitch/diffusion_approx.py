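"""Kramers-Moyal diffusion approximation of the GB model (tag "DA-GB").

The jump process with burst events at rate a and geometric sizes of
mean B is approximated by an Ito SDE for the concentrations x = N/K:

    dx = v_x dt + sqrt(D_x) dW,   v_x = B*a_X/K - gamma0*x,
    D_x = a_X*(2B^2+B)/K^2 + gamma0*x/K,

where 2B^2+B is the second moment of the geometric burst law and the
gamma0*x/K term is the degradation shot noise.  Both coefficients are
validated against brute-force jump moments of the GB SSA in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from . import _kernels
from .model_core import ModelParams, find_attractors, transcription_propensity
from .ssa_simulators import Trajectory, _mask_seed, regulation_array

__all__ = ["DriftDiffusion", "km_coefficients", "integrate_sde"]

DEFAULT_DT = 1e-3


@dataclass(frozen=True)
class DriftDiffusion:
    """Drift and diffusion fields of the GB diffusion approximation.

    ``drift(x, y)`` and ``diffusion(x, y)`` return per-species pairs in
    concentration units; ``K`` carries the population scale of the 1/K
    noise prefactor.
    """

    drift: Callable
    diffusion: Callable
    K: float
    params: ModelParams


def km_coefficients(params: ModelParams) -> DriftDiffusion:
    """Drift/diffusion coefficient functions from the jump moments."""
    B, K, g0 = params.B, params.K, params.gamma0
    m2 = 2.0 * B * B + B

    def drift(x, y):
        ax = transcription_propensity(params, N_other=K * y, N_self=K * x)
        ay = transcription_propensity(params, N_other=K * x, N_self=K * y)
        return B * ax / K - g0 * x, B * ay / K - g0 * y

    def diffusion(x, y):
        ax = transcription_propensity(params, N_other=K * y, N_self=K * x)
        ay = transcription_propensity(params, N_other=K * x, N_self=K * y)
        return ax * m2 / K**2 + g0 * x / K, ay * m2 / K**2 + g0 * y / K

    return DriftDiffusion(drift=drift, diffusion=diffusion, K=K, params=params)


def _default_initial(params: ModelParams) -> tuple:
    fp = find_attractors(params).high_x_attractor()
    return fp.x / params.K, fp.y / params.K


def integrate_sde(
    params: ModelParams,
    initial: Optional[tuple] = None,
    t_end: float = 10.0,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    noise: bool = True,
    record_stride: int = 10,
    max_records: int = 2_000_000,
) -> Trajectory:
    """Euler-Maruyama path of the GB diffusion approximation.

    Negative excursions are reflected at 0.  ``noise=False`` integrates
    the deterministic mean-field flow (the K -> infinity limit switch).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if initial is None:
        initial = _default_initial(params)
    x0, y0 = float(initial[0]), float(initial[1])
    if x0 < 0 or y0 < 0:
        raise ValueError("initial concentrations must be non-negative")
    n_steps = int(np.ceil(t_end / dt))
    cap = min(n_steps // record_stride + 2, max_records)
    buf = np.empty((cap, 3))
    out = _kernels.da_gb_sde(
        _mask_seed(seed), 0.0, t_end, x0, y0, dt, params.B, params.gamma0,
        params.K, regulation_array(params),
        np.zeros((1, 1)), False, np.inf, False, buf, cap, record_stride, noise,
    )
    t, x, y, n_rec = out[0], out[1], out[2], out[3]
    if not (np.isfinite(x) and np.isfinite(y)):
        raise RuntimeError(f"SDE integration produced non-finite state at t={t}")
    return Trajectory(
        model="DA-GB",
        columns=("t", "x", "y"),
        data=buf[:n_rec],
        seed=seed,
        params=params,
        final_state={"t": t, "x": float(x), "y": float(y)},
    )


def _stationary_weights(params, t_burn, t_total, seed, nmax, initial, dt=DEFAULT_DT):
    if initial is None:
        initial = _default_initial(params)
    W = np.zeros((nmax, nmax))
    out = _kernels.da_gb_sde(
        _mask_seed(seed), 0.0, t_total, float(initial[0]), float(initial[1]),
        dt, params.B, params.gamma0, params.K, regulation_array(params),
        W, True, t_burn, False, np.zeros((0, 3)), 0, 1, True,
    )
    stats = {"w_tot": out[5], "mean_x": out[6] / out[5], "mean_y": out[7] / out[5], "dt": dt}
    return W, stats
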