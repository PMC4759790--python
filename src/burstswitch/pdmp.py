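"""Piecewise deterministic Markov process engines.

``PDMP`` (finite gamma) keeps three discrete mRNA modes {ZERO, X, Y}; at
most one mRNA of either type is present.  Between Markovian mode
switches the concentrations follow linear ODEs: both species decay at
rate gamma0 and the active species is additionally produced at rate
gamma*b (b = B/K).  Mode transitions 0->X and 0->Y occur at the full
model's transcription rates; X->0 and Y->0 at rate gamma; there are no
direct X<->Y transitions.

``PDMP-SN`` is its shot-noise limit gamma -> infinity: each
transcription event instantaneously adds an Exp(mean b) increment of
concentration, and between events both species decay at rate gamma0.

Time-dependent event rates are sampled exactly by thinning against a
constant majorant (the global supremum of the transcription rate,
which for the toggle form is K*(r0+r)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .model_core import ModelParams, find_attractors, max_transcription_propensity
from .ssa_simulators import Trajectory, _mask_seed, regulation_array

__all__ = ["PDMPState", "MODE_NAMES", "simulate_pdmp", "simulate_shotnoise"]

MODE_NAMES = {0: "ZERO", 1: "X", 2: "Y"}

#: spacing of the occupancy-sampling grid for stationary histograms
DEFAULT_SAMPLE_DT = 0.01


@dataclass(frozen=True)
class PDMPState:
    mode: int = 0  # 0 = ZERO, 1 = X, 2 = Y
    x: float = 0.0
    y: float = 0.0
    t: float = 0.0

    def __post_init__(self):
        if self.mode not in MODE_NAMES:
            raise ValueError("mode must be 0 (ZERO), 1 (X) or 2 (Y)")
        if self.x < 0 or self.y < 0:
            raise ValueError("concentrations must be non-negative")


def _default_initial(params: ModelParams) -> PDMPState:
    fp = find_attractors(params).high_x_attractor()
    return PDMPState(mode=0, x=fp.x / params.K, y=fp.y / params.K)


def _majorant(params: ModelParams) -> float:
    # exact supremum for the toggle form; 10% inflated for three-way
    amax = max_transcription_propensity(params)
    if params.regulation != "toggle":
        amax *= 1.1
    return amax


def simulate_pdmp(
    params: ModelParams,
    initial: Optional[PDMPState] = None,
    t_end: float = 10.0,
    seed: int = 0,
    max_events: int = 2_000_000,
) -> Trajectory:
    """Exact sample path of the finite-gamma three-state PDMP.

    The trajectory records (t, mode, x, y) at mode-switch times.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if not np.isfinite(params.gamma):
        raise ValueError("finite-gamma PDMP requires finite gamma")
    if initial is None:
        initial = _default_initial(params)
    buf = np.empty((max_events, 4))
    out = _kernels.pdmp_ssa(
        _mask_seed(seed), initial.t, t_end, initial.mode, initial.x, initial.y,
        params.gamma, params.gamma0, params.gamma * params.b, _majorant(params),
        params.K, regulation_array(params),
        np.zeros((1, 1)), False, np.inf, DEFAULT_SAMPLE_DT, False, buf, max_events,
    )
    t, mode, x, y, n_rec = out[:5]
    return Trajectory(
        model="PDMP",
        columns=("t", "mode", "x", "y"),
        data=buf[:n_rec],
        seed=seed,
        params=params,
        final_state={"t": t, "mode": int(mode), "x": float(x), "y": float(y),
                     "time_active": float(out[7])},
    )


def simulate_shotnoise(
    params: ModelParams,
    initial: Optional[tuple] = None,
    t_end: float = 10.0,
    seed: int = 0,
    max_events: int = 2_000_000,
) -> Trajectory:
    """Sample path of the shot-noise (gamma -> infinity) PDMP limit.

    Records pre- and post-jump states at each burst time so that
    time-weighted statistics follow the left-continuous convention.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if initial is None:
        fp = _default_initial(params)
        initial = (fp.x, fp.y)
    x0, y0 = float(initial[0]), float(initial[1])
    if x0 < 0 or y0 < 0:
        raise ValueError("concentrations must be non-negative")
    buf = np.empty((max_events, 3))
    out = _kernels.shotnoise_ssa(
        _mask_seed(seed), 0.0, t_end, x0, y0, params.b, params.gamma0,
        _majorant(params), params.K, regulation_array(params),
        np.zeros((1, 1)), False, np.inf, DEFAULT_SAMPLE_DT, False, buf, max_events,
    )
    t, x, y, n_rec = out[:4]
    return Trajectory(
        model="PDMP-SN",
        columns=("t", "x", "y"),
        data=buf[:n_rec],
        seed=seed,
        params=params,
        final_state={"t": t, "x": float(x), "y": float(y), "n_events": float(out[6])},
    )


def _stationary_weights(
    model_tag, params, t_burn, t_total, seed, nmax, initial, sample_dt=DEFAULT_SAMPLE_DT
):
    W = np.zeros((nmax, nmax))
    rp = regulation_array(params)
    if model_tag == "PDMP":
        if initial is None:
            initial = _default_initial(params)
        out = _kernels.pdmp_ssa(
            _mask_seed(seed), initial.t, t_total, initial.mode, initial.x, initial.y,
            params.gamma, params.gamma0, params.gamma * params.b, _majorant(params),
            params.K, rp, W, True, t_burn, sample_dt, False, np.zeros((0, 4)), 0,
        )
        stats = {"w_tot": out[6], "time_active": out[7], "sample_dt": sample_dt}
    else:
        if initial is None:
            fp = _default_initial(params)
            initial = (fp.x, fp.y)
        out = _kernels.shotnoise_ssa(
            _mask_seed(seed), 0.0, t_total, float(initial[0]), float(initial[1]),
            params.b, params.gamma0, _majorant(params), params.K, rp,
            W, True, t_burn, sample_dt, False, np.zeros((0, 3)), 0,
        )
        stats = {"w_tot": out[5], "n_events": out[6], "sample_dt": sample_dt}
    return W, stats
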