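"""Exact Gillespie simulation of the four discrete models.

Model tags:

``FM``
    full model with explicit mRNA and protein populations,
``GB``
    protein-only model with geometrically distributed bursts,
``CB``
    protein-only model with constant bursts of size B,
``NB``
    protein-only model producing single proteins at a B-fold rate.

All simulators are statistically exact samplers of the corresponding
continuous-time Markov chains (direct method with on-the-fly propensity
recomputation; the channel count is tiny so no dependency graph is
used).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .model_core import ModelParams, find_attractors

__all__ = [
    "DiscreteState",
    "Trajectory",
    "DISCRETE_TAGS",
    "simulate",
    "sample_burst",
    "stationary_histogram",
    "proteins_per_mrna_lifetime",
    "regulation_array",
    "default_initial_counts",
]

DISCRETE_TAGS = ("FM", "GB", "CB", "NB")
_BURST_KIND = {"NB": _kernels.NB_KIND, "GB": _kernels.GB_KIND, "CB": _kernels.CB_KIND}

#: default burn-in for stationary estimates [cell cycles]
DEFAULT_BURN_IN = 50.0
#: default protein-number axis: unit bins 0..899
DEFAULT_NMAX = 900


@dataclass(frozen=True)
class DiscreteState:
    """Integer copy-number state; mX/mY are meaningful for the FM only."""

    NX: int
    NY: int
    mX: int = 0
    mY: int = 0
    t: float = 0.0

    def __post_init__(self):
        if min(self.NX, self.NY, self.mX, self.mY) < 0:
            raise ValueError("copy numbers must be non-negative")


@dataclass
class Trajectory:
    """Time-stamped sample path with seed provenance.

    ``data`` holds one row per recorded event; the first column is time.
    """

    model: str
    columns: tuple
    data: np.ndarray
    seed: int
    params: ModelParams
    final_state: dict = field(default_factory=dict)

    @property
    def t(self) -> np.ndarray:
        return self.data[:, 0]

    def column(self, name: str) -> np.ndarray:
        return self.data[:, self.columns.index(name)]

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.data, columns=list(self.columns))


def regulation_array(params: ModelParams) -> np.ndarray:
    """Pack regulation parameters for the numba kernels."""
    flag = 0.0 if params.regulation == "toggle" else 1.0
    return np.array(
        [
            flag,
            params.K,
            params.r0,
            params.r,
            params.n,
            params.q0,
            params.r1,
            params.r2,
            params.n1,
            params.n2,
            params.K1,
            params.K2,
        ],
        dtype=np.float64,
    )


def _mask_seed(seed: int) -> int:
    return int(seed) & 0x7FFFFFFF


def spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Derive n independent kernel seeds from one global seed."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) & 0x7FFFFFFF


def default_initial_counts(params: ModelParams) -> DiscreteState:
    """High-X deterministic attractor, rounded to integers."""
    att = find_attractors(params)
    fp = att.high_x_attractor()
    return DiscreteState(NX=int(round(fp.x)), NY=int(round(fp.y)))


_DUMMY_W = np.zeros((1, 1))
_DUMMY_BUF = np.zeros((0, 5))


def _check_overflow(n_rec: int, switch_t: float, state) -> None:
    if n_rec == -1 or switch_t == -2.0:
        raise RuntimeError(f"negative copy number encountered; state dump: {state}")


def simulate(
    model_tag: str,
    params: ModelParams,
    initial: Optional[DiscreteState] = None,
    t_end: float = 10.0,
    seed: int = 0,
    max_events: int = 2_000_000,
) -> Trajectory:
    """Exact sample path of one of the four discrete models.

    Identical (seed, params, initial) yield identical trajectories.  If
    the event buffer fills before ``t_end`` the simulation continues in
    chunks (with per-chunk seeds derived from ``seed``).
    """
    if model_tag not in DISCRETE_TAGS:
        raise ValueError(f"unknown model tag {model_tag!r}; expected one of {DISCRETE_TAGS}")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if model_tag == "CB" and abs(params.B - round(params.B)) > 1e-9:
        raise ValueError("CB model requires integer burst size B")
    if initial is None:
        initial = default_initial_counts(params)
    rp = regulation_array(params)
    chunk_seeds = spawn_seeds(seed, 64)
    chunks = []
    t, mX, mY, NX, NY = initial.t, initial.mX, initial.mY, initial.NX, initial.NY
    for chunk in range(64):
        if model_tag == "FM":
            buf = np.empty((max_events, 5))
            out = _kernels.fm_ssa(
                _mask_seed(chunk_seeds[chunk]), t, t_end, mX, mY, NX, NY,
                params.gamma, params.gamma * params.B, params.gamma0, rp,
                _DUMMY_W, False, np.inf, False, buf, max_events,
            )
            t, mX, mY, NX, NY, n_rec, switch_t = out[:7]
            _check_overflow(n_rec, switch_t, out)
            chunks.append(buf[:n_rec])
        else:
            buf = np.empty((max_events, 3))
            out = _kernels.burst_ssa(
                _mask_seed(chunk_seeds[chunk]), t, t_end, NX, NY,
                _BURST_KIND[model_tag], params.B, params.gamma0, rp,
                _DUMMY_W, False, np.inf, False, buf, max_events,
            )
            t, NX, NY, n_rec, switch_t = out[:5]
            _check_overflow(n_rec, switch_t, out)
            chunks.append(buf[:n_rec])
        if t >= t_end:
            break
    data = np.vstack(chunks)
    if model_tag == "FM":
        columns = ("t", "mX", "mY", "NX", "NY")
    else:
        columns = ("t", "NX", "NY")
    return Trajectory(
        model=model_tag,
        columns=columns,
        data=data,
        seed=seed,
        params=params,
        final_state={"t": t, "mX": int(mX), "mY": int(mY), "NX": int(NX), "NY": int(NY)},
    )


def sample_burst(kind: str, B: float, rng: np.random.Generator, size=None):
    """Draw burst sizes.

    ``geometric``: support {0, 1, 2, ...} with mean B (the law of the
    number of proteins one mRNA produces); ``constant``: exactly B
    (B must be an integer).
    """
    if B <= 0:
        raise ValueError("B must be positive")
    if kind == "geometric":
        out = rng.geometric(1.0 / (1.0 + B), size=size) - 1
    elif kind == "constant":
        if abs(B - round(B)) > 1e-9:
            raise ValueError("constant bursts require integer B")
        if size is None:
            out = int(round(B))
        else:
            out = np.full(size, int(round(B)), dtype=np.int64)
    else:
        raise ValueError(f"unknown burst kind {kind!r}")
    return out


def proteins_per_mrna_lifetime(params: ModelParams, n_rep: int, seed: int = 0) -> np.ndarray:
    """Simulate n_rep single-mRNA lifecycles (translation vs degradation
    race at rates gamma*B and gamma) and return proteins produced."""
    return _kernels.mrna_lifecycles(
        _mask_seed(seed), n_rep, params.gamma, params.gamma * params.B
    )


def _check_cb_burst(model_tag: str, params: ModelParams) -> None:
    if model_tag == "CB" and abs(params.B - round(params.B)) > 1e-9:
        raise ValueError("CB model requires integer burst size B")


def _discrete_stationary_weights(
    model_tag, params, t_burn, t_total, seed, nmax, initial
):
    _check_cb_burst(model_tag, params)
    rp = regulation_array(params)
    W = np.zeros((nmax, nmax))
    if initial is None:
        initial = default_initial_counts(params)
    if model_tag == "FM":
        out = _kernels.fm_ssa(
            _mask_seed(seed), initial.t, t_total, initial.mX, initial.mY,
            initial.NX, initial.NY, params.gamma, params.gamma * params.B,
            params.gamma0, rp, W, True, t_burn, False, _DUMMY_BUF, 0,
        )
        _check_overflow(out[5], out[6], out)
        stats = {
            "w_tot": out[7],
            "mean_mX": out[8] / out[7] if out[7] > 0 else np.nan,
            "mean_mY": out[9] / out[7] if out[7] > 0 else np.nan,
            "mean_NX": out[10] / out[7] if out[7] > 0 else np.nan,
            "mean_NY": out[11] / out[7] if out[7] > 0 else np.nan,
            "prodX": out[12],
        }
    else:
        out = _kernels.burst_ssa(
            _mask_seed(seed), initial.t, t_total, initial.NX, initial.NY,
            _BURST_KIND[model_tag], params.B, params.gamma0, rp,
            W, True, t_burn, False, _DUMMY_BUF, 0,
        )
        _check_overflow(out[3], out[4], out)
        stats = {
            "w_tot": out[5],
            "mean_NX": out[6] / out[5] if out[5] > 0 else np.nan,
            "mean_NY": out[7] / out[5] if out[5] > 0 else np.nan,
            "prodX": out[8],
        }
    return W, stats


def stationary_histogram(
    model_tag: str,
    params: ModelParams,
    t_burn: float = DEFAULT_BURN_IN,
    t_total: float = 1000.0,
    seed: int = 0,
    nmax: int = DEFAULT_NMAX,
    initial=None,
):
    """Time-weighted stationary occupancy histogram of (NX, NY).

    Unit protein-number bins 0..nmax-1 (the last bin absorbs any
    overflow).  Dispatches to the continuous engines for model tags
    "DA-GB", "PDMP" and "PDMP-SN" so that all engines share one binning.
    """
    from .summary_stats import Histogram2D

    if t_burn >= t_total:
        raise ValueError("t_total must exceed t_burn")
    meta = {
        "model": model_tag,
        "seed": int(seed),
        "t_burn": float(t_burn),
        "t_total": float(t_total),
    }
    if model_tag in DISCRETE_TAGS:
        W, stats = _discrete_stationary_weights(
            model_tag, params, t_burn, t_total, seed, nmax, initial
        )
        meta.update(stats)
    elif model_tag == "DA-GB":
        from .diffusion_approx import _stationary_weights as da_weights

        W, stats = da_weights(params, t_burn, t_total, seed, nmax, initial)
        meta.update(stats)
    elif model_tag in ("PDMP", "PDMP-SN"):
        from .pdmp import _stationary_weights as pdmp_weights

        W, stats = pdmp_weights(model_tag, params, t_burn, t_total, seed, nmax, initial)
        meta.update(stats)
    else:
        raise ValueError(f"unknown model tag {model_tag!r}")
    return Histogram2D.from_weights(W, meta=meta)
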