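"""Model parameters, regulation functions and the deterministic mean-field limit.

Every stochastic engine in this package (discrete Gillespie simulators,
the diffusion approximation, the piecewise deterministic Markov process
and its shot-noise limit) draws its transcription rates from the single
implementation in this module, so that the engines differ only in how
they represent noise, never in the underlying kinetics.

Two regulation schemes are supported:

``toggle``
    Mutual repression of two genes via a Hill function of the *other*
    protein's copy number: the transcription rate of gene X is
    ``K*(r0 + r/(1 + (N_Y/K)**n))`` per cell cycle, and symmetrically
    for gene Y.

``three_way``
    Mutual repression plus positive autoregulation.  The transcription
    rate of gene X is ``q0*(1 + r1/(1 + (N_X/K1)**n1))*(1 + r2/(1 +
    (N_Y/K2)**n2))``; the negative value of ``r1`` turns the first
    factor into an activating function of the gene's own protein.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
import numpy as np
from scipy.optimize import fsolve

__all__ = [
    "ModelParams",
    "FixedPoint",
    "AttractorSet",
    "hill",
    "transcription_propensity",
    "max_transcription_propensity",
    "mean_field_rhs",
    "find_attractors",
    "get_preset",
    "load_params",
    "PRESETS",
]

TOGGLE = "toggle"
THREE_WAY = "three_way"

#: ratio gamma/gamma0 below which the burst-limit engines become dubious
_FAST_MRNA_RATIO = 10.0


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the symmetric two-gene switch.

    Times are measured in cell cycles and copy numbers in molecules.
    The defaults are the E. coli estimates used throughout.
    """

    B: float = 30.0          # mean number of proteins per mRNA lifetime
    gamma: float = 30.0      # mRNA degradation rate [1/cell cycle]
    gamma0: float = 1.0      # protein degradation rate [1/cell cycle]
    r: float = 6.0 / 100.0   # maximum suppressed transcription rate [1/cycle]
    r0: float = 1.0 / 150.0  # basal transcription rate [1/cycle]
    K: float = 200.0         # typical protein population scale [molecules]
    n: float = 3.0           # Hill coefficient
    regulation: str = TOGGLE
    # --- three-way switch extras (ignored for regulation="toggle") ---
    q0: float = 4.0
    r1: float = -4.0 / 5.0
    r2: float = 7.0 / 3.0
    n1: float = 3.0
    n2: float = 1.0
    K1: float = 160.0
    K2: float = 320.0

    def __post_init__(self) -> None:
        if self.B <= 0 or self.gamma <= 0 or self.gamma0 <= 0 or self.K <= 0:
            raise ValueError("B, gamma, gamma0 and K must be positive")
        if self.r < 0 or self.r0 < 0:
            raise ValueError("r and r0 must be non-negative")
        if self.n <= 0:
            raise ValueError("Hill coefficient n must be positive")
        if self.regulation not in (TOGGLE, THREE_WAY):
            raise ValueError(
                f"unknown regulation {self.regulation!r}; "
                f"expected {TOGGLE!r} or {THREE_WAY!r}"
            )
        if self.regulation == THREE_WAY:
            if self.K1 <= 0 or self.K2 <= 0 or self.n1 <= 0 or self.n2 <= 0:
                raise ValueError("K1, K2, n1, n2 must be positive")
            if self.q0 <= 0:
                raise ValueError("q0 must be positive")
            if self.q0 * (1.0 + min(self.r1, 0.0)) <= 0:
                raise ValueError("three-way rate must stay strictly positive")
        if self.gamma / self.gamma0 < _FAST_MRNA_RATIO:
            warnings.warn(
                f"gamma/gamma0 = {self.gamma / self.gamma0:.2f} < "
                f"{_FAST_MRNA_RATIO}: burst-limit engines (GB/CB/NB, PDMP) "
                "assume fast mRNA degradation",
                stacklevel=2,
            )

    @property
    def b(self) -> float:
        """Mean burst size in concentration units, b = B/K."""
        return self.B / self.K

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def with_overrides(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


def _table1() -> ModelParams:
    return ModelParams()


def _threeway() -> ModelParams:
    return ModelParams(regulation=THREE_WAY)


PRESETS = {
    "ecoli_table1": _table1,
    "lu_threeway": _threeway,
}


def get_preset(name: str) -> ModelParams:
    """Return a packaged parameter preset by name."""
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def load_params(path: str | Path) -> ModelParams:
    """Load parameters from a JSON or YAML config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if "preset" in data:
        base = get_preset(data.pop("preset"))
        return base.with_overrides(**data)
    return ModelParams.from_dict(data)


# ---------------------------------------------------------------------------
# Regulation functions and propensities
# ---------------------------------------------------------------------------


def hill(N, K: float, n: float):
    """Repressive Hill function 1/(1 + (N/K)**n).

    Monotone decreasing, equals 1 at N=0 and 1/2 at N=K.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("copy numbers must be non-negative")
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + (N / K) ** n)
    return out if out.ndim else float(out)


def transcription_propensity(params: ModelParams, N_other, N_self=0.0):
    """Transcription rate of a gene [events per cell cycle].

    ``N_other`` is the copy number of the repressing (other) protein;
    ``N_self`` is the gene's own protein and only enters for the
    three-way regulation.  Vectorized over copy-number arrays.
    """
    N_other = np.asarray(N_other, dtype=float)
    N_self = np.asarray(N_self, dtype=float)
    if np.any(N_other < 0) or np.any(N_self < 0):
        raise ValueError("copy numbers must be non-negative")
    if params.regulation == TOGGLE:
        out = params.K * (params.r0 + params.r * hill(N_other, params.K, params.n))
    else:
        out = (
            params.q0
            * (1.0 + params.r1 * hill(N_self, params.K1, params.n1))
            * (1.0 + params.r2 * hill(N_other, params.K2, params.n2))
        )
    return out if np.ndim(out) else float(out)


def max_transcription_propensity(params: ModelParams) -> float:
    """Supremum of the transcription rate over the non-negative quadrant."""
    if params.regulation == TOGGLE:
        return params.K * (params.r0 + params.r)
    hi1 = max(1.0, 1.0 + params.r1)  # r1 < 0: factor increases towards 1
    hi2 = max(1.0, 1.0 + params.r2)
    return params.q0 * hi1 * hi2


# ---------------------------------------------------------------------------
# Deterministic mean-field limit
# ---------------------------------------------------------------------------


def mean_field_rhs(params: ModelParams, x) -> np.ndarray:
    """Right-hand side of the deterministic protein-number dynamics.

    dN_X/dt = B*a_X(N_Y, N_X) - gamma0*N_X (and symmetrically for Y),
    in molecules per cell cycle.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (2,):
        raise ValueError("state must be a pair of protein numbers")
    nx, ny = x
    ax = transcription_propensity(params, N_other=ny, N_self=nx)
    ay = transcription_propensity(params, N_other=nx, N_self=ny)
    return np.array(
        [params.B * ax - params.gamma0 * nx, params.B * ay - params.gamma0 * ny]
    )


@dataclass(frozen=True)
class FixedPoint:
    x: float
    y: float
    eigenvalues: tuple
    stable: bool

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class AttractorSet:
    stable: list = field(default_factory=list)
    unstable: list = field(default_factory=list)
    failures: list = field(default_factory=list)  # starting points that failed

    @property
    def saddle(self) -> FixedPoint | None:
        """The symmetric unstable point, if present."""
        for fp in self.unstable:
            if abs(fp.x - fp.y) < 1e-6 * (1.0 + abs(fp.x)):
                return fp
        return None

    def high_x_attractor(self) -> FixedPoint:
        return max(self.stable, key=lambda fp: fp.x - fp.y)


_STABILITY_EPS = 1e-9


def _jacobian(params: ModelParams, p: np.ndarray, h: float = 1e-5) -> np.ndarray:
    J = np.zeros((2, 2))
    for i in range(2):
        e = np.zeros(2)
        e[i] = h * max(1.0, abs(p[i]))
        J[:, i] = (
            mean_field_rhs(params, np.maximum(p + e, 0.0))
            - mean_field_rhs(params, np.maximum(p - e, 0.0))
        ) / (2 * e[i])
    return J


def find_attractors(
    params: ModelParams, n_grid: int = 9, box: float | None = None
) -> AttractorSet:
    """Locate fixed points of the mean-field flow and classify stability.

    A deterministic ``n_grid`` x ``n_grid`` multi-start over the box
    ``[0, 3*B*a_max/gamma0]**2`` feeds a Newton-type root finder; roots
    are deduplicated and classified by the eigenvalues of the numerical
    Jacobian (stable iff all real parts < -1e-9).  Starting points whose
    solve does not converge are recorded in ``failures``.
    """
    if box is None:
        box = 3.0 * params.B * max_transcription_propensity(params) / params.gamma0
    rhs = lambda v: mean_field_rhs(params, np.maximum(v, 0.0))
    roots: list[np.ndarray] = []
    result = AttractorSet()
    grid = np.linspace(0.0, box, n_grid)
    for x0 in grid:
        for y0 in grid:
            sol, _info, ier, msg = fsolve(rhs, [x0, y0], full_output=True)
            if ier != 1:
                result.failures.append(((float(x0), float(y0)), msg))
                continue
            sol = np.maximum(sol, 0.0)
            if np.max(np.abs(rhs(sol))) > 1e-6:
                result.failures.append(((float(x0), float(y0)), "spurious root"))
                continue
            if not any(np.allclose(sol, q, atol=1e-3 * (1 + box)) for q in roots):
                roots.append(sol)
    for p in roots:
        ev = np.linalg.eigvals(_jacobian(params, p))
        fp = FixedPoint(
            x=float(p[0]),
            y=float(p[1]),
            eigenvalues=tuple(ev),
            stable=bool(np.max(ev.real) < -_STABILITY_EPS),
        )
        (result.stable if fp.stable else result.unstable).append(fp)
    result.stable.sort(key=lambda fp: (fp.x, fp.y))
    result.unstable.sort(key=lambda fp: (fp.x, fp.y))
    return result
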