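"""Histograms, Jensen-Shannon distances, mode detection and sweeps."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import jensenshannon

from .model_core import ModelParams

__all__ = [
    "Histogram2D",
    "js_distance",
    "rebin",
    "count_modes",
    "sweep_compare",
    "ALL_TAGS",
]

ALL_TAGS = ("FM", "GB", "CB", "NB", "DA-GB", "PDMP", "PDMP-SN")


@dataclass
class Histogram2D:
    """Normalized stationary distribution on a protein-number grid.

    Unit bins: ``masses[i, j]`` is the probability of (NX, NY) in bin
    (i, j) with bin centres at integer copy numbers.
    """

    edges_x: np.ndarray
    edges_y: np.ndarray
    masses: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (len(self.edges_x) - 1, len(self.edges_y) - 1):
            raise ValueError("masses shape inconsistent with bin edges")
        if np.any(self.masses < 0):
            raise ValueError("histogram masses must be non-negative")
        tot = self.masses.sum()
        if not np.isclose(tot, 1.0, atol=1e-12, rtol=1e-9):
            raise ValueError(f"histogram not normalized (sum = {tot})")

    @classmethod
    def from_weights(cls, W: np.ndarray, meta: dict | None = None) -> "Histogram2D":
        """Normalize raw occupancy weights on unit bins [-0.5, 0.5, ...]."""
        W = np.asarray(W, dtype=float)
        tot = W.sum()
        if tot <= 0:
            raise ValueError("empty histogram")
        edges = np.arange(W.shape[0] + 1) - 0.5
        edges_y = np.arange(W.shape[1] + 1) - 0.5
        return cls(edges, edges_y, W / tot, meta=dict(meta or {}))

    def same_binning(self, other: "Histogram2D") -> bool:
        return (
            self.masses.shape == other.masses.shape
            and np.allclose(self.edges_x, other.edges_x)
            and np.allclose(self.edges_y, other.edges_y)
        )

    def marginal_x(self) -> np.ndarray:
        return self.masses.sum(axis=1)

    def marginal_y(self) -> np.ndarray:
        return self.masses.sum(axis=0)

    def mean(self) -> tuple:
        cx = 0.5 * (self.edges_x[:-1] + self.edges_x[1:])
        cy = 0.5 * (self.edges_y[:-1] + self.edges_y[1:])
        return float(self.marginal_x() @ cx), float(self.marginal_y() @ cy)

    def variance(self) -> tuple:
        cx = 0.5 * (self.edges_x[:-1] + self.edges_x[1:])
        cy = 0.5 * (self.edges_y[:-1] + self.edges_y[1:])
        mx, my = self.mean()
        return (
            float(self.marginal_x() @ (cx - mx) ** 2),
            float(self.marginal_y() @ (cy - my) ** 2),
        )


def rebin(h: Histogram2D, factor: int) -> Histogram2D:
    """Coarsen a histogram by an integer factor along both axes.

    Trailing bins that do not fill a complete block are dropped (their
    mass is renormalized away); useful to compare sampled histograms
    above the finite-sample Jensen-Shannon floor of 1-molecule bins.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    nx = (h.masses.shape[0] // factor) * factor
    ny = (h.masses.shape[1] // factor) * factor
    m = h.masses[:nx, :ny].reshape(nx // factor, factor, ny // factor, factor)
    m = m.sum(axis=(1, 3))
    tot = m.sum()
    if tot <= 0:
        raise ValueError("rebinned histogram is empty")
    return Histogram2D(
        edges_x=h.edges_x[: nx + 1 : factor],
        edges_y=h.edges_y[: ny + 1 : factor],
        masses=m / tot,
        meta={**h.meta, "rebin_factor": factor * h.meta.get("rebin_factor", 1)},
    )


def js_distance(p: Histogram2D | np.ndarray, q: Histogram2D | np.ndarray) -> float:
    """Jensen-Shannon distance (square root of the base-2 divergence).

    Lies in [0, 1]; zero-mass bins contribute nothing (0*log 0 = 0).
    """
    if isinstance(p, Histogram2D) or isinstance(q, Histogram2D):
        if not (isinstance(p, Histogram2D) and isinstance(q, Histogram2D)):
            raise ValueError("both arguments must be Histogram2D (or both arrays)")
        if not p.same_binning(q):
            raise ValueError("histograms must share identical binning")
        a, b = p.masses.ravel(), q.masses.ravel()
    else:
        a, b = np.asarray(p, float).ravel(), np.asarray(q, float).ravel()
        if a.shape != b.shape:
            raise ValueError("distributions must share identical binning")
    d = float(jensenshannon(a, b, base=2))
    return 0.0 if np.isnan(d) else d


def count_modes(
    h: Histogram2D,
    smoothing_bw: float = 15.0,
    rel_threshold: float = 0.05,
):
    """Count modes of a histogram after Gaussian smoothing.

    Local maxima of the smoothed mass exceeding
    rel_threshold * (global max), merged when closer than one
    bandwidth.  Returns (n_modes, coordinates) with coordinates in bin
    centres, sorted by descending peak mass.
    """
    sm = ndimage.gaussian_filter(h.masses, sigma=smoothing_bw, mode="constant")
    size = max(3, int(round(smoothing_bw)) | 1)
    local_max = ndimage.maximum_filter(sm, size=size, mode="constant") == sm
    thresh = rel_threshold * sm.max()
    cand = np.argwhere(local_max & (sm >= thresh) & (sm > 0))
    # sort by peak height, then greedily merge within one bandwidth
    order = np.argsort(-sm[cand[:, 0], cand[:, 1]])
    kept: list[np.ndarray] = []
    for idx in order:
        c = cand[idx]
        if all(np.hypot(*(c - k)) > smoothing_bw for k in kept):
            kept.append(c)
    cx = 0.5 * (h.edges_x[:-1] + h.edges_x[1:])
    cy = 0.5 * (h.edges_y[:-1] + h.edges_y[1:])
    coords = [(float(cx[i]), float(cy[j])) for i, j in kept]
    return len(coords), coords


def sweep_compare(
    engines: Sequence[str],
    params: ModelParams,
    sweep_axis: str,
    values: Iterable[float],
    seeds: Sequence[int],
    t_total: float = 2000.0,
    t_burn: float = 50.0,
    nmax: int = 900,
    mfst_reps: int = 0,
    t_cap: float = 2000.0,
):
    """JS distance to the FM (and optionally attractor-start MFSTs)
    along a sweep of B or K.

    Returns a pandas DataFrame with one row per (sweep value, engine).
    Engine failures at a sweep point are recorded and the sweep
    continues.
    """
    import pandas as pd

    from .first_passage import mfst_monte_carlo
    from .model_core import find_attractors
    from .ssa_simulators import stationary_histogram

    if sweep_axis not in ("B", "K"):
        raise ValueError("sweep_axis must be 'B' or 'K'")
    values = list(values)
    seeds = list(seeds)
    if len(seeds) < len(values):
        raise ValueError("need at least one seed per sweep value")
    rows = []
    for val, seed in zip(values, seeds):
        p = params.with_overrides(**{sweep_axis: float(val)})
        try:
            ref = stationary_histogram("FM", p, t_burn, t_total, seed=seed, nmax=nmax)
        except Exception as exc:  # noqa: BLE001 - sweep must continue
            for tag in engines:
                rows.append({sweep_axis: val, "engine": tag, "js": np.nan,
                             "mfst": np.nan, "error": f"FM failed: {exc}"})
            continue
        for k, tag in enumerate(engines):
            row = {sweep_axis: val, "engine": tag, "b": p.b, "js": np.nan,
                   "mfst": np.nan, "error": ""}
            try:
                hst = stationary_histogram(
                    tag, p, t_burn, t_total, seed=seed + 1 + k, nmax=nmax
                )
                row["js"] = js_distance(ref, hst)
                if mfst_reps > 0:
                    fp = find_attractors(p).high_x_attractor()
                    grid = [(fp.x, fp.y)]
                    res = mfst_monte_carlo(
                        tag, p, grid, n_rep=mfst_reps, seed=seed + 101 + k, t_cap=t_cap
                    )
                    row["mfst"] = float(res.mean[0])
            except Exception as exc:  # noqa: BLE001
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)
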