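"""Interval propagation of parameter uncertainty through a response function.

Given a box of parameter intervals and a scalar response ``f`` (surrogate or
simulator), the response interval is ``[min f, max f]`` over the box.  Two
methods are provided: ``multistart-local`` (bounded quasi-Newton descent from
the box centre, every corner and random interior starts — the production
path) and ``grid-oracle`` (exhaustive tensor-grid evaluation — the reference
used in tests and for re-verifying optimization results).  The uncertainty
report flags an operating condition as unreliable when the skin-surface
temperature interval is not certainly below the allowable value.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import minimize

from .intervals import Box, Interval, rpdi_degenerate

__all__ = [
    "UncertaintyScenario",
    "UncertaintyReport",
    "response_interval",
    "joint_grid_intervals",
    "analyze_uncertainty",
]

ResponseFn = Callable[[np.ndarray], float]
Method = Literal["multistart-local", "grid-oracle"]


def _grid_points(box: Box, points_per_dim: int) -> np.ndarray:
    axes = [np.linspace(iv.lower, iv.upper, points_per_dim) for iv in box]
    grids = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def joint_grid_intervals(
    f_multi: Callable[[np.ndarray], np.ndarray], box: Box, points_per_dim: int = 9
) -> list[Interval]:
    """Tensor-grid response intervals of a vector-valued response.

    ``f_multi(points (n, dim)) -> (n, k)``; returns one Interval per output
    column.  Evaluating all outputs in a single batched call matters when
    they share expensive common work (e.g. the RBF kernel matrix).
    """
    pts = _grid_points(box, points_per_dim)
    vals = np.asarray(f_multi(pts), dtype=float)
    if vals.ndim != 2 or vals.shape[0] != len(pts):
        raise ValueError("joint response must return an (n_points, k) array")
    if not np.all(np.isfinite(vals)):
        raise ValueError("response is not finite everywhere on the box")
    return [Interval(float(c.min()), float(c.max())) for c in vals.T]


def _grid_extrema(f: ResponseFn, box: Box, points_per_dim: int) -> tuple[float, float]:
    pts = _grid_points(box, points_per_dim)
    try:  # vectorized responses evaluate the whole grid at once
        vals = np.asarray(f(pts), dtype=float)
        if vals.shape != (len(pts),):
            raise TypeError
    except Exception:  # noqa: BLE001 - scalar-only response
        vals = np.array([float(f(p)) for p in pts])
    if not np.all(np.isfinite(vals)):
        raise ValueError("response is not finite everywhere on the box")
    return float(vals.min()), float(vals.max())


def response_interval(
    f: ResponseFn,
    box: Box,
    method: Method = "multistart-local",
    seed: int = 0,
    n_random_starts: int = 8,
    grid_points_per_dim: int = 9,
    jac: Callable[[np.ndarray], np.ndarray] | None = None,
) -> Interval:
    """Response interval ``[min f, max f]`` over an axis-aligned box.

    ``multistart-local`` runs L-BFGS-B from the box centre, all 2^dim
    corners and ``n_random_starts`` seeded interior points, for the minimum
    and (on ``-f``) the maximum; if every start fails it falls back to the
    grid oracle with a warning.  ``grid-oracle`` evaluates a full
    ``grid_points_per_dim``-per-dimension tensor grid.

    A degenerate box (all radii zero) short-circuits to the point value.
    """
    lower = np.asarray(box.lower)
    upper = np.asarray(box.upper)
    if np.all(lower == upper):
        v = float(f(lower.astype(float)))
        return Interval(v, v)

    if method == "grid-oracle":
        lo, hi = _grid_extrema(f, box, grid_points_per_dim)
        return Interval(lo, hi)
    if method != "multistart-local":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    starts = [0.5 * (lower + upper)]
    starts += [np.array(c, dtype=float) for c in itertools.product(*zip(lower, upper))]
    starts += [rng.uniform(lower, upper) for _ in range(n_random_starts)]
    bounds = list(zip(lower, upper))

    results = {}
    for sign, label in ((1.0, "min"), (-1.0, "max")):
        fun = (lambda x: sign * float(f(x)))
        sjac = None if jac is None else (lambda x: sign * np.asarray(jac(x), dtype=float))
        best, best_x = np.inf, None
        for x0 in starts:
            try:
                res = minimize(fun, x0, jac=sjac, method="L-BFGS-B", bounds=bounds)
            except Exception:  # noqa: BLE001
                continue
            val = float(res.fun) if np.isfinite(res.fun) else np.inf
            if val < best:
                best, best_x = val, res.x
        if best_x is None:
            warnings.warn(
                "all local starts failed; falling back to the grid oracle", stacklevel=2
            )
            lo, hi = _grid_extrema(f, box, grid_points_per_dim)
            return Interval(lo, hi)
        results[label] = sign * best
    lo, hi = results["min"], results["max"]
    if lo > hi:  # numerically flat response
        lo, hi = hi, lo
    return Interval(lo, hi)


@dataclass
class UncertaintyScenario:
    """Inputs of an interval uncertainty analysis of the two indicators."""

    box: Box                       # over (t1, d, h, omega_c)
    hpm: ResponseFn
    st: ResponseFn
    allowable_st: float = 45.5     # degC
    method: Method = "multistart-local"
    seed: int = 0
    jac_hpm: Callable[[np.ndarray], np.ndarray] | None = None
    jac_st: Callable[[np.ndarray], np.ndarray] | None = None


@dataclass
class UncertaintyReport:
    """Response intervals of both indicators plus the reliability verdict."""

    hpm_interval: Interval
    st_interval: Interval
    allowable_st: float
    st_rpdi: float = field(init=False)
    reliable: bool = field(init=False)

    def __post_init__(self) -> None:
        self.st_rpdi = rpdi_degenerate(self.st_interval, self.allowable_st)
        self.reliable = self.st_interval.upper <= self.allowable_st

    def to_json_dict(self) -> dict:
        return {
            "HPM_interval": self.hpm_interval.to_json(),
            "ST_interval": self.st_interval.to_json(),
            "allowable_ST": self.allowable_st,
            "ST_rpdi": self.st_rpdi,
            "reliable": self.reliable,
        }


def analyze_uncertainty(scenario: UncertaintyScenario) -> UncertaintyReport:
    """Propagate the scenario box through both indicators.

    The condition is *reliable* when the ST interval lies entirely at or
    below the allowable surface temperature (RPDI >= 1); an upper bound
    above the allowable marks the overlap with the infeasible region.
    """
    hpm_iv = response_interval(
        scenario.hpm, scenario.box, scenario.method, scenario.seed, jac=scenario.jac_hpm
    )
    st_iv = response_interval(
        scenario.st, scenario.box, scenario.method, scenario.seed, jac=scenario.jac_st
    )
    return UncertaintyReport(
        hpm_interval=hpm_iv, st_interval=st_iv, allowable_st=scenario.allowable_st
    )
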