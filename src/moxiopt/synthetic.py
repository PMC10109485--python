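"""Synthetic stand-ins that exercise every pipeline stage without the PDE.

Three generators:

* :func:`make_pseudo_simulator` — cheap closed-form response surfaces
  ``(t1, d, h, omega_c) -> (HPM, ST)`` with the empirically established sign
  structure (hotter stick / bigger stick / closer stick => warmer; wetter
  skin => deeper penetration) and physiologic output bands, with seeded
  coefficient jitter so different seeds give genuinely different surfaces;

* :func:`make_toy_problems` — tiny interval-optimization problems with
  closed-form optima, used to validate the nested solver against algebra;

* :func:`reference_fixtures` — the tabulated constants of the moxibustion model
  (tissue properties, parameter levels, moisture-dependent skin properties,
  design domain and interval radii, the 45.5 degC allowable) as one nested
  dict, consumable as a config fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .intervals import Box, Interval, interval_from_bounds
from .interval_opt import IntervalOptimizationProblem, ProblemVariable

__all__ = [
    "PseudoSimulator",
    "ToyProblem",
    "make_pseudo_simulator",
    "make_toy_problems",
    "reference_fixtures",
    "design_domain_box",
]

# operating-parameter design domain: t1 degC, d mm, h mm, omega_c percent
DESIGN_DOMAIN = {
    "t1": (600.0, 650.0),
    "d": (12.0, 18.0),
    "h": (25.0, 35.0),
    "omega_c": (29.0, 52.0),
}
INTERVAL_RADII = {"t1": 2.5, "d": 0.15, "h": 0.8, "omega_c": 1.1}
ALLOWABLE_ST = 45.5  # degC
ST_BAND = (38.0, 62.0)   # physiologic band over the design domain
HPM_BAND = (37.0, 45.0)


def design_domain_box() -> Box:
    """The operating-parameter design domain as a Box (t1, d, h, omega_c)."""
    return Box([interval_from_bounds(*DESIGN_DOMAIN[k]) for k in DESIGN_DOMAIN])


@dataclass
class PseudoSimulator:
    """Closed-form indicator surfaces with the bioheat model's sign structure.

    ``sim(t1, d, h, omega_c)`` (omega_c in percent) returns ``(HPM, ST)`` in
    degC.  With ``noise == 0`` the map is exactly deterministic; with noise,
    independent Gaussian perturbations of that amplitude are added per call.
    """

    st_coeffs: np.ndarray   # (const, t1, d, h, wc, t1*d) on unit-cube inputs
    hpm_coeffs: np.ndarray  # (const, t1, d, h, wc, t1*wc)
    noise: float = 0.0
    seed: int = 0
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._rng = np.random.default_rng(self.seed + 1)

    @staticmethod
    def _unit(t1, d, h, omega_c):
        return (
            (np.asarray(t1, dtype=float) - 600.0) / 50.0,
            (np.asarray(d, dtype=float) - 12.0) / 6.0,
            (np.asarray(h, dtype=float) - 25.0) / 10.0,
            (np.asarray(omega_c, dtype=float) - 29.0) / 23.0,
        )

    def st(self, t1, d, h, omega_c):
        ut, ud, uh, uw = self._unit(t1, d, h, omega_c)
        c = self.st_coeffs
        return c[0] + c[1] * ut + c[2] * ud + c[3] * uh + c[4] * uw + c[5] * ut * ud

    def hpm(self, t1, d, h, omega_c):
        ut, ud, uh, uw = self._unit(t1, d, h, omega_c)
        c = self.hpm_coeffs
        return c[0] + c[1] * ut + c[2] * ud + c[3] * uh + c[4] * uw + c[5] * ut * uw

    def __call__(self, t1, d, h, omega_c) -> tuple[float, float]:
        hpm = self.hpm(t1, d, h, omega_c)
        st = self.st(t1, d, h, omega_c)
        if self.noise > 0:
            hpm = hpm + self._rng.normal(0.0, self.noise)
            st = st + self._rng.normal(0.0, self.noise)
        return float(hpm), float(st)


def _monotone_and_banded(sim: PseudoSimulator, n_grid: int = 4) -> bool:
    """Finite-difference sign checks plus output-band containment on a grid."""
    axes = [np.linspace(lo, hi, n_grid) for lo, hi in DESIGN_DOMAIN.values()]
    T1, D, H, W = np.meshgrid(*axes, indexing="ij")
    st = sim.st(T1, D, H, W)
    hpm = sim.hpm(T1, D, H, W)
    if st.min() < ST_BAND[0] or st.max() > ST_BAND[1]:
        return False
    if hpm.min() < HPM_BAND[0] or hpm.max() > HPM_BAND[1]:
        return False
    for arr, signs in ((st, (+1, +1, -1, None)), (hpm, (+1, +1, -1, +1))):
        for ax, sgn in enumerate(signs):
            if sgn is None:
                continue
            diff = np.diff(arr, axis=ax) * sgn
            if not np.all(diff > 0):
                return False
    return True


def make_pseudo_simulator(seed: int = 0, noise: float = 0.0) -> PseudoSimulator:
    """Deterministic-per-seed pseudo-simulator with verified sign structure.

    Base coefficients are jittered by up to +/-8% per seed; a candidate whose
    jitter breaks the monotonicity or band invariants is rejected and
    resampled (verified by finite-difference sign checks on a grid).
    """
    if noise < 0:
        raise ValueError("noise amplitude must be >= 0")
    base_st = np.array([44.0, 7.0, 5.0, -5.0, -1.0, 1.5])
    base_hpm = np.array([38.8, 2.0, 1.6, -1.5, 1.2, 0.3])
    rng = np.random.default_rng(seed)
    for _ in range(100):
        sim = PseudoSimulator(
            st_coeffs=base_st * (1.0 + 0.08 * rng.uniform(-1, 1, size=6)),
            hpm_coeffs=base_hpm * (1.0 + 0.08 * rng.uniform(-1, 1, size=6)),
            noise=noise,
            seed=seed,
        )
        if _monotone_and_banded(sim):
            return sim
    raise RuntimeError("could not draw a monotone pseudo-simulator")  # pragma: no cover


# ---------------------------------------------------------------------------
# Toy interval-optimization problems with algebraic optima
# ---------------------------------------------------------------------------

@dataclass
class ToyProblem:
    """A small interval program whose optimum is known in closed form."""

    name: str
    problem: IntervalOptimizationProblem
    expected_midpoints: tuple[float, ...]
    expected_objective: float
    notes: str = ""

    def validate(self, atol: float = 1e-9) -> None:
        """Re-check that the stored optimum is feasible under its own
        constraint (self-validating fixture)."""
        from .interval_opt import reliability_constraint
        from .uq import response_interval

        p = self.problem
        box = p.candidate_box(self.expected_midpoints)
        S = response_interval(p.constraint, box, "grid-oracle", grid_points_per_dim=33)
        rel = reliability_constraint(S, p.allowable)
        if rel < p.reliability - 1e-6:
            raise AssertionError(
                f"{self.name}: stored optimum violates its constraint (rpdi={rel})"
            )


def _scalar(f: Callable[[np.ndarray], np.ndarray]) -> Callable:
    def g(x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        out = f(x)
        return float(out[0]) if out.shape == (1,) else out

    return g


def make_toy_problems() -> list[ToyProblem]:
    """The standard validation set: linear 1-D, quadratic 1-D with an
    interior constraint extremum, and a separable 2-D problem."""
    toys = []

    # linear: H = S = x, b = 10, radius 1, lambda 1  =>  m* = 9
    lin = IntervalOptimizationProblem(
        objective=_scalar(lambda X: X[:, 0]),
        constraint=_scalar(lambda X: X[:, 0]),
        variables=(ProblemVariable("x", 1.0, interval_from_bounds(0.0, 20.0)),),
        allowable=10.0,
        reliability=1.0,
    )
    toys.append(
        ToyProblem(
            "linear-1d", lin, (9.0,), 9.0,
            notes="pr = (10 - (m-1))/2 >= 1 iff m <= 9; S interval [8, 10]",
        )
    )

    # quadratic constraint S = (x-5)^2, objective H = x, b = 9  =>  m* = 7
    quad = IntervalOptimizationProblem(
        objective=_scalar(lambda X: X[:, 0]),
        constraint=_scalar(lambda X: (X[:, 0] - 5.0) ** 2),
        variables=(ProblemVariable("x", 1.0, interval_from_bounds(0.0, 10.0)),),
        allowable=9.0,
        reliability=1.0,
    )
    toys.append(
        ToyProblem(
            "quadratic-1d", quad, (7.0,), 7.0,
            notes="box [6,8]: S in [1,9], pr = (9-1)/8 = 1 exactly at m = 7",
        )
    )

    # separable 2-D: H = x + y, S = x + 2y, b = 12, radii (1, 0.5)  =>
    # S interval [m1 + 2 m2 - 2, m1 + 2 m2 + 2]; pr >= 1 iff m1 + 2 m2 <= 10
    sep = IntervalOptimizationProblem(
        objective=_scalar(lambda X: X[:, 0] + X[:, 1]),
        constraint=_scalar(lambda X: X[:, 0] + 2.0 * X[:, 1]),
        variables=(
            ProblemVariable("x", 1.0, interval_from_bounds(0.0, 8.0)),
            ProblemVariable("y", 0.5, interval_from_bounds(0.0, 8.0)),
        ),
        allowable=12.0,
        reliability=1.0,
    )
    # maximize m1 + m2 s.t. m1 + 2 m2 <= 10, m1 <= 7, m2 <= 7.5 => (7, 1.5)
    toys.append(
        ToyProblem(
            "separable-2d", sep, (7.0, 1.5), 8.5,
            notes="active constraints: m1 at its upper midpoint bound, m1 + 2 m2 = 10",
        )
    )
    return toys


# ---------------------------------------------------------------------------
# Tabulated model constants
# ---------------------------------------------------------------------------

def reference_fixtures() -> dict:
    """The moxibustion model's tabulated constants as one config fragment.

    Keys: ``tissue`` (fat/muscle constants), ``layer_thicknesses_mm``,
    ``parameter_levels`` (the three single-factor levels per parameter),
    ``skin_properties_by_moisture`` (the moisture-table oracle),
    ``design_domain`` / ``interval_radii`` (the uncertainty model) and
    ``allowable_st``.
    """
    return {
        "tissue": {
            "fat": {"heat_capacity": 2348.0, "density": 911.0, "conductivity": 0.21},
            "muscle": {"heat_capacity": 3421.0, "density": 1090.0, "conductivity": 0.49},
        },
        "layer_thicknesses_mm": {"skin": 2.2, "fat": 12.4, "muscle": 10.4},
        "parameter_levels": {
            "t1": [600.0, 625.0, 650.0],          # degC
            "moxa_radius": [6.0, 7.5, 9.0],       # mm (diameter d = 12, 15, 18)
            "h": [25.0, 30.0, 35.0],              # mm
            "omega_c": [29.0, 40.0, 52.0],        # percent
        },
        "skin_properties_by_moisture": {
            # percent: (heat capacity J/kg/K, density kg/m^3, conductivity W/m/K)
            29: {"heat_capacity": 2222.0, "density": 1213.0, "conductivity": 0.19},
            40: {"heat_capacity": 2502.0, "density": 1180.0, "conductivity": 0.25},
            52: {"heat_capacity": 2826.0, "density": 1144.0, "conductivity": 0.32},
        },
        "design_domain": {k: list(v) for k, v in DESIGN_DOMAIN.items()},
        "interval_radii": dict(INTERVAL_RADII),
        "allowable_st": ALLOWABLE_ST,
    }
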