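"""Nonlinear interval optimization of the moxibustion operating parameters.

The design variables are the *midpoints* of the controllable parameter
intervals (burning temperature t1, stick diameter d, stick-to-skin distance
h); each interval's radius is fixed by the operating tolerance, and the skin
moisture content omega_c enters as an uncontrolled uncertain interval.  The
objective is the thermal-penetration interval H (maximized through a scalar
view, by default its midpoint) subject to the reliability constraint that
the skin-surface-temperature interval S lies below the allowable b:

    pr(S <= b) = (b - S_lower) / (2 * S_radius) >= lambda

(the reliability-based possibility degree, RPDI).  lambda = 1 is exactly the
hard constraint S_upper <= b; lambda > 1 demands a safety margin; lambda < 1
tolerates partial overlap with the infeasible region.

The solve is nested: an outer real-coded genetic algorithm searches the
midpoint box, and every fitness evaluation computes the candidate's H and S
response intervals (inner bound evaluation) on the surrogate.  The returned
optimum is re-verified against the tensor-grid interval oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .intervals import Box, Interval, interval_from_center_radius, rpdi_degenerate
from .uq import ResponseFn, joint_grid_intervals, response_interval

__all__ = [
    "ProblemVariable",
    "IntervalOptimizationProblem",
    "GASettings",
    "OptimizationResult",
    "reliability_constraint",
    "transform_to_deterministic",
    "solve_nested",
    "rpdi_sweep",
]

Scalarization = Literal["midpoint", "lower", "upper"]


def reliability_constraint(S_interval: Interval, b: float) -> float:
    """RPDI of the constraint interval against the allowable value.

    ``(b - S.lower) / (2 * S.radius)``; the reliability requirement is
    satisfied iff this is >= lambda.  Identity: value >= 1 iff
    ``S.upper <= b``.  A zero-radius interval uses the degenerate limit
    convention (+/-inf, or 0.5 at equality).
    """
    return rpdi_degenerate(S_interval, b)


@dataclass(frozen=True)
class ProblemVariable:
    """One parameter of the interval program, in response-argument order.

    ``design=True``: the midpoint is optimized within
    ``[domain.lower + radius, domain.upper - radius]`` (the interval must
    stay inside the design domain).  ``design=False``: an uncontrolled
    uncertainty with a fixed midpoint.
    """

    name: str
    radius: float
    domain: Interval
    design: bool = True
    fixed_midpoint: float | None = None

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError(f"{self.name}: radius must be >= 0")
        if self.design:
            if self.domain.lower + self.radius > self.domain.upper - self.radius:
                raise ValueError(
                    f"{self.name}: radius {self.radius} exceeds the domain half-width; "
                    "no feasible midpoint exists"
                )
        elif self.fixed_midpoint is None:
            raise ValueError(f"{self.name}: non-design variables need fixed_midpoint")

    def interval(self, midpoint: float) -> Interval:
        return interval_from_center_radius(midpoint, self.radius)

    @property
    def midpoint_bounds(self) -> tuple[float, float]:
        return (self.domain.lower + self.radius, self.domain.upper - self.radius)


@dataclass
class IntervalOptimizationProblem:
    """The RPDI-constrained interval program over the operating parameters."""

    objective: ResponseFn                  # H, thermal penetration
    constraint: ResponseFn                 # S, skin surface temperature
    variables: tuple[ProblemVariable, ...]
    allowable: float = 45.5                # b, degC
    reliability: float = 1.0               # lambda
    scalarization: Scalarization = "midpoint"
    objective_jac: Callable[[np.ndarray], np.ndarray] | None = None
    constraint_jac: Callable[[np.ndarray], np.ndarray] | None = None
    # optional batched evaluator returning columns (H, S) for a point matrix;
    # lets the inner loop compute both intervals from one model call
    joint_response: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        if self.reliability <= 0:
            raise ValueError("reliability level lambda must be > 0")
        if not any(v.design for v in self.variables):
            raise ValueError("at least one design variable required")

    @property
    def design_variables(self) -> tuple[ProblemVariable, ...]:
        return tuple(v for v in self.variables if v.design)

    def candidate_box(self, midpoints: Sequence[float]) -> Box:
        """Uncertainty box of one candidate: design midpoints +/- their fixed
        radii, with the uncontrolled intervals interleaved in order."""
        midpoints = list(midpoints)
        if len(midpoints) != len(self.design_variables):
            raise ValueError("one midpoint per design variable required")
        ivs, k = [], 0
        for v in self.variables:
            if v.design:
                ivs.append(v.interval(midpoints[k]))
                k += 1
            else:
                ivs.append(v.interval(v.fixed_midpoint))
        return Box(ivs)

    def scalarize(self, H: Interval) -> float:
        if self.scalarization == "midpoint":
            return H.midpoint
        if self.scalarization == "lower":
            return H.lower
        if self.scalarization == "upper":
            return H.upper
        raise ValueError(f"unknown scalarization {self.scalarization!r}")


@dataclass(frozen=True)
class GASettings:
    """Outer-loop real-coded GA configuration."""

    population: int = 40
    generations: int = 100
    crossover_prob: float = 0.9
    crossover_eta: float = 15.0   # SBX distribution index
    mutation_eta: float = 20.0    # polynomial-mutation distribution index
    mutation_prob: float | None = None  # default 1/n_design
    tournament: int = 2
    penalty: float = 1.0e4        # per unit of reliability violation
    inner_grid: int = 9           # tensor-grid points/dim for fitness intervals


@dataclass
class OptimizationResult:
    """Solved midpoints plus grid-verified response intervals and reliability."""

    midpoints: dict[str, float]
    hpm_interval: Interval
    st_interval: Interval
    achieved_rpdi: float
    objective_value: float
    reliability: float
    feasible: bool
    generations: int
    evaluations: int
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "midpoints": self.midpoints,
            "HPM_interval": self.hpm_interval.to_json(),
            "ST_interval": self.st_interval.to_json(),
            "achieved_rpdi": self.achieved_rpdi,
            "objective_value": self.objective_value,
            "lambda": self.reliability,
            "feasible": self.feasible,
            "generations": self.generations,
            "evaluations": self.evaluations,
            "seed": self.seed,
        }


def _box_intervals(
    problem: IntervalOptimizationProblem, box: Box, grid: int
) -> tuple[Interval, Interval]:
    """Tensor-grid response intervals (H, S) of one candidate box."""
    if problem.joint_response is not None:
        H, S = joint_grid_intervals(problem.joint_response, box, grid)
        return H, S
    H = response_interval(problem.objective, box, "grid-oracle", grid_points_per_dim=grid)
    S = response_interval(problem.constraint, box, "grid-oracle", grid_points_per_dim=grid)
    return H, S


@dataclass
class DeterministicProgram:
    """The RPDI-transformed program: a penalized scalar objective over the
    midpoint box, solvable by any box-constrained global optimizer."""

    problem: IntervalOptimizationProblem
    inner_grid: int = 9
    penalty: float = 1.0e4
    evaluations: int = field(default=0, init=False)

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [v.midpoint_bounds for v in self.problem.design_variables]

    def evaluate(self, midpoints: Sequence[float]) -> dict:
        """Objective, reliability and intervals of one candidate."""
        self.evaluations += 1
        p = self.problem
        box = p.candidate_box(midpoints)
        H, S = _box_intervals(p, box, self.inner_grid)
        rel = reliability_constraint(S, p.allowable)
        return {
            "objective": p.scalarize(H),
            "reliability": rel,
            "violation": max(0.0, p.reliability - min(rel, p.reliability)),
            "H": H,
            "S": S,
        }

    def fitness(self, midpoints: Sequence[float]) -> float:
        """Penalized scalar fitness (to maximize)."""
        ev = self.evaluate(midpoints)
        return ev["objective"] - self.penalty * ev["violation"]


def transform_to_deterministic(
    problem: IntervalOptimizationProblem,
    inner_grid: int = 9,
    penalty: float = 1.0e4,
) -> DeterministicProgram:
    """RPDI transform of the interval program into a deterministic one.

    The interval constraint ``S(box) <= b`` becomes the scalar condition
    ``(b - S_lower)/(2 S_radius) >= lambda`` on every candidate's response
    interval; at lambda = 1 this is exactly the hard constraint
    ``S_upper <= b``.  Box containment is enforced through the midpoint
    bounds (domain shrunk by the fixed radii).
    """
    return DeterministicProgram(problem=problem, inner_grid=inner_grid, penalty=penalty)


# ---------------------------------------------------------------------------
# Real-coded GA (SBX crossover + polynomial mutation, tournament selection)
# ---------------------------------------------------------------------------

def _sbx(p1, p2, low, high, eta, rng):
    u = rng.random(len(p1))
    beta = np.where(u <= 0.5, (2 * u) ** (1 / (eta + 1)), (1 / (2 * (1 - u))) ** (1 / (eta + 1)))
    c1 = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
    c2 = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
    return np.clip(c1, low, high), np.clip(c2, low, high)


def _poly_mutation(x, low, high, eta, prob, rng):
    y = x.copy()
    for i in range(len(x)):
        if rng.random() < prob:
            u = rng.random()
            span = high[i] - low[i]
            if u < 0.5:
                delta = (2 * u) ** (1 / (eta + 1)) - 1
            else:
                delta = 1 - (2 * (1 - u)) ** (1 / (eta + 1))
            y[i] = np.clip(x[i] + delta * span, low[i], high[i])
    return y


def solve_nested(
    problem: IntervalOptimizationProblem,
    ga: GASettings | None = None,
    seed: int = 42,
) -> OptimizationResult:
    """Solve the interval program by the nested global/inner-bound scheme.

    Outer loop: real-coded GA (SBX crossover, polynomial mutation, binary
    tournament, one elite) over the design midpoints, with the reliability
    violation handled by a penalty.  Inner loop: each candidate's H and S
    response intervals evaluated on its uncertainty box.  The best candidate
    is re-verified with the 9-per-dimension tensor-grid oracle; the result
    is flagged infeasible (least-violating candidate reported) when no
    candidate satisfies the reliability level.
    """
    ga = ga or GASettings()
    prog = transform_to_deterministic(problem, inner_grid=ga.inner_grid, penalty=ga.penalty)
    low = np.array([b[0] for b in prog.bounds])
    high = np.array([b[1] for b in prog.bounds])
    nd = len(low)
    mut_prob = ga.mutation_prob if ga.mutation_prob is not None else 1.0 / nd
    rng = np.random.default_rng(seed)

    pop = rng.uniform(low, high, size=(ga.population, nd))
    pop[0] = 0.5 * (low + high)  # deterministic anchor at the box centre
    fit = np.array([prog.fitness(ind) for ind in pop])

    for _ in range(ga.generations):
        order = np.argsort(fit)[::-1]
        elite = pop[order[0]].copy()
        children = [elite]
        while len(children) < ga.population:
            idx = rng.integers(0, ga.population, size=(2, ga.tournament))
            p1 = pop[idx[0][np.argmax(fit[idx[0]])]]
            p2 = pop[idx[1][np.argmax(fit[idx[1]])]]
            if rng.random() < ga.crossover_prob:
                c1, c2 = _sbx(p1, p2, low, high, ga.crossover_eta, rng)
            else:
                c1, c2 = p1.copy(), p2.copy()
            for c in (c1, c2):
                if len(children) < ga.population:
                    children.append(_poly_mutation(c, low, high, ga.mutation_eta, mut_prob, rng))
        pop = np.asarray(children)
        fit = np.array([prog.fitness(ind) for ind in pop])

    best = pop[int(np.argmax(fit))]

    # authoritative re-verification of the winner with the grid oracle
    box = problem.candidate_box(best)
    H, S = _box_intervals(problem, box, 9)
    rel = reliability_constraint(S, problem.allowable)
    feasible = rel >= problem.reliability - 1e-9

    names = [v.name for v in problem.design_variables]
    return OptimizationResult(
        midpoints={n: float(m) for n, m in zip(names, best)},
        hpm_interval=H,
        st_interval=S,
        achieved_rpdi=float(rel),
        objective_value=float(problem.scalarize(H)),
        reliability=problem.reliability,
        feasible=bool(feasible),
        generations=ga.generations,
        evaluations=prog.evaluations,
        seed=seed,
    )


def rpdi_sweep(
    problem: IntervalOptimizationProblem,
    lambdas: Sequence[float],
    ga: GASettings | None = None,
    seed: int = 42,
) -> tuple[pd.DataFrame, list[OptimizationResult]]:
    """One nested solve per reliability level; returns the comparison table
    (lambda, ST/HPM interval bounds, objective, achieved RPDI, feasibility)
    plus the full results.  Per-level seeds derive deterministically from
    the base seed."""
    lambdas = list(lambdas)
    if not lambdas:
        raise ValueError("need at least one reliability level")
    results = []
    for i, lam in enumerate(lambdas):
        sub_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31)
        prob_i = replace_reliability(problem, lam)
        results.append(solve_nested(prob_i, ga=ga, seed=sub_seed))
    rows = [
        {
            "lambda": lam,
            "ST_lo": r.st_interval.lower,
            "ST_hi": r.st_interval.upper,
            "HPM_lo": r.hpm_interval.lower,
            "HPM_hi": r.hpm_interval.upper,
            "objective": r.objective_value,
            "achieved_rpdi": r.achieved_rpdi,
            "feasible": r.feasible,
        }
        for lam, r in zip(lambdas, results)
    ]
    return pd.DataFrame(rows), results


def replace_reliability(
    problem: IntervalOptimizationProblem, lam: float
) -> IntervalOptimizationProblem:
    """Copy of the problem at a different reliability level."""
    return IntervalOptimizationProblem(
        objective=problem.objective,
        constraint=problem.constraint,
        variables=problem.variables,
        allowable=problem.allowable,
        reliability=lam,
        scalarization=problem.scalarization,
        objective_jac=problem.objective_jac,
        constraint_jac=problem.constraint_jac,
        joint_response=problem.joint_response,
    )
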