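"""Closed real intervals and the reliability-based possibility degree (RPDI).

An uncertain quantity is carried as a closed interval ``[lower, upper]``,
equivalently midpoint ± radius, with no distributional assumption.  The RPDI
``pr(A <= B) = (B.upper - A.lower) / (2*A.radius + 2*B.radius)`` measures how
reliably interval ``A`` lies below interval ``B``; values >= 1 mean certain
satisfaction, values <= 0 certain violation, and intermediate values grade
the overlap.  These two primitives underpin every downstream stage: interval
uncertainty propagation, the reliability constraint of the optimizer and the
reporting of response ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

__all__ = [
    "Interval",
    "Box",
    "interval_from_bounds",
    "interval_from_center_radius",
    "rpdi",
    "rpdi_degenerate",
]

#: Absolute tolerance for closed-interval membership tests (parameter units).
MEMBERSHIP_ATOL = 1e-9


@dataclass(frozen=True)
class Interval:
    """A closed real interval ``[lower, upper]`` with ``lower <= upper``."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ValueError(f"interval bounds must be finite, got [{self.lower}, {self.upper}]")
        if self.lower > self.upper:
            raise ValueError(
                f"reversed interval bounds: lower={self.lower} > upper={self.upper}; "
                "pass (lower, upper) in increasing order"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def radius(self) -> float:
        return 0.5 * (self.upper - self.lower)

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x: float, atol: float = MEMBERSHIP_ATOL) -> bool:
        """Closed membership test with an absolute tolerance."""
        return self.lower - atol <= x <= self.upper + atol

    def to_json(self) -> list[float]:
        """Serialize as the two-element array used in JSON results."""
        return [self.lower, self.upper]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Interval({self.lower:g}, {self.upper:g})"


def interval_from_bounds(lower: float, upper: float) -> Interval:
    """Build an interval from its lower/upper bounds (rejects reversed bounds)."""
    return Interval(float(lower), float(upper))


def interval_from_center_radius(center: float, radius: float) -> Interval:
    """Build an interval from midpoint and radius; the radius must be >= 0."""
    if radius < 0:
        raise ValueError(f"interval radius must be non-negative, got {radius}")
    center = float(center)
    radius = float(radius)
    return Interval(center - radius, center + radius)


@dataclass(frozen=True)
class Box:
    """An axis-aligned box: one :class:`Interval` per parameter dimension."""

    intervals: tuple[Interval, ...]

    def __init__(self, intervals: Sequence[Interval]):
        intervals = tuple(intervals)
        if len(intervals) < 1:
            raise ValueError("a Box needs at least one dimension")
        object.__setattr__(self, "intervals", intervals)

    @property
    def dim(self) -> int:
        return len(self.intervals)

    @property
    def lower(self) -> tuple[float, ...]:
        return tuple(iv.lower for iv in self.intervals)

    @property
    def upper(self) -> tuple[float, ...]:
        return tuple(iv.upper for iv in self.intervals)

    @property
    def midpoint(self) -> tuple[float, ...]:
        return tuple(iv.midpoint for iv in self.intervals)

    def contains(self, point: Sequence[float], atol: float = MEMBERSHIP_ATOL) -> bool:
        if len(point) != self.dim:
            raise ValueError(f"point has {len(point)} coordinates, box has {self.dim}")
        return all(iv.contains(x, atol) for iv, x in zip(self.intervals, point))

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return self.dim


def rpdi(A: Interval, B: Interval) -> float:
    """Reliability-based possibility degree that interval ``A`` lies below ``B``.

    ``pr(A <= B) = (B.upper - A.lower) / (2*A.radius + 2*B.radius)``.

    The degree is unbounded: >= 1 whenever ``A.upper <= B.lower`` (certain),
    <= 0 whenever ``B.upper <= A.lower`` (impossible), and complementary in
    its arguments, ``rpdi(A, B) + rpdi(B, A) == 1``.

    When both intervals are degenerate (zero radius) the 0/0 form is resolved
    by the limit convention: +inf if ``A < B``, -inf if ``A > B``, 0.5 if
    equal.  This keeps optimizer edge cases from aborting runs.
    """
    denom = 2.0 * A.radius + 2.0 * B.radius
    if denom == 0.0:
        if A.lower < B.upper:
            return math.inf
        if A.lower > B.upper:
            return -math.inf
        return 0.5
    return (B.upper - A.lower) / denom


def rpdi_degenerate(A: Interval, b: float) -> float:
    """RPDI of interval ``A`` against a crisp number ``b``.

    ``pr(A <= b) = (b - A.lower) / (2*A.radius)`` — the limit of :func:`rpdi`
    as the second interval degenerates to a point.  For a degenerate ``A``
    the same limit convention as :func:`rpdi` applies.
    """
    if A.radius == 0.0:
        if A.lower < b:
            return math.inf
        if A.lower > b:
            return -math.inf
        return 0.5
    return (b - A.lower) / (2.0 * A.radius)
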