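"""Design of experiments and the RBF-network surrogate.

The bioheat simulator is too expensive to call inside a nested interval
optimization, so the four operating parameters (t1, d, h, omega_c) are
sampled with an optimal (maximin) Latin hypercube, the simulator is run at
the sample points, and a Gaussian radial-basis-function network is fitted to
each indicator (HPM, ST).  The usual error metrics (relative error range,
SSE/SST, R^2, RMSE) quantify surrogate accuracy on training or held-out
points.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import qmc

from .intervals import Box

__all__ = [
    "DesignTable",
    "SurrogateModel",
    "FitMetrics",
    "latin_hypercube",
    "evaluate_responses",
    "train_rbnn",
    "fit_metrics",
]

RESPONSE_NAMES = ("HPM", "ST")


@dataclass
class DesignTable:
    """An n x dim sample of the operating-parameter domain (Latin per column)."""

    names: tuple[str, ...]
    values: np.ndarray  # (n, dim)
    domain: Box

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values must be (n_rows, n_parameters)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.names))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def is_latin(self) -> bool:
        """Exact stratum-occupancy check: one point per equal-width stratum
        per dimension."""
        n = self.n
        for j, iv in enumerate(self.domain):
            u = (self.values[:, j] - iv.lower) / iv.width
            strata = np.floor(np.clip(u, 0, 1 - 1e-12) * n).astype(int)
            if len(np.unique(strata)) != n:
                return False
        return True


def latin_hypercube(
    n: int,
    domain: Box,
    seed: int,
    names: Sequence[str] | None = None,
    optimize: bool = True,
    candidates: int = 100,
) -> DesignTable:
    """Latin hypercube design over ``domain``, optionally maximin-optimized.

    When ``optimize`` is set the design is the best of ``candidates`` random
    Latin hypercubes under the maximin-distance criterion (largest minimum
    pairwise distance in the unit cube).  Identical arguments give identical
    tables.
    """
    if n < 2:
        raise ValueError(f"need at least 2 design points, got {n}")
    dim = domain.dim
    if names is None:
        names = tuple(f"x{j}" for j in range(dim))
    if len(names) != dim:
        raise ValueError("one name per domain dimension required")

    sampler = qmc.LatinHypercube(d=dim, seed=np.random.default_rng(seed))
    best_unit, best_score = None, -math.inf
    rounds = candidates if optimize else 1
    for _ in range(rounds):
        unit = sampler.random(n)
        score = pdist(unit).min()
        if score > best_score:
            best_unit, best_score = unit, score
    lower = np.asarray(domain.lower)
    upper = np.asarray(domain.upper)
    values = qmc.scale(best_unit, lower, upper)
    return DesignTable(names=tuple(names), values=values, domain=domain)


def evaluate_responses(
    design: DesignTable,
    simulator: Callable[..., tuple[float, float]],
    max_failure_fraction: float = 0.1,
) -> pd.DataFrame:
    """Run ``simulator(*row) -> (HPM, ST)`` for every design row.

    Failed rows are kept (as NaN, with the error message in a ``status``
    column) rather than silently dropped; more than ``max_failure_fraction``
    failures aborts.
    """
    records = []
    failures = 0
    for row in design.values:
        try:
            hpm, st = simulator(*row)
            if not (np.isfinite(hpm) and np.isfinite(st)):
                raise ValueError(f"non-finite response ({hpm}, {st})")
            records.append({"HPM": hpm, "ST": st, "status": "ok"})
        except Exception as exc:  # noqa: BLE001 - per-row fault isolation
            failures += 1
            records.append({"HPM": np.nan, "ST": np.nan, "status": f"failed: {exc}"})
    if failures > max_failure_fraction * design.n:
        raise RuntimeError(
            f"{failures}/{design.n} simulator evaluations failed "
            f"(> {max_failure_fraction:.0%} allowed)"
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# RBF network
# ---------------------------------------------------------------------------

@dataclass
class SurrogateModel:
    """Gaussian RBF network mapping scaled inputs to one or more responses.

    Inputs are affinely mapped to the unit cube; kernel centres sit at the
    (scaled) training points; one weight vector per response column.  With
    zero regularization the network interpolates its training data exactly.
    """

    names: tuple[str, ...]
    response_names: tuple[str, ...]
    scale_low: np.ndarray
    scale_high: np.ndarray
    centers: np.ndarray        # (m, dim), scaled
    width: float
    weights: np.ndarray        # (m, n_responses)
    poly: np.ndarray           # (dim + 1, n_responses) affine tail [const; linear]
    regularization: float = 0.0
    extrapolation_margin: float = 0.10
    _warned: bool = field(default=False, repr=False, compare=False)

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scale_low) / (self.scale_high - self.scale_low)

    def _kernel(self, U: np.ndarray) -> np.ndarray:
        d2 = ((U[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-d2 / (2.0 * self.width**2))

    def predict(self, X: np.ndarray | Sequence[float]) -> np.ndarray:
        """Predict responses at one point (dim,) or a batch (n, dim)."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        U = self._scale(X)
        if not self._warned and (
            np.any(U < -self.extrapolation_margin) or np.any(U > 1 + self.extrapolation_margin)
        ):
            warnings.warn(
                "prediction point lies well outside the training domain; "
                "RBF extrapolation is unreliable",
                stacklevel=2,
            )
            self._warned = True
        P = np.hstack([np.ones((len(U), 1)), U])
        Y = self._kernel(U) @ self.weights + P @ self.poly
        return Y[0] if single else Y

    def response(self, name: str) -> Callable[[np.ndarray], float | np.ndarray]:
        """A scalar response function ``f(point) -> value`` for one output."""
        j = self.response_names.index(name)

        def f(X):
            Y = self.predict(np.asarray(X, dtype=float))
            return float(Y[j]) if Y.ndim == 1 else Y[:, j]

        return f

    def gradient(self, x: Sequence[float], response: str) -> np.ndarray:
        """Analytic gradient of one response w.r.t. the *unscaled* inputs."""
        j = self.response_names.index(response)
        u = self._scale(np.asarray(x, dtype=float))[None, :]
        diff = u[:, None, :] - self.centers[None, :, :]          # (1, m, dim)
        phi = np.exp(-(diff**2).sum(axis=2) / (2.0 * self.width**2))  # (1, m)
        dphi_du = -phi[:, :, None] * diff / self.width**2        # (1, m, dim)
        grad_u = np.einsum("nmd,m->nd", dphi_du, self.weights[:, j])[0] + self.poly[1:, j]
        return grad_u / (self.scale_high - self.scale_low)

    # -- persistence -------------------------------------------------------

    def to_json(self) -> dict:
        return {
            "names": list(self.names),
            "response_names": list(self.response_names),
            "scale_low": self.scale_low.tolist(),
            "scale_high": self.scale_high.tolist(),
            "centers": self.centers.tolist(),
            "width": self.width,
            "weights": self.weights.tolist(),
            "poly": self.poly.tolist(),
            "regularization": self.regularization,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh)

    @classmethod
    def from_json(cls, payload: dict) -> "SurrogateModel":
        return cls(
            names=tuple(payload["names"]),
            response_names=tuple(payload["response_names"]),
            scale_low=np.asarray(payload["scale_low"], dtype=float),
            scale_high=np.asarray(payload["scale_high"], dtype=float),
            centers=np.asarray(payload["centers"], dtype=float),
            width=float(payload["width"]),
            weights=np.asarray(payload["weights"], dtype=float),
            poly=np.asarray(payload["poly"], dtype=float),
            regularization=float(payload.get("regularization", 0.0)),
        )

    @classmethod
    def load(cls, path) -> "SurrogateModel":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


def train_rbnn(
    design: DesignTable,
    responses: pd.DataFrame,
    width: float | None = None,
    regularization: float = 0.0,
) -> SurrogateModel:
    """Fit a Gaussian RBF network (with an affine tail) to the tables.

    The network is ``f(u) = sum_i w_i exp(-|u - u_i|^2 / 2 width^2) + c0 +
    c.u`` on unit-cube-scaled inputs; the affine tail keeps the dominant
    linear trends of the indicators out of the kernel weights, which makes
    the interpolant behave near the domain boundary.  ``width=None`` uses
    the median pairwise distance of the scaled design points.  The
    augmented (saddle-point) system is solved per response column; a singular
    (numerically unsolvable) system triggers automatic ridge regularization
    with a warning.  Rows whose response is NaN (failed simulations) are
    dropped before fitting.
    """
    resp_names = tuple(c for c in RESPONSE_NAMES if c in responses.columns) or tuple(
        c for c in responses.columns if c != "status"
    )
    Y = responses.loc[:, list(resp_names)].to_numpy(dtype=float)
    X = design.values
    if len(Y) != len(X):
        raise ValueError("design and response tables must have the same row count")
    ok = np.all(np.isfinite(Y), axis=1)
    X, Y = X[ok], Y[ok]
    if len(X) < design.domain.dim + 1:
        raise ValueError("need at least dim+1 usable training rows")

    low = np.asarray(design.domain.lower, dtype=float)
    high = np.asarray(design.domain.upper, dtype=float)
    U = (X - low) / (high - low)
    if regularization == 0.0 and pdist(U).min() < 1e-12:
        raise ValueError("duplicate design points require regularization > 0")
    if width is None:
        width = float(np.median(pdist(U)))

    m = len(U)
    dim = U.shape[1]
    d2 = ((U[:, None, :] - U[None, :, :]) ** 2).sum(axis=2)
    Phi = np.exp(-d2 / (2.0 * width**2))
    # augmented (saddle-point) system: kernel weights plus an affine tail,
    # with the weights orthogonal to the polynomial space
    P = np.hstack([np.ones((m, 1)), U])
    q = dim + 1

    def _assemble(reg: float) -> np.ndarray:
        A = np.zeros((m + q, m + q))
        A[:m, :m] = Phi + reg * np.eye(m)
        A[:m, m:] = P
        A[m:, :m] = P.T
        return A

    rhs = np.vstack([Y, np.zeros((q, Y.shape[1]))])
    try:
        A = _assemble(regularization)
        cond = np.linalg.cond(A)
        if cond > 1e14:
            raise np.linalg.LinAlgError(f"ill-conditioned kernel matrix (cond={cond:.2e})")
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        bumped = max(regularization, 1e-10)
        warnings.warn(
            f"kernel system near-singular ({exc}); refitting with ridge {bumped:g}",
            stacklevel=2,
        )
        regularization = bumped
        sol = np.linalg.solve(_assemble(bumped), rhs)
    W, C = sol[:m], sol[m:]

    return SurrogateModel(
        names=design.names,
        response_names=resp_names,
        scale_low=low,
        scale_high=high,
        centers=U,
        width=width,
        weights=W,
        poly=C,
        regularization=regularization,
    )


# ---------------------------------------------------------------------------
# Error metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitMetrics:
    """Surrogate accuracy summary: RE range (%), SSE, SST, R^2, RMSE."""

    re_min: float
    re_max: float
    sse: float
    sst: float
    r2: float | None
    rmse: float

    def to_json_dict(self) -> dict:
        return {
            "RE_percent": [self.re_min, self.re_max],
            "SSE": self.sse,
            "SST": self.sst,
            "R2": self.r2,
            "RMSE": self.rmse,
        }


def fit_metrics(y: np.ndarray, y_hat: np.ndarray) -> FitMetrics:
    """Error metrics between reference responses ``y`` and predictions ``y_hat``.

    Per-sample relative error ``(y_i - y_hat_i)/y_i`` (reported as a
    min..max percent range; zero-valued references are skipped with a
    warning), ``SSE = sum (y - y_hat)^2``, ``SST = sum (y - mean(y))^2``,
    ``R^2 = 1 - SSE/SST`` (None when SST is zero) and
    ``RMSE = sqrt(SSE/k)``.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1:
        raise ValueError("y and y_hat must be equal-length 1-D arrays")
    k = len(y)
    if k < 2:
        raise ValueError("need at least 2 samples")

    nz = y != 0
    if not np.all(nz):
        warnings.warn("zero reference values skipped in relative error", stacklevel=2)
    re = (y[nz] - y_hat[nz]) / y[nz] * 100.0
    sse = float(np.sum((y - y_hat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = None if sst == 0 else 1.0 - sse / sst
    if sst == 0:
        warnings.warn("constant reference responses: R^2 undefined", stacklevel=2)
    return FitMetrics(
        re_min=float(re.min()) if re.size else 0.0,
        re_max=float(re.max()) if re.size else 0.0,
        sse=sse,
        sst=sst,
        r2=r2,
        rmse=math.sqrt(sse / k),
    )
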