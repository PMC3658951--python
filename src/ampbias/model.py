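"""Endpoint-shortening model of two-cycle linear RNA amplification.

A transcript occupies ``[0, L]`` with 0 the 3' end. During two-cycle IVT
labeling the surviving fragment ``[A, B]`` shrinks three times:

1. first-cycle degradation:  ``A1 ~ U[0, a]``, ``B1 ~ U[L - b, L]``;
2. random-primer truncation at the start of the second cycle, which only
   shortens the 5' side: ``A2 = A1``, ``B2 ~ U[A1, B1]``;
3. second-cycle degradation: ``A3 ~ U[A2, A2 + a]``, ``B3 ~ U[B2 - b, B2]``.

``a`` and ``b`` are the maximal degradation extents (bp) from the 3' and 5'
ends; they are shared by both cycles.  The retaining rate ``p_i(z)`` is the
probability that the nucleotide at distance ``z`` from the 3' end is still
covered by the fragment after stage ``i`` of interest (cycle 1 uses
``[A1, B1]``, cycle 2 the final ``[A3, B3]``).  Positions are treated as
continuous, which is accurate for transcripts longer than a few hundred bp.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "DegradationParams",
    "EndpointTrajectories",
    "RetainingRateCurve",
    "p1_retaining_rate",
    "joint_cdf_cycle1",
    "sample_trajectories",
    "p2_retaining_rate",
    "retaining_rate_curve",
]


class ParameterError(ValueError):
    """Invalid degradation-model parameters."""


class DomainError(ValueError):
    """Position argument outside the transcript ``[0, L]``."""


@dataclass(frozen=True)
class DegradationParams:
    """Transcript length and per-cycle degradation limits, all in bp.

    Parameters
    ----------
    L : float
        Transcript length; the 3' end is position 0, the 5' end is ``L``.
    a : float
        Maximal degradation extent from the 3' end per cycle.
    b : float
        Maximal degradation extent from the 5' end per cycle.
    """

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.L > 0 and np.isfinite(self.L)):
            raise ParameterError(f"transcript length L must be positive, got {self.L}")
        if not (self.a > 0 and np.isfinite(self.a)):
            raise ParameterError(f"3' degradation limit a must be positive, got {self.a}")
        if not (self.b > 0 and np.isfinite(self.b)):
            raise ParameterError(f"5' degradation limit b must be positive, got {self.b}")
        if self.a + self.b >= self.L:
            warnings.warn(
                f"a + b = {self.a + self.b} >= L = {self.L}: transcript shorter than "
                "the combined degradation limits; the fully-retained plateau vanishes "
                "and some fragments degrade completely",
                stacklevel=3,
            )

    @property
    def standard_regime(self) -> bool:
        """True when ``a + b < L`` (the piecewise plateau exists)."""
        return self.a + self.b < self.L


@dataclass
class EndpointTrajectories:
    """Vectorized sample of fragment endpoints after each shortening.

    ``A2 == A1`` by construction.  Fully degraded fragments (``B3 < A3``)
    are retained: they simply cover no position.
    """

    A1: np.ndarray
    B1: np.ndarray
    A2: np.ndarray
    B2: np.ndarray
    A3: np.ndarray
    B3: np.ndarray
    params: DegradationParams

    def __len__(self) -> int:
        return self.A1.size

    def covers(self, z: float) -> np.ndarray:
        """Boolean mask of trajectories whose final fragment covers ``z``."""
        return (self.A3 <= z) & (z <= self.B3)


def _check_positions(z, L: float) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > L):
        raise DomainError(f"positions must lie in [0, {L}]")
    return z


def p1_retaining_rate(z, params: DegradationParams):
    """First-cycle retaining rate ``p1(z) = P(A1 <= z <= B1)``.

    With independent uniform endpoints this is the product
    ``P(A1 <= z) * P(B1 >= z)``, i.e. the piecewise-linear ramp

    ``z/a`` on ``[0, a]``, ``1`` on ``(a, L-b)``, ``(L-z)/b`` on ``[L-b, L]``

    when ``a + b < L``.  For short transcripts (``a + b >= L``) the plateau
    vanishes and the same product form applies with overlapping ramps.

    Accepts scalar or array ``z``; returns the same shape.
    """
    zz = _check_positions(z, params.L)
    p = np.clip(zz / params.a, 0.0, 1.0) * np.clip((params.L - zz) / params.b, 0.0, 1.0)
    return p if np.ndim(z) else float(p)


def joint_cdf_cycle1(x, y, params: DegradationParams):
    """Joint CDF ``F1(x, y) = P(A1 <= x, B1 <= y)`` of the cycle-1 endpoints.

    Equals ``x (y + b - L) / (a b)`` on the support rectangle
    ``[0, a] x [L-b, L]``; arguments outside it are clamped per CDF
    semantics (below the support contributes 0, above contributes the full
    marginal).
    """
    a, b, L = params.a, params.b, params.L
    xc = np.clip(np.asarray(x, dtype=float), 0.0, a)
    yc = np.clip(np.asarray(y, dtype=float), L - b, L)
    f = xc * (yc + b - L) / (a * b)
    return f if (np.ndim(x) or np.ndim(y)) else float(f)


def sample_trajectories(
    params: DegradationParams, n: int, seed: int
) -> EndpointTrajectories:
    """Draw ``n`` endpoint trajectories of the three-stage process.

    Deterministic given ``seed``.  When ``a + b >= L`` some first-cycle
    fragments are empty (``B1 < A1``); for those the random-primer stage has
    nothing to prime and ``B2`` is set to ``A1``, so the trajectory covers no
    position downstream.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    a, b, L = params.a, params.b, params.L
    rng = np.random.default_rng(seed)
    A1 = rng.uniform(0.0, a, n)
    B1 = rng.uniform(L - b, L, n)
    hi = np.maximum(A1, B1)  # empty fragments collapse to a point
    B2 = rng.uniform(A1, hi)
    A3 = A1 + rng.uniform(0.0, a, n)
    B3 = B2 - rng.uniform(0.0, b, n)
    return EndpointTrajectories(A1=A1, B1=B1, A2=A1.copy(), B2=B2, A3=A3, B3=B3, params=params)


# --- second-cycle retaining rate -------------------------------------------
#
# p2(z) = P(A3 <= z <= B3).  Conditional on (A1, B2) the two final endpoints
# are independent uniforms, so
#
#   p2(z) = E[ clip((z - A1)/a, 0, 1) * clip((B2 - z)/b, 0, 1) ]
#
# The expectation over B2 ~ U[A1, B1] has a closed-form antiderivative;
# what remains is a 2-D integral over the independent uniforms (A1, B1),
# evaluated by the trapezoid rule.


def _ramp_antideriv(t: np.ndarray, z: np.ndarray, b: float) -> np.ndarray:
    """Antiderivative of ``y -> clip((y - z)/b, 0, 1)`` evaluated at ``t``."""
    u = np.clip(t - z, 0.0, b)
    return u * u / (2.0 * b) + np.maximum(t - z - b, 0.0)


def _p2_quadrature(z: np.ndarray, params: DegradationParams, step: float) -> np.ndarray:
    a, b, L = params.a, params.b, params.L
    nx = max(int(round(a / step)), 2) + 1
    ny = max(int(round(b / step)), 2) + 1
    x = np.linspace(0.0, a, nx)  # A1 grid
    y1 = np.linspace(L - b, L, ny)  # B1 grid

    out = np.empty(z.size)
    # chunk over z to bound the (nz, nx, ny) intermediate
    max_cells = 20_000_000
    chunk = max(1, max_cells // (nx * ny))
    for lo in range(0, z.size, chunk):
        zc = z[lo : lo + chunk][:, None, None]
        xg = x[None, :, None]
        yg = y1[None, None, :]
        span = yg - xg
        with np.errstate(divide="ignore", invalid="ignore"):
            g = (_ramp_antideriv(yg, zc, b) - _ramp_antideriv(xg, zc, b)) / span
        # empty first-cycle fragments (only when a + b >= L) cover nothing
        g = np.where(span > 0, g, 0.0)
        t1 = np.clip((zc - xg) / a, 0.0, 1.0)
        inner = np.trapezoid(t1 * g, y1, axis=2)
        out[lo : lo + chunk] = np.trapezoid(inner, x, axis=1) / (a * b)
    return np.clip(out, 0.0, 1.0)


def p2_retaining_rate(
    z,
    params: DegradationParams,
    method: Literal["quadrature", "monte-carlo"] = "quadrature",
    *,
    step: float | None = None,
    n_samples: int = 10**6,
    seed: int = 0,
    check_convergence: bool = False,
    convergence_tol: float = 1e-3,
):
    """Second-cycle retaining rate ``p2(z) = P(A3 <= z <= B3)``.

    Parameters
    ----------
    z : scalar or array of positions in ``[0, L]``.
    method : ``"quadrature"`` integrates the conditional coverage kernel over
        the cycle-1 endpoints (A1, B1) by the trapezoid rule, with the inner
        average over the random-primer endpoint B2 done in closed form;
        deterministic.  ``"monte-carlo"`` is the empirical coverage fraction
        of ``n_samples`` simulated trajectories.
    step : quadrature grid step in bp; default ``max(1, L/2000)``.
    check_convergence : re-evaluate the quadrature at half the step and warn
        if any value moves by more than ``convergence_tol``.
    """
    zz = np.atleast_1d(_check_positions(z, params.L))
    if method == "quadrature":
        h = step if step is not None else max(1.0, params.L / 2000.0)
        p = _p2_quadrature(zz, params, h)
        if check_convergence:
            p_half = _p2_quadrature(zz, params, h / 2.0)
            err = float(np.max(np.abs(p - p_half)))
            if err > convergence_tol:
                warnings.warn(
                    f"p2 quadrature not converged: halving the step moved values "
                    f"by up to {err:.2e} (> {convergence_tol:.0e})",
                    stacklevel=2,
                )
    elif method == "monte-carlo":
        traj = sample_trajectories(params, n_samples, seed)
        p = np.array([traj.covers(zi).mean() for zi in zz])
    else:
        raise ValueError(f"unknown method {method!r}")
    return p if np.ndim(z) else float(p[0])


@dataclass
class RetainingRateCurve:
    """Tabulated retaining rate on an even position grid over ``[0, L]``.

    Evaluation between grid points is linear interpolation (:meth:`__call__`).
    """

    cycle: Literal[1, 2]
    grid: np.ndarray
    values: np.ndarray
    params: DegradationParams
    method: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have equal length")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("retaining rates must lie in [0, 1]")

    def __call__(self, z):
        zz = _check_positions(z, self.params.L)
        p = np.interp(zz, self.grid, self.values)
        return p if np.ndim(z) else float(p)

    def to_tsv(self, path) -> None:
        hdr = (
            f"# retaining-rate curve: cycle={self.cycle} L={self.params.L} "
            f"a={self.params.a} b={self.params.b} method={self.method}"
        )
        for k, v in sorted(self.meta.items()):
            hdr += f" {k}={v}"
        body = "\n".join(f"{z:.6g}\t{p:.10g}" for z, p in zip(self.grid, self.values))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(hdr + "\nz\tp\n" + body + "\n")

    @classmethod
    def from_tsv(cls, path) -> "RetainingRateCurve":
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        meta: dict = {}
        cycle, method = 2, "unknown"
        L = a = b = None
        rows = []
        for line in io.StringIO(text):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.lstrip("# ").split():
                    if "=" not in tok:
                        continue
                    k, v = tok.split("=", 1)
                    if k == "cycle":
                        cycle = int(v)
                    elif k == "L":
                        L = float(v)
                    elif k == "a":
                        a = float(v)
                    elif k == "b":
                        b = float(v)
                    elif k == "method":
                        method = v
                    else:
                        meta[k] = v
                continue
            if line.startswith("z\t"):
                continue
            zs, ps = line.split("\t")
            rows.append((float(zs), float(ps)))
        if L is None or a is None or b is None:
            raise ValueError(f"{path}: missing params in curve header comment")
        grid, values = map(np.array, zip(*rows))
        return cls(
            cycle=cycle,  # type: ignore[arg-type]
            grid=grid,
            values=values,
            params=DegradationParams(L=L, a=a, b=b),
            method=method,
            meta=meta,
        )


def retaining_rate_curve(
    params: DegradationParams,
    cycle: Literal[1, 2],
    grid_step: float = 2.0,
    method: Literal["closed-form", "quadrature", "monte-carlo"] | None = None,
    *,
    quad_step: float | None = None,
    n_samples: int = 10**6,
    seed: int = 0,
) -> RetainingRateCurve:
    """Tabulate ``p1`` or ``p2`` on an even grid including both endpoints 0, L.

    Cycle 1 uses the closed form; cycle 2 defaults to quadrature (set
    ``method="monte-carlo"`` for the simulation estimate).  Deterministic
    given ``(params, cycle, grid_step, method, quad_step/n_samples, seed)``.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    npts = max(int(round(params.L / grid_step)), 1) + 1
    grid = np.linspace(0.0, params.L, npts)
    if cycle == 1:
        values = p1_retaining_rate(grid, params)
        used = "closed-form"
        meta = {"grid_step": grid_step}
    elif cycle == 2:
        used = method or "quadrature"
        if used == "quadrature":
            values = p2_retaining_rate(grid, params, "quadrature", step=quad_step)
            meta = {"grid_step": grid_step, "quad_step": quad_step or max(1.0, params.L / 2000.0)}
        elif used == "monte-carlo":
            values = p2_retaining_rate(
                grid, params, "monte-carlo", n_samples=n_samples, seed=seed
            )
            meta = {"grid_step": grid_step, "n_samples": n_samples, "seed": seed}
        else:
            raise ValueError(f"unknown method {used!r} for cycle 2")
    else:
        raise ValueError("cycle must be 1 or 2")
    return RetainingRateCurve(
        cycle=cycle, grid=grid, values=np.asarray(values), params=params, method=used, meta=meta
    )
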