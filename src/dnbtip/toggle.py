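"""Dimensionless mutual-repression (toggle-switch) model of two genes.

The state (x, y) is the mean expression of two mutually repressing genes
(in the motivating fibrosis system, Tgfb3 and Mmp13):

    dx/dt = alpha1 / (1 + y**beta1) - x
    dy/dt = alpha2 / (1 + x**beta2) - y

alpha1/alpha2 are effective synthesis rates, beta1/beta2 cooperativity
exponents.  Two consecutive negative interactions form a positive feedback
loop; for sufficient synthesis and cooperativity > 1 the system is
bistable: two stable nodes (one high-x/low-y, one low-x/high-y) separated
by a saddle.  In the symmetric case (alpha1 = alpha2 = alpha,
beta1 = beta2 = beta) the symmetric fixed point x = y = s with
s * (1 + s**beta) = alpha loses stability through a pitchfork when the
loop gain beta * s**beta / (1 + s**beta) exceeds one, i.e. at
s_c = (beta - 1)**(-1/beta) and

    alpha_c = s_c * beta / (beta - 1),

so alpha_c = 2 at beta = 2 and alpha_c = 1.5 / 2**(1/3) ~= 1.1906 at
beta = 3; beta <= 1 is monostable for every alpha.

Root finding reduces to one dimension: any fixed point satisfies
y = alpha2 / (1 + x**beta2) and x = alpha1 / (1 + y**beta1) <= alpha1, so a
dense bracket scan of x in (0, alpha1] followed by bisection finds every
generic root.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .datamodel import ValidationError

__all__ = [
    "ToggleParams",
    "FixedPoint",
    "rates",
    "jacobian",
    "fixed_points",
    "is_bistable",
    "critical_alpha_analytic",
    "bifurcation_scan",
    "simulate",
    "phase_map",
    "stochastic_simulate",
]


@dataclass(frozen=True)
class ToggleParams:
    """Synthesis rates (alpha) and cooperativity exponents (beta)."""

    alpha1: float = 3.0
    alpha2: float = 3.0
    beta1: float = 2.0
    beta2: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha1 <= 0 or self.alpha2 <= 0:
            raise ValidationError("synthesis rates must be positive")
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValidationError("cooperativity exponents must be >= 0")
        if not all(map(math.isfinite, (self.alpha1, self.alpha2, self.beta1, self.beta2))):
            raise ValidationError("parameters must be finite")


@dataclass(frozen=True)
class FixedPoint:
    x: float
    y: float
    eigenvalues: tuple[complex, complex]
    stability: str  # stable_node | saddle | other

    @property
    def state(self) -> tuple[float, float]:
        return (self.x, self.y)


def rates(state, params: ToggleParams) -> tuple[float, float]:
    """Exact right-hand side (dx/dt, dy/dt) at one state."""
    x, y = float(state[0]), float(state[1])
    dx = params.alpha1 / (1.0 + y**params.beta1) - x
    dy = params.alpha2 / (1.0 + x**params.beta2) - y
    return dx, dy


def jacobian(state, params: ToggleParams) -> np.ndarray:
    x, y = float(state[0]), float(state[1])
    # d/dy [a/(1+y^b)] = -a*b*y^(b-1)/(1+y^b)^2; zero exponent kills coupling
    j12 = (
        -params.alpha1 * params.beta1 * y ** (params.beta1 - 1.0)
        / (1.0 + y**params.beta1) ** 2
        if params.beta1 > 0
        else 0.0
    )
    j21 = (
        -params.alpha2 * params.beta2 * x ** (params.beta2 - 1.0)
        / (1.0 + x**params.beta2) ** 2
        if params.beta2 > 0
        else 0.0
    )
    return np.array([[-1.0, j12], [j21, -1.0]])


def _classify(eigs: np.ndarray) -> str:
    re = eigs.real
    if np.all(re < 0):
        return "stable_node"
    if re.min() < 0 < re.max():
        return "saddle"
    return "other"


def fixed_points(params: ToggleParams, scan_resolution: int = 4000) -> list[FixedPoint]:
    """All fixed points via the 1-D reduction and a bracketed scan.

    The scan grid on x in (0, alpha1] mixes log and linear spacing so
    roots near zero and near alpha1 are both bracketed; each sign change
    is refined by bisection to 1e-12.  Every returned point satisfies both
    rate equations to 1e-9.
    """

    def residual(x: float) -> float:
        y = params.alpha2 / (1.0 + x**params.beta2)
        return x - params.alpha1 / (1.0 + y**params.beta1)

    lo = params.alpha1 * 1e-9
    n = scan_resolution // 2
    xs = np.unique(
        np.concatenate(
            [
                np.geomspace(lo, params.alpha1, n),
                np.linspace(lo, params.alpha1, n),
            ]
        )
    )
    vals = np.array([residual(x) for x in xs])
    roots: list[float] = []
    for i in range(len(xs) - 1):
        if vals[i] == 0.0:
            roots.append(float(xs[i]))
        elif vals[i] * vals[i + 1] < 0:
            roots.append(float(brentq(residual, xs[i], xs[i + 1], xtol=1e-12)))
    if vals[-1] == 0.0:
        roots.append(float(xs[-1]))
    # de-duplicate near-coincident roots
    uniq: list[float] = []
    for r in sorted(roots):
        if not uniq or abs(r - uniq[-1]) > 1e-9 * max(1.0, params.alpha1):
            uniq.append(r)
    out = []
    for x in uniq:
        y = params.alpha2 / (1.0 + x**params.beta2)
        dx, dy = rates((x, y), params)
        if max(abs(dx), abs(dy)) > 1e-9:
            continue  # spurious bracket artefact
        eigs = np.linalg.eigvals(jacobian((x, y), params))
        out.append(FixedPoint(x, y, (complex(eigs[0]), complex(eigs[1])), _classify(eigs)))
    return out


def is_bistable(params: ToggleParams, scan_resolution: int = 4000) -> bool:
    """True iff the system has exactly two stable nodes."""
    fps = fixed_points(params, scan_resolution)
    return sum(fp.stability == "stable_node" for fp in fps) == 2


def critical_alpha_analytic(beta: float) -> float | None:
    """Symmetric-case pitchfork threshold; None when no bifurcation exists
    (beta <= 1 is monostable for every alpha)."""
    if beta <= 1.0:
        return None
    s_c = (beta - 1.0) ** (-1.0 / beta)
    return s_c * beta / (beta - 1.0)


def bifurcation_scan(
    beta: float,
    alpha_grid: np.ndarray | None = None,
    tol: float = 1e-4,
    scan_resolution: int = 2000,
) -> float | None:
    """Locate the symmetric critical synthesis rate by a count scan.

    Counts stable fixed points over ``alpha_grid`` (default 64 points on
    (0.2, 5]); if the mono/bistable pattern is non-monotone the grid is too
    coarse and an error is raised.  The transition is refined by bisection
    to ``tol``.  Returns None when the whole grid is monostable.
    """
    if alpha_grid is None:
        alpha_grid = np.linspace(0.2, 5.0, 64)
    alpha_grid = np.asarray(alpha_grid, dtype=float)

    def bistable(a: float) -> bool:
        return is_bistable(
            ToggleParams(alpha1=a, alpha2=a, beta1=beta, beta2=beta), scan_resolution
        )

    flags = [bistable(a) for a in alpha_grid]
    if not any(flags):
        return None
    first = flags.index(True)
    if any(flags[first:]) and not all(flags[first:]):
        raise ValidationError(
            "non-monotone stability pattern on grid; increase resolution"
        )
    if first == 0:
        raise ValidationError("grid starts inside the bistable regime; extend it down")
    lo, hi = float(alpha_grid[first - 1]), float(alpha_grid[first])
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if bistable(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def simulate(
    params: ToggleParams,
    initial_state,
    t_end: float = 200.0,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    require_convergence: bool = True,
) -> dict:
    """Integrate one trajectory with an adaptive explicit scheme.

    Returns ``{"t", "x", "y", "converged", "final"}``; convergence means
    the rate norm at the final state is below 1e-8.  Non-convergence
    raises unless ``require_convergence=False``.
    """
    x0, y0 = float(initial_state[0]), float(initial_state[1])
    if x0 < 0 or y0 < 0:
        raise ValidationError("initial state must be non-negative")
    sol = solve_ivp(
        lambda t, s: rates(s, params),
        (0.0, t_end),
        (x0, y0),
        method="RK45",
        rtol=rtol,
        atol=atol,
        dense_output=False,
    )
    final = sol.y[:, -1]
    speed = float(np.hypot(*rates(final, params)))
    converged = speed < 1e-8
    if require_convergence and not converged:
        raise ValidationError(
            f"trajectory not converged within t_end={t_end} (|rates|={speed:.2e})"
        )
    return {
        "t": sol.t,
        "x": sol.y[0],
        "y": sol.y[1],
        "converged": converged,
        "final": (float(final[0]), float(final[1])),
    }


def phase_map(
    params: ToggleParams,
    grid: np.ndarray | None = None,
    t_end: float = 200.0,
    match_tol: float = 1e-4,
) -> dict:
    """Basin-of-attraction labels on a grid of initial states.

    Each grid start is integrated to convergence and assigned the index of
    the stable node it lands on (within ``match_tol``); unassignable
    starts get label -1.
    """
    fps = fixed_points(params)
    stable = [fp for fp in fps if fp.stability == "stable_node"]
    if grid is None:
        hi = max(params.alpha1, params.alpha2)
        grid = np.linspace(0.0, hi, 13)
    grid = np.asarray(grid, dtype=float)
    labels = np.full((len(grid), len(grid)), -1, dtype=int)
    for i, x0 in enumerate(grid):
        for j, y0 in enumerate(grid):
            traj = simulate(params, (x0, y0), t_end=t_end, require_convergence=False)
            fx, fy = traj["final"]
            for k, fp in enumerate(stable):
                if math.hypot(fx - fp.x, fy - fp.y) < max(match_tol, 1e-6):
                    labels[i, j] = k
                    break
    return {"grid": grid, "labels": labels, "stable_points": stable, "fixed_points": fps}


def stochastic_simulate(
    params: ToggleParams,
    noise_sd: float,
    n_steps: int = 20000,
    dt: float = 0.01,
    n_traj: int = 10,
    seed: int = 0,
    initial_state=None,
) -> np.ndarray:
    """Euler-Maruyama ensemble with additive noise and reflection at 0.

    Returns an array of shape (n_traj, n_steps + 1, 2).  The linear decay
    rate of the model is 1, so ``dt`` must stay well below that relaxation
    time; dt > 0.2 is rejected.
    """
    if dt <= 0 or dt > 0.2:
        raise ValidationError("dt must be in (0, 0.2] for a stable explicit step")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if initial_state is None:
        fps = fixed_points(params)
        stable = [fp for fp in fps if fp.stability == "stable_node"]
        start = stable[0].state if stable else (params.alpha1 / 2, params.alpha2 / 2)
    else:
        start = (float(initial_state[0]), float(initial_state[1]))
    out = np.empty((n_traj, n_steps + 1, 2))
    state = np.tile(np.asarray(start, dtype=float), (n_traj, 1))
    out[:, 0] = state
    sqdt = math.sqrt(dt)
    for k in range(1, n_steps + 1):
        x, y = state[:, 0], state[:, 1]
        dx = params.alpha1 / (1.0 + y**params.beta1) - x
        dy = params.alpha2 / (1.0 + x**params.beta2) - y
        state = state + dt * np.column_stack([dx, dy])
        if noise_sd > 0:
            state = state + noise_sd * sqdt * rng.standard_normal(state.shape)
        state = np.abs(state)  # reflecting boundary at 0
        out[:, k] = state
    return out
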