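"""Deterministic extended logistic growth law and its analytics.

The model is

    dx/dt = f(x) = r_p x^(alpha+1) (1 - (x/K)^beta) - n x^(delta+1)

an extended logistic law with a density-dependent intrinsic proliferation
rate r_p x^alpha (cell-cell cooperation), an allometric crowding exponent
beta, and a harvesting-like negative feedback n x^(delta+1) from
growth-inhibiting molecules. With n > 0 the law behaves like a strong-Allee
model: it has a stable extinction state, an interior unstable threshold
density, and a largest stable equilibrium — the maximum sustainable stable
cell density (MSSCD) — that sits below the carrying capacity K.

This module provides the rate functions, equilibrium and inflection
analytics, the potential function, closed-form series approximations about
K for the threshold/MSSCD and the density of maximum relative proliferation
rate (the fitness measure), and trajectory integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import GrowthParams

__all__ = [
    "Equilibrium",
    "EquilibriumSet",
    "Trajectory",
    "Theorem1Result",
    "MaxRPRResult",
    "apr",
    "rpr",
    "apr_derivative",
    "find_equilibria",
    "mssd_approx",
    "threshold_approx",
    "inflection_densities",
    "max_rpr_density_approx",
    "potential",
    "solve_trajectory",
]

# ---------------------------------------------------------------------------
# rate functions
# ---------------------------------------------------------------------------


def _check_nonnegative(x, what: str = "density"):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError(f"{what} must be >= 0 (fractional powers of negative "
                         "densities are undefined)")
    return x


def apr(params: GrowthParams, x):
    """Absolute proliferation rate f(x) = dx/dt, elementwise over ``x``.

    Parameters
    ----------
    params : GrowthParams
    x : float or array_like
        Scaled cell density, >= 0.
    """
    x = _check_nonnegative(x)
    r_p, K, n, a, b, d = params.astuple()
    out = r_p * x ** (a + 1.0) * (1.0 - (x / K) ** b) - n * x ** (d + 1.0)
    return out if out.ndim else float(out)


def rpr(params: GrowthParams, x):
    """Relative proliferation rate f(x)/x = r_p x^a (1-(x/K)^b) - n x^d.

    Defined for x > 0 only; this is Fisher's relative growth rate evaluated
    on the model, and can be negative below the Allee threshold.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("rpr requires density > 0")
    r_p, K, n, a, b, d = params.astuple()
    out = r_p * x ** a * (1.0 - (x / K) ** b) - n * x ** d
    return out if out.ndim else float(out)


def apr_derivative(params: GrowthParams, x):
    """df/dx = r_p(a+1)x^a - r_p(a+b+1)/K^b x^(a+b) - n(d+1)x^d, x > 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("apr_derivative requires density > 0")
    r_p, K, n, a, b, d = params.astuple()
    out = (r_p * (a + 1.0) * x ** a
           - r_p * (a + b + 1.0) / K ** b * x ** (a + b)
           - n * (d + 1.0) * x ** d)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# equilibria
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Equilibrium:
    density: float
    stability: Literal["stable", "unstable"]
    method: Literal["exact_zero", "numeric_root", "closed_form"]


@dataclass(frozen=True)
class EquilibriumSet:
    """Equilibria of f ordered by density.

    ``threshold`` is the interior unstable equilibrium (the Allee threshold:
    initial densities below it decay to extinction); ``mssd`` is the largest
    stable interior equilibrium, the conditional MSSCD. Either may be None.
    """

    equilibria: tuple[Equilibrium, ...]
    mssd: float | None = None
    threshold: float | None = None

    def __post_init__(self):
        dens = [e.density for e in self.equilibria]
        if any(b <= a for a, b in zip(dens, dens[1:])):
            raise ValueError("equilibria must be strictly increasing in density")
        if self.mssd is not None and self.threshold is not None:
            if not self.threshold < self.mssd:
                raise ValueError("threshold must be below mssd")


def _scan_grid(K: float, upper: float, n_points: int = 2400) -> np.ndarray:
    """Composite log + linear scan grid on (1e-8*K, upper].

    Interior roots can sit orders of magnitude below K (Allee thresholds),
    so half the points are log-spaced near zero.
    """
    half = n_points // 2
    lo = np.geomspace(1e-8 * K, 0.2 * K, half)
    hi = np.linspace(0.2 * K, upper, n_points - half)
    return np.unique(np.concatenate([lo, hi]))


def _bracketed_roots(fn, grid: np.ndarray, xtol: float) -> list[float]:
    vals = fn(grid)
    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0:
            roots.append(float(brentq(fn, grid[i], grid[i + 1], xtol=xtol)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    # collapse near-duplicates from grid points landing exactly on roots
    out: list[float] = []
    for r in roots:
        if not out or r - out[-1] > 10 * xtol:
            out.append(r)
    return out


def find_equilibria(params: GrowthParams, search_upper: float | None = None) -> EquilibriumSet:
    """All equilibria of f on [0, search_upper], classified by stability.

    x = 0 is always an equilibrium; it is classified by the sign of f just
    above zero (f may be non-differentiable at 0 when delta < 1). Interior
    roots are located by bracketing sign changes of f on a composite
    log+linear grid and polished by Brent's method to |dx| <= 1e-12*K; they
    are classified by the sign of f' (negative -> stable), falling back to
    the sign of f on either side when f' vanishes at the root.
    """
    K = params.K
    if search_upper is None:
        search_upper = 3.0 * K
    if search_upper <= K:
        raise ValueError("search_upper must exceed K")
    xtol = 1e-12 * K

    fn = lambda x: apr(params, x)
    roots = _bracketed_roots(fn, _scan_grid(K, search_upper), xtol)

    eqs: list[Equilibrium] = []
    # boundary equilibrium at 0
    zero_stable = apr(params, 1e-6 * K) < 0
    eqs.append(Equilibrium(0.0, "stable" if zero_stable else "unstable", "exact_zero"))

    for r in roots:
        if r <= 1e-7 * K:
            continue
        slope = apr_derivative(params, r)
        if slope != 0.0:
            stab = "stable" if slope < 0 else "unstable"
        else:
            h = max(1e-8 * K, 1e-10)
            stab = ("stable"
                    if apr(params, r - h) > 0 and apr(params, r + h) < 0
                    else "unstable")
        eqs.append(Equilibrium(r, stab, "numeric_root"))

    interior = [e for e in eqs if e.density > 0]
    stable_interior = [e.density for e in interior if e.stability == "stable"]
    unstable_interior = [e.density for e in interior if e.stability == "unstable"]
    mssd = max(stable_interior) if stable_interior else None
    threshold = None
    if unstable_interior and mssd is not None:
        below = [u for u in unstable_interior if u < mssd]
        threshold = max(below) if below else None
    elif unstable_interior:
        threshold = max(unstable_interior)
    return EquilibriumSet(tuple(eqs), mssd=mssd, threshold=threshold)


# ---------------------------------------------------------------------------
# closed-form approximations about K
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Theorem1Result:
    """Quadratic-expansion-about-K approximation to an interior equilibrium.

    ``value`` is the branch value (None when the discriminant is negative, in
    which case the conditional MSSCD does not exist in the approximation).
    ``numeric`` carries the matching numeric root of f when requested, so the
    (sometimes large) gap between series and exact root is visible. The
    expansion is accurate near K and degrades for roots far from K — the
    plus-branch threshold estimate in particular can be several-fold off.
    """

    value: float | None
    exists: bool
    discriminant: float
    numeric: float | None = None


def _theorem1_pieces(params: GrowthParams) -> tuple[float, float, float]:
    r_p, K, n, a, b, d = params.astuple()
    S = b * r_p * K ** a + n * d * K ** d
    denom = (2.0 * a * b * r_p * K ** a
             + b * (b - 1.0) * r_p * K ** a
             + d * (d - 1.0) * n * K ** d)
    disc = S * S - 2.0 * denom * n * K ** d
    return S, denom, disc


def _theorem1_branch(params: GrowthParams, sign: float) -> Theorem1Result:
    S, denom, disc = _theorem1_pieces(params)
    if denom == 0.0:
        raise ZeroDivisionError("Theorem-1 expansion denominator vanishes for these parameters")
    if disc < 0.0:
        return Theorem1Result(None, False, disc)
    K = params.K
    value = K - K * (S + sign * math.sqrt(disc)) / denom
    return Theorem1Result(float(value), True, disc)


def mssd_approx(params: GrowthParams) -> Theorem1Result:
    """Minus-branch series approximation to the conditional MSSCD.

    A quadratic expansion of f about x = K; agrees with the numeric largest
    stable root to a few parts in a thousand when that root is near K. A
    negative discriminant signals that no conditional MSSCD exists in the
    expansion (typed result, not an exception).
    """
    return _theorem1_branch(params, -1.0)


def threshold_approx(params: GrowthParams, with_numeric: bool = True) -> Theorem1Result:
    """Plus-branch series approximation to the Allee threshold density.

    The expansion is about K while the true threshold usually lies far below
    K, so this value can diverge badly from the numeric root (for the fitted
    seeding-1 hexad: ~0.243 vs 0.0671). The companion numeric root is
    returned alongside so callers see the gap; prefer
    :func:`find_equilibria` for quantitative work.
    """
    res = _theorem1_branch(params, +1.0)
    if with_numeric:
        numeric = find_equilibria(params).threshold
        res = Theorem1Result(res.value, res.exists, res.discriminant, numeric)
    return res


def inflection_densities(params: GrowthParams, upper: float | None = None) -> list[float]:
    """Roots of f' on (0, upper), ascending — the inflection points of x(t).

    At these densities the absolute proliferation rate has a local minimum /
    maximum. ``upper`` defaults to the MSSCD when one exists, else K.
    """
    if upper is None:
        eq = find_equilibria(params)
        upper = eq.mssd if eq.mssd is not None else params.K
    fn = lambda x: apr_derivative(params, x)
    return _bracketed_roots(fn, _scan_grid(params.K, upper), 1e-12 * params.K)


@dataclass(frozen=True)
class MaxRPRResult:
    """Density of maximum relative proliferation rate (fitness measure).

    ``concave`` evaluates the second-order condition for the profile to be
    concave downward at the returned density; ``exact`` is True when the
    alpha = delta closed form (which is exact) was used rather than the
    expansion about K.
    """

    value: float | None
    concave: bool
    exact: bool = False
    degenerate: bool = False


def max_rpr_density_approx(params: GrowthParams) -> MaxRPRResult:
    """Closed-form density at which the RPR profile peaks.

    For alpha = delta the feedback folds into the cooperation term and the
    argmax K((r_p-n) alpha / (r_p (alpha+beta)))^(1/beta) is exact (requires
    r_p > n and alpha > 0). Otherwise the series expansion about K

        x* = K - K (r_p b K^(a-1) + n d K^(d-1)) /
                   (2 r_p a b K^(a-1) + r_p b (b-1) K^(a-1) + n d (d-1) K^(d-1))

    is returned. The concavity flag evaluates

        r_p a(a-1) x^(a-2) - r_p/K^b (a+b)(a+b-1) x^(a+b-2) - n d(d-1) x^(d-2) < 0

    at the returned density.
    """
    r_p, K, n, a, b, d = params.astuple()
    if a == d:
        if r_p <= n or a <= 0:
            return MaxRPRResult(None, False, exact=True, degenerate=True)
        x = K * ((r_p - n) * a / (r_p * (a + b))) ** (1.0 / b)
        return MaxRPRResult(float(x), _rpr_concave(params, x), exact=True)
    num = r_p * b * K ** (a - 1.0) + n * d * K ** (d - 1.0)
    den = (2.0 * r_p * a * b * K ** (a - 1.0)
           + r_p * b * (b - 1.0) * K ** (a - 1.0)
           + n * d * (d - 1.0) * K ** (d - 1.0))
    if den == 0.0:
        return MaxRPRResult(None, False, degenerate=True)
    x = K - K * num / den
    concave = x > 0 and _rpr_concave(params, x)
    return MaxRPRResult(float(x), bool(concave))


def _rpr_concave(params: GrowthParams, x: float) -> bool:
    r_p, K, n, a, b, d = params.astuple()
    val = (r_p * a * (a - 1.0) * x ** (a - 2.0)
           - r_p / K ** b * (a + b) * (a + b - 1.0) * x ** (a + b - 2.0)
           - n * d * (d - 1.0) * x ** (d - 2.0))
    return bool(val < 0)


# ---------------------------------------------------------------------------
# potential and trajectories
# ---------------------------------------------------------------------------


def potential(params: GrowthParams, x):
    """Deterministic potential U(x) = -integral_0^x f(s) ds.

    U(0) = 0 and dU/dx = -f; stable equilibria are minima of U, the Allee
    threshold is the intervening maximum (bistable double-well shape when
    the threshold exists).
    """
    x = _check_nonnegative(x)
    r_p, K, n, a, b, d = params.astuple()
    out = -(r_p * x ** (a + 2.0) / (a + 2.0)
            - r_p / K ** b * x ** (a + b + 2.0) / (a + b + 2.0)
            - n * x ** (d + 2.0) / (d + 2.0))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Trajectory:
    times: np.ndarray
    densities: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.densities, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing with length >= 2")
        if y.shape != t.shape or not np.all(np.isfinite(y)):
            raise ValueError("densities must be finite and aligned with times")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "densities", y)

    @property
    def terminal(self) -> float:
        return float(self.densities[-1])


class TrajectoryError(RuntimeError):
    """Integration failure; carries the last good state."""

    def __init__(self, message: str, last_time: float, last_density: float):
        super().__init__(message)
        self.last_time = last_time
        self.last_density = last_density


def solve_trajectory(params: GrowthParams, x0: float, times: Sequence[float]) -> Trajectory:
    """Integrate dx/dt = f(x) from x0 at the requested times.

    Adaptive explicit Runge-Kutta (RK45) with rtol 1e-9 / atol 1e-12;
    densities are clipped at 0 from below (the vector field is only defined
    for nonnegative density).
    """
    if x0 < 0:
        raise ValueError("x0 must be >= 0")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing with length >= 2")

    def rhs(_t, y):
        return [apr(params, max(y[0], 0.0))]

    sol = solve_ivp(rhs, (times[0], times[-1]), [float(x0)], t_eval=times,
                    method="RK45", rtol=1e-9, atol=1e-12)
    if not sol.success:
        last_t = float(sol.t[-1]) if sol.t.size else float(times[0])
        last_y = float(sol.y[0, -1]) if sol.t.size else float(x0)
        raise TrajectoryError(f"ODE integration failed: {sol.message}", last_t, last_y)
    return Trajectory(times, np.clip(sol.y[0], 0.0, None))
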