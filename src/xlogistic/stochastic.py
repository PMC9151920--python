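"""Stochastic analog with correlated multiplicative and additive noise.

The Langevin form of the growth law is

    dx/dt = f(x) - x^(delta+1) eps(t) + Gamma(t)

interpreted in the Stratonovich sense, where eps and Gamma are zero-mean
Gaussian white noises with <eps eps'> = 2 D delta(t-t'), <Gamma Gamma'> =
2 Q delta(t-t') and cross-correlation 2 lam sqrt(DQ) delta(t-t').
Multiplicative noise (strength D) enters through the negative-feedback rate
— heterogeneity of growth-inhibiting molecules — and additive noise
(strength Q) models environmental fluctuation of the culture.

Eliminating the two noises yields a one-dimensional Fokker-Planck equation

    dP/dt = -d[A(x) P]/dx + d^2[B(x) P]/dx^2

with noise-induced drift A and diffusion B:

    A(x) = f(x) + D (delta+1) x^(2 delta+1) - lam sqrt(DQ) (delta+1) x^delta
    B(x) = D x^(2 delta+2) - 2 lam sqrt(DQ) x^(delta+1) + Q

whose stationary solution P_st(x) = N/B(x) exp( int A/B dx ) is computed
here, together with its extrema (roots of A - B'), a first-order
approximation to the stochastic conditional MSSCD, ensemble SDE simulation,
and steady-state mode classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import find_peaks

from .growth import _bracketed_roots, _scan_grid
from .params import GrowthParams, NoiseParams

__all__ = [
    "NoiseParams",
    "SSPDF",
    "Ensemble",
    "ModeReport",
    "StochasticMSSCD",
    "drift_A",
    "diffusion_B",
    "diffusion_B_prime",
    "stationary_pdf",
    "sspdf_extrema",
    "mssd_stochastic_approx",
    "simulate_ensemble",
    "classify_steady_state",
]


# ---------------------------------------------------------------------------
# effective drift and diffusion
# ---------------------------------------------------------------------------


def drift_A(params: GrowthParams, noise: NoiseParams, x):
    """Noise-induced drift A(x), defined for x > 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("drift_A requires density > 0")
    r_p, K, n, a, b, d = params.astuple()
    out = (r_p * x ** (a + 1.0) * (1.0 - (x / K) ** b) - n * x ** (d + 1.0)
           + noise.D * (d + 1.0) * x ** (2.0 * d + 1.0)
           - noise.cross * (d + 1.0) * x ** d)
    return out if out.ndim else float(out)


def diffusion_B(params: GrowthParams, noise: NoiseParams, x):
    """Noise-induced diffusion B(x) = D x^(2d+2) - 2 lam sqrt(DQ) x^(d+1) + Q.

    Nonnegative for |lam| <= 1: B >= (1-|lam|)(D x^(2d+2) + Q) by AM-GM.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("diffusion_B requires density >= 0")
    d = params.delta
    out = (noise.D * x ** (2.0 * d + 2.0)
           - 2.0 * noise.cross * x ** (d + 1.0) + noise.Q)
    return out if out.ndim else float(out)


def diffusion_B_prime(params: GrowthParams, noise: NoiseParams, x):
    """dB/dx = D(2d+2) x^(2d+1) - 2 lam sqrt(DQ) (d+1) x^d."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("diffusion_B_prime requires density >= 0")
    d = params.delta
    out = (noise.D * (2.0 * d + 2.0) * x ** (2.0 * d + 1.0)
           - 2.0 * noise.cross * (d + 1.0) * x ** d)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# stationary Fokker-Planck density
# ---------------------------------------------------------------------------


class SingularDiffusionError(ValueError):
    """B(x) vanishes inside the integration range and regularization is off."""


@dataclass(frozen=True)
class SSPDF:
    """Normalized stationary probability density on a truncated grid.

    The analytic form lives on (0, inf); ``x_max`` truncates the upper limit
    where the density has decayed to numerical zero. ``regularized`` flags
    the |lam| = 1 case where B has an interior zero lifted by a tiny floor.
    """

    grid: np.ndarray
    values: np.ndarray
    x_max: float
    normalization_residual: float
    regularized: bool = False

    def cdf(self) -> np.ndarray:
        """Trapezoid cumulative distribution on the grid."""
        dx = np.diff(self.grid)
        c = np.concatenate([[0.0], np.cumsum(0.5 * dx * (self.values[1:] + self.values[:-1]))])
        return c / c[-1]

    @property
    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.values))])


def stationary_pdf(params: GrowthParams, noise: NoiseParams,
                   x_max: float | None = None, n_grid: int = 4000,
                   regularize: bool = True) -> SSPDF:
    """Stationary density P_st(x) = N/B(x) exp( int_0^x A/B ds ), normalized.

    log P is accumulated by trapezoid quadrature of A/B from the lower grid
    edge, exponentiated stably after subtracting the running max, and
    normalized so the trapezoid integral over (0, x_max] equals 1.
    ``x_max`` defaults to 3 K and is raised (up to a cap) until the density
    at the upper edge is below 1e-10 of the peak, emulating the infinite
    upper limit of the analytic normalization.
    """
    if noise.D + noise.Q <= 0:
        raise ValueError("stationary_pdf requires D + Q > 0")
    auto = x_max is None
    if x_max is None:
        x_max = 3.0 * params.K

    # |lam| = 1 makes B a perfect square with an interior zero at
    # (Q/D)^(1/(2 delta + 2)); the quadrature needs a floor there
    singular_zero = None
    if abs(noise.lam) == 1.0 and noise.D > 0 and noise.Q > 0:
        singular_zero = (noise.Q / noise.D) ** (1.0 / (2.0 * params.delta + 2.0))

    for _ in range(8):
        grid = np.linspace(x_max * 1e-6, x_max, n_grid)
        B = diffusion_B(params, noise, grid)
        interior_zero = (np.any(B <= 0)
                         or (singular_zero is not None
                             and grid[0] < singular_zero < x_max))
        if interior_zero:
            if not regularize:
                raise SingularDiffusionError(
                    "B(x) vanishes inside the grid (|lam| = 1); enable "
                    "regularization or move the grid")
            B = np.maximum(B, 0.0) + 1e-12 * max(noise.Q, noise.D, 1.0)
            regularized = True
        else:
            regularized = False
        A = drift_A(params, noise, grid)
        ratio = A / B
        dx = np.diff(grid)
        logP = np.concatenate([[0.0], np.cumsum(0.5 * dx * (ratio[1:] + ratio[:-1]))])
        logP -= np.log(B)
        logP -= logP.max()
        P = np.exp(logP)
        Z = np.trapezoid(P, grid)
        P /= Z
        if not auto or P[-1] < 1e-10 * P.max():
            break
        x_max *= 2.0

    residual = abs(1.0 - np.trapezoid(P, grid))
    return SSPDF(grid, P, float(x_max), float(residual), regularized)


def sspdf_extrema(params: GrowthParams, noise: NoiseParams,
                  x_max: float | None = None) -> list[float]:
    """Densities where dP_st/dx = 0, i.e. the roots of A(x) - B'(x).

    Found with the same bracket-and-polish engine as the deterministic
    equilibria; ascending order.
    """
    if noise.D + noise.Q <= 0:
        raise ValueError("sspdf_extrema requires D + Q > 0")
    if x_max is None:
        x_max = 3.0 * params.K
    fn = lambda x: drift_A(params, noise, x) - diffusion_B_prime(params, noise, x)
    return _bracketed_roots(fn, _scan_grid(params.K, x_max), 1e-12 * params.K)


# ---------------------------------------------------------------------------
# first-order stochastic MSSCD
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StochasticMSSCD:
    """First-order (about K) stochastic conditional MSSCD.

    ``condition`` evaluates the stated second-order maximality condition
    (d[A - B']/dx < 0 at the value); ``degenerate`` flags a vanishing
    expansion denominator.
    """

    value: float | None
    condition: bool
    degenerate: bool = False


def mssd_stochastic_approx(params: GrowthParams, noise: NoiseParams) -> StochasticMSSCD:
    """Linearisation of A - B' = 0 about x = K.

        x* ~= K - K (n K^(d+1) + D(d+1) K^(2d+1) - lam sqrt(DQ)(d+1) K^d) /
              (b r_p K^(a+1) + n(d+1) K^(d+1) + D(d+1)(2d+1) K^(2d+1)
               - lam sqrt(DQ) d(d+1) K^d)

    In the deterministic limit D = Q = 0 this reduces continuously to the
    first-order deterministic MSSCD expansion. The alpha = delta case is the
    same expression with delta = alpha (the two printed variants coincide).
    The stated maximality condition is evaluated with the cross-amplitude
    lam sqrt(DQ) throughout.
    """
    r_p, K, n, a, b, d = params.astuple()
    D, lamDQ = noise.D, noise.cross
    num = (n * K ** (d + 1.0) + D * (d + 1.0) * K ** (2.0 * d + 1.0)
           - lamDQ * (d + 1.0) * K ** d)
    den = (b * r_p * K ** (a + 1.0) + n * (d + 1.0) * K ** (d + 1.0)
           + D * (d + 1.0) * (2.0 * d + 1.0) * K ** (2.0 * d + 1.0)
           - lamDQ * d * (d + 1.0) * K ** d)
    if den == 0.0:
        return StochasticMSSCD(None, False, degenerate=True)
    x = K - K * num / den
    if x <= 0:
        return StochasticMSSCD(float(x), False)
    cond = (r_p * (a + 1.0) * x ** a
            - r_p / K ** b * (a + b + 1.0) * x ** (a + b)
            - n * (d + 1.0) * x ** d
            - D * (d + 1.0) * (2.0 * d + 1.0) * x ** (2.0 * d)
            + lamDQ * d * (d + 1.0) * x ** (d - 1.0))
    return StochasticMSSCD(float(x), bool(cond < 0))


# ---------------------------------------------------------------------------
# ensemble simulation
# ---------------------------------------------------------------------------

Scheme = Literal["ito_equivalent", "stratonovich_heun"]
Boundary = Literal["reflecting", "absorbing"]


@dataclass(frozen=True)
class Ensemble:
    """Terminal densities of an SDE ensemble, reproducible from the seed."""

    final_densities: np.ndarray
    n_paths: int
    T: float
    dt: float
    seed: int
    scheme: Scheme
    boundary: Boundary = "reflecting"
    reflect_fraction: float = 0.0
    reflect_warning: bool = False

    def __post_init__(self):
        y = np.asarray(self.final_densities, dtype=float)
        if np.any(y < 0):
            raise ValueError("terminal densities must be >= 0")
        object.__setattr__(self, "final_densities", y)


def simulate_ensemble(params: GrowthParams, noise: NoiseParams, x0: float,
                      T: float, dt: float = 1e-3, n_paths: int = 500,
                      seed: int = 0, scheme: Scheme = "ito_equivalent",
                      boundary: Boundary = "reflecting") -> Ensemble:
    """Simulate ``n_paths`` trajectories to horizon T, return terminal densities.

    Two integration routes, statistically equivalent at small dt:

    ``ito_equivalent`` (default)
        Euler-Maruyama on the Ito equation dx = A(x) dt + sqrt(2 B(x)) dW,
        the one-dimensional diffusion whose Fokker-Planck equation is
        exactly dP/dt = -d[A P]/dx + d^2[B P]/dx^2, i.e. the convention the
        stationary density in this module uses.

    ``stratonovich_heun``
        Heun predictor-corrector on the original two-noise Stratonovich form
        dx = f(x) dt - x^(d+1) sqrt(2D) dW1 + sqrt(2Q) dW2 with correlated
        increments dW2 = lam dW1 + sqrt(1-lam^2) dW3.

    Two boundary behaviours at x = 0:

    ``reflecting`` (default)
        x <- |x| after each step. Consistent with the stationary density,
        which is normalized on (0, x_max]; use this when comparing terminal
        distributions against :func:`stationary_pdf`. If more than 1% of
        steps reflect, the result carries a warning flag suggesting a
        smaller dt.

    ``absorbing``
        A path whose density reaches 0 stays extinct: a well with no cells
        cannot be re-seeded by environmental fluctuation. Additive noise
        makes the reflecting boundary effectively repulsive, so sustained
        extinction modes in terminal-density histograms only form under
        absorption; use this for steady-state mode structure studies.
    """
    if T <= 0 or dt <= 0:
        raise ValueError("T and dt must be > 0")
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    if x0 < 0:
        raise ValueError("x0 must be >= 0")
    if boundary not in ("reflecting", "absorbing"):
        raise ValueError(f"unknown boundary {boundary!r}")
    rng = np.random.default_rng(seed)
    n_steps = int(round(T / dt))
    r_p, K, n, a, b, d = params.astuple()
    D, Q, lam = noise.D, noise.Q, noise.lam
    cross = noise.cross

    x = np.full(n_paths, float(x0))
    alive = np.ones(n_paths, dtype=bool)
    n_reflect = 0
    sqrt_dt = math.sqrt(dt)
    tiny = 1e-12  # power-law exponents are undefined at exactly 0

    def _apply_boundary(xnew):
        nonlocal n_reflect, alive, x
        if boundary == "reflecting":
            neg = xnew < 0
            n_reflect += int(neg.sum())
            np.abs(xnew, out=xnew)
            x = xnew
        else:
            xnew = np.where(alive, xnew, 0.0)
            dead = xnew <= 0
            alive &= ~dead
            xnew[dead] = 0.0
            x = xnew

    if scheme == "ito_equivalent":
        for _ in range(n_steps):
            xs = np.maximum(x, tiny)
            A = (r_p * xs ** (a + 1.0) * (1.0 - (xs / K) ** b)
                 - n * xs ** (d + 1.0)
                 + D * (d + 1.0) * xs ** (2.0 * d + 1.0)
                 - cross * (d + 1.0) * xs ** d)
            B = D * xs ** (2.0 * d + 2.0) - 2.0 * cross * xs ** (d + 1.0) + Q
            np.maximum(B, 0.0, out=B)
            _apply_boundary(x + A * dt + np.sqrt(2.0 * B)
                            * (sqrt_dt * rng.standard_normal(n_paths)))
    elif scheme == "stratonovich_heun":
        amp1 = math.sqrt(2.0 * D)
        amp2 = math.sqrt(2.0 * Q)
        root = math.sqrt(max(0.0, 1.0 - lam * lam))

        def drift(z):
            return r_p * z ** (a + 1.0) * (1.0 - (z / K) ** b) - n * z ** (d + 1.0)

        def gmult(z):
            return -amp1 * z ** (d + 1.0)

        for _ in range(n_steps):
            dW1 = sqrt_dt * rng.standard_normal(n_paths)
            dW3 = sqrt_dt * rng.standard_normal(n_paths)
            dW2 = lam * dW1 + root * dW3
            xs = np.maximum(x, tiny)
            f0 = drift(xs)
            g0 = gmult(xs)
            pred = np.maximum(x + f0 * dt + g0 * dW1 + amp2 * dW2, tiny)
            f1 = drift(pred)
            g1 = gmult(pred)
            _apply_boundary(x + 0.5 * (f0 + f1) * dt + 0.5 * (g0 + g1) * dW1
                            + amp2 * dW2)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    frac = n_reflect / max(1, n_steps * n_paths)
    return Ensemble(x, n_paths, float(T), float(dt), int(seed), scheme,
                    boundary=boundary, reflect_fraction=float(frac),
                    reflect_warning=frac > 0.01)


# ---------------------------------------------------------------------------
# steady-state mode classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModeReport:
    """Histogram-based modality of the terminal-density distribution."""

    modality: Literal["unimodal", "bimodal", "degenerate"]
    mode_locations: tuple[float, ...]
    extinction_mass: float
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        n_modes = len(self.mode_locations)
        ok = ((self.modality == "degenerate" and n_modes == 0)
              or (self.modality == "unimodal" and n_modes == 1)
              or (self.modality == "bimodal" and n_modes >= 2))
        if not ok:
            raise ValueError("mode count inconsistent with modality label")
        if not 0.0 <= self.extinction_mass <= 1.0:
            raise ValueError("extinction_mass must lie in [0, 1]")


def classify_steady_state(ensemble: Ensemble, extinction_cutoff: float) -> ModeReport:
    """Classify the terminal-density distribution as uni-/bi-modal.

    Densities below ``extinction_cutoff`` go into a dedicated extinction bin
    at zero; the rest are histogrammed with Freedman-Diaconis bins. Modes
    are local maxima of the padded count sequence with prominence at least
    10% of the tallest bin, the extinction bin included as a candidate mode.
    """
    if ensemble.n_paths < 100:
        raise ValueError("need at least 100 paths for mode classification")
    if extinction_cutoff <= 0:
        raise ValueError("extinction_cutoff must be > 0")
    y = ensemble.final_densities
    ext = y < extinction_cutoff
    ext_mass = float(ext.mean())
    surv = y[~ext]

    if surv.size < 2:
        # everything is in the extinction bin
        edges = np.array([0.0, extinction_cutoff])
        counts = np.array([int(ext.sum())])
        return ModeReport("unimodal", (0.0,), ext_mass, edges, counts)

    q75, q25 = np.percentile(surv, [75, 25])
    iqr = q75 - q25
    if iqr > 0:
        width = 2.0 * iqr / surv.size ** (1.0 / 3.0)
        n_bins = max(5, int(math.ceil((surv.max() - surv.min()) / width))) if width > 0 else 10
    else:
        n_bins = 10
    n_bins = min(n_bins, 200)
    lo = min(float(surv.min()), extinction_cutoff)
    counts, edges = np.histogram(surv, bins=n_bins, range=(lo, float(surv.max()) + 1e-12))
    centers = 0.5 * (edges[:-1] + edges[1:])

    full_counts = np.concatenate([[int(ext.sum())], counts])
    full_centers = np.concatenate([[0.0], centers])
    padded = np.concatenate([[0.0], full_counts.astype(float), [0.0]])
    prominence = 0.10 * padded.max()
    peaks, _ = find_peaks(padded, prominence=prominence)
    modes = tuple(float(full_centers[p - 1]) for p in peaks)

    if len(modes) == 0:
        modality: Literal["unimodal", "bimodal", "degenerate"] = "degenerate"
    elif len(modes) == 1:
        modality = "unimodal"
    else:
        modality = "bimodal"
    edges_out = np.concatenate([[0.0], edges])
    return ModeReport(modality, modes, ext_mass, edges_out, full_counts)
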