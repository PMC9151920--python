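"""Parameter containers for the extended logistic proliferation model.

The deterministic growth law is parameterised by a hexad

    dx/dt = r_p * x**(alpha+1) * (1 - (x/K)**beta) - n * x**(delta+1)

where ``r_p`` is the constant intrinsic proliferation rate (per hour), ``K``
the carrying capacity (scaled density), ``alpha`` the cell-cell cooperation
regulator entering the density-dependent intrinsic rate r_p*x**alpha,
``beta`` the allometric crowding / environmental-resistance exponent, and
``n * x**(delta+1)`` the additional negative feedback from growth-inhibiting
molecules, with ``delta`` regulating how that interaction scales with density.

The stochastic analog carries a noise triple ``(D, Q, lam)``: multiplicative
noise of strength D enters through the negative-feedback rate, additive noise
of strength Q through the rate equation itself, and ``lam`` is the cross
correlation between the two Gaussian white noises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

__all__ = ["GrowthParams", "NoiseParams"]


@dataclass(frozen=True)
class GrowthParams:
    """Hexad (r_p, K, n, alpha, beta, delta) of the extended logistic law.

    All exponents are dimensionless; ``r_p`` and ``n`` are rates per hour and
    ``K`` is in scaled density units. Validation enforces r_p > 0, K > 0,
    beta > 0 and n, alpha, delta >= 0; non-finite values are rejected.
    """

    r_p: float
    K: float
    n: float
    alpha: float
    beta: float
    delta: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValueError(f"{f.name} must be a finite number, got {v!r}")
            object.__setattr__(self, f.name, float(v))
        if self.r_p <= 0:
            raise ValueError(f"r_p must be > 0, got {self.r_p}")
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.n < 0:
            raise ValueError(f"n must be >= 0, got {self.n}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")

    def to_dict(self) -> dict[str, float]:
        """Flat key-value form with keys r_p, K, n, alpha, beta, delta."""
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "GrowthParams":
        known = {f.name for f in fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown parameter keys: {sorted(extra)}")
        missing = known - set(d)
        if missing:
            raise ValueError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def astuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.r_p, self.K, self.n, self.alpha, self.beta, self.delta)


@dataclass(frozen=True)
class NoiseParams:
    """Noise triple for the stochastic model.

    D : multiplicative noise strength (>= 0), heterogeneity of the
        growth-inhibiting molecules acting through the feedback rate.
    Q : additive noise strength (>= 0), environmental fluctuation.
    lam : correlation strength between the two white noises, in [-1, 1].

    ``(D, Q) = (0, 0)`` is the deterministic limit and is legal.
    """

    D: float = 0.0
    Q: float = 0.0
    lam: float = 0.0

    def __post_init__(self) -> None:
        for name in ("D", "Q", "lam"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValueError(f"{name} must be a finite number, got {v!r}")
            object.__setattr__(self, name, float(v))
        if self.D < 0:
            raise ValueError(f"D must be >= 0, got {self.D}")
        if self.Q < 0:
            raise ValueError(f"Q must be >= 0, got {self.Q}")
        if not -1.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must lie in [-1, 1], got {self.lam}")

    @property
    def cross(self) -> float:
        """lam * sqrt(D*Q), the cross-correlation amplitude."""
        return self.lam * math.sqrt(self.D * self.Q)

    def to_dict(self) -> dict[str, float]:
        return {"D": self.D, "Q": self.Q, "lam": self.lam}
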