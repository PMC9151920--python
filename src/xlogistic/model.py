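"""Model / Results interface over the fitting and analytics machinery.

``CellProliferationModel`` wraps a replicated density time series; ``fit``
runs the exhaustive hexad grid search on its Fisher RPR profile and returns
a ``CellProliferationResults`` carrying the estimates, both RSS diagnostics,
the equilibrium analytics of the fitted law, and a ``summary()`` table.
Stochastic steady-state analysis and ensemble simulation hang off the
results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Sequence

import numpy as np
import pandas as pd

from . import fitting, growth, stochastic
from .fitting import FitResult, ParameterGrid, RPRProfile, TimeSeries
from .params import GrowthParams, NoiseParams

__all__ = ["CellProliferationModel", "CellProliferationResults"]


class CellProliferationModel:
    """Extended logistic proliferation model bound to one observed series.

    Parameters
    ----------
    timeseries : TimeSeries
        Replicated density observations for one seeding condition.
    pairing : {"midpoint", "left", "geometric_mean"}
        Which density accompanies each Fisher RGR increment in the profile.

    Examples
    --------
    >>> from xlogistic import datasets
    >>> from xlogistic.model import CellProliferationModel
    >>> pre = datasets.presets()
    >>> series = datasets.synth_timeseries(
    ...     pre.table2_hexads[1],
    ...     datasets.AssayDesign(n_seedings=1, initial_densities=(0.1,),
    ...                          obs_noise_sd=0.0, seed=1))[0]
    >>> res = CellProliferationModel(series).fit(pre.table1_grids[1])
    >>> round(res.params.K, 2)
    1.43
    """

    def __init__(self, timeseries: TimeSeries, pairing: str = "midpoint"):
        self.data = timeseries
        self.pairing = pairing

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, seeding: str | None = None,
                       pairing: str = "midpoint") -> "CellProliferationModel":
        """Build from a long-format frame with columns
        time_h, density, replicate[, seeding]."""
        if seeding is not None:
            df = df[df["seeding"].astype(str) == str(seeding)]
            if df.empty:
                raise ValueError(f"no rows for seeding {seeding!r}")
        label = str(seeding) if seeding is not None else "1"
        rep_ids = sorted(df["replicate"].unique())
        times = None
        reps = []
        for rid in rep_ids:
            sub = df[df["replicate"] == rid].sort_values("time_h")
            t = sub["time_h"].to_numpy(dtype=float)
            if times is None:
                times = t
            elif t.shape != times.shape or not np.allclose(t, times):
                raise ValueError(f"replicate {rid} is on a mismatched time grid")
            reps.append(sub["density"].to_numpy(dtype=float))
        ts = TimeSeries(seeding_id=label, times=times, replicates=np.vstack(reps))
        return cls(ts, pairing=pairing)

    @cached_property
    def profile(self) -> RPRProfile:
        """Fisher RPR profile of the replicate-mean series."""
        return fitting.rpr_profile(self.data, pairing=self.pairing)

    def fit(self, grid: ParameterGrid, progress: bool = False) -> "CellProliferationResults":
        """Exhaustive grid search minimising the RPR-profile RSS."""
        res = fitting.grid_search(self.profile, grid, progress=progress)
        rssd = fitting.rss_density(res.best_params, self.data)
        return CellProliferationResults(self, FitResult(
            res.best_params, res.rss_rpr, res.n_evaluated,
            rss_density=rssd, grid=grid))

    def fit_logistic(self, r_grid: Sequence[float],
                     K_grid: Sequence[float]) -> "CellProliferationResults":
        """Logistic baseline (alpha=0, beta=1, n=0) for model comparison."""
        res = fitting.fit_logistic(self.profile, r_grid, K_grid)
        rssd = fitting.rss_density(res.best_params, self.data)
        return CellProliferationResults(self, FitResult(
            res.best_params, res.rss_rpr, res.n_evaluated,
            rss_density=rssd, grid=res.grid))


@dataclass(frozen=True)
class CellProliferationResults:
    """Fit results: estimated hexad, diagnostics, and downstream analytics."""

    model: CellProliferationModel
    fit_result: FitResult

    @property
    def params(self) -> GrowthParams:
        return self.fit_result.best_params

    @property
    def rss_rpr(self) -> float:
        return self.fit_result.rss_rpr

    @property
    def rss_density(self) -> float | None:
        return self.fit_result.rss_density

    @cached_property
    def equilibria(self) -> growth.EquilibriumSet:
        return growth.find_equilibria(self.params)

    @property
    def threshold(self) -> float | None:
        """Allee threshold density (interior unstable equilibrium)."""
        return self.equilibria.threshold

    @property
    def mssd(self) -> float | None:
        """Conditional maximum sustainable stable cell density."""
        return self.equilibria.mssd

    @cached_property
    def inflection_densities(self) -> list[float]:
        return growth.inflection_densities(self.params)

    def predict(self, times: Sequence[float], x0: float | None = None) -> np.ndarray:
        """Model density trajectory at the requested times."""
        if x0 is None:
            x0 = float(self.model.data.mean_density[0])
        return growth.solve_trajectory(self.params, x0, times).densities

    def simulate(self, noise: NoiseParams, T: float, x0: float | None = None,
                 dt: float = 1e-3, n_paths: int = 500, seed: int = 0,
                 scheme: str = "ito_equivalent") -> stochastic.Ensemble:
        """Ensemble simulation of the stochastic analog at the fitted hexad."""
        if x0 is None:
            x0 = float(self.model.data.mean_density[0])
        return stochastic.simulate_ensemble(self.params, noise, x0, T, dt=dt,
                                            n_paths=n_paths, seed=seed,
                                            scheme=scheme)

    def stationary_pdf(self, noise: NoiseParams, **kwargs) -> stochastic.SSPDF:
        """Stationary Fokker-Planck density at the fitted hexad."""
        return stochastic.stationary_pdf(self.params, noise, **kwargs)

    def summary(self) -> str:
        """Plain-text summary table of estimates and derived densities."""
        p = self.params
        lines = [
            "Extended logistic proliferation model — grid-search fit",
            "=" * 58,
            f"seeding id:          {self.model.data.seeding_id}",
            f"observations:        {self.model.data.times.size} times x "
            f"{self.model.data.n_replicates} replicates",
            f"profile points:      {len(self.model.profile)}",
            f"hexads evaluated:    {self.fit_result.n_evaluated}",
            "-" * 58,
            f"r_p    (intrinsic rate, /h):        {p.r_p:10.4f}",
            f"K      (carrying capacity):         {p.K:10.4f}",
            f"n      (feedback rate, /h):         {p.n:10.4f}",
            f"alpha  (cooperation exponent):      {p.alpha:10.4f}",
            f"beta   (crowding exponent):         {p.beta:10.4f}",
            f"delta  (feedback regulation):       {p.delta:10.4f}",
            "-" * 58,
            f"RSS (RPR profile):                  {self.rss_rpr:10.4g}",
            f"RSS (density profile):              "
            f"{self.rss_density if self.rss_density is not None else float('nan'):10.4g}",
        ]
        thr = self.threshold
        mssd = self.mssd
        infl = self.inflection_densities
        lines += [
            "-" * 58,
            f"Allee threshold density:            "
            + (f"{thr:10.4f}" if thr is not None else "      none"),
            f"conditional MSSCD:                  "
            + (f"{mssd:10.4f}" if mssd is not None else "      none"),
            f"inflection densities:               "
            + ", ".join(f"{v:.4f}" for v in infl),
            "=" * 58,
        ]
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed RPR profile and the fitted RPR curve (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        prof = self.model.profile
        ax.plot(prof.densities, prof.rprs, "o", label="observed RPR")
        xs = np.linspace(prof.densities.min() * 0.5, self.params.K, 400)
        ax.plot(xs, growth.rpr(self.params, xs), "-", label="fitted model")
        ax.set_xlabel("scaled density")
        ax.set_ylabel("RPR (/h)")
        ax.legend()
        return ax
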