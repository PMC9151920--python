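"""Synthetic scratch-assay data, table presets, and time-series CSV I/O.

The emulated assay follows the PC-3 scratch-assay design the model was
fitted to: three initial seeding conditions, three replicates each, densities
observed every 2 h for the first 18 h and every 6 h thereafter up to 48 h
(15 time points). Synthetic replicates are noiseless trajectories of the
growth law plus independent additive Gaussian observation noise, truncated
at zero.

``presets()`` ships the published parameter-search grids, the fitted hexads
per seeding condition, and the reference threshold / MSSCD / inflection
densities used for regression tests.

CSV dialect: header ``time_h,density,replicate,seeding``, UTF-8, decimal
floats; every replicate of a seeding must share the same time grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import growth
from .fitting import ParameterGrid, TimeSeries
from .params import GrowthParams

__all__ = [
    "DEFAULT_TIME_GRID",
    "AssayDesign",
    "Presets",
    "presets",
    "synth_timeseries",
    "save_timeseries",
    "load_timeseries",
]

# 0..18 h every 2 h, then 24..48 h every 6 h: 15 observation times
DEFAULT_TIME_GRID: tuple[float, ...] = tuple(float(t) for t in list(range(0, 20, 2)) + list(range(24, 54, 6)))


@dataclass(frozen=True)
class AssayDesign:
    """Design of the emulated scratch assay.

    ``initial_densities`` (one per seeding, model units) default to
    (0.1, 0.15, 0.2), loosely mirroring the 12k/16k/20k cells-per-well
    seeding ratios of the assay; the density scale of the model is
    arbitrary, so these are placeholders rather than calibrated values.
    ``obs_noise_sd`` is the standard deviation of the additive Gaussian
    observation noise on densities (default 0.02, roughly 1-2% of a typical
    carrying capacity); the true assay error magnitude is unknown.
    """

    n_seedings: int = 3
    n_replicates: int = 3
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID
    initial_densities: tuple[float, ...] = (0.1, 0.15, 0.2)
    obs_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        t = tuple(float(v) for v in self.time_grid)
        if len(t) < 2 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("time_grid must be strictly increasing, length >= 2")
        x0 = tuple(float(v) for v in self.initial_densities)
        if len(x0) != self.n_seedings:
            raise ValueError("need one initial density per seeding")
        if any(v <= 0 for v in x0):
            raise ValueError("initial densities must be > 0")
        if self.obs_noise_sd < 0:
            raise ValueError("obs_noise_sd must be >= 0")
        object.__setattr__(self, "time_grid", t)
        object.__setattr__(self, "initial_densities", x0)


def synth_timeseries(params: GrowthParams | Sequence[GrowthParams],
                     design: AssayDesign) -> list[TimeSeries]:
    """Generate one TimeSeries per seeding condition from the growth law.

    Each seeding integrates the deterministic law from its initial density
    over the design time grid; each replicate then receives independent iid
    Gaussian observation noise (sd = ``design.obs_noise_sd``) on the
    densities, truncated at 0. Deterministic given ``design.seed``. A single
    hexad may be shared across seedings or one hexad supplied per seeding.
    """
    if isinstance(params, GrowthParams):
        hexads = [params] * design.n_seedings
    else:
        hexads = list(params)
        if len(hexads) != design.n_seedings:
            raise ValueError("need one GrowthParams per seeding (or a single shared one)")
    rng = np.random.default_rng(design.seed)
    times = np.asarray(design.time_grid)
    out: list[TimeSeries] = []
    for i, (p, x0) in enumerate(zip(hexads, design.initial_densities), start=1):
        traj = growth.solve_trajectory(p, x0, times)
        reps = traj.densities[None, :] + design.obs_noise_sd * rng.standard_normal(
            (design.n_replicates, times.size))
        np.clip(reps, 0.0, None, out=reps)
        if design.obs_noise_sd == 0.0:
            reps = np.broadcast_to(traj.densities, (design.n_replicates, times.size)).copy()
        out.append(TimeSeries(seeding_id=str(i), times=times, replicates=reps))
    return out


def save_timeseries(series: Sequence[TimeSeries], path: str | Path) -> None:
    """Write time series to the package CSV dialect."""
    rows = []
    for ts in series:
        for r in range(ts.n_replicates):
            for t, x in zip(ts.times, ts.replicates[r]):
                rows.append((t, x, r + 1, ts.seeding_id))
    df = pd.DataFrame(rows, columns=["time_h", "density", "replicate", "seeding"])
    df.to_csv(path, index=False)


def load_timeseries(path: str | Path) -> list[TimeSeries]:
    """Read time series from CSV, validating grid alignment across replicates."""
    df = pd.read_csv(path)
    required = ["time_h", "density", "replicate", "seeding"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"CSV is missing columns {missing}; expected header "
                         f"{','.join(required)}")
    if df["density"].isna().any() or df["time_h"].isna().any():
        row = int(df[df[["time_h", "density"]].isna().any(axis=1)].index[0]) + 2
        raise ValueError(f"malformed row at line {row}: non-numeric time or density")
    if (df["density"] < 0).any():
        row = int(df.index[df["density"] < 0][0]) + 2
        raise ValueError(f"negative density at line {row}")

    out: list[TimeSeries] = []
    for seeding, g in df.groupby("seeding", sort=True):
        rep_ids = sorted(g["replicate"].unique())
        grids = []
        for rid in rep_ids:
            sub = g[g["replicate"] == rid]
            t = sub["time_h"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                bad = int(sub.index[np.argmin(np.diff(t) > 0) + 1]) + 2
                raise ValueError(f"non-monotone time column at line {bad} "
                                 f"(seeding {seeding}, replicate {rid})")
            grids.append((t, sub["density"].to_numpy(dtype=float)))
        t0 = grids[0][0]
        for (t, _), rid in zip(grids[1:], rep_ids[1:]):
            if t.shape != t0.shape or not np.allclose(t, t0):
                raise ValueError(f"replicate {rid} of seeding {seeding} is on a "
                                 "mismatched time grid")
        reps = np.vstack([x for _, x in grids])
        out.append(TimeSeries(seeding_id=str(seeding), times=t0, replicates=reps))
    return out


# ---------------------------------------------------------------------------
# frozen presets
# ---------------------------------------------------------------------------

# single source: the structured-config file shipped inside the package
PRESETS_FILE = Path(__file__).with_name("presets.yaml")


@dataclass(frozen=True)
class Presets:
    """Frozen published constants: search grids, fitted hexads, reference densities."""

    table1_grids: dict[int, ParameterGrid]
    table2_hexads: dict[int, GrowthParams]
    table3_reference: dict[int, dict[str, float]]


def presets() -> Presets:
    """The published parameter grids (per seeding), fitted hexads, and
    reference threshold/MSSCD/inflection densities, loaded from the
    ``presets.yaml`` config shipped with the package."""
    import yaml

    with open(PRESETS_FILE) as fh:
        raw = yaml.safe_load(fh)
    # the r_p grid of seeding 3 starts at 0.00, which the hexad validator
    # forbids as a fitted value but is legal as a search grid point;
    # ParameterGrid itself polices only ordering, not positivity.
    grids = {int(s): ParameterGrid.from_dict(g)
             for s, g in raw["table1_grids"].items()}
    hexads = {int(s): GrowthParams.from_dict(h)
              for s, h in raw["table2_hexads"].items()}
    ref = {int(s): {k: float(v) for k, v in r.items()}
           for s, r in raw["table3_reference"].items()}
    return Presets(table1_grids=grids, table2_hexads=hexads,
                   table3_reference=ref)
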