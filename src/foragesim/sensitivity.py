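"""Morris Elementary Effects screening over the simulator's parameters.

One-at-a-time global sensitivity analysis: r random trajectories through a
p-level grid on the unit hypercube, each trajectory perturbing every
parameter exactly once by +/- Delta = p/(2(p-1)) in rescaled units.  For
each parameter the elementary effects EE = (y(x + Delta e_i) - y(x))/Delta
are collected across trajectories; mu* (the mean |EE|, a main-effect
measure) and sigma (the standard deviation of EE, an interaction /
non-linearity measure) are reported in the units of the output because
Delta is expressed on the rescaled [0, 1] scale.

Three named scenarios bound the screened parameter space: ``general`` (the
full calibrated ranges), ``fast_slow`` (extraction-rate mean and the patch
regrowth interval restricted to the upper thirds of their ranges — fast
extraction, infrequent renewal, the high-depletability regime), and
``slow_fast`` (both restricted to their lower thirds).  Parameters screened
for pattern-matching only (quality sd, regrowth rate, movement noise, the
two detection radii) are held at mid-range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import MEE_PARAMS, PARAM_RANGES, SimulationConfig, midpoint

SCENARIOS = ("general", "fast_slow", "slow_fast")

#: Outputs screened for each scenario run.
OUTPUTS = ("mean_intake_rate", "mean_daily_distance", "monthly_intake_variance")


@dataclass
class MorrisDesign:
    """An r-trajectory, p-level one-at-a-time design on [0, 1]^k."""

    names: list[str]
    bounds: np.ndarray          # (k, 2) low/high on the natural scale
    r: int
    p: int
    delta: float
    X: np.ndarray               # (r*(k+1), k) points in rescaled [0, 1]
    steps: list[list[tuple[int, int]]]  # per trajectory: (param index, +/-1)

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def scaled(self) -> np.ndarray:
        """Design points on the natural parameter scale."""
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        return lo + self.X * (hi - lo)


@dataclass
class MorrisResult:
    """Per-parameter mu* and sigma for one output."""

    names: list[str]
    mu_star: np.ndarray
    sigma: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": self.names,
                             "mu_star": self.mu_star,
                             "sigma": self.sigma})

    def ranked(self) -> list[str]:
        """Parameter names by descending mu*."""
        order = np.argsort(self.mu_star)[::-1]
        return [self.names[i] for i in order]


def build_morris_design(ranges: Mapping[str, tuple[float, float]], r: int,
                        p: int, seed: int | np.random.Generator) -> MorrisDesign:
    """Sample r Morris trajectories on a p-level grid.

    Base points lie on the grid {0, 1/(p-1), ..., 1 - Delta}; each
    trajectory perturbs the parameters once each, in random order, by
    +Delta or -Delta (direction random where both stay in [0, 1]).
    Degenerate ranges (min = max) are excluded with a warning.
    """
    if r < 2:
        raise ValueError("r must be >= 2 (sigma needs two elementary effects)")
    if p < 2 or p % 2:
        raise ValueError("p must be an even integer >= 2")
    names, bounds = [], []
    for name, (lo, hi) in ranges.items():
        if lo == hi:
            warnings.warn(f"parameter {name!r} has a degenerate range "
                          f"[{lo}, {hi}]; excluded from the design",
                          stacklevel=2)
            continue
        names.append(name)
        bounds.append((lo, hi))
    if not names:
        raise ValueError("no non-degenerate parameters to screen")
    k = len(names)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    delta = p / (2.0 * (p - 1))
    levels = np.arange(p // 2) / (p - 1)  # base grid: x and x+delta in [0,1]

    rows = np.empty((r * (k + 1), k))
    steps: list[list[tuple[int, int]]] = []
    for t in range(r):
        x = levels[rng.integers(p // 2, size=k)].astype(float)
        order = rng.permutation(k)
        traj_steps: list[tuple[int, int]] = []
        rows[t * (k + 1)] = x
        for j, pi in enumerate(order):
            up_ok = x[pi] + delta <= 1.0 + 1e-12
            dn_ok = x[pi] - delta >= -1e-12
            if up_ok and dn_ok:
                direction = 1 if rng.random() < 0.5 else -1
            else:
                direction = 1 if up_ok else -1
            x = x.copy()
            x[pi] = min(1.0, max(0.0, x[pi] + direction * delta))
            rows[t * (k + 1) + j + 1] = x
            traj_steps.append((int(pi), direction))
        steps.append(traj_steps)

    return MorrisDesign(names, np.asarray(bounds, float), r, p, delta, rows,
                        steps)


def elementary_effects(design: MorrisDesign,
                       outputs: Sequence[float]) -> MorrisResult:
    """mu* and sigma per parameter from one output value per design row."""
    y = np.asarray(outputs, float)
    if y.shape != (design.n_rows,):
        raise ValueError(
            f"need one output per design row ({design.n_rows}), got {y.shape}")
    if np.isnan(y).any():
        missing = np.flatnonzero(np.isnan(y)).tolist()
        raise ValueError(f"missing outputs at design rows {missing}")
    k = design.k
    ee = np.empty((design.r, k))
    for t, traj in enumerate(design.steps):
        base = t * (k + 1)
        for j, (pi, direction) in enumerate(traj):
            dy = y[base + j + 1] - y[base + j]
            ee[t, pi] = direction * dy / design.delta
    return MorrisResult(design.names, np.abs(ee).mean(axis=0),
                        ee.std(axis=0, ddof=1))


# ---------------------------------------------------------------------------
# scenarios


def _third(lo: float, hi: float, which: str) -> tuple[float, float]:
    span = (hi - lo) / 3.0
    return (lo, lo + span) if which == "lower" else (hi - span, hi)


def scenario_ranges(name: str) -> dict[str, tuple[float, float]]:
    """Screened-parameter ranges for a named scenario."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    ranges = {p: PARAM_RANGES[p][:2] for p in MEE_PARAMS}
    if name == "fast_slow":
        ranges["extraction_rate_mean"] = _third(
            *PARAM_RANGES["extraction_rate_mean"][:2], "upper")
        ranges["patch_regrowth_interval"] = _third(
            *PARAM_RANGES["patch_regrowth_interval"][:2], "upper")
    elif name == "slow_fast":
        ranges["extraction_rate_mean"] = _third(
            *PARAM_RANGES["extraction_rate_mean"][:2], "lower")
        ranges["patch_regrowth_interval"] = _third(
            *PARAM_RANGES["patch_regrowth_interval"][:2], "lower")
    return ranges


#: Reduced desk-scale world: a 141-patch side (a quarter of the full area)
#: with abundance scaled by the same area ratio, preserving energy density
#: and agent density.  Runs keep the full 4,300-tick length: the regrowth
#: interval spans 500-3,000 ticks, so shortening the run would silence most
#: of that parameter's range.
REDUCED_SIDE = 141
REDUCED_TICKS = 4_300


def row_config(design: MorrisDesign, row: int, seed: int,
               reduced: bool = False,
               run_ticks: int | None = None) -> SimulationConfig:
    """Concrete configuration for one design row.  Integer parameters are
    rounded here, at evaluation time; the design matrix itself stays
    continuous."""
    values = design.scaled()[row]
    kwargs: dict[str, float] = {p: midpoint(p) for p in PARAM_RANGES}
    for name, v in zip(design.names, values):
        kwargs[name] = int(round(v)) if PARAM_RANGES[name][2] else float(v)
    cfg = SimulationConfig(**kwargs, seed=seed)
    if reduced:
        area_ratio = (REDUCED_SIDE / cfg.side) ** 2
        cfg = cfg.replace(side=REDUCED_SIDE,
                          abundance=cfg.abundance * area_ratio,
                          run_ticks=run_ticks or REDUCED_TICKS)
    elif run_ticks is not None:
        cfg = cfg.replace(run_ticks=run_ticks)
    return cfg


def run_scenario(name: str, r: int = 4, p: int = 8, seed: int = 0,
                 reduced: bool = True, run_ticks: int | None = None,
                 progress: Callable[[int, int], None] | None = None,
                 ) -> tuple[dict[str, MorrisResult], pd.DataFrame, MorrisDesign]:
    """Screen a named scenario: build the design, run the simulator on
    every row, and return Morris results for intake rate, daily distance
    and monthly intake variance, plus the raw per-row metrics table and
    the design itself."""
    from .scheduler import run_simulation

    design = build_morris_design(scenario_ranges(name), r, p, seed)
    ss = np.random.SeedSequence(seed)
    row_seeds = [int(s.generate_state(1)[0] % 2**31) for s in
                 ss.spawn(design.n_rows)]
    records = []
    for row in range(design.n_rows):
        cfg = row_config(design, row, row_seeds[row], reduced=reduced,
                         run_ticks=run_ticks)
        summary, _ = run_simulation(cfg)
        rec = {"row": row, **{n: design.scaled()[row][i]
                              for i, n in enumerate(design.names)},
               **summary.as_dict()}
        records.append(rec)
        if progress is not None:
            progress(row + 1, design.n_rows)
    table = pd.DataFrame.from_records(records)
    results = {out: elementary_effects(design, table[out].to_numpy())
               for out in OUTPUTS}
    return results, table, design
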