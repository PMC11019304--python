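"""Output statistics computed from run logs.

Four population-level outcomes summarize a run: the mean energy intake
rate (energy gained per tick, averaged across agents), the mean daily
distance traveled (patch-lengths per 24-tick day; one patch-length is
10 m), the mean per-agent variance of energy intake summed over fixed
windows (720 ticks ~ one month is the analyzed scale; 360 ticks is
recorded alongside), and the activity-budget ratio of ticks spent moving
to ticks spent eating.  Two pattern-matching flags compare the run against
ranges observed across living primates: daily path length 0.25-4.0 km and
a moving:eating ratio of 0.25-0.6.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .agents import Agent
from .landscape import PATCH_SCALE_M

if TYPE_CHECKING:  # pragma: no cover
    from .config import SimulationConfig

MONTH_TICKS = 720
BIWEEK_TICKS = 360

DAILY_KM_RANGE = (0.25, 4.0)
MOVING_EATING_RANGE = (0.25, 0.6)


@dataclass
class MetricsSummary:
    mean_intake_rate: float             # energy units / tick
    mean_daily_distance: float          # patch-lengths / day
    mean_daily_distance_m: float        # meters / day
    monthly_intake_variance: float      # energy units², 720-tick windows
    biweekly_intake_variance: float     # energy units², 360-tick windows
    moving_eating_ratio: float
    n_ratio_excluded: int               # agents with zero eating ticks
    pattern_daily_path: bool
    pattern_moving_eating: bool
    n_agents: int
    run_ticks: int

    @property
    def mean_daily_distance_km(self) -> float:
        return self.mean_daily_distance_m / 1000.0

    def as_dict(self) -> dict:
        return asdict(self)


def energy_intake_rate(agents: Sequence[Agent], ticks: int) -> float:
    """Population mean of (total energy gained / ticks)."""
    if ticks <= 0:
        raise ValueError("ticks must be positive")
    return float(np.mean([a.total_intake() / ticks for a in agents]))


def daily_distance(agents: Sequence[Agent], ticks: int,
                   ticks_per_day: int = 24) -> float:
    """Population mean distance traveled per day, in patch-lengths
    (multiply by 10 for meters)."""
    if ticks < ticks_per_day:
        raise ValueError("need at least one full day of ticks")
    days = ticks / ticks_per_day
    return float(np.mean([a.distance_traveled / days for a in agents]))


def windowed_intake_variance(agents: Sequence[Agent], window: int,
                             run_ticks: int) -> float:
    """Population mean of the per-agent sample variance of energy intake
    summed over complete non-overlapping windows of ``window`` ticks (the
    trailing partial window is discarded)."""
    n_win = run_ticks // window
    if n_win < 2:
        raise ValueError(
            f"run of {run_ticks} ticks has {n_win} complete {window}-tick "
            "windows; variance needs at least 2"
        )
    variances = []
    for a in agents:
        sums = np.zeros(n_win)
        if a.intake_ticks:
            t = np.asarray(a.intake_ticks)
            g = np.asarray(a.intake_gains)
            keep = t < n_win * window
            np.add.at(sums, t[keep] // window, g[keep])
        variances.append(sums.var(ddof=1))
    return float(np.mean(variances))


def moving_eating_ratio(agents: Sequence[Agent]) -> float:
    """Population mean of ticks_moving / ticks_eating, over agents that ate
    at least once (agents that never ate are excluded with a warning)."""
    ratios = [a.ticks_moving / a.ticks_eating for a in agents
              if a.ticks_eating > 0]
    excluded = len(agents) - len(ratios)
    if excluded:
        warnings.warn(f"{excluded} agent(s) never ate; excluded from the "
                      "moving:eating ratio", stacklevel=2)
    if not ratios:
        return 0.0
    return float(np.mean(ratios))


def pattern_match(summary: "MetricsSummary") -> tuple[bool, bool]:
    """(daily path length in 0.25-4.0 km, moving:eating ratio in 0.25-0.6),
    closed intervals."""
    km = summary.mean_daily_distance_m / 1000.0
    in_path = DAILY_KM_RANGE[0] <= km <= DAILY_KM_RANGE[1]
    in_ratio = (MOVING_EATING_RANGE[0] <= summary.moving_eating_ratio
                <= MOVING_EATING_RANGE[1])
    return in_path, in_ratio


def summarize(agents: Sequence[Agent], config: "SimulationConfig") -> MetricsSummary:
    """Full metrics summary of a finished run.  Variances are NaN when the
    run is too short for two complete windows (small fixtures)."""
    ticks = config.run_ticks
    if ticks <= 0 or not agents:
        return MetricsSummary(0.0, 0.0, 0.0, math.nan, math.nan, 0.0,
                              0, False, False, len(agents), ticks)
    intake = energy_intake_rate(agents, ticks)
    dist = (daily_distance(agents, ticks, config.ticks_per_day)
            if ticks >= config.ticks_per_day else 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ratio = moving_eating_ratio(agents)
    excluded = sum(1 for a in agents if a.ticks_eating == 0)

    def _var(window: int) -> float:
        try:
            return windowed_intake_variance(agents, window, ticks)
        except ValueError:
            return math.nan

    summary = MetricsSummary(
        mean_intake_rate=intake,
        mean_daily_distance=dist,
        mean_daily_distance_m=dist * PATCH_SCALE_M,
        monthly_intake_variance=_var(MONTH_TICKS),
        biweekly_intake_variance=_var(BIWEEK_TICKS),
        moving_eating_ratio=ratio,
        n_ratio_excluded=excluded,
        pattern_daily_path=False,
        pattern_moving_eating=False,
        n_agents=len(agents),
        run_ticks=ticks,
    )
    summary.pattern_daily_path, summary.pattern_moving_eating = pattern_match(summary)
    return summary
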