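"""Simulation configuration: the global parameter set and its slider ranges.

Fifteen parameters control gregariousness (target neighbors / target
distance), the resource landscape (abundance, per-capita energy, clump size,
patch quality, regrowth, extraction rate) and agent movement/sensing.
Defaults sit at the midpoint of each hypothesis-testing range, which is the
calibrated "general scenario" configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterator


class ConfigurationError(ValueError):
    """A parameter value violates its declared slider range."""


#: (low, high, integer?) for every slider parameter.  ``max_move`` uses the
#: hypothesis-testing range 25-50 (the pattern-matching range extended down
#: to 10).  The extraction-rate-mean upper bound is 14 energy units/tick.
PARAM_RANGES: dict[str, tuple[float, float, bool]] = {
    "tgt_neighbor": (0, 11, True),
    "tgt_distance": (1, 49, False),
    "abundance": (200_000, 1_200_000, False),
    "energy_per_capita": (4_000, 9_000, False),
    "clump_size": (0, 500, True),
    "qual_mean": (25, 150, True),
    "qual_sd": (1, 20, True),
    "regrowth_rate": (0.5, 1.0, False),
    "patch_regrowth_interval": (500, 3_000, True),
    "extraction_rate_mean": (2, 8, False),
    "extraction_rate_sd": (0, 3, False),
    "movement_noise": (10, 45, False),
    "max_move": (25, 50, False),
    "resource_detection_radius": (50, 100, False),
    "other_primate_detection_radius": (50, 100, False),
}

#: Parameters varied in hypothesis-testing sensitivity screens; the rest are
#: "pattern-matching only" and held at mid-range there.
MEE_PARAMS: tuple[str, ...] = (
    "tgt_neighbor",
    "tgt_distance",
    "abundance",
    "energy_per_capita",
    "clump_size",
    "qual_mean",
    "patch_regrowth_interval",
    "extraction_rate_mean",
    "extraction_rate_sd",
    "max_move",
)


def midpoint(name: str) -> float:
    """Midpoint of a parameter's range, rounded for integer parameters."""
    lo, hi, is_int = PARAM_RANGES[name]
    mid = (lo + hi) / 2
    return int(round(mid)) if is_int else mid


@dataclass
class SimulationConfig:
    """Full parameter set for one simulation run.

    One field per slider parameter, plus run-control fields (grid side,
    run length in ticks, ticks per simulated day, RNG seed).  Values are
    validated against :data:`PARAM_RANGES` by :meth:`validate`; test
    fixtures may construct out-of-range configs directly.
    """

    tgt_neighbor: int = 6
    tgt_distance: float = 25.0
    abundance: float = 700_000.0
    energy_per_capita: float = 6_500.0
    clump_size: int = 250
    qual_mean: int = 88
    qual_sd: int = 10
    regrowth_rate: float = 0.75
    patch_regrowth_interval: int = 1_750
    extraction_rate_mean: float = 5.0
    extraction_rate_sd: float = 1.5
    movement_noise: float = 27.5
    max_move: float = 37.5
    resource_detection_radius: float = 75.0
    other_primate_detection_radius: float = 75.0

    # run control (not slider parameters)
    side: int = 281
    run_ticks: int = 4_300
    ticks_per_day: int = 24
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        """Raise :class:`ConfigurationError` for out-of-range parameters."""
        for name, (lo, hi, is_int) in PARAM_RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                kind = "Integer" if is_int else "Value"
                raise ConfigurationError(
                    f"{name}={v!r} outside its range: {kind} between {lo} and {hi}"
                )
            if is_int and v != int(v):
                raise ConfigurationError(f"{name}={v!r} must be an integer")
        if self.abundance <= 0 or self.qual_mean <= 0:
            raise ConfigurationError("abundance and qual_mean must be positive")
        if self.side < 3 or self.run_ticks < 0 or self.ticks_per_day < 1:
            raise ConfigurationError("invalid run-control field")
        return self

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def param_items(self) -> Iterator[tuple[str, float]]:
        for name in PARAM_RANGES:
            yield name, getattr(self, name)


def general_config(**overrides) -> SimulationConfig:
    """The calibrated general-scenario configuration: every slider at the
    midpoint of its hypothesis-testing range."""
    kwargs = {name: midpoint(name) for name in PARAM_RANGES}
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
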