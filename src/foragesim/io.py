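"""Config files, CSV writers, and run manifests.

Configuration files are flat ``key = value`` text, one slider parameter
per line, using the slider names (hyphens and underscores are
interchangeable).  Unknown keys and out-of-range values are rejected;
omitted keys take the mid-range defaults.  Each run writes into a fresh
``run-NNN`` subdirectory containing a manifest (config snapshot, seed,
version, timings) from which the run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd

from .config import ConfigurationError, PARAM_RANGES, SimulationConfig

if TYPE_CHECKING:  # pragma: no cover
    from .metrics import MetricsSummary
    from .scheduler import SimulationState

@dataclasses.dataclass
class RunManifest:
    """Reproducibility record written alongside every run's outputs."""

    config: dict
    seed: int
    version: str
    started: float | None
    finished: float
    outputs: list[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


_RUN_CONTROL = ("side", "run_ticks", "ticks_per_day", "seed")
_INT_FIELDS = {"tgt_neighbor", "clump_size", "qual_mean", "qual_sd",
               "patch_regrowth_interval", *_RUN_CONTROL}


def _canon(key: str) -> str:
    return key.strip().lower().replace("-", "_")


def load_config(path: str | Path) -> SimulationConfig:
    """Parse and validate a flat key-value configuration file."""
    path = Path(path)
    kwargs: dict[str, float] = {}
    known = set(PARAM_RANGES) | set(_RUN_CONTROL)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ConfigurationError(
                f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = stripped.partition("=")
        name = _canon(key)
        if name not in known:
            raise ConfigurationError(f"{path}:{lineno}: unknown parameter "
                                     f"{key.strip()!r}")
        try:
            num = float(value.strip())
        except ValueError as exc:
            raise ConfigurationError(
                f"{path}:{lineno}: could not parse value {value.strip()!r}"
            ) from exc
        kwargs[name] = int(num) if name in _INT_FIELDS else num
    return SimulationConfig(**kwargs).validate()


def save_config(config: SimulationConfig, path: str | Path) -> Path:
    """Write a config as a flat key-value file that round-trips through
    :func:`load_config`."""
    path = Path(path)
    lines = [f"{name} = {value!r}" for name, value in
             sorted(config.as_dict().items())]
    path.write_text("\n".join(lines) + "\n")
    return path


def fresh_run_dir(out_dir: str | Path) -> Path:
    """Next unused ``run-NNN`` subdirectory of ``out_dir`` (no clobbering)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = 0
    while (out_dir / f"run-{n:03d}").exists():
        n += 1
    run_dir = out_dir / f"run-{n:03d}"
    run_dir.mkdir()
    return run_dir


def write_outputs(state: "SimulationState", summary: "MetricsSummary",
                  out_dir: str | Path, config: SimulationConfig,
                  started: float | None = None) -> Path:
    """Write metrics, agent, fight-log and landscape CSVs plus a manifest
    into a fresh run subdirectory; returns that directory."""
    from . import __version__

    run_dir = fresh_run_dir(out_dir)

    metrics_row = {**config.as_dict(), **summary.as_dict()}
    pd.DataFrame([metrics_row]).to_csv(run_dir / "metrics.csv", index=False)

    pd.DataFrame([{
        "id": a.id, "x": a.xcor, "y": a.ycor, "heading": a.heading,
        "rhp": a.rhp, "xp": a.xp, "stored_energy": a.stored_energy,
        "distance_traveled": a.distance_traveled,
        "ticks_eating": a.ticks_eating, "ticks_moving": a.ticks_moving,
    } for a in state.agents]).to_csv(run_dir / "agents.csv", index=False)

    if state.fight_log:
        pd.DataFrame([dataclasses.asdict(rec) for rec in state.fight_log]
                     ).to_csv(run_dir / "fights.csv", index=False)

    if state.trace:
        pd.DataFrame(state.trace, columns=[
            "tick", "id", "x", "y", "action", "energy_gained",
            "stored_energy", "xp"]).to_csv(run_dir / "timeseries.csv",
                                           index=False)

    state.landscape.to_dataframe().to_csv(run_dir / "landscape.csv",
                                          index=False)
    state.landscape.save_matrix(run_dir / "penergy_matrix.txt")
    save_config(config, run_dir / "config.cfg")

    manifest = RunManifest(
        config=config.as_dict(),
        seed=config.seed,
        version=__version__,
        started=started,
        finished=time.time(),
        outputs=sorted(p.name for p in run_dir.iterdir()),
    )
    (run_dir / "manifest.json").write_text(manifest.to_json())
    return run_dir


def write_morris_outputs(design, results, table, out_dir: str | Path,
                         plot: bool = True) -> Path:
    """Write the design matrix, per-row metrics, per-output mu*/sigma CSVs
    and (optionally) mu*-sigma scatter plots."""
    run_dir = fresh_run_dir(out_dir)
    pd.DataFrame(design.scaled(), columns=design.names).to_csv(
        run_dir / "design.csv", index=False)
    table.to_csv(run_dir / "metrics.csv", index=False)
    for out_name, res in results.items():
        res.to_dataframe().to_csv(run_dir / f"morris_{out_name}.csv",
                                  index=False)
        if plot:
            plot_mu_star_sigma(res.to_dataframe(), out_name,
                               run_dir / f"morris_{out_name}.png")
    return run_dir


def plot_mu_star_sigma(df: pd.DataFrame, output_name: str,
                       path: str | Path) -> None:
    """mu*-sigma scatter, one labeled point per parameter."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(df["mu_star"], df["sigma"])
    for _, row in df.iterrows():
        ax.annotate(row["parameter"], (row["mu_star"], row["sigma"]),
                    fontsize=8, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel(r"$\mu^*$ (main effect, output units)")
    ax.set_ylabel(r"$\sigma$ (interactions/non-linearity, output units)")
    ax.set_title(output_name)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
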