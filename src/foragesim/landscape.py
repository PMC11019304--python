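"""Resource landscape: a wrapping square grid of depletable, renewing patches.

The world is a torus of ``side`` x ``side`` patches (default 281, i.e.
78,961 cells), each representing roughly a 10 m x 10 m area -- a single tree
canopy.  Energy is laid down at setup in "clumps": compact groups of
resource patches grown around uniformly random centers until the total
allocated energy reaches the ``abundance`` parameter.  Each resource patch
carries a fixed maximum energy content (``quality``), a current content
(``penergy``) that agents deplete, and a fixed per-tick ``extraction_rate``.
On a longer timescale the whole landscape regrows at once: every resource
patch regains a fraction of its quality each regrowth interval, capped at
quality.

Internally the grid is stored as flat numpy arrays (row-major index
``pycor * side + pxcor``); :class:`Patch` is a lightweight read-only view
used at the API surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .config import ConfigurationError

if TYPE_CHECKING:  # pragma: no cover
    from .config import SimulationConfig

#: Meters per patch side.
PATCH_SCALE_M = 10.0

#: Lower truncation for per-patch extraction-rate draws (energy units/tick).
MIN_EXTRACTION_RATE = 0.1


class SaturationError(RuntimeError):
    """The grid filled up before the requested abundance could be placed."""


@dataclass(frozen=True)
class Patch:
    """Read-only snapshot of one grid cell."""

    pxcor: int
    pycor: int
    penergy: float
    quality: float
    extraction_rate: float


class Landscape:
    """Array-backed torus grid of patches.

    Attributes
    ----------
    side : int
        Grid dimension; total patch count is ``side ** 2``.
    quality, penergy, extraction : numpy.ndarray
        Flat float arrays of length ``side ** 2``.
    res_idx : numpy.ndarray
        Flat indices of resource patches (``quality > 0``); fixed after
        initialization.
    total_initial_energy : float
        Energy distributed at setup.
    """

    def __init__(self, side: int):
        if side < 3:
            raise ConfigurationError(f"side={side} too small (need >= 3)")
        self.side = int(side)
        n = self.side * self.side
        self.quality = np.zeros(n)
        self.penergy = np.zeros(n)
        self.extraction = np.zeros(n)
        self.res_idx = np.empty(0, dtype=np.intp)
        self.total_initial_energy = 0.0
        self._nbr: np.ndarray | None = None
        # resource-patch coordinate caches, filled by _finalize()
        self.res_x = np.empty(0)
        self.res_y = np.empty(0)

    # -- indexing helpers ------------------------------------------------
    def index(self, pxcor: int, pycor: int) -> int:
        return (pycor % self.side) * self.side + (pxcor % self.side)

    def coords(self, idx: int) -> tuple[int, int]:
        py, px = divmod(int(idx), self.side)
        return px, py

    def patch_at(self, x: float, y: float) -> Patch:
        """The patch containing continuous position (x, y)."""
        px = int(math.floor(x)) % self.side
        py = int(math.floor(y)) % self.side
        i = py * self.side + px
        return Patch(px, py, float(self.penergy[i]), float(self.quality[i]),
                     float(self.extraction[i]))

    def patch(self, idx: int) -> Patch:
        px, py = self.coords(idx)
        return Patch(px, py, float(self.penergy[idx]), float(self.quality[idx]),
                     float(self.extraction[idx]))

    # -- construction ----------------------------------------------------
    def set_patch(self, pxcor: int, pycor: int, quality: float,
                  extraction_rate: float, penergy: float | None = None) -> None:
        """Hand-build one resource patch (fixtures/tests); call
        :meth:`finalize` afterwards."""
        i = self.index(pxcor, pycor)
        self.quality[i] = quality
        self.penergy[i] = quality if penergy is None else penergy
        self.extraction[i] = extraction_rate

    def finalize(self) -> "Landscape":
        self.res_idx = np.flatnonzero(self.quality > 0)
        ys, xs = np.divmod(self.res_idx, self.side)
        self.res_x = xs + 0.5  # patch centers
        self.res_y = ys + 0.5
        self.total_initial_energy = float(self.penergy.sum())
        return self

    # -- neighborhoods ---------------------------------------------------
    def neighbor_indices(self) -> np.ndarray:
        """(n_patches, 8) flat indices of each cell's Moore neighborhood,
        torus-wrapped.  Built lazily and cached."""
        if self._nbr is None:
            s = self.side
            ys, xs = np.divmod(np.arange(s * s), s)
            cols = []
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dx == 0 and dy == 0:
                        continue
                    cols.append(((ys + dy) % s) * s + (xs + dx) % s)
            self._nbr = np.stack(cols, axis=1)
        return self._nbr

    def total_energy(self) -> float:
        return float(self.penergy.sum())

    def save_matrix(self, path, field: str = "penergy") -> None:
        """Write one per-patch field as a dense side x side text matrix
        (rows are pycor, columns pxcor) for plotting."""
        if field not in ("penergy", "quality", "extraction"):
            raise ValueError(f"unknown field {field!r}")
        grid = getattr(self, field).reshape(self.side, self.side)
        np.savetxt(path, grid, fmt="%.6g")

    def to_dataframe(self):
        """Snapshot of all resource patches as a pandas DataFrame."""
        import pandas as pd

        ys, xs = np.divmod(self.res_idx, self.side)
        return pd.DataFrame({
            "pxcor": xs, "pycor": ys,
            "quality": self.quality[self.res_idx],
            "penergy": self.penergy[self.res_idx],
            "extraction_rate": self.extraction[self.res_idx],
        })


def torus_distance(a, b, side: int):
    """Euclidean distance between points on the torus, using the minimal
    wrapped displacement per axis.  Accepts scalars or numpy arrays."""
    dx = np.abs(np.asarray(a[0]) - np.asarray(b[0]))
    dy = np.abs(np.asarray(a[1]) - np.asarray(b[1]))
    dx = np.minimum(dx, side - dx)
    dy = np.minimum(dy, side - dy)
    d = np.hypot(dx, dy)
    return float(d) if np.ndim(d) == 0 else d


def neighboring_patches(p: Patch, landscape: Landscape) -> list[Patch]:
    """The Moore (8-cell) neighborhood of a patch, torus-wrapped."""
    i = landscape.index(p.pxcor, p.pycor)
    return [landscape.patch(j) for j in landscape.neighbor_indices()[i]]


def _sorted_offsets(side: int) -> tuple[np.ndarray, np.ndarray]:
    """All (dx, dy) grid offsets sorted by wrapped distance from the origin
    (ties: dy, then dx).  Defines the deterministic clump fill order."""
    half = side // 2
    rng_ax = np.arange(-half, side - half)
    dx, dy = np.meshgrid(rng_ax, rng_ax)
    dx = dx.ravel()
    dy = dy.ravel()
    wx = np.minimum(np.abs(dx), side - np.abs(dx))
    wy = np.minimum(np.abs(dy), side - np.abs(dy))
    d2 = wx * wx + wy * wy
    order = np.lexsort((dx, dy, d2))
    return dx[order], dy[order]


def _nearest_empty(center: int, n: int, filled: np.ndarray,
                   ox: np.ndarray, oy: np.ndarray, side: int) -> np.ndarray:
    """Flat indices of the n nearest not-yet-filled cells to ``center``,
    scanning the precomputed offset order in growing chunks."""
    cy, cx = divmod(center, side)
    total = side * side
    out: list[np.ndarray] = []
    got = 0
    start = 0
    chunk = max(64, 4 * n)
    while start < total and got < n:
        end = min(total, start + chunk)
        idx = ((cy + oy[start:end]) % side) * side + (cx + ox[start:end]) % side
        empties = idx[~filled[idx]]
        if empties.size:
            out.append(empties[: n - got])
            got += min(empties.size, n - got)
        start = end
        chunk *= 2
    return np.concatenate(out) if out else np.empty(0, dtype=np.intp)


def generate_landscape(config: "SimulationConfig", rng: np.random.Generator) -> Landscape:
    """Allocate energy to the grid in clumps until ``abundance`` is reached.

    Clumps are created one at a time: a uniformly random center cell, a
    patch count drawn from Normal(clump_size, max(1, 0.1 * clump_size))
    (rounded, floored at 1), and members filled in order of torus distance
    from the center, skipping already-filled cells.  Each member gets an
    integer quality ~ Normal(qual_mean, qual_sd) truncated below at 1 (and
    penergy = quality) plus an extraction rate ~ Normal truncated below at
    0.1.  Allocation stops as soon as the running total reaches abundance,
    so the overshoot is less than one patch's quality; energy a saturated
    clump region cannot hold is simply carried into the next clump.
    """
    if config.abundance <= 0 or config.qual_mean <= 0:
        raise ConfigurationError("abundance and qual_mean must be positive")

    side = config.side
    land = Landscape(side)
    ox, oy = _sorted_offsets(side)
    filled = np.zeros(side * side, dtype=bool)

    clump_sd = max(1.0, 0.1 * config.clump_size)
    total = 0.0
    while total < config.abundance:
        if filled.all():
            raise SaturationError(
                f"grid saturated with {config.abundance - total:.1f} "
                "energy units left to place"
            )
        center = int(rng.integers(side * side))
        n = max(1, int(round(rng.normal(config.clump_size, clump_sd))))
        cells = _nearest_empty(center, n, filled, ox, oy, side)
        if cells.size == 0:
            continue
        quals = np.maximum(1.0, np.rint(
            rng.normal(config.qual_mean, config.qual_sd, cells.size)))
        # stop mid-clump at the patch that pushes the total past abundance
        cum = total + np.cumsum(quals)
        cut = min(int(np.searchsorted(cum, config.abundance)) + 1, cells.size)
        cells, quals = cells[:cut], quals[:cut]
        rates = np.maximum(MIN_EXTRACTION_RATE, rng.normal(
            config.extraction_rate_mean, config.extraction_rate_sd, cells.size))
        land.quality[cells] = quals
        land.penergy[cells] = quals
        land.extraction[cells] = rates
        filled[cells] = True
        total = float(cum[cut - 1])

    return land.finalize()


def regrow(landscape: Landscape, regrowth_rate: float, tick: int,
           interval: int) -> Landscape:
    """Global regrowth: on ticks that are positive multiples of ``interval``
    every resource patch gains ``regrowth_rate * quality``, capped at
    quality.  Mutates and returns the landscape."""
    if interval < 1:
        raise ConfigurationError(f"interval={interval} must be >= 1")
    if tick > 0 and tick % interval == 0:
        idx = landscape.res_idx
        q = landscape.quality[idx]
        landscape.penergy[idx] = np.minimum(
            q, landscape.penergy[idx] + regrowth_rate * q)
    return landscape
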