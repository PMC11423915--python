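"""Synthetic laminae, division simulations and growth series with known truth.

Early kelp sporophyte embryos grow as flat monolayers of roughly cuboid
cells arranged in rows and columns; embryos attached to the maternal stalk
stay elongated (blade l/w up to ~3.5) while stalk-severed ones grow
disc-like with more irregular cells.  This module fabricates such tissues
with controllable geometry so that every analysis stage can be validated
against an analytically known ground truth:

* :func:`generate_lamina` — a jittered rectangular tessellation (8–300
  quadrilateral cells), optional blade elongation shaping and elliptical
  masking; shared walls between neighbouring cells are emitted as duplicated
  but exactly coincident polylines, matching how per-cell manual tracing is
  ingested.
* :func:`simulate_division_growth` — an event-driven division simulator on a
  unit lattice.  Cells carry gamma-distributed cycle times (mean 26 h by
  default); the first division is always transverse, and longitudinal
  divisions are only permitted once the embryo reaches a mode-dependent cell
  count (8 for intact embryos, 2 for severed ones), which reproduces the
  direction of the intact-vs-severed shape phenotype.
* :func:`generate_growth_series` — exponential cell-count series with
  multiplicative observation noise, for exercising the growth regression.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np

from .growth import GrowthSeries
from .segio import CellContour, Lamina

__all__ = [
    "LaminaSpec",
    "DivisionSimSpec",
    "LaminaGroundTruth",
    "DivisionEvent",
    "generate_lamina",
    "simulate_division_growth",
    "generate_growth_series",
]

#: Default target cell side (µm), a typical early-embryo cell size.
DEFAULT_CELL_SIZE_UM = 8.0

#: Default mean cell-cycle time (h).
DEFAULT_MEAN_CYCLE_H = 26.0


@dataclass(frozen=True)
class LaminaSpec:
    """Recipe for a jittered grid lamina."""

    rows: int = 6
    cols: int = 6
    cell_size: float = DEFAULT_CELL_SIZE_UM
    jitter: float = 0.0  # vertex displacement as a fraction of cell_size, < 0.5
    elongation_target: float | None = None  # stretch rows axis to this blade l/w
    mask: str = "none"  # none | ellipse
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if not (0.0 <= self.jitter < 0.5):
            raise ValueError("jitter must be in [0, 0.5) to keep cells simple")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.elongation_target is not None and self.elongation_target < 1.0:
            raise ValueError("elongation_target must be >= 1")
        if self.mask not in ("none", "ellipse"):
            raise ValueError(f"unknown mask {self.mask!r}")


@dataclass(frozen=True)
class LaminaGroundTruth:
    """Analytic truth for a generated lamina, derived from the construction.

    Per-cell shape values (elongation, rectangularity) are exact only for
    jitter = 0, where every cell is a perfect rectangle; areas and the
    adjacency are exact for any jitter because they follow directly from the
    constructed lattice.
    """

    cell_area: dict[str, float]
    cell_perimeter: dict[str, float] | None
    cell_elongation: dict[str, float] | None
    cell_rectangularity: dict[str, float] | None
    adjacency: set[frozenset]
    neighbour_counts: dict[str, int]
    shared_wall: dict[frozenset, float]
    blade_main_length: float | None
    blade_secondary_length: float | None
    blade_lw: float | None
    blade_angle: float | None


def _shoelace(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def generate_lamina(spec: LaminaSpec) -> tuple[Lamina, LaminaGroundTruth]:
    """Build a lamina of rows × cols quadrilateral cells plus its ground truth.

    The lattice runs with columns along x and rows along y (the apico-basal
    axis), so an r×1 spec is a phase-I-like stack.  Each lattice vertex is
    jittered once and shared by all adjacent cells, so duplicated walls are
    exactly coincident.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    sx = spec.cell_size
    sy = spec.cell_size
    if spec.elongation_target is not None:
        # stretch the rows (y) axis so the full-grid blade l/w hits the target
        sy = spec.elongation_target * spec.cols * sx / spec.rows
    # lattice vertices, shape (cols+1, rows+1, 2)
    gx, gy = np.meshgrid(
        np.arange(spec.cols + 1) * sx, np.arange(spec.rows + 1) * sy, indexing="ij"
    )
    lattice = np.stack([gx, gy], axis=-1)
    if spec.jitter > 0:
        lattice = lattice + rng.uniform(
            -spec.jitter * min(sx, sy),
            spec.jitter * min(sx, sy),
            size=lattice.shape,
        )

    if spec.mask == "ellipse":
        cx, cy = spec.cols * sx / 2.0, spec.rows * sy / 2.0
        keep = {
            (r, c)
            for r in range(spec.rows)
            for c in range(spec.cols)
            if ((c + 0.5) * sx - cx) ** 2 / cx**2 + ((r + 0.5) * sy - cy) ** 2 / cy**2
            <= 1.0
        }
        if not keep:
            keep = {(spec.rows // 2, spec.cols // 2)}
    else:
        keep = {(r, c) for r in range(spec.rows) for c in range(spec.cols)}

    cells: list[CellContour] = []
    areas: dict[str, float] = {}
    perims: dict[str, float] | None = {} if spec.jitter == 0 else None
    elong: dict[str, float] | None = {} if spec.jitter == 0 else None
    rect: dict[str, float] | None = {} if spec.jitter == 0 else None
    index: dict[tuple[int, int], str] = {}
    for r in range(spec.rows):
        for c in range(spec.cols):
            if (r, c) not in keep:
                continue
            cid = f"r{r:02d}c{c:02d}"
            index[(r, c)] = cid
            quad = np.array(
                [
                    lattice[c, r],
                    lattice[c + 1, r],
                    lattice[c + 1, r + 1],
                    lattice[c, r + 1],
                ]
            )
            cells.append(CellContour(cell_id=cid, vertices=quad))
            areas[cid] = _shoelace(quad) if spec.jitter > 0 else sx * sy
            if spec.jitter == 0:
                perims[cid] = 2.0 * (sx + sy)
                elong[cid] = max(sx, sy) / min(sx, sy)
                rect[cid] = 1.0

    adjacency: set[frozenset] = set()
    shared: dict[frozenset, float] = {}
    ncounts: dict[str, int] = {cid: 0 for cid in index.values()}
    for (r, c), cid in index.items():
        for dr, dc, wall in ((0, 1, sy), (1, 0, sx)):
            other = index.get((r + dr, c + dc))
            if other is None:
                continue
            pair = frozenset((cid, other))
            adjacency.add(pair)
            if spec.jitter == 0:
                shared[pair] = wall
            else:
                a, b = lattice[c + dc, r + dr], lattice[c + dc + (1 - dc), r + dr + (1 - dr)]
                shared[pair] = float(np.hypot(*(a - b)))
            ncounts[cid] += 1
            ncounts[other] += 1

    if spec.jitter == 0 and spec.mask == "none":
        length, width = spec.rows * sy, spec.cols * sx
        if length >= width:
            main, secondary, angle = length, width, math.pi / 2.0
        else:
            main, secondary, angle = width, length, 0.0
        lw = main / secondary
    else:
        main = secondary = lw = angle = None

    lamina = Lamina(embryo_id=f"synthetic-{spec.seed}", cells=tuple(cells))
    truth = LaminaGroundTruth(
        cell_area=areas,
        cell_perimeter=perims,
        cell_elongation=elong,
        cell_rectangularity=rect,
        adjacency=adjacency,
        neighbour_counts=ncounts,
        shared_wall=shared,
        blade_main_length=main,
        blade_secondary_length=secondary,
        blade_lw=lw,
        blade_angle=angle,
    )
    return lamina, truth


# ---------------------------------------------------------------------------
# division simulation


@dataclass(frozen=True)
class DivisionSimSpec:
    """Recipe for an event-driven embryo division simulation."""

    mode: str = "intact"  # intact | severed
    n_target_cells: int = 64
    mean_cycle_h: float = DEFAULT_MEAN_CYCLE_H
    cycle_cv: float = 0.2
    longitudinal_onset: int | None = None  # default: 8 intact, 2 severed
    p_longitudinal: float = 0.5  # once permitted
    cell_size: float = DEFAULT_CELL_SIZE_UM
    shape_jitter: float = 0.12  # lattice-vertex displacement, fraction of cell_size
    sample_step_h: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("intact", "severed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_target_cells < 2:
            raise ValueError("n_target_cells must be >= 2")
        if self.mean_cycle_h <= 0 or self.cycle_cv < 0:
            raise ValueError("cycle parameters out of range")

    @property
    def onset(self) -> int:
        if self.longitudinal_onset is not None:
            return self.longitudinal_onset
        return 8 if self.mode == "intact" else 2


@dataclass(frozen=True)
class DivisionEvent:
    time_h: float
    orientation: str  # transverse | longitudinal
    n_cells_after: int
    plane_angle: float  # radians; transverse plane lies along x (0), longitudinal along y


def _draw_cycle(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv == 0:
        return mean
    k = 1.0 / cv**2
    return float(rng.gamma(k, mean / k))


def _vertex_offset(x: int, y: int, seed: int, amplitude: float) -> np.ndarray:
    """Deterministic jitter for lattice vertex (x, y): every cell touching the
    vertex sees the same displacement, so duplicated walls stay coincident."""
    if amplitude == 0.0:
        return np.zeros(2)
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, x + 1_000_003, y + 1_000_003])
    )
    return rng.uniform(-amplitude, amplitude, 2)


def _occupancy_lamina(
    sites: dict[tuple[int, int], int], s: float, embryo_id: str, seed: int, jitter: float
) -> Lamina:
    amp = jitter * s
    cache: dict[tuple[int, int], np.ndarray] = {}

    def vert(x: int, y: int) -> np.ndarray:
        if (x, y) not in cache:
            cache[(x, y)] = np.array([x * s, y * s]) + _vertex_offset(x, y, seed, amp)
        return cache[(x, y)]

    cells = []
    for (x, y), cid in sorted(sites.items(), key=lambda kv: kv[1]):
        quad = np.array([vert(x, y), vert(x + 1, y), vert(x + 1, y + 1), vert(x, y + 1)])
        cells.append(CellContour(cell_id=f"c{cid:03d}", vertices=quad))
    return Lamina(embryo_id=embryo_id, cells=tuple(cells))


def simulate_division_growth(
    spec: DivisionSimSpec,
) -> tuple[list[Lamina], GrowthSeries, list[DivisionEvent]]:
    """Simulate embryo growth by successive cell divisions on a unit lattice.

    Cells occupy integer lattice sites (x medio-lateral, y apico-basal) and
    divide after gamma-distributed cycle times.  A transverse division places
    the daughter at ±y, a longitudinal one at ±x; occupied sites are shoved
    outward along the division direction, which keeps the tissue a compact
    monolayer.  The first division is always transverse; longitudinal planes
    are permitted only from ``spec.onset`` cells on (8 intact, 2 severed) and
    then occur with probability ``p_longitudinal``; no oblique planes exist.

    Returns snapshot laminae (at each doubling of cell count and at the end),
    the sampled :class:`GrowthSeries` with t0 flagged at the first
    longitudinal division, and the division-event log.
    """
    rng = np.random.default_rng(spec.seed)
    sites: dict[tuple[int, int], int] = {(0, 0): 0}
    positions: dict[int, tuple[int, int]] = {0: (0, 0)}
    heap: list[tuple[float, int]] = [(_draw_cycle(rng, spec.mean_cycle_h, spec.cycle_cv), 0)]
    next_id = 1
    events: list[DivisionEvent] = []
    snapshots: list[Lamina] = []
    next_snapshot = 2
    t_first_long: float | None = None
    t = 0.0

    def shove(start: tuple[int, int], d: tuple[int, int]) -> None:
        chain = []
        p = start
        while p in sites:
            chain.append(p)
            p = (p[0] + d[0], p[1] + d[1])
        for p in reversed(chain):
            cid = sites.pop(p)
            q = (p[0] + d[0], p[1] + d[1])
            sites[q] = cid
            positions[cid] = q

    while len(sites) < spec.n_target_cells:
        t, mother = heapq.heappop(heap)
        n = len(sites)
        if n == 1 or n < spec.onset:
            orientation = "transverse"
        else:
            orientation = "longitudinal" if rng.random() < spec.p_longitudinal else "transverse"
        d = (0, 1) if orientation == "transverse" else (1, 0)
        if rng.random() < 0.5:
            d = (-d[0], -d[1])
        mx, my = positions[mother]
        target = (mx + d[0], my + d[1])
        if target in sites:
            shove(target, d)
        sites[target] = next_id
        positions[next_id] = target
        if orientation == "longitudinal" and t_first_long is None:
            t_first_long = t
        events.append(
            DivisionEvent(
                time_h=t,
                orientation=orientation,
                n_cells_after=len(sites),
                plane_angle=0.0 if orientation == "transverse" else math.pi / 2.0,
            )
        )
        for cid in (mother, next_id):
            heapq.heappush(heap, (t + _draw_cycle(rng, spec.mean_cycle_h, spec.cycle_cv), cid))
        next_id += 1
        if len(sites) >= next_snapshot:
            snapshots.append(
                _occupancy_lamina(
                    sites, spec.cell_size, f"{spec.mode}-{spec.seed}-n{len(sites)}",
                    spec.seed, spec.shape_jitter,
                )
            )
            next_snapshot *= 2
    if not snapshots or snapshots[-1].n_cells != len(sites):
        snapshots.append(
            _occupancy_lamina(
                sites, spec.cell_size, f"{spec.mode}-{spec.seed}-n{len(sites)}",
                spec.seed, spec.shape_jitter,
            )
        )

    # sample the count trajectory every sample_step_h
    div_times = np.array([e.time_h for e in events])
    t_end = float(div_times[-1])
    sample_t = np.arange(0.0, t_end + spec.sample_step_h, spec.sample_step_h)
    counts = 1 + np.searchsorted(div_times, sample_t, side="right")
    t0_index = None
    if t_first_long is not None:
        t0_index = int(np.searchsorted(sample_t, t_first_long, side="left"))
        t0_index = min(t0_index, sample_t.size - 1)
    series = GrowthSeries(
        embryo_id=f"{spec.mode}-{spec.seed}",
        times_h=sample_t,
        n_cells=counts,
        t0_index=t0_index,
        stage_group="intact" if spec.mode == "intact" else "E2",
    )
    return snapshots, series, events


def generate_growth_series(
    doubling_h: float = DEFAULT_MEAN_CYCLE_H,
    duration_h: float = 120.0,
    step_h: float = 2.0,
    noise_cv: float = 0.0,
    n0_at_t0: float = 8.0,
    seed: int | None = None,
    embryo_id: str = "synthetic-growth",
) -> GrowthSeries:
    """Exponential cell-count series N(t) = N0 · 2^(t/doubling_h).

    Times span [−48 h, −48 h + duration_h] with the t0 observation (phase
    I→II transition) flagged at t = 0; ``noise_cv`` applies multiplicative
    log-normal observation noise (counts are then made non-decreasing, since
    cells never merge).  Noiseless output is exact; fixed seeds reproduce.
    """
    if doubling_h <= 0:
        raise ValueError("doubling_h must be positive")
    times = np.arange(0.0, duration_h + 0.5 * step_h, step_h) - 48.0
    counts = n0_at_t0 * np.power(2.0, times / doubling_h)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        counts = counts * rng.lognormal(-0.5 * sigma**2, sigma, size=counts.size)
        counts = np.maximum.accumulate(np.maximum(counts, 1.0))
    t0_index = int(np.argmin(np.abs(times)))
    return GrowthSeries(
        embryo_id=embryo_id, times_h=times, n_cells=counts, t0_index=t0_index
    )
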