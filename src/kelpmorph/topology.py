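"""Tissue topology: the cell-neighbour graph from contour geometry.

Each cell is traced as its own closed outline, so the wall between two
adjacent cells appears twice — once per cell — and is coincident only up to
tracing precision.  Two cells are neighbours when they share at least
``min_shared`` micrometres of wall (default 0.2 µm = 200 nm, adjustable),
where "shared" means the stretch of one cell's boundary that runs within a
small proximity tolerance of the other's.

The shared length is measured as the length of the *projection onto b's
boundary* of the portion of a's boundary lying within ``proximity_tol`` of
b.  Projecting is what makes the measure honest at corners: near a shared
corner, short stretches of a's other walls come within tolerance of b, but
they all project onto (essentially) the corner point and contribute no
length.  Coincident walls project isometrically and measure exactly.  The
two directed measurements are averaged, which makes the measure symmetric.
"""

from __future__ import annotations

import itertools
from collections import Counter

import networkx as nx
import numpy as np
import shapely
from shapely.geometry import LineString

from .segio import CellContour, Lamina

__all__ = [
    "DEFAULT_MIN_SHARED_UM",
    "DEFAULT_PROXIMITY_TOL_UM",
    "shared_wall_length",
    "neighbour_graph",
    "neighbour_count_distribution",
    "binned_neighbour_counts",
    "NEIGHBOUR_BINS",
]

#: Minimum shared wall for two cells to count as neighbours (µm): 200 nm.
DEFAULT_MIN_SHARED_UM = 0.2

#: How far apart duplicated traces of the same wall may sit (µm).
DEFAULT_PROXIMITY_TOL_UM = 0.05

#: Sampling step, as a fraction of proximity_tol, used when measuring the
#: projected length of near-coincident (not exactly coincident) wall runs.
_SAMPLE_STEP_FRAC = 0.5

#: Histogram bins used for the neighbour-count contingency tests.
NEIGHBOUR_BINS = ("1", "2", "3", "4", ">=5")


def _projected_length(piece: LineString, target: LineString, tol: float) -> float:
    """Length of ``piece`` as seen after projection onto the ring ``target``.

    Exactly-coincident runs keep their length; runs that merely approach
    ``target`` (corner spillover) collapse to ~0.  The piece is sampled
    densely, consecutive projections are differenced on the *circular*
    parameter of the ring (the ring's start vertex must not create a fake
    jump), and each increment is capped by the arc step along the piece
    (projection onto a curve is 1-Lipschitz, so larger jumps are artefacts
    of the projection switching branches, not shared wall).
    """
    step = tol * _SAMPLE_STEP_FRAC
    n = max(2, int(np.ceil(piece.length / step)) + 1)
    ts = np.linspace(0.0, piece.length, n)
    pts = shapely.line_interpolate_point(piece, ts)
    proj = shapely.line_locate_point(target, pts)
    d = np.abs(np.diff(proj))
    d = np.minimum(d, target.length - d)  # circular parameter distance
    d = np.minimum(d, np.diff(ts))  # Lipschitz cap
    return float(d.sum())


def _directed_shared(a: LineString, b: LineString, tol: float) -> float:
    near = a.intersection(b.buffer(tol))
    if near.is_empty:
        return 0.0
    pieces = getattr(near, "geoms", [near])
    total = 0.0
    for piece in pieces:
        if piece.geom_type != "LineString" or piece.length == 0.0:
            continue
        total += _projected_length(piece, b, tol)
    return total


def shared_wall_length(
    a: CellContour,
    b: CellContour,
    proximity_tol: float = DEFAULT_PROXIMITY_TOL_UM,
) -> float:
    """Length of cell wall (µm) shared between two cells.

    Symmetric by construction (average of the two directed measurements).
    """
    ba = LineString(np.vstack([a.vertices, a.vertices[:1]]))
    bb = LineString(np.vstack([b.vertices, b.vertices[:1]]))
    if ba.distance(bb) > proximity_tol:
        return 0.0
    return 0.5 * (_directed_shared(ba, bb, proximity_tol) + _directed_shared(bb, ba, proximity_tol))


def neighbour_graph(
    lamina: Lamina,
    min_shared: float = DEFAULT_MIN_SHARED_UM,
    proximity_tol: float = DEFAULT_PROXIMITY_TOL_UM,
    *,
    prune: bool = True,
) -> nx.Graph:
    """Undirected neighbour graph over the lamina's cells.

    Nodes are cell ids (every cell, connected or not); an edge carries
    ``shared_um`` and exists iff the shared wall is at least ``min_shared``.
    With ``prune`` (default), candidate pairs are limited to cells whose
    bounding boxes, expanded by ``proximity_tol``, overlap — a pure
    optimisation that cannot change the result, since farther pairs share
    nothing.
    """
    g = nx.Graph()
    g.add_nodes_from(c.cell_id for c in lamina.cells)
    boxes = [
        (c.vertices.min(axis=0) - proximity_tol, c.vertices.max(axis=0) + proximity_tol)
        for c in lamina.cells
    ]
    for i, j in itertools.combinations(range(lamina.n_cells), 2):
        if prune:
            (lo_i, hi_i), (lo_j, hi_j) = boxes[i], boxes[j]
            if np.any(hi_i < lo_j) or np.any(hi_j < lo_i):
                continue
        shared = shared_wall_length(lamina.cells[i], lamina.cells[j], proximity_tol)
        if shared >= min_shared:
            g.add_edge(lamina.cells[i].cell_id, lamina.cells[j].cell_id, shared_um=shared)
    return g


def neighbour_count_distribution(graph: nx.Graph) -> dict[int, int]:
    """Histogram {neighbour count -> number of cells}; totals sum to n cells."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty neighbour graph")
    return dict(sorted(Counter(dict(graph.degree()).values()).items()))


def binned_neighbour_counts(graph: nx.Graph) -> dict[str, int]:
    """Neighbour counts pooled into the {1, 2, 3, 4, >=5} bins used for χ².

    Cells with zero neighbours (isolated outlines) are excluded — they carry
    no topological information about the monolayer.
    """
    dist = neighbour_count_distribution(graph)
    out = {b: 0 for b in NEIGHBOUR_BINS}
    for k, n in dist.items():
        if k == 0:
            continue
        out[str(k) if k < 5 else ">=5"] += n
    return out
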