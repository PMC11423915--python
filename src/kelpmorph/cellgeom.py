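"""Per-cell geometric descriptors.

For each segmented cell the pipeline derives, in order: perimeter and area
straight from the contour; the convex hull; the minimal bounding rectangle
(MBR) of the hull, whose long axis defines the cell's main axis and whose
side ratio defines the cell's elongation (l/w); and a rectangularity score —
the overlap fraction between the cell and its MBR after the MBR has been
rescaled to the cell's own area.  Rectangularity is exactly 1 for a
rectangular (cuboid-in-2D) cell and decreases towards 0 as the outline
departs from perpendicular sides, which is what distinguishes the orderly
bricks of an intact kelp embryo lamina from the irregular polygons of
stalk-severed ones.

The MBR is computed by rotating calipers: the minimal-area enclosing
rectangle of a convex polygon has one side collinear with a hull edge, so
scanning hull-edge orientations is exact.  Orientations whose areas tie to
within 1e-9 relative are resolved towards the smallest angle in [0, π).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely import affinity
from shapely.geometry import Polygon

from .segio import CellContour, Lamina, MalformedCellError, signed_area

__all__ = [
    "DegeneratePolygonError",
    "MinimalBoundingRectangle",
    "CellMorphometrics",
    "polygon_area",
    "polygon_perimeter",
    "convex_hull",
    "min_bounding_rectangle",
    "rectangularity",
    "cell_morphometrics",
]

#: Absolute geometric tolerance (µm) — far below hand-tracing precision.
GEOM_TOL = 1e-9

#: Relative area tolerance for the MBR orientation tie-break: orientations
#: whose areas agree to this precision are ties, resolved towards the
#: smallest angle.  Relative, so the choice is invariant under uniform
#: scaling of the input.
MBR_TIE_RTOL = 1e-9


class DegeneratePolygonError(MalformedCellError):
    """All points collinear (or otherwise area-free): no 2-D shape to measure."""


@dataclass(frozen=True)
class MinimalBoundingRectangle:
    """Smallest-area rectangle enclosing a convex polygon.

    ``angle`` is the direction of the *long* side relative to +x, folded into
    [0, π); ``length >= width``.
    """

    centre: tuple[float, float]
    angle: float
    length: float
    width: float

    @property
    def area(self) -> float:
        return self.length * self.width

    @property
    def elongation(self) -> float:
        return self.length / self.width

    def corners(self) -> np.ndarray:
        """The four corners, counter-clockwise, as an (4, 2) array."""
        c, s = math.cos(self.angle), math.sin(self.angle)
        u = np.array([c, s]) * (self.length / 2.0)
        v = np.array([-s, c]) * (self.width / 2.0)
        o = np.asarray(self.centre)
        return np.array([o - u - v, o + u - v, o + u + v, o - u + v])

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.corners())


@dataclass(frozen=True)
class CellMorphometrics:
    """The full per-cell record mirrored into the cell-level output table."""

    cell_id: str
    area: float
    perimeter: float
    hull_area: float
    mbr: MinimalBoundingRectangle
    elongation: float
    rectangularity: float
    main_axis_angle: float
    n_neighbours: int | None = None


def polygon_area(contour: CellContour) -> float:
    """Shoelace area in µm² (contours are CCW, so this is positive)."""
    a = abs(signed_area(contour.vertices))
    if a < GEOM_TOL:
        raise DegeneratePolygonError(f"cell {contour.cell_id!r}: degenerate polygon")
    return a


def polygon_perimeter(contour: CellContour) -> float:
    """Total edge length in µm, closing edge included."""
    v = contour.vertices
    if abs(signed_area(v)) < GEOM_TOL:
        raise DegeneratePolygonError(f"cell {contour.cell_id!r}: degenerate polygon")
    return float(np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1).sum())


def convex_hull(contour: CellContour) -> CellContour:
    """Convex hull of the contour's vertices, CCW, as a new contour."""
    poly = Polygon(contour.vertices).convex_hull
    if poly.geom_type != "Polygon":
        raise DegeneratePolygonError(
            f"cell {contour.cell_id!r}: collinear points, hull is degenerate"
        )
    v = np.asarray(poly.exterior.coords)[:-1]
    if signed_area(v) < 0:
        v = v[::-1]
    return CellContour(cell_id=contour.cell_id, vertices=v)


def _mbr_at_angle(hull_v: np.ndarray, theta: float) -> tuple[float, float, float, np.ndarray]:
    """(area, extent_u, extent_v, centre) of the bbox in a frame rotated by theta."""
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, s], [-s, c]])  # world -> edge frame
    p = hull_v @ rot.T
    lo, hi = p.min(axis=0), p.max(axis=0)
    ext = hi - lo
    centre_local = (lo + hi) / 2.0
    centre = rot.T @ centre_local
    return float(ext[0] * ext[1]), float(ext[0]), float(ext[1]), centre


def min_bounding_rectangle(hull: CellContour) -> MinimalBoundingRectangle:
    """Minimal-area enclosing rectangle of a convex polygon (rotating calipers).

    Accepts any simple contour; the hull of its vertices is used, so passing
    the raw cell contour is equivalent to passing its convex hull.
    """
    hull = convex_hull(hull)
    v = hull.vertices
    edges = np.roll(v, -1, axis=0) - v
    # candidate orientations: each hull edge, folded into [0, pi/2)
    angles = np.mod(np.arctan2(edges[:, 1], edges[:, 0]), math.pi / 2.0)
    best: tuple | None = None
    for theta in np.unique(angles):
        area, eu, ev, centre = _mbr_at_angle(v, theta)
        # side angle folded into [0, pi): long side direction
        if eu >= ev:
            length, width, ang = eu, ev, theta % math.pi
        else:
            length, width, ang = ev, eu, (theta + math.pi / 2.0) % math.pi
        cand = (area, ang, length, width, centre)
        if best is None:
            best = cand
            continue
        tol = MBR_TIE_RTOL * max(area, best[0])
        if area < best[0] - tol:
            best = cand
        elif abs(area - best[0]) <= tol and ang < best[1]:
            best = cand
    assert best is not None
    area, ang, length, width, centre = best
    if width < GEOM_TOL:
        raise DegeneratePolygonError(f"cell {hull.cell_id!r}: flat hull")
    return MinimalBoundingRectangle(
        centre=(float(centre[0]), float(centre[1])),
        angle=float(ang),
        length=length,
        width=width,
    )


def rectangularity(
    contour: CellContour, mbr: MinimalBoundingRectangle | None = None
) -> float:
    """Overlap fraction between the cell and its area-rescaled MBR.

    The MBR is shrunk uniformly about its own centre until its area equals
    the cell's area, and the score is area(cell ∩ scaled MBR) / area(cell).
    A rectangle coincides with its MBR, so it scores exactly 1; any outline
    with non-perpendicular sides leaves part of the scaled rectangle
    uncovered and scores below 1.  Invariant under rigid motions and uniform
    scaling.
    """
    if mbr is None:
        mbr = min_bounding_rectangle(contour)
    cell_area = polygon_area(contour)
    f = math.sqrt(cell_area / mbr.area)
    if abs(f - 1.0) < 1e-12:
        return 1.0  # the cell fills its MBR: it *is* the rectangle
    scaled = affinity.scale(mbr.shapely, xfact=f, yfact=f, origin=mbr.centre)
    inter = contour.shapely.intersection(scaled).area
    return min(1.0, inter / cell_area)


def cell_morphometrics(
    lamina: Lamina, neighbour_counts: dict[str, int] | None = None
) -> list[CellMorphometrics]:
    """All per-cell descriptors for a lamina, one record per cell.

    ``neighbour_counts`` (cell_id -> count), when supplied by the topology
    stage, is merged into the records.
    """
    records: list[CellMorphometrics] = []
    for cell in lamina.cells:
        try:
            area = polygon_area(cell)
            perim = polygon_perimeter(cell)
            hull = convex_hull(cell)
            hull_area = polygon_area(hull)
            mbr = min_bounding_rectangle(hull)
            rect = rectangularity(cell, mbr)
        except MalformedCellError:
            raise
        except Exception as exc:  # pragma: no cover - defensive relabelling
            raise MalformedCellError(f"cell {cell.cell_id!r}: {exc}") from exc
        records.append(
            CellMorphometrics(
                cell_id=cell.cell_id,
                area=area,
                perimeter=perim,
                hull_area=hull_area,
                mbr=mbr,
                elongation=mbr.elongation,
                rectangularity=rect,
                main_axis_angle=mbr.angle,
                n_neighbours=(
                    neighbour_counts.get(cell.cell_id) if neighbour_counts else None
                ),
            )
        )
    return records
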