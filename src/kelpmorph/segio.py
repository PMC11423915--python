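"""Segmentation I/O: read and write cell-wall contours stored as SVG.

A lamina (the flat monolayer blade of an early kelp sporophyte embryo) is
segmented manually, one closed outline per cell, and saved as a plain SVG
file — one file per embryo per time point.  This module turns such a file
into a :class:`Lamina` of :class:`CellContour` polygons expressed in
micrometres, and writes laminae back out (round-trip safe, and the substrate
for per-cell heatmaps).

Only the segmentation dialect is supported: ``path`` elements closed with
``Z`` and built from straight-line commands (M/L/H/V), ``polygon`` and
``rect`` elements.  Anything else is ignored with a warning; curve commands
inside a cell path are a format error.  Physical calibration never comes
from the SVG itself — the micrometre-per-unit scale is always supplied by
the caller (or the experiment manifest).  On ingest the y axis is flipped so
the in-memory frame is right-handed (+y up), and every contour is normalised
to counter-clockwise orientation.
"""

from __future__ import annotations

import csv
import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "STAGE_GROUPS",
    "CellContour",
    "Lamina",
    "SegmentationFormatError",
    "MalformedCellError",
    "read_lamina_svg",
    "write_lamina_svg",
    "read_manifest",
]

logger = logging.getLogger("kelpmorph")

#: Microdissection stage labels: E_n = stalk severed at the n-cell stage
#: (E0 = egg, E1 = zygote), PhII = severed in early phase II, intact = control.
STAGE_GROUPS = ("E0", "E1", "E2", "E4", "E8", "PhII", "intact")

#: Consecutive vertices closer than this (µm) are merged on ingest.
DUPLICATE_VERTEX_TOL = 1e-9


class SegmentationFormatError(ValueError):
    """The file is not parseable as a segmentation SVG."""


class MalformedCellError(ValueError):
    """A cell outline violates the contract (open, self-crossing, degenerate)."""


@dataclass(frozen=True)
class CellContour:
    """A single cell outline: a simple polygon in micrometres.

    ``vertices`` is an (n, 2) float array, n >= 3, first vertex not repeated
    (closure is implicit), counter-clockwise.
    """

    cell_id: str
    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise MalformedCellError(
                f"cell {self.cell_id!r}: need >=3 two-dimensional vertices"
            )
        object.__setattr__(self, "vertices", v)

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.vertices)

    def translated(self, dx: float, dy: float) -> "CellContour":
        return replace(self, vertices=self.vertices + [dx, dy])


@dataclass(frozen=True)
class Lamina:
    """One embryo at one time point: its cells plus sample metadata.

    ``scale`` is the micrometres-per-drawing-unit calibration that was applied
    on ingest (kept for provenance and for writing back out).  ``time_h`` is
    hours since the experiment reference and may be ``None`` for single
    snapshots.
    """

    embryo_id: str
    cells: tuple[CellContour, ...]
    scale: float = 1.0
    stage_group: str | None = None
    time_h: float | None = None

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError(f"lamina {self.embryo_id!r}: no cells")
        if not (self.scale > 0):
            raise ValueError(f"lamina {self.embryo_id!r}: scale must be > 0")
        if self.stage_group is not None and self.stage_group not in STAGE_GROUPS:
            raise ValueError(
                f"lamina {self.embryo_id!r}: unknown stage group "
                f"{self.stage_group!r} (expected one of {STAGE_GROUPS})"
            )
        object.__setattr__(self, "cells", tuple(self.cells))

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell(self, cell_id: str) -> CellContour:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(cell_id)


# ---------------------------------------------------------------------------
# geometry normalisation helpers


def signed_area(vertices: np.ndarray) -> float:
    """Shoelace signed area (positive for counter-clockwise)."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _dedupe(vertices: np.ndarray, tol: float = DUPLICATE_VERTEX_TOL) -> np.ndarray:
    keep = [vertices[0]]
    for p in vertices[1:]:
        if np.hypot(*(p - keep[-1])) > tol:
            keep.append(p)
    # closing duplicate (first == last within tol)
    if len(keep) > 1 and np.hypot(*(keep[-1] - keep[0])) <= tol:
        keep.pop()
    return np.asarray(keep)


def normalise_contour(cell_id: str, raw: np.ndarray) -> CellContour:
    """Merge duplicate vertices, validate simplicity, force CCW orientation."""
    v = _dedupe(np.asarray(raw, dtype=float))
    if v.shape[0] < 3:
        raise MalformedCellError(f"cell {cell_id!r}: fewer than 3 distinct vertices")
    a = signed_area(v)
    if abs(a) < DUPLICATE_VERTEX_TOL:
        raise MalformedCellError(f"cell {cell_id!r}: zero signed area (degenerate)")
    if a < 0:
        v = v[::-1]
    poly = Polygon(v)
    if not poly.is_valid or not poly.is_simple:
        raise MalformedCellError(f"cell {cell_id!r}: self-intersecting outline")
    return CellContour(cell_id=cell_id, vertices=v)


# ---------------------------------------------------------------------------
# SVG path mini-parser (straight-line segmentation dialect only)

_NUM = r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?"
_TOKEN_RE = re.compile(rf"([MmLlHhVvZz])|({_NUM})")
_SUPPORTED = set("MmLlHhVvZz")


def _parse_path_d(d: str, path_id: str) -> tuple[np.ndarray, bool]:
    """Parse a path ``d`` string into vertices; return (vertices, closed)."""
    tokens: list[str] = []
    pos = 0
    for m in _TOKEN_RE.finditer(d):
        if d[pos : m.start()].strip(" ,\t\n"):
            raise SegmentationFormatError(
                f"path {path_id!r}: unparseable data near {d[pos:m.start()]!r}"
            )
        tokens.append(m.group(0))
        pos = m.end()
    if d[pos:].strip(" ,\t\n"):
        bad = d[pos:].strip()[0]
        if bad.isalpha():
            raise SegmentationFormatError(
                f"path {path_id!r}: unsupported path command {bad!r} "
                "(only straight-line segmentation paths are accepted)"
            )
        raise SegmentationFormatError(f"path {path_id!r}: trailing junk {d[pos:]!r}")

    pts: list[tuple[float, float]] = []
    closed = False
    cmd: str | None = None
    i = 0
    x = y = 0.0

    def take(n: int) -> list[float]:
        nonlocal i
        if i + n > len(tokens):
            raise SegmentationFormatError(f"path {path_id!r}: truncated command")
        vals = []
        for t in tokens[i : i + n]:
            try:
                vals.append(float(t))
            except ValueError:
                raise SegmentationFormatError(
                    f"path {path_id!r}: expected number, got {t!r}"
                ) from None
        i += n
        return vals

    while i < len(tokens):
        t = tokens[i]
        if t in _SUPPORTED:
            cmd = t
            i += 1
            if cmd in "Zz":
                closed = True
                if i < len(tokens):
                    raise SegmentationFormatError(
                        f"path {path_id!r}: multiple subpaths are not supported"
                    )
                break
            continue
        if cmd is None:
            raise SegmentationFormatError(f"path {path_id!r}: data before command")
        if cmd in "ML":
            x, y = take(2)
        elif cmd in "ml":
            dx, dy = take(2)
            if cmd == "m" and not pts:
                x, y = dx, dy  # leading relative moveto is absolute
            else:
                x, y = x + dx, y + dy
            if cmd == "m":
                cmd = "l"  # subsequent implicit pairs are lineto
        elif cmd == "l":
            dx, dy = take(2)
            x, y = x + dx, y + dy
        elif cmd == "H":
            (x,) = take(1)
        elif cmd == "h":
            x += take(1)[0]
        elif cmd == "V":
            (y,) = take(1)
        elif cmd == "v":
            y += take(1)[0]
        pts.append((x, y))

    return np.asarray(pts, dtype=float), closed


def _element_vertices(el: ET.Element, el_id: str) -> tuple[np.ndarray, bool] | None:
    """Vertices in drawing units for a supported element, else ``None``."""
    tag = el.tag.rsplit("}", 1)[-1]
    if tag == "path":
        return _parse_path_d(el.get("d", ""), el_id)
    if tag == "polygon":
        raw = el.get("points", "").replace(",", " ").split()
        if len(raw) % 2:
            raise SegmentationFormatError(f"polygon {el_id!r}: odd coordinate count")
        pts = np.asarray(raw, dtype=float).reshape(-1, 2)
        return pts, True
    if tag == "rect":
        x, y = float(el.get("x", 0)), float(el.get("y", 0))
        w, h = float(el.get("width")), float(el.get("height"))
        pts = np.array([[x, y], [x + w, y], [x + w, y + h], [x, y + h]])
        return pts, True
    return None


def read_lamina_svg(
    path: str | Path,
    scale: float,
    *,
    embryo_id: str | None = None,
    stage_group: str | None = None,
    time_h: float | None = None,
) -> Lamina:
    """Read a segmentation SVG into a :class:`Lamina`.

    Every closed ``path``/``polygon``/``rect`` element becomes one cell;
    coordinates are multiplied by ``scale`` (µm per drawing unit) and the
    y axis is flipped so the result lives in a right-handed frame.
    Unsupported elements are skipped with a warning; an *open* path is a
    :class:`MalformedCellError` naming the offending element.
    """
    path = Path(path)
    if not (scale > 0):
        raise ValueError(f"scale must be strictly positive, got {scale}")
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise SegmentationFormatError(f"{path}: not parseable as SVG: {exc}") from exc

    cells: list[CellContour] = []
    seq = 0
    for el in tree.getroot().iter():
        tag = el.tag.rsplit("}", 1)[-1]
        if tag in ("svg", "g", "defs", "title", "desc", "metadata"):
            continue
        el_id = el.get("id") or f"cell{seq:03d}"
        parsed = _element_vertices(el, el_id)
        if parsed is None:
            logger.warning("%s: ignoring unsupported element <%s>", path.name, tag)
            continue
        raw, closed = parsed
        if not closed:
            raise MalformedCellError(
                f"{path.name}: path {el_id!r} is not closed (missing Z)"
            )
        seq += 1
        um = raw * scale
        um[:, 1] *= -1.0  # SVG y grows downward; flip to +y up
        cells.append(normalise_contour(el_id, um))

    if not cells:
        raise SegmentationFormatError(f"{path}: no closed cell outlines found")
    return Lamina(
        embryo_id=embryo_id or path.stem,
        cells=tuple(cells),
        scale=scale,
        stage_group=stage_group,
        time_h=time_h,
    )


def write_lamina_svg(
    lamina: Lamina,
    path: str | Path,
    *,
    fills: Sequence[str] | None = None,
    stroke: str = "#303030",
    stroke_width_units: float = 0.25,
    extra_svg: str = "",
) -> Path:
    """Write a lamina back to SVG (inverse of :func:`read_lamina_svg`).

    Re-reading the written file with ``lamina.scale`` reproduces every vertex
    to well below 1e-6 µm.  ``fills`` (one CSS colour per cell, optional)
    paints cells — the substrate for metric heatmaps.  ``extra_svg`` is raw
    markup appended before the closing tag (used for heatmap legends).
    """
    path = Path(path)
    if fills is not None and len(fills) != lamina.n_cells:
        raise ValueError(
            f"{len(fills)} fill colours for {lamina.n_cells} cells"
        )
    s = lamina.scale
    all_xy = np.vstack([c.vertices for c in lamina.cells]) / s
    xmin, ymin = all_xy.min(axis=0) - 1
    xmax, ymax = all_xy.max(axis=0) + 1

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'viewBox="{xmin:.6f} {-ymax:.6f} {xmax - xmin:.6f} {ymax - ymin:.6f}">\n'
    ]
    for k, cell in enumerate(lamina.cells):
        units = cell.vertices / s
        pts = " ".join(f"{float(x)!r},{float(-y)!r}" for x, y in units)
        fill = fills[k] if fills is not None else "none"
        parts.append(
            f'  <polygon id="{cell.cell_id}" points="{pts}" fill="{fill}" '
            f'stroke="{stroke}" stroke-width="{stroke_width_units}" />\n'
        )
    if extra_svg:
        parts.append(extra_svg)
    parts.append("</svg>\n")
    try:
        path.write_text("".join(parts))
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# experiment manifest (sidecar metadata CSV)

MANIFEST_COLUMNS = ("embryo_id", "file", "stage_group", "time_h", "scale_um_per_unit")


def read_manifest(path: str | Path) -> list[dict]:
    """Read the experiment manifest CSV.

    Columns: embryo_id, file (SVG path relative to the manifest), stage_group,
    time_h (may be empty), scale_um_per_unit.
    """
    path = Path(path)
    rows: list[dict] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise SegmentationFormatError(
                f"{path}: manifest missing columns {sorted(missing)}"
            )
        for rec in reader:
            rows.append(
                {
                    "embryo_id": rec["embryo_id"],
                    "file": (path.parent / rec["file"]).resolve(),
                    "stage_group": rec["stage_group"],
                    "time_h": float(rec["time_h"]) if rec["time_h"] else None,
                    "scale_um_per_unit": float(rec["scale_um_per_unit"]),
                }
            )
    if not rows:
        raise SegmentationFormatError(f"{path}: empty manifest")
    return rows


def load_manifest_laminae(path: str | Path) -> list[Lamina]:
    """Read every lamina referenced by a manifest, failing with a full list."""
    rows = read_manifest(path)
    missing = [str(r["file"]) for r in rows if not Path(r["file"]).exists()]
    if missing:
        raise FileNotFoundError("missing segmentation files: " + ", ".join(missing))
    return [
        read_lamina_svg(
            r["file"],
            r["scale_um_per_unit"],
            embryo_id=r["embryo_id"],
            stage_group=r["stage_group"],
            time_h=r["time_h"],
        )
        for r in rows
    ]
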