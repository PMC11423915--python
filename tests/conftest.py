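"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library-under-test's code paths:
Monte Carlo rejection sampling for areas and overlaps, an O(n^3) half-plane
scan for convex hulls, a dense orientation sweep for minimal bounding
rectangles, and exhaustive rank-assignment enumeration for the Mann-Whitney
test live in the individual test modules that need them.
"""

from __future__ import annotations

import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon

from kelpmorph import CellContour, Lamina, LaminaSpec, generate_lamina


# --- Monte Carlo oracles ----------------------------------------------------


def mc_region_area(region, n_samples: int, rng: np.random.Generator):
    """(estimate, standard error) of a shapely region's area by rejection
    sampling over its bounding box."""
    minx, miny, maxx, maxy = region.bounds
    box_area = (maxx - minx) * (maxy - miny)
    xs = rng.uniform(minx, maxx, n_samples)
    ys = rng.uniform(miny, maxy, n_samples)
    hits = shapely.contains_xy(region, xs, ys)
    p = hits.mean()
    se = np.sqrt(p * (1 - p) / n_samples) * box_area
    return p * box_area, se


def assert_mc_close(analytic: float, region, n_samples: int, seed: int) -> None:
    est, se = mc_region_area(region, n_samples, np.random.default_rng(seed))
    assert abs(analytic - est) <= 3 * max(se, 1e-12), (analytic, est, se)


# --- geometry fixtures ------------------------------------------------------


def contour(points, cell_id: str = "c") -> CellContour:
    return CellContour(cell_id=cell_id, vertices=np.asarray(points, dtype=float))


def random_simple_polygon(rng: np.random.Generator, n: int = 12) -> CellContour:
    """A star-shaped (hence simple) random polygon around the origin."""
    theta = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = rng.uniform(1.0, 4.0, n)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return contour(pts, "random")


def random_convex_polygon(rng: np.random.Generator, n: int = 10) -> CellContour:
    pts = rng.normal(size=(n, 2)) * 3.0
    hull = Polygon(pts).convex_hull
    v = np.asarray(hull.exterior.coords)[:-1]
    return contour(v, "hull")


@pytest.fixture
def grid3() -> Lamina:
    """3x3 grid of unit squares."""
    lam, _ = generate_lamina(LaminaSpec(rows=3, cols=3, cell_size=1.0))
    return lam


@pytest.fixture
def stack8() -> Lamina:
    """1x8 phase-I-like stack of unit squares."""
    lam, _ = generate_lamina(LaminaSpec(rows=8, cols=1, cell_size=1.0))
    return lam


# --- SVG fixture ------------------------------------------------------------

THREE_SQUARES_SVG = """<?xml version="1.0"?>
<svg xmlns="http://www.w3.org/2000/svg" viewBox="0 0 40 20">
  <path id="a" d="M 0 0 L 10 0 L 10 10 L 0 10 Z" />
  <polygon id="b" points="12,0 22,0 22,10 12,10" />
  <rect id="c" x="24" y="0" width="10" height="10" />
</svg>
"""

OPEN_PATH_SVG = """<?xml version="1.0"?>
<svg xmlns="http://www.w3.org/2000/svg">
  <path id="ok" d="M 0 0 L 10 0 L 10 10 L 0 10 Z" />
  <path id="dangling" d="M 20 0 L 30 0 L 30 10" />
</svg>
"""


@pytest.fixture
def three_squares_svg(tmp_path):
    p = tmp_path / "three_squares.svg"
    p.write_text(THREE_SQUARES_SVG)
    return p


@pytest.fixture
def open_path_svg(tmp_path):
    p = tmp_path / "open_path.svg"
    p.write_text(OPEN_PATH_SVG)
    return p
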