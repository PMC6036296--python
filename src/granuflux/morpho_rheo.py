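"""Area-ratio morphometry on cell contours.

Real-time deformability cytometry images cells in flow and extracts a
closed contour per event.  The *area ratio* — convex-hull area divided by
contour area — is a sensitive, label-free surrogate for shape change:
it equals 1 for a convex (resting, spherical) cell and grows as membrane
protrusions and blebs carve concavities into the outline.

Contours are simple polygons in pixel units.  Areas come from the shoelace
formula, hulls from the monotone-chain algorithm; self-intersecting
contours are rejected rather than repaired, because silent repair would
bias the statistic.  A seed-controlled radial-polygon generator provides
synthetic smooth and protruded populations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "CellContour",
    "AreaRatioResult",
    "PopulationSummary",
    "polygon_area",
    "convex_hull",
    "area_ratio",
    "summarize_population",
    "synthetic_contour",
    "synthetic_population",
    "read_contour_table",
    "write_contour_table",
]

DEFAULT_MIN_EVENTS = 5000


def _segments_properly_intersect(p: np.ndarray) -> bool:
    """True if any two non-adjacent edges of the closed polygon cross.

    Vectorized orientation test over all edge pairs; O(n^2) pairs, which is
    fine for contour-sized polygons.
    """
    n = len(p)
    a = p
    b = np.roll(p, -1, axis=0)

    def cross(o, u, v):
        return (u[..., 0] - o[..., 0]) * (v[..., 1] - o[..., 1]) - (
            u[..., 1] - o[..., 1]
        ) * (v[..., 0] - o[..., 0])

    i = np.arange(n)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    # non-adjacent, unordered pairs (adjacency wraps around)
    mask = (jj > ii + 1) & ~((ii == 0) & (jj == n - 1))
    ai, bi = a[ii[mask]], b[ii[mask]]
    aj, bj = a[jj[mask]], b[jj[mask]]
    d1 = cross(ai, bi, aj)
    d2 = cross(ai, bi, bj)
    d3 = cross(aj, bj, ai)
    d4 = cross(aj, bj, bi)
    return bool(np.any((d1 * d2 < 0) & (d3 * d4 < 0)))


@dataclass
class CellContour:
    """Closed simple polygon: ordered (x, y) vertices in pixels.

    The last vertex connects implicitly back to the first.  At least three
    distinct vertices are required and the outline must not self-intersect.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValidationError("vertices must be an (n, 2) array")
        # drop an explicit closing vertex if present
        if len(v) > 1 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(np.unique(v, axis=0)) < 3:
            raise ValidationError("contour needs >= 3 distinct vertices")
        if _segments_properly_intersect(v):
            raise ValidationError("self-intersecting contour rejected")
        self.vertices = v

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass(frozen=True)
class AreaRatioResult:
    """Contour area, hull area (px^2) and their ratio (>= 1)."""

    contour_area: float
    hull_area: float
    area_ratio: float


def polygon_area(contour: CellContour) -> float:
    """Absolute shoelace area; independent of vertex orientation."""
    v = contour.vertices
    x, y = v[:, 0], v[:, 1]
    area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    if area == 0.0:
        raise ValidationError("degenerate (zero-area) contour")
    return area


def convex_hull(contour: CellContour) -> CellContour:
    """Convex hull of the contour's vertices (Andrew monotone chain).

    Output is counter-clockwise with collinear boundary points dropped.
    """
    pts = np.unique(contour.vertices, axis=0)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def half(points):
        chain: list[np.ndarray] = []
        for p in points:
            while len(chain) >= 2 and cross(chain[-2], chain[-1], p) <= 0:
                chain.pop()
            chain.append(p)
        return chain

    lower = half(pts)
    upper = half(pts[::-1])
    hull = np.array(lower[:-1] + upper[:-1])
    if len(hull) < 3:
        raise ValidationError("all contour points are collinear")
    return CellContour(hull)


def area_ratio(contour: CellContour) -> AreaRatioResult:
    """Hull-to-contour area ratio for one event."""
    c_area = polygon_area(contour)
    h_area = polygon_area(convex_hull(contour))
    return AreaRatioResult(
        contour_area=c_area, hull_area=h_area, area_ratio=h_area / c_area
    )


@dataclass(frozen=True)
class PopulationSummary:
    """Event count and median/mean area ratio of a population.

    ``below_threshold`` flags populations with fewer events than the
    acquisition minimum (default 5000), where the summary is reported but
    considered under-sampled.
    """

    n: int
    median_ratio: float
    mean_ratio: float
    min_events: int
    below_threshold: bool


def summarize_population(
    contours: Sequence[CellContour],
    min_events: int = DEFAULT_MIN_EVENTS,
) -> PopulationSummary:
    """Median and mean area ratio over a collection of events.

    Both the median (robust to the heavy right tail of protruded cells)
    and the mean are reported, since the preferred per-donor aggregate is a
    matter of convention.
    """
    if not contours:
        raise ValidationError("empty contour collection")
    ratios = np.array([area_ratio(c).area_ratio for c in contours])
    return PopulationSummary(
        n=len(ratios),
        median_ratio=float(np.median(ratios)),
        mean_ratio=float(np.mean(ratios)),
        min_events=min_events,
        below_threshold=len(ratios) < min_events,
    )


# ---------------------------------------------------------------------------
# Synthetic contours
# ---------------------------------------------------------------------------


def synthetic_contour(
    rng: np.random.Generator,
    radius: float = 30.0,
    protrusion_amplitude: float = 0.0,
    protrusion_frequency: int = 8,
    noise_amplitude: float = 0.01,
    n_vertices: int = 64,
    center: tuple[float, float] = (0.0, 0.0),
    phase: float | None = None,
) -> CellContour:
    """Radial polygon r(theta) = R (1 + a sin(f theta + phi) + smooth noise).

    ``protrusion_amplitude`` a controls how far the outline departs from
    convexity; a = 0 with zero noise gives a regular (convex) polygon.
    Radial contours are star-shaped around the centre, so they never
    self-intersect as long as the radius stays positive.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    phi = rng.uniform(0, 2 * np.pi) if phase is None else phase
    r = 1.0 + protrusion_amplitude * np.sin(protrusion_frequency * theta + phi)
    if noise_amplitude > 0:
        # smooth low-order harmonic noise keeps the outline cell-like
        for harmonic in (2, 3):
            r += noise_amplitude * rng.normal() * np.sin(
                harmonic * theta + rng.uniform(0, 2 * np.pi)
            )
    r = radius * np.maximum(r, 0.1)
    pts = np.column_stack(
        (center[0] + r * np.cos(theta), center[1] + r * np.sin(theta))
    )
    return CellContour(pts)


def synthetic_population(
    n_events: int,
    protrusion_amplitude: float = 0.0,
    seed: int | None = None,
    radius: float = 30.0,
    radius_cv: float = 0.1,
    **kwargs,
) -> list[CellContour]:
    """Population of synthetic cells; primed/activated-like populations use
    a larger protrusion amplitude."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_events):
        r = radius * float(np.exp(rng.normal(0.0, radius_cv)))
        out.append(
            synthetic_contour(
                rng, radius=r, protrusion_amplitude=protrusion_amplitude, **kwargs
            )
        )
    return out


# ---------------------------------------------------------------------------
# Contour I/O
# ---------------------------------------------------------------------------


def write_contour_table(contours: Sequence[CellContour], sink, sep: str = ",") -> None:
    """Delimited long format: event_id, vertex_index, x, y."""
    rows = []
    for e, c in enumerate(contours):
        for k, (x, y) in enumerate(c.vertices):
            rows.append({"event_id": e, "vertex_index": k, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(sink, sep=sep, index=False)


def read_contour_table(source, sep: str = ",") -> list[CellContour]:
    df = pd.read_csv(source, sep=sep, comment="#")
    required = {"event_id", "vertex_index", "x", "y"}
    if not required <= set(df.columns):
        raise FormatError(
            f"contour table missing columns: {sorted(required - set(df.columns))}"
        )
    out = []
    for _, sub in df.groupby("event_id", sort=True):
        sub = sub.sort_values("vertex_index")
        out.append(CellContour(sub[["x", "y"]].to_numpy()))
    return out


def write_contours_jsonl(contours: Sequence[CellContour], sink) -> None:
    """JSON-lines dialect: one {"event_id", "vertices"} object per line."""
    own = not hasattr(sink, "write")
    handle = open(sink, "w") if own else sink
    try:
        for e, c in enumerate(contours):
            handle.write(
                json.dumps({"event_id": e, "vertices": c.vertices.tolist()}) + "\n"
            )
    finally:
        if own:
            handle.close()


def read_contours_jsonl(source) -> list[CellContour]:
    own = not hasattr(source, "read")
    handle = open(source) if own else source
    try:
        return [
            CellContour(np.asarray(json.loads(line)["vertices"]))
            for line in handle
            if line.strip()
        ]
    finally:
        if own:
            handle.close()
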