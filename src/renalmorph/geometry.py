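"""Exact conversions between binary rasters and polygons.

Masks are treated as unions of unit pixel squares; the traced polygon
boundary runs along integer grid lines, and rasterization tests pixel
centers (at half-integer coordinates), so mask -> polygon -> mask is an
exact round trip.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon

__all__ = ["mask_to_polygon", "rasterize_polygon", "RoiPolygon"]


def _boundary_edges(mask: np.ndarray) -> dict[tuple[int, int], list[tuple[int, int]]]:
    """Directed boundary edges of the pixel-square union, keyed by start vertex."""
    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    inner = padded[1:-1, 1:-1]
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def add(p, q):
        edges.setdefault(p, []).append(q)

    rs, cs = np.nonzero(inner & ~padded[:-2, 1:-1])  # top side exposed
    for r, c in zip(rs.tolist(), cs.tolist()):
        add((c, r), (c + 1, r))
    rs, cs = np.nonzero(inner & ~padded[1:-1, 2:])  # right side exposed
    for r, c in zip(rs.tolist(), cs.tolist()):
        add((c + 1, r), (c + 1, r + 1))
    rs, cs = np.nonzero(inner & ~padded[2:, 1:-1])  # bottom side exposed
    for r, c in zip(rs.tolist(), cs.tolist()):
        add((c + 1, r + 1), (c, r + 1))
    rs, cs = np.nonzero(inner & ~padded[1:-1, :-2])  # left side exposed
    for r, c in zip(rs.tolist(), cs.tolist()):
        add((c, r + 1), (c, r))
    return edges


def _stitch_rings(edges: dict[tuple[int, int], list[tuple[int, int]]]) -> list[list[tuple[int, int]]]:
    rings: list[list[tuple[int, int]]] = []
    while edges:
        start = next(iter(edges))
        ring = [start]
        prev = None
        cur = start
        while True:
            outs = edges[cur]
            if len(outs) == 1 or prev is None:
                nxt = outs.pop()
            else:
                # checkerboard vertex: take the right turn relative to the
                # incoming direction so diagonal pixels trace separate rings
                din = (cur[0] - prev[0], cur[1] - prev[1])
                right = (-din[1], din[0])
                nxt = None
                for cand in outs:
                    d = (cand[0] - cur[0], cand[1] - cur[1])
                    if d == right:
                        nxt = cand
                        break
                if nxt is None:
                    nxt = outs[0]
                outs.remove(nxt)
            if not edges[cur]:
                del edges[cur]
            prev, cur = cur, nxt
            if cur == start:
                break
            ring.append(cur)
        # collapse collinear runs to keep rings compact
        rings.append(_simplify_ring(ring))
    return rings


def _simplify_ring(ring: list[tuple[int, int]]) -> list[tuple[int, int]]:
    n = len(ring)
    out = []
    for i in range(n):
        a, b, c = ring[i - 1], ring[i], ring[(i + 1) % n]
        if (b[0] - a[0]) * (c[1] - b[1]) != (b[1] - a[1]) * (c[0] - b[0]):
            out.append(b)
    return out


def _signed_area(ring: list[tuple[int, int]]) -> float:
    xs = np.array([p[0] for p in ring], dtype=float)
    ys = np.array([p[1] for p in ring], dtype=float)
    return 0.5 * float(np.sum(xs * np.roll(ys, -1) - np.roll(xs, -1) * ys))


def mask_to_polygon(mask: np.ndarray, origin: tuple[int, int] = (0, 0)) -> MultiPolygon:
    """Trace a binary mask into an exact MultiPolygon in pixel coordinates.

    ``origin`` is the (x, y) slide coordinate of raster pixel (0, 0).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return MultiPolygon([])
    rings = _stitch_rings(_boundary_edges(mask))
    outers: list[tuple[Polygon, list]] = []
    holes: list[list[tuple[int, int]]] = []
    for ring in rings:
        if _signed_area(ring) > 0:
            outers.append((Polygon(ring), []))
        else:
            holes.append(ring)
    for hole in holes:
        # assign to the smallest outer ring whose polygon covers the hole
        candidates = [
            (poly.area, i)
            for i, (poly, _) in enumerate(outers)
            if poly.covers(shapely.Point(_hole_probe(hole)))
        ]
        if not candidates:
            raise RuntimeError("hole ring without containing outer ring")
        _, idx = min(candidates)
        outers[idx][1].append(hole)
    ox, oy = origin
    polys = [
        Polygon(
            [(x + ox, y + oy) for x, y in outer.exterior.coords],
            [[(x + ox, y + oy) for x, y in h] for h in hs],
        )
        for outer, hs in outers
    ]
    return MultiPolygon(polys)


def _hole_probe(hole: list[tuple[int, int]]) -> tuple[float, float]:
    """A point strictly inside the filled region that surrounds the hole ring."""
    # centroid of the first edge, nudged nowhere: use ring vertex midpoint on
    # the boundary — covers() accepts boundary points of the outer polygon.
    (x0, y0), (x1, y1) = hole[0], hole[1]
    return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


def rasterize_polygon(
    polygon: Polygon | MultiPolygon,
    shape: tuple[int, int],
    origin: tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Rasterize by pixel-center containment into a (H, W) boolean array.

    A pixel (r, c) is inside iff its center (c+0.5, r+0.5) (plus ``origin``
    offset) is covered by the polygon. Inverse of :func:`mask_to_polygon`.
    """
    h, w = shape
    out = np.zeros((h, w), dtype=bool)
    if polygon.is_empty:
        return out
    ox, oy = origin
    minx, miny, maxx, maxy = polygon.bounds
    c0 = max(int(np.floor(minx - ox)), 0)
    c1 = min(int(np.ceil(maxx - ox)), w)
    r0 = max(int(np.floor(miny - oy)), 0)
    r1 = min(int(np.ceil(maxy - oy)), h)
    if c0 >= c1 or r0 >= r1:
        return out
    cs, rs = np.meshgrid(
        np.arange(c0, c1) + 0.5 + ox, np.arange(r0, r1) + 0.5 + oy
    )
    inside = shapely.contains_xy(polygon, cs.ravel(), rs.ravel()).reshape(rs.shape)
    out[r0:r1, c0:c1] = inside
    return out


class RoiPolygon:
    """A region-of-interest polygon in slide pixel coordinates.

    The region a pathologist outlines (typically renal cortex, excluding
    capsule and medulla). Must be a valid simple polygon of positive area.
    """

    def __init__(self, polygon: Polygon | MultiPolygon, label: str = "renal cortex"):
        if polygon.is_empty or polygon.area <= 0:
            raise ValueError("ROI polygon must have positive area")
        if not polygon.is_valid:
            raise ValueError("ROI polygon is not a valid (simple) polygon")
        self.polygon = polygon
        self.label = label

    @classmethod
    def full_frame(cls, shape: tuple[int, int], label: str = "full frame") -> "RoiPolygon":
        h, w = shape
        return cls(shapely.box(0, 0, w, h), label)

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        return rasterize_polygon(self.polygon, shape)
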