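"""Barn geometry: functional areas and point-in-polygon assignment.

The freestall barn is modeled as a bounding rectangle partitioned into named
polygons of three kinds: *resting* (cubicles plus inner alleys), *feeding*
(feed tables plus outer alleys), and *excluded* (areas out of bounds for the
cows, e.g. the strip toward the milking parlor).  Every position fix is
assigned to exactly one of ``{"resting", "feeding", "excluded"}``; points
outside all listed polygons fall through to ``excluded``, which also absorbs
positions recorded while a cow is out of the pen.

Geometry is read from / written to a small YAML config listing the bounding
rectangle and, per kind, named polygons as vertex lists in meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
import yaml
from shapely.geometry import Polygon

RESTING_CODE = 0
FEEDING_CODE = 1
EXCLUDED_CODE = 2
AREA_LABELS = ("resting", "feeding", "excluded")

#: Width of one cubicle in the resting area (m).  Two cows lying in adjacent
#: cubicles are at most two cubicle widths apart, which motivates the default
#: 2.5 m contact radius used by the contact module.
CUBICLE_WIDTH = 1.25


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class BarnGeometry:
    """Rectangular barn with named area polygons.

    ``resting``/``feeding``/``excluded`` are lists of shapely Polygons; the
    bounding rectangle is ``width`` x ``height`` meters with origin (0, 0).
    """

    width: float
    height: float
    resting: tuple = field(default_factory=tuple)
    feeding: tuple = field(default_factory=tuple)
    excluded: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        bounds = Polygon([(0, 0), (self.width, 0), (self.width, self.height), (0, self.height)])
        for kind in ("resting", "feeding", "excluded"):
            polys = tuple(self._as_polygon(p) for p in getattr(self, kind))
            object.__setattr__(self, kind, polys)
            for poly in polys:
                if not poly.is_valid:
                    raise GeometryError(f"self-intersecting {kind} polygon: {poly.wkt}")
                if not bounds.buffer(1e-9).covers(poly):
                    raise GeometryError(f"{kind} polygon extends outside the barn bounds")
        for rp in self.resting:
            for fp in self.feeding:
                if rp.intersection(fp).area > 1e-9:
                    raise GeometryError("resting and feeding polygons overlap")

    @staticmethod
    def _as_polygon(p) -> Polygon:
        return p if isinstance(p, Polygon) else Polygon(p)

    # -- serialization -----------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "BarnGeometry":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        bounds = raw["bounds"]

        def polys(kind):
            return tuple(Polygon(entry["vertices"]) for entry in raw.get(kind, []))

        return cls(
            width=float(bounds["width"]),
            height=float(bounds["height"]),
            resting=polys("resting"),
            feeding=polys("feeding"),
            excluded=polys("excluded"),
        )

    def to_yaml(self, path) -> None:
        def dump(kind):
            return [
                {
                    "name": f"{kind}_{k}",
                    "vertices": [[float(x), float(y)] for x, y in poly.exterior.coords[:-1]],
                }
                for k, poly in enumerate(getattr(self, kind))
            ]

        raw = {
            "bounds": {"width": float(self.width), "height": float(self.height)},
            "resting": dump("resting"),
            "feeding": dump("feeding"),
            "excluded": dump("excluded"),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    # -- queries -----------------------------------------------------------
    def area_codes(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Vectorized area assignment: 0 resting, 1 feeding, 2 excluded.

        Precedence is resting, then feeding, then excluded; boundary points
        count as inside (closed polygons).  NaN coordinates map to excluded.
        """
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        out = np.full(xs.shape, EXCLUDED_CODE, dtype=np.int8)
        ok = np.isfinite(xs) & np.isfinite(ys)
        undecided = ok.copy()
        for code, polys in ((RESTING_CODE, self.resting), (FEEDING_CODE, self.feeding)):
            for poly in polys:
                if not undecided.any():
                    break
                shapely.prepare(poly)
                hit = undecided & shapely.intersects_xy(poly, xs, ys)
                out[hit] = code
                undecided &= ~hit
        return out

    def assign_area(self, x: float, y: float) -> str:
        """Area label for a single fix (total function; see :meth:`area_codes`)."""
        return AREA_LABELS[int(self.area_codes(np.array([x]), np.array([y]))[0])]

    def area_polygons(self, area: str) -> tuple:
        if area not in ("resting", "feeding"):
            raise GeometryError(f"unknown functional area {area!r}")
        return getattr(self, area)


def default_barn(width: float = 74.0, height: float = 33.0) -> BarnGeometry:
    """Synthetic stand-in for the study barn's floor plan.

    A 74 x 33 m rectangle with the resting block (cubicles + inner alleys) in
    the center band, feeding strips (feed tables + outer alleys) along both
    long walls, and a 4 m excluded strip at one short end for the route to the
    milking parlor.  The real barn's plan is not published in machine-readable
    form; this layout preserves its advertised dimensions and the
    center-resting / flank-feeding arrangement.
    """
    usable_w = width - 4.0  # excluded strip on the right
    resting = (Polygon([(0, 10), (usable_w, 10), (usable_w, height - 10), (0, height - 10)]),)
    feeding = (
        Polygon([(0, 0), (usable_w, 0), (usable_w, 9), (0, 9)]),
        Polygon([(0, height - 9), (usable_w, height - 9), (usable_w, height), (0, height)]),
    )
    excluded = (Polygon([(usable_w, 0), (width, 0), (width, height), (usable_w, height)]),)
    return BarnGeometry(width, height, resting, feeding, excluded)
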