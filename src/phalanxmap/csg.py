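"""Cross-sectional geometric properties of the cortical ring.

Standard beam-theory section properties from the periosteal and endosteal
outlines of a diaphyseal cross-section:

* ``CA``   — cortical area (mm^2), a proxy for axial strength;
* ``Ixx``, ``Iyy`` — second moments of area about the ring centroid
  (x = radioulnar, y = dorsopalmar axis), mm^4;
* ``J``    — polar moment of area, ``Ixx + Iyy``, a proxy for bending and
  torsional rigidity;
* ``Zpol`` — polar section modulus, ``J / r_max`` with ``r_max`` the
  maximum distance from the ring centroid to the periosteal outline, a
  proxy for maximum bending strength.

Moments are computed by the exact shoelace (Green's theorem) formulas on
the outline polygons, with the parallel-axis theorem used to refer the
outer and inner contributions to the common ring centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "SectionProperties",
    "polygon_moments",
    "ring_properties",
    "csg_at_levels",
    "scale_csg",
]


@dataclass(frozen=True)
class SectionProperties:
    level: float
    CA: float
    Ixx: float
    Iyy: float
    J: float
    Zpol: float
    r_max: float
    scaled: bool = False


def polygon_moments(outline: np.ndarray, validate: bool = True):
    """Area, centroid and centroidal second moments of a simple polygon.

    Parameters
    ----------
    outline : (n, 2) array of vertices, closed implicitly (last edge joins
        the last vertex back to the first).  Winding is auto-corrected.

    Returns
    -------
    (area, centroid, Ixx, Iyy) with the moments about axes through the
    polygon's own centroid, parallel to x and y.
    """
    p = np.asarray(outline, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or len(p) < 3:
        raise ValueError("outline must be an (n, 2) array with n >= 3")
    if np.allclose(p[0], p[-1]):
        p = p[:-1]
    if validate and not Polygon(p).is_valid:
        raise ValueError("self-intersecting (invalid) polygon")
    x, y = p[:, 0], p[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * np.sum(cross)
    if a < 0:  # enforce counter-clockwise winding
        p = p[::-1]
        x, y = p[:, 0], p[:, 1]
        x1, y1 = np.roll(x, -1), np.roll(y, -1)
        cross = x * y1 - x1 * y
        a = 0.5 * np.sum(cross)
    if a == 0:
        raise ValueError("degenerate polygon with zero area")
    cx = np.sum((x + x1) * cross) / (6.0 * a)
    cy = np.sum((y + y1) * cross) / (6.0 * a)
    ixx_o = np.sum((y * y + y * y1 + y1 * y1) * cross) / 12.0
    iyy_o = np.sum((x * x + x * x1 + x1 * x1) * cross) / 12.0
    # parallel-axis transport from the origin to the centroid
    ixx = ixx_o - a * cy * cy
    iyy = iyy_o - a * cx * cx
    return float(a), np.array([cx, cy]), float(ixx), float(iyy)


def ring_properties(
    periosteal: np.ndarray, endosteal: np.ndarray, level: float = 0.5
) -> SectionProperties:
    """Section properties of the cortical ring between two outlines.

    The endosteal outline must lie inside the periosteal one.  Outer and
    inner moments are transported to the centroid of the ring area
    (outer minus inner) by the parallel-axis theorem; ``r_max`` is measured
    from that centroid to the periosteal vertices.
    """
    a_o, c_o, ixx_o, iyy_o = polygon_moments(periosteal)
    a_i, c_i, ixx_i, iyy_i = polygon_moments(endosteal)
    if a_i >= a_o:
        raise ValueError("endosteal area must be smaller than periosteal area")
    if not Polygon(np.asarray(periosteal)).contains(
        Polygon(np.asarray(endosteal)).representative_point()
    ):
        raise ValueError("endosteal outline does not lie inside the periosteal one")
    ca = a_o - a_i
    c_ring = (a_o * c_o - a_i * c_i) / ca
    ixx = (ixx_o + a_o * (c_o[1] - c_ring[1]) ** 2) - (
        ixx_i + a_i * (c_i[1] - c_ring[1]) ** 2
    )
    iyy = (iyy_o + a_o * (c_o[0] - c_ring[0]) ** 2) - (
        iyy_i + a_i * (c_i[0] - c_ring[0]) ** 2
    )
    j = ixx + iyy
    p = np.asarray(periosteal, dtype=float)
    r_max = float(np.max(np.hypot(p[:, 0] - c_ring[0], p[:, 1] - c_ring[1])))
    return SectionProperties(
        level=float(level),
        CA=float(ca),
        Ixx=float(ixx),
        Iyy=float(iyy),
        J=float(j),
        Zpol=float(j / r_max),
        r_max=r_max,
    )


def csg_at_levels(roi, levels=(0.35, 0.50, 0.65)) -> list[SectionProperties]:
    """Ring properties at fractions of the shaft (ROI) length.

    ``roi`` is a :class:`phalanxmap.mapping.ShaftROI`; each requested level
    is a fraction of the ROI span.  The conventional sampling levels are
    35%, 50% and 65% of shaft length.
    """
    from .mapping import cross_section_at  # late import: mapping imports csg

    out = []
    for lv in levels:
        sec = cross_section_at(roi, lv)
        props = ring_properties(sec.periosteal_outline, sec.endosteal_outline, lv)
        out.append(props)
    return out


_POWERS = {"CA": 2, "Ixx": 4, "Iyy": 4, "J": 4, "Zpol": 3, "r_max": 1}


def scale_csg(
    props: SectionProperties, length_mm: float, power: str = "dimensional"
) -> SectionProperties:
    """Length-scale section properties to dimensionless form.

    ``power='dimensional'`` divides each property by the bone length raised
    to its length dimension (CA/L^2, J/L^4, Zpol/L^3, r_max/L), so scaled
    values are invariant under isometric size change.  ``power='linear'``
    divides every property by L once (naive scaling, for sensitivity
    comparisons).
    """
    if props.scaled:
        raise ValueError("properties are already scaled")
    if length_mm <= 0:
        raise ValueError("length must be positive")
    if power not in ("dimensional", "linear"):
        raise ValueError("power must be 'dimensional' or 'linear'")
    kw = {}
    for name, p in _POWERS.items():
        exponent = p if power == "dimensional" else 1
        kw[name] = getattr(props, name) / length_mm**exponent
    return replace(props, scaled=True, **kw)
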