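"""Shaft ROI definition, cross-section extraction, equiangular paired
semi-landmarking and cortical thickness maps.

The measurement protocol: the diaphyseal region of interest (ROI) runs
from the distal-most extent of the base to the proximal end of the
trochlea, cropped with a 2% buffer at each end; 97 cross-sections are
taken at 1% increments between 2% and 98% of ROI length; on each section
50 paired semi-landmarks are placed where equiangular rays from the
centroid of the cortical ring area cross the periosteal and endosteal
outlines; cortical thickness is the length of the ray segment between the
paired landmarks.  A bone therefore yields a 97 x 50 thickness matrix
(4850 measurements), optionally scaled by bone length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .csg import polygon_moments
from .phantom import MeshPair

__all__ = [
    "ShaftROI",
    "CrossSection",
    "LandmarkSet",
    "ThicknessMap",
    "ExclusionError",
    "section_loops",
    "standard_orientation",
    "define_roi",
    "define_roi_from_frame",
    "slice_sections",
    "cross_section_at",
    "place_landmarks",
    "build_thickness_map",
    "compute_thickness_map",
    "bone_length",
    "scale_map",
    "geometric_mean_size",
    "measure_breadths",
    "palmar_dorsal_partition",
    "render_morphometric_map",
    "N_SECTIONS",
    "N_LANDMARKS",
]

N_SECTIONS = 97
N_LANDMARKS = 50
SECTION_LEVELS = np.arange(2, 99) / 100.0  # 2% .. 98% at 1% increments


class ExclusionError(RuntimeError):
    """A specimen cannot be mapped (e.g. no endosteal outline in the ROI)."""


# ---------------------------------------------------------------------------
# sectioning primitives

def section_loops(mesh, z: float) -> list[np.ndarray]:
    """Closed intersection loops of a mesh with the plane at height ``z``.

    Returns world-frame (x, y) polygons (first point not repeated).
    """
    sec = mesh.section(plane_origin=[0, 0, z], plane_normal=[0, 0, 1])
    if sec is None:
        return []
    planar, _ = sec.to_2D(normal=[0, 0, 1])
    loops = []
    for d in planar.discrete:
        pts = np.asarray(d, dtype=float)[:, :2]
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) >= 3:
            loops.append(pts)
    return loops


def _multi_section_loops(mesh, z_levels) -> list[list[np.ndarray]]:
    """``section_loops`` for many planes at once (vectorized in trimesh)."""
    paths = mesh.section_multiplane(
        plane_origin=[0, 0, 0], plane_normal=[0, 0, 1], heights=np.asarray(z_levels)
    )
    out = []
    for p in paths:
        loops = []
        if p is not None:
            for d in p.discrete:
                pts = np.asarray(d, dtype=float)[:, :2]
                if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
                    pts = pts[:-1]
                if len(pts) >= 3:
                    loops.append(pts)
        out.append(loops)
    return out


def _largest_loop(loops) -> np.ndarray | None:
    best, best_area = None, 0.0
    for lp in loops:
        x, y = lp[:, 0], lp[:, 1]
        a = abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        if a > best_area:
            best, best_area = lp, a
    return best


# ---------------------------------------------------------------------------
# orientation

def _section_cues(mesh, n_levels=20):
    """Dorsal-direction cues from planar sections of a z-aligned mesh.

    Returns ``(bow, ridge)`` 2-vectors in the section plane: ``bow`` is the
    mean deviation of the interior section centroids from the chord between
    the end centroids (points dorsally — the shaft apex bulges dorsal), and
    ``ridge`` is the radial-excess-weighted mean outline direction (points
    palmar, toward the flexor-sheath ridges).
    """
    z0, z1 = mesh.bounds[0][2], mesh.bounds[1][2]
    levels = z0 + (z1 - z0) * np.linspace(0.12, 0.88, n_levels)
    loops = _multi_section_loops(mesh, levels)
    cents, ridge = [], np.zeros(2)
    for lps in loops:
        lp = _largest_loop(lps)
        if lp is None:
            continue
        _, c, _, _ = polygon_moments(lp, validate=False)
        cents.append(c)
        d = lp - c
        r = np.linalg.norm(d, axis=1)
        u = d / np.maximum(r, 1e-12)[:, None]
        ridge += ((r - r.mean())[:, None] * u).mean(axis=0)
    cents = np.asarray(cents)
    if len(cents) < 5:
        return np.zeros(2), np.zeros(2)
    frac = np.linspace(0, 1, len(cents))
    chord = cents[0] + frac[:, None] * (cents[-1] - cents[0])
    bow = (cents - chord)[1:-1].mean(axis=0)
    return bow, ridge / len(cents)


def standard_orientation(pair: MeshPair, dorsal_hint=None):
    """Rotate a mesh pair into the canonical frame.

    The periosteal vertex cloud's principal axis is aligned to +z with the
    larger (proximal, base) end at low z.  Dorsal (+y) is recovered from
    the dorsopalmar asymmetry: primarily the dorsal bow of the shaft
    centroid curve, secondarily the palmar flexor-ridge mass; if both cues
    are negligible and no ``dorsal_hint`` (approximate world-frame dorsal
    vector) is given, the ambiguity is flagged rather than guessed silently.

    Returns ``(oriented_pair, info)`` where ``info`` records the 4x4
    transform and the ``mirrored`` / ``ambiguous_dorsal`` flags.
    """
    verts = np.asarray(pair.periosteal.vertices, dtype=float)
    mirrored = bool(pair.periosteal.volume < 0)
    center = verts.mean(axis=0)
    cov = np.cov((verts - center).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[2] < 1.5 * evals[1]:
        raise ValueError("no dominant long axis (near-spherical input)")
    axis_z = evecs[:, 2]

    # proximal (larger) end at low z: compare lateral spread in end quartiles
    z = (verts - center) @ axis_z
    lat = verts - center - np.outer(z, axis_z)
    r = np.linalg.norm(lat, axis=1)
    lo, hi = np.quantile(z, [0.25, 0.75])
    if np.mean(r[z <= lo]) < np.mean(r[z >= hi]):
        axis_z = -axis_z

    # dorsal cues come from planar sections in a temporary z-aligned frame
    b1 = evecs[:, 1] - (evecs[:, 1] @ axis_z) * axis_z
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(axis_z, b1)
    R0 = np.vstack([b1, b2, axis_z])
    import trimesh as _tm

    tmp = _tm.Trimesh((verts - center) @ R0.T, pair.periosteal.faces, process=False)
    bow, ridge = _section_cues(tmp)
    span = float(z.max() - z.min())
    mean_r = float(np.mean(r))
    dorsal2 = None
    if np.linalg.norm(bow) > 1e-3 * span:
        dorsal2 = bow / np.linalg.norm(bow)  # shaft apex bulges dorsally
    elif np.linalg.norm(ridge) > 2e-3 * mean_r:
        dorsal2 = -ridge / np.linalg.norm(ridge)  # ridges sit palmar
    ambiguous = dorsal2 is None
    if ambiguous:
        if dorsal_hint is not None:
            h = np.asarray(dorsal_hint, dtype=float)
            h2 = np.array([h @ b1, h @ b2])
            if np.linalg.norm(h2) == 0:
                raise ValueError("dorsal_hint is parallel to the long axis")
            dorsal2 = h2 / np.linalg.norm(h2)
            ambiguous = False
        else:
            dorsal2 = np.array([0.0, 1.0])  # arbitrary, flagged
    dorsal = dorsal2[0] * b1 + dorsal2[1] * b2

    axis_y = dorsal - (dorsal @ axis_z) * axis_z
    axis_y /= np.linalg.norm(axis_y)
    axis_x = np.cross(axis_y, axis_z)
    R = np.vstack([axis_x, axis_y, axis_z])  # world -> canonical rotation

    T = np.eye(4)
    T[:3, :3] = R
    new_verts = verts @ R.T
    # proximal end at z = 0, shaft centered in x/y
    shift = np.array([new_verts[:, 0].mean(), new_verts[:, 1].mean(), new_verts[:, 2].min()])
    T[:3, 3] = -shift
    oriented = pair.apply_transform(T)
    info = {"transform": T, "mirrored": mirrored, "ambiguous_dorsal": ambiguous}
    return oriented, info


# ---------------------------------------------------------------------------
# ROI

@dataclass
class ShaftROI:
    """Cropped diaphyseal region of interest with its section levels."""

    pair: MeshPair
    z_start: float
    z_end: float
    buffer_fraction: float
    proximal_fraction: float
    distal_fraction: float

    @property
    def span(self) -> float:
        return self.z_end - self.z_start

    def level_z(self, level) -> np.ndarray:
        return self.z_start + np.asarray(level, dtype=float) * self.span


def define_roi(
    pair: MeshPair,
    proximal_fraction: float,
    distal_fraction: float,
    buffer: float = 0.02,
) -> ShaftROI:
    """Crop the oriented pair to the shaft ROI plus a buffer.

    Fractions locate the distal-most extent of the base and the proximal
    end of the trochlea along the bone's z-extent; the crop extends
    ``buffer`` (default 2%) of the ROI span beyond each end so that every
    section level from 2% to 98% lies strictly inside cropped geometry.
    """
    if not (0 < proximal_fraction < distal_fraction < 1):
        raise ValueError("need 0 < proximal_fraction < distal_fraction < 1")
    z0, z1 = pair.periosteal.bounds[0][2], pair.periosteal.bounds[1][2]
    bone_span = z1 - z0
    z_start = z0 + proximal_fraction * bone_span
    z_end = z0 + distal_fraction * bone_span
    span = z_end - z_start
    if span < 0.05 * bone_span:
        raise ValueError("ROI shorter than five sections' worth of shaft")
    z_lo = z_start - buffer * span
    z_hi = z_end + buffer * span

    def crop(mesh):
        m = mesh.slice_plane([0, 0, z_lo], [0, 0, 1])
        m = m.slice_plane([0, 0, z_hi], [0, 0, -1])
        if len(m.vertices) == 0:
            raise ValueError("crop removed the entire mesh")
        return m

    cropped = MeshPair(
        periosteal=crop(pair.periosteal),
        endosteal=crop(pair.endosteal),
        frame=dict(pair.frame),
    )
    return ShaftROI(
        pair=cropped,
        z_start=z_start,
        z_end=z_end,
        buffer_fraction=buffer,
        proximal_fraction=proximal_fraction,
        distal_fraction=distal_fraction,
    )


def define_roi_from_frame(pair: MeshPair, buffer: float = 0.02) -> ShaftROI:
    """ROI from a phantom's self-declared shaft endpoints (frame metadata)."""
    if "shaft_ends_3d" not in pair.frame and "shaft_z" not in pair.frame:
        raise ValueError("mesh pair carries no self-declared shaft ROI")
    if "shaft_ends_3d" in pair.frame:
        ends = np.asarray(pair.frame["shaft_ends_3d"], dtype=float)
        zp, zd = float(ends[0][2]), float(ends[1][2])
    else:
        zp, zd = pair.frame["shaft_z"]
    z0, z1 = pair.periosteal.bounds[0][2], pair.periosteal.bounds[1][2]
    return define_roi(
        pair, (zp - z0) / (z1 - z0), (zd - z0) / (z1 - z0), buffer=buffer
    )


# ---------------------------------------------------------------------------
# cross-sections and landmarks

@dataclass
class CrossSection:
    level: float
    periosteal_outline: np.ndarray
    endosteal_outline: np.ndarray
    centroid: np.ndarray  # centroid of the cortical ring area

    def __post_init__(self):
        a_o, _, _, _ = polygon_moments(self.periosteal_outline, validate=False)
        a_i, _, _, _ = polygon_moments(self.endosteal_outline, validate=False)
        if a_i >= a_o:
            raise ValueError("endosteal outline area must be below periosteal area")


def _ring_centroid(outer: np.ndarray, inner: np.ndarray) -> np.ndarray:
    a_o, c_o, _, _ = polygon_moments(outer, validate=False)
    a_i, c_i, _, _ = polygon_moments(inner, validate=False)
    return (a_o * c_o - a_i * c_i) / (a_o - a_i)


def _make_section(level, outer_loops, inner_loops) -> CrossSection:
    outer = _largest_loop(outer_loops)
    inner = _largest_loop(inner_loops)
    if outer is None:
        raise ExclusionError(f"no periosteal outline at level {level:.2f}")
    if inner is None:
        raise ExclusionError(
            f"no endosteal outline at level {level:.2f} (in-filled medullary cavity)"
        )
    return CrossSection(
        level=float(level),
        periosteal_outline=outer,
        endosteal_outline=inner,
        centroid=_ring_centroid(outer, inner),
    )


def slice_sections(roi: ShaftROI, levels=None) -> list[CrossSection]:
    """Extract the 97 standard cross-sections (or custom levels) of the ROI.

    Raises :class:`ExclusionError` if the endosteal outline is missing at
    any requested level, propagating the specimen-exclusion rule for
    distally in-filled cortices.
    """
    levels = SECTION_LEVELS if levels is None else np.asarray(levels, dtype=float)
    z = roi.level_z(levels)
    outer_all = _multi_section_loops(roi.pair.periosteal, z)
    inner_all = _multi_section_loops(roi.pair.endosteal, z)
    return [
        _make_section(lv, o, i) for lv, o, i in zip(levels, outer_all, inner_all)
    ]


def cross_section_at(roi: ShaftROI, level: float) -> CrossSection:
    z = float(roi.level_z(level))
    return _make_section(
        level,
        section_loops(roi.pair.periosteal, z),
        section_loops(roi.pair.endosteal, z),
    )


@dataclass
class LandmarkSet:
    angles_deg: np.ndarray  # 50 ray angles from dorsal (+y), clockwise to +x
    external_pts: np.ndarray  # (k, 2)
    internal_pts: np.ndarray  # (k, 2)
    thickness: np.ndarray  # (k,) mm


def _ray_farthest_hit(origin, direction, poly) -> float:
    """Largest positive ray parameter t where origin + t*direction crosses
    the polygon boundary; NaN if the ray misses entirely."""
    p = np.asarray(poly, dtype=float)
    q = np.roll(p, -1, axis=0)
    e = q - p  # edge vectors
    w = p - origin
    denom = direction[0] * (-e[:, 1]) - direction[1] * (-e[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w[:, 0] * (-e[:, 1]) - w[:, 1] * (-e[:, 0])) / denom
        u = (direction[0] * w[:, 1] - direction[1] * w[:, 0]) / denom
    # tolerant edge-parameter window: a ray through a polygon vertex must
    # register on at least one of the two incident edges
    eps = 1e-9
    ok = (np.abs(denom) > 1e-14) & (u >= -eps) & (u <= 1.0 + eps) & (t > 1e-12)
    return float(np.max(t[ok])) if ok.any() else float("nan")


def place_landmarks(section: CrossSection, k: int = N_LANDMARKS) -> LandmarkSet:
    """Place ``k`` paired equiangular semi-landmarks on one cross-section.

    Rays start at the cortical-ring centroid, the first pointing dorsally
    (+y) and subsequent rays at increments of 360/k degrees toward +x.
    Each ray's landmark on an outline is its farthest boundary crossing, a
    tie-break that remains stable when FSR ridges make the outline concave.
    """
    angles = np.arange(k) * (360.0 / k)
    rad = np.radians(angles)
    dirs = np.column_stack([np.sin(rad), np.cos(rad)])
    ext = np.empty((k, 2))
    intr = np.empty((k, 2))
    thick = np.empty(k)
    o = section.centroid
    for j in range(k):
        t_out = _ray_farthest_hit(o, dirs[j], section.periosteal_outline)
        t_in = _ray_farthest_hit(o, dirs[j], section.endosteal_outline)
        if not np.isfinite(t_out) or not np.isfinite(t_in):
            raise ValueError(
                f"ray {j} at level {section.level:.2f} misses an outline "
                "(centroid outside the medullary cavity?)"
            )
        ext[j] = o + t_out * dirs[j]
        intr[j] = o + t_in * dirs[j]
        thick[j] = t_out - t_in
    if np.any(thick <= 0):
        raise ValueError(f"non-positive thickness at level {section.level:.2f}")
    return LandmarkSet(angles_deg=angles, external_pts=ext, internal_pts=intr, thickness=thick)


# ---------------------------------------------------------------------------
# thickness maps

@dataclass
class ThicknessMap:
    """97 x 50 cortical thickness matrix (sections x rays) plus metadata.

    Rows run proximal to distal (ROI levels 2%..98%), columns start at the
    dorsal ray and advance toward +x.  ``scaled`` marks division by bone
    length (entries then dimensionless).
    """

    values: np.ndarray
    bone_length_mm: float
    scaled: bool = False
    taxon: str | None = None
    digit: int | None = None
    levels: np.ndarray = field(default_factory=lambda: SECTION_LEVELS.copy())
    angles_deg: np.ndarray = field(
        default_factory=lambda: np.arange(N_LANDMARKS) * (360.0 / N_LANDMARKS)
    )

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.values.shape[0] * self.values.shape[1]:
            raise ValueError("values must be a 2D matrix")
        if np.any(self.values <= 0):
            raise ValueError("all thickness entries must be positive")

    @property
    def n_measurements(self) -> int:
        return int(self.values.size)


def build_thickness_map(
    sections,
    landmark_sets,
    bone_length_mm: float,
    taxon: str | None = None,
    digit: int | None = None,
) -> ThicknessMap:
    """Assemble per-section landmark thicknesses into the map matrix."""
    if len(sections) != len(landmark_sets):
        raise ValueError("sections and landmark sets differ in count")
    k = len(landmark_sets[0].thickness)
    if any(len(ls.thickness) != k for ls in landmark_sets):
        raise ValueError("inconsistent landmark counts across sections")
    values = np.vstack([ls.thickness for ls in landmark_sets])
    return ThicknessMap(
        values=values,
        bone_length_mm=float(bone_length_mm),
        taxon=taxon,
        digit=digit,
        levels=np.asarray([s.level for s in sections], dtype=float),
        angles_deg=landmark_sets[0].angles_deg.copy(),
    )


def compute_thickness_map(
    roi: ShaftROI,
    bone_length_mm: float | None = None,
    k: int = N_LANDMARKS,
    taxon: str | None = None,
    digit: int | None = None,
) -> ThicknessMap:
    """Full mapping of one ROI: 97 sections, k paired landmarks each.

    ``bone_length_mm`` should be the full (uncropped) bone length; if not
    given it is inferred from the ROI span and its bone-length fractions.
    """
    if bone_length_mm is None:
        bone_length_mm = roi.span / (roi.distal_fraction - roi.proximal_fraction)
    sections = slice_sections(roi)
    landmark_sets = [place_landmarks(s, k=k) for s in sections]
    return build_thickness_map(
        sections,
        landmark_sets,
        bone_length_mm=bone_length_mm,
        taxon=taxon,
        digit=digit,
    )


def bone_length(pair: MeshPair) -> float:
    """Bone length: z-extent of the oriented periosteal surface (most
    proximal extent of the base to most distal extent of the trochlea)."""
    b = pair.periosteal.bounds
    return float(b[1][2] - b[0][2])


def scale_map(tmap: ThicknessMap, length_mm: float) -> ThicknessMap:
    """Divide every entry by bone length, making the map dimensionless."""
    if tmap.scaled:
        raise ValueError("map is already scaled")
    if length_mm <= 0:
        raise ValueError("length must be positive")
    return ThicknessMap(
        values=tmap.values / length_mm,
        bone_length_mm=length_mm,
        scaled=True,
        taxon=tmap.taxon,
        digit=tmap.digit,
        levels=tmap.levels.copy(),
        angles_deg=tmap.angles_deg.copy(),
    )


def geometric_mean_size(
    length: float, midshaft_breadth: float, base_breadth: float, trochlea_breadth: float
) -> float:
    """Composite size proxy: fourth root of the product of phalangeal
    length, mid-shaft breadth, base breadth and trochlea breadth."""
    vals = np.array([length, midshaft_breadth, base_breadth, trochlea_breadth], float)
    if np.any(vals <= 0):
        raise ValueError("all size measurements must be positive")
    return float(np.prod(vals) ** 0.25)


def measure_breadths(pair: MeshPair, roi: ShaftROI):
    """(length, midshaft, base, trochlea) breadths: x-extents of periosteal
    sections at mid-ROI, 7.5% and 92.5% of bone length."""
    z0, z1 = pair.periosteal.bounds[0][2], pair.periosteal.bounds[1][2]
    L = z1 - z0

    def breadth(z):
        loops = section_loops(pair.periosteal, z)
        lp = _largest_loop(loops)
        if lp is None:
            raise ValueError(f"no section at z = {z:.2f}")
        return float(lp[:, 0].max() - lp[:, 0].min())

    return (
        L,
        breadth(roi.z_start + 0.5 * roi.span),
        breadth(z0 + 0.075 * L),
        breadth(z0 + 0.925 * L),
    )


def _sector_indices(k: int, n_sector: int):
    if n_sector % 2 == 0:
        raise ValueError("sector size must be odd to center on the midline ray")
    if 2 * n_sector > k:
        raise ValueError("sectors overlap: reduce sector size")
    half = n_sector // 2
    dorsal = np.array([(j % k) for j in range(-half, half + 1)])
    palmar = (dorsal + k // 2) % k
    return dorsal, palmar


def palmar_dorsal_partition(tmap: ThicknessMap, n_sector: int = 13):
    """Mean thickness of palmar and dorsal sectors and their ratio.

    Uses ``n_sector`` rays centered on the dorsal (+y) and palmar (-y)
    midlines (default 13 each of 50, leaving 12 medial and 12 lateral rays
    excluded so the FSR bands do not contribute), matching the protocol of
    comparing equal landmark counts away from the ridges.  Returns
    ``(palmar_mean, dorsal_mean, palmar/dorsal ratio)``.
    """
    k = tmap.values.shape[1]
    dorsal_idx, palmar_idx = _sector_indices(k, n_sector)
    dorsal_mean = float(tmap.values[:, dorsal_idx].mean())
    palmar_mean = float(tmap.values[:, palmar_idx].mean())
    return palmar_mean, dorsal_mean, palmar_mean / dorsal_mean


def render_morphometric_map(tmap: ThicknessMap, out_png=None, out_csv=None, cmap="inferno"):
    """Unrolled 2D morphometric map (and CSV) of one bone.

    Rows are sections proximal (bottom) to distal (top); columns are rays
    with the dorsal midline at the center of the image.  The color scale is
    per-bone (maps of different bones are independent).  Returns the
    matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = tmap.values.shape[1]
    rolled = np.roll(tmap.values, k // 2, axis=1)
    fig, ax = plt.subplots(figsize=(5, 7))
    im = ax.imshow(
        rolled,
        origin="lower",
        aspect="auto",
        cmap=cmap,
        extent=[-180, 180, tmap.levels[0] * 100, tmap.levels[-1] * 100],
    )
    ax.set_xlabel("angle from dorsal (deg; 0 = dorsal, +/-180 = palmar)")
    ax.set_ylabel("shaft level (% ROI, proximal to distal)")
    unit = "" if tmap.scaled else " (mm)"
    fig.colorbar(im, ax=ax, label=f"cortical thickness{unit}")
    if out_png is not None:
        fig.savefig(out_png, dpi=150, bbox_inches="tight")
    if out_csv is not None:
        df = pd.DataFrame(
            tmap.values,
            index=[f"{lv:.2f}" for lv in tmap.levels],
            columns=[f"phi_{a:.1f}" for a in tmap.angles_deg],
        )
        df.to_csv(out_csv, float_format="%.17g")  # exact round trip
    plt.close(fig)
    return fig


def load_map_csv(path) -> np.ndarray:
    """Matrix back from a map CSV written by :func:`render_morphometric_map`."""
    return pd.read_csv(path, index_col=0, float_precision="round_trip").to_numpy()
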