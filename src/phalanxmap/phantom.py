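"""Parametric proximal-phalanx phantoms with known ground truth.

A phantom is a pair of closed triangulated surfaces (periosteal outside,
endosteal inside) swept along a circular-arc centerline.  Every geometric
quantity the analysis pipeline later measures — the cortical thickness
field, the included angle of longitudinal curvature, cross-sectional
areas and moments — is known analytically from the generating
:class:`PhalanxSpec`, so the phantoms serve as end-to-end oracles.

Coordinate convention (fixed throughout the package): the proximodistal
axis is +z with the proximal end at low z, dorsal is +y, the radial side
is +x.  The circumferential angle ``phi`` is measured in degrees from
dorsal (+y), increasing toward +x, so palmar is ``phi = 180``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "PhalanxSpec",
    "MeshPair",
    "VoxelPhantom",
    "generate_centerline",
    "thickness_field",
    "generate_mesh_pair",
    "taxon_preset",
    "cohort_specs",
    "voxelize",
    "save_mesh_pair",
    "load_mesh_pair",
    "PRESET_NAMES",
]

# extra flare of the proximal (base) cap relative to the distal (trochlea) cap,
# so that "proximal end is the larger end" is true by construction
_BASE_FLARE = 0.18
# fraction of the designed FSR thickness that is also expressed as an
# outward ridge on the periosteal wall (the rest thickens the cortex inward)
_FSR_OUTER_FRACTION = 0.5


@dataclass(frozen=True)
class PhalanxSpec:
    """Generative parameters of one phalanx phantom.

    Lengths are millimetres, angles degrees.  ``included_angle_deg`` is the
    arc angle subtended by the shaft centerline in the dorsopalmar plane
    (0 = straight).  ``taper`` is the fractional radius reduction at
    mid-shaft relative to the flared ends.  The cortical thickness field is
    ``base_thickness_mm`` plus Gaussian flexor-sheath-ridge (FSR) bumps at
    ``fsr_angles_deg`` and a distodorsal term growing toward the distal
    dorsal shaft.
    """

    length_mm: float = 40.0
    included_angle_deg: float = 0.0
    outer_radius_mm: float = 5.0
    taper: float = 0.12
    base_thickness_mm: float = 1.2
    fsr_amplitude: float = 0.0
    fsr_angles_deg: tuple[float, float] = (120.0, 240.0)
    fsr_sigma_deg: float = 10.0
    fsr_window_center: float = 0.5
    fsr_window_sd: float = 0.22
    flattening: float = 0.10  # dorsopalmar elliptical flattening of the outer wall
    distodorsal_amplitude: float = 0.0
    distodorsal_sigma_deg: float = 40.0
    noise_sd: float = 0.0
    mesh_resolution: tuple[int, int] = (200, 128)
    seed: int = 0
    # shaft (ROI) occupies [shaft_start, shaft_end] of the centerline; the
    # remainder is base / trochlea cap anatomy that ROI cropping must exclude
    shaft_start: float = 0.15
    shaft_end: float = 0.85
    # fraction of the shaft, measured from its distal end, whose medullary
    # cavity is filled with bone (emulates distally in-filled specimens)
    lumen_fill_distal_fraction: float = 0.0

    def __post_init__(self):
        if self.length_mm <= 0 or self.outer_radius_mm <= 0:
            raise ValueError("length_mm and outer_radius_mm must be positive")
        if self.included_angle_deg < 0:
            raise ValueError("included_angle_deg must be >= 0")
        if not (0 <= self.taper < 1):
            raise ValueError("taper must be in [0, 1)")
        if self.base_thickness_mm <= 0:
            raise ValueError("base_thickness_mm must be positive")
        if self.fsr_amplitude < 0 or self.distodorsal_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.shaft_start < self.shaft_end < 1):
            raise ValueError("shaft fractions must satisfy 0 < start < end < 1")
        if not (0 <= self.lumen_fill_distal_fraction < 1):
            raise ValueError("lumen_fill_distal_fraction must be in [0, 1)")
        if not (0 <= self.flattening < 0.5):
            raise ValueError("flattening must be in [0, 0.5)")
        n_ax, n_circ = self.mesh_resolution
        if n_ax < 16 or n_circ < 16:
            raise ValueError("mesh_resolution too coarse (minimum 16 x 16)")
        # thickness positivity over a dense grid; the field is smooth so a
        # grid check at the analysis resolution is sufficient
        s = np.linspace(0, 1, 97)
        phi = np.arange(0, 360, 360 / 50)
        t = thickness_field(self, s[:, None], phi[None, :])
        if np.min(t) <= 0:
            raise ValueError("parameters produce a non-positive thickness field")
        # inner surface must stay strictly inside the outer one
        r_out = _shaft_outer_radius(self, s[:, None], phi[None, :])
        if np.min(r_out - t) <= 0.05 * self.outer_radius_mm:
            raise ValueError("thickness too large: endosteal surface would collapse")

    @property
    def shaft_fractional_span(self) -> float:
        return self.shaft_end - self.shaft_start

    @property
    def shaft_arc_length_mm(self) -> float:
        """Arc length of the shaft (ROI) portion of the centerline."""
        return self.length_mm * self.shaft_fractional_span

    @property
    def arc_radius_mm(self) -> float:
        """Radius of the centerline arc; ``inf`` for a straight shaft.

        ``included_angle_deg`` is the angle subtended by the *shaft*
        portion of the centerline (the segment the included-angle method
        actually measures), so the radius is shaft arc length over theta.
        """
        th = np.radians(self.included_angle_deg)
        return float("inf") if th == 0 else self.shaft_arc_length_mm / th

    def scaled(self, c: float) -> "PhalanxSpec":
        """Return a copy with every linear (mm) parameter multiplied by ``c``."""
        return dataclasses.replace(
            self,
            length_mm=self.length_mm * c,
            outer_radius_mm=self.outer_radius_mm * c,
            base_thickness_mm=self.base_thickness_mm * c,
            fsr_amplitude=self.fsr_amplitude * c,
            distodorsal_amplitude=self.distodorsal_amplitude * c,
            noise_sd=self.noise_sd * c,
        )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["fsr_angles_deg"] = list(d["fsr_angles_deg"])
        d["mesh_resolution"] = list(d["mesh_resolution"])
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhalanxSpec":
        d = json.loads(text)
        d["fsr_angles_deg"] = tuple(d["fsr_angles_deg"])
        d["mesh_resolution"] = tuple(d["mesh_resolution"])
        return cls(**d)


@dataclass
class MeshPair:
    """Periosteal (outer) and endosteal (inner) closed surfaces of one bone.

    ``frame`` records the orientation convention and, for phantoms, the
    self-declared shaft ROI as absolute z bounds.
    """

    periosteal: trimesh.Trimesh
    endosteal: trimesh.Trimesh
    frame: dict = field(default_factory=dict)

    def copy(self) -> "MeshPair":
        return MeshPair(self.periosteal.copy(), self.endosteal.copy(), dict(self.frame))

    def apply_transform(self, matrix: np.ndarray) -> "MeshPair":
        out = self.copy()
        out.periosteal.apply_transform(matrix)
        out.endosteal.apply_transform(matrix)
        if "shaft_ends_3d" in out.frame:
            pts = np.asarray(out.frame["shaft_ends_3d"], dtype=float)
            h = np.hstack([pts, np.ones((len(pts), 1))])
            out.frame["shaft_ends_3d"] = (h @ np.asarray(matrix).T)[:, :3]
        return out


@dataclass
class VoxelPhantom:
    """Binary cortex mask on an isotropic grid.

    ``cortex_mask`` is indexed ``[z, y, x]``; world coordinates of voxel
    centres are ``origin + (index + 0.5) * voxel_size`` per axis.
    """

    cortex_mask: np.ndarray
    voxel_size_mm: float
    origin: np.ndarray
    undersampled: bool = False
    shaft_z: tuple | None = None  # absolute z bounds of the shaft ROI, if known


# ---------------------------------------------------------------------------
# centerline and analytic fields

def _arc_alpha(spec: PhalanxSpec, s):
    """Arc parameter angle (radians) at fractional position s along the bone.

    The shaft portion [shaft_start, shaft_end] subtends the spec's included
    angle, so the full centerline subtends theta / shaft_fractional_span.
    """
    th = np.radians(spec.included_angle_deg) / spec.shaft_fractional_span
    return (np.asarray(s, dtype=float) - 0.5) * th


def centerline_frame(spec: PhalanxSpec, s):
    """Centerline points and local dorsal normals at fractional positions s.

    Returns ``(C, N)`` where ``C[k]`` is the 3D centerline point and ``N[k]``
    the unit vector pointing dorsally (outward from the arc center), both in
    the canonical frame.  The binormal (radial) direction is +x everywhere.
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    th = np.radians(spec.included_angle_deg) / spec.shaft_fractional_span
    L = spec.length_mm
    C = np.zeros(s.shape + (3,))
    N = np.zeros_like(C)
    if th == 0:
        C[..., 2] = s * L
        N[..., 1] = 1.0
        return C, N
    R = L / th
    a = _arc_alpha(spec, s)
    # circle center sits palmar of the shaft; apex of the arc bulges dorsally
    C[..., 1] = R * np.cos(a) - R * np.cos(th / 2)
    C[..., 2] = R * np.sin(a) + R * np.sin(th / 2)
    N[..., 1] = np.cos(a)
    N[..., 2] = np.sin(a)
    return C, N


def generate_centerline(spec: PhalanxSpec, n: int = 101) -> np.ndarray:
    """Sample the bone centerline: a circular arc of total arc length
    ``length_mm`` in the dorsopalmar plane, whose shaft (ROI) portion
    subtends ``included_angle_deg`` (a straight segment when the angle is
    zero).  The arc radius is therefore shaft arc length / theta."""
    if spec.included_angle_deg >= 180 and spec.arc_radius_mm < 2 * spec.outer_radius_mm:
        raise ValueError("degenerate shaft: arc radius smaller than shaft radius")
    C, _ = centerline_frame(spec, np.linspace(0, 1, n))
    return C


def _wrapped_dphi(phi_deg, center_deg):
    d = (np.asarray(phi_deg, dtype=float) - center_deg + 180.0) % 360.0 - 180.0
    return d


def thickness_field(spec: PhalanxSpec, s, phi_deg):
    """Ground-truth cortical thickness (mm) at shaft fraction ``s`` in [0, 1]
    (proximal to distal along the ROI) and circumferential angle ``phi_deg``
    from dorsal.

    The field is ``t0`` plus Gaussian FSR bumps (in angle, windowed along
    the shaft) plus a distodorsal term that grows quadratically toward the
    distal end and is peaked at the dorsal midline.  Broadcasting over
    array-valued ``s`` and ``phi_deg`` is supported.
    """
    s = np.asarray(s, dtype=float)
    phi = np.asarray(phi_deg, dtype=float)
    t = np.full(np.broadcast_shapes(s.shape, phi.shape), spec.base_thickness_mm)
    if spec.fsr_amplitude > 0:
        win = np.exp(-(((s - spec.fsr_window_center) / spec.fsr_window_sd) ** 2))
        bump = np.zeros_like(t)
        for ang in spec.fsr_angles_deg:
            d = _wrapped_dphi(phi, ang)
            bump = np.maximum(bump, np.exp(-((d / spec.fsr_sigma_deg) ** 2)))
        t = t + spec.fsr_amplitude * win * bump
    if spec.distodorsal_amplitude > 0:
        d = _wrapped_dphi(phi, 0.0)
        t = t + (
            spec.distodorsal_amplitude
            * s**2
            * np.exp(-((d / spec.distodorsal_sigma_deg) ** 2))
        )
    return t


def _shaft_fraction(spec: PhalanxSpec, s):
    """Map bone fraction s in [0,1] to shaft (ROI) fraction, clamped."""
    return np.clip(
        (np.asarray(s, dtype=float) - spec.shaft_start)
        / (spec.shaft_end - spec.shaft_start),
        0.0,
        1.0,
    )


def _shaft_outer_radius(spec: PhalanxSpec, s_shaft, phi_deg):
    """Outer (periosteal) radius of the shaft tube, before end caps.

    ``s_shaft`` is the shaft fraction.  Combines the mid-shaft radius, the
    taper/flare profile, dorsopalmar elliptical flattening and the outward
    half of the FSR ridges.
    """
    s = np.asarray(s_shaft, dtype=float)
    phi = np.asarray(phi_deg, dtype=float)
    c = spec.taper / (1.0 - spec.taper)
    flare = 1.0 + c * (2.0 * s - 1.0) ** 2
    ell = 1.0 - spec.flattening * np.cos(2.0 * np.radians(phi))
    r = spec.outer_radius_mm * flare * ell
    if spec.fsr_amplitude > 0:
        win = np.exp(-(((s - spec.fsr_window_center) / spec.fsr_window_sd) ** 2))
        bump = np.zeros(np.broadcast_shapes(s.shape, phi.shape))
        for ang in spec.fsr_angles_deg:
            d = _wrapped_dphi(phi, ang)
            bump = np.maximum(bump, np.exp(-((d / spec.fsr_sigma_deg) ** 2)))
        r = r + _FSR_OUTER_FRACTION * spec.fsr_amplitude * win * bump
    return r


def _cap_factor(s, lo, hi):
    """Smooth radius envelope: 1 inside [lo, hi], falling to 0 at s=0 / s=1
    with zero slope at the junctions (hemispheroidal caps)."""
    s = np.asarray(s, dtype=float)
    f = np.ones_like(s)
    m = s < lo
    u = np.clip((lo - s[m]) / lo, 0.0, 1.0)
    f[m] = np.sqrt(np.clip(1.0 - u**2, 0.0, None))
    m = s > hi
    u = np.clip((s[m] - hi) / (1.0 - hi), 0.0, 1.0)
    f[m] = np.sqrt(np.clip(1.0 - u**2, 0.0, None))
    return f


def _base_flare(spec: PhalanxSpec, s):
    """Extra proximal flare making the base the larger end."""
    s = np.asarray(s, dtype=float)
    w = np.clip((spec.shaft_start - s) / spec.shaft_start, 0.0, None)
    return 1.0 + _BASE_FLARE * w


def _build_tube(radii, centers, normals, pole_lo, pole_hi):
    """Triangulate a closed swept tube: rings plus two pole vertices."""
    n_ax = len(centers)
    n_circ = radii.shape[1]
    phi = np.arange(n_circ) * (2 * np.pi / n_circ)
    # direction from dorsal (+N) toward radial (+x)
    dirs = (
        np.cos(phi)[None, :, None] * normals[:, None, :]
        + np.sin(phi)[None, :, None] * np.array([1.0, 0.0, 0.0])[None, None, :]
    )
    verts = centers[:, None, :] + radii[:, :, None] * dirs
    verts = verts.reshape(-1, 3)
    # poles at the exact cap ends
    verts = np.vstack([verts, pole_lo, pole_hi])
    i_lo = n_ax * n_circ
    i_hi = i_lo + 1
    faces = []
    ring = np.arange(n_circ)
    nxt = np.roll(ring, -1)
    for k in range(n_ax - 1):
        a = k * n_circ + ring
        b = k * n_circ + nxt
        c = (k + 1) * n_circ + ring
        d = (k + 1) * n_circ + nxt
        faces.append(np.stack([a, b, d], axis=1))
        faces.append(np.stack([a, d, c], axis=1))
    # pole fans
    a = ring
    b = nxt
    faces.append(np.stack([np.full(n_circ, i_lo), b, a], axis=1))
    a = (n_ax - 1) * n_circ + ring
    b = (n_ax - 1) * n_circ + nxt
    faces.append(np.stack([np.full(n_circ, i_hi), a, b], axis=1))
    mesh = trimesh.Trimesh(
        vertices=verts, faces=np.vstack(faces), process=False
    )
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def generate_mesh_pair(spec: PhalanxSpec) -> MeshPair:
    """Generate the watertight periosteal/endosteal surface pair.

    The periosteal surface sweeps the flared, flattened, ridge-bearing
    radius profile along the arc centerline and is closed with
    hemispheroidal base and trochlea caps outside the shaft ROI.  The
    endosteal surface lies at the outer radius minus the ground-truth
    thickness field and closes inside the caps (or earlier distally when
    ``lumen_fill_distal_fraction`` > 0, emulating an in-filled medullary
    cavity).  Per-vertex radial Gaussian noise (seeded) emulates
    segmentation roughness.
    """
    if spec.included_angle_deg > 0 and spec.arc_radius_mm < 3 * spec.outer_radius_mm:
        raise ValueError("degenerate shaft: arc radius too small for shaft radius")
    n_ax, n_circ = spec.mesh_resolution
    rng = np.random.default_rng(spec.seed)
    phi_deg = np.arange(n_circ) * (360.0 / n_circ)

    # ---- outer surface over the full bone s in (0, 1)
    s_out = np.linspace(0.0, 1.0, n_ax + 2)[1:-1]
    ss = _shaft_fraction(spec, s_out)
    r_out = _shaft_outer_radius(spec, ss[:, None], phi_deg[None, :])
    r_out = r_out * _base_flare(spec, s_out)[:, None]
    r_out = r_out * _cap_factor(s_out, spec.shaft_start, spec.shaft_end)[:, None]
    # dimensionless noise draws scale exactly with noise_sd (similarity)
    if spec.noise_sd > 0:
        r_out = r_out + spec.noise_sd * np.clip(
            rng.standard_normal(r_out.shape), -3, 3
        )
    C, N = centerline_frame(spec, s_out)
    (p_lo, p_hi), _ = centerline_frame(spec, [0.0, 1.0])
    outer = _build_tube(r_out, C, N, p_lo, p_hi)

    # ---- inner surface over the lumen extent
    lumen_lo = 0.5 * spec.shaft_start
    lumen_hi = 1.0 - 0.5 * (1.0 - spec.shaft_end)
    if spec.lumen_fill_distal_fraction > 0:
        lumen_hi = spec.shaft_end - spec.lumen_fill_distal_fraction * (
            spec.shaft_end - spec.shaft_start
        )
    n_ax_in = max(16, int(n_ax * (lumen_hi - lumen_lo)))
    s_in = np.linspace(lumen_lo, lumen_hi, n_ax_in + 2)[1:-1]
    ss_in = _shaft_fraction(spec, s_in)
    r_ref = _shaft_outer_radius(spec, ss_in[:, None], phi_deg[None, :])
    r_ref = r_ref * _base_flare(spec, s_in)[:, None]
    r_ref = r_ref * _cap_factor(s_in, spec.shaft_start, spec.shaft_end)[:, None]
    t = thickness_field(spec, ss_in[:, None], phi_deg[None, :])
    r_in = r_ref - t
    # close the lumen smoothly with its own hemispheroidal envelope
    blend = 0.10 * (lumen_hi - lumen_lo)
    cap_in = _cap_factor(
        (s_in - lumen_lo) / (lumen_hi - lumen_lo), blend, 1.0 - blend
    )
    r_in = np.clip(r_in, 0.05 * spec.outer_radius_mm, None) * cap_in[:, None]
    if spec.noise_sd > 0:
        r_in = r_in + spec.noise_sd * np.clip(
            rng.standard_normal(r_in.shape), -3, 3
        )
        r_in = np.minimum(r_in, r_ref - 0.25 * spec.base_thickness_mm)
    C_in, N_in = centerline_frame(spec, s_in)
    (q_lo, q_hi), _ = centerline_frame(spec, [lumen_lo, lumen_hi])
    inner = _build_tube(r_in, C_in, N_in, q_lo, q_hi)

    if not (outer.is_watertight and inner.is_watertight):
        raise RuntimeError("phantom surfaces are not watertight")

    # self-declared shaft ROI as absolute z of the centerline shaft ends
    (z_lo,), _ = centerline_frame(spec, [spec.shaft_start])
    (z_hi,), _ = centerline_frame(spec, [spec.shaft_end])
    frame = {
        "axis": "z-proximodistal",
        "dorsal": "+y",
        "radial": "+x",
        "shaft_z": (float(z_lo[2]), float(z_hi[2])),
        "shaft_ends_3d": np.vstack([z_lo, z_hi]),
        "spec": spec,
    }
    return MeshPair(periosteal=outer, endosteal=inner, frame=frame)


# ---------------------------------------------------------------------------
# taxon presets

PRESET_NAMES = ("pongo", "gorilla", "pan", "homo")

_PRESETS = {
    # strongly curved, moderate FSRs, thin cortex
    "pongo": dict(
        length_mm=45.0,
        included_angle_deg=60.0,
        outer_radius_mm=4.5,
        base_thickness_mm=0.9,
        fsr_amplitude=0.55,
    ),
    # straight-ish, massive FSRs shifted distally, thick cortex
    "gorilla": dict(
        length_mm=40.0,
        included_angle_deg=25.0,
        outer_radius_mm=5.5,
        base_thickness_mm=1.6,
        fsr_amplitude=0.95,
        fsr_window_center=0.6,
    ),
    # intermediate curvature and cortex
    "pan": dict(
        length_mm=42.0,
        included_angle_deg=45.0,
        outer_radius_mm=4.8,
        base_thickness_mm=1.2,
        fsr_amplitude=0.7,
    ),
    # nearly straight, weak FSRs, the thinnest cortex of the four, with the
    # thickening that remains concentrated distodorsally
    "homo": dict(
        length_mm=40.0,
        included_angle_deg=8.0,
        outer_radius_mm=4.6,
        base_thickness_mm=0.75,
        fsr_amplitude=0.10,
        distodorsal_amplitude=0.5,
    ),
}


def taxon_preset(name: str, **overrides) -> PhalanxSpec:
    """Documented parameter bundle emulating one great-ape taxon archetype.

    The bundles encode only the comparative ordering of curvature, cortical
    thickness and ridge prominence across *Pongo*, *Gorilla*, *Pan* and
    *Homo*; the magnitudes are this package's constants, not measurements.
    """
    key = name.lower()
    if key not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available presets: {', '.join(PRESET_NAMES)}"
        )
    params = dict(_PRESETS[key])
    params.update(overrides)
    return PhalanxSpec(**params)


def cohort_specs(
    base: PhalanxSpec,
    n: int,
    seed: int,
    cv_length: float = 0.04,
    cv_thickness: float = 0.06,
    cv_radius: float = 0.04,
    cv_angle: float = 0.08,
    noise_sd: float = 0.02,
) -> list[PhalanxSpec]:
    """Individual specimens around a preset: lognormal multiplicative
    variation on length, radius, thickness, ridge amplitude and included
    angle, plus per-vertex surface noise.  Seeded and deterministic."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        f = rng.lognormal(0.0, [cv_length, cv_radius, cv_thickness, cv_angle, 0.10])
        out.append(
            dataclasses.replace(
                base,
                length_mm=base.length_mm * f[0],
                outer_radius_mm=base.outer_radius_mm * f[1],
                base_thickness_mm=base.base_thickness_mm * f[2],
                included_angle_deg=base.included_angle_deg * f[3],
                fsr_amplitude=base.fsr_amplitude * f[4],
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# voxelization

def _rasterize_polygon(poly_xy, origin_xy, voxel, shape_yx):
    """Boolean mask of voxel centres inside a polygon (matplotlib path test)."""
    from matplotlib.path import Path as MplPath

    ny, nx = shape_yx
    xs = origin_xy[0] + (np.arange(nx) + 0.5) * voxel
    ys = origin_xy[1] + (np.arange(ny) + 0.5) * voxel
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    mask = MplPath(poly_xy).contains_points(pts)
    return mask.reshape(ny, nx)


def voxelize(pair: MeshPair, voxel_size_mm: float) -> VoxelPhantom:
    """Rasterize a mesh pair into a binary cortex mask.

    The cortex is the region inside the periosteal surface and outside the
    endosteal surface, evaluated slice-by-slice from mesh-plane
    cross-sections.  If the voxel size exceeds one third of the minimum
    designed cortical thickness the result is flagged ``undersampled``.
    """
    if voxel_size_mm <= 0:
        raise ValueError("voxel_size_mm must be positive")
    if len(pair.periosteal.vertices) == 0 or len(pair.endosteal.vertices) == 0:
        raise ValueError("empty mesh input")
    undersampled = False
    spec = pair.frame.get("spec")
    if spec is not None and voxel_size_mm > spec.base_thickness_mm / 3.0:
        warnings.warn(
            "voxel size exceeds one third of the minimum cortical thickness; "
            "mask flagged as undersampled",
            stacklevel=2,
        )
        undersampled = True

    lo = pair.periosteal.bounds[0] - 2 * voxel_size_mm
    hi = pair.periosteal.bounds[1] + 2 * voxel_size_mm
    nx, ny, nz = np.ceil((hi - lo) / voxel_size_mm).astype(int)
    mask = np.zeros((nz, ny, nx), dtype=bool)
    z_centers = lo[2] + (np.arange(nz) + 0.5) * voxel_size_mm

    from .mapping import section_loops  # local import avoids a cycle

    for k, z in enumerate(z_centers):
        outer_loops = section_loops(pair.periosteal, z)
        if not outer_loops:
            continue
        sl = np.zeros((ny, nx), dtype=bool)
        for loop in outer_loops:
            sl |= _rasterize_polygon(loop, lo[:2], voxel_size_mm, (ny, nx))
        for loop in section_loops(pair.endosteal, z):
            sl &= ~_rasterize_polygon(loop, lo[:2], voxel_size_mm, (ny, nx))
        mask[k] = sl
    if not mask.any():
        raise ValueError("voxelization produced an empty mask")
    shaft_z = None
    if "shaft_ends_3d" in pair.frame:
        ends = np.asarray(pair.frame["shaft_ends_3d"], dtype=float)
        shaft_z = (float(ends[0][2]), float(ends[1][2]))
    elif "shaft_z" in pair.frame:
        shaft_z = tuple(pair.frame["shaft_z"])
    return VoxelPhantom(
        cortex_mask=mask,
        voxel_size_mm=float(voxel_size_mm),
        origin=np.asarray(lo, dtype=float),
        undersampled=undersampled,
        shaft_z=shaft_z,
    )


# ---------------------------------------------------------------------------
# mesh I/O

def save_mesh_pair(pair: MeshPair, directory, stem: str = "bone", fmt: str = "ply"):
    """Write ``<stem>_periosteal.<fmt>`` and ``<stem>_endosteal.<fmt>``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, mesh in (("periosteal", pair.periosteal), ("endosteal", pair.endosteal)):
        p = directory / f"{stem}_{label}.{fmt}"
        mesh.export(p)
        paths.append(p)
    return paths


def load_mesh_pair(periosteal_path, endosteal_path, frame: dict | None = None) -> MeshPair:
    outer = trimesh.load_mesh(periosteal_path)
    inner = trimesh.load_mesh(endosteal_path)
    return MeshPair(periosteal=outer, endosteal=inner, frame=frame or {})
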