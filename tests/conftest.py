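"""Shared fixtures: phantoms and derived products are expensive to build,
so they are session-scoped and reused across test modules."""

import numpy as np
import pytest

from phalanxmap import (
    PhalanxSpec,
    generate_mesh_pair,
    taxon_preset,
)
from phalanxmap import mapping
from phalanxmap.pipeline import arc_tube_spec, demo_cohort_table


def tube_spec(**overrides) -> PhalanxSpec:
    """Straight constant-thickness tube: the exact-annulus oracle phantom."""
    kw = dict(
        length_mm=40.0,
        included_angle_deg=0.0,
        outer_radius_mm=5.0,
        taper=0.0,
        flattening=0.0,
        base_thickness_mm=2.0,
        mesh_resolution=(200, 256),
    )
    kw.update(overrides)
    return PhalanxSpec(**kw)


@pytest.fixture(scope="session")
def tube_pair():
    return generate_mesh_pair(tube_spec())


@pytest.fixture(scope="session")
def tube_roi(tube_pair):
    return mapping.define_roi_from_frame(tube_pair)


@pytest.fixture(scope="session")
def tube_map(tube_roi):
    return mapping.compute_thickness_map(tube_roi)


@pytest.fixture(scope="session")
def preset_pairs():
    return {
        name: generate_mesh_pair(taxon_preset(name, mesh_resolution=(160, 96)))
        for name in ("pongo", "gorilla", "pan", "homo")
    }


@pytest.fixture(scope="session")
def preset_rois(preset_pairs):
    return {k: mapping.define_roi_from_frame(v) for k, v in preset_pairs.items()}


@pytest.fixture(scope="session")
def preset_maps(preset_rois):
    return {
        k: mapping.compute_thickness_map(roi, taxon=k)
        for k, roi in preset_rois.items()
    }


@pytest.fixture(scope="session")
def arc_rois():
    """Slender arc-tube ROIs at the four canonical included angles."""
    out = {}
    for th in (0, 30, 60, 120):
        pair = generate_mesh_pair(arc_tube_spec(float(th), seed=1))
        out[th] = mapping.define_roi_from_frame(pair)
    return out


@pytest.fixture(scope="session")
def cohort_table():
    """10 gorilla-like + 10 homo-like specimens, measured end-to-end."""
    return demo_cohort_table(seed=7, n_per_group=10)


def ring_polygon(radius, n=512, center=(0.0, 0.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )
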