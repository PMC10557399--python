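"""End-to-end orchestration: simulate -> orient -> map -> CSG -> curvature
-> statistics, as a reproducible, fully seeded run.

The run writes per-specimen thickness maps, a specimen feature table, the
statistical summaries and a manifest recording configuration, seeds,
exclusions (with reasons) and SHA-256 checksums of every output file, so
re-running the same config reproduces the outputs bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import csg as csg_mod
from . import curvature as curv_mod
from . import mapping, stats
from .phantom import (
    MeshPair,
    PhalanxSpec,
    cohort_specs,
    generate_mesh_pair,
    save_mesh_pair,
    taxon_preset,
)

__all__ = [
    "RunConfig",
    "analyze_specimen",
    "build_specimen_table",
    "run_statistics",
    "run_pipeline",
    "make_fixture_suite",
]

CSG_LEVELS = (0.35, 0.50, 0.65)


def arc_tube_spec(theta_deg: float, seed: int = 0, noise_sd: float = 0.0) -> PhalanxSpec:
    """Canonical curvature-validation phantom: a slender constant-radius
    arc tube (60 mm long, 2 mm outer radius, 0.5 mm wall).  Slenderness
    keeps planar z-sections valid over the whole shaft up to an included
    angle of 120 degrees (requires outer radius / arc radius < 1 -
    sin(theta/2))."""
    return PhalanxSpec(
        length_mm=60.0,
        included_angle_deg=theta_deg,
        taper=0.0,
        outer_radius_mm=2.0,
        base_thickness_mm=0.5,
        noise_sd=noise_sd,
        mesh_resolution=(240, 128),
        seed=seed,
    )


@dataclass
class RunConfig:
    """Configuration of one pipeline run.  Every stochastic stage has an
    explicit seed derived from ``seed``."""

    roster: dict = field(default_factory=lambda: {"gorilla": 6, "homo": 6, "pan": 6, "pongo": 6})
    seed: int = 0
    digit: int = 3
    scaling: str = "length"  # or "geometric_mean"
    sector: int = 13
    n_perm: int = 999
    mesh_resolution: tuple[int, int] = (160, 96)
    noise_sd: float = 0.02
    out_dir: str = "phalanxmap_run"
    write_meshes: bool = False
    # extra demo specimens with a distally in-filled medullary cavity; these
    # exercise (and must appear in) the manifest's exclusion accounting
    n_infilled_demo: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mesh_resolution"] = list(d["mesh_resolution"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "mesh_resolution" in d:
            d["mesh_resolution"] = tuple(d["mesh_resolution"])
        return cls(**d)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def analyze_specimen(
    pair: MeshPair,
    specimen_id: str,
    taxon: str,
    digit: int = 3,
    scaling: str = "length",
    sector: int = 13,
    seed: int = 0,
    orient: bool = True,
):
    """Measure one bone: thickness map, CSG at 35/50/65%, included angle,
    palmar/dorsal sector means.  Returns ``(row_dict, scaled_map)``."""
    if orient:
        pair, _ = mapping.standard_orientation(pair, dorsal_hint=[0, 1, 0])
    roi = mapping.define_roi_from_frame(pair)
    length = mapping.bone_length(pair)
    tmap = mapping.compute_thickness_map(roi, bone_length_mm=length, taxon=taxon, digit=digit)
    if scaling == "geometric_mean":
        size = mapping.geometric_mean_size(*mapping.measure_breadths(pair, roi))
    elif scaling == "length":
        size = length
    else:
        raise ValueError("scaling must be 'length' or 'geometric_mean'")
    smap = mapping.scale_map(tmap, size)
    palmar, dorsal, ratio = mapping.palmar_dorsal_partition(smap, n_sector=sector)
    props = [
        csg_mod.scale_csg(p, size)
        for p in csg_mod.csg_at_levels(roi, levels=CSG_LEVELS)
    ]
    ia = curv_mod.measure_ia(roi, seed=seed)
    row = {
        "specimen": specimen_id,
        "taxon": taxon,
        "digit": digit,
        "length_mm": length,
        "size_scale": size,
        "mean_thickness_mm": float(tmap.values.mean()),
        "mean_thickness_scaled": float(smap.values.mean()),
        "palmar_mean": palmar,
        "dorsal_mean": dorsal,
        "palmar_dorsal_ratio": ratio,
        "theta_deg": ia.theta_mean,
        "theta_replicate_range": max(ia.replicates) - min(ia.replicates),
    }
    for p in props:
        tag = f"{int(round(p.level * 100))}"
        row[f"CA_{tag}"] = p.CA
        row[f"J_{tag}"] = p.J
        row[f"Zpol_{tag}"] = p.Zpol
    return row, smap


def build_specimen_table(rows, maps) -> pd.DataFrame:
    """Feature table: one row per specimen, scalar traits plus the 4850
    scaled thickness variables (columns ``t0000`` .. ``t4849``, section-major
    order, proximal-to-distal then dorsal-clockwise)."""
    thick = np.vstack([m.values.ravel() for m in maps])
    tcols = pd.DataFrame(
        thick, columns=[f"t{i:04d}" for i in range(thick.shape[1])]
    )
    df = pd.DataFrame(rows).reset_index(drop=True)
    return pd.concat([df, tcols], axis=1)


def thickness_matrix(table: pd.DataFrame) -> np.ndarray:
    cols = [c for c in table.columns if c.startswith("t") and c[1:].isdigit()]
    return table[cols].to_numpy(dtype=float)


def run_statistics(table: pd.DataFrame, n_perm: int = 999, seed: int = 0) -> dict:
    """The full statistical chain on a specimen feature table."""
    out = {}
    X = thickness_matrix(table)
    groups = table["taxon"].to_numpy()
    pca = stats.pca_thickness(X)
    out["pca"] = pca
    out["pca_variance_fraction"] = pca.variance_fraction[:3].tolist()
    scores3 = pca.scores[:, : min(3, pca.scores.shape[1])]
    if len(np.unique(groups)) >= 2:
        omni = stats.permanova(scores3, groups, n_perm=n_perm, seed=seed)
        out["permanova_omnibus"] = omni
        if omni.p_value < 0.05:
            out["permanova_pairwise"] = stats.permanova_pairwise(
                scores3, groups, n_perm=n_perm, seed=seed + 1
            )
        route, shapiro = stats.normality_gate(
            table["mean_thickness_scaled"].to_numpy(), groups
        )
        out["normality_route"] = route
        out["shapiro"] = shapiro
        out["kruskal_mean_thickness"] = stats.kruskal_dunn(
            table["mean_thickness_scaled"].to_numpy(), groups
        )
    paired = {}
    regression = {}
    for taxon, sub in table.groupby("taxon"):
        if len(sub) >= 2:
            paired[taxon] = stats.paired_palmar_dorsal(
                sub["palmar_mean"].to_numpy(), sub["dorsal_mean"].to_numpy()
            )
        if len(sub) >= 3:
            regression[taxon] = stats.regress_ia_thickness(
                sub["theta_deg"].to_numpy(), sub["mean_thickness_scaled"].to_numpy()
            )
    out["paired_palmar_dorsal"] = paired
    out["regression_ia_thickness"] = regression
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline per the config; returns the run report.

    Excluded specimens (e.g. in-filled medullary cavities that leave no
    endosteal outline inside the shaft ROI) are logged in the manifest with
    their reason, never dropped silently.
    """
    out_dir = Path(config.out_dir)
    maps_dir = out_dir / "maps"
    maps_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    rows, maps, exclusions = [], [], []
    manifest_specs = {}
    for preset_i, (preset, n) in enumerate(sorted(config.roster.items())):
        base = taxon_preset(
            preset,
            mesh_resolution=config.mesh_resolution,
        )
        specs = cohort_specs(
            base,
            n,
            seed=int(ss.spawn(1)[0].generate_state(1)[0] % (2**31)),
            noise_sd=config.noise_sd,
        )
        for i, spec in enumerate(specs):
            sid = f"{preset}_{i:02d}"
            manifest_specs[sid] = json.loads(spec.to_json())
            try:
                pair = generate_mesh_pair(spec)
                if config.write_meshes:
                    save_mesh_pair(pair, out_dir / "meshes", stem=sid)
                row, smap = analyze_specimen(
                    pair,
                    sid,
                    taxon=preset,
                    digit=config.digit,
                    scaling=config.scaling,
                    sector=config.sector,
                    seed=config.seed + 1000 + i + 100 * preset_i,
                )
            except (mapping.ExclusionError, ValueError) as e:
                exclusions.append({"specimen": sid, "reason": str(e)})
                continue
            rows.append(row)
            maps.append(smap)
            mapping.render_morphometric_map(
                smap,
                out_png=maps_dir / f"{sid}.png",
                out_csv=maps_dir / f"{sid}.csv",
            )
    for i in range(config.n_infilled_demo):
        sid = f"infilled_{i:02d}"
        spec = taxon_preset(
            "gorilla",
            mesh_resolution=config.mesh_resolution,
            lumen_fill_distal_fraction=0.5,
            seed=config.seed + 9000 + i,
        )
        manifest_specs[sid] = json.loads(spec.to_json())
        try:
            pair = generate_mesh_pair(spec)
            row, smap = analyze_specimen(
                pair, sid, taxon="gorilla", digit=config.digit,
                scaling=config.scaling, sector=config.sector,
                seed=config.seed + 9000 + i,
            )
            rows.append(row)
            maps.append(smap)
        except (mapping.ExclusionError, ValueError) as e:
            exclusions.append({"specimen": sid, "reason": str(e)})
    if not rows:
        raise RuntimeError("all specimens were excluded; nothing to analyze")
    table = build_specimen_table(rows, maps)
    table.to_csv(out_dir / "specimen_table.csv", index=False)
    results = run_statistics(table, n_perm=config.n_perm, seed=config.seed)

    # tidy per-family outputs
    pd.DataFrame(
        {"component": [f"PC{i+1}" for i in range(len(results["pca"].variance_fraction))],
         "variance_fraction": results["pca"].variance_fraction}
    ).to_csv(out_dir / "pca_variance.csv", index=False)
    if "permanova_omnibus" in results:
        om = results["permanova_omnibus"]
        pd.DataFrame(
            [{"pseudo_F": om.pseudo_F, "R2": om.R2, "p": om.p_value,
              "n_permutations": om.n_permutations}]
        ).to_csv(out_dir / "permanova_omnibus.csv", index=False)
    if "permanova_pairwise" in results:
        results["permanova_pairwise"].to_csv(out_dir / "permanova_pairwise.csv", index=False)
    if "kruskal_mean_thickness" in results:
        kw = results["kruskal_mean_thickness"]
        kw.dunn.to_csv(out_dir / "dunn_mean_thickness.csv", index=False)
    pd.DataFrame(
        [
            {"taxon": k, "palmar_mean": v.palmar_mean, "dorsal_mean": v.dorsal_mean,
             "t": v.t_ratio, "p": v.p_value, "n": v.n}
            for k, v in results["paired_palmar_dorsal"].items()
        ]
    ).to_csv(out_dir / "paired_palmar_dorsal.csv", index=False)
    pd.DataFrame(
        [
            {"taxon": k, "slope": v.slope, "intercept": v.intercept,
             "R2": v.R2, "p": v.p_value, "n": v.n}
            for k, v in results["regression_ia_thickness"].items()
        ]
    ).to_csv(out_dir / "regression_ia_thickness.csv", index=False)

    files = sorted(p for p in out_dir.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": config.to_dict(),
        "specimens": manifest_specs,
        "exclusions": exclusions,
        "n_analyzed": len(rows),
        "files": {str(p.relative_to(out_dir)): _sha256(p) for p in files},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    report = {
        "table": table,
        "results": results,
        "exclusions": exclusions,
        "manifest": manifest,
    }
    return report


def demo_cohort_table(
    seed: int,
    n_per_group: int = 10,
    presets=("gorilla", "homo"),
    mesh_resolution=(160, 96),
    noise_sd: float = 0.02,
) -> pd.DataFrame:
    """Simulate and measure a multi-taxon cohort, returning the specimen
    feature table (scalar traits + 4850 scaled thickness variables)."""
    ss = np.random.SeedSequence(seed)
    rows, maps = [], []
    for pi, preset in enumerate(presets):
        base = taxon_preset(preset, mesh_resolution=tuple(mesh_resolution))
        specs = cohort_specs(
            base,
            n_per_group,
            seed=int(ss.spawn(1)[0].generate_state(1)[0] % (2**31)),
            noise_sd=noise_sd,
        )
        for i, spec in enumerate(specs):
            pair = generate_mesh_pair(spec)
            row, smap = analyze_specimen(
                pair, f"{preset}_{i:02d}", taxon=preset, seed=seed + 100 * pi + i
            )
            rows.append(row)
            maps.append(smap)
    return build_specimen_table(rows, maps)


def make_fixture_suite(seed: int, out_dir) -> dict:
    """Write the canonical small test fixtures used across the test suite.

    Contents: a straight constant-thickness tube spec, an annulus polygon
    pair, arc phantom specs at several included angles, and a two-taxon
    cohort roster.  Returns the fixture paths keyed by name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    tube = PhalanxSpec(
        length_mm=40.0,
        included_angle_deg=0.0,
        outer_radius_mm=5.0,
        taper=0.0,
        base_thickness_mm=2.0,
        seed=seed,
    )
    p = out / "tube_spec.json"
    p.write_text(tube.to_json())
    paths["tube_spec"] = p

    theta = np.linspace(0, 2 * np.pi, 257)[:-1]
    annulus = {
        "outer": np.column_stack([2 * np.cos(theta), 2 * np.sin(theta)]).tolist(),
        "inner": np.column_stack([np.cos(theta), np.sin(theta)]).tolist(),
    }
    p = out / "annulus_polygons.json"
    p.write_text(json.dumps(annulus))
    paths["annulus"] = p

    # slender constant-radius arc tubes: their silhouette midline is an
    # exact offset circle, the geometry the included-angle model assumes,
    # and planar z-sections remain valid out to theta = 120 degrees
    for th in (0, 30, 60, 120):
        spec = arc_tube_spec(float(th), seed=seed)
        p = out / f"arc_{th:03d}_spec.json"
        p.write_text(spec.to_json())
        paths[f"arc_{th}"] = p

    cfg = RunConfig(roster={"gorilla": 10, "homo": 10}, seed=seed)
    p = out / "cohort_config.yaml"
    cfg.to_yaml(p)
    paths["cohort_config"] = p
    return paths
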