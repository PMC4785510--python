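"""End-to-end pipeline driver: phantom -> features -> mesh -> projections ->
(optional) boundary init -> multiresolution registration -> evaluation.

A single structured configuration (YAML on disk, :class:`PipelineConfig` in
memory) holds every tunable: phantom recipe, feature/density parameters,
mesh size and seed, projection geometry and noise, registration weights and
schedule, boundary-initializer parameters, and output paths.  Runs are
deterministic given the seeds, and a JSON manifest of the resolved
configuration is written next to the artifacts.
"""
from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import boundary as bnd
from . import deform, features, meshing, metrics, phantom, project
from .register import DEFAULT_MU, multires_register
from .volume import Volume, write_volume


@dataclass
class PipelineConfig:
    # phantom
    shape: int = 48
    body_intensity: float = 0.02
    inner_intensity: float = 0.04
    dvf_kind: str = "sinusoidal"
    dvf_amplitude: tuple = (3.0, 3.0, 0.0)
    dvf_wavelength: tuple = (96.0, 96.0, 96.0)
    # features
    smoothing_width: float = 1.5
    edge_threshold_frac: float = 0.05
    mask_threshold: float = 0.01
    # meshing
    n_vertices: int = 200
    mesh_kind: str = "feature"  # feature | uniform-grid | uniform-tet
    mesh_iterations: int = 60
    seed: int = 0
    # projections
    n_projections: int = 12
    det_rows: int = 72
    det_cols: int = 72
    pixel_pitch_mm: float = 1.6
    sad_mm: float = 1000.0
    sdd_mm: float = 1500.0
    noise: bool = False
    i0: float = project.DEFAULT_I0
    sigma_e2: float = project.DEFAULT_SIGMA_E2
    # registration
    mu: float = DEFAULT_MU
    schedule: list = field(default_factory=lambda: [(2, 2, 30), (1, 1, 15)])
    use_boundary_init: bool = False
    boundary_iterations: int = 15
    delta_d: float = bnd.DEFAULT_DELTA_D
    band_halfwidth: float = bnd.DEFAULT_BAND_HALFWIDTH
    # output
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.schedule, list):
            cfg.schedule = [tuple(level) for level in cfg.schedule]
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full flow and return a result dictionary.

    Returns metric report entries plus run bookkeeping; artifacts are
    written to ``config.output_dir`` when set.
    """
    t0 = time.time()
    cfg = config
    rng_seed = int(cfg.seed)
    timings: dict[str, float] = {}

    def _stage(name):
        timings[name] = time.time() - t0

    # --- phantom and ground truth ---------------------------------------
    u_orig = phantom.default_phantom(cfg.shape, cfg.body_intensity,
                                     cfg.inner_intensity)
    true_dvf = phantom.AnalyticDVF(cfg.dvf_kind, amplitude=cfg.dvf_amplitude,
                                   wavelength=cfg.dvf_wavelength)
    u_target = phantom.warp_groundtruth(u_orig, true_dvf)
    _stage("phantom")

    # --- features, density, mesh ----------------------------------------
    mask = features.body_mask(u_orig, cfg.mask_threshold)
    edges = features.extract_feature_edges(u_orig, cfg.smoothing_width,
                                           cfg.edge_threshold_frac)
    density = features.density_from_edges(edges)
    if cfg.mesh_kind == "feature":
        mesh = meshing.feature_mesh(cfg.n_vertices, density, mask,
                                    u_orig.shape, seed=rng_seed,
                                    max_iter=cfg.mesh_iterations)
    elif cfg.mesh_kind == "uniform-grid":
        mesh = meshing.uniform_orthogonal_mesh(cfg.n_vertices, u_orig.shape)
    elif cfg.mesh_kind == "uniform-tet":
        mesh = meshing.uniform_tet_mesh(cfg.n_vertices, u_orig.shape, mask,
                                        seed=rng_seed,
                                        max_iter=cfg.mesh_iterations)
    else:
        raise ValueError(f"unknown mesh kind {cfg.mesh_kind!r}")
    _stage("mesh")

    # --- target projections ---------------------------------------------
    geoms = project.default_geometries(
        cfg.n_projections, u_orig, det_shape=(cfg.det_rows, cfg.det_cols),
        pixel_pitch_mm=cfg.pixel_pitch_mm, sad_mm=cfg.sad_mm,
        sdd_mm=cfg.sdd_mm)
    geoms[0].check_coverage(u_orig)
    measured = []
    for k, g in enumerate(geoms):
        p = project.siddon_project(u_target, g)
        if cfg.noise:
            _, p = project.add_projection_noise(
                p, cfg.i0, cfg.sigma_e2, seed=rng_seed + 1000 + k)
        measured.append(p.pixels)
    _stage("projections")

    # --- optional boundary-based initialization -------------------------
    d_init = None
    if cfg.use_boundary_init:
        target_mask = features.body_mask(u_target, cfg.mask_threshold)
        target_bounds = []
        for g in geoms:
            surf_t = bnd.extract_surface_voxels(target_mask)
            wk = bnd.splat_project(surf_t, g, u_target, with_kernel=True)
            from skimage.filters import threshold_otsu
            from scipy import ndimage as ndi
            sil = ndi.binary_fill_holes(wk.pixels > threshold_otsu(wk.pixels))
            target_bounds.append(bnd.extract_projection_boundary(
                project.ProjectionImage(sil.astype(float), meaning="boundary")))
        d_init = bnd.register_boundary(
            mask, target_bounds, geoms, mesh, u_orig, mu=cfg.mu,
            max_iter=cfg.boundary_iterations, delta_d=cfg.delta_d)
    _stage("boundary_init")

    # --- multiresolution intensity registration -------------------------
    d_opt, histories = multires_register(
        u_orig, measured, geoms, mesh, schedule=cfg.schedule, mu=cfg.mu,
        d_init=d_init)
    _stage("register")

    # --- evaluation ------------------------------------------------------
    assign = deform.grid_assignment(mesh, u_orig.shape)
    dv_est = deform.interpolate_dvf(mesh, d_opt, u_orig.shape, assign)
    u_reg = deform.warp_image(u_orig, dv_est)
    centers = u_orig.voxel_centers()
    dv_true_flat = phantom.evaluate_dvf(true_dvf, centers)
    dv_true = tuple(dv_true_flat[:, d].reshape(u_orig.shape) for d in range(3))
    img_rep = metrics.image_metrics(u_reg.data, u_target.data, mask.data)
    if any(np.any(c) for c in dv_true):
        dvf_rep = metrics.dvf_metrics(dv_est, dv_true, mask.data)
    else:  # identity ground truth: DVF error metrics are undefined
        dvf_rep = metrics.MetricReport()
    initial_rep = metrics.image_metrics(u_orig.data, u_target.data, mask.data)
    _stage("evaluate")

    result = {
        "ncc_image": img_rep.ncc_image,
        "nrmse_image": img_rep.nrmse_image,
        "ncc_dvf": dvf_rep.ncc_dvf,
        "nrmse_dvf": dvf_rep.nrmse_dvf,
        "ncc_image_initial": initial_rep.ncc_image,
        "nrmse_image_initial": initial_rep.nrmse_image,
        "max_displacement": float(np.max(np.abs(d_opt))),
        "n_mesh_vertices": int(mesh.n_vertices),
        "energy_history": [h.total for h in histories],
        "timings_s": timings,
    }

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_volume(u_reg, str(out / "deformed.mhd"))
        write_volume(u_target, str(out / "target.mhd"))
        from .export import write_vtk
        write_vtk(mesh, str(out / "mesh.vtk"))
        np.savetxt(out / "vertex_dvf.txt", d_opt, header="D1 D2 D3 (voxels)")
        rows = ["level,iteration,total,regularization,similarity"]
        for lvl, h in enumerate(histories):
            for it, (tot, reg_e, sim_e) in enumerate(
                    zip(h.total, h.regularization, h.similarity)):
                rows.append(f"{lvl},{it},{tot:.8g},{reg_e:.8g},{sim_e:.8g}")
        (out / "energy_log.csv").write_text("\n".join(rows) + "\n")
        manifest = {"config": dataclasses.asdict(cfg),
                    "results": {k: v for k, v in result.items()
                                if not isinstance(v, (list, dict))}}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
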