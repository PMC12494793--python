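"""Configuration-driven orchestration of the full synthetic-data workflow.

structures -> flexible variants -> crowded packing -> acquisition grid ->
tilt-series simulation (or external-simulator export) -> reconstruction ->
binning -> ground truth, with deterministic per-stage seeds derived from a
master seed and a JSON run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import flexvar, simgen, structio, tetris

log = logging.getLogger("cryocrowd")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    """Resolved run configuration; every run echoes it into the manifest."""

    output_dir: str = "run"
    templates: list[str] = dataclasses.field(default_factory=list)  # PDB/MRC paths
    distractors: list[str] = dataclasses.field(default_factory=list)
    fixtures: bool = False          # auto-generate synthetic pools instead
    n_samples: int = 2
    dims: tuple[int, int, int] = (64, 64, 32)   # (x, y, z) voxels as users write it
    voxel_size: float = 16.0        # packing/simulation sampling, Å
    target_voxel_size: float = 16.0  # training sampling after binning, Å
    template_frequency: int = 5     # 1 template per k distractors
    radius: int = 2                 # compactness radius, voxels
    max_molecules: int | None = None
    n_variants: int = 0             # flexible variants per template
    nma_amplitude: float = 100.0
    nma_modes: int = 20
    grid_defocus: list[float] = dataclasses.field(default_factory=lambda: [-2.0, -3.0, -4.0])
    grid_dose: list[float] = dataclasses.field(default_factory=lambda: [80.0, 120.0])
    grid_tilt_range: list[float] = dataclasses.field(default_factory=lambda: [54.0, 60.0])
    grid_tilt_step: list[float] = dataclasses.field(default_factory=lambda: [2.0, 3.0])
    grid_ice: list[float] = dataclasses.field(default_factory=lambda: [0.9, 1.1])
    phase_plate: bool = True
    ground_truth_mode: str = "shape"
    sphere_radius: int = 6
    export_external: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.dims, list):
            cfg.dims = tuple(cfg.dims)
        return cfg


def _load_pools(config: PipelineConfig, rng: np.random.Generator):
    if config.fixtures:
        pools = simgen.make_synthetic_molecules(rng, voxel_size=config.voxel_size)
        return (pools.template_models, pools.template_volumes,
                pools.distractor_models, pools.distractor_volumes)
    t_models = [structio.read_structure(p) for p in config.templates]
    d_models = [structio.read_structure(p) for p in config.distractors]
    if not t_models or not d_models:
        raise ValueError("template and distractor pools must both be non-empty")
    t_vols = [structio.rasterize(m, config.voxel_size) for m in t_models]
    d_vols = [structio.rasterize(m, config.voxel_size) for m in d_models]
    return t_models, t_vols, d_models, d_vols


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the workflow; returns the run directory (with manifest.json)."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(
        ("pools", "variants", "packing", "acquisition"), master.spawn(4))}

    rng_pools = np.random.default_rng(seeds["pools"])
    t_models, t_vols, d_models, d_vols = _load_pools(config, rng_pools)
    log.info("pools: %d templates, %d distractors", len(t_vols), len(d_vols))

    if config.n_variants > 0:
        rng_var = np.random.default_rng(seeds["variants"])
        extra = []
        for m in t_models:
            variants = flexvar.generate_variants(
                m, config.n_variants, config.nma_amplitude,
                n_modes=config.nma_modes, rng=rng_var)
            rmsds = [v.rmsd for v in variants]
            log.info("variants of %s: mean RMSD %.2f Å", m.label, np.mean(rmsds))
            extra.extend(structio.rasterize(v.model, config.voxel_size)
                         for v in variants)
        t_vols = t_vols + extra

    grid = simgen.build_param_grid(
        config.grid_defocus, config.grid_dose, config.grid_tilt_range,
        config.grid_tilt_step, config.grid_ice, phase_plate=config.phase_plate)
    dims_zyx = tuple(int(d) for d in config.dims[::-1])
    bin_factor = max(int(round(config.target_voxel_size / config.voxel_size)), 1)

    pack_ss = seeds["packing"].spawn(config.n_samples)
    acq_ss = seeds["acquisition"].spawn(config.n_samples)
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "n_grid_combinations": len(grid),
        "samples": [],
    }
    model_index = {("template", i): m for i, m in enumerate(t_models)}
    model_index.update({("distractor", i): m for i, m in enumerate(d_models)})

    for i in range(config.n_samples):
        t_sample = time.time()
        sdir = outdir / f"sample_{i:03d}"
        sdir.mkdir(exist_ok=True)
        params = grid[i % len(grid)]  # sample i paired with grid entry i
        rng_pack = np.random.default_rng(pack_ss[i])
        sample = tetris.pack(
            t_vols, d_vols, dims=dims_zyx, voxel_size=config.voxel_size,
            template_frequency=config.template_frequency, radius=config.radius,
            rng=rng_pack, max_molecules=config.max_molecules)
        structio.write_mrc(sample.occupancy, sdir / "occupancy.mrc")
        _write_placements(sample, sdir / "placements.tsv")

        rng_acq = np.random.default_rng(acq_ss[i])
        density = structio.DensityVolume(
            grid=_render_sample(sample), voxel_size=config.voxel_size)
        ts = simgen.simulate_tilt_series(density, params, rng_acq)
        tomo = simgen.reconstruct_wbp(ts)
        if bin_factor > 1:
            tomo = structio.bin_volume(tomo, bin_factor)
        structio.write_mrc(tomo, sdir / "tomogram.mrc")

        gt = simgen.make_ground_truth(
            sample, mode=config.ground_truth_mode,
            sphere_radius=config.sphere_radius,
            target_voxel_size=config.target_voxel_size)
        structio.write_mrc(
            structio.DensityVolume(grid=gt.segmentation.grid.astype(np.float32),
                                   voxel_size=gt.segmentation.voxel_size),
            sdir / "segmentation.mrc")
        gt.coordinates.to_csv(sdir / "coordinates.tsv", sep="\t", index=False,
                              float_format="%.4f")
        if config.export_external:
            # restrict the model index to molecules actually placed; variant
            # volumes beyond the base template pool map back to their template
            used = {}
            for p in sample.placements:
                key = (p.mol_class, p.molecule_id)
                base = key if key in model_index else \
                    ("template", p.molecule_id % max(len(t_models), 1))
                used[key] = model_index.get(key, model_index[base])
            simgen.export_external_sim_config(sample, used, params,
                                              sdir / "external_sim")
        manifest["samples"].append({
            "dir": sdir.name,
            "grid_index": i % len(grid),
            "params": dataclasses.asdict(params),
            "n_molecules": len(sample.placements),
            "n_templates": sample.n_templates,
            "stop_reason": sample.stop_reason,
            "occupancy_fraction": float(sample.occupancy.grid.mean()),
            "seconds": round(time.time() - t_sample, 2),
        })
        log.info("sample %d: %d molecules (%d templates) in %.1f s", i,
                 len(sample.placements), sample.n_templates,
                 time.time() - t_sample)

    manifest["total_seconds"] = round(time.time() - t0, 2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


def _render_sample(sample: tetris.CrowdedSample) -> np.ndarray:
    """Sum the placed binary masks into a density-like sample volume."""
    grid = np.zeros(sample.dims, dtype=float)
    for p in sample.placements:
        sl = tuple(slice(o, o + s) for o, s in zip(p.offset, p.mask.shape))
        grid[sl] += p.mask
    return grid


def _write_placements(sample: tetris.CrowdedSample, path: Path) -> None:
    import pandas as pd

    rows = []
    for p in sample.placements:
        rows.append({
            "iteration": p.iteration, "class": p.mol_class,
            "molecule_id": p.molecule_id,
            "x_vox": p.position_voxels[2], "y_vox": p.position_voxels[1],
            "z_vox": p.position_voxels[0],
            "x_angstrom": p.position_angstrom[0],
            "y_angstrom": p.position_angstrom[1],
            "z_angstrom": p.position_angstrom[2],
            "q_w": p.quaternion[0], "q_x": p.quaternion[1],
            "q_y": p.quaternion[2], "q_z": p.quaternion[3],
            "phi": p.euler_zyz_deg[0], "theta": p.euler_zyz_deg[1],
            "psi": p.euler_zyz_deg[2],
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")
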