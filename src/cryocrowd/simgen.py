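"""Acquisition-parameter grids, tilt-series forward model, WBP, ground truth, fixtures.

The forward model here is a deliberately simplified desk-scale stand-in for a
physics-based cryo-TEM simulator: line-integral projections of the sample
density at dose-symmetric tilt angles, a phase-contrast CTF at the requested
defocus (phase-plate variant supported), an additive ice background coupled
to the ice-density knob, and per-pixel Poisson counting at the per-tilt dose.
It honors the five domain-randomization parameters (dose, defocus, tilt
range, tilt step, ice density) and produces plausible contrast, noise and
missing-wedge structure; multislice wave optics, detector response and
beam-induced motion are intentionally absent. For full-fidelity simulation,
sample descriptions can be exported for an external simulator instead.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage.morphology import ball

from .structio import (AtomicModel, BinaryMask, DensityVolume, bin_volume,
                       model_from_points, rasterize, write_pdb)
from .tetris import CrowdedSample

__all__ = [
    "AcquisitionParams",
    "TiltSeries",
    "Tomogram",
    "GroundTruth",
    "build_param_grid",
    "dose_symmetric_angles",
    "simulate_tilt_series",
    "reconstruct_wbp",
    "make_ground_truth",
    "export_external_sim_config",
    "read_external_sim_config",
    "SyntheticPools",
    "make_synthetic_molecules",
    "synthetic_nucleosome_model",
]

ELECTRON_WAVELENGTH_300KV = 0.01969  # Å
CS_DEFAULT = 2.7e7                   # spherical aberration, Å (2.7 mm)
SOLVENT_DENSITY = 0.05               # ice background per voxel of thickness, density units


@dataclasses.dataclass
class AcquisitionParams:
    """The five randomized acquisition knobs plus the phase-plate flag."""

    dose: float = 100.0        # total e-/Å^2
    defocus: float = -3.0      # µm (negative = underfocus)
    tilt_range: float = 60.0   # ± degrees
    tilt_step: float = 3.0     # degrees
    ice_density: float = 1.0   # relative solvent density multiplier
    phase_plate: bool = True

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise ValueError("dose must be > 0")
        if not self.tilt_step > 0:
            raise ValueError("tilt_step must be > 0")
        if self.tilt_range < self.tilt_step:
            raise ValueError("tilt_range must be >= tilt_step")


@dataclasses.dataclass
class TiltSeries:
    images: np.ndarray         # (n_tilts, ny, nx)
    angles: np.ndarray         # degrees, dose-symmetric order
    pixel_size: float          # Å
    params: AcquisitionParams
    depth: int                 # z extent (voxels) of the originating sample

    def __post_init__(self) -> None:
        if len(self.images) != len(self.angles):
            raise ValueError("images and angles length mismatch")


@dataclasses.dataclass
class Tomogram(DensityVolume):
    params: AcquisitionParams | None = None
    method: str = "wbp"


@dataclasses.dataclass
class GroundTruth:
    segmentation: BinaryMask
    coordinates: pd.DataFrame  # x, y, z (voxels), phi/theta/psi (ZYZ deg), class, molecule_id
    mode: str                  # "shape" | "sphere"
    sphere_radius: int | None = None


# ---------------------------------------------------------------------------
# Parameter grid

def build_param_grid(
    defocus: list[float],
    dose: list[float],
    tilt_range: list[float],
    tilt_step: list[float],
    ice: list[float],
    phase_plate: bool = True,
) -> list[AcquisitionParams]:
    """Full Cartesian product in deterministic defocus-major order."""
    for nm, lst in (("defocus", defocus), ("dose", dose), ("tilt_range", tilt_range),
                    ("tilt_step", tilt_step), ("ice", ice)):
        if not lst:
            raise ValueError(f"parameter list {nm!r} is empty")
    return [
        AcquisitionParams(dose=d, defocus=df, tilt_range=tr, tilt_step=ts,
                          ice_density=ic, phase_plate=phase_plate)
        for df, d, tr, ts, ic in itertools.product(defocus, dose, tilt_range,
                                                   tilt_step, ice)
    ]


def dose_symmetric_angles(tilt_range: float, tilt_step: float) -> np.ndarray:
    """0, +s, -s, +2s, -2s, ... out to ±tilt_range (inclusive)."""
    n = int(np.floor(tilt_range / tilt_step + 1e-9))
    out = [0.0]
    for k in range(1, n + 1):
        out.extend([k * tilt_step, -k * tilt_step])
    return np.array(out)


# ---------------------------------------------------------------------------
# Forward model and reconstruction

def _ctf_2d(shape: tuple[int, int], pixel_size: float, defocus_um: float,
            phase_plate: bool) -> np.ndarray:
    ny, nx = shape
    fy = np.fft.fftfreq(ny, d=pixel_size)[:, None]
    fx = np.fft.fftfreq(nx, d=pixel_size)[None, :]
    f2 = fy**2 + fx**2
    lam = ELECTRON_WAVELENGTH_300KV
    dz = abs(defocus_um) * 1e4  # Å underfocus
    chi = np.pi * lam * dz * f2 - 0.5 * np.pi * CS_DEFAULT * lam**3 * f2**2
    return np.cos(chi) if phase_plate else np.sin(chi)


def project(volume_grid: np.ndarray, angle_deg: float) -> np.ndarray:
    """Line-integral projection along z after tilting about the y axis."""
    if angle_deg == 0.0:
        return volume_grid.sum(axis=0)
    rot = ndimage.rotate(volume_grid, angle_deg, axes=(0, 2), reshape=False,
                         order=1, prefilter=False)
    return rot.sum(axis=0)


def simulate_tilt_series(
    sample_density: DensityVolume,
    params: AcquisitionParams,
    rng: np.random.Generator | None = None,
    add_noise: bool = True,
    apply_ctf: bool = True,
) -> TiltSeries:
    """Simplified tilt-series forward model (see module docstring)."""
    rng = np.random.default_rng() if rng is None else rng
    angles = dose_symmetric_angles(params.tilt_range, params.tilt_step)
    dose_per_tilt = params.dose / len(angles)
    nz = sample_density.grid.shape[0]
    background = params.ice_density * SOLVENT_DENSITY * nz
    images = []
    for ang in angles:
        proj = project(sample_density.grid, float(ang))
        if apply_ctf:
            ctf = _ctf_2d(proj.shape, sample_density.voxel_size, params.defocus,
                          params.phase_plate)
            proj = np.fft.ifft2(np.fft.fft2(proj) * ctf).real
        mean = np.clip((proj + background) * dose_per_tilt, 0, None)
        images.append(rng.poisson(mean).astype(float) if add_noise else mean)
    return TiltSeries(images=np.stack(images), angles=angles,
                      pixel_size=sample_density.voxel_size, params=params, depth=nz)


def _ramp_filter(image: np.ndarray) -> np.ndarray:
    """Ramp (|f|) filter along the tilt-perpendicular in-plane axis (x, last axis)."""
    nx = image.shape[-1]
    ramp = np.abs(np.fft.fftfreq(nx))
    return np.fft.ifft(np.fft.fft(image, axis=-1) * ramp[None, :], axis=-1).real


def reconstruct_wbp(ts: TiltSeries) -> Tomogram:
    """Weighted (ramp-filtered) back projection of a tilt series."""
    if len(ts.images) < 1:
        raise ValueError("tilt series is empty")
    shapes = {im.shape for im in ts.images}
    if len(shapes) != 1:
        raise ValueError("inconsistent image sizes in tilt series")
    ny, nx = ts.images[0].shape
    vol = np.zeros((ts.depth, ny, nx), dtype=float)
    for img, ang in zip(ts.images, ts.angles):
        filt = _ramp_filter(np.asarray(img, float))
        bp = np.broadcast_to(filt, (ts.depth, ny, nx)).copy()
        if ang != 0.0:
            bp = ndimage.rotate(bp, -float(ang), axes=(0, 2), reshape=False,
                                order=1, prefilter=False)
        vol += bp
    vol *= np.pi / (2.0 * len(ts.images))
    return Tomogram(grid=vol, voxel_size=ts.pixel_size, params=ts.params, method="wbp")


# ---------------------------------------------------------------------------
# Ground truth

def make_ground_truth(
    sample: CrowdedSample,
    mode: str = "shape",
    sphere_radius: int | None = None,
    target_voxel_size: float | None = None,
) -> GroundTruth:
    """White-on-black segmentation of template instances plus a coordinate table.

    ``shape`` mode re-renders the union of placed template masks at the
    target voxel size; ``sphere`` mode stamps balls of ``sphere_radius``
    (target voxels) at template centers — for shell-like particles whose
    interior is not segmented by the shape itself. Distractors never appear.
    """
    if mode not in ("shape", "sphere"):
        raise ValueError(f"unknown ground-truth mode {mode!r}")
    if mode == "sphere" and sphere_radius is None:
        raise ValueError("sphere mode requires sphere_radius")
    target_voxel_size = target_voxel_size or sample.voxel_size
    factor = max(int(round(target_voxel_size / sample.voxel_size)), 1)
    out_dims = tuple(d // factor for d in sample.dims)

    rows = []
    grid = np.zeros(sample.dims, dtype=float)
    for p in sample.placements:
        if p.mol_class != "template":
            continue
        sl = tuple(slice(o, o + s) for o, s in zip(p.offset, p.mask.shape))
        if mode == "shape":
            grid[sl] = np.maximum(grid[sl], p.mask)
        center = p.position_voxels / factor
        rows.append({
            "x": center[2], "y": center[1], "z": center[0],
            "phi": p.euler_zyz_deg[0], "theta": p.euler_zyz_deg[1],
            "psi": p.euler_zyz_deg[2],
            "class": p.mol_class, "molecule_id": p.molecule_id,
        })
    coords = pd.DataFrame(rows, columns=["x", "y", "z", "phi", "theta", "psi",
                                         "class", "molecule_id"])
    if mode == "shape":
        binned = bin_volume(DensityVolume(grid=grid, voxel_size=sample.voxel_size),
                            factor)
        seg = binned.grid >= 0.5
    else:
        seg = np.zeros(out_dims, dtype=bool)
        stamp = ball(sphere_radius).astype(bool)
        for _, r in coords.iterrows():
            c = np.array([r["z"], r["y"], r["x"]])
            lo = np.round(c).astype(int) - sphere_radius
            sl_seg, sl_stamp = [], []
            for ax, (l, d, s) in enumerate(zip(lo, out_dims, stamp.shape)):
                a, b = max(l, 0), min(l + s, d)
                if a >= b:
                    sl_seg = None
                    break
                sl_seg.append(slice(a, b))
                sl_stamp.append(slice(a - l, b - l))
            if sl_seg is None:
                continue
            seg[tuple(sl_seg)] |= stamp[tuple(sl_stamp)]
    segmentation = BinaryMask(grid=seg, voxel_size=sample.voxel_size * factor)
    return GroundTruth(segmentation=segmentation, coordinates=coords, mode=mode,
                       sphere_radius=sphere_radius)


# ---------------------------------------------------------------------------
# External-simulator export

def export_external_sim_config(
    sample: CrowdedSample,
    models: dict[tuple[str, int], AtomicModel],
    params: AcquisitionParams,
    outdir: str | Path,
) -> Path:
    """Write a YAML config + positions/orientations TSV + model PDBs for an
    external physics simulator; round-trip readable by :func:`read_external_sim_config`.

    ``models`` maps (class, molecule_id) to the atomic model of each pool entry.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in sample.placements:
        key = (p.mol_class, p.molecule_id)
        if key not in models:
            raise KeyError(f"placement references unknown molecule {key}")
        rows.append({
            "model": f"{p.mol_class}_{p.molecule_id}.pdb",
            "class": p.mol_class, "molecule_id": p.molecule_id,
            "x_angstrom": p.position_angstrom[0],
            "y_angstrom": p.position_angstrom[1],
            "z_angstrom": p.position_angstrom[2],
            "phi": p.euler_zyz_deg[0], "theta": p.euler_zyz_deg[1],
            "psi": p.euler_zyz_deg[2],
        })
    positions = pd.DataFrame(rows)
    positions.to_csv(outdir / "positions.tsv", sep="\t", index=False,
                     float_format="%.6f")
    for (cls, mid), model in models.items():
        write_pdb(model, outdir / f"{cls}_{mid}.pdb")
    config = {
        "sample": {
            "box_angstrom": [d * sample.voxel_size for d in sample.dims[::-1]],
            "voxel_size": sample.voxel_size,
            "positions_file": "positions.tsv",
            "ice_density": params.ice_density,
        },
        "scan": {
            "mode": "dose_symmetric",
            "tilt_range": params.tilt_range,
            "tilt_step": params.tilt_step,
            "total_dose": params.dose,
        },
        "microscope": {
            "defocus_um": params.defocus,
            "phase_plate": params.phase_plate,
        },
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return outdir / "config.yaml"


def read_external_sim_config(path: str | Path) -> tuple[dict, pd.DataFrame]:
    """Re-parse an exported config; returns (config dict, positions table)."""
    path = Path(path)
    with open(path) as fh:
        config = yaml.safe_load(fh)
    positions = pd.read_csv(path.parent / config["sample"]["positions_file"], sep="\t")
    return config, positions


# ---------------------------------------------------------------------------
# Synthetic molecule fixtures

@dataclasses.dataclass
class SyntheticPools:
    template_models: list[AtomicModel]
    distractor_models: list[AtomicModel]
    template_volumes: list[DensityVolume]
    distractor_volumes: list[DensityVolume]


PROTEIN_ELECTRONS_PER_A3 = 0.44  # ~1.35 g/cm^3 protein at ~0.54 e-/Da


def _scale_to_diameter(points: np.ndarray, diameter: float) -> np.ndarray:
    points = points - points.mean(axis=0)
    r = np.linalg.norm(points, axis=1).max()
    return points * (diameter / (2 * r))


def _weighted_cloud_model(points: np.ndarray, envelope_volume: float,
                          name: str, label: str) -> AtomicModel:
    """Point-cloud model carrying a realistic total electron count.

    Each point is assigned an equal share of the envelope's electron mass so
    rasterized densities sit on the same scale as an all-atom rasterization
    (summed atomic numbers) — the scale on which the conventional
    binarization threshold of 100 cuts near the molecular envelope.
    """
    n = len(points)
    w = max(int(round(PROTEIN_ELECTRONS_PER_A3 * envelope_volume / n)), 1)
    m = model_from_points(points, element="C", name=name, label=label)
    m.atomic_number = np.full(n, w, dtype=int)
    return m


def make_synthetic_molecules(
    rng: np.random.Generator,
    n_templates: int = 2,
    n_distractors: int = 8,
    size_range: tuple[float, float] = (40.0, 130.0),
    voxel_size: float = 16.0,
    points_per_molecule: int = 220,
) -> SyntheticPools:
    """Procedurally generated molecule stand-ins for download-free testing.

    Templates are multi-lobed blob point clouds with a distinctive ring
    geometry; distractors are ellipsoidal clouds whose bounding-sphere
    diameters span ``size_range`` (emulating a pool of diverse assemblies,
    e.g. 30 kDa-1 MDa). Template atoms are named CA, one residue per atom,
    so the elastic-network machinery applies to them unchanged. Fully
    deterministic for a seeded generator.
    """
    lo, hi = size_range
    if lo <= 0 or hi <= lo:
        raise ValueError("size_range must be increasing and positive")
    t_models, d_models, t_vols, d_vols = [], [], [], []
    for t in range(n_templates):
        n_lobes = 3 + t % 3
        centers = np.stack([
            np.cos(2 * np.pi * np.arange(n_lobes) / n_lobes),
            np.sin(2 * np.pi * np.arange(n_lobes) / n_lobes),
            0.3 * rng.standard_normal(n_lobes),
        ], axis=1)
        pts = np.concatenate([
            c + 0.35 * rng.standard_normal((points_per_molecule // n_lobes, 3))
            for c in centers
        ])
        d_t = hi * (0.85 + 0.1 * t / max(n_templates, 1))
        pts = _scale_to_diameter(pts, d_t)
        vol_t = 0.4 * (4 / 3) * np.pi * (d_t / 2) ** 3  # lobed, non-convex
        m = _weighted_cloud_model(pts, vol_t, "CA", f"template_{t}")
        t_models.append(m)
        t_vols.append(rasterize(m, voxel_size))
    diam = rng.permutation(np.linspace(lo, hi, n_distractors))
    for d in range(n_distractors):
        axes = np.array([1.0, rng.uniform(0.4, 1.0), rng.uniform(0.4, 1.0)])
        u = rng.standard_normal((points_per_molecule, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts = u * axes * rng.uniform(0.3, 1.0, (points_per_molecule, 1)) ** (1 / 3)
        pts = _scale_to_diameter(pts, diam[d])
        vol_d = (4 / 3) * np.pi * (diam[d] / 2) ** 3 * axes[1] * axes[2]
        m = _weighted_cloud_model(pts, vol_d, "C", f"distractor_{d}")
        d_models.append(m)
        d_vols.append(rasterize(m, voxel_size))
    return SyntheticPools(t_models, d_models, t_vols, d_vols)


def synthetic_nucleosome_model(rng: np.random.Generator | None = None) -> AtomicModel:
    """Synthetic nucleosome-scale stand-in (no experimental structure involved).

    Emulates the coarse architecture and node count of a nucleosome core
    particle: an 8-chain protein core (121 residues each, Cα + 4 side atoms
    per residue) inside a ~70 Å disc, wrapped by a 147-bp DNA duplex
    superhelix (P + 6 atoms per nucleotide, radius 41.8 Å, ~1.65 turns).
    Yields ~1260 Cα/P coarse-grained nodes — the scale that matters for
    elastic-network amplitude calibration.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    element, z, name, res_id, chain, coords, pseudo = [], [], [], [], [], [], []

    def add(el, zz, nm, rid, ch, xyz):
        element.append(el); z.append(zz); name.append(nm)
        res_id.append(rid); chain.append(ch); coords.append(xyz); pseudo.append(False)

    # protein core: 8 chains as helical worms filling a disc r~32 Å, h~50 Å
    n_chain, n_res = 8, 121
    for c in range(n_chain):
        phase = 2 * np.pi * c / n_chain
        t = np.arange(n_res) * 3.8  # Cα spacing along the worm, Å
        rr = 10.0 + 20.0 * (0.5 + 0.5 * np.sin(t / 40.0 + phase))
        th = phase + t / rr.clip(8.0)
        zz = 20.0 * np.sin(t / 60.0 + phase * 1.7)
        ca = np.stack([rr * np.cos(th), rr * np.sin(th), zz], axis=1)
        ca += 0.6 * rng.standard_normal(ca.shape)
        ch = chr(ord("A") + c)
        for r in range(n_res):
            add("C", 6, "CA", r + 1, ch, tuple(ca[r]))
            for el, zz2, nm in (("N", 7, "N"), ("C", 6, "C"), ("O", 8, "O"),
                                ("C", 6, "CB")):
                add(el, zz2, nm, r + 1, ch,
                    tuple(ca[r] + rng.uniform(-1.6, 1.6, 3)))
    # DNA duplex superhelix: 147 bp, two strands
    n_bp, sh_radius, pitch, turns = 147, 41.8, 25.9, 1.65
    s = np.linspace(0, 1, n_bp)
    ang = 2 * np.pi * turns * s
    for strand, (ch, off) in enumerate((("I", -0.03), ("J", 0.03))):
        for i in range(n_bp):
            a = ang[i] + off * 2 * np.pi
            p = np.array([sh_radius * np.cos(a), sh_radius * np.sin(a),
                          pitch * turns * (s[i] - 0.5) + 9.0 * strand])
            p += 0.4 * rng.standard_normal(3)
            rid = i + 1 if strand == 0 else n_bp - i
            add("P", 15, "P", rid, ch, tuple(p))
            inward = -p / np.linalg.norm(p)
            for k, (el, zz2, nm) in enumerate((("C", 6, "C5'"), ("C", 6, "C4'"),
                                               ("O", 8, "O4'"), ("C", 6, "C1'"),
                                               ("N", 7, "N1"), ("C", 6, "C2"))):
                add(el, zz2, nm, rid, ch,
                    tuple(p + inward * (1.5 + 1.2 * k)
                          + 0.5 * rng.standard_normal(3)))
    return AtomicModel(
        element=np.array(element), atomic_number=np.array(z, int),
        name=np.array(name), res_id=np.array(res_id, int), chain=np.array(chain),
        coords=np.array(coords, float), is_pseudo=np.array(pseudo, bool),
        label="synthetic_nucleosome",
    )
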