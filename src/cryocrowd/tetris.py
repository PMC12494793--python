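"""Iterative maximal-compactness packing of rotated molecules ("Tetris" packing).

One molecule at a time is rotated to a uniformly random orientation,
binarized, and scored against the current occupancy with an FFT
cross-correlation of its *insertion shell* — the dilated mask minus the mask
itself weighted by a large positive constant. Positive correlation entries
mark offsets where the molecule touches the existing sample within the
dilation radius without intersecting it; the molecule is placed at the
maximum entry. Packing stops when no positive entry remains (or at an
optional molecule budget). The dilation radius directly controls the
compactness (minimum spacing) of the sample.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, signal
from scipy.spatial.transform import Rotation

from .structio import BinaryMask, DensityVolume, binarize, dilate

__all__ = [
    "PlacementRecord",
    "CrowdedSample",
    "sample_uniform_rotation",
    "rotate_density",
    "make_insertion_shell",
    "placement_map",
    "place_molecule",
    "pack",
]


@dataclasses.dataclass
class PlacementRecord:
    molecule_id: int
    mol_class: str                 # "template" | "distractor"
    quaternion: np.ndarray         # (w, x, y, z), unit norm
    euler_zyz_deg: np.ndarray      # intrinsic ZYZ Euler angles, degrees
    position_voxels: np.ndarray    # (z, y, x) centroid of the placed mask
    position_angstrom: np.ndarray  # (x, y, z) Å of the centroid
    offset: tuple[int, int, int]   # (z, y, x) of the mask bounding box corner
    mask: np.ndarray               # placed binary mask (tight bounding box)
    iteration: int
    score: float = float("nan")    # placement-map value (NaN for the first molecule)


@dataclasses.dataclass
class CrowdedSample:
    dims: tuple[int, int, int]     # (z, y, x) voxels
    voxel_size: float
    placements: list[PlacementRecord]
    occupancy: BinaryMask
    stop_reason: str = ""          # "exhausted" | "max_count"

    @property
    def n_templates(self) -> int:
        return sum(p.mol_class == "template" for p in self.placements)


def sample_uniform_rotation(rng: np.random.Generator) -> np.ndarray:
    """Unit quaternion (w, x, y, z) drawn uniformly from SO(3)."""
    q = Rotation.random(random_state=rng).as_quat()  # (x, y, z, w)
    return np.array([q[3], q[0], q[1], q[2]])


def _rotation_from_quat(q_wxyz: np.ndarray) -> Rotation:
    w, x, y, z = q_wxyz
    return Rotation.from_quat([x, y, z, w])


def rotate_density(volume: DensityVolume, q_wxyz: np.ndarray) -> DensityVolume:
    """Rotate a density about its center (trilinear interpolation).

    The grid is first padded to a cube covering the rotated extents so no
    density is clipped; rotation is applied to the density, not to a binary
    mask, to avoid aliasing holes.
    """
    rot = _rotation_from_quat(q_wxyz)
    side = int(np.ceil(np.linalg.norm(volume.grid.shape)))
    padded = np.zeros((side,) * 3, dtype=float)
    lo = [(side - s) // 2 for s in volume.grid.shape]
    sl = tuple(slice(l, l + s) for l, s in zip(lo, volume.grid.shape))
    padded[sl] = volume.grid
    # grid axes are (z, y, x): map the xyz rotation matrix into index space
    m_xyz = rot.as_matrix()
    m_zyx = m_xyz[::-1, ::-1]
    center = (np.array(padded.shape) - 1) / 2.0
    inv = m_zyx.T  # orthonormal
    out = ndimage.affine_transform(
        padded, inv, offset=center - inv @ center, order=1, prefilter=False,
    )
    return DensityVolume(grid=out, voxel_size=volume.voxel_size)


def _tight_mask(mask_grid: np.ndarray) -> np.ndarray:
    nz = np.argwhere(mask_grid)
    if len(nz) == 0:
        raise ValueError("degenerate molecule: empty mask after binarization")
    lo, hi = nz.min(axis=0), nz.max(axis=0) + 1
    return mask_grid[tuple(slice(a, b) for a, b in zip(lo, hi))]


def make_insertion_shell(
    mask: BinaryMask | np.ndarray, radius: int, big_m: float | None = None,
) -> tuple[np.ndarray, float]:
    """Signed shell volume: ``dilate(mask, radius) - big_m * mask``.

    Values are 1 on the shell ring, ``1 - big_m`` (< 0) inside the molecule
    and 0 elsewhere. ``big_m`` defaults to (dilated voxel count + 1), the
    smallest "integer infinity" guaranteeing that a single-voxel overlap
    outweighs any possible shell contribution. The input mask is padded by
    ``radius`` so the shell is never clipped.
    """
    grid = mask.grid if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if not grid.any():
        raise ValueError("degenerate molecule: empty mask")
    padded = np.pad(grid, radius)
    dil = dilate(BinaryMask(grid=padded, voxel_size=1.0), radius).grid
    if big_m is None:
        big_m = float(dil.sum() + 1)
    shell = dil.astype(np.float64) - big_m * padded
    return shell, big_m


def placement_map(shell: np.ndarray, occupancy: BinaryMask | np.ndarray) -> np.ndarray:
    """Cross-correlate the insertion shell with the occupancy at all in-bounds offsets.

    Entry ``[o]`` is the shell score with its bounding box placed at offset
    ``o`` (z, y, x); only offsets keeping the shell box fully inside the
    sample are evaluated, so the returned map has shape
    ``sample_dims - shell_dims + 1``. Positive entries are legal compact
    positions; entries <= 0 mean overlap or excessive distance.
    """
    occ = occupancy.grid if isinstance(occupancy, BinaryMask) else np.asarray(occupancy)
    if any(s > o for s, o in zip(shell.shape, occ.shape)):
        raise ValueError("insertion shell larger than the sample")
    cmap = signal.correlate(occ.astype(np.float64), shell, mode="valid", method="fft")
    return np.rint(cmap)


def _record(mask: np.ndarray, offset: np.ndarray, q: np.ndarray,
            molecule_id: int, mol_class: str, iteration: int,
            voxel_size: float, score: float = float("nan")) -> PlacementRecord:
    centroid = np.argwhere(mask).mean(axis=0) + offset  # (z, y, x)
    pos_ang = (centroid[::-1] + 0.5) * voxel_size       # (x, y, z)
    return PlacementRecord(
        molecule_id=molecule_id, mol_class=mol_class, quaternion=q,
        euler_zyz_deg=_rotation_from_quat(q).as_euler("ZYZ", degrees=True),
        position_voxels=centroid, position_angstrom=pos_ang,
        offset=tuple(int(v) for v in offset), mask=mask, iteration=iteration,
        score=score,
    )


def place_molecule(
    sample: CrowdedSample,
    molecule: DensityVolume,
    rng: np.random.Generator,
    radius: int = 2,
    rotation_retries: int = 0,
    sigma: float = 2.0,
    threshold: float = 100.0,
    relative: bool = False,
    molecule_id: int = 0,
    mol_class: str = "template",
    require_contact: bool = False,
) -> PlacementRecord | None:
    """Rotate, binarize and place one molecule; ``None`` signals failure.

    The first molecule of an empty sample is placed at the grid center.
    Later molecules go to the argmax of the placement map (ties resolve to
    the lexicographically smallest (z, y, x) offset). Failure — optionally
    retried with fresh rotations — is an *entirely negative* map: every
    in-bounds offset overlaps the occupancy. Zero-valued offsets (no contact
    within the compactness radius) are legal fallbacks once no positive
    entry remains; set ``require_contact=True`` to treat them as failures
    instead (strict-compactness mode).
    """
    dims = np.array(sample.dims)
    for _ in range(rotation_retries + 1):
        q = sample_uniform_rotation(rng)
        rotated = rotate_density(molecule, q)
        bgrid = binarize(rotated, sigma=sigma, threshold=threshold,
                         relative=relative).grid
        if not bgrid.any():
            raise ValueError(
                "degenerate molecule: empty mask after binarization "
                "(density too weak for the threshold)")
        mask = _tight_mask(bgrid)
        msh = np.array(mask.shape)
        if np.any(msh > dims):
            return None
        it = len(sample.placements)
        score = float("nan")
        if not sample.occupancy.grid.any():
            offset = (dims - msh) // 2
        else:
            shell, _ = make_insertion_shell(mask, radius)
            if np.any(np.array(shell.shape) > dims):
                continue
            cmap = placement_map(shell, sample.occupancy)
            score = float(cmap.max())
            if score < 0 or (require_contact and score <= 0):
                continue
            offset = np.array(np.unravel_index(np.argmax(cmap), cmap.shape)) + radius
        sl = tuple(slice(o, o + s) for o, s in zip(offset, msh))
        region = sample.occupancy.grid[sl]
        if (region & mask).any():  # cannot happen by construction; guard anyway
            continue
        sample.occupancy.grid[sl] = region | mask
        rec = _record(mask, offset, q, molecule_id, mol_class, it,
                      sample.voxel_size, score)
        sample.placements.append(rec)
        return rec
    return None


def pack(
    templates: list[DensityVolume],
    distractors: list[DensityVolume],
    dims: tuple[int, int, int],
    voxel_size: float,
    template_frequency: int = 5,
    radius: int = 2,
    rng: np.random.Generator | None = None,
    max_molecules: int | None = None,
    rotation_retries: int = 0,
    sigma: float = 2.0,
    threshold: float = 100.0,
    relative: bool = False,
    require_contact: bool = False,
) -> CrowdedSample:
    """Pack a sample with a deterministic 1-template-per-``k``-distractors cycle.

    Pool members are drawn uniformly at random with replacement within their
    class. The first placement is a centered template. Packing terminates at
    the first placement failure (after the configured retries) or at
    ``max_molecules``; with ``require_contact`` placements must touch the
    existing sample within the compactness radius, otherwise isolated
    positions are used once no compact position exists (the stopping
    criterion is then a fully overlapping map).
    """
    if not templates:
        raise ValueError("template pool is empty")
    if template_frequency < 1:
        raise ValueError("template_frequency must be >= 1 (one template per k distractors)")
    rng = np.random.default_rng() if rng is None else rng
    dims = tuple(int(d) for d in dims)
    sample = CrowdedSample(
        dims=dims, voxel_size=float(voxel_size), placements=[],
        occupancy=BinaryMask(grid=np.zeros(dims, bool), voxel_size=float(voxel_size)),
    )

    def schedule(i: int) -> str:
        return "template" if i % (template_frequency + 1) == 0 else "distractor"

    i = 0
    while max_molecules is None or i < max_molecules:
        cls = schedule(i)
        pool = templates if cls == "template" else distractors
        if not pool:
            raise ValueError(f"{cls} pool is empty")
        rec = None
        for _ in range(20):  # redraw on degenerate pool members
            mol_id = int(rng.integers(len(pool)))
            try:
                rec = place_molecule(
                    sample, pool[mol_id], rng, radius=radius,
                    rotation_retries=rotation_retries, sigma=sigma,
                    threshold=threshold, relative=relative,
                    molecule_id=mol_id, mol_class=cls,
                    require_contact=require_contact,
                )
                break
            except ValueError:
                continue
        if rec is None:
            if i == 0:
                raise ValueError("first molecule does not fit in the sample dims")
            sample.stop_reason = "exhausted"
            return sample
        i += 1
    sample.stop_reason = "max_count"
    return sample
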