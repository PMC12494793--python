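"""Coarse-grained elastic-network normal modes and random flexible variants.

The model is the standard anisotropic network model (ANM): one node per
Cα (protein) or P (nucleic acid) atom, Hookean springs of constant ``gamma``
between all node pairs within ``cutoff`` Å. Eigenvectors of the 3N x 3N
Hessian are the normal modes; the six near-zero eigenpairs are rigid-body
motions and are discarded. Low-frequency modes encode collective, global
deformations and are used to generate random flexible variants of a template
with a controlled RMSD from the reference.

Mode displacements computed on the coarse-grained nodes are extended to the
full atomic structure by copying each node's displacement to every atom of
its residue (nearest node for residues without their own Cα/P).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import eigsh
from scipy.spatial import cKDTree

from .structio import AtomicModel

__all__ = [
    "CoarseGrainMap",
    "NormalModeSet",
    "FlexibleVariant",
    "coarse_grain",
    "build_enm",
    "compute_modes",
    "extend_modes",
    "sample_variant",
    "generate_variants",
    "rmsd",
]

#: eigenvalues below RIGID_TOL * (largest-eigenvalue estimate) count as rigid-body
RIGID_TOL = 1e-8

_DENSE_LIMIT = 900  # 3N at or below this: full dense eigendecomposition


@dataclasses.dataclass
class CoarseGrainMap:
    """Selected Cα/P node indices and the governing node of every atom."""

    cg_indices: np.ndarray   # indices into the full model
    atom_to_node: np.ndarray  # for each atom, index into cg_indices
    node_coords: np.ndarray  # (N_cg, 3) Å

    @property
    def n_nodes(self) -> int:
        return len(self.cg_indices)


@dataclasses.dataclass
class NormalModeSet:
    """Retained low-frequency modes: unit-norm columns over 3*N_cg coordinates."""

    modes: np.ndarray        # (3*N_cg, n_modes), orthonormal, ascending eigenvalue
    eigenvalues: np.ndarray  # (n_modes,) stiffness eigenvalues (ENM units)
    n_rigid: int             # near-zero eigenpairs excluded (6 for a connected network)
    cutoff: float
    gamma: float

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]


@dataclasses.dataclass
class FlexibleVariant:
    model: AtomicModel
    amplitudes: np.ndarray   # per-mode coefficients
    rmsd: float              # Å, no superposition


def coarse_grain(model: AtomicModel) -> CoarseGrainMap:
    """Select Cα and P nodes and map every atom to its governing node.

    An atom maps to the node of its own residue when that residue has a
    Cα/P, otherwise to the spatially nearest node.
    """
    names = np.asarray(model.name)
    is_ca = (names == "CA") & (np.asarray(model.element) != "Ca")
    is_p = (names == "P") & (np.asarray(model.element) == "P")
    cg = np.flatnonzero(is_ca | is_p)
    if len(cg) < 2:
        raise ValueError("need at least 2 Cα/P atoms to build an elastic network")
    node_coords = model.coords[cg]

    res_key = {}
    for node_idx, atom_idx in enumerate(cg):
        key = (str(model.chain[atom_idx]), int(model.res_id[atom_idx]))
        res_key.setdefault(key, node_idx)  # first node of the residue wins

    atom_to_node = np.empty(len(model), dtype=int)
    missing = []
    for i in range(len(model)):
        key = (str(model.chain[i]), int(model.res_id[i]))
        if key in res_key:
            atom_to_node[i] = res_key[key]
        else:
            missing.append(i)
    if missing:
        tree = cKDTree(node_coords)
        _, nearest = tree.query(model.coords[missing])
        atom_to_node[missing] = nearest
    return CoarseGrainMap(cg_indices=cg, atom_to_node=atom_to_node,
                          node_coords=node_coords)


def build_enm(model: AtomicModel, cg_map: CoarseGrainMap,
              cutoff: float = 15.0, gamma: float = 1.0) -> sparse.csr_matrix:
    """Assemble the ANM Hessian (3N_cg x 3N_cg, symmetric PSD, sparse).

    For each node pair (i, j) within ``cutoff``, the off-diagonal 3x3
    super-element is ``-gamma * r̂ r̂ᵀ`` with r̂ the unit inter-node vector;
    diagonal blocks are the negated sum of the row's off-diagonal blocks.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be > 0")
    x = cg_map.node_coords
    n = len(x)
    pairs = cKDTree(x).query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        raise ValueError("no node pairs within cutoff; elastic network is empty")
    i, j = pairs[:, 0], pairs[:, 1]
    d = x[j] - x[i]
    r2 = (d**2).sum(axis=1)
    # super-elements: -gamma * outer(d, d) / |d|^2
    blocks = -gamma * d[:, :, None] * d[:, None, :] / r2[:, None, None]  # (m, 3, 3)

    rows, cols, vals = [], [], []
    for a in range(3):
        for b in range(3):
            v = blocks[:, a, b]
            rows.extend([3 * i + a, 3 * j + a, 3 * i + a, 3 * j + a])
            cols.extend([3 * j + b, 3 * i + b, 3 * i + b, 3 * j + b])
            vals.extend([v, v, -v, -v])
    h = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * n, 3 * n),
    ).tocsr()
    return h


def compute_modes(hessian: sparse.spmatrix | np.ndarray, n_modes: int = 20) -> NormalModeSet:
    """Eigendecompose the Hessian, drop rigid-body modes, keep the lowest ``n_modes``.

    Rigid-body eigenpairs are identified by a relative eigenvalue threshold
    (not a fixed count); a warning is raised if their number differs from 6,
    which indicates a disconnected elastic network.
    """
    h = sparse.csr_matrix(hessian)
    dim = h.shape[0]
    scale = float(np.abs(h).sum(axis=1).max())  # Gershgorin bound on the largest eigenvalue
    if dim <= _DENSE_LIMIT:
        evals, evecs = np.linalg.eigh(h.toarray())
    else:
        k = min(n_modes + 12, dim - 1)
        # shift-invert around a small negative sigma: H - sigma*I is positive
        # definite even with exact zero modes, so the factorization is stable
        evals, evecs = eigsh(h, k=k, sigma=-1e-6 * scale, which="LM")
    order = np.argsort(evals)
    evals, evecs = evals[order], evecs[:, order]

    rigid = evals < RIGID_TOL * scale
    n_rigid = int(rigid.sum())
    if n_rigid != 6:
        warnings.warn(
            f"expected 6 rigid-body modes, found {n_rigid} "
            "(disconnected or degenerate elastic network)",
            stacklevel=2,
        )
    avail = len(evals) - n_rigid
    if avail < n_modes:
        warnings.warn(f"only {avail} flexible modes available; reducing n_modes",
                      stacklevel=2)
        n_modes = avail
    sel = slice(n_rigid, n_rigid + n_modes)
    modes = evecs[:, sel]
    modes = modes / np.linalg.norm(modes, axis=0, keepdims=True)
    return NormalModeSet(modes=modes, eigenvalues=evals[sel], n_rigid=n_rigid,
                         cutoff=np.nan, gamma=np.nan)


def extend_modes(modes: NormalModeSet, cg_map: CoarseGrainMap) -> np.ndarray:
    """Extend node displacements to all atoms: (n_modes, N_atoms, 3) field."""
    node_disp = modes.modes.T.reshape(modes.n_modes, cg_map.n_nodes, 3)
    return node_disp[:, cg_map.atom_to_node, :]


def rmsd(a: AtomicModel, b: AtomicModel) -> float:
    """Root mean square per-atom deviation in Å, without superposition."""
    if len(a) != len(b):
        raise ValueError(f"atom count mismatch: {len(a)} vs {len(b)}")
    d = a.coords - b.coords
    return float(np.sqrt((d**2).sum(axis=1).mean()))


def sample_variant(
    model: AtomicModel,
    modes: NormalModeSet,
    cg_map: CoarseGrainMap,
    amplitude: float,
    rng: np.random.Generator,
    coefficients: np.ndarray | None = None,
) -> FlexibleVariant:
    """Deform the model along a random direction in mode space.

    The deformation magnitude ``a`` is drawn from Uniform(-amplitude,
    amplitude) and distributed over the retained modes along a uniformly
    random direction of the mode-coefficient sphere, so ``amplitude`` bounds
    the total coefficient norm rather than growing with the mode count.
    Explicit ``coefficients`` override the random draw (e.g. a single forced
    mode).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if coefficients is None:
        direction = rng.normal(size=modes.n_modes)
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 0 else direction
        coefficients = rng.uniform(-amplitude, amplitude) * direction
    coefficients = np.asarray(coefficients, float)
    field = extend_modes(modes, cg_map)  # (M, N_atoms, 3)
    disp = np.tensordot(coefficients, field, axes=(0, 0))
    variant = model.with_coords(model.coords + disp)
    return FlexibleVariant(model=variant, amplitudes=coefficients,
                           rmsd=rmsd(model, variant))


def generate_variants(
    model: AtomicModel,
    n_variants: int,
    amplitude: float,
    n_modes: int = 20,
    cutoff: float = 15.0,
    gamma: float = 1.0,
    rng: np.random.Generator | None = None,
) -> list[FlexibleVariant]:
    """Convenience chain: coarse-grain, ENM, modes, then ``n_variants`` draws."""
    rng = np.random.default_rng() if rng is None else rng
    cg_map = coarse_grain(model)
    hessian = build_enm(model, cg_map, cutoff=cutoff, gamma=gamma)
    modes = compute_modes(hessian, n_modes=n_modes)
    modes.cutoff, modes.gamma = cutoff, gamma
    return [sample_variant(model, modes, cg_map, amplitude, rng)
            for _ in range(n_variants)]
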