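# Methods

`cryocrowd` generates domain-randomized synthetic cryo-electron tomography
(cryo-ET) samples for training voxel-segmentation particle pickers, and
evaluates picking results against ground truth. This note documents the
models, the conventions, the parameters that matter, and what the synthetic
fixtures do and do not demonstrate.

## Coordinate and density conventions

Atom coordinates are Cartesian x, y, z in Å. Volumes are numpy arrays in
`(z, y, x)` axis order with an isotropic voxel size; the `origin` is the Å
position of the corner of voxel `(0, 0, 0)` and voxel centers sit at
`origin + (i + 0.5) * voxel_size`. MRC files are MRC2014 mode-2 float,
written and read through gemmi, with the voxel size carried in the cell
dimensions and the origin in header words 50–52. PDB files are fixed-width;
pseudoatoms (points of generic density used to represent low-resolution
maps) are emitted as nonstandard `DENS` records and read back as such.

## Rasterization

An atomic model is rendered as a sum of per-atom isotropic Gaussians with
integral equal to the atom's atomic number (pseudoatoms carry a nominal
weight of 1). The kernel width is a parameter, default 0.5 voxel. The
default is deliberately narrow: the density scale is then "summed electron
counts per voxel", on which the conventional binarization recipe below
behaves as it does on atom-sharp reference rasterizations. A broader kernel
(e.g. 1 voxel) gives smoother maps but inflates the apparent footprint of
small molecules once low-pass filtering is added on top, which distorts
packing density; with the half-voxel default the total blur after the
standard σ = 2 smoothing is √(0.5² + 2²) ≈ 2.06 voxels. The discretization
error of the narrow kernel is ~1.5 % per axis on the total mass, irrelevant
for every downstream use.

Binarization is a Gaussian low-pass (default σ = 2 voxels) followed by a
hard threshold. Two thresholding modes exist: absolute (default 100 density
units — meaningful on the summed-electron scale at ~16 Å voxels, where a
protein interior plateaus near 0.44 e⁻/ų × voxel volume ≈ 1800) and
relative (a fraction of the smoothed maximum, recommended when the absolute
scale of a map is unknown, e.g. experimental input maps).

## Volume → pseudoatoms with contrast tuning

A density map is converted to a simulator-ready point model by binarizing
and placing one atom per foreground voxel. A deterministic, evenly strided
subset of `round(ratio·N)` atoms is converted to phosphorus to raise
projected contrast. The projected contrast measure is
`std(z-projection) / solvent_level`, i.e. referenced to a fixed solvent
density: a measure normalized within the particle footprint would be
invariant under uniform weight scaling and could not distinguish conversion
ratios, whereas real image contrast grows with scattering mass against the
same ice. `tune_contrast_ratio` sweeps candidate ratios and returns the one
nearest a target contrast (ties to the smaller ratio).

## Elastic-network flexible variants

Structural variability is generated with an anisotropic network model (ANM)
on Cα/P nodes: Hookean springs (γ = 1, arbitrary units) between node pairs
within a 15 Å cutoff — common ANM defaults. Eigenvectors of the 3N×3N
Hessian are the normal modes; eigenpairs below 1e-8 × (largest-eigenvalue
bound) are rigid-body motions and are discarded, with a warning when their
count differs from 6 (a disconnected network). The 20 lowest remaining
modes are retained by default. Mode displacements are extended from nodes to
all atoms by rigid per-residue copying (nearest node for residues without
their own Cα/P). Dense eigendecomposition is used up to 3N = 900;
above that, sparse shift-invert Lanczos around a small negative shift (the
Hessian minus a negative shift is positive definite even with exact zero
modes, so the factorization is stable).

**Amplitude convention.** A variant is drawn as `coefficients = a · u` with
`a ~ Uniform(−A, A)` and `u` uniform on the unit sphere of the retained
mode space; displacements are the coefficient-weighted mode sum, and RMSD is
computed without superposition (rigid modes are excluded, so none is
needed). With orthonormal modes this gives per-variant RMSD ≈ |a|/√N_cg and
mean RMSD ≈ (A/2)/√N_cg, independent of the mode count. The alternative of
sampling every mode independently from Uniform(−A, A) makes RMSD grow with
√(number of modes), so "amplitude" would mean different deformation sizes
for different mode counts; the magnitude–direction convention keeps the
amplitude an interpretable single knob while still exploring all retained
modes. On a nucleosome-scale structure (~1260 Cα/P nodes) amplitude 100
yields ≈1.5–1.6 Å mean RMSD (the package's calibration check accepts
1–3 Å); the closed form predicts ≈0.6 Å at amplitude 150 for a
ribosome-scale node count (~18 000), consistent in order with the ~1 Å
deformations customary for ribosome training data.

## Crowded packing ("Tetris" insertion-shell packing)

Molecules are placed one at a time, each at a fresh uniform random
orientation (Shoemake-style sampling via `scipy.spatial.transform.Rotation`).
The rotation is applied to the *density* with trilinear interpolation and
the rotated density is re-binarized — rotating a binary mask directly
produces aliasing holes. The first molecule is a template placed at the grid
center. For each subsequent molecule the binarized mask is dilated by a
ball of user radius (default 2 voxels = 32 Å at 16 Å sampling, approximate
molecular-contact spacing) and the *insertion shell* is formed:
`dilate(mask, r) − M·mask`, with `M` = (dilated voxel count + 1), the
smallest constant that makes any single-voxel overlap outweigh every
possible shell contribution. The shell is FFT-cross-correlated against the
current occupancy over all offsets that keep the shell box inside the
sample; the molecule is placed at the argmax (ties: first in C order, i.e.
lexicographically smallest (z, y, x)).

Score semantics: positive = contact within the radius and no overlap;
zero = no overlap but no contact; negative = overlap. Packing fails a
placement only when the map is *entirely negative* (every offset overlaps);
zero-score offsets are legal fallbacks that only win the argmax once no
compact position remains, so samples grow compactly and then fill residual
space until jamming. `require_contact=True` switches to a strict mode in
which zero-score offsets are failures too — this is the mode under which
the compactness invariant (every new molecule within `radius` of the
existing sample) holds exactly and is tested. Degenerate pool members
(masks that vanish under the binarization threshold) are redrawn rather
than terminating the sample. The class schedule is deterministic — one
template then k distractors, cycling — with uniform with-replacement draws
within each class. Larger dilation radii give sparser samples; occupancy
fraction decreases monotonically in the radius.

Capacity: at 16 Å voxels, a pool of 90–115 Å templates at 1 : 5 frequency
with distractors spanning 40–130 Å (the 30 kDa–1 MDa range typical of a
distractor library) jams at ~52 % occupancy with ~4200 molecules in a full
3072×3072×1024 ų sample (~15 min on one CPU; the acceptance suite runs
this once). At 1/5.33 of that volume the same pool jams at ~580–680
molecules — linear volume extrapolation from small boxes underestimates the
full-volume capacity by ~20 % because the unusable boundary margin weighs
more in a small box; the reproduction script reports the fast scaled
measurement with its linear equivalent, labelled as such.

## Acquisition randomization and the internal forward model

Domain randomization varies five acquisition knobs: total electron dose,
defocus, tilt range, tilt step and relative ice density; the default grid
(defocus {−2, −3, −4} µm × dose {80, 120} e⁻/Ų × range {±54, ±60}° × step
{2, 3}° × ice {0.9, 1.1}, phase plate on) has 3·2·2·2·2 = 48 combinations
in defocus-major order. These default values are this package's choices of
plausible ranges; they are configurable.

The internal tilt-series simulator is explicitly a desk-scale stand-in for
a physics-based external simulator (whose input decks `simgen` exports):
for each angle of a dose-symmetric scheme (0, +s, −s, +2s, −2s, …) the
sample is rotated about the y axis and integrated along z; a phase-contrast
CTF (sin χ, or cos χ with a phase plate; λ = 0.0197 Å i.e. 300 kV,
Cs = 2.7 mm) multiplies the projection in Fourier space; a constant ice
background `ice_density × 0.05 × thickness` is added; the image is scaled
to the per-tilt dose `dose/n_tilts` and Poisson counts are drawn per pixel.
No multislice optics, detector response or beam-induced motion — enough to
give plausible contrast, shot noise and missing-wedge structure for
testing. Reconstruction is weighted back projection: each image is
ramp-filtered along the tilt-perpendicular in-plane axis, back-projected
along its viewing direction and accumulated with a π/(2·n_tilts) scale.

Binning is block-mean pooling in real space (voxel size multiplied,
trailing partial blocks cropped), keeping Poisson statistics interpretable.

## Ground truth

Segmentations are white-on-black masks of *template* instances only
(distractors are deliberately absent — the model must learn to reject
them). Shape mode re-renders the union of placed template masks at the
target (binned) voxel size; sphere mode stamps balls of a given radius
(default 6 voxels) at template centers, for shell-like particles whose
interior the shape mask would leave hollow. The coordinate table carries
center positions (target-voxel units), intrinsic ZYZ Euler angles in
degrees, class and pool index, and always has exactly one row per placed
template.

## Picking evaluation

Foreground voxels of a segmentation are clustered by flat-kernel mean shift
(scikit-learn's `MeanShift`; bandwidth = clustering radius, chosen ≈ the
particle radius); each cluster yields a pick with centroid and size
(supporting voxel count). Picks are matched to ground truth greedily by
ascending pairwise distance, one-to-one, within 10 voxels by default —
one-to-one prevents a single segment from claiming several particles.
Precision, recall and F1 = 2PR/(P+R) are swept over segment-size cutoffs
(picks below the cutoff are dropped; recall is therefore non-increasing).
When a mask (e.g. a cytosol mask) is supplied, picks outside it are
additionally dropped for the *masked precision* only. With zero surviving
picks precision defaults to 1 and is flagged vacuous, keeping the
high-threshold tail defined. The operating threshold is the argmin of
|P − R| on curves pooled over all tomograms (masked precision when
available; ties to the smaller threshold), and per-tomogram F1 and its
median are reported there.

Orientation diagnostics: `wedge_constrained_cc` restricts both volumes to
the Fourier support of a ±tilt-range single-tilt acquisition and computes
the normalized zero-lag correlation. For a noiseless pair of identical
volumes this is 1 by construction; the orientation dependence that biases
template matching appears for noisy observations — a disc-shaped particle
keeps more signal power inside the support in side view than in top view,
so side views score higher at equal noise. `orientation_coverage` bins
viewing vectors into equal-area sphere cells (uniform cos-polar bands ×
azimuth sectors) and chi-square-tests detected counts against the placed
distribution, so p ≈ 1 means orientation-blind detection.

## Synthetic fixtures

`make_synthetic_molecules` builds procedurally generated molecule stand-ins:
templates are multi-lobed ring-shaped point clouds (atoms named CA, one
residue per atom, so the elastic-network machinery applies to them
unchanged) and distractors are ellipsoidal clouds whose bounding-sphere
diameters span the requested range exactly (shuffled even spacing). Every
point carries an equal share of a realistic electron mass
(0.44 e⁻/ų × envelope volume) so rasterized fixtures sit on the same
density scale as all-atom models. `synthetic_nucleosome_model` is a
synthetic stand-in emulating the coarse architecture of a nucleosome core
particle — 8 protein chains × 121 residues (Cα + 4 atoms each) in a ~110 Å
disc wrapped by a 147-bp DNA duplex superhelix (P + 6 atoms per
nucleotide) — giving ~1260 Cα/P nodes, the quantity that controls
elastic-network amplitude calibration.

What fixture-based tests show: geometric and statistical correctness of
packing, simulation, ground truth and evaluation, and end-to-end
consistency (feeding the ground-truth segmentation back through clustering
and matching recovers every template: P = R = F1 = 1). What they do not
show: transfer of trained models to experimental tomograms, fidelity of the
internal forward model to real optics, or behavior on real atomic
structures with non-uniform mass distributions.

## Numerical choices and limitations

- FFT cross-correlation maps are rounded to the nearest integer (inputs are
  integer-valued), eliminating FFT roundoff from the argmax and the
  stopping rule.
- Placement keeps molecules ≥ radius voxels from the sample boundary (the
  shell box must fit); capacities measured in small boxes therefore
  underestimate large-box densities slightly.
- Mean-shift uses bin seeding above 5000 foreground voxels for speed.
- Degenerate inputs raise `ValueError` with specific messages (empty
  models, empty masks, non-ascending grids); placement failure is a value
  (`None`), not an exception.
- The rigid-body eigenvalue threshold is relative (1e-8 × a Gershgorin
  bound), not a fixed count of 6, so disconnected networks are detected
  rather than silently mis-handled.
- Runtime scales used by the test-suite and the reproduction script (small
  boxes, 50-variant calibrations, 1/5.33-volume packing) are the package's
  default desk-scale choices; all are parameters.
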