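# cryocrowd

Synthetic training data for cryo-electron tomography (cryo-ET) particle
picking, without annotated tomograms. `cryocrowd` builds domain-randomized,
highly crowded 3D samples from structural templates — flexible variants via
elastic-network normal modes, lookalike "distractor" molecules, iterative
maximal-compactness packing, randomized acquisition parameters, a simplified
tilt-series/weighted-back-projection forward model (plus export decks for an
external physics simulator) — together with white-on-black ground-truth
segmentations and coordinate tables for training any voxel-segmentation
picker. It also implements the matching evaluation protocol:
mean-shift coordinate extraction, one-to-one matching within a distance
threshold, precision/recall/F1 swept over segment-size cutoffs, and
orientation-bias diagnostics under the missing wedge.

Who it is for: structural biologists and method developers who have PDB
structures (or low-resolution maps) of a target particle and want to train
and honestly evaluate a deep-learning picker on simulations instead of
hand-annotated tomograms.

## The core ideas

- **Crowding by insertion-shell correlation.** Each new molecule is rotated
  uniformly at random, binarized (Gaussian low-pass σ = 2 voxels, then a
  threshold), and dilated by a ball of radius *r*. The signed *insertion
  shell* `dilate(mask, r) − M·mask` (with `M` larger than any possible
  contact score) is FFT-cross-correlated with the current occupancy: positive
  map entries are non-overlapping positions in contact within *r*; the
  molecule is placed at the argmax. Packing stops only when every position
  overlaps, so samples grow compactly and then fill residual space until
  jamming. The radius *r* directly controls sample compactness.
- **Flexible variants from an anisotropic network model.** Cα/P nodes,
  springs within 15 Å; the 20 lowest non-rigid modes of the Hessian are
  extended to all atoms per residue. A variant displaces along a random
  direction in mode space with magnitude ~ Uniform(−A, A), giving mean RMSD
  ≈ (A/2)/√N_nodes — amplitude 100 on a nucleosome-scale structure deforms
  by roughly 1.5–2 Å.
- **Domain randomization.** Dose, defocus, tilt range, tilt step and ice
  density are varied over a Cartesian grid (3 defocus × 2⁴ = 48 settings by
  default); everything else stays at defaults.
- **Evaluation at the precision–recall intersection.** Picks below a
  segment-size cutoff are discarded; the operating cutoff is where pooled
  precision and recall curves cross, and per-tomogram F1 is reported there,
  with and without a region mask.

## Worked example

Generate two small fixture samples end to end (procedural molecule pools,
no downloads) and evaluate picking on the generated ground truth:

```bash
cryocrowd run --fixtures --n-samples 2 --dims 48,48,24 --seed 3 --out run/
cryocrowd curves --seg run/sample_000/segmentation.mrc \
    --truth run/sample_000/coordinates.tsv \
    --cluster-radius 4 --out run/report/
```

The first command writes, per sample, `tomogram.mrc`, `segmentation.mrc`,
`coordinates.tsv`, `placements.tsv`, `occupancy.mrc` and an
`external_sim/` config deck, plus a `manifest.json`; with these settings it
logs

```
INFO pools: 2 templates, 8 distractors
INFO sample 0: 40 molecules (7 templates) in 0.6 s
INFO sample 1: 35 molecules (6 templates) in 0.5 s
```

(the samples pack to jamming since no molecule budget was given). The
second command prints

```
median F1 1.000 at size threshold 0
```

meaning every template instance in the ground-truth segmentation is
recovered exactly (precision = recall = 1 before any size filtering) — the
expected self-consistency result when the "model output" is the ground
truth itself. With a real picker's segmentation in place of
`segmentation.mrc`, the same command produces the full precision/recall
curves (`curves.csv`), the picks table and the per-tomogram F1 summary.

Library use mirrors the CLI: `structio` (PDB/MRC I/O, rasterization,
pseudoatom conversion), `flexvar` (normal modes and variants), `tetris`
(packing), `simgen` (grids, simulation, ground truth, fixtures),
`pickeval` (evaluation), `pipeline` (orchestration). See `docs/methods.md`
for models, conventions, parameters and limitations.

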