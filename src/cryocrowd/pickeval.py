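"""Segmentation-to-picks conversion and precision/recall evaluation of particle picking.

A segmentation map is converted to particle coordinates by flat-kernel
mean-shift clustering of its foreground voxels; each cluster reports its
centroid and size (supporting voxel count). Picks are matched one-to-one to
ground-truth coordinates within a spatial distance threshold (10 voxels by
convention), and precision/recall/F1 are swept over segment-size cutoffs —
small segments are predominantly false positives, so raising the cutoff
trades recall for precision. The per-tomogram F1 is reported at the cutoff
where the pooled precision and recall curves intersect. A diagnostic for
orientation bias (the classic weakness of template matching under the
missing wedge) is provided via wedge-constrained cross-correlation and
viewing-sphere coverage statistics.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation
from sklearn.cluster import MeanShift

from .structio import BinaryMask, DensityVolume

__all__ = [
    "MatchResult",
    "PRCurve",
    "CoverageResult",
    "mean_shift_extract",
    "match_picks",
    "pr_sweep",
    "f1_at_intersection",
    "evaluate_picking",
    "wedge_constrained_cc",
    "orientation_coverage",
]


@dataclasses.dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int]]   # (pick index, truth index)
    distance_threshold: float


@dataclasses.dataclass
class PRCurve:
    thresholds: np.ndarray
    precision: np.ndarray
    precision_masked: np.ndarray | None
    recall: np.ndarray
    f1: np.ndarray
    vacuous: np.ndarray  # True where no picks survived and precision defaulted to 1


@dataclasses.dataclass
class CoverageResult:
    ratios: np.ndarray       # detected/placed per viewing-sphere bin
    detected_counts: np.ndarray
    placed_counts: np.ndarray
    chi2: float
    pvalue: float


# ---------------------------------------------------------------------------
# Coordinate extraction

def mean_shift_extract(segmentation: DensityVolume | BinaryMask,
                       radius: float = 10.0) -> pd.DataFrame:
    """Cluster foreground voxels with flat-kernel mean shift.

    Returns a PickSet table with columns x, y, z (voxel coordinates of the
    cluster centroid, rounded) and size (member voxel count). An empty
    foreground yields an empty table, not an error.
    """
    if not radius > 0:
        raise ValueError("radius must be > 0")
    fg = np.argwhere(np.asarray(segmentation.grid) > 0.5)  # (n, 3) z, y, x
    cols = ["x", "y", "z", "size"]
    if len(fg) == 0:
        return pd.DataFrame(columns=cols)
    pts = fg.astype(float)
    ms = MeanShift(bandwidth=float(radius), bin_seeding=len(pts) > 5000,
                   cluster_all=True)
    labels = ms.fit_predict(pts)
    rows = []
    for lab in np.unique(labels):
        member = pts[labels == lab]
        cz, cy, cx = np.round(member.mean(axis=0)).astype(int)
        rows.append({"x": cx, "y": cy, "z": cz, "size": len(member)})
    return pd.DataFrame(rows, columns=cols).sort_values("size", ascending=False,
                                                        ignore_index=True)


# ---------------------------------------------------------------------------
# Matching and PR curves

def match_picks(picks: pd.DataFrame, truth: pd.DataFrame,
                threshold: float = 10.0) -> MatchResult:
    """Greedy one-to-one matching by ascending pairwise distance (<= threshold)."""
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    np_, nt = len(picks), len(truth)
    if np_ == 0 or nt == 0:
        return MatchResult(tp=0, fp=np_, fn=nt, pairs=[], distance_threshold=threshold)
    d = cdist(picks[["x", "y", "z"]].to_numpy(float),
              truth[["x", "y", "z"]].to_numpy(float))
    cand = np.argwhere(d <= threshold)
    order = np.argsort(d[cand[:, 0], cand[:, 1]], kind="stable")
    used_p, used_t, pairs = set(), set(), []
    for pi, ti in cand[order]:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi); used_t.add(ti)
        pairs.append((int(pi), int(ti)))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=np_ - tp, fn=nt - tp, pairs=pairs,
                       distance_threshold=threshold)


def _prf(tp: int, n_picks: int, n_truth: int) -> tuple[float, float, float, bool]:
    vacuous = n_picks == 0
    p = 1.0 if vacuous else tp / n_picks
    r = tp / n_truth if n_truth else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return p, r, f1, vacuous


def pr_sweep(
    picks: pd.DataFrame,
    truth: pd.DataFrame,
    mask: BinaryMask | None = None,
    threshold: float = 10.0,
    size_grid: list[float] | np.ndarray = (0,),
) -> PRCurve:
    """Precision/recall/F1 against segment-size cutoff.

    At each cutoff, picks with ``size < cutoff`` are dropped. When a mask is
    given, picks outside it are additionally dropped for the masked precision
    only. With zero surviving picks, precision defaults to 1 (vacuous,
    flagged) so the high-threshold curve tail is well defined.
    """
    size_grid = np.asarray(size_grid, float)
    if np.any(np.diff(size_grid) < 0):
        raise ValueError("size_grid must be ascending")
    in_mask = None
    if mask is not None:
        idx = picks[["z", "y", "x"]].to_numpy(int)
        idx = np.clip(idx, 0, np.array(mask.grid.shape) - 1)
        in_mask = mask.grid[idx[:, 0], idx[:, 1], idx[:, 2]]
    p_arr, pm_arr, r_arr, f1_arr, vac = [], [], [], [], []
    for cutoff in size_grid:
        keep = picks["size"].to_numpy(float) >= cutoff if len(picks) else \
            np.zeros(0, bool)
        retained = picks[keep]
        m = match_picks(retained, truth, threshold)
        p, r, f1, v = _prf(m.tp, len(retained), len(truth))
        p_arr.append(p); r_arr.append(r); f1_arr.append(f1); vac.append(v)
        if mask is not None:
            rm = picks[keep & in_mask]
            mm = match_picks(rm, truth, threshold)
            pm, _, _, _ = _prf(mm.tp, len(rm), len(truth))
            pm_arr.append(pm)
    return PRCurve(
        thresholds=size_grid,
        precision=np.array(p_arr),
        precision_masked=np.array(pm_arr) if mask is not None else None,
        recall=np.array(r_arr),
        f1=np.array(f1_arr),
        vacuous=np.array(vac),
    )


def f1_at_intersection(curve: PRCurve, use_masked: bool | None = None) -> float:
    """Operating segment-size threshold: argmin |P - R| on the pooled curves.

    Ties resolve to the smaller threshold. Uses the masked precision curve
    when one is present (unless overridden).
    """
    if len(curve.thresholds) == 0:
        raise ValueError("empty curve")
    if use_masked is None:
        use_masked = curve.precision_masked is not None
    p = curve.precision_masked if use_masked else curve.precision
    gap = np.abs(np.asarray(p) - curve.recall)
    return float(curve.thresholds[int(np.argmin(gap))])  # argmin takes first = smallest


def evaluate_picking(
    per_tomogram: list[tuple[pd.DataFrame, pd.DataFrame, BinaryMask | None]],
    threshold: float = 10.0,
    size_grid: list[float] | np.ndarray = (0,),
) -> dict:
    """Pooled PR curves over tomograms, operating threshold, per-tomogram F1.

    ``per_tomogram`` holds (picks, truth, mask-or-None) triples. Pooled
    precision/recall are computed from summed counts over all tomograms
    jointly; the operating threshold is the pooled intersection point, and
    per-tomogram F1 (and its median) is reported at that threshold.
    """
    size_grid = np.asarray(size_grid, float)
    any_mask = any(m is not None for _, _, m in per_tomogram)
    curves = [pr_sweep(pk, tr, mask=m, threshold=threshold, size_grid=size_grid)
              for pk, tr, m in per_tomogram]
    # pooled counts
    pooled = {"precision": [], "precision_masked": [], "recall": [], "f1": [],
              "vacuous": []}
    for k, cutoff in enumerate(size_grid):
        tp = fp = fn = tpm = fpm = 0
        for (pk, tr, m) in per_tomogram:
            keep = pk["size"].to_numpy(float) >= cutoff if len(pk) else \
                np.zeros(0, bool)
            mt = match_picks(pk[keep], tr, threshold)
            tp += mt.tp; fp += mt.fp; fn += mt.fn
            if m is not None:
                idx = np.clip(pk[["z", "y", "x"]].to_numpy(int), 0,
                              np.array(m.grid.shape) - 1)
                inm = m.grid[idx[:, 0], idx[:, 1], idx[:, 2]]
                mm = match_picks(pk[keep & inm], tr, threshold)
                tpm += mm.tp; fpm += mm.fp
        p, r, f1, v = _prf(tp, tp + fp, tp + fn)
        pooled["precision"].append(p); pooled["recall"].append(r)
        pooled["f1"].append(f1); pooled["vacuous"].append(v)
        if any_mask:
            pooled["precision_masked"].append(
                1.0 if (tpm + fpm) == 0 else tpm / (tpm + fpm))
    curve = PRCurve(
        thresholds=size_grid,
        precision=np.array(pooled["precision"]),
        precision_masked=np.array(pooled["precision_masked"]) if any_mask else None,
        recall=np.array(pooled["recall"]),
        f1=np.array(pooled["f1"]),
        vacuous=np.array(pooled["vacuous"]),
    )
    op = f1_at_intersection(curve)
    k = int(np.flatnonzero(size_grid == op)[0])
    per_f1 = [c.f1[k] for c in curves]
    return {
        "curve": curve,
        "per_tomogram_curves": curves,
        "operating_threshold": op,
        "per_tomogram_f1": np.array(per_f1),
        "median_f1": float(np.median(per_f1)),
    }


# ---------------------------------------------------------------------------
# Orientation-bias diagnostics

def _wedge_support(shape: tuple[int, int, int], tilt_range: float) -> np.ndarray:
    """Binary Fourier support of a ±tilt_range single-tilt series (axis y).

    A coefficient is sampled when the angle of its (kx, kz) component from the
    kz = 0 plane is within the tilt range; the missing wedge is the rest.
    """
    nz, ny, nx = shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    kx = np.fft.fftfreq(nx)[None, None, :]
    ang = np.degrees(np.arctan2(np.abs(kz), np.abs(kx)))
    return np.broadcast_to(ang <= tilt_range + 1e-9, (nz, ny, nx))


def wedge_constrained_cc(reference: DensityVolume, particle: DensityVolume,
                         tilt_range: float = 60.0) -> float:
    """Normalized zero-lag correlation of the two volumes after missing-wedge filtering.

    Both volumes are restricted to the Fourier support of a ±tilt_range
    single-tilt acquisition before correlating, mimicking the constrained
    cross-correlation of template matching: elongated particles correlate
    better in side views than top views because more of their power lies
    inside the wedge support.
    """
    a, b = np.asarray(reference.grid, float), np.asarray(particle.grid, float)
    if a.shape != b.shape:
        raise ValueError(f"volume shapes differ: {a.shape} vs {b.shape}")
    support = _wedge_support(a.shape, tilt_range)
    fa = np.fft.ifftn(np.fft.fftn(a) * support).real
    fb = np.fft.ifftn(np.fft.fftn(b) * support).real
    fa -= fa.mean()
    fb -= fb.mean()
    denom = np.sqrt((fa**2).sum() * (fb**2).sum())
    if denom == 0:
        return 0.0
    return float((fa * fb).sum() / denom)


def _view_vectors(orientations: np.ndarray) -> np.ndarray:
    """Accept (n, 3) unit vectors or (n, 4) quaternions (w, x, y, z)."""
    arr = np.asarray(orientations, float)
    if arr.ndim != 2 or arr.shape[1] not in (3, 4):
        raise ValueError("orientations must be (n, 3) vectors or (n, 4) quaternions")
    if arr.shape[1] == 3:
        return arr / np.linalg.norm(arr, axis=1, keepdims=True)
    q = arr[:, [1, 2, 3, 0]]  # to scipy (x, y, z, w)
    return Rotation.from_quat(q).apply(np.array([0.0, 0.0, 1.0]))


def orientation_coverage(detected: np.ndarray, placed: np.ndarray,
                         n_bins: int = 32) -> CoverageResult:
    """Equal-area viewing-sphere coverage of detected vs placed orientations.

    Bins the sphere into equal-area cells (uniform cos(polar) bands x equal
    azimuth sectors), reports the detected/placed ratio per cell and a
    chi-square test of the detected counts against the placed distribution
    (p ≈ 1 when detection is orientation-blind, small when biased).
    """
    placed_v = _view_vectors(placed)
    if len(placed_v) == 0:
        raise ValueError("placed orientation list is empty")
    detected_v = _view_vectors(detected) if len(detected) else np.zeros((0, 3))
    n_bands = max(int(round(np.sqrt(n_bins / 2))), 1)
    n_sectors = max(n_bins // n_bands, 1)

    def bin_index(v: np.ndarray) -> np.ndarray:
        band = np.minimum((((v[:, 2] + 1) / 2) * n_bands).astype(int), n_bands - 1)
        az = np.mod(np.arctan2(v[:, 1], v[:, 0]), 2 * np.pi)
        sector = np.minimum((az / (2 * np.pi) * n_sectors).astype(int), n_sectors - 1)
        return band * n_sectors + sector

    nbin = n_bands * n_sectors
    placed_counts = np.bincount(bin_index(placed_v), minlength=nbin)
    detected_counts = np.bincount(bin_index(detected_v), minlength=nbin) \
        if len(detected_v) else np.zeros(nbin, int)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(placed_counts > 0, detected_counts / placed_counts, 0.0)
    occ = placed_counts > 0
    if detected_counts.sum() == 0 or occ.sum() < 2:
        return CoverageResult(ratios, detected_counts, placed_counts,
                              chi2=np.nan, pvalue=np.nan)
    expected = placed_counts[occ] * detected_counts.sum() / placed_counts[occ].sum()
    chi2, p = stats.chisquare(detected_counts[occ], expected)
    return CoverageResult(ratios=ratios, detected_counts=detected_counts,
                          placed_counts=placed_counts, chi2=float(chi2),
                          pvalue=float(p))
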