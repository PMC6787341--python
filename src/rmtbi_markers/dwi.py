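"""Diffusion-tensor scalar maps and track-weighted imaging.

Tensor volumes are arrays shaped ``grid + (6,)`` holding the unique
elements of the symmetric diffusion tensor in lower-triangular order
(dxx, dxy, dyy, dxz, dyz, dzz), in mm^2/s, with a NIfTI affine mapping
voxel indices to world mm.  From these the standard scalar metrics are
computed per voxel:

* trace      TR = l1 + l2 + l3
* axial      AD = l1
* radial     RD = (l2 + l3) / 2
* fractional anisotropy
             FA = sqrt(3/2) * ||l - mean(l)|| / ||l||

Track-weighted images are built from streamline tractograms on a
reference voxel grid:

* TDI  — number of streamlines passing through each voxel;
* APM  — mean total length of the streamlines passing through the voxel;
* CURV — mean of the per-track mean (Menger) curvatures of those tracks.

Voxel convention: 0-based indices, voxel-centered world mapping through
the affine, half-open voxel extents [i - 0.5, i + 0.5) in voxel space.
Each streamline contributes at most once to a voxel no matter how often
it re-enters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_LOWER_TRI = ((0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2))


class DataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tensor scalars

def lower_tri_to_matrices(vol: np.ndarray) -> np.ndarray:
    """(..., 6) lower-triangular elements -> (..., 3, 3) symmetric matrices."""
    vol = np.asarray(vol, float)
    if vol.shape[-1] != 6:
        raise DataError(f"expected trailing dimension 6, got {vol.shape}")
    m = np.empty(vol.shape[:-1] + (3, 3))
    for k, (i, j) in enumerate(_LOWER_TRI):
        m[..., i, j] = vol[..., k]
        m[..., j, i] = vol[..., k]
    return m


def tensor_eigenvalues(tensor: np.ndarray) -> np.ndarray:
    """Eigenvalues of symmetric tensors, sorted descending along the last axis.

    Accepts a single 3x3 matrix, an array of matrices (..., 3, 3), or
    lower-triangular element vectors (..., 6).
    """
    tensor = np.asarray(tensor, float)
    if tensor.shape[-1] == 6:
        tensor = lower_tri_to_matrices(tensor)
    if not np.isfinite(tensor).all():
        raise DataError("non-finite tensor elements")
    return np.linalg.eigvalsh(tensor)[..., ::-1]


def fa_from_eigenvalues(ev: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from eigenvalue triples (last axis).

    FA = sqrt(3/2) * sqrt(sum (l_i - lbar)^2) / sqrt(sum l_i^2),
    defined as 0 where all eigenvalues vanish.
    """
    ev = np.asarray(ev, float)
    dev = ev - ev.mean(axis=-1, keepdims=True)
    num = np.sqrt((dev ** 2).sum(axis=-1))
    den = np.sqrt((ev ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = math.sqrt(1.5) * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return fa if fa.ndim else float(fa)


def tensor_scalars(tensor: np.ndarray) -> dict[str, np.ndarray]:
    """FA/RD/AD/TR maps plus a validity mask.

    Negative eigenvalues are not clamped; the affected voxels are simply
    flagged invalid (``valid = False``) so that downstream summaries can
    see them.
    """
    ev = tensor_eigenvalues(tensor)
    out = {
        "FA": fa_from_eigenvalues(ev),
        "AD": ev[..., 0],
        "RD": (ev[..., 1] + ev[..., 2]) / 2.0,
        "TR": ev.sum(axis=-1),
        "valid": ev[..., 2] >= 0,
    }
    return out


# ---------------------------------------------------------------------------
# streamline geometry

def streamline_length(points: np.ndarray) -> float:
    """Polyline length: sum of consecutive-point Euclidean distances (mm)."""
    points = np.asarray(points, float)
    if points.ndim != 2 or len(points) < 2:
        raise DataError("streamline needs >= 2 points")
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def streamline_mean_curvature(points: np.ndarray) -> float:
    """Mean Menger curvature over interior points (mm^-1).

    For each consecutive triple (a, b, c) the Menger curvature is the
    inverse circumradius, 4 * area(abc) / (|ab| |bc| |ca|); collinear
    triples contribute 0.  Requires >= 3 points.
    """
    points = np.asarray(points, float)
    if points.ndim != 2 or len(points) < 3:
        raise DataError("curvature needs >= 3 points")
    a, b, c = points[:-2], points[1:-1], points[2:]
    ab = np.linalg.norm(b - a, axis=1)
    bc = np.linalg.norm(c - b, axis=1)
    ca = np.linalg.norm(a - c, axis=1)
    cross = np.cross(b - a, c - a)
    area2 = np.linalg.norm(cross, axis=1)          # 2 * triangle area
    denom = ab * bc * ca
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = np.where(denom > 0, 2.0 * area2 / np.where(denom > 0, denom, 1.0), 0.0)
    return float(kappa.mean())


# ---------------------------------------------------------------------------
# rasterization

def rasterize_streamline(points: np.ndarray, shape: tuple[int, int, int],
                         affine: np.ndarray) -> set[tuple[int, int, int]]:
    """Voxels intersected by the polyline (exact traversal).

    World coordinates are mapped to voxel space through the inverse
    affine; each segment is walked with an exact amortized grid traversal
    (equivalent to supersampling in the limit of infinitely fine steps),
    so every voxel whose half-open extent the segment crosses is
    reported exactly once.  Voxels outside the grid are dropped; a
    streamline entirely outside the grid yields an empty set.
    """
    points = np.asarray(points, float)
    inv = np.linalg.inv(np.asarray(affine, float))
    vox = points @ inv[:3, :3].T + inv[:3, 3]
    # shift so voxel i spans [i, i+1): boundaries at integers
    u = vox + 0.5
    out: set[tuple[int, int, int]] = set()
    for k in range(len(u) - 1):
        _traverse_segment(u[k], u[k + 1], shape, out)
    return out


def _traverse_segment(u0: np.ndarray, u1: np.ndarray,
                      shape: tuple[int, int, int],
                      out: set[tuple[int, int, int]]) -> None:
    d = u1 - u0
    idx = np.floor(u0).astype(int)
    step = np.sign(d).astype(int)
    t_max = np.full(3, np.inf)
    t_delta = np.full(3, np.inf)
    for ax in range(3):
        if d[ax] > 0:
            t_max[ax] = (idx[ax] + 1 - u0[ax]) / d[ax]
            t_delta[ax] = 1.0 / d[ax]
        elif d[ax] < 0:
            t_max[ax] = (idx[ax] - u0[ax]) / d[ax]
            t_delta[ax] = -1.0 / d[ax]

    def _add(i):
        if all(0 <= i[ax] < shape[ax] for ax in range(3)):
            out.add((int(i[0]), int(i[1]), int(i[2])))

    _add(idx)
    while True:
        ax = int(np.argmin(t_max))
        if t_max[ax] > 1.0:
            break
        t_max[ax] += t_delta[ax]
        idx[ax] += step[ax]
        _add(idx)


# ---------------------------------------------------------------------------
# track-weighted maps

@dataclass
class TrackWeightedMaps:
    tdi: np.ndarray    # streamline count per voxel
    apm: np.ndarray    # mean total streamline length, mm
    curv: np.ndarray   # mean per-track mean curvature, mm^-1
    valid: np.ndarray  # True where TDI > 0 (APM/CURV defined)


def track_weighted_maps(streamlines: list[np.ndarray],
                        shape: tuple[int, int, int],
                        affine: np.ndarray) -> TrackWeightedMaps:
    """Track density, average pathlength, and mean curvature maps.

    TDI(v) counts the streamlines whose raster set contains v; APM(v) is
    the mean *total* length of those streamlines (the whole-track length,
    not the in-voxel portion); CURV(v) is the mean of their per-track
    mean curvatures.  APM and CURV are NaN (and masked invalid) where no
    streamline passes.
    """
    if not streamlines:
        raise DataError("empty tractogram")
    # per-voxel contribution lists, summed in sorted order so the maps are
    # bit-identical under any permutation of the input streamlines
    contrib: dict[tuple[int, int, int], list[tuple[float, float]]] = {}
    for sl in streamlines:
        voxels = rasterize_streamline(sl, shape, affine)
        if not voxels:
            continue
        length = streamline_length(sl)
        kappa = streamline_mean_curvature(sl) if len(sl) >= 3 else 0.0
        for v in voxels:
            contrib.setdefault(v, []).append((length, kappa))
    tdi = np.zeros(shape, float)
    apm = np.full(shape, np.nan)
    curv = np.full(shape, np.nan)
    for v, pairs in contrib.items():
        pairs.sort()
        n = len(pairs)
        tdi[v] = n
        apm[v] = sum(p[0] for p in pairs) / n
        curv[v] = sum(p[1] for p in pairs) / n
    valid = tdi > 0
    return TrackWeightedMaps(tdi=tdi, apm=apm, curv=curv, valid=valid)


# ---------------------------------------------------------------------------
# ROI statistics

def roi_mean(volume: np.ndarray, mask: np.ndarray,
             valid: np.ndarray | None = None,
             nonzero_only: bool = False) -> float:
    """Arithmetic mean of ``volume`` over the ROI ``mask``.

    By default this is the whole-ROI mean: every mask voxel counts, and
    voxels flagged invalid (e.g. APM/CURV where TDI = 0) contribute 0.
    ``nonzero_only`` restricts the mean to valid, nonzero voxels
    instead.
    """
    volume = np.asarray(volume, float)
    mask = np.asarray(mask, bool)
    if volume.shape != mask.shape:
        raise DataError(f"shape mismatch: {volume.shape} vs {mask.shape}")
    if not mask.any():
        raise DataError("empty ROI mask")
    vals = volume.copy()
    if valid is not None:
        vals = np.where(np.asarray(valid, bool), vals, 0.0)
    else:
        vals = np.nan_to_num(vals, nan=0.0)
    if nonzero_only:
        sel = mask & (vals != 0)
        if not sel.any():
            raise DataError("no valid nonzero voxels in ROI")
        return float(vals[sel].mean())
    return float(vals[mask].mean())
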