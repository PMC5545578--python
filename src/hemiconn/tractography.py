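"""Deterministic FACT-style streamline tracking.

Fibre Assignment by Continuous Tracking: from each seed voxel, propagate
bidirectionally along the (non-interpolated) principal eigenvector of the
voxel the current point falls in, with a fixed step of half the smallest
voxel dimension.  Propagation stops when

* the next point would enter a voxel with FA below ``fa_stop`` (default
  0.2), or would leave the grid / brain mask, or
* the turn between the current and previous path segment exceeds
  ``angle_stop`` degrees (default 45), or
* the half-track reaches ``max_len / 2`` millimetres (cycle guard).

The eigenvector sign at each step is chosen to minimize turning.  There is
no randomness anywhere: identical inputs give identical streamline sets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .volume import FAVolume, TensorVolume

__all__ = ["Streamline", "fractional_anisotropy", "fact_track",
           "save_trk", "load_trk", "save_jsonl"]


def fractional_anisotropy(eigenvalues, tol: float = 1e-8) -> float:
    """FA of a diffusion-tensor spectrum.

    FA = sqrt(3/2) * sqrt(sum (li - lbar)^2) / sqrt(sum li^2), defined as 0
    for the all-zero spectrum.  Eigenvalues more negative than ``tol`` are
    rejected (a physical diffusion tensor is positive semi-definite).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("expected 3 eigenvalues")
    if np.any(lam < -tol):
        raise ValueError("negative eigenvalue beyond tolerance")
    lam = np.clip(lam, 0.0, None)
    ss = np.sum(lam * lam, axis=-1)
    dev = lam - np.mean(lam, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * np.sum(dev * dev, axis=-1) / ss)
    fa = np.where(ss > 0, fa, 0.0)
    out = np.clip(fa, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class Streamline:
    """Ordered world-coordinate points (mm) with the seed voxel it grew from."""

    points: np.ndarray     # (n, 3) float
    seed: tuple            # (i, j, k)

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.seed = tuple(int(v) for v in self.seed)

    def __len__(self):
        return self.points.shape[0]

    @property
    def length_mm(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


def _half_track(p0, d0, grid, dirs, fa_data, mask, fa_stop, cos_stop, step, max_steps):
    """Propagate one direction from p0 with initial direction d0."""
    pts = []
    p = p0
    prev = d0
    for _ in range(max_steps):
        i, j, k = grid.nearest_voxel(p)[0]
        v = dirs[i, j, k]
        dot = v[0] * prev[0] + v[1] * prev[1] + v[2] * prev[2]
        if dot < 0:
            v = -v
            dot = -dot
        if dot < cos_stop:           # turn sharper than angle_stop
            break
        q = p + step * v
        iq = grid.nearest_voxel(q)[0]
        if not grid.inside(iq[None, :])[0]:
            break
        qi, qj, qk = iq
        if not mask[qi, qj, qk] or fa_data[qi, qj, qk] < fa_stop:
            break
        pts.append(q)
        prev = v
        p = q
    return pts


def fact_track(
    tensors: TensorVolume,
    seeds=None,
    fa_stop: float = 0.2,
    angle_stop: float = 45.0,
    step: float = None,
    max_len: float = 300.0,
    fa: FAVolume = None,
) -> list:
    """Whole-brain deterministic tracking.

    Parameters
    ----------
    seeds
        Iterable of voxel index triples; default: every brain-mask voxel
        with FA >= ``fa_stop`` (whole-brain seeding, one seed per voxel).
    step
        Step length in mm; default half the smallest voxel dimension.

    Returns a list of :class:`Streamline`.  Seeds in sub-threshold voxels
    yield single-point streamlines of length zero (kept, so the caller can
    audit seed coverage).
    """
    if not (0.0 < fa_stop < 1.0):
        raise ValueError("fa_stop must lie in (0, 1)")
    if not (0.0 < angle_stop <= 90.0):
        raise ValueError("angle_stop must lie in (0, 90]")
    grid = tensors.grid
    if fa is None:
        fa = tensors.fa()
    fa_data = fa.data
    mask = tensors.mask
    dirs = tensors.principal_directions()
    if step is None:
        step = 0.5 * float(np.min(grid.spacing))
    cos_stop = math.cos(math.radians(angle_stop))
    max_steps = max(1, int(math.floor((max_len / 2.0) / step)))

    if seeds is None:
        sel = mask & (fa_data >= fa_stop)
        seeds = list(zip(*np.nonzero(sel)))

    out = []
    for seed in seeds:
        i, j, k = (int(v) for v in seed)
        p0 = grid.index_to_world(np.array([i, j, k], dtype=float))
        if not mask[i, j, k] or fa_data[i, j, k] < fa_stop:
            out.append(Streamline(points=p0[None, :], seed=(i, j, k)))
            continue
        d0 = dirs[i, j, k]
        fwd = _half_track(p0, d0, grid, dirs, fa_data, mask,
                          fa_stop, cos_stop, step, max_steps)
        bwd = _half_track(p0, -d0, grid, dirs, fa_data, mask,
                          fa_stop, cos_stop, step, max_steps)
        pts = bwd[::-1] + [p0] + fwd
        out.append(Streamline(points=np.array(pts), seed=(i, j, k)))
    return out


def save_trk(streamlines, grid, path) -> None:
    """Write streamlines (with >= 2 points) to a TRK file."""
    import nibabel.streamlines as nibs

    tract = nibs.Tractogram(
        [s.points for s in streamlines if len(s) >= 2],
        affine_to_rasmm=np.eye(4),
    )
    hdr = {"voxel_sizes": tuple(grid.spacing), "dimensions": tuple(grid.shape),
           "voxel_to_rasmm": np.asarray(grid.affine, dtype=np.float32)}
    nibs.save(nibs.TrkFile(tract, header=hdr), str(path))


def load_trk(path) -> list:
    import nibabel.streamlines as nibs

    trk = nibs.load(str(path))
    return [Streamline(points=p, seed=(-1, -1, -1)) for p in trk.tractogram.streamlines]


def save_jsonl(streamlines, path) -> None:
    """Plain-text debug format: one JSON object per streamline."""
    with open(path, "w") as fh:
        for s in streamlines:
            fh.write(json.dumps({"seed": list(s.seed),
                                 "points": np.round(s.points, 6).tolist()}) + "\n")
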