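"""Diffusion-tensor phantoms with known fibre-bundle geometry.

A phantom is a tensor field on a regular grid containing tube-shaped
"bundles" along straight or polyline axes.  Inside a bundle the tensor is
cylindrically symmetric (lambda1 > lambda2 = lambda3) with its principal
axis along the local bundle direction and a prescribed fractional
anisotropy; outside, a low-FA background tensor.  Because the eigenvalues
are solved in closed form from the target FA, the phantom's FA map is known
exactly, which makes it a ground-truth fixture for the tracker and the
network builder.

Grids are generated with an odd x-dimension and a world-centred affine so
the midsagittal plane (world x=0) runs through the centre voxel column;
``mirror_bundles`` then yields exactly bilaterally symmetric phantoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .volume import Grid, TensorVolume, centered_affine

__all__ = [
    "Bundle",
    "PhantomSpec",
    "make_tensor_phantom",
    "mirror_bundles",
    "cylinder_eigenvalues",
]

_FA_TRACK_STOP = 0.2  # default tracking stop threshold the invariants refer to


@dataclass(frozen=True)
class Bundle:
    """A tube of radius ``radius`` (mm) around a polyline of waypoints (mm)."""

    points: tuple          # ((x,y,z), ...) >= 2 waypoints, world mm
    radius: float          # mm
    fa: float              # target FA inside the tube, (0, 1)

    def __post_init__(self):
        pts = tuple(tuple(float(c) for c in p) for p in self.points)
        if len(pts) < 2:
            raise ValueError("a bundle needs at least 2 waypoints")
        object.__setattr__(self, "points", pts)
        if not (0.0 < self.fa < 1.0):
            raise ValueError("bundle FA must lie in (0, 1)")


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple = (21, 11, 11)
    voxel_size: tuple = (2.0, 2.0, 2.0)
    bundles: tuple = ()
    background_fa: float = 0.05
    noise_sd: float = 0.0
    mean_diffusivity: float = 0.7   # trace/3, arbitrary diffusivity units
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "bundles", tuple(self.bundles))

    def validate(self) -> None:
        if any(n < 1 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if not (0.0 <= self.background_fa <= _FA_TRACK_STOP):
            raise ValueError(
                f"background_fa must lie in [0, {_FA_TRACK_STOP}] "
                "(the tracking stop threshold)"
            )
        for b in self.bundles:
            if b.fa <= _FA_TRACK_STOP:
                raise ValueError(
                    f"bundle FA {b.fa} must exceed the tracking stop threshold "
                    f"{_FA_TRACK_STOP} for a trackable phantom"
                )
            if b.radius <= max(self.voxel_size):
                raise ValueError("bundle radius must exceed the voxel size")

    @property
    def grid(self) -> Grid:
        return Grid(self.grid_shape, centered_affine(self.grid_shape, self.voxel_size))


def cylinder_eigenvalues(fa: float, md: float) -> tuple:
    """Eigenvalues (a, b, b) of a cylindrically symmetric tensor with the
    given FA and mean diffusivity, solved from the closed-form FA of the
    (a, b, b) spectrum: FA = (a - b) / sqrt(a^2 + 2 b^2)."""
    if fa == 0.0:
        return md, md, md
    if not (0.0 < fa < 1.0):
        raise ValueError("FA must lie in [0, 1) for the closed-form solve")
    f2 = fa * fa
    r = (1.0 + math.sqrt(1.0 - (1.0 - f2) * (1.0 - 2.0 * f2))) / (1.0 - f2)
    b = 3.0 * md / (r + 2.0)
    return r * b, b, b


def _segment_geometry(centers: np.ndarray, p0: np.ndarray, p1: np.ndarray):
    """Distance of each point to segment p0-p1 and the segment direction."""
    d = p1 - p0
    seg_len2 = float(d @ d)
    if seg_len2 == 0:
        raise ValueError("zero-length bundle segment")
    t = np.clip(((centers - p0) @ d) / seg_len2, 0.0, 1.0)
    closest = p0 + t[:, None] * d
    dist = np.linalg.norm(centers - closest, axis=1)
    return dist, d / math.sqrt(seg_len2)


def mirror_bundles(bundles) -> tuple:
    """x-mirrored copies of the given bundles (for symmetric phantoms)."""
    out = []
    for b in bundles:
        pts = tuple((-p[0], p[1], p[2]) for p in b.points)
        out.append(Bundle(points=pts, radius=b.radius, fa=b.fa))
    return tuple(out)


def make_tensor_phantom(spec: PhantomSpec):
    """Build the phantom tensor field.

    Returns ``(TensorVolume, masks)`` where ``masks`` is a list of boolean
    bundle-membership volumes, one per bundle, in spec order.

    Raises if two bundles claim the same voxel with conflicting local
    directions (or different FA), naming the colliding bundles.
    """
    spec.validate()
    grid = spec.grid
    nvox = int(np.prod(grid.shape))
    idx = np.indices(grid.shape).reshape(3, -1).T
    centers = grid.index_to_world(idx)

    # background: mildly anisotropic along +z (mirror-neutral) or isotropic
    if spec.background_fa > 0:
        a0, b0, _ = cylinder_eigenvalues(spec.background_fa, spec.mean_diffusivity)
        bg = np.array([b0, 0.0, 0.0, b0, 0.0, a0])
    else:
        md = spec.mean_diffusivity
        bg = np.array([md, 0.0, 0.0, md, 0.0, md])
    data = np.tile(bg, (nvox, 1))

    owner = np.full(nvox, -1, dtype=int)
    directions = np.zeros((nvox, 3))
    masks = []
    for bi, bundle in enumerate(spec.bundles):
        pts = np.asarray(bundle.points, dtype=float)
        best_dist = np.full(nvox, np.inf)
        best_dir = np.zeros((nvox, 3))
        for s in range(len(pts) - 1):
            dist, u = _segment_geometry(centers, pts[s], pts[s + 1])
            closer = dist < best_dist
            best_dist[closer] = dist[closer]
            best_dir[closer] = u
        inside = best_dist <= bundle.radius
        clash = inside & (owner >= 0)
        if np.any(clash):
            cross = np.abs(np.einsum("ij,ij->i", directions[clash], best_dir[clash]))
            fa_conflict = np.array(
                [spec.bundles[o].fa != bundle.fa for o in owner[clash]]
            )
            bad = (cross < 1.0 - 1e-9) | fa_conflict
            if np.any(bad):
                other = sorted(set(int(o) for o in owner[clash][bad]))
                raise ValueError(
                    f"bundle {bi} overlaps bundle(s) {other} with conflicting "
                    f"directions or FA"
                )
        fresh = inside & (owner < 0)
        a, b, _ = cylinder_eigenvalues(bundle.fa, spec.mean_diffusivity)
        u = best_dir[fresh]
        ab = a - b
        data[fresh, 0] = b + ab * u[:, 0] * u[:, 0]
        data[fresh, 1] = ab * u[:, 0] * u[:, 1]
        data[fresh, 2] = ab * u[:, 0] * u[:, 2]
        data[fresh, 3] = b + ab * u[:, 1] * u[:, 1]
        data[fresh, 4] = ab * u[:, 1] * u[:, 2]
        data[fresh, 5] = b + ab * u[:, 2] * u[:, 2]
        owner[fresh] = bi
        directions[fresh] = best_dir[fresh]
        masks.append(inside.reshape(grid.shape))

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)

    vol = TensorVolume(data=data.reshape(grid.shape + (6,)), grid=grid)
    return vol, masks
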