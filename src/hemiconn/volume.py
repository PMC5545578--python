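"""Voxel-grid containers shared by the imaging stages.

Conventions
-----------
* voxel indices are 0-based ``(i, j, k)``; world coordinates are millimetres
  obtained through a NIfTI-style affine.
* only axis-aligned diagonal affines are supported: the pipeline's own
  products (phantoms, templates) are always written that way, and the
  midsagittal-plane contract (world ``x = 0``) is only meaningful on such
  grids.  Obliquely oriented inputs must be resampled upstream.
* the midsagittal plane is world ``x = 0``; voxels with centre ``x < 0`` are
  left-hemisphere, ``x > 0`` right-hemisphere, ``x = 0`` belongs to neither.
* nearest-voxel lookup on the x axis rounds half away from the grid-centre
  column.  On a grid with an odd x-dimension centred on ``x = 0`` this makes
  the lookup exactly mirror-symmetric: a world point and its x-reflection
  always map to mirrored voxels, down to the last bit.  This property is what
  lets a bilaterally symmetric phantom produce bitwise-identical left and
  right networks (and hence asymmetry indices that are exactly zero).

Tensor component order is ``(Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Grid",
    "BinaryMask",
    "LabelVolume",
    "TensorVolume",
    "FAVolume",
    "centered_affine",
    "fa_from_components",
]


def centered_affine(shape, voxel_size) -> np.ndarray:
    """Diagonal affine placing the world origin at the grid centre.

    With an odd dimension the centre falls on a voxel centre (for x: the
    midsagittal column); with an even dimension it falls between voxels.
    """
    shape = np.asarray(shape, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = vs
    # translation = -c * s computed per axis so that center_world == 0 exactly
    aff[:3, 3] = [-((n - 1.0) / 2.0) * s for n, s in zip(shape, vs)]
    return aff


def _check_diagonal(affine: np.ndarray) -> None:
    rot = np.asarray(affine, dtype=float)[:3, :3]
    if np.any(rot != np.diag(np.diag(rot))) or np.any(np.diag(rot) <= 0):
        raise ValueError(
            "only axis-aligned diagonal affines with positive spacings are "
            "supported; resample the input volume"
        )


@dataclass(frozen=True)
class Grid:
    """A 3D voxel lattice with a diagonal voxel-to-world affine."""

    shape: tuple
    affine: np.ndarray

    def __post_init__(self):
        _check_diagonal(self.affine)
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @property
    def spacing(self) -> np.ndarray:
        return np.diag(np.asarray(self.affine, dtype=float)[:3, :3]).copy()

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.affine, dtype=float)[:3, 3].copy()

    @property
    def center_world(self) -> np.ndarray:
        """World position of the grid centre, ((n-1)/2) in index units."""
        c = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return self.origin + c * self.spacing

    def index_to_world(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx * self.spacing + self.origin

    def world_to_continuous(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - self.origin) / self.spacing

    def nearest_voxel(self, pts) -> np.ndarray:
        """Nearest voxel indices with midplane-symmetric x rounding.

        Rounds the centre-relative offset half away from zero on every axis
        whose dimension is odd (the boundary cases then mirror exactly);
        even-dimension axes use plain half-up rounding.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        out = np.empty(pts.shape, dtype=np.int64)
        for ax in range(3):
            n = self.shape[ax]
            if n % 2 == 1:
                c = (n - 1) // 2
                d = (pts[:, ax] - self.center_world[ax]) / self.spacing[ax]
                out[:, ax] = c + np.trunc(d + np.copysign(0.5, d)).astype(np.int64)
            else:
                v = (pts[:, ax] - self.origin[ax]) / self.spacing[ax]
                out[:, ax] = np.floor(v + 0.5).astype(np.int64)
        return out

    def inside(self, idx) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx))
        ok = np.ones(idx.shape[0], dtype=bool)
        for ax in range(3):
            ok &= (idx[:, ax] >= 0) & (idx[:, ax] < self.shape[ax])
        return ok

    def x_world(self) -> np.ndarray:
        """World x coordinate of every column index (length shape[0])."""
        i = np.arange(self.shape[0], dtype=float)
        return i * self.spacing[0] + self.origin[0]

    def flip_alignable(self, atol: float = 1e-9) -> bool:
        """True if the grid x-flip is an exact world mirror about x=0."""
        return abs(self.center_world[0]) <= atol

    def __eq__(self, other):
        return (
            isinstance(other, Grid)
            and self.shape == other.shape
            and np.array_equal(np.asarray(self.affine), np.asarray(other.affine))
        )


@dataclass
class BinaryMask:
    """A {0,1} voxel mask on a grid; midsagittal plane is world x=0."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError("mask shape does not match grid shape")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def hemisphere_mask(self, side: str) -> np.ndarray:
        """Boolean mask restricted to one hemisphere ('left' or 'right')."""
        x = self.grid.x_world()
        if side == "right":
            keep = x > 0
        elif side == "left":
            keep = x < 0
        else:
            raise ValueError(f"unknown hemisphere {side!r}")
        out = self.data.copy()
        out[~keep, :, :] = False
        return out

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), self.grid.affine), str(path))

    @classmethod
    def load(cls, path) -> "BinaryMask":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj) > 0
        return cls(data=data, grid=Grid(data.shape, img.affine))


@dataclass
class LabelVolume:
    """Integer ROI labels; 0 = background.

    ``hemisphere`` maps each label to 'left'/'right'.  ``homolog`` maps a
    right label to its mirror-image left label (populated once the template
    is bilateral).
    """

    data: np.ndarray
    grid: Grid
    hemisphere: dict = field(default_factory=dict)
    homolog: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be integer")
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError("label shape does not match grid shape")

    @property
    def labels(self) -> np.ndarray:
        lab = np.unique(self.data)
        return lab[lab > 0]

    def labels_for(self, side: str) -> list:
        return sorted(l for l, h in self.hemisphere.items() if h == side)

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.int32), self.grid.affine), str(path))

    def save_homolog_table(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("right_label\tleft_label\n")
            for r, l in sorted(self.homolog.items()):
                fh.write(f"{r}\t{l}\n")

    @classmethod
    def load(cls, path, homolog_table=None) -> "LabelVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj).astype(np.int32)
        vol = cls(data=data, grid=Grid(data.shape, img.affine))
        if homolog_table is not None:
            homolog = {}
            with open(homolog_table) as fh:
                next(fh)
                for line in fh:
                    r, l = line.split()
                    homolog[int(r)] = int(l)
            vol.homolog = homolog
            vol.hemisphere = {r: "right" for r in homolog}
            vol.hemisphere.update({l: "left" for l in homolog.values()})
        else:
            x = vol.grid.x_world()
            for lab in vol.labels:
                cols = np.unique(np.nonzero(vol.data == lab)[0])
                if np.all(x[cols] > 0):
                    vol.hemisphere[int(lab)] = "right"
                elif np.all(x[cols] < 0):
                    vol.hemisphere[int(lab)] = "left"
        return vol


def fa_from_components(d6: np.ndarray) -> np.ndarray:
    """FA from tensor invariants (trace and Frobenius norm).

    Avoids eigendecomposition so that an x-mirrored tensor (sign-flipped
    Dxy, Dxz) yields the bitwise-identical FA value.
    """
    d6 = np.asarray(d6, dtype=float)
    dxx, dxy, dxz, dyy, dyz, dzz = np.moveaxis(d6, -1, 0)
    mean = (dxx + dyy + dzz) / 3.0
    ss = dxx * dxx + dyy * dyy + dzz * dzz + 2.0 * (dxy * dxy + dxz * dxz + dyz * dyz)
    num = ss - 3.0 * mean * mean
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * np.clip(num, 0.0, None) / ss)
    fa = np.where(ss > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensors, (..., 6) component order
    (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz), plus a brain mask."""

    data: np.ndarray
    grid: Grid
    mask: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != tuple(self.grid.shape) + (6,):
            raise ValueError("tensor data must have shape grid.shape + (6,)")
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        self._dirs = None

    def tensors_3x3(self) -> np.ndarray:
        d = self.data
        out = np.empty(d.shape[:-1] + (3, 3), dtype=float)
        out[..., 0, 0] = d[..., 0]
        out[..., 0, 1] = out[..., 1, 0] = d[..., 1]
        out[..., 0, 2] = out[..., 2, 0] = d[..., 2]
        out[..., 1, 1] = d[..., 3]
        out[..., 1, 2] = out[..., 2, 1] = d[..., 4]
        out[..., 2, 2] = d[..., 5]
        return out

    def fa(self) -> "FAVolume":
        return FAVolume(data=fa_from_components(self.data), grid=self.grid)

    def principal_directions(self) -> np.ndarray:
        """Unit principal eigenvector per voxel, mirror-canonicalized.

        The tensor is conjugated into a canonical x-orientation (Dxy, Dxz
        made lexicographically nonnegative) before eigendecomposition and
        the eigenvector's x component flipped back afterwards, so two
        tensors related by an x-mirror yield exactly mirrored directions.
        """
        if self._dirs is not None:
            return self._dirs
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data).all(axis=-1))[0]
            raise ValueError(f"non-finite tensor at voxel {tuple(int(v) for v in bad)}")
        d = self.data.reshape(-1, 6).copy()
        flip = (d[:, 1] < 0) | ((d[:, 1] == 0) & (d[:, 2] < 0))
        d[flip, 1] *= -1.0
        d[flip, 2] *= -1.0
        mats = np.empty((d.shape[0], 3, 3), dtype=float)
        mats[:, 0, 0] = d[:, 0]
        mats[:, 0, 1] = mats[:, 1, 0] = d[:, 1]
        mats[:, 0, 2] = mats[:, 2, 0] = d[:, 2]
        mats[:, 1, 1] = d[:, 3]
        mats[:, 1, 2] = mats[:, 2, 1] = d[:, 4]
        mats[:, 2, 2] = d[:, 5]
        _, vecs = np.linalg.eigh(mats)
        v = vecs[:, :, 2]  # eigenvector of the largest eigenvalue
        v[flip, 0] *= -1.0
        self._dirs = v.reshape(self.grid.shape + (3,))
        return self._dirs

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data, self.grid.affine), str(path))

    @classmethod
    def load(cls, path, mask_path=None) -> "TensorVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        grid = Grid(data.shape[:3], img.affine)
        mask = None
        if mask_path is not None:
            mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
        return cls(data=data, grid=grid, mask=mask)


@dataclass
class FAVolume:
    """Scalar fractional-anisotropy map in [0, 1]."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError("FA shape does not match grid shape")
        if np.nanmin(self.data) < -1e-9 or np.nanmax(self.data) > 1 + 1e-9:
            raise ValueError("FA values must lie in [0, 1]")

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data, self.grid.affine), str(path))

    @classmethod
    def load(cls, path) -> "FAVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        return cls(data=data, grid=Grid(data.shape, img.affine))
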