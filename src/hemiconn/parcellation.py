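"""Bilaterally symmetric random parcellation.

The node template is built in three steps, mirroring standard practice for
high-resolution connectome node sets:

1. ``symmetrize_mask`` — make a cortical mask exactly symmetric about the
   midsagittal plane by combining it with its x-flip (union by default;
   intersection available, since the binarization rule of an "averaged"
   mask is a free choice).
2. ``random_partition`` — tile one hemisphere with ``n_rois`` connected,
   near-equal-size ROIs by seeded region growing: seed voxels are sampled
   uniformly without replacement, then the currently smallest ROI accretes
   one 6-connected voxel per iteration (ties broken by lowest linear voxel
   index), which keeps sizes within a factor ~2 of each other.
3. ``mirror_parcellation`` — flip the right-hemisphere labels through the
   midplane to obtain the bilateral template with a one-to-one homologous
   correspondence (left label = right label + n_rois).

Determinism: identical (mask, n_rois, seed) give identical templates.
"""

from __future__ import annotations

import heapq

import numpy as np

from .volume import BinaryMask, LabelVolume

__all__ = ["symmetrize_mask", "random_partition", "mirror_parcellation"]


def symmetrize_mask(mask: BinaryMask, rule: str = "union") -> BinaryMask:
    """Combine a mask with its x-flip into an exactly symmetric mask.

    ``rule`` is 'union' (keep voxels present on either side; preserves
    coverage) or 'intersection' (keep voxels present on both).
    """
    if mask.n_voxels == 0:
        raise ValueError("mask nonempty is required")
    if not mask.grid.flip_alignable():
        raise ValueError(
            "grid is not aligned with the midsagittal plane (world x=0); "
            "resample the mask to a grid whose x-flip is an exact mirror"
        )
    flipped = mask.data[::-1, :, :]
    if rule == "union":
        data = mask.data | flipped
    elif rule == "intersection":
        data = mask.data & flipped
    else:
        raise ValueError(f"unknown combine rule {rule!r}")
    return BinaryMask(data=data, grid=mask.grid)


_NBR = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


def _components(flat_idx, shape):
    """Connected components (6-connectivity) of a voxel set; returns sizes."""
    from scipy.ndimage import label as cc_label

    vol = np.zeros(shape, dtype=bool)
    vol.reshape(-1)[flat_idx] = True
    lab, ncomp = cc_label(vol)  # default structure is 6-connectivity in 3D
    sizes = np.bincount(lab.reshape(-1))[1:]
    return ncomp, sizes.tolist()


def random_partition(mask: BinaryMask, hemisphere: str, n_rois: int,
                     seed: int) -> LabelVolume:
    """Seeded region-growing partition of one hemisphere into n_rois ROIs."""
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    grid = mask.grid
    hemi = mask.hemisphere_mask(hemisphere)
    flat = np.nonzero(hemi.reshape(-1))[0]
    if flat.size < n_rois:
        raise ValueError(
            f"hemisphere has {flat.size} voxels, fewer than n_rois={n_rois}")
    ncomp, sizes = _components(flat, grid.shape)
    if ncomp > n_rois:
        raise ValueError(
            f"mask fragments into {ncomp} components (sizes {sorted(sizes)}), "
            f"more than n_rois={n_rois} seeds can cover")

    shape = grid.shape
    strides = (shape[1] * shape[2], shape[2], 1)
    inside = hemi.reshape(-1)
    labels = np.zeros(int(np.prod(shape)), dtype=np.int32)

    rng = np.random.default_rng(seed)
    seeds = rng.choice(flat, size=n_rois, replace=False)
    sizes_arr = np.zeros(n_rois + 1, dtype=np.int64)
    frontiers = [None] + [[] for _ in range(n_rois)]

    def neighbours(lin):
        i, j, k = np.unravel_index(lin, shape)
        for di, dj, dk in _NBR:
            ni, nj, nk = i + di, j + dj, k + dk
            if 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]:
                yield ni * strides[0] + nj * strides[1] + nk

    for lab, s in enumerate(seeds, start=1):
        labels[s] = lab
        sizes_arr[lab] = 1
        for nb in neighbours(int(s)):
            if inside[nb] and labels[nb] == 0:
                heapq.heappush(frontiers[lab], int(nb))

    active = [(1, lab) for lab in range(1, n_rois + 1)]
    heapq.heapify(active)
    assigned = n_rois
    total = flat.size
    while active and assigned < total:
        size, lab = heapq.heappop(active)
        if size != sizes_arr[lab]:
            continue  # stale entry
        fr = frontiers[lab]
        vox = None
        while fr:
            cand = heapq.heappop(fr)
            if labels[cand] == 0:
                vox = cand
                break
        if vox is None:
            continue  # ROI can no longer grow
        labels[vox] = lab
        sizes_arr[lab] += 1
        assigned += 1
        for nb in neighbours(vox):
            if inside[nb] and labels[nb] == 0:
                heapq.heappush(fr, nb)
        heapq.heappush(active, (int(sizes_arr[lab]), lab))

    # orphan voxels unreachable from any seed: nearest ROI centroid
    orphan = flat[labels[flat] == 0]
    if orphan.size:
        centroids = np.zeros((n_rois, 3))
        for lab in range(1, n_rois + 1):
            lin = np.nonzero(labels == lab)[0]
            ijk = np.array(np.unravel_index(lin, shape)).T
            centroids[lab - 1] = grid.index_to_world(ijk).mean(axis=0)
        ijk = np.array(np.unravel_index(orphan, shape)).T
        pts = grid.index_to_world(ijk)
        d = np.linalg.norm(pts[:, None, :] - centroids[None, :, :], axis=2)
        labels[orphan] = np.argmin(d, axis=1) + 1

    vol = LabelVolume(data=labels.reshape(shape), grid=grid,
                      hemisphere={lab: hemisphere for lab in range(1, n_rois + 1)})
    return vol


def mirror_parcellation(right_labels: LabelVolume) -> LabelVolume:
    """Flip a right-hemisphere parcellation into the left hemisphere.

    The bilateral template uses left label = right label + n_rois; the
    homolog map records the pairing.  Left-ROI i is voxel-for-voxel the
    x-mirror of right-ROI i, which guarantees one-to-one node
    correspondence between the hemispheric networks.
    """
    grid = right_labels.grid
    if not grid.flip_alignable():
        raise ValueError("grid is not mirror-aligned with world x=0; resample")
    data = right_labels.data
    x = grid.x_world()
    straddle = sorted(
        int(l) for l in right_labels.labels
        if np.any(x[np.unique(np.nonzero(data == l)[0])] <= 0)
    )
    if straddle:
        raise ValueError(
            f"labels not confined to the right hemisphere: {straddle}")
    labs = right_labels.labels
    n_rois = int(labs.max())
    flipped = data[::-1, :, :]
    out = data.copy()
    left_region = flipped > 0
    out[left_region] = flipped[left_region] + n_rois
    hemisphere = {int(l): "right" for l in labs}
    hemisphere.update({int(l) + n_rois: "left" for l in labs})
    homolog = {int(l): int(l) + n_rois for l in labs}
    return LabelVolume(data=out, grid=grid, hemisphere=hemisphere,
                       homolog=homolog)
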