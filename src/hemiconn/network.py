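"""FA-weighted hemispheric network construction from streamlines.

Each hemisphere yields one N x N symmetric weighted adjacency matrix whose
nodes are the hemisphere's parcellation ROIs.  A streamline contributes to
edge (i, j) when its two terminal points fall in distinct ROIs of the same
hemisphere; the edge weight is the mean FA sampled (nearest voxel) at every
point of every connecting streamline.  Cross-hemisphere and self-loop
assignments are discarded, as are endpoints outside the labelled grid
(counted in the dropped-fibre log).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import FAVolume, LabelVolume

log = logging.getLogger(__name__)

__all__ = ["HemisphericNetwork", "assign_endpoints", "build_network",
           "save_matrix", "load_matrix"]


@dataclass
class HemisphericNetwork:
    """One hemisphere's weighted network.

    weights : (N, N) symmetric, zero diagonal, entries in [0, 1] (mean FA)
    counts  : (N, N) fibre counts backing each edge
    nodes   : table with columns label, hemisphere (and optional name)
    """

    weights: np.ndarray
    counts: np.ndarray
    nodes: pd.DataFrame
    hemisphere: str = ""

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n) or self.counts.shape != (n, n):
            raise ValueError("weights and counts must be square, same size")
        if not np.array_equal(self.weights, self.weights.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("weight matrix must have zero diagonal")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def assign_endpoints(streamline, labels: LabelVolume):
    """ROI pair connected by a streamline, or ``None``.

    ``None`` when either endpoint is background/outside the grid, both
    endpoints share one ROI (self-loop), or the ROIs lie in different
    hemispheres (hemispheric networks are intra-hemispheric).
    """
    if len(streamline) < 2:
        return None
    ends = streamline.points[[0, -1]]
    idx = labels.grid.nearest_voxel(ends)
    ok = labels.grid.inside(idx)
    lab = []
    for m in range(2):
        if not ok[m]:
            return None
        l = int(labels.data[tuple(idx[m])])
        if l == 0:
            return None
        lab.append(l)
    a, b = lab
    if a == b:
        return None
    if labels.hemisphere.get(a) != labels.hemisphere.get(b):
        return None
    return a, b


def build_network(
    streamlines,
    labels: LabelVolume,
    fa: FAVolume,
    hemisphere: str,
    edge_min_fibers: int = 1,
    weight_mode: str = "pooled",
) -> HemisphericNetwork:
    """Build one hemisphere's FA-weighted network.

    Parameters
    ----------
    edge_min_fibers
        Minimum connecting-fibre count for an edge to receive a weight
        (1 keeps every connection; 2 is the strict "more than one fibre"
        reading).  Counts are recorded either way.
    weight_mode
        'pooled'    -- mean over all FA samples of all connecting fibres
                       (default estimator)
        'per-fiber' -- mean of per-fibre mean FA values

    FA sample sums use exactly-rounded order-independent summation so the
    result does not depend on streamline enumeration order (this is what
    makes mirrored hemispheres bitwise identical).
    """
    if labels.grid != fa.grid:
        raise ValueError("labels and FA volume must share one grid/affine")
    if weight_mode not in ("pooled", "per-fiber"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    node_labels = labels.labels_for(hemisphere)
    if not node_labels:
        raise ValueError(f"no labels tagged for hemisphere {hemisphere!r}")
    pos = {lab: i for i, lab in enumerate(node_labels)}
    n = len(node_labels)
    counts = np.zeros((n, n), dtype=np.int64)
    samples = {}      # (i, j) i<j -> list of FA samples (pooled) or fiber means
    dropped = 0
    for s in streamlines:
        pair = assign_endpoints(s, labels)
        if pair is None:
            if len(s) >= 2:
                dropped += 1
            continue
        a, b = pair
        if a not in pos or b not in pos:   # other hemisphere's network
            continue
        i, j = sorted((pos[a], pos[b]))
        idx = labels.grid.nearest_voxel(s.points)
        inside = labels.grid.inside(idx)
        vals = fa.data[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
        counts[i, j] += 1
        counts[j, i] += 1
        bucket = samples.setdefault((i, j), [])
        if weight_mode == "pooled":
            bucket.extend(float(v) for v in vals)
        else:
            bucket.append(math.fsum(float(v) for v in vals) / len(vals))
    if not any(len(s) >= 2 for s in streamlines):
        log.warning("empty streamline set: returning all-zero matrices")
    if dropped:
        log.info("dropped %d fibres (unlabelled/self-loop/cross-hemisphere ends)",
                 dropped)

    weights = np.zeros((n, n), dtype=float)
    for (i, j), vals in samples.items():
        if counts[i, j] >= edge_min_fibers:
            w = math.fsum(vals) / len(vals)
            weights[i, j] = w
            weights[j, i] = w
    nodes = pd.DataFrame({"label": node_labels,
                          "hemisphere": [hemisphere] * n})
    return HemisphericNetwork(weights=weights, counts=counts, nodes=nodes,
                              hemisphere=hemisphere)


def save_matrix(matrix: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(matrix), fmt="%.17g", delimiter="\t")


def load_matrix(path) -> np.ndarray:
    m = np.loadtxt(path, delimiter="\t")
    return np.atleast_2d(m)
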