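"""Weighted efficiency metrics and the hemispheric asymmetry index.

Definitions (Latora-Marchiori efficiency family, weighted form):

* shortest path length ``L_ij`` minimizes the sum of edge lengths along a
  path, with the edge length of a weight ``w`` equal to ``1/w`` (the
  reciprocal convention of the standard connectome toolboxes; ``-log(w)``
  is available as an alternative and the rule used is recorded in the
  result).  Disconnected pairs have ``L_ij = inf``.
* global efficiency  E_glob = (1 / (N (N-1))) * sum_{i != j} 1 / L_ij
* nodal efficiency   E_nodal(i) = (1 / (N-1)) * sum_{j != i} 1 / L_ij
* local efficiency   E_loc = (1/N) * sum_i E_glob(G_i), where G_i is the
  subgraph induced by the neighbours of i (i excluded, original weights
  kept); nodes with fewer than two neighbours contribute 0.

Disconnected pairs contribute 0 to every efficiency sum, so all values lie
in [0, max weight] for weights in (0, 1].

The asymmetry index for a paired measure is AI = (M_R - M_L)/(M_R + M_L);
positive AI means rightward asymmetry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "PathLengthMatrix", "shortest_paths", "global_efficiency",
    "local_efficiency", "nodal_efficiency", "asymmetry_index",
    "mean_nodal_ai", "network_metrics", "cohort_metric_tables",
]


@dataclass
class PathLengthMatrix:
    """All-pairs shortest path lengths plus the weight-to-length rule used."""

    lengths: np.ndarray          # (N, N), inf for disconnected pairs
    distance_rule: str           # 'inverse' or 'neglog'

    @property
    def n(self) -> int:
        return self.lengths.shape[0]


def _as_weights(net) -> np.ndarray:
    w = net.weights if hasattr(net, "weights") else np.asarray(net, dtype=float)
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if not np.array_equal(w, w.T):
        raise ValueError("weight matrix must be symmetric")
    return w


def shortest_paths(net, distance_rule: str = "inverse") -> PathLengthMatrix:
    """All-pairs shortest path lengths by Dijkstra from every node."""
    w = _as_weights(net)
    with np.errstate(divide="ignore"):
        if distance_rule == "inverse":
            lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
        elif distance_rule == "neglog":
            if np.any(w > 1):
                raise ValueError("neglog rule requires weights <= 1")
            lengths = np.where(w > 0, -np.log(np.where(w > 0, w, 1.0)), 0.0)
        else:
            raise ValueError(f"unknown distance rule {distance_rule!r}")
    graph = csr_matrix(lengths)
    L = dijkstra(graph, directed=False)
    np.fill_diagonal(L, 0.0)
    return PathLengthMatrix(lengths=L, distance_rule=distance_rule)


def _inverse_offdiag(L: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        inv = 1.0 / L
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv


def global_efficiency(L) -> float:
    """Average inverse shortest path length over ordered node pairs."""
    lengths = L.lengths if isinstance(L, PathLengthMatrix) else np.asarray(L, dtype=float)
    n = lengths.shape[0]
    if n < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    inv = _inverse_offdiag(lengths)
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(L, i=None):
    """Mean inverse distance from node(s) to all others.

    With ``i`` given, returns that node's value; otherwise the full vector.
    The vector's mean equals the global efficiency (algebraic identity).
    """
    lengths = L.lengths if isinstance(L, PathLengthMatrix) else np.asarray(L, dtype=float)
    n = lengths.shape[0]
    if n < 2:
        raise ValueError("nodal efficiency requires at least 2 nodes")
    inv = _inverse_offdiag(lengths)
    vec = inv.sum(axis=1) / (n - 1)
    if i is None:
        return vec
    return float(vec[int(i)])


def local_efficiency(net, distance_rule: str = "inverse") -> float:
    """Mean, over nodes, of the global efficiency of the neighbour subgraph."""
    w = _as_weights(net)
    n = w.shape[0]
    if n < 1:
        raise ValueError("local efficiency requires at least 1 node")
    total = 0.0
    for i in range(n):
        nbrs = np.nonzero(w[i] > 0)[0]
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        total += global_efficiency(shortest_paths(sub, distance_rule))
    return total / n


def asymmetry_index(m_right: float, m_left: float) -> float:
    """(M_R - M_L) / (M_R + M_L); positive = rightward asymmetry.

    Undefined (NaN, with a warning) when both measures are zero.
    """
    m_right = float(m_right)
    m_left = float(m_left)
    if m_right < 0 or m_left < 0:
        raise ValueError("AI is defined for nonnegative measures")
    denom = m_right + m_left
    if denom == 0.0:
        warnings.warn("AI undefined: M_R + M_L = 0; returning NaN", stacklevel=2)
        return float("nan")
    return (m_right - m_left) / denom


def mean_nodal_ai(ai_values, node_subset) -> float:
    """Arithmetic mean of nodal AI over a nonempty node subset."""
    ai_values = np.asarray(ai_values, dtype=float)
    subset = np.asarray(list(node_subset), dtype=int)
    if subset.size == 0:
        raise ValueError("node subset must be nonempty")
    return float(np.mean(ai_values[subset]))


def network_metrics(net, distance_rule: str = "inverse"):
    """(E_glob, E_loc, E_nodal vector) for one hemispheric network."""
    L = shortest_paths(net, distance_rule)
    return (global_efficiency(L),
            local_efficiency(net, distance_rule),
            nodal_efficiency(L))


def cohort_metric_tables(subject_networks, distance_rule: str = "inverse"):
    """Long-format metric and AI tables for a cohort.

    Parameters
    ----------
    subject_networks
        Iterable of ``(subject_id, left_weights, right_weights)``.

    Returns
    -------
    metrics : DataFrame (subject, hemisphere, measure, node, value)
        measure in {'e_glob', 'e_loc', 'e_nodal'}; node is -1 except for
        e_nodal rows.
    ai : DataFrame (subject, measure, node, m_right, m_left, ai)
    """
    mrows, arows = [], []
    for sid, wl, wr in subject_networks:
        gl, ll, nl = network_metrics(wl, distance_rule)
        gr, lr, nr = network_metrics(wr, distance_rule)
        for hemi, (g, l, nod) in (("left", (gl, ll, nl)), ("right", (gr, lr, nr))):
            mrows.append((sid, hemi, "e_glob", -1, g))
            mrows.append((sid, hemi, "e_loc", -1, l))
            mrows.extend((sid, hemi, "e_nodal", i, v) for i, v in enumerate(nod))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            arows.append((sid, "e_glob", -1, gr, gl, asymmetry_index(gr, gl)))
            arows.append((sid, "e_loc", -1, lr, ll, asymmetry_index(lr, ll)))
            arows.extend((sid, "e_nodal", i, nr[i], nl[i],
                          asymmetry_index(nr[i], nl[i]))
                         for i in range(len(nl)))
    metrics = pd.DataFrame(mrows, columns=["subject", "hemisphere", "measure",
                                           "node", "value"])
    ai = pd.DataFrame(arows, columns=["subject", "measure", "node",
                                      "m_right", "m_left", "ai"])
    return metrics, ai
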