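"""Weighted efficiency metrics on small hand-checkable graphs.

Edge weights are treated as connection strengths (here: mean FA values in
(0, 1]); the length of an edge is the reciprocal of its weight, and the
efficiency family averages inverse shortest-path lengths.
"""

import numpy as np

from hemiconn.metrics import (
    asymmetry_index, global_efficiency, local_efficiency, nodal_efficiency,
    shortest_paths)

# complete unit-weight graph: every pair at distance 1 -> E_glob = 1
complete = np.ones((4, 4)) - np.eye(4)
print("E_glob(complete K4)    =", global_efficiency(shortest_paths(complete)))

# 3-node unit path A-B-C: pairs at distances 1,1,2 -> E_glob = 5/6
path3 = np.array([[0, 1.0, 0], [1.0, 0, 1.0], [0, 1.0, 0]])
print("E_glob(3-node path)    =", global_efficiency(shortest_paths(path3)),
      "(= 5/6)")

# unit triangle: each neighbour subgraph is a connected pair -> E_loc = 1
triangle = np.ones((3, 3)) - np.eye(3)
print("E_loc(unit triangle)   =", local_efficiency(triangle))

# star: leaves have one neighbour, the hub's neighbours are unconnected
star = np.zeros((5, 5))
star[0, 1:] = star[1:, 0] = 1.0
print("E_loc(star)            =", local_efficiency(star))
print("E_nodal(star hub)      =",
      nodal_efficiency(shortest_paths(star), 0), "(hub reaches all at 1)")

# asymmetry index: positive = rightward lateralization
print("AI(right=0.6, left=0.3) =", asymmetry_index(0.6, 0.3), "(= 1/3)")
print("AI(right=0.3, left=0.6) =", asymmetry_index(0.3, 0.6))
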