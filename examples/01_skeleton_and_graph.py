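"""Build the 19-node skeleton graph and inspect its normalized adjacency.

The classifier aggregates joint features over this graph: 17 body joints
plus the racket handle and head, connected by 18 anatomical edges.
"""

import numpy as np

from tennisgcn import NeighborSpec, canonical_graph, neighbor_set

graph = canonical_graph()
print(f"nodes: {graph.n_nodes}, spatial edges: {len(graph.edges)}")
print("node names:", ", ".join(graph.node_names))

# The normalized adjacency Lambda^{-1/2}(A+I)Lambda^{-1/2} is what the
# network multiplies into the joint axis; its rows sum to <= 1 and every
# node keeps a self-link.
A_norm = graph.A_norm
print(f"A_norm: symmetric={np.allclose(A_norm, A_norm.T)}, "
      f"max row sum={A_norm.sum(axis=1).max():.3f}")

# Distance-1 neighborhoods are the receptive field of one spatial layer.
for joint in ("elbow_r", "racket_handle", "pelvis"):
    ids = neighbor_set(graph, joint, NeighborSpec(D=1))
    print(f"G({joint}) = {{{', '.join(sorted(graph.node_names[i] for i in ids))}}}")
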