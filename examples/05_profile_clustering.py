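"""Cluster residues by shared correlation partners (onion-skin layers).

Residues that correlate with similar *subsets* of residues cluster
together even when mutually uncorrelated; layers are then ordered by their
distance to a chosen center set.
"""

import numpy as np

from icnet import divisive_cluster, layer_summary
from icnet.correlation import ResidueCorrelationMatrix
from icnet.synthetic import generate_toy_complex

# three groups defined by partners: X--Y coupled at 0.9, Y--Z at 0.4
n, g = 12, 4
v = np.zeros((n, n))
v[np.ix_(range(g), range(g, 2 * g))] = 0.9
v[np.ix_(range(g, 2 * g), range(2 * g, n))] = 0.4
v = np.maximum(v, v.T)
M = ResidueCorrelationMatrix(v, "max-normalized")

tree = divisive_cluster(M, n_clusters=3)
for members in tree.cut(3):
    print("cluster:", members)
print("within-cluster couplings are all zero; grouping is by shared partners")

complex = generate_toy_complex(12, seed=3)
layers = layer_summary(tree, complex, center_residues=[1, 2, 3, 4],
                       n_clusters=3)
print(layers.drop(columns="members").to_string(index=False))
print("layers are ordered by mean distance from the center set")
print("newick:", tree.to_newick()[:60], "...")
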