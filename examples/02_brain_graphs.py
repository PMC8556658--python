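"""The two brain views: learned functional connectivity and electrode distance.

Evaluates the adaptive adjacency on a hand-made feature matrix, the Gaussian
distance kernel on a ring montage, and the scaled Laplacian used by the
spectral filter.
"""

import numpy as np

from sleepgcn.graphs import (
    GraphLearner,
    build_distance_adjacency,
    graph_learning_loss,
    learn_fc_adjacency,
    scaled_laplacian,
)
from sleepgcn.synthetic import ring_montage

np.set_printoptions(precision=3, suppress=True)

# three nodes, two features: nodes 0 and 1 are similar, node 2 differs
X = np.array([[0.0, 0.1], [0.2, 0.0], [2.0, 2.5]])
learner = GraphLearner(w=np.array([1.0, 1.0]), lambda_reg=0.001)
A_fc = learn_fc_adjacency(X, learner)
print("learned functional-connectivity adjacency (row-stochastic):")
print(A_fc)
print("row sums:", A_fc.sum(axis=1))
print("graph-learning loss:", round(graph_learning_loss(X, A_fc, learner.lambda_reg), 4))
print("-> each row is a probability distribution over neighbours. With these "
      "untrained positive weights the most dissimilar pair gets the largest "
      "edge; the graph-learning loss charges every edge by the squared "
      "feature distance it spans, so minimising it during training drives w "
      "to shrink exactly those edges.\n")

montage = ring_montage(6)
A_dc = build_distance_adjacency(montage, sigma=1.0, threshold=0.1)
print("distance adjacency of a 6-electrode ring (Gaussian kernel, hollow):")
print(A_dc)

L_tilde = scaled_laplacian(A_dc)
eigs = np.linalg.eigvalsh(L_tilde)
print("scaled-Laplacian spectrum:", eigs)
print("-> the spectrum lies in [-1, 1], the domain of the Chebyshev filter.")
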