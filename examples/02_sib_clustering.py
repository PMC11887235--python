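"""Sequential information-bottleneck clustering on Gaussian feature blobs.

Draws four well-separated feature blobs, clusters them with the
draw-and-merge sweep maximizing L = I(T;Y) - I(T;X)/lambda, and contrasts
the recovered partition with a zero-separation null.  The objective trace
is non-decreasing by construction (each merge minimizes the merger cost).
"""

import numpy as np

from logstage import SibConfig, nmi, sib_cluster
from logstage.phantom import generate_feature_blobs

features, truth = generate_feature_blobs(n=200, d=16, k=4, separation=10.0, seed=7)
state = sib_cluster(features, SibConfig(k=4, lam=100.0, seed=0))

print(f"separated blobs (separation = 10 within-sd):")
print(f"  objective L = {state.objective:.4f} nats, "
      f"converged in {state.passes} pass(es)")
print(f"  cluster sizes: {state.cluster_sizes().tolist()}")
print(f"  NMI against ground truth: {nmi(state.assignment, truth):.3f} "
      "(1.0 = exact recovery up to relabeling)")
trace = np.array(state.objective_trace)
print(f"  objective trace: monotone non-decreasing = "
      f"{bool(np.all(np.diff(trace) >= -1e-12))}")

null_features, null_truth = generate_feature_blobs(n=500, d=16, k=4,
                                                   separation=0.0, seed=3)
null_state = sib_cluster(null_features, SibConfig(seed=1, restarts=2))
print(f"\nnull case (zero separation): NMI = "
      f"{nmi(null_state.assignment, null_truth):.3f} "
      "(near 0: no structure to find)")
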