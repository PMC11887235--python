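"""The staged phantom generator and its radial-profile oracle.

Generates labeled ring phantoms whose wall thickness and boundary
irregularity grow with stage (emulating depth of wall invasion), verifies
the 18/27/35/20% stage mix, and shows that the radial-profile oracle
recovers every stage exactly when noise is off -- the reference bar any
learned pipeline is compared against.
"""

import numpy as np

from logstage.phantom import (PhantomSpec, generate_phantoms, oracle_stage,
                              ring_thickness)

spec = PhantomSpec(n=100, seed=0, noise_sigma=0.0)
images, stages = generate_phantoms(spec)

counts = np.bincount(stages, minlength=5)[1:]
print(f"stage counts at n=100: {counts.tolist()} "
      "(largest-remainder rounding of 18/27/35/20%)")

print("\nmean measured wall thickness by stage (px):")
for s in (1, 2, 3, 4):
    ts = [ring_thickness(im) for im, st in zip(images, stages) if st == s]
    print(f"  T{s}: {np.mean(ts):5.2f} +/- {np.std(ts):4.2f}")
print("thickness increases monotonically with stage: the invasion-depth cue.")

acc = np.mean([oracle_stage(im) == s for im, s in zip(images, stages)])
print(f"\nradial-profile oracle accuracy at zero noise: {acc:.3f} "
      "(stages are exactly separable from geometry alone)")
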