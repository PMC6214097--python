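"""Built-in scoring objectives with known global minima.

Every search algorithm in the package optimizes a pluggable scoring function
(pose -> kcal/mol, with an evaluation counter).  Three toy objectives make the
engine testable without any external dataset.
"""
import numpy as np

from cuckoodock import (
    DockingBox,
    FixtureSpec,
    PoseVector,
    make_toy_complex,
    multifunnel_landscape,
    quadratic_landscape,
    toy_atomic_scorer,
)

box = DockingBox([0, 0, 0], [22.5, 22.5, 22.5])

# 1. convex quadratic bowl: sanity-checks any optimizer
optimum = PoseVector(box.center, [1, 0, 0, 0], np.zeros(2))
quad = quadratic_landscape(optimum, np.ones(9))
off = optimum.copy()
off.position = off.position + [1.0, 0.0, 0.0]
print(f"quadratic: E(optimum) = {quad.evaluate(optimum):.3f}, "
      f"E(optimum + 1 A in x) = {quad.evaluate(off):.3f} kcal/mol")

# 2. multifunnel landscape: several Gaussian wells, one strictly deepest —
#    the structure that causes premature convergence in docking searches
funnels = multifunnel_landscape(box, n_torsions=2, seed=7)
gm = funnels.global_minimum_pose
print(f"multifunnel: {len(funnels.centers)} funnels, depths "
      f"{np.round(funnels.depths, 1)}, E(deepest center) = "
      f"{funnels.evaluate(gm):.3f} kcal/mol")

# 3. toy atomic scorer: soft-core 12-6 wells between ligand atoms and receptor
#    probe points, constructed so a known native pose is the global minimum
complex_ = make_toy_complex(FixtureSpec(seed=42))
scorer = toy_atomic_scorer(complex_)
print(f"toy complex: native energy {scorer.evaluate(complex_.native_pose):.3f} "
      f"kcal/mol (declared {complex_.native_energy:.3f})")
print(f"evaluation counter after 3 calls: {scorer.n_evaluations + quad.n_evaluations}"
      f" total across scorers — every search is budgeted in these units")
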