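"""Concave and disjoint target volumes with the alpha hull.

Two well-separated color clusters cannot be described by one convex hull
without swallowing everything between them.  Limiting the facet edge
length (alpha) splits the hull into one component per cluster.
"""

import numpy as np

from hullseg import build_hull, contains, distance_to_surface

rng = np.random.default_rng(1)
cluster_a = rng.normal([40, -35, 25], 2.0, size=(12, 3))
cluster_b = rng.normal([55, 30, 10], 2.0, size=(12, 3))
points = np.vstack([cluster_a, cluster_b])

convex = build_hull(points, alpha=0.0)
alpha = build_hull(points, alpha=10.0)

midpoint = points.mean(axis=0)  # between the clusters
print(f"convex hull:  {convex.n_components} component, volume {convex.volume():8.1f}")
print(f"alpha hull:   {alpha.n_components} components, volume {alpha.volume():8.1f}")
print(f"midpoint inside convex hull: {contains(midpoint, convex)}")
print(f"midpoint inside alpha hull:  {contains(midpoint, alpha)}")
print(f"midpoint ΔE to alpha surface: {distance_to_surface(midpoint, alpha):.1f}")
# The convex hull classifies the gap between clusters as target; the
# alpha hull keeps two tight volumes and rejects the midpoint by ~30 ΔE.
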