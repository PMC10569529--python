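"""The normalized Ripley-K polarity statistic on synthetic patterns.

K is ~0 for spatially uniform molecules, rises with clustering, and its
maximum over distance is the scalar polarity score: >= 1.5 counts as
polarized and >= 3 as stable polarity in the 2D geometry (30/50 in 3D).
"""

import cdc42polarity as cp

plane = cp.Geometry.plane()
sphere = cp.Geometry.sphere()

for sigma in (None, 1.0, 0.5, 0.2, 0.05):
    if sigma is None:
        pts = cp.uniform_pattern(3000, plane, seed=1)
        label = "uniform"
    else:
        pts = cp.gaussian_cluster_pattern(3000, plane, sigma, seed=1)
        label = f"Gaussian cluster sigma={sigma}"
    k = cp.ripley_k(pts, plane).K
    print(f"2D {label:28s} K = {k:6.2f}  ({cp.classify_state(k, 'plane2d')})")

pts = cp.uniform_pattern(3000, sphere, seed=2)
print(f"3D uniform                       K = {cp.ripley_k(pts, sphere).K:6.2f}")
pts = cp.gaussian_cluster_pattern(3000, sphere, 0.2, seed=2)
k = cp.ripley_k(pts, sphere).K
print(f"3D cluster sigma=0.2             K = {k:6.2f}  ({cp.classify_state(k, 'sphere3d')})")
print()
print("Point-mass limits: 2D max K -> sqrt(A/pi) = 5.0; 3D max K -> 4*pi*R^2 = 78.5")
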