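"""Geometry identities and 2D -> 3D rate conversions.

The 2D model lives on a periodic square whose area equals the membrane
area of a 2.5-um-radius spherical cell; cytosol-coupled rates pick up the
volume-to-area factor V_c/A_m = R/3 when moving to 3D, and bimolecular
rates additionally trade the reaction disc (pi rho^2) for the half-sphere
reaction volume ((2/3) pi rho^3).
"""

import cdc42polarity as cp

sphere = cp.Geometry.sphere()
print(f"membrane area A_m = 4*pi*R^2      = {sphere.A_m:8.3f} um^2")
print(f"matching 2D square side sqrt(A_m) = {sphere.A_m ** 0.5:8.4f} um")
print(f"cytosolic volume V_c              = {sphere.V_c:8.3f} um^3")
print()
for sym, k2d in (("k_1a", 10.0), ("k_5a", 36.0)):
    k3d = cp.convert_rate_first_order_to_3d(k2d, sphere)
    print(f"{sym}: {k2d:6.1f} /s  (2D)  ->  {k3d:8.3f} um/s (3D surface association)")
for sym, l2d in (("lambda_7", 256.0), ("lambda_8a", 300.0), ("lambda_9", 0.025)):
    l3d = cp.convert_rate_second_order_to_3d(l2d, 0.05, sphere)
    print(f"{sym}: {l2d:6.3f} /s  (2D)  ->  {l3d:8.3f} /s   (3D, cytosolic partner)")
print()
for n in (3000, 170, 30):
    c = cp.molecules_to_concentration(n, sphere)
    print(f"{n:5d} molecules in the cytosolic volume = {c:6.2f} nM")
print()
print("1/k_10 = receptor membrane residence time "
      f"= {1 / 0.002 / 60:.2f} min (endocytic turnover)")
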