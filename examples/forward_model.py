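"""Forward photoselection model: from a tilt distribution to dichroic curves.

Builds a wrapped-Gaussian distribution of transition-dipole tilt angles
(mean tilt alpha0 from the membrane normal, width sigma), computes its
dichroic shape parameters, and prints the predicted log2 r(theta) curve for
one- and two-photon excitation.
"""

import numpy as np

import ldquant as lq

# DiI-like: TDM in the membrane plane (alpha0 = 90 deg), narrow spread
dist = lq.TiltDistribution.single(90.0, 10.0, geometry="membrane")

params = lq.shape_params(dist)
print(f"B1P = {params.b1p:+.4f}   B2P = {params.b2p:+.4f}   C2P = {params.c2p:+.4f}")
# B1P near -1 means almost fully polarized 1P absorption along the membrane.

thetas = np.array([0.0, 30.0, 45.0, 60.0, 90.0])
c1 = lq.predict_log2r(dist, thetas, "1p")
c2 = lq.predict_log2r(dist, thetas, "2p")
print("theta(deg)  log2r(1P)  log2r(2P)")
for t, a, b in zip(thetas, c1, c2):
    print(f"{t:9.0f} {a:+10.3f} {b:+10.3f}")
# log2 r peaks at theta = 0 (membrane tangent parallel to the horizontal
# polarization), vanishes at 45 deg, and flips sign at 90 deg — the
# antisymmetry of an offset-free dichroic curve.

# every closed form is checked against the brute-force Monte-Carlo oracle:
mc = lq.sample_orientations_mc(dist, 10**6, seed=1)
m = lq.compute_moments(dist)
print(f"\n<cos^2 a>: quadrature {m.m2:.5f}  MC {mc.m2:.5f} (+-{mc.se_m2:.5f})")
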