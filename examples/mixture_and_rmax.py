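"""Interpret measured LD parameters: mixtures and the r_max shortcut.

Two accessory analyses: (1) search pairs of wrapped-Gaussian components
matching measured (B1P, B2P, C2P) — e.g. a probe in two conformations; and
(2) list all (alpha0, sigma) combinations consistent with measured
log2(r_max) values alone.
"""

import ldquant as lq
from ldquant.orientation import default_lookup_table

# -- two-Gaussian mixture search -------------------------------------------
# targets computed from a true 50/50 mixture of in-plane and tilted dye
mix = lq.TiltDistribution.mixture((90.0, 10.0), (20.0, 10.0), 0.5)
targets = lq.shape_params(mix)
print(f"targets: B1P={targets.b1p:+.4f} B2P={targets.b2p:+.4f} C2P={targets.c2p:+.4f}")

cands = lq.mixture_search(targets, top_k=5)
print("top mixture candidates (alpha0/sigma + alpha0/sigma, fraction, residual):")
for c in cands:
    print(f"  ({c.alpha0_a:4.0f},{c.sigma_a:3.0f}) + ({c.alpha0_b:4.0f},{c.sigma_b:3.0f})"
          f"  f={c.fraction_a:.1f}  residual={c.residual:.2e}  "
          f"entropy={c.entropy_bits:.2f} bits")
# Several distinct pairs fit almost equally well — the inverse problem is
# degenerate, which is why candidates are ranked and the entropy of the
# implied tilt density breaks near-ties toward the least committed answer.

# -- orientation from r_max alone ------------------------------------------
table = default_lookup_table(5.0)
dist = lq.TiltDistribution.single(25.0, 25.0)
v1 = lq.predict_log2r(dist, [0.0], "1p")[0]
only_1p = lq.rmax_to_orientation(log2_rmax_1p=v1, table=table)
print(f"\nlog2(rmax) 1P = {v1:+.3f}: {len(only_1p.cells)} consistent cells (a band)")
from ldquant.quant import _signed_extremum  # noqa: E402

v2 = _signed_extremum(lambda t: lq.predict_log2r(dist, t, "2p"))
both = lq.rmax_to_orientation(log2_rmax_1p=v1, log2_rmax_2p=v2, table=table)
print(f"adding the 2P value {v2:+.3f}: {len(both.cells)} cells "
      f"{both.cells[:4]} ...")
# A single 1P r_max value traces a curve through the (alpha0, sigma) plane;
# combining it with the 2P value intersects two curves and nearly pins the
# distribution.
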