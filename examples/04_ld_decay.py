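"""Linkage disequilibrium: rare-band masking, permutation significance,
background LD and the logarithmic decay fit.

The pairwise step runs on simulated lines; the decay fit is then shown on
a constructed curve because the generator places markers without physical
linkage (decay on such data is rightly undetectable).
"""

import numpy as np

import lxthet as lx

cfg = lx.demo_config(seed=7)
marker_map, lines, _, _ = lx.simulate_parents(cfg)

masked = lx.mask_rare(lines, threshold=0.05)
pairs = lx.pairwise_ld(masked, marker_map, shuffles=1000, seed=1)
print(f"locus pairs: {len(pairs)} "
      f"({int(pairs['linked'].sum())} same-chromosome)")
print(f"mean r2: {pairs['r2'].mean():.4f}, "
      f"background (99th pct of unlinked r2): {lx.background_ld(pairs):.4f}")
print(f"pairs with permutation p < 0.05: {(pairs['p_perm'] < 0.05).sum()}")

# decay on an exact logarithmic curve: r2 = 0.9 - 0.1 ln(d_kb)
d_kb = np.geomspace(1, 2000, 25)
fit = lx.decay_fit_xy(d_kb, 0.9 - 0.1 * np.log(d_kb), threshold=0.2)
print(f"\ndecay fit: r2 = {fit.intercept:.3f} + {fit.slope:.3f} ln(d)")
print(f"decay distance at r2 = 0.2: {fit.decay_distance:.1f} kb "
      f"(analytic: {np.exp(7):.1f} kb)")
# The crossing distance solves intercept + slope * ln(d) = 0.2.
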