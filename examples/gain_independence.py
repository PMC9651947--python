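"""Visual x motor gain-independence test.

Simulates probe responses under the 2x2 design {visual saccade} x {walking}
with exactly multiplicative gains (visual 0.6, behavioral 0.7), and tests
whether the jointly measured gain equals the product of the marginal gains.
Deviation confidence intervals covering zero indicate independent,
multiplicatively combining gain mechanisms.
"""

import numpy as np

from glomcode import gain_analysis as ga
from glomcode import population_analysis as pa

rng = np.random.default_rng(0)
n, G = 50, 8
base = rng.uniform(0.8, 1.2, G)
values, vis, walk = [], [], []
for (v, w), (gv, gb) in {(0, 0): (1, 1), (1, 0): (0.6, 1),
                         (0, 1): (1, 0.7), (1, 1): (0.6, 0.7)}.items():
    values.append(base * gv * gb + rng.normal(0.0, 0.15, (n, G)))
    vis += [v] * n
    walk += [w] * n
amps = pa.AmplitudeMatrix(np.vstack(values), np.zeros(4 * n, dtype=int))
table = ga.build_gain_table(amps, np.array(vis), np.array(walk))
res = ga.independence_test(table, seed=1)

print("glomerulus  g_vis  g_beh  predicted  observed  deviation [95% CI]")
for g in range(G):
    print(f"  glom{g:02d}    {res['g_visual'][g]:5.2f}  {res['g_behavior'][g]:5.2f}"
          f"     {res['predicted'][g]:5.2f}     {res['observed'][g]:5.2f}"
          f"   {res['deviation'][g]:+5.2f} [{res['ci_low'][g]:+.2f}, {res['ci_high'][g]:+.2f}]")
print(f"\nCIs covering zero: {res['covers_zero'].sum()}/{G} "
      "(multiplicative combination, i.e. independent gain controls)")
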