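"""Stratify fitted force constants and fit their distance dependence.

Fits OFCs on a synthetic ensemble with frustrated second neighbors,
summarizes the per-contact-order statistics and the k=1/k=2 coupling,
then demonstrates the two standard distance-decay fits (Gaussian
A*exp(-d^2/r0^2) and inverse power A/d^alpha) on a magnitude-vs-
distance curve with a known exponent.
"""

import numpy as np
import pandas as pd

import ofcnet as oc

K_true, topo = oc.generate_network(oc.SyntheticNetworkSpec(n=40, seed=11))
samples = oc.sample_scalar_displacements(K_true, 2000, seed=12)
C = oc.empirical_scalar_covariance(samples)
K = oc.optimize_K(C, K_true.constraints)

mean = oc.MeanStructure(oc.ideal_helix_ensemble(40, m=2).model_coords[0])
table = oc.normalize_ofc(oc.force_constant_table(K, mean))

strat = oc.stratify(table, "k")
print("force constants by contact order (normalized units):")
for row in strat.table.itertuples():
    if row.group <= 3:
        print(f"  k={row.group}   mean={row.mean:+.3f}  sd={row.std:.3f}"
              f"  n={row.count}")
long_range = table[table.k > 3]["gamma"]
print(f"  k>3  mean={long_range.mean():+.3f}  sd={long_range.std():.3f}"
      f"  n={len(long_range)}")

cc12 = oc.inter_order_correlation(table, k=2, n=1)
print(f"\ncorr(gamma_k2, nested mean gamma_k1) = {cc12:+.3f}")
print("(near zero here: the generator draws k=1 and k=2 springs")
print(" independently; on real ensembles this statistic probes")
print(" compensation between nested interactions)")

# distance-decay fitting on a curve with a known inverse-square law
rng = np.random.default_rng(0)
d = np.linspace(4, 12, 25)
curve = pd.DataFrame({"d": d,
                      "mean_abs_gamma": 31.93 / d ** 2
                      + rng.normal(0, 0.02, d.size)})
fit_p = oc.fit_distance_dependence(curve, "power")
fit_g = oc.fit_distance_dependence(curve, "gaussian")
print(f"\ndistance-decay fits on a 1/d^2 curve:")
print(f"  power    alpha={fit_p.parameter:.3f}  cc={fit_p.correlation:.3f}")
print(f"  gaussian r0={fit_g.parameter:.3f} A  cc={fit_g.correlation:.3f}")
print()
print("Bonded (k=1) springs are strong and positive; second neighbors")
print("are weak or negative (local frustration). The power fit recovers")
print("the generating exponent alpha = 2.")
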