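"""Building a virtual BV+ patient population.

Latin Hypercube Sampling of resident-community gLV parameters, analytic
equilibrium-behavior labelling of every draw, and stratified resampling to
the clinically observed distribution of BV-capable equilibrium behaviors
(60% mono-stable nAB, 31% bi-stable nAB/Li, 9% bi-stable nAB/oLB).
"""

import numpy as np

import vmbsim as v

pool = v.generate_pool(n_pool=8_000, rng=1)
print("base pool equilibrium behaviors (8,000 LHS draws):")
for label, frac in sorted(pool.label_frequencies().items(), key=lambda kv: -kv[1]):
    print(f"  {label:20s} {frac:6.1%}")

pop = v.resample_population(pool, n=500, rng=2)
print("\nresampled BV+ population (n=500), HMP-matched strata:")
for label, frac in pop.label_frequencies().items():
    print(f"  {label:20s} {frac:6.1%}")

nab0 = pop.initial[:, 0]
print(f"\nbaseline nAB abundance across patients: median {np.median(nab0):.1f}, "
      f"IQR [{np.percentile(nab0, 25):.1f}, {np.percentile(nab0, 75):.1f}] density units")
print("every patient starts at a stable nAB-dominant state (BV positive), with")
print("subdominant residents seeded at a 1% detection-limit floor.")
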