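"""Stochastic resonance: signal transmission versus noise level.

A period-50 square wave is clamped at a seeder node and every other node's
activity is scored against it with the spectral similarity measure
(negative log of the amplitude-weighted residual after an optimal
rescaling of the output spectrum).  Near a critical threshold, an
intermediate noise level transmits the signal best.
"""

import numpy as np

from srnet import GeneratorConfig, generate_random_connectome
from srnet.similarity import sr_curve

net = generate_random_connectome(GeneratorConfig(seed=1))
rng = np.random.default_rng(0)
seeders = sorted(rng.choice(net.n_nodes, 10, replace=False).tolist())

# T = 5.2 is near this network's critical threshold at p_ee = 0.1
grid = [0.05, 0.15, 0.25, 0.35, 0.45, 0.7, 0.95]
res = sr_curve(net, p_ee=0.1, threshold=5.2, pqe_grid=grid, rng=rng,
               seeders=seeders, n_realizations=2, steps=5000)

print("p_qe   mean sim   median sim")
for _, row in res.table.iterrows():
    print(f"{row.p_qe:<6} {row.mean_sim:8.3f} {row.median_sim:10.3f}")
print(f"\nmean-similarity peak at p_qe = {res.peak_mean}")
print("Both very quiet (0.05) and saturated (0.95) systems transmit poorly;")
print("the peak sits at the intermediate noise that tips the network's")
print("collective dynamics - the stochastic-resonance effect.")
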