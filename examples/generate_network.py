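"""Generate a synthetic weighted connectome and inspect its statistics.

The generator draws node degrees from Normal(20.92, 7.01), wires them with
a configuration model, and gives each edge a Normal(0.5, 0.12) weight
(redrawn until positive).  These moments emulate a 114-region cortical
connectome while randomizing all topology beyond them.
"""

import numpy as np

from srnet import GeneratorConfig, generate_random_connectome, save_connectome

cfg = GeneratorConfig(seed=1)
net = generate_random_connectome(cfg)

upper = net.weights[np.triu_indices_from(net.weights, k=1)]
print(f"nodes:                {net.n_nodes}")
print(f"edges:                {np.count_nonzero(upper)}")
print(f"mean degree:          {net.degrees.mean():.2f}  (target 20.92)")
print(f"degree SD:            {net.degrees.std():.2f}  (target 7.01)")
print(f"mean edge weight:     {upper[upper > 0].mean():.3f}  (target 0.5)")
print(f"mean node strength:   {net.strengths.mean():.2f}")
print(f"connected components: {net.n_components()}")

save_connectome(net, "scratch_network.csv")
print("\nwrote scratch_network.csv (delimited text, label header row)")
print("Degrees and weights match their Gaussian targets; strength ~ degree x mean weight.")
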