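# srnet — stochastic resonance and criticality on weighted connectomes

`srnet` simulates a noisy excitable Boolean network on weighted, symmetric
connectivity matrices (connectomes) and quantifies how well a weak periodic
signal travels through it.  It is aimed at computational neuroscientists and
complex-systems researchers studying the interplay between **stochastic
resonance** — noise enhancing signal transmission — and **criticality** in
brain-like network models.

The package provides four building blocks:

* **synthetic connectomes** — a Gaussian random-network generator
  (configuration-model wiring with prescribed degree and weight
  distributions) plus delimited-text I/O for real weight matrices;
* **dynamics** — a fast vectorized simulator of the two-state excitable
  model, with optional square-wave signal injection at a "seeder" node;
* **spectral similarity** — a Fourier-amplitude measure of how closely each
  node's activity tracks the injected signal, assembled into seeder ×
  receiver similarity matrices and stochastic-resonance curves;
* **phase space** — activity distributions, Gaussian-mixture bimodality
  detection, coexistence curves and critical-point location.

## The model

Each of the *N* nodes carries a binary state *s<sub>i</sub>(t)* ∈ {0, 1}
(quiescent/excited), updated synchronously.  With weighted input
*α<sub>i</sub> = Σ<sub>j</sub> w<sub>ij</sub> s<sub>j</sub>(t)*:

* *Q → E* with probability *P<sub>QE</sub>* (spontaneous, the **noise**), or
  deterministically when *α<sub>i</sub> ≥ T*;
* *E → E* with probability *P<sub>EE</sub>* provided the node is still
  stimulated (spontaneously or by *α<sub>i</sub> ≥ T*);
* *E → Q* otherwise.  There is no refractory state.

The order parameter is the time-averaged density of active nodes
⟨S⟩ = (1/L) Σ<sub>t</sub> S(t), with S(t) = (1/N) Σ<sub>i</sub> s<sub>i</sub>(t).

Signal transmission is scored in the frequency domain.  For input spectrum
φ<sup>i</sup> and output spectrum φ<sup>j</sup> over the input's *M*
principal frequencies,

    λᵢⱼ = Σₘ (φⁱₘ)² φʲₘ / Σₘ (φʲₘ)² φⁱₘ
    sim(i,j) = −log( Σₙ (φⁱₙ − λᵢⱼ φʲₙ)² φⁱₙ / Σₘ (φⁱₘ)³ )

so a rescaled copy of the input scores maximally and an output carrying
none of the input's principal frequencies scores zero.

## Worked example

```python
import numpy as np
from srnet import GeneratorConfig, generate_random_connectome
from srnet.similarity import sr_curve

net = generate_random_connectome(GeneratorConfig(seed=1))   # N=114 control
rng = np.random.default_rng(0)
seeders = sorted(rng.choice(net.n_nodes, 10, replace=False).tolist())
res = sr_curve(net, p_ee=0.1, threshold=5.2,
               pqe_grid=[0.05, 0.15, 0.25, 0.35, 0.45, 0.7, 0.95],
               rng=rng, seeders=seeders, n_realizations=2, steps=5000)
print(res.table)
print("peak:", res.peak_mean)
```

prints (`examples/sr_scan.py`):

```
p_qe   mean sim   median sim
0.05      0.780      0.730
0.15      0.693      0.656
0.25      0.652      0.592
0.35      1.459      1.300
0.45      0.633      0.463
0.7       0.262      0.191
0.95      0.128      0.098

mean-similarity peak at p_qe = 0.35
```

At the near-critical threshold *T* = 5.2, similarity peaks at the
intermediate noise level *P<sub>QE</sub>* ≈ 0.35 — the stochastic-resonance
effect — and that same noise level is where the signal-free phase analysis
places the critical point (`examples/phase_portrait.py` prints
`T_c = 5.06, p_qe_c = 0.325` with skewness −0.011, negative excess
kurtosis and maximal fluctuations).  Quiet (0.05) and saturated (0.95)
systems both transmit poorly.

The other example scripts cover network generation
(`examples/generate_network.py`), the discontinuous low/high activity
transition (`examples/simulate_dynamics.py`) and the coexistence curve
(`examples/phase_portrait.py`).

A thin CLI mirrors the library:
`srnet generate-network`, `srnet simulate`, `srnet sr-scan`,
`srnet phase-scan`, `srnet critical-point`, `srnet compare-criticality`
(see `--help` on each).

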