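# Methods

## Model and assumptions

The dynamics is a two-state (quiescent/excited) excitable cellular
automaton on a weighted, symmetric, non-negative adjacency matrix with zero
diagonal.  All nodes are updated synchronously from a frozen copy of the
previous state.  Per node and step, two independent uniforms r₁, r₂ ∈ [0, 1)
are drawn; with weighted input αᵢ = Σⱼ wᵢⱼ sⱼ(t):

* stimulation factor B = 1 iff r₁ < P_QE or αᵢ ≥ T;
* persistence factor A = 1 if sᵢ = 0, else A = 1 iff r₂ < P_EE;
* sᵢ(t+1) = A·B.

The strict comparison `r < p` is probabilistically identical to a
threshold step function on uniform draws but makes the two edge cases
exact: P_QE = 0 never fires spontaneously (the all-quiescent state is
absorbing) and P_QE = 1 always fires.  Nodes represent whole regions
containing many excitable units, so there is no refractory state.
Runs start from the all-quiescent state and discard a transient
(default 1,000 steps) before recording.

Signal injection clamps one node (the seeder) to a square wave — excited
for period/2 steps, quiescent for period/2, default period 50 — at every
step, transient included.  The clamp overrides the seeder's own update but
the seeder still drives its neighbours.  We chose full clamping over
letting the seeder run free during its quiescent half-period: the input is
then exactly the intended signal, and the input spectrum is identical for
every seeder.

## Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| P_QE | spontaneous activation probability (noise) | per step | scanned |
| P_EE | persistence probability of a stimulated excited node | per step | 0.1 |
| T | activation threshold on the weighted input αᵢ | summed edge weight | scanned |
| transient | discarded equilibration steps | steps | 1,000 |
| steps | recorded steps | steps | 10,000 (phase), 5,000 (similarity) |
| period | square-wave signal period | steps | 50 |

Run lengths are the package's defaults for desk-scale work: 5,000 steps
resolve ≥ 100 cycles of the period-50 signal, and 10,000 steps give
distribution moments with kurtosis standard error ≈ 0.05 per pooled
three-run scan point.

## Synthetic connectome generator

Degrees are drawn from Normal(20.92, 7.01), rounded to integers, clipped
to [1, N−1] and parity-adjusted by incrementing one uniformly chosen
node when the stub count is odd.  The graph is wired by configuration-model
stub pairing; self-loops and duplicate edges are repaired by
degree-preserving endpoint swaps (bounded retries, explicit failure with a
diagnostic if the sequence cannot be realized).  The degree sequence is
therefore realized *exactly*.  Each realized edge receives an independent
Normal(0.5, 0.12) weight, redrawn until positive — truncation rather than
clipping, because a zero weight would delete the edge and distort the
degree sequence.  Connectedness is not enforced; the component count is
reported (at the default parameters the network is almost always a single
component).

What the generator emulates — and what it does not: it reproduces the
degree and weight *moments* of a cortical connectome while randomizing all
other structure.  Real connectomes carry hub topology, hemispheric
organization, weight–degree correlations and spatial embedding that the
configuration model destroys.  Phase boundaries and critical points of
threshold dynamics depend on this finer structure, not only on the two
matched moments, so parameter values quoted for one construction (for
example, the threshold at which a particular network is critical) need not
transfer to another with identical moments.  Passing tests on the
synthetic control therefore validate the machinery and the qualitative
phenomena, not the quantitative phase diagram of any empirical network.

## Spectral similarity

Spectra are one-sided amplitude spectra |DFT|/L of the mean-removed
series; the zero-frequency bin is excluded.  Removing the mean keeps the
binary series' DC offset — which carries no information at the signal
frequencies — out of the amplitude ranking.  Normalizing by the length L
makes the principal-frequency threshold (amplitude > 10⁻⁴) independent of
run length; users rescaling the threshold should account for this
convention.  Input and output series come from the same recorded window,
so their frequency grids match exactly and no interpolation is needed.

The rescaling factor λᵢⱼ is the closed-form minimizer of the
input-amplitude-weighted squared spectral difference; similarity is the
negative natural log (the base affects only a global scale) of the
normalized weighted residual, summed over the input's principal
frequencies.  Numerical choices:

* residual floor 10⁻¹², capping sim at −log 10⁻¹² ≈ 27.6 when a rescaled
  output matches the input exactly;
* an output spectrum that vanishes on every principal bin has no defined
  λ; λ = 0 is used, giving the minimal similarity (exactly 0) for that
  input;
* an input with no principal frequencies (a constant series) makes the
  measure undefined; entries are reported as missing (NaN).

A useful reference value: an output with a *flat* spectrum across the
input's principal bins (structureless noise) scores ≈ 0.76 against a
period-50 square-wave input — the measure's noise floor, not evidence of
transmission.  Similarity matrices average sim values (not spectra) over
independent realizations (default 5; scans in the examples and acceptance
runs use 3).  Deaf nodes are receivers whose column-mean similarity falls
strictly below a configurable quantile (default 15%) of all column means;
an exactly uniform matrix therefore flags nothing.

## Phase-space analysis

Distributions are over the integer count of active nodes (unit bins avoid
bin-width choices); reported means and SDs are converted to densities.
One- and two-component Gaussian mixtures are fitted by EM
(`sklearn.mixture.GaussianMixture`).  A fit is bimodal when
|μ₂ − μ₁| > max(σ₁ + σ₂, 3 counts) and both weights ≥ 0.1.  The σ-based
separation is the usual "distinct modes" rule; the 3-count floor prevents
the discrete spike at zero counts of a near-silent phase from posing as a
second macroscopic mode (genuine phase gaps here are ~25–30 counts).

The integrated autocorrelation time is 1 + 2 Σₖ ρ(k), summed to the first
non-positive ρ(k) (initial-positive-sequence cutoff), computed by FFT.  A
series whose ACF never decays (e.g. perfectly periodic) is flagged
non-mixing.

**Coexistence points.** The bimodal window in P_QE is narrow, so the
equal-height search first locates the low/high transition with a cheap
single-run order-parameter sweep, then scans ±0.05 around the jump at
0.005 resolution, and finally bisects on the sign of the mode-peak-height
difference (component height w/(σ√2π)) until the relative difference is
within 5%.  Exact equality is a measure-zero event in stochastic
estimates, hence the tolerance; setting it to zero is documented as
impractical.  Three realizations are pooled per evaluation; pooling also
covers runs that fail to switch phases within one run length.

**Critical points.** For fixed P_EE, the critical threshold is the largest
T at which bimodality still occurs (bisection over T, tolerance 0.05).
The noise level is then scanned at 0.005 resolution (refined to 0.001
around the best point): the critical point has skewness closest to zero,
negative excess kurtosis, the largest autocorrelation time and maximal SD
of S(t).  Two robustness choices:

* "negative kurtosis" is enforced as excess kurtosis below −3 standard
  errors of the sample-kurtosis estimator (SE = √(24/n)), because a point
  estimate of −0.01 on a flat off-transition distribution is zero within
  noise, and treating it as "negative" lets the skewness criterion select
  arbitrary off-transition points;
* when the criteria disagree (their argmax/argmin fall on different scan
  points, which happens away from a genuine critical point and, within a
  grid step or two, from estimator noise at one), the best-skewness point
  among the kurtosis-eligible ones is returned and a diagnostic warning
  names the conflicting criteria.

At a genuine critical point the four criteria align to within one or two
grid steps; deep inside the coexistence region they *cannot* align —
skewness sweeps steeply through zero at the equal-occupancy point while
flat single-phase points nearby have near-zero skewness — and the
selection then lands on the switching point, where fluctuations and
autocorrelation peak.

## Pipeline

Experiments are described by a validated config (YAML/JSON or Python),
echoed into a JSON manifest together with a SHA-256 hash of the weight
matrix, the master seed and per-stage wall times.  All randomness flows
from the master seed through a single generator, so identical config +
seed reproduce identical numeric outputs (manifests differ only in wall
times).  The criticality comparison refuses parameter settings whose
signal-free activity is bimodal: a system jumping between phases during a
run produces spurious input/output interdependence.

## Known limitations

* The critical surface measured on the moment-matched random control is a
  property of that construction; networks with the same degree/weight
  moments but different higher-order structure place their coexistence
  region and critical points at different (T, P_QE) — see the generator
  section.  At thresholds deep inside the coexistence region there is no
  interior stochastic-resonance peak: the similarity scan is then
  dominated by the structureless-output floor at low noise.
* Similarity is measured against a clean clamped square wave only;
  mutual-information or correlation-based measures are out of scope.
* The equal-height and critical-point searches assume a single
  low-to-high transition in the scanned bracket.
* Estimates at the default desk-scale run lengths carry sampling noise of
  roughly one 0.005 grid step in located noise levels; halving it costs
  ~4× the runtime.
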