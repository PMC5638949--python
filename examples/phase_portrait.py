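"""Coexistence curve and critical point of the signal-free dynamics.

For fixed p_ee, each threshold T inside the coexistence region has a noise
level at which the low- and high-activity phases are equally likely (the
two modes of the activity PDF have equal peak heights).  As T grows the
modes approach and merge; the merge point - skewness near zero, negative
excess kurtosis, maximal autocorrelation time and maximal SD of S(t) - is
the critical point.
"""

import warnings

from srnet import GeneratorConfig, generate_random_connectome
from srnet.phase import coexistence_curve, find_critical_point

net = generate_random_connectome(GeneratorConfig(seed=1))

print("coexistence curve at p_ee = 0.1:")
print("T      p_qe(balance)  low <S>  high <S>   gap")
pts = coexistence_curve(net, 0.1, [4.4, 4.7, 5.0], rng=3,
                        n_realizations=3, steps=8000)
for p in pts:
    gap = p.high_mean - p.low_mean
    print(f"{p.threshold:<6} {p.p_qe:<14.3f} {p.low_mean:<8.3f} {p.high_mean:<10.3f} {gap:.3f}")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    cp = find_critical_point(net, 0.1, T_bracket=(4.4, 5.8), pqe_resolution=0.005,
                             rng=4, n_realizations=3, steps=8000)
d = cp.diagnostics
print(f"\ncritical point: T_c = {cp.threshold:.2f}, p_qe_c = {cp.p_qe:.3f}")
print(f"  skewness {d.skewness:+.3f}, excess kurtosis {d.excess_kurtosis:+.2f}, "
      f"autocorr time {d.autocorr_time:.0f} steps, SD(S) {d.sd_activity:.3f}")
print("\nThe mode gap shrinks as T rises; at the critical threshold the two")
print("activity levels merge into one broad, flat-topped, slowly mixing")
print("distribution - the fingerprint of criticality.")
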