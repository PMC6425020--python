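"""Group inference: cluster-corrected significance and bootstrap latencies.

Builds a synthetic group of subject time courses with a known effect window
(100-200 ms), runs the cluster-based sign-permutation test, and estimates
onset and peak latencies with subject bootstrap.  Shows how the cluster
length criterion suppresses isolated noise excursions while the injected
window is recovered, and how the bootstrap CI quantifies onset uncertainty.
"""

import numpy as np

from megrsa import GroupTimecourse, bootstrap_latencies, cluster_sign_permutation

rng = np.random.default_rng(3)
n_subjects, n_tp = 14, 100
times = -100.0 + 5.0 * np.arange(n_tp)

signal = np.zeros(n_tp)
window = (times >= 100.0) & (times <= 200.0)
signal[window] = 0.08                       # effect size in correlation units
data = signal + 0.05 * rng.standard_normal((n_subjects, n_tp))
tc = GroupTimecourse(data, times, chance_level=0.0, name="demo")

result = cluster_sign_permutation(tc, n_permutations=1000, seed=0)
print(f"cluster length threshold: {result.cluster_length_threshold} timepoints")
for c in result.clusters:
    print(f"significant cluster: {c['start_ms']:.0f}-{c['end_ms']:.0f} ms "
          f"(p = {c['p_value']:.3f})")

post = times >= 0.0
est = bootstrap_latencies(
    GroupTimecourse(data[:, post], times[post], 0.0),
    n_bootstrap=500, n_permutations=500, peak_window=(80.0, 250.0), seed=1,
)
print(f"onset: {est.onset_ms:.0f} ms, 95% CI [{est.onset_ci[0]:.0f}, {est.onset_ci[1]:.0f}] ms")
print(f"peak:  {est.peak_ms:.0f} ms, 95% CI [{est.peak_ci[0]:.0f}, {est.peak_ci[1]:.0f}] ms")
print("\nThe injected effect spans 100-200 ms; the detected onset lies at or "
      "shortly after 100 ms and isolated noise excursions form no clusters.")
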