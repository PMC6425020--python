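"""Behavioral similarity, noise ceiling, and commonality analysis.

Simulates multi-arrangement behavior for several subjects whose perceived
similarity mixes the gender, age and identity models, computes behavioral
RDMs from squared on-screen distances, estimates the group noise ceiling,
and partitions the variance a (synthetic) neural RDM shares with behavior
into per-model commonality coefficients.  Also summarizes a synthetic
1-back trial log (d', response times, familiarity effect).
"""

import numpy as np

from megrsa import DesignSpec, make_model_rdm, noise_ceiling
from megrsa.behavior import behavioral_performance, behavioral_rdm, commonality_analysis
from megrsa.core import RDMSeries, square_from_lower_triangle
from megrsa.synthetic_data import condition_table, generate_behavioral_positions, generate_trial_log

design = DesignSpec(n_identities=8, images_per_identity=2)
conditions = condition_table(design)
weights = {"gender": 1.0, "age": 0.6, "identity": 0.3}

subject_rdms = []
for s in range(8):
    pos = generate_behavioral_positions(design, weights, noise_sd=0.08, seed=s)
    subject_rdms.append(behavioral_rdm(pos))
lower, upper = noise_ceiling([r.vector() for r in subject_rdms])
print(f"behavioral noise ceiling over 8 subjects: [{lower:.3f}, {upper:.3f}]")

# synthetic neural RDM sharing the same mixture (plus noise) at one time point
rng = np.random.default_rng(99)
models = {f: make_model_rdm(conditions, f) for f in ("gender", "age", "identity")}
neural_vec = sum(w * models[f].vector() for f, w in weights.items())
neural_vec = neural_vec + 0.15 * rng.standard_normal(neural_vec.size)
rdms = RDMSeries(
    square_from_lower_triangle(neural_vec[None], conditions.n_conditions),
    np.array([120.0]), conditions.condition_ids,
)
out = commonality_analysis(rdms, subject_rdms[0], models)
print(f"total neural-behavior shared variance (r^2): {out.reference[0]:.3f}")
for name, coef in out.coefficients.items():
    print(f"  commonality({name}): {coef[0]:+.3f}")
print(
    "Gender explains the most shared variance, then age, as injected.  The\n"
    "identity coefficient is near zero: a 2-D arrangement cannot express the\n"
    "high-dimensional identity structure, so behavior carries little unique\n"
    "identity variance to share."
)

log = generate_trial_log(design, n_subjects=10, seed=5)
perf = behavioral_performance(log)
print(f"\n1-back performance: d' = {perf.dprime_mean:.2f} +/- {perf.dprime_sem:.2f}, "
      f"RT = {perf.rt_mean:.0f} +/- {perf.rt_sem:.0f} ms")
print(f"familiar vs unfamiliar RT: {perf.rt_familiar_ms.mean():.0f} vs "
      f"{perf.rt_unfamiliar_ms.mean():.0f} ms (signed-rank p = {perf.p_rt_familiarity:.3f})")
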