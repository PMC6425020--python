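"""Time-resolved representational similarity analysis with confound control.

Builds binary model RDMs for gender, age, identity and familiarity from the
condition table, then correlates each with the decoding RDMs over time using
partial Spearman correlation, partialling out the competing models.  Because
the category models overlap (every between-gender pair is also a
between-identity pair), the partial correlation is what isolates each
dimension's unique representational signature.
"""

import numpy as np

from megrsa import DecodingConfig, DesignSpec, EffectSpec, build_rdm_series, make_model_rdm, rsa_timecourse
from megrsa.preprocess import preprocess_epochs
from megrsa.synthetic_data import condition_table, generate_subject_epochs

design = DesignSpec(
    n_identities=8, images_per_identity=3, n_trials_per_condition=28,
    n_channels=40, tmin_ms=-200.0, tmax_ms=300.0, tstep_ms=10.0,
)
effects = EffectSpec(seed=0)
del effects.components["familiarity"]

epochs = generate_subject_epochs(design, effects, subject_index=0)
components = preprocess_epochs(epochs)
conditions = condition_table(design)
rdms = build_rdm_series(
    components, conditions, DecodingConfig(n_repetitions=5, seed=1),
    window=(-100.0, 300.0),
)

models = {f: make_model_rdm(conditions, f) for f in ("gender", "age", "identity", "familiarity")}
print("model RDM sizes:", {k: m.values.shape for k, m in models.items()})

rho = {}
for name, target in models.items():
    covariates = [m for key, m in models.items() if key != name]
    rho[name] = rsa_timecourse(rdms, target, covariates)

header = "time (ms)  " + "  ".join(f"{m:>10}" for m in rho)
print("\npartial Spearman rho (one subject)")
print(header)
for i, t in enumerate(rdms.times[::3]):
    row = "  ".join(f"{rho[m][3 * i]:+10.3f}" for m in rho)
    print(f"  {t:6.0f}   {row}")
print(
    "\nInjected onsets are age 60 ms < gender 72 ms < identity 91 ms: each "
    "rho fluctuates around 0 before its component's onset and rises after it."
)
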