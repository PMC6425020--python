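"""Simulate one subject's epochs and build the decoding RDM time series.

Generates a small factorial face-study design (16 conditions: 8 identities
x 2 images, crossing gender, age and familiarity), injects the default
signal components, preprocesses the epochs (baseline, 30 Hz low-pass, PCA)
and runs time-resolved pairwise SVM decoding.  Prints the image-decoding
time course: the mean cross-validated accuracy over all condition pairs,
which should rise from chance (50%) after the earliest component onset
(46 ms) and peak near 100 ms.
"""

import numpy as np

from megrsa import DecodingConfig, DesignSpec, EffectSpec, build_rdm_series, image_decoding_timecourse
from megrsa.preprocess import preprocess_epochs
from megrsa.synthetic_data import condition_table, generate_subject_epochs

design = DesignSpec(
    n_identities=8, images_per_identity=2, n_trials_per_condition=28,
    n_channels=40, tmin_ms=-200.0, tmax_ms=300.0, tstep_ms=10.0,
)
effects = EffectSpec(seed=0)
del effects.components["familiarity"]          # peaks beyond this short epoch

epochs = generate_subject_epochs(design, effects, subject_index=0)
print(f"epochs: {epochs.n_trials} trials x {epochs.n_channels} channels x "
      f"{epochs.n_timepoints} timepoints")

components = preprocess_epochs(epochs)
print(f"PCA kept {components.n_components} components "
      f"({100 * components.explained_variance_fraction.sum():.2f}% variance)")

conditions = condition_table(design)
rdms = build_rdm_series(
    components, conditions, DecodingConfig(n_repetitions=10, seed=1),
    window=(-100.0, 300.0),
)
timecourse = image_decoding_timecourse(rdms)
print("\ntime (ms)  image decoding (%)")
for t, acc in zip(rdms.times[::2], timecourse[::2]):
    bar = "#" * int(max(0.0, acc - 0.5) * 100)
    print(f"  {t:6.0f}   {100 * acc:5.1f}  {bar}")
print("\nValues near 50% before ~46 ms are chance; the rise afterwards is the "
      "injected image signal becoming linearly decodable.")
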