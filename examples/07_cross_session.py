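"""Cross-session robustness check.

Three synthetic sessions share generative parameters except for a +/-10 %
per-session amplitude jitter (electrode/impedance drift between days).
Training on session S1 and testing on S2 and S3 probes how well the
classifier survives that drift; accuracies should stay close to the
within-session figure.
"""

import numpy as np

from emgtune import (
    FilterSpec,
    SyntheticSpec,
    apply_preprocessing,
    cross_session_eval,
    evaluate,
    extract_feature_matrix,
    generate_records,
    temporal_split,
    train_classifier,
)

spec = SyntheticSpec(task_duration_s=10.0, session_jitter=0.1, seed=0)
records = generate_records(spec, sessions=["S1", "S2", "S3"])
clean = [apply_preprocessing(r, FilterSpec(fs=spec.fs)) for r in records]
features = extract_feature_matrix(clean)

s1 = features.take(np.flatnonzero(features.session == "S1"))
tr, te = temporal_split(s1, 0.7)
within = evaluate(train_classifier("ET", {}, tr, seed=0), te)
print(f"within-session (S1 70/30): {100 * within.accuracy:.2f} %")

for sid, rep in cross_session_eval(features, "S1", ["S2", "S3"], seed=0):
    print(f"train S1 -> test {sid}: {100 * rep.accuracy:.2f} %")
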