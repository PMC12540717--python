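"""Tune the Extra-Trees hyperparameters with L-SHADE.

The objective is 3-fold contiguous-block cross-validation accuracy inside
the training split (the held-out 30 % is never touched during tuning).
The search space is the five classifier dimensions: n_estimators [10,100],
criterion {gini, entropy}, min_samples_split [2,30], max_features [2,34],
max_depth [1,25].  A short 6 s-per-task world keeps the demo quick.
"""

from emgtune import (
    FilterSpec,
    LShadeConfig,
    SyntheticSpec,
    apply_preprocessing,
    evaluate,
    extract_feature_matrix,
    generate_records,
    temporal_split,
    train_classifier,
    tune,
)

spec = SyntheticSpec(task_duration_s=6.0, seed=3)
records = generate_records(spec)
clean = [apply_preprocessing(r, FilterSpec(fs=spec.fs)) for r in records]
train, test = temporal_split(extract_feature_matrix(clean), 0.7)

base = evaluate(train_classifier("ET", {}, train, seed=0), test)
print(f"default hyperparameters: {100 * base.accuracy:.2f} % test accuracy")

cfg = LShadeConfig(np_init=10, np_min=4, max_generations=8, seed=0)
best_hp, history = tune(train, "ET", None, cfg)
tuned = evaluate(train_classifier("ET", best_hp, train, seed=0), test)
print(f"tuned ({len(history)} objective evaluations): "
      f"{100 * tuned.accuracy:.2f} % test accuracy")
print(f"best hyperparameters: {best_hp}")
# At small budgets tuning should at worst match the default configuration;
# larger budgets (np_init 20, 20 generations) add roughly a point.
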