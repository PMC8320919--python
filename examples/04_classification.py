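"""End-to-end: synthesise tiles, extract 38 features, classify one-vs-all.

Builds a small balanced dataset, extracts the full descriptor per tile,
and evaluates one-vs-all logistic regression under both protocols: a
stratified 70/30 holdout and repeated 5-fold cross-validation.
"""

from her2feat import (
    evaluate,
    extract_from_tiles,
    generate_tiles,
    holdout_split,
    repeated_cv,
    train_ova,
)

tiles, labels, _ = generate_tiles(n_per_class=30, seed=1)
features = extract_from_tiles(tiles, labels)
print(f"feature table: {len(features)} tiles x "
      f"{features.shape[1] - 2} features")

train, test = holdout_split(features, train_frac=0.70, seed=0)
report = evaluate(train_ova(train, learner="logreg"), test)
print(f"\nholdout (70/30) accuracy: {report.accuracy:.3f}")
print("confusion matrix (rows = actual, columns = predicted):")
print(report.confusion_frame().to_string())

cv = repeated_cv(features, learner="logreg", folds=5, repeats=5, seed=1)
print(f"\n5-fold CV x 5 repeats: mean accuracy {cv.accuracy_mean:.3f}, "
      f"std {cv.accuracy_std:.3f}")
print("\nHigh accuracy here shows the 38 features separate the synthetic")
print("classes; per-class recall pinpoints which adjacent scores confuse.")
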