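"""Cross-validated classification of synthetic sequence classes.

Five classes of order-1 Markov sequences stand in for taxa with distinct
composition; logistic regression on the 3 * 2**k grouped k-mer features
recovers the class labels, and accuracy improves with k.
"""

from pcmer import (
    ClassifierSpec,
    build_feature_matrix,
    cross_validate,
    generate_class_dataset,
    random_class_models,
)

models = random_class_models(n_classes=5, seed=7)
dataset = generate_class_dataset(models, n_per_class=50, length=400, seed=8)
print(f"{len(dataset)} sequences, classes: {dataset.classes}\n")

spec = ClassifierSpec("logistic_regression")
for k in (3, 6, 8):
    X, y = build_feature_matrix(dataset, k)
    report = cross_validate(X, y, spec, n_folds=10, seed=9)
    m = report.mean_metrics
    print(f"k={k}: features={X.shape[1]:4d}  accuracy={m['accuracy']:.3f}  "
          f"macro-F1={m['f1_macro']:.3f}")

print("\nEach row is a 10-fold stratified CV mean. These classes are well")
print("separated, so accuracy is perfect at every k; on harder data larger")
print("k resolves longer composition patterns and accuracy climbs with it,")
print("while the feature count stays 3*2^k, far below 4^k raw k-mer counts.")
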