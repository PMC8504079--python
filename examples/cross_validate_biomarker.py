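"""Five-fold cross-validated CNN classification of a binary biomarker.

Simulates a cohort with a planted binary effect (a Ki67-like label),
renders 32x32 image objects and evaluates the two-branch 2D CNN with
stratified five-fold cross-validation.  Held-out predictions are pooled
across folds before the metrics are computed.  Expect accuracy and AUC
well above chance (the planted effect is strong); on a permuted-label
cohort the same pipeline sits at ~0.5.
"""

import aiocnn as ac

cohort = ac.simulate_cohort(
    ac.SyntheticConfig(n_samples=200, n_genes=1024, n_blocks=32, seed=2)
)
order = ac.shared_gene_order(
    cohort.annotation, [cohort.expression.gene_ids], 1024
)
scaled, _ = ac.rescale_per_gene(ac.log2_transform(cohort.expression), order)
pmap = ac.make_pixel_map(order, ac.AIOConfig(32, 32, 1))
aios = ac.build_aios(scaled, pmap)
y = cohort.labels["ki67"].to_numpy(dtype=int)
print(f"{len(y)} samples, class balance {y.mean():.2f}")

spec = ac.default_model_spec("2d", input_shape=(1, 32, 32), n_classes=2)
report = ac.cross_validate(
    aios, y,
    builder=lambda seed: ac.build_2d_classifier(spec, seed),
    cfg=ac.TrainConfig(epochs=15, seed=0),
    k=5, seed=0,
)

print("\npooled held-out metrics (all 200 samples predicted exactly once):")
for name in ("accuracy", "auc", "precision", "recall", "f1"):
    print(f"  {name:9s} {report.overall[name]:.3f}")
print("\nper-class and weighted rows:")
print(report.to_frame().round(3).to_string())
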