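"""Train, cross-validate and apply the full terminator predictor.

Runs the default protocol — group-8 features, F-score + IFS,
gradient-boosted trees — with repeated stratified 5-fold CV, then holds
out 20% as an independent test set.
"""

from pseterm import (
    CVConfig,
    PipelineConfig,
    SimulationConfig,
    TerminatorPredictor,
    cross_validate_pipeline,
    simulate_dataset,
    split_dataset,
)

dataset = simulate_dataset(SimulationConfig(n_pos=100, n_neg=100, seed=11))
config = PipelineConfig(seed=11)

report = cross_validate_pipeline(dataset, config, CVConfig(folds=5, repeats=3, seed=11))
print("repeated 5-fold CV (3 repeats), mean +/- standard error over repeats:")
print(f"  Sn  = {report.sn:.4f} +/- {report.se_sn:.4f}   (terminators recognised)")
print(f"  Sp  = {report.sp:.4f} +/- {report.se_sp:.4f}   (background rejected)")
print(f"  Acc = {report.acc:.4f} +/- {report.se_acc:.4f}")
print(f"  MCC = {report.mcc:.4f} +/- {report.se_mcc:.4f}")
print(f"  AUC = {report.auc:.4f}")

train, held = split_dataset(dataset, 0.8, seed=11)
predictor = TerminatorPredictor(config).fit(train)
preds, independent = predictor.evaluate(held)
print(f"\nindependent 20% holdout: Acc = {independent.acc:.4f}, MCC = {independent.mcc:.4f}")
print("first predictions (positive-class probability and call):")
print(preds.head(4).round(4).to_string(index=False))
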