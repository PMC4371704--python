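"""Run the full detection pipeline on a small synthetic study.

Simulates three classes of segments, extracts 30 features per segment,
reduces to two dimensions with the scatter-matrix criterion, designs the
two-stage piecewise quadratic classifier on the first half of each class and
scores the second half. The confusion matrix rows are true classes, columns
predictions; sensitivity/specificity/accuracy are the standard per-class and
overall percentages. For the full-size study (100 segments per class) use
PipelineConfig() defaults instead; it takes a few minutes.
"""

from eegspike.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    per_class=30,
    train_per_class=15,
    cv_folds=5,
    seed=1,
)
result = run_pipeline(config)
print(result.report)
print(f"cross-validation loss on the design set: {result.cv_loss:.3f}")
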