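"""Train a small radial-to-aortic model and reconstruct a held-out record.

A compact run (60 subjects, short schedule) that shows the full pipeline:
simulate, split 70/30, normalize, fit by MSE, denormalize and score the
reconstruction in mmHg.  Expect a couple of minutes on one CPU; accuracy
improves with more subjects and epochs (see docs/methods.md).
"""

import numpy as np

from capwave import (
    CohortSpec,
    ModelConfig,
    NormalizationScheme,
    TCNAttention,
    TrainConfig,
    evaluate_model,
    fit,
    generate_cohort,
    prepare_pairs,
    split_dataset,
    waveform_metrics,
)

cohort = generate_cohort(60, CohortSpec(), seed=3)
train, test = split_dataset(cohort.records, 0.70, seed=3)
print(f"{len(train)} training / {len(test)} held-out records")

model = TCNAttention(ModelConfig(channels=32, dropout=0.0), seed=3)
for lr, epochs in [(3e-3, 30), (1e-3, 30)]:
    result = fit(model, prepare_pairs(train),
                 TrainConfig(epochs=epochs, batch_size=4, learning_rate=lr, seed=3))
    print(f"lr={lr:g}: {result.epochs_run} epochs, "
          f"final training MSE {result.loss_history[-1]:.5f} (normalized)")

metrics = evaluate_model(model, test, name="tcn-attention")
print("\nheld-out reconstruction accuracy (mean per record):")
print(f"  waveform MAE: {metrics.per_record['TW_MAE'].mean():.2f} mmHg")
print(f"  SBP error:    {metrics.per_record['SBP_MAE'].mean():.2f} mmHg")
print(f"  DBP error:    {metrics.per_record['DBP_MAE'].mean():.2f} mmHg")
print(f"  Spearman corr of waveforms: {metrics.scc_mean:.4f}")

scheme = NormalizationScheme()
rec = test[0]
estimate = scheme.invert(model.forward(scheme.apply(rec.radial.values)))
mae, rmse, mx, scc = waveform_metrics(rec.aortic.values, estimate)
print(f"\nfirst held-out record ({rec.record_id}): "
      f"MAE {mae:.2f}, RMSE {rmse:.2f}, MAX {mx:.2f} mmHg, SCC {scc:.4f}")
print(f"  true  SBP/DBP: {rec.aortic.sbp:.1f}/{rec.aortic.dbp:.1f} mmHg")
print(f"  est.  SBP/DBP: {estimate.max():.1f}/{estimate.min():.1f} mmHg")
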