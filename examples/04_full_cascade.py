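"""Run the complete duo-cascade on the default synthetic study.

Stage 1 ranks five Gaussian blocks (three informative, two noise), runs both
greedy searches and autoencoder-fuses the winning set; stage 2 trains the
SVM/RF/QDA ensemble on the fused code and majority-votes their labels on the
held-out patients.  The report prints the selected sets, the fused widths
before/after the autoencoder, and the second-stage metrics.
"""

import duofuse as d

report = d.run_pipeline(d.PipelineConfig(n_samples=300, seed=0))

print("block ranking:", report.ranking["ordered_blocks"])
for strategy, res in report.stage1_metrics.items():
    print(f"stage 1 {strategy:8s}: selected {res['selected']} "
          f"at accuracy {res['accuracy']:.3f}")
print(f"fused width: {report.fused_dim_before_ae} -> {report.fused_dim_after_ae} (autoencoder)")
print("per-member test accuracy:",
      {k: round(v, 3) for k, v in report.member_test_accuracy.items()})
print(f"stage 2 majority vote accuracy: {report.stage2_metrics['vote_accuracy']:.3f}")
print("stage 2 metrics (positive class = class0):")
for k in ("accuracy", "sensitivity", "specificity", "precision", "f1"):
    print(f"  {k:12s} {report.stage2_metrics[k]:.3f}")
print("\nThe noise blocks are excluded by the search, and the voted decision "
      "tracks the best individual classifier on the same fused features.")
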