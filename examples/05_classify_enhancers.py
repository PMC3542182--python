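"""Bolasso classification of cardiac vs non-cardiac enhancers from
motif-hit densities.

Features are per-kb hit densities standardized over the dataset; LASSO is
fit on bootstrap resamples and each motif's confidence is the fraction of
fits selecting it. The final panel keeps motifs above a confidence
threshold chosen by greedy descent from 95% while leave-one-out AUC
improves; a positive coefficient means above-average density predicts the
cardiac class.
"""

from crmscan import classify, simulate

study = simulate.generate_study(simulate.cardiac_design(seed=5))
fm = classify.build_features(study.enhancers, consensi=study.motifs)
fm_std = classify.standardize(fm)
y = study.enhancers.labels

result = classify.bolasso(fm_std, y, n_bootstrap=200, seed=5)
print("top bootstrap confidences:")
for motif, freq in sorted(result.selection_freq.items(), key=lambda kv: -kv[1])[:5]:
    print(f"  {motif:10s} {100 * freq:.0f}%")

clf = classify.select_final(result, fm_std, y)
print(f"\nfinal classifier at confidence >= {100 * clf.confidence_threshold:.0f}%:")
for motif in clf.motifs:
    print(f"  {motif:10s} coefficient {clf.coefficients[motif]:+.3f}")
print(f"LOOCV AUC: {clf.loocv_auc:.3f}")

# score one enhancer: coefficients times its standardized densities
row = fm_std.values.iloc[0]
print(f"\nscore of {fm_std.enhancer_ids[0]} (label {y[0]:+d}): "
      f"{classify.score_enhancer(clf, row):+.3f} "
      "(positive scores predict cardiac activity)")
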