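"""Nested 10x10 cross-validation with planted ground truth.

Six feature columns carry a real class difference; the rest are noise. The
outer loop never sees its held-out subjects during selection or tuning, so
the pooled out-of-fold AUC is an honest estimate, and features selected in
all 10 outer loops form the consensus ("most valuable") set.
"""

import warnings

warnings.filterwarnings("ignore")

from gliomics import consensus_features, planted_feature_table, roc_analysis, run_nested_cv

features, labels, idh = planted_feature_table(
    n_codel=65, n_noncodel=92, n_signal=6, n_noise=194, effect_size=2.0, seed=42
)
result = run_nested_cv(features, labels, seed=42)

auc, _, _ = roc_analysis(result.pooled_posterior.to_numpy(), labels.to_numpy())
print(f"pooled out-of-fold AUC: {auc:.3f}")
print(f"features selected per outer fold: {result.selected_counts_per_fold}")

cons = consensus_features(result)
print("\nconsensus features (selected in all 10 outer loops):")
print(cons[cons.consensus].to_string())
# With a large planted effect the consensus recovers the six signal columns
# and the per-feature t-tests confirm the class difference; noise columns
# rarely survive all 10 loops.
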