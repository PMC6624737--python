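"""Differential KO abundance between metagenomes without replicates.

Generates two KO inventories with 5% of features planted at 8-fold
enrichment, normalizes to counts per billion bases, and calls differential
features with the simulated-replicates scheme (multinomial technical
replicates; a feature is significant when its (|M|, D) signal dominates
more than 90% of the within-condition noise cloud).
"""

from thermoprobe import funcprofile, gen_ko_counts

inv, sizes, truth = gen_ko_counts(n_features=1000, n_differential=50,
                                  effect_fold=8.0, seed=7)
samples = list(sizes)
calls = funcprofile.differential_profile(
    inv, samples[0], samples[-1], sizes, mode="abundance", seed=7)

called = set(calls.loc[calls["significant"], "feature"])
planted = set(truth["planted_features"])
recall = len(called & planted) / len(planted)
fpr = len(called - planted) / (len(calls) - len(planted))
print(f"features: {len(calls)}, planted 8x: {len(planted)}, called: {len(called)}")
print(f"recall {recall:.2f}, false-positive rate {fpr:.3f}")
print("Recall near 1 with near-zero FPR means the probability-0.9 threshold")
print("separates an 8-fold shift from multinomial sampling noise at this depth.")

top = calls.sort_values("probability", ascending=False).head(3)
print("\nstrongest calls (M = log2 fold change of counts-per-billion-bases):")
print(top[["feature", "m_stat", "probability"]].to_string(index=False))
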