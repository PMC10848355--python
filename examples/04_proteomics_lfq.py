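"""Label-free proteomics DE with repeated down-shift imputation.

Missing LFQ values are left-censored (low-abundance proteins drop out).
Groups with <=1 detection get missing values drawn 2.5 column-SDs below
the column mean (width 0.3 SD); the rest are filled with the group MLE
mean.  A moderated t-test plus a volcano significance curve (|log2FC| > 1,
adjusted p <= 0.05 asymptotically) is repeated over 20 imputation cycles;
proteins significant in every cycle carry the 'consistent' flag.
"""

from bpomics import dep_counts, gen_lfq, repeated_imputation_de

lfq, truth = gen_lfq(300, {"control": 4, "treated": 4}, frac_de=0.2,
                     censor_quantile=0.3, delta=3.0, seed=1)
print(f"{len(lfq.proteins)} proteins, missing fraction "
      f"{lfq.mask.to_numpy().mean():.0%} (left-censored + 2% random)")

dep = repeated_imputation_de(lfq, ("treated", "control"), n_cycles=20, base_seed=0)
sig = dep_counts(dep, "significant")
con = dep_counts(dep, "consistent")
print(f"cycle-0 significant: {sig['up']} up / {sig['down']} down")
print(f"consistent across all 20 cycles: {con['total']}")

planted = truth.de_features["treated_vs_control"]
flagged = dep.consistent()
recall = len(flagged & planted) / len(planted)
fdr = len(flagged - planted) / max(1, len(flagged))
print(f"against ground truth: recall {recall:.0%}, FDR {fdr:.0%} — the "
      "consistency flag trades a little sensitivity for reproducibility.")
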