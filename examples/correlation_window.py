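"""Recover the cluster-span signal from a synthetic peak cohort.

Generates 100 peak regions, each with one strong κB site at the center and
several weak sites planted within a 150-bp span, where the ChIP-like score
tracks the cluster's summed affinity.  The Pearson correlation between
occupancy and cumulative Z-score is then traced across window lengths, with
and without the weak sites, and weak-site abundance is compared between the
high- and low-occupancy peak halves.
"""

from kbsites import (
    CohortSpec,
    compare_ranked_halves,
    correlation_curve,
    gen_peak_cohort,
    gen_zscore_table,
)

table = gen_zscore_table(200, seed=1)
spec = CohortSpec(n_peaks=100, span_bp=150, alpha=1.0, noise_sd=10.0, seed=1)
peaks, truth = gen_peak_cohort(spec, table)
print(f"cohort: {len(peaks)} peaks, planted span {spec.span_bp} bp, noise sd {spec.noise_sd}")

curve = correlation_curve(peaks, [10, 50, 150, 300, 500])
print("\nwindow_bp  r_all   r_strong_only")
for L, ra, rs in zip(curve.window_lengths, curve.r_all, curve.r_strong_only):
    print(f"{L:9d}  {ra:6.3f}  {rs:6.3f}")

halves = compare_ranked_halves(peaks)
print(
    f"\nweak sites per peak: top half {halves.mean_top:.2f}, "
    f"bottom half {halves.mean_bottom:.2f} "
    f"(t = {halves.t_statistic:.2f}, p = {halves.p_value:.2g})"
)
print(
    "\nr_all rises until the window covers the planted 150-bp cluster and then"
    "\nplateaus; excluding weak sites flattens the curve, showing that the"
    "\noccupancy signal lives in the cluster, not the single strongest site."
)
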