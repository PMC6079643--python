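"""Simulate a cryosection series and preprocess it to filtered VST values.

Generates counts for 600 genes across three replicate trees (14-18 pooled
tangential sections each), normalizes with median-of-ratios size factors,
applies the closed-form NB variance-stabilizing transform, and filters for
genes expressed above VST 3 in at least two sections of at least two trees.
"""

import xylemnet as xn

counts, truth = xn.simulate_series(xn.SimulationConfig(rng_seed=1))
print(f"simulated {counts.n_genes} genes x {counts.n_samples} sections "
      f"across trees {counts.trees}")

size_factors = xn.compute_size_factors(counts)
print(f"size factors span {size_factors.min():.3f} - {size_factors.max():.3f} "
      "(library-depth correction per section)")

vst = xn.vst_transform(counts, size_factors)
expressed = xn.filter_expressed(vst)
print(f"{len(expressed)} / {counts.n_genes} genes pass the expression filter "
      "(VST > 3 in >= 2 sections of >= 2 trees)")

# a deliberately blanked section can be imputed from its flanking sections
gap = xn.simulate_series(xn.SimulationConfig(rng_seed=1, missing_sample=("T2", 5)))[0]
imputed = xn.impute_missing_sample(gap, "T2", 5)
print(f"imputed section T2:05 as the mean of T2:04 and T2:06; "
      f"matrix back to {imputed.n_samples} sections")
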