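"""What a clean border inspection does and does not prove.

A 150,000-seed working sample is inspected for regulated weed seeds.  At a
hard-to-detect contamination rate of one contaminant per 100,000 crop
seeds, a substantial share of samples are contaminant-free by chance alone,
yet a ten-tonne shipment can still carry tens of thousands of weed seeds.
"""

from seednet import (CLOVER, RYEGRASS, contaminants_per_hectare,
                     expected_contaminants, max_rate_at_confidence,
                     prob_clean_sample)

rate = 1e-5          # one contaminant per 100,000 crop seeds
n_sample = 150_000   # seeds inspected per lot

p_clean = prob_clean_sample(n_sample, rate)
print(f"P(sample of {n_sample:,} seeds is contaminant-free) = {p_clean:.4f}")
print("  -> more than a fifth of truly contaminated lots pass untouched\n")

bound = max_rate_at_confidence(n_sample, 0.95)
print(f"clean sample => 95% confident rate < {bound:.3e} (~1 in {1/bound:,.0f})\n")

for spec in (RYEGRASS, CLOVER):
    per_shipment = expected_contaminants(10_000, spec.thousand_seed_weight_g,
                                         rate)
    per_ha = contaminants_per_hectare(spec.sowing_rate_kg_per_ha,
                                      spec.thousand_seed_weight_g, rate)
    print(f"{spec.crop}: a 10-tonne shipment carries ~{per_shipment:,.0f} "
          f"contaminant seeds;")
    print(f"  sowing at {spec.sowing_rate_kg_per_ha:g} kg/ha plants "
          f"~{per_ha.whole} weed seeds per hectare")
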