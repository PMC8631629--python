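"""From seed-lot inspection records to dispersal-rate inputs.

Synthetic inspection records (country-level Bernoulli contamination, rare
quarantine hits) are summarised into per-country contamination rates and
the event counts that, together with trade volumes, set the simulator's
per-tonne dispersal rate.
"""

from seednet import (IncursionSpec, SyntheticInspectionSpec,
                     count_detection_events, estimate_rate,
                     generate_inspections, summarize_contamination)

spec = SyntheticInspectionSpec(rng_seed=1)
records = generate_inspections(spec)
summ = summarize_contamination(records)

crop = summ.per_crop["ryegrass"]
print(f"{crop['n_lots']} ryegrass lots inspected, "
      f"{crop['pct_contaminated']:.1f}% contaminated, "
      f"{crop['n_species']} distinct species-level taxa")
print("\nmost-contaminated exporters (>= 10 lots):")
pc = summ.per_country
print(pc[pc.n_lots >= 10].sort_values("pct_contaminated", ascending=False)
      .head(5).to_string(index=False))

detections = count_detection_events(records)["ryegrass"]
incursions = IncursionSpec(events=1, window_years=20)
det_rate = estimate_rate(detections, 199.0, 5, basis="detection")
inc_rate = estimate_rate(incursions.events, 199.0, incursions.window_years,
                         basis="incursion")
print(f"\n{detections} quarantine detection events -> "
      f"r = {det_rate.rate_per_tonne:.2e} per tonne")
print(f"{incursions.events} incursion in {incursions.window_years} yr -> "
      f"r = {inc_rate.rate_per_tonne:.2e} per tonne")
print("  the detection basis bounds preventable spread; the incursion "
      "basis bounds what slips through")
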