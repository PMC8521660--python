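"""What fraction of the outside phyllosphere community can reach plants
from soil?

Plants in sealed growth-chamber microboxes can only be colonised from the
soil, so taxa on their leaves/flowers are soil-capable by construction.
Pooling reads per location and repeatedly subsampling both pools to equal
depth gives a depth-robust overlap estimate.
"""

import phyllocom as pc
from phyllocom.overlap import (
    incremental_overlap,
    pool_reads,
    reachable_asv_set,
    reachable_read_fraction,
    restrict_to_top_fraction,
)
from phyllocom.simulate import SimulationConfig, generate_study

table, sheet, _, truth = generate_study(
    SimulationConfig(seed=3, n_asvs=400, n_replicates_per_cell=3)
)
cleaned, _ = pc.remove_control_asvs(table, sheet.select(habitat="negative_control"))
cleaned = cleaned.drop_samples(sheet.select(habitat="mock_control"))

phyllo = ["rosette", "leaf_no_soil_contact", "flower"]
outside = pool_reads(cleaned, sheet.select(location="outside", treatment="AG", habitat=phyllo))
chamber = pool_reads(cleaned, sheet.select(location="growth_chamber", treatment="AG", habitat=phyllo))

curve = incremental_overlap(outside, chamber, step=100, replicates=5, seed=0)
print(f"depths sampled: {curve.depths[0]:,} down to {curve.depths[-1]}")
print(f"overlap at convergence: {100 * curve.converged():.1f}% of outside-"
      "detected taxa are also detected in the sealed chamber")

top10, share = restrict_to_top_fraction(outside, 0.10)
c10 = incremental_overlap(top10, chamber, step=100, replicates=5, seed=1)
print(f"top 10% most abundant outside taxa ({100 * share:.0f}% of reads): "
      f"{100 * c10.converged():.1f}% chamber-detectable")
# Abundant phyllosphere taxa are predominantly soil-capable; rare ones are
# more often aerial-only.

# read mass attributable to soil-reachable taxa in outside flowers
chamber_ids = sheet.select(location="growth_chamber", treatment="AG", habitat=phyllo)
reach = reachable_asv_set(
    pc.apply_presence_threshold(cleaned, 3).select_samples(chamber_ids), 3
)
flowers = sheet.select(location="outside", treatment="AG", habitat="flower")
rarefied = pc.rarefy(cleaned.select_samples(flowers), 1084, seed=2)
fracs = [reachable_read_fraction(rarefied.row(s), reach) for s in flowers]
print(f"soil-reachable taxa carry {100 * sum(fracs) / len(fracs):.0f}% of "
      "outside floral reads")
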