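"""Clean a raw ASV table the way the analysis expects.

Three rules: drop ASVs present in every negative control (reagent
contamination), derive a read-count presence threshold from the mock
community's off-target bleed, and discard samples with fewer than 1,000
reads.
"""

import phyllocom as pc
from phyllocom.simulate import SimulationConfig, generate_study

table, sheet, _, truth = generate_study(
    SimulationConfig(seed=7, n_asvs=300, n_replicates_per_cell=2)
)

negatives = sheet.select(habitat="negative_control")
cleaned, removed = pc.remove_control_asvs(table, negatives)
print(f"ASVs found in all {len(negatives)} negative controls, removed: {removed}")

mock = sheet.select(habitat="mock_control")[0]
threshold = pc.derive_presence_threshold(table.row(mock), truth.mock_member_asvs)
print(f"presence threshold from mock bleed reads: {threshold} reads")
# Mean off-target bleed is ~2 reads, so presence requires 3: anything below
# is indistinguishable from cross-contamination or index switching.

cleaned = cleaned.drop_samples([mock])
cleaned, small = pc.filter_small_samples(cleaned, 1000)
print(f"samples below 1,000 reads, discarded: {len(small)}")
print(f"analysed table: {cleaned.shape[0]} samples x {cleaned.shape[1]} ASVs")

thresholded = pc.apply_presence_threshold(cleaned, threshold)
zeroed = int((cleaned.counts > 0).sum() - (thresholded.counts > 0).sum())
print(f"sub-threshold presences zeroed: {zeroed}")
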