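"""Sensor montage and balanced trial design.

Builds the 129-channel geodesic layout, applies the conventional 19-channel
peripheral-belt exclusion (keeping the 110 analyzed channels), and generates
one participant's balanced 288-trial three-condition design.
"""

from erpfield import PERIPHERAL_BELT, apply_exclusion, build_montage, generate_design

full = build_montage()
study = apply_exclusion(full, PERIPHERAL_BELT)
print(f"layout channels:   {len(full.labels)} (includes the vertex 'Cz')")
print(f"excluded belt:     {len(PERIPHERAL_BELT)} channels")
print(f"retained channels: {len(study.retained)}")
regions = sorted(set(study.clusters.values()))
print(f"scalp clusters:    {regions}")

design = generate_design(1, seed=1)
print(f"\ntrials per participant: {len(design)}")
print(design.condition.value_counts().to_string())
print(f"identity repetitions:   {design.identity.value_counts().unique().tolist()}")
print("Each condition has 96 trials (16 per block x 6 blocks); every face")
print("identity recurs 12 times and meets each context at most once.")
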