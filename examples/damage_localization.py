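"""Localize simulated tubular damage on the TP-aligned coordinate.

Simulates 4 control and 8 treated tubules whose radius is enlarged ×1.75
only between −75 μm and +175 μm of the turning point, then bins the
cross-section area profiles (25 μm bins) and tests control vs treated per
bin with Welch's t-test. The significant bins should recover the damaged
window, and the PST region should stay quiet.
"""

import tubulometry as tm

cohort, binned, comparison = tm.run_localization_experiment(
    window=(-75.0, 175.0), radius_scale=1.75, seed=0
)

print("bin center  control  treated       p  sig region")
for _, row in comparison.table.iterrows():
    star = "*" if row.significant else " "
    print(f"{row.bin_center_um:10.1f} {row.control_mean:8.1f} {row.treated_mean:8.1f} "
          f"{row.p_value:7.4f}  {star}   {row.region}")
print("region verdicts:", dict(comparison.region_verdicts))

# Significant (*) bins mark where the treated lumen area exceeds control;
# they should span the scaled window and stop at the PCT/PST split (175 um).
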