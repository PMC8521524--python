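"""Fit pressure coefficients of amide chemical shifts and classify residues.

Generates a synthetic shift table for the amyloid-beta(1-40) N-terminus with
known quadratic truths (the delta0/B1/B2 per residue emulate the observed
pattern: positive B1 at Glu3/Glu11/Val12, negative at Arg5-His6 and
His13-His14, near-zero at Asp7-Tyr10), fits delta(p) at 1-2000 bar, applies
the (all-zero default) random-coil correction and prints the sign class per
residue.  A corrected |B1| above 0.2 ppm/kbar marks a pressure-sensitive
site — a candidate for transient structure such as a salt bridge.
"""

from absb.shift_pressure import RandomCoilReference, fit_shift_table
from absb.synthetic import ShiftTableConfig, gen_shift_table

series, truth = gen_shift_table(ShiftTableConfig(noise_sigma=0.005), seed=11)
table = fit_shift_table(series, RandomCoilReference.zero(), threshold=0.2)

cols = ["residue_index", "residue_name", "nucleus",
        "B1_ppm_per_kbar", "B2_ppm_per_kbar2", "response_class"]
print(table[cols].round(3).to_string(index=False))
print()
print("B1 is the linear pressure coefficient (ppm/kbar): 'negative' residues")
print("(here Arg5, His6, His13, His14) lose local interactions under pressure;")
print("'near_zero' residues respond like random coil.")
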