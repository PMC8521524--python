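"""Group-energy contrast of Ser8 phosphorylation.

Generates a conformer energy table from the reference group laws (7
conformers with both Arg5-Glu3 and Arg5-Asp7 bridges, 8 with only the Asp7
bridge, 12 bridge-free controls) and computes the per-group phosphorylation
energy dE = E_phos - E_nonphos and the contrast ddE against the control
group, in hartrees and kJ/mol.  A positive ddE means phosphorylation
destabilises salt-bridged conformers relative to bridge-free ones.
"""

from absb.energetics import group_stats_from_frame
from absb.synthetic import EnergyTableConfig, gen_energy_table

df, truth = gen_energy_table(EnergyTableConfig(), seed=5)
comp = group_stats_from_frame(df)
print(comp.to_frame().round(4).to_string(index=False))
print("\nWith zero-variance groups at the reference means the contrast is")
print("exactly mean(dE_test) - mean(dE_control); with sampled groups it")
print("fluctuates with the group standard deviations shown above.")
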