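"""Proton budget of raising intracellular pH for cell proliferation.

Computes how many protons must be removed from a typical 100-um^3 human
cell to raise its intracellular pH from the resting 6.8 to the
proliferative 7.4 against cytosolic buffering, and expresses that count
as ATPs (respiratory ATP synthesis consumes one proton each) and as a
fraction of the ATP cost of replicating the genome.
"""

from warburgph import PhShiftSpec, genome_fraction_equivalent, net_protons, protons_for_ph_shift

spec = PhShiftSpec()  # pH 6.8 -> 7.4, 100 um^3, buffering coefficient 2e5
budget = protons_for_ph_shift(spec)
fraction = genome_fraction_equivalent(budget["protons"], spec)

print(f"protons to remove:      {budget['protons']:.4g}")
print(f"equivalent ATPs:        {budget['atp_equivalent']:.4g}")
print(f"genome-synthesis cost:  {100 * fraction:.2f} % of the genome's ATP budget")
print()
print("per-ATP proton ledger (synthesis + hydrolysis):")
print(f"  glycolytic ATP:  {net_protons('glycolysis_synthesis', 1):+d} H+")
print(f"  respiratory ATP: {net_protons('respiration_synthesis', 1):+d} H+")

# The ~1.4e9 protons equal the proton yield of hydrolyzing the same number
# of respiration-made ATPs: accumulating respiratory ATP alkalinizes the
# cytosol, while glycolytic ATP turnover releases one net proton each --
# the stoichiometric backbone of the pH interpretation of the Warburg
# effect in proliferating cells.
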