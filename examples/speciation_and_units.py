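"""Trimethylamine speciation and the clinical unit conversion.

Why a cation sensor can stand in for the smell-based "whiff test": below
pH 8 virtually all trimethylamine (pKa 9.8) is protonated, so measuring
the trimethylammonium cation captures the whole analyte pool.  The second
half converts the literature's clinically relevant mass fraction of TMA
in vaginal fluid into the molarity used for spiking experiments.
"""

from potsense import ProtonationSpec, fraction_protonated, mass_per_gram_to_molar

tma = ProtonationSpec(pKa=9.8)

print("pH   fraction protonated (TMA+, pKa 9.8)")
for ph in (4.0, 6.6, 8.0, 9.8, 11.8):
    print(f"{ph:4.1f}  {fraction_protonated(ph, tma):.4f}")
print("-> across the vaginal pH range (4-6.6, even up to 8) more than 97%")
print("   of the analyte carries charge and is visible to the electrode.\n")

molar = mass_per_gram_to_molar(24.5, density_g_per_ml=1.01, molar_mass_g_per_mol=95.57)
print(f"24.5 ug TMA per g fluid (density 1.01 g/mL, TMA.HCl 95.57 g/mol)"
      f" = {molar * 1e6:.1f} uM")
print("-> the 'clinically relevant' spike level, usually rounded to 260 uM.")
molar_free = mass_per_gram_to_molar(24.5, 1.01, 59.11)
print(f"Same mass fraction on the free-amine basis (59.11 g/mol)"
      f" = {molar_free * 1e6:.1f} uM — the molar-mass choice matters.")
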