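# Tietz simulated vaginal fluid: electrolyte recipe per litre of DI water.
# pH is adjusted with HCl after mixing (set it on the loaded composition);
# the HCl contribution to ionic strength is small and not modelled.
salts:
  sodium_chloride:
    grams_per_L: 3.50
    molar_mass: 58.44
    ions:
      Na: {charge: 1, stoich: 1}
      Cl: {charge: -1, stoich: 1}
  potassium_chloride:
    grams_per_L: 1.50
    molar_mass: 74.55
    ions:
      K: {charge: 1, stoich: 1}
      Cl: {charge: -1, stoich: 1}
  potassium_hydrogen_phosphate:
    grams_per_L: 1.74
    molar_mass: 174.18
    ions:
      K: {charge: 1, stoich: 2}
      HPO4: {charge: -2, stoich: 1}
  potassium_dihydrogen_phosphate:
    grams_per_L: 1.36
    molar_mass: 136.09
    ions:
      K: {charge: 1, stoich: 1}
      H2PO4: {charge: -1, stoich: 1}
neutral_solutes:
  glucose_monohydrate:
    grams_per_L: 10.80
    molar_mass: 198.17
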