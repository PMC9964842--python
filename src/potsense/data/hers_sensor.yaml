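# Ground-truth parameters for a trimethylammonium-selective yarn electrode,
# used by the simulator as the generating truth for round-trip tests.
# Selectivities are the separate-solution-method (SSM) values; the
# fixed-interference-method column of the same characterisation reads
# Na -1.25, K -1.12, Ca -1.09 (no Mg entry).
name: hers
E0_mV: 400.0
temperature_K: 298.15
slope_mV_per_decade: null   # null -> theoretical Nernstian 2.303*RT/zF
primary_ion: {name: TMA, charge: 1, molar_mass: 60.12}
selectivities:
  Na: {charge: 1, log10_k: -2.69}
  K: {charge: 1, log10_k: -2.03}
  Ca: {charge: 2, log10_k: -3.99}
  Mg: {charge: 2, log10_k: -4.28}
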