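"""Estimate selectivity coefficients by SSM and FIM from simulated data.

One Nikolsky-Eisenman ground truth generates both experiments per
interferer: the separate-solution method reads the electrode in two
single-ion solutions (10 mM each), the fixed-interference method runs a
full dilution calibration in a constant 0.1 mM interferer background.
Both inversions should land on the generating log k.  A final section
reproduces the bulky-reference-cation comparison used to demonstrate
that the ionophore, not mere lipophilicity, drives the response.
"""

import numpy as np

from potsense import (
    DilutionProtocol,
    ElectrolyteComposition,
    IonSpecies,
    MembraneMeasurement,
    NoiseModel,
    SensorParams,
    extract_plateaus,
    fim_selectivity,
    ionophore_shift,
    nikolsky_emf,
    simulate_dilution_trace,
    ssm_selectivity,
)

TMA = IonSpecies("TMA", 1, 60.12)
CL = IonSpecies("Cl", -1, 35.45)

# Generating truths in the style of a measured selectivity table
TRUTHS = [
    (IonSpecies("Na", 1, 22.99), -2.69),
    (IonSpecies("K", 1, 39.10), -2.03),
    (IonSpecies("Ca", 2, 40.08), -3.99),
    (IonSpecies("Mg", 2, 24.31), -4.28),
]

print(f"{'ion':<4} {'true log k':>10} {'SSM':>8} {'FIM':>8}")
for ion, log_k in TRUTHS:
    sensor = SensorParams(TMA, E0_mV=400.0, selectivities={ion: 10.0**log_k})
    # --- SSM: two separate 10 mM solutions
    a = 1e-2
    E_i = nikolsky_emf(sensor, a)
    E_j = nikolsky_emf(sensor, 0.0, {ion: a})
    ssm = ssm_selectivity(E_i, E_j, a, a, z_i=1, z_j=ion.charge)
    # --- FIM: dilution in constant 0.1 mM background (where a plateau exists)
    a_j = 1e-4
    bg = ElectrolyteComposition({ion: a_j, CL: a_j * ion.charge})
    proto = DilutionProtocol(tuple(10.0 ** -np.arange(1.0, 10.0)), dwell_s=30.0,
                             background=bg)
    (trace,) = simulate_dilution_trace(proto, sensor, NoiseModel(), 1)
    try:
        fim = f"{fim_selectivity(extract_plateaus(trace, proto), a_j, 1, ion.charge).log10_k:8.2f}"
    except ValueError:
        fim = "   (no plateau in range)"
    print(f"{ion.name:<4} {log_k:>10.2f} {ssm.log10_k:8.2f} {fim}")
print("-> more negative = better rejected. SSM inverts exactly; FIM carries the")
print("   small bias intrinsic to the two-regression intersection. (An ion with")
print("   no sensed interference would leave no plateau and raise an error.)\n")

# Ionophore effect: emfs rescaled so the non-binding reference cation reads 0 mV
with_ionophore = MembraneMeasurement(emf_target_mV=500.0, emf_reference_mV=200.0)
without_ionophore = MembraneMeasurement(emf_target_mV=350.0, emf_reference_mV=400.0)
shift = ionophore_shift(with_ionophore, without_ionophore)
print(f"ionophore comparison (reference cation = 0 mV): "
      f"{shift.emf_tma_with:+.0f} mV with vs {shift.emf_tma_without:+.0f} mV without"
      f" -> delta {shift.delta:.0f} mV")
print("-> a several-hundred-mV rescaled difference signals strong")
print("   ionophore-analyte complexation in the membrane.")
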