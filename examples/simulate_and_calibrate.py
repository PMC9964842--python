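"""Simulate a replicate dilution experiment and run the inverse pipeline.

Five replicate electrodes (with between-electrode slope scatter and 1 mV
measurement noise) record a stepwise dilution from 0.1 M down to 10 nM in
a 0.1 mM KCl background.  The analysis then recovers the Nernstian slope,
the linear range, and the interference-limited IUPAC detection limit.
"""

import numpy as np

from potsense import (
    DilutionProtocol,
    ElectrolyteComposition,
    IonSpecies,
    NoiseModel,
    SensorParams,
    compute_lod,
    extract_plateaus,
    fit_calibration,
    select_linear_range,
    simulate_dilution_trace,
)

TMA = IonSpecies("TMA", 1, 60.12)
K = IonSpecies("K", 1, 39.10)
CL = IonSpecies("Cl", -1, 35.45)

# Ground truth: mean slope 55.14 mV/decade, 4.44 between electrodes,
# potassium selectivity log k = -1.12 against the fixed 0.1 mM background.
sensor = SensorParams(TMA, E0_mV=400.0, slope_mV_per_decade=55.14,
                      selectivities={K: 10.0**-1.12})
background = ElectrolyteComposition({K: 1e-4, CL: 1e-4})
protocol = DilutionProtocol(tuple(10.0 ** -np.arange(1.0, 9.0)), dwell_s=30.0,
                            background=background)
noise = NoiseModel(sd_mV=1.0, electrode_offset_sd_mV=10.0,
                   electrode_slope_sd_mV=4.44, seed=2024)

traces = simulate_dilution_trace(protocol, sensor, noise, n_electrodes=5)
points = [p for tr in traces for p in extract_plateaus(tr, protocol)]

low, high = select_linear_range(points)
curve = fit_calibration(points, fit_range=(low, high))
lod = compute_lod(points)

print(f"linear range: 10^{low:.0f} to 10^{high:.0f} M "
      f"(levels below are pinned by the K+ background)")
print(f"slope: {curve.slope:.2f} +/- {curve.slope_sd:.2f} mV/decade "
      f"(n = {len(curve.electrode_fits)} electrodes; truth 55.14 +/- 4.44)")
print(f"LOD: {lod.lod * 1e6:.2f} uM  (log10 {lod.intersection_log10:.2f}; "
      f"analytic interference floor k*a_j -> log10 = -5.12)")
print("-> the detection limit is set by the background, not the electronics:")
print("   the emf plateaus where k_ij * a_j outweighs the diluted analyte.")
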