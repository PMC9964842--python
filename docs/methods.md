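# Methods

## Forward model

The electrode potential is the Nikolsky–Eisenman response

    emf = E⁰ + s · log₁₀( a_i + Σ_j k_ij · a_j^(z_i/z_j) )

with slope `s = 2.303·RT/z_iF` (59.16 mV/decade at 298.15 K for z = 1)
unless overridden by an explicit `slope_mV_per_decade`, which emulates
sub-Nernstian electrodes.  The interference exponent follows the
standard `a_j^(z_i/z_j)` convention.  Interferent matching is by ion
name; ions without a selectivity entry are treated as fully rejected
(k = 0).  When the logarithm's argument is non-positive — no primary ion
and no sensed interference — the potential is physically undefined and
the model raises an error rather than returning −∞.

Assumptions worth stating: activities default to concentrations
(`activity_model="none"`), matching how calibrations are usually plotted
as emf vs log[concentration]; an extended Debye–Hückel mode
(`log₁₀γ = −0.509·z²√I/(1+√I)`, 25 °C constants, valid to roughly
I ≈ 0.1 M) can be switched on, in which case the primary ion is assumed
added as a 1:1 salt with a monovalent counter-ion for its
ionic-strength contribution.  Temperature enters only through the
Nernst factor; membrane kinetics, junction potentials and drift
mechanisms beyond a linear term are out of scope.

## Synthetic traces

Two experiment designs are generated, both sampled at 1 s by default
(instrument acquisition rates vary; this is configurable):

- **Stepwise dilution**: one dwell-long plateau per concentration level,
  levels strictly decreasing.
- **Baseline + spikes**: background-only baseline, then cumulative
  standard additions of the primary ion; spike volume change is
  neglected.

Replicate electrodes perturb E⁰ and slope once each (Gaussian, SDs from
the noise model) — the minimal mechanism that reproduces the
"mean ± SD over n = 5 electrodes" reporting convention; selectivities
are shared across replicates.  White noise is added per sample, drift
is linear, and an optional first-order settling time constant (default
0: instantaneous steps, consistent with response times of a few
seconds against 30–60 s dwells) smooths each transition.  All
randomness flows from one integer seed through `numpy`'s Generator, so
fixed seed ⇒ bitwise-identical traces.

What the generator does **not** emulate: activity drift from electrode
conditioning, super-Nernstian transients, carry-over between dilution
steps, temperature excursions, or correlated (1/f) noise.  Passing
round-trip tests therefore demonstrates correctness of the estimators
under the stated noise model, not robustness to every artefact of real
recordings.

## Inverse pipeline

**Plateau extraction** averages the last `settle_fraction` (default
0.5) of each dwell window into one calibration point per level per
electrode, discarding the transition at the window start.

**Calibration fitting** is per-electrode ordinary least squares of emf
on log₁₀ activity; the reported slope/intercept are across-electrode
means and `slope_sd` the across-electrode sample SD — replicates are
summarised, not pooled into one regression, so a high-noise electrode
cannot silently dominate.

**Linear-range selection** returns the widest contiguous run of levels
whose consecutive decade slopes all lie within `tolerance` (default
10 mV/decade) of the run's median slope, requiring the run's overall
slope to exceed the tolerance (a flat, dead electrode has no linear
range).  Ties break toward the higher-concentration run.

**Detection limit** follows the IUPAC two-regression construction.  With
an explicit `split`, the levels are partitioned exactly there.  Without
one, each limb is grown from its own end of the curve: starting from the
outermost inter-level slope, the next slope joins the run while it lies
within `tolerance` of the median of the slopes accepted so far.  Levels
in the curved transition between the two runs belong to neither fit.
This trimming matters: forcing every level into one of two covering
segments (e.g. by residual-sum minimisation over all splits) drags
transition curvature into the regressions and biases the recovered LOD
by ~0.1 decade on a dilution spanning 10⁻⁸–10⁻¹ M with an interference
floor at 10⁻⁵·¹²; the trimmed construction recovers the analytic floor
`k_ij·a_j^(z_i/z_j)` to within ~0.04 decade at zero noise (a small
positive bias is intrinsic to the intersection definition, since the
true curve lies above both asymptotes).  Degenerate cases raise typed
errors: a curve with no knee (straight line, or an interferent too weak
to produce a plateau inside the dilution window), parallel segments, or
an intersection falling outside the calibrated span.

**Selectivity.** SSM uses the canonical expression
`log k = z_iF(E_j−E_i)/(2.303RT) + log a_i − (z_i/z_j)·log a_j`
(printed forms of this equation are frequently garbled; the equal-charge
special case `z_iF(E_j−E_i)/(2.303RT)` is pinned by a unit test).  FIM
reuses the LOD intersection — one breakpoint algorithm, tested once —
and inserts its abscissa into `log(a_i*/a_j^(z_i/z_j))`.  The
ionophore-effect comparison rescales each membrane's emfs so a
non-complexing bulky reference cation reads 0 mV, cancelling
fabrication offsets; the with/without difference of the rescaled
analyte emfs is the ionophore's contribution.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| temperature | 298.15 | K | room-temperature convention |
| sample interval | 1 | s | typical potentiometer logging rate |
| dwell per level | 30–60 | s | settles well before averaging |
| settle_fraction | 0.5 | — | robust to transition tails |
| linear-range / LOD tolerance | 10 | mV/decade | ≈ 6× the plateau-mean noise at 1 mV sample noise |
| noise sd | 1 | mV | matches the scatter of bench recordings |
| between-electrode slope SD | 4.44 | mV/decade | hand-fabricated electrode spread used as generating truth |
| between-electrode offset SD | 5–10 | mV | same provenance |
| FIM background | 10⁻⁴ | mol/L | standard 0.1 mM fixed-interference level |
| SSM activity | 10⁻² | mol/L | standard 10 mM separate solutions |

The bundled `svf_tietz.yaml` encodes the Tietz simulated-vaginal-fluid
recipe (NaCl 3.50 g/L, glucose monohydrate 10.80 g/L, KCl 1.50 g/L,
K₂HPO₄ 1.74 g/L, KH₂PO₄ 1.36 g/L; ionic strength 0.120 M).  Glucose is
carried as a neutral solute and contributes nothing to ionic strength;
the HCl used to titrate the fluid to pH 4.0 or 6.6 is a small,
unquantified chloride addition and is ignored.  `hers_sensor.yaml`
carries a TMA⁺ electrode ground truth with selectivities
Na −2.69, K −2.03, Ca −3.99, Mg −4.28 (log₁₀, SSM-style single-ion
values; the FIM column of the same characterisation — Na −1.25,
K −1.12, Ca −1.09 — is noted in the file).  SSM and FIM genuinely
disagree for divalent ions under this model family; the package treats
that as an expected property of the methods, not an inconsistency to
reconcile.

The µg/g → molar conversion takes the molar mass explicitly because
clinical mass fractions are ambiguous about the basis: 24.5 µg/g at
density 1.01 g/mL is 258.9 µM on the trimethylammonium-chloride basis
(95.57 g/mol) but 418.6 µM on the free-amine basis (59.11 g/mol).

## Problem sizes

Round-trip tests and the acceptance script use dilutions of 5–9 levels
(10⁻¹ down to 10⁻⁸·/10⁻⁹ M), 20–30 s dwells at 1 s sampling, 1–5
electrodes, and 100 seeded repetitions for the slope-recovery study —
sizes chosen to match a realistic bench session while keeping the whole
suite near-instant.

## Known limitations

- Detection limits measured on real electrodes in low-interference
  media (e.g. DI water, where the floor comes from membrane leaching
  rather than a known k·a_j) can only be validated procedurally here;
  the simulator has no leaching term.
- The FIM estimator inherits the intersection method's positive bias
  (≲ 0.05 decade on an 8-level decade grid); finer level spacing around
  the knee reduces it.
- Activity corrections beyond extended Debye–Hückel (ion pairing,
  Pitzer interactions) are out of scope; at the simulated-vaginal-fluid
  ionic strength (0.12 M) the Debye–Hückel option is itself at the edge
  of its validity.
- Configuration schemas reject unknown keys, but compositions are not
  checked for electroneutrality — deliberate, since partial recipes are
  common inputs.
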