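"""Solution chemistry underpinning the sensor model.

Acid-base speciation (Henderson-Hasselbalch), ionic strength, extended
Debye-Hueckel activity coefficients, and the mass-fraction to molarity
conversion used to translate clinical analyte levels into spike
concentrations.  Everything downstream (forward emf model, calibration,
selectivity) builds on the types defined here.

Concentrations are mol/L throughout unless a function name says otherwise;
emf-related quantities live in :mod:`potsense.model`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "R_GAS",
    "FARADAY",
    "IonSpecies",
    "ElectrolyteComposition",
    "ProtonationSpec",
    "TMA",
    "SODIUM",
    "POTASSIUM",
    "CALCIUM",
    "MAGNESIUM",
    "CHLORIDE",
    "TETRABUTYLAMMONIUM",
    "fraction_protonated",
    "ionic_strength",
    "activity_coefficient",
    "activities",
    "mass_per_gram_to_molar",
    "load_composition",
    "svf_tietz",
]

#: Universal gas constant, J mol^-1 K^-1 (CODATA 2018).
R_GAS = 8.31446261815324
#: Faraday constant, C mol^-1 (CODATA 2018).
FARADAY = 96485.33212

# Extended Debye-Hueckel constants at 25 degC in water.
_DH_A = 0.509  # (mol/L)^-1/2
_DH_B = 1.0  # (mol/L)^-1/2, denominator coefficient


@dataclass(frozen=True)
class IonSpecies:
    """A charged solution species.

    Parameters
    ----------
    name : str
        Identifier used to match species across compositions and
        selectivity maps (e.g. ``"TMA"``, ``"K"``).
    charge : int
        Signed charge number z.  Must be nonzero: only true ions enter
        the emf equations.
    molar_mass : float, optional
        g/mol; only needed when the species is specified by weight.
    """

    name: str
    charge: int
    molar_mass: float | None = None

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError(f"ion {self.name!r} must carry a nonzero charge")
        if self.molar_mass is not None and not self.molar_mass > 0:
            raise ValueError(f"ion {self.name!r}: molar_mass must be positive")


# Species that recur throughout the simulated-vaginal-fluid matrix and the
# sensor's selectivity table.  Molar masses are for the bare ion.
TMA = IonSpecies("TMA", +1, 60.12)  # trimethylammonium, pKa 9.8
SODIUM = IonSpecies("Na", +1, 22.99)
POTASSIUM = IonSpecies("K", +1, 39.10)
CALCIUM = IonSpecies("Ca", +2, 40.08)
MAGNESIUM = IonSpecies("Mg", +2, 24.31)
CHLORIDE = IonSpecies("Cl", -1, 35.45)
TETRABUTYLAMMONIUM = IonSpecies("Bu4N", +1, 242.47)

#: Molar mass of trimethylammonium chloride, g/mol — the salt actually
#: weighed out when spiking, and the mass basis that reproduces the
#: 24.5 ug/g -> ~260 uM clinical conversion.
TMA_HCL_MOLAR_MASS = 95.57


@dataclass(frozen=True)
class ElectrolyteComposition:
    """A sample matrix: ionic species with concentrations, plus neutrals.

    Neutral solutes (glucose and friends) are carried for bookkeeping but
    contribute nothing to ionic strength or the emf model.
    """

    entries: Mapping[IonSpecies, float] = field(default_factory=dict)
    pH: float | None = None
    neutral_solutes: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ion, conc in self.entries.items():
            if conc < 0 or not math.isfinite(conc):
                raise ValueError(
                    f"concentration of {ion.name!r} must be finite and >= 0, got {conc}"
                )
        for name, conc in self.neutral_solutes.items():
            if conc < 0 or not math.isfinite(conc):
                raise ValueError(
                    f"concentration of neutral solute {name!r} must be >= 0, got {conc}"
                )
        if self.pH is not None and not (0.0 <= self.pH <= 14.0):
            raise ValueError(f"pH must lie in [0, 14], got {self.pH}")

    def concentration(self, name: str) -> float:
        """Total concentration (mol/L) of the ion with this name; 0 if absent."""
        return sum(c for ion, c in self.entries.items() if ion.name == name)

    def ions(self) -> list[IonSpecies]:
        return list(self.entries)

    def with_pH(self, pH: float | None) -> "ElectrolyteComposition":
        return ElectrolyteComposition(dict(self.entries), pH, dict(self.neutral_solutes))


@dataclass(frozen=True)
class ProtonationSpec:
    """A single protonation equilibrium HA^(z) <-> A^(z-1) + H+."""

    pKa: float
    acid_form_charge: int = +1

    def __post_init__(self) -> None:
        if not (0.0 < self.pKa < 14.0):
            raise ValueError(f"pKa must lie in (0, 14), got {self.pKa}")


#: Trimethylamine / trimethylammonium equilibrium.
TMA_PROTONATION = ProtonationSpec(pKa=9.8, acid_form_charge=+1)


def fraction_protonated(pH: float, spec: ProtonationSpec = TMA_PROTONATION) -> float:
    """Henderson-Hasselbalch fraction of the acid (protonated) form.

    ``1 / (1 + 10**(pH - pKa))``; at ``pH == pKa`` exactly one half.  For
    trimethylamine (pKa 9.8) this exceeds 0.97 anywhere below pH 8, which
    is why a cation-selective electrode sees essentially all of the
    analyte in vaginal-fluid pH ranges.
    """
    if not math.isfinite(pH):
        raise ValueError(f"pH must be finite, got {pH}")
    return 1.0 / (1.0 + 10.0 ** (pH - spec.pKa))


def ionic_strength(comp: ElectrolyteComposition) -> float:
    """Ionic strength I = 1/2 * sum(c_i * z_i**2) in mol/L.

    Neutral solutes contribute nothing (charge zero).
    """
    return 0.5 * sum(c * ion.charge**2 for ion, c in comp.entries.items())


def activity_coefficient(z: int, I: float) -> float:
    """Single-ion activity coefficient from the extended Debye-Hueckel law.

    ``log10(gamma) = -A z^2 sqrt(I) / (1 + B sqrt(I))`` with A = 0.509 and
    B = 1 at 25 degC.  Valid up to roughly I ~ 0.1 mol/L; gamma -> 1 at
    infinite dilution and depends on z only through z**2.
    """
    if I < 0 or not math.isfinite(I):
        raise ValueError(f"ionic strength must be finite and >= 0, got {I}")
    sqrt_i = math.sqrt(I)
    log10_gamma = -_DH_A * z**2 * sqrt_i / (1.0 + _DH_B * sqrt_i)
    return 10.0**log10_gamma


def activities(
    comp: ElectrolyteComposition, activity_model: str = "none"
) -> dict[IonSpecies, float]:
    """Per-ion activities for a composition.

    ``activity_model="none"`` returns concentrations unchanged (the default
    throughout the pipeline: calibrations are plotted against
    log-concentration).  ``"debye_huckel"`` multiplies each concentration
    by the extended Debye-Hueckel coefficient at the composition's total
    ionic strength.
    """
    if activity_model == "none":
        return dict(comp.entries)
    if activity_model == "debye_huckel":
        I = ionic_strength(comp)
        return {
            ion: c * activity_coefficient(ion.charge, I)
            for ion, c in comp.entries.items()
        }
    raise ValueError(f"unknown activity model {activity_model!r}")


def mass_per_gram_to_molar(
    w_ug_per_g: float, density_g_per_ml: float, molar_mass_g_per_mol: float
) -> float:
    """Convert a mass fraction (ug analyte per g fluid) to molarity (mol/L).

    ug/g times g/mL gives ug/mL = mg/L; dividing by g/mol yields mmol/L,
    hence the 1e-3 to mol/L.  The molar mass is an explicit argument
    because clinical reports are ambiguous about the mass basis: 24.5 ug/g
    of vaginal fluid at density 1.01 g/mL is ~259 uM on the
    trimethylammonium chloride basis (95.57 g/mol) but ~419 uM on the
    free-amine basis (59.11 g/mol).
    """
    for label, v in (
        ("w_ug_per_g", w_ug_per_g),
        ("density_g_per_ml", density_g_per_ml),
        ("molar_mass_g_per_mol", molar_mass_g_per_mol),
    ):
        if not (math.isfinite(v) and v > 0):
            raise ValueError(f"{label} must be finite and positive, got {v}")
    return w_ug_per_g * density_g_per_ml / molar_mass_g_per_mol * 1e-3


# ---------------------------------------------------------------------------
# Composition files
# ---------------------------------------------------------------------------


def load_composition(path: str | Path) -> ElectrolyteComposition:
    """Read an electrolyte composition from a YAML file.

    The format has three optional sections::

        pH: 6.6               # optional
        salts:                # weighed-in salts, fully dissociated
          sodium_chloride:
            grams_per_L: 3.50       # or mol_per_L
            molar_mass: 58.44       # required with grams_per_L
            ions:
              Na: {charge: 1, stoich: 1}
              Cl: {charge: -1, stoich: 1}
        ions:                 # direct ionic entries
          K: {charge: 1, mol_per_L: 1.0e-4}
        neutral_solutes:
          glucose_monohydrate: {grams_per_L: 10.80, molar_mass: 198.17}

    Ion entries arising from several salts are summed per ion name.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: composition file must be a mapping")

    totals: dict[tuple[str, int], float] = {}

    def _add(name: str, charge: int, conc: float) -> None:
        key = (name, int(charge))
        totals[key] = totals.get(key, 0.0) + conc

    for salt_name, salt in (raw.get("salts") or {}).items():
        if "mol_per_L" in salt:
            c_salt = float(salt["mol_per_L"])
        elif "grams_per_L" in salt:
            c_salt = float(salt["grams_per_L"]) / float(salt["molar_mass"])
        else:
            raise ValueError(f"{path}: salt {salt_name!r} needs mol_per_L or grams_per_L")
        for ion_name, ion in (salt.get("ions") or {}).items():
            _add(ion_name, ion["charge"], c_salt * float(ion.get("stoich", 1)))

    for ion_name, ion in (raw.get("ions") or {}).items():
        _add(ion_name, ion["charge"], float(ion["mol_per_L"]))

    neutrals: dict[str, float] = {}
    for sol_name, sol in (raw.get("neutral_solutes") or {}).items():
        if "mol_per_L" in sol:
            neutrals[sol_name] = float(sol["mol_per_L"])
        else:
            neutrals[sol_name] = float(sol["grams_per_L"]) / float(sol["molar_mass"])

    entries = {
        IonSpecies(name, charge): conc for (name, charge), conc in totals.items()
    }
    pH = raw.get("pH")
    return ElectrolyteComposition(entries, None if pH is None else float(pH), neutrals)


def svf_tietz(pH: float | None = 6.6) -> ElectrolyteComposition:
    """The Tietz simulated-vaginal-fluid electrolyte matrix.

    NaCl 3.50 g/L, glucose monohydrate 10.80 g/L, KCl 1.50 g/L, K2HPO4
    1.74 g/L and KH2PO4 1.36 g/L in water, pH adjusted with HCl (the
    adjustment's small ionic-strength contribution is not modelled).
    """
    from importlib.resources import files

    comp = load_composition(Path(str(files("potsense").joinpath("data/svf_tietz.yaml"))))
    return comp.with_pH(pH)
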