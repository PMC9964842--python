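"""Potentiometric selectivity coefficients: SSM, FIM, ionophore effect.

Two classical routes to log10 k_ij^pot:

* **Separate solution method (SSM)** — the electrode's emf is read in two
  single-ion solutions, one of the primary ion i and one of the
  interferer j, and the selectivity follows from the emf difference:

      log10 k_ij = z_i F (E_j - E_i) / (2.303 R T)
                   + log10 a_i - (z_i/z_j) log10 a_j

* **Fixed interference method (FIM)** — the primary ion is calibrated in
  a constant interferer background; below the detection limit the emf is
  pinned by the interferer at the plateau k_ij * a_j^(z_i/z_j).  The
  two-regression intersection (the same IUPAC construction used for the
  LOD) gives the primary-ion activity a_i at which both contributions are
  equal, and log10 k_ij = log10(a_i / a_j^(z_i/z_j)).

The module also implements the bulky-reference-cation comparison used to
demonstrate an ionophore effect: emfs of membranes with and without the
ionophore are rescaled so a non-complexing reference cation (here
tetrabutylammonium) reads 0 mV, cancelling fabrication offsets, and the
remaining difference in the target-ion emf is the ionophore contribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .calibration import CalibrationPoint, compute_lod
from .chem import FARADAY, R_GAS, IonSpecies

__all__ = [
    "SelectivityEstimate",
    "MembraneMeasurement",
    "IonophoreComparison",
    "ssm_selectivity",
    "fim_selectivity",
    "ionophore_shift",
]


@dataclass(frozen=True)
class SelectivityEstimate:
    """A log10 selectivity coefficient with its method and provenance."""

    interferer: IonSpecies
    log10_k: float
    method: str  # "SSM" or "FIM"
    inputs: dict = field(default_factory=dict)


@dataclass(frozen=True)
class MembraneMeasurement:
    """Paired emfs of one membrane in target and reference-cation solutions."""

    emf_target_mV: float
    emf_reference_mV: float | None

    def rescaled_target(self) -> float:
        if self.emf_reference_mV is None:
            raise ValueError("missing reference-cation emf for this membrane")
        return self.emf_target_mV - self.emf_reference_mV


@dataclass(frozen=True)
class IonophoreComparison:
    """Reference-rescaled emf difference attributable to the ionophore."""

    emf_tma_with: float
    emf_tma_without: float
    delta: float  # mV; positive = ionophore raises the target-ion response


def ssm_selectivity(
    E_i: float,
    E_j: float,
    a_i: float,
    a_j: float,
    z_i: int = 1,
    z_j: int = 1,
    temperature_K: float = 298.15,
    interferer: IonSpecies | None = None,
) -> SelectivityEstimate:
    """Separate-solution-method selectivity from two single-ion emfs (mV).

    With equal activities a_i = a_j the expression reduces to the familiar
    ``z_i F (E_j - E_i)/(2.303 R T) + (1 - z_i/z_j) log10 a_i``.
    """
    if not (a_i > 0 and a_j > 0):
        raise ValueError(f"activities must be positive, got a_i={a_i}, a_j={a_j}")
    if z_i == 0 or z_j == 0:
        raise ValueError("ion charges must be nonzero")
    nernst_mV = 1000.0 * math.log(10.0) * R_GAS * temperature_K / FARADAY  # per z=1
    log10_k = (
        z_i * (E_j - E_i) / nernst_mV
        + math.log10(a_i)
        - (z_i / z_j) * math.log10(a_j)
    )
    return SelectivityEstimate(
        interferer or IonSpecies("j", z_j),
        log10_k,
        "SSM",
        {"E_i_mV": E_i, "E_j_mV": E_j, "a_i": a_i, "a_j": a_j,
         "z_i": z_i, "z_j": z_j, "temperature_K": temperature_K},
    )


def fim_selectivity(
    points: Sequence[CalibrationPoint],
    a_j: float,
    z_i: int = 1,
    z_j: int = 1,
    interferer: IonSpecies | None = None,
    split: int | None = None,
    tolerance: float = 10.0,
) -> SelectivityEstimate:
    """Fixed-interference-method selectivity from a background calibration.

    ``points`` must come from a primary-ion calibration in a constant
    interferer background at activity ``a_j``, showing both a Nernstian
    limb and an interference plateau.  The plateau/limb intersection is
    located with :func:`potsense.calibration.compute_lod` (one breakpoint
    algorithm for both jobs) and its abscissa a_i inserted into
    ``log10(a_i / a_j^(z_i/z_j))``.
    """
    if not a_j > 0:
        raise ValueError(f"interferer activity must be positive, got {a_j}")
    if z_i == 0 or z_j == 0:
        raise ValueError("ion charges must be nonzero")
    lod = compute_lod(points, split=split, tolerance=tolerance)
    log10_k = lod.intersection_log10 - (z_i / z_j) * math.log10(a_j)
    return SelectivityEstimate(
        interferer or IonSpecies("j", z_j),
        log10_k,
        "FIM",
        {"a_j": a_j, "z_i": z_i, "z_j": z_j,
         "intersection_log10": lod.intersection_log10, "lod": lod.lod},
    )


def ionophore_shift(
    with_ionophore: MembraneMeasurement,
    without_ionophore: MembraneMeasurement,
) -> IonophoreComparison:
    """Ionophore contribution to the target-ion emf, reference-rescaled.

    Each membrane's emfs are shifted so its reference-cation reading is
    0 mV; the returned ``delta`` is the with-minus-without difference of
    the rescaled target-ion emfs.  Adding any constant to one membrane's
    raw emfs leaves ``delta`` unchanged.
    """
    e_with = with_ionophore.rescaled_target()
    e_without = without_ionophore.rescaled_target()
    return IonophoreComparison(
        emf_tma_with=e_with,
        emf_tma_without=e_without,
        delta=e_with - e_without,
    )
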