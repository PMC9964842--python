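"""Forward emf model for ion-selective electrodes.

The phase-boundary potential of an ISE against a reference electrode
follows the Nikolsky-Eisenman equation

    emf = E0 + (2.303 RT / z_i F) * log10( a_i + sum_j k_ij * a_j^(z_i/z_j) )

where a_i is the primary-ion activity, a_j the activities of interfering
ions and k_ij the (linear-scale) potentiometric selectivity coefficients.
This module evaluates that equation and synthesises timestamped emf traces
for the two experiment designs the inverse pipeline consumes: stepwise
serial dilutions (calibration curves) and baseline-then-spike recordings
(matrix validation), with replicate electrodes, additive white noise,
linear drift and between-electrode offset/slope variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chem import (
    FARADAY,
    R_GAS,
    ElectrolyteComposition,
    IonSpecies,
    activities,
    activity_coefficient,
    ionic_strength,
)

__all__ = [
    "nernstian_slope",
    "SensorParams",
    "DilutionProtocol",
    "SpikeProtocol",
    "NoiseModel",
    "TimeTrace",
    "nikolsky_emf",
    "simulate_dilution_trace",
    "simulate_spike_trace",
]


def nernstian_slope(charge: int = 1, temperature_K: float = 298.15) -> float:
    """Theoretical Nernstian slope 2.303*RT/zF in mV per decade.

    59.16 mV/decade for a monovalent cation at 25 degC.
    """
    if charge == 0:
        raise ValueError("charge must be nonzero")
    return 1000.0 * math.log(10.0) * R_GAS * temperature_K / (charge * FARADAY)


@dataclass(frozen=True)
class SensorParams:
    """Ground-truth electrode parameters.

    ``slope_mV_per_decade`` overrides the theoretical Nernstian slope to
    emulate sub-Nernstian electrodes; ``selectivities`` maps interfering
    ions to linear-scale k_ij (all positive).
    """

    primary_ion: IonSpecies
    E0_mV: float = 0.0
    temperature_K: float = 298.15
    slope_mV_per_decade: float | None = None
    selectivities: Mapping[IonSpecies, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.temperature_K > 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.slope_mV_per_decade == 0:
            raise ValueError("slope_factor must be nonzero")
        for ion, k in self.selectivities.items():
            if not k > 0:
                raise ValueError(f"selectivity for {ion.name!r} must be > 0, got {k}")

    @property
    def slope(self) -> float:
        """Effective slope in mV/decade (override or theoretical)."""
        if self.slope_mV_per_decade is not None:
            return self.slope_mV_per_decade
        return nernstian_slope(self.primary_ion.charge, self.temperature_K)

    def with_perturbation(self, d_E0: float, d_slope: float) -> "SensorParams":
        """A copy with offset/slope shifted — one replicate electrode."""
        return SensorParams(
            self.primary_ion,
            self.E0_mV + d_E0,
            self.temperature_K,
            self.slope + d_slope,
            self.selectivities,
        )

    def interference_sum(self, interferer_activities: Mapping[IonSpecies, float]) -> float:
        """sum_j k_ij * a_j^(z_i/z_j) over ions with a selectivity entry.

        Matching is by ion name; ions the electrode has no selectivity
        coefficient for are treated as fully rejected (k = 0).
        """
        by_name = {ion.name: k for ion, k in self.selectivities.items()}
        z_i = self.primary_ion.charge
        total = 0.0
        for ion, a_j in interferer_activities.items():
            if ion.name == self.primary_ion.name:
                continue
            k = by_name.get(ion.name)
            if k is None or a_j == 0:
                continue
            if a_j < 0:
                raise ValueError(f"activity of {ion.name!r} must be >= 0, got {a_j}")
            total += k * a_j ** (z_i / ion.charge)
        return total


def nikolsky_emf(
    params: SensorParams,
    a_primary: float,
    interferer_activities: Mapping[IonSpecies, float] | None = None,
) -> float:
    """Evaluate the Nikolsky-Eisenman equation, in mV.

    Raises a ``ValueError`` when the logarithm argument is not positive —
    a fully selective electrode in a sample without its primary ion has no
    defined potential, rather than minus infinity.
    """
    if a_primary < 0:
        raise ValueError(f"primary-ion activity must be >= 0, got {a_primary}")
    arg = a_primary + params.interference_sum(interferer_activities or {})
    if arg <= 0:
        names = sorted(ion.name for ion in (interferer_activities or {}))
        raise ValueError(
            "emf undefined: zero primary-ion activity and no sensed interference "
            f"(interferers present: {names or 'none'})"
        )
    return params.E0_mV + params.slope * math.log10(arg)


@dataclass(frozen=True)
class DilutionProtocol:
    """Stepwise serial dilution: hold each level for ``dwell_s`` seconds.

    ``levels`` are primary-ion concentrations in mol/L, strictly
    decreasing (the experiment dilutes).  ``background`` holds fixed
    interfering electrolytes present at every level.
    """

    levels: tuple[float, ...]
    dwell_s: float = 60.0
    background: ElectrolyteComposition = field(default_factory=ElectrolyteComposition)

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(float(c) for c in self.levels))
        if len(self.levels) < 1 or any(c <= 0 for c in self.levels):
            raise ValueError("levels must be positive concentrations")
        if any(b >= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError("levels must be strictly decreasing")
        if not self.dwell_s > 0:
            raise ValueError("dwell must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.levels) * self.dwell_s


@dataclass(frozen=True)
class SpikeProtocol:
    """Baseline recording followed by standard-addition spikes.

    Each spike adds ``added_mol_per_L`` of the primary ion at ``time_s``
    (cumulative).  Dilution by the spike volume is neglected.
    """

    baseline_s: float = 60.0
    spikes: tuple[tuple[float, float], ...] = ()
    background: ElectrolyteComposition = field(default_factory=ElectrolyteComposition)
    final_dwell_s: float = 60.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "spikes", tuple((float(t), float(c)) for t, c in self.spikes)
        )
        if not self.baseline_s > 0:
            raise ValueError("baseline duration must be positive")
        times = [t for t, _ in self.spikes]
        if any(t < self.baseline_s for t in times):
            raise ValueError("spike times must be >= baseline duration")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("spike times must be strictly increasing")
        if any(c <= 0 for _, c in self.spikes):
            raise ValueError("spike additions must be positive")

    @property
    def duration_s(self) -> float:
        last = self.spikes[-1][0] if self.spikes else self.baseline_s
        return last + self.final_dwell_s


@dataclass(frozen=True)
class NoiseModel:
    """Measurement and replicate-variation model for synthetic traces.

    ``sd_mV`` is additive white noise per sample; ``drift_mV_per_s`` a
    linear baseline drift; the two ``electrode_*`` spreads are drawn once
    per replicate electrode and emulate fabrication variability (the
    source of the "slope 55.14 +/- 4.44 mV/decade over n = 5 electrodes"
    style of reporting).
    """

    sd_mV: float = 0.0
    drift_mV_per_s: float = 0.0
    electrode_offset_sd_mV: float = 0.0
    electrode_slope_sd_mV: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for label in ("sd_mV", "electrode_offset_sd_mV", "electrode_slope_sd_mV"):
            if getattr(self, label) < 0:
                raise ValueError(f"{label} must be >= 0")


@dataclass
class TimeTrace:
    """Timestamped emf record for one electrode."""

    electrode_id: str
    time_s: np.ndarray
    emf_mV: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.emf_mV = np.asarray(self.emf_mV, dtype=float)
        if self.time_s.shape != self.emf_mV.shape:
            raise ValueError("time and emf arrays must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError(f"trace {self.electrode_id!r}: times must strictly increase")
        if not np.all(np.isfinite(self.emf_mV)):
            raise ValueError(f"trace {self.electrode_id!r}: emf must be finite")

    def __len__(self) -> int:
        return len(self.time_s)


def _primary_activity(
    conc: float,
    params: SensorParams,
    background: ElectrolyteComposition,
    activity_model: str,
) -> float:
    if activity_model == "none":
        return conc
    # Primary ion assumed added as a 1:1 salt with a monovalent counter-ion.
    z = params.primary_ion.charge
    I = ionic_strength(background) + conc * abs(z) * (abs(z) + 1) / 2.0
    return conc * activity_coefficient(z, I)


def _replicates(
    params: SensorParams, noise: NoiseModel, n_electrodes: int, rng: np.random.Generator
) -> list[tuple[str, SensorParams]]:
    if n_electrodes < 1:
        raise ValueError("n_electrodes must be >= 1")
    out = []
    for i in range(n_electrodes):
        d_e0 = rng.normal(0.0, noise.electrode_offset_sd_mV) if noise.electrode_offset_sd_mV else 0.0
        d_sl = rng.normal(0.0, noise.electrode_slope_sd_mV) if noise.electrode_slope_sd_mV else 0.0
        out.append((f"E{i + 1}", params.with_perturbation(d_e0, d_sl)))
    return out


def _emit(
    electrode_id: str,
    times: np.ndarray,
    ideal_of_t: np.ndarray,
    noise: NoiseModel,
    rng: np.random.Generator,
    metadata: dict,
) -> TimeTrace:
    emf = ideal_of_t + noise.drift_mV_per_s * times
    if noise.sd_mV:
        emf = emf + rng.normal(0.0, noise.sd_mV, size=times.shape)
    return TimeTrace(electrode_id, times, emf, metadata)


def _step_response(
    times: np.ndarray,
    change_times: Sequence[float],
    targets: Sequence[float],
    settling_tau_s: float,
) -> np.ndarray:
    """Piecewise-constant target emf with optional first-order settling."""
    idx = np.searchsorted(change_times, times, side="right") - 1
    idx = np.clip(idx, 0, len(targets) - 1)
    out = np.asarray(targets, dtype=float)[idx]
    if settling_tau_s > 0:
        for k in range(1, len(targets)):
            m = idx == k
            if not np.any(m):
                continue
            dt = times[m] - change_times[k]
            out[m] = targets[k] + (targets[k - 1] - targets[k]) * np.exp(
                -dt / settling_tau_s
            )
    return out


def simulate_dilution_trace(
    protocol: DilutionProtocol,
    params: SensorParams,
    noise: NoiseModel = NoiseModel(),
    n_electrodes: int = 1,
    sample_interval_s: float = 1.0,
    activity_model: str = "none",
    settling_tau_s: float = 0.0,
) -> list[TimeTrace]:
    """Synthesise stepwise-dilution emf traces for replicate electrodes.

    Each electrode's offset and slope perturbations are drawn once; each
    dilution level then contributes a dwell-long plateau at its
    Nikolsky-Eisenman emf, with white noise and linear drift on top.
    Fixed seed implies bitwise-reproducible output.
    """
    rng = np.random.default_rng(noise.seed)
    bg_act = activities(protocol.background, activity_model)
    times = np.arange(0.0, protocol.duration_s, sample_interval_s)
    change_times = [i * protocol.dwell_s for i in range(len(protocol.levels))]
    meta = {"protocol": "dilution", "levels_mol_per_L": list(protocol.levels),
            "dwell_s": protocol.dwell_s}
    traces = []
    for electrode_id, params_e in _replicates(params, noise, n_electrodes, rng):
        plateaus = [
            nikolsky_emf(
                params_e,
                _primary_activity(c, params_e, protocol.background, activity_model),
                bg_act,
            )
            for c in protocol.levels
        ]
        ideal = _step_response(times, change_times, plateaus, settling_tau_s)
        traces.append(_emit(electrode_id, times, ideal, noise, rng, dict(meta)))
    return traces


def simulate_spike_trace(
    protocol: SpikeProtocol,
    params: SensorParams,
    noise: NoiseModel = NoiseModel(),
    n_electrodes: int = 1,
    sample_interval_s: float = 1.0,
    activity_model: str = "none",
    settling_tau_s: float = 0.0,
) -> list[TimeTrace]:
    """Synthesise baseline-then-spike traces.

    The baseline emf comes from the background interference alone, so the
    background must contain ions the electrode senses (otherwise the
    baseline potential is undefined and a ``ValueError`` is raised).  Each
    spike raises the primary-ion concentration cumulatively and the emf
    steps up accordingly.
    """
    rng = np.random.default_rng(noise.seed)
    bg_act = activities(protocol.background, activity_model)
    times = np.arange(0.0, protocol.duration_s, sample_interval_s)
    change_times = [0.0] + [t for t, _ in protocol.spikes]
    concs = [0.0] + list(np.cumsum([c for _, c in protocol.spikes]))
    meta = {"protocol": "spike", "baseline_s": protocol.baseline_s,
            "spikes": [list(s) for s in protocol.spikes]}
    traces = []
    for electrode_id, params_e in _replicates(params, noise, n_electrodes, rng):
        plateaus = [
            nikolsky_emf(
                params_e,
                _primary_activity(c, params_e, protocol.background, activity_model),
                bg_act,
            )
            for c in concs
        ]
        ideal = _step_response(times, change_times, plateaus, settling_tau_s)
        traces.append(_emit(electrode_id, times, ideal, noise, rng, dict(meta)))
    return traces
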