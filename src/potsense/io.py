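"""File formats and run configuration.

Traces travel as long-format delimited text with the fixed header
``time_s,emf_mV,electrode_id`` — one file per experiment, replicate
electrodes stacked.  Run configurations are YAML (or JSON, which YAML
subsumes) validated against pydantic schemas that reject unknown keys, so
a typo in a config fails before any computation starts.
"""

from __future__ import annotations

import csv
import os
import re
import tempfile
from pathlib import Path
from typing import Literal, Sequence, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .chem import ElectrolyteComposition, IonSpecies, load_composition
from .model import DilutionProtocol, NoiseModel, SensorParams, SpikeProtocol, TimeTrace

__all__ = [
    "TRACE_HEADER",
    "read_trace",
    "write_trace",
    "parse_concentration",
    "RunConfig",
    "load_run_config",
    "atomic_write_text",
]

TRACE_HEADER = ("time_s", "emf_mV", "electrode_id")


class TraceParseError(ValueError):
    """Malformed trace file; message carries the offending line number."""


def read_trace(path: str | Path) -> list[TimeTrace]:
    """Read an experiment's traces, grouped by electrode id.

    Rows for one electrode need not be contiguous; times must increase
    strictly within each electrode.  Electrodes are returned in order of
    first appearance.
    """
    path = Path(path)
    times: dict[str, list[float]] = {}
    emfs: dict[str, list[float]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TraceParseError(f"{path}: empty file") from None
        if tuple(h.strip() for h in header) != TRACE_HEADER:
            raise TraceParseError(
                f"{path}: line 1: expected header {','.join(TRACE_HEADER)!r}, "
                f"got {','.join(header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise TraceParseError(f"{path}: line {lineno}: expected 3 fields, got {len(row)}")
            t_raw, e_raw, eid = (f.strip() for f in row)
            try:
                t, e = float(t_raw), float(e_raw)
            except ValueError:
                raise TraceParseError(
                    f"{path}: line {lineno}: non-numeric value in {row!r}"
                ) from None
            times.setdefault(eid, []).append(t)
            emfs.setdefault(eid, []).append(e)
    if not times:
        raise TraceParseError(f"{path}: no data rows")
    traces = []
    for eid in times:
        ts = times[eid]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise TraceParseError(
                f"{path}: electrode {eid!r}: times must strictly increase"
            )
        traces.append(TimeTrace(eid, ts, emfs[eid]))
    return traces


def write_trace(traces: Sequence[TimeTrace], path: str | Path) -> None:
    """Write traces in the long CSV format (atomic: write then rename)."""
    lines = [",".join(TRACE_HEADER)]
    for tr in traces:
        for t, e in zip(tr.time_s, tr.emf_mV):
            lines.append(f"{t:.10g},{e:.10g},{tr.electrode_id}")
    atomic_write_text(path, "\n".join(lines) + "\n")


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


_CONC_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*(M|mM|uM|µM|nM)?\s*$")
_CONC_SCALE = {None: 1.0, "M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}


def parse_concentration(text: str | float) -> float:
    """Parse ``"0.1mM"``-style strings (suffix M/mM/uM/nM) into mol/L.

    Bare numbers are taken as mol/L.
    """
    if isinstance(text, (int, float)):
        return float(text)
    m = _CONC_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse concentration {text!r}")
    return float(m.group(1)) * _CONC_SCALE[m.group(2)]


# ---------------------------------------------------------------------------
# Run configuration schemas
# ---------------------------------------------------------------------------


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class IonConfig(_Strict):
    name: str
    charge: int
    molar_mass: float | None = None

    def to_species(self) -> IonSpecies:
        return IonSpecies(self.name, self.charge, self.molar_mass)


class SelectivityEntry(_Strict):
    charge: int
    log10_k: float


class SensorConfig(_Strict):
    name: str = "sensor"
    E0_mV: float = 0.0
    temperature_K: float = 298.15
    slope_mV_per_decade: float | None = None
    primary_ion: IonConfig
    selectivities: dict[str, SelectivityEntry] = Field(default_factory=dict)

    def to_params(self) -> SensorParams:
        sel = {
            IonSpecies(name, entry.charge): 10.0**entry.log10_k
            for name, entry in self.selectivities.items()
        }
        return SensorParams(
            self.primary_ion.to_species(),
            self.E0_mV,
            self.temperature_K,
            self.slope_mV_per_decade,
            sel,
        )


class NoiseConfig(_Strict):
    sd_mV: float = 0.0
    drift_mV_per_s: float = 0.0
    electrode_offset_sd_mV: float = 0.0
    electrode_slope_sd_mV: float = 0.0

    def to_model(self, seed: int) -> NoiseModel:
        return NoiseModel(
            self.sd_mV,
            self.drift_mV_per_s,
            self.electrode_offset_sd_mV,
            self.electrode_slope_sd_mV,
            seed,
        )


class BackgroundIon(_Strict):
    charge: int
    mol_per_L: float


class BackgroundConfig(_Strict):
    """Fixed electrolyte background: a composition file, inline ions, or both."""

    composition_file: str | None = None
    ions: dict[str, BackgroundIon] = Field(default_factory=dict)
    pH: float | None = None

    def to_composition(self, base_dir: Path | None = None) -> ElectrolyteComposition:
        entries: dict[IonSpecies, float] = {}
        pH = self.pH
        neutrals: dict[str, float] = {}
        if self.composition_file:
            p = Path(self.composition_file)
            if base_dir is not None and not p.is_absolute():
                p = base_dir / p
            comp = load_composition(p)
            entries.update(comp.entries)
            neutrals.update(comp.neutral_solutes)
            if pH is None:
                pH = comp.pH
        for name, ion in self.ions.items():
            entries[IonSpecies(name, ion.charge)] = ion.mol_per_L
        return ElectrolyteComposition(entries, pH, neutrals)


class DilutionConfig(_Strict):
    kind: Literal["dilution"] = "dilution"
    levels_mol_per_L: list[float]
    dwell_s: float = 60.0
    background: BackgroundConfig = Field(default_factory=BackgroundConfig)

    def to_protocol(self, base_dir: Path | None = None) -> DilutionProtocol:
        return DilutionProtocol(
            tuple(self.levels_mol_per_L),
            self.dwell_s,
            self.background.to_composition(base_dir),
        )


class SpikeEvent(_Strict):
    time_s: float
    added_mol_per_L: float


class SpikeConfig(_Strict):
    kind: Literal["spike"] = "spike"
    baseline_s: float = 60.0
    spikes: list[SpikeEvent] = Field(default_factory=list)
    final_dwell_s: float = 60.0
    background: BackgroundConfig = Field(default_factory=BackgroundConfig)

    def to_protocol(self, base_dir: Path | None = None) -> SpikeProtocol:
        return SpikeProtocol(
            self.baseline_s,
            tuple((s.time_s, s.added_mol_per_L) for s in self.spikes),
            self.background.to_composition(base_dir),
            self.final_dwell_s,
        )


class RunConfig(_Strict):
    """Top-level configuration for a simulation / analysis run.

    ``seed`` is mandatory — simulations never draw silent entropy.
    """

    sensor: SensorConfig
    protocol: Union[DilutionConfig, SpikeConfig] = Field(discriminator="kind")
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    seed: int
    n_electrodes: int = Field(default=5, ge=1)
    sample_interval_s: float = Field(default=1.0, gt=0)
    activity_model: Literal["none", "debye_huckel"] = "none"
    settle_fraction: float = Field(default=0.5, gt=0, lt=1)
    settling_tau_s: float = Field(default=0.0, ge=0)

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if not (0 <= v < 2**32):
            raise ValueError("seed must lie in [0, 2**32)")
        return v


def load_run_config(path: str | Path) -> tuple[RunConfig, Path]:
    """Load and validate a run config; returns (config, directory).

    The directory is returned so relative ``composition_file`` paths can
    be resolved against the config's own location.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    return RunConfig.model_validate(raw), path.parent
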