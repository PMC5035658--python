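"""Domain types and I/O for scanning flow-cytometry pulse-shape data.

A scanning flow cytometer records, for every detected particle, a short
sampled intensity curve ("pulse shape") per optical channel instead of a
single integrated value.  The types here model one channel's curve
(:class:`PulseShape`), one particle (:class:`ParticleRecord`), and one
measured sample (:class:`SampleBatch`), together with a line-oriented JSON
interchange format and an FCS 3.1 export of integrated per-particle
parameters for use with conventional cytometry software.

Channels follow the CytoSense-style naming used throughout the package:
two forward-scatter detectors (``FWS_L``, ``FWS_R``), one sideward scatter
(``SWS``) and three fluorescence channels — yellow/green (``FLY``, the FDA
viability channel), orange (``FLO``) and red (``FLR``, the PI channel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "CHANNELS",
    "REQUIRED_CHANNELS",
    "TRUTH_LABELS",
    "AcquisitionSettings",
    "ParticleRecord",
    "PulseFormatError",
    "PulseShape",
    "SampleBatch",
    "SampleMetadata",
    "read_pulse_jsonl",
    "register_sensitivity_level",
    "sensitivity_gain",
    "validate_record",
    "write_pulse_jsonl",
]

#: All channel names a record may carry, in canonical order.
CHANNELS = ("FWS_L", "FWS_R", "SWS", "FLY", "FLO", "FLR")

#: Channels that must be present on every particle.
REQUIRED_CHANNELS = ("FWS_L", "SWS", "FLY", "FLO")

#: Ground-truth classes assignable by the simulator or manual annotation.
TRUTH_LABELS = (
    "non_germinated",
    "germinating",
    "germinated",
    "hypha_unbranched",
    "hypha_branched",
    "dead",
    "debris",
)

SCHEMA_TAG = "pulsegerm/1"

# Registry of known FLY sensitivity (gain) levels.  The gain is the
# multiplicative factor applied to fluorescence amplitudes relative to the
# low-sensitivity reference level; a higher gain extracts more signal from
# dim particles at the cost of clipping bright ones at the digitiser
# ceiling.  Values are package defaults: the instrument's true gain curve
# is not public.
_SENSITIVITY_REGISTRY: dict[int, float] = {50: 1.0, 65: 8.0}


def register_sensitivity_level(level: int, gain: float) -> None:
    """Register a FLY sensitivity level and its relative gain."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    _SENSITIVITY_REGISTRY[int(level)] = float(gain)


def sensitivity_gain(level: int) -> float:
    try:
        return _SENSITIVITY_REGISTRY[int(level)]
    except KeyError:
        raise KeyError(
            f"unknown sensitivity level {level!r}; "
            f"known levels: {sorted(_SENSITIVITY_REGISTRY)}"
        ) from None


def known_sensitivity_levels() -> tuple[int, ...]:
    return tuple(sorted(_SENSITIVITY_REGISTRY))


class PulseFormatError(ValueError):
    """Malformed pulse JSON-Lines input.  Carries a 1-based line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class PulseShape:
    """One channel's sampled intensity curve for one particle.

    Parameters
    ----------
    samples
        Non-negative intensities in arbitrary units (AU), ordered along the
        flow direction.
    sample_spacing
        Spatial distance between consecutive samples, in micrometres.
    baseline
        Noise-floor intensity (AU) below which samples carry no signal.
    """

    samples: np.ndarray
    sample_spacing: float = 0.5
    baseline: float = 0.0

    def __post_init__(self):
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=float)
        )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    def saturated_count(self, ceiling: float) -> int:
        """Number of samples clipped at the acquisition ceiling."""
        return int(np.count_nonzero(self.samples >= ceiling))

    def scaled(self, factor: float) -> "PulseShape":
        return replace(self, samples=self.samples * factor)


@dataclass(frozen=True)
class AcquisitionSettings:
    """Instrument settings shared by all particles of one measurement.

    ``dilution_factor`` is the total dilution between the culture broth and
    the measured suspension (default 500: a 1:10 step into buffer for
    staining followed by a 1:50 step before measurement).
    """

    fly_sensitivity_level: int = 50
    saturation_ceiling: float = 1023.0
    sample_spacing_um: float = 0.5
    dilution_factor: float = 500.0
    baseline: float = 0.0

    def __post_init__(self):
        if self.saturation_ceiling <= self.baseline or self.baseline < 0:
            raise ValueError("require saturation_ceiling > baseline >= 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.sample_spacing_um <= 0:
            raise ValueError("sample_spacing_um must be positive")
        # Raises KeyError for unregistered levels.
        sensitivity_gain(self.fly_sensitivity_level)

    @property
    def fly_gain(self) -> float:
        return sensitivity_gain(self.fly_sensitivity_level)


@dataclass
class ParticleRecord:
    """All channels plus optional ground truth for one detected particle."""

    particle_id: int
    channels: dict[str, PulseShape]
    truth_label: Optional[str] = None


@dataclass
class SampleMetadata:
    """Provenance of one measured sample."""

    time_h: float = 0.0
    batch_id: str = ""
    analyzed_volume_ul: float = 100.0

    def __post_init__(self):
        if self.analyzed_volume_ul <= 0:
            raise ValueError("analyzed volume must be positive")
        if self.time_h < 0:
            raise ValueError("sample time must be >= 0")


@dataclass
class SampleBatch:
    """Ordered particle records with shared acquisition settings."""

    records: list[ParticleRecord]
    acquisition: AcquisitionSettings = field(default_factory=AcquisitionSettings)
    metadata: SampleMetadata = field(default_factory=SampleMetadata)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ParticleRecord]:
        return iter(self.records)


def validate_record(
    record: ParticleRecord, settings: AcquisitionSettings
) -> list[str]:
    """Check a particle record against the type invariants.

    Returns a list of human-readable violations (empty when the record is
    well formed); violations are data, not exceptions, so a batch can be
    screened without aborting.
    """
    violations: list[str] = []
    for name in REQUIRED_CHANNELS:
        if name not in record.channels:
            violations.append(f"missing required channel {name}")
    spacings = set()
    for name, pulse in record.channels.items():
        if name not in CHANNELS:
            violations.append(f"unknown channel {name}")
        if pulse.n_samples < 1:
            violations.append(f"{name}: needs at least 1 sample")
        if not np.all(np.isfinite(pulse.samples)):
            violations.append(f"{name}: samples must be finite")
        elif np.any(pulse.samples < 0):
            violations.append(f"{name}: samples must be >= 0")
        if pulse.sample_spacing <= 0:
            violations.append(f"{name}: sample_spacing must be positive")
        spacings.add(pulse.sample_spacing)
    if len(spacings) > 1:
        violations.append(
            "sample_spacing differs between channels: "
            + ", ".join(f"{s:g}" for s in sorted(spacings))
        )
    if record.truth_label is not None and record.truth_label not in TRUTH_LABELS:
        violations.append(f"unknown truth_label {record.truth_label!r}")
    return violations


# ---------------------------------------------------------------------------
# JSON-Lines interchange format
#
# Line 1:   {"schema": "pulsegerm/1", "acquisition": {...}, "metadata": {...}}
# Line 2+:  {"id": <int>, "channels": {"FWS_L": [...], ...}, "truth": <str>?}
# ---------------------------------------------------------------------------


def write_pulse_jsonl(batch: SampleBatch, path) -> None:
    """Write a batch in the pulse JSON-Lines format (header + one particle
    per line).  Floats are written in round-trip-safe decimal text."""
    acq = batch.acquisition
    header = {
        "schema": SCHEMA_TAG,
        "acquisition": {
            "fly_sensitivity_level": acq.fly_sensitivity_level,
            "saturation_ceiling": acq.saturation_ceiling,
            "sample_spacing_um": acq.sample_spacing_um,
            "dilution_factor": acq.dilution_factor,
            "baseline": acq.baseline,
        },
        "metadata": {
            "time_h": batch.metadata.time_h,
            "batch_id": batch.metadata.batch_id,
            "analyzed_volume_ul": batch.metadata.analyzed_volume_ul,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps(header) + "\n")
        for record in batch.records:
            obj = {
                "id": record.particle_id,
                "channels": {
                    name: record.channels[name].samples.tolist()
                    for name in CHANNELS
                    if name in record.channels
                },
            }
            if record.truth_label is not None:
                obj["truth"] = record.truth_label
            fh.write(json.dumps(obj) + "\n")


def read_pulse_jsonl(path) -> SampleBatch:
    """Read a pulse JSON-Lines file written by :func:`write_pulse_jsonl`.

    Raises :class:`PulseFormatError` carrying the 1-based line number of
    the first malformed line; a missing or foreign header is an error.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.strip():
            raise PulseFormatError("missing header object", line=1)
        try:
            header = json.loads(first)
        except json.JSONDecodeError as exc:
            raise PulseFormatError(f"invalid JSON header: {exc}", line=1) from exc
        if not isinstance(header, dict) or header.get("schema") != SCHEMA_TAG:
            raise PulseFormatError(
                f"expected header with schema {SCHEMA_TAG!r}", line=1
            )
        acq_d = header.get("acquisition", {})
        meta_d = header.get("metadata", {})
        try:
            acquisition = AcquisitionSettings(**acq_d)
            metadata = SampleMetadata(**meta_d)
        except (TypeError, ValueError, KeyError) as exc:
            raise PulseFormatError(f"bad header fields: {exc}", line=1) from exc

        records: list[ParticleRecord] = []
        seen_ids: set[int] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise PulseFormatError(
                    f"invalid JSON: {exc}", line=lineno
                ) from exc
            if not isinstance(obj, dict) or "id" not in obj or "channels" not in obj:
                raise PulseFormatError(
                    "particle object needs 'id' and 'channels'", line=lineno
                )
            pid = obj["id"]
            if pid in seen_ids:
                raise PulseFormatError(
                    f"duplicate particle id {pid}", line=lineno
                )
            seen_ids.add(pid)
            channels = {
                name: PulseShape(
                    np.asarray(samples, dtype=float),
                    sample_spacing=acquisition.sample_spacing_um,
                    baseline=acquisition.baseline,
                )
                for name, samples in obj["channels"].items()
            }
            records.append(
                ParticleRecord(
                    particle_id=pid,
                    channels=channels,
                    truth_label=obj.get("truth"),
                )
            )
    return SampleBatch(records=records, acquisition=acquisition, metadata=metadata)


def write_fcs_integrated(batch: SampleBatch, features, path) -> None:
    """Export integrated per-particle parameters as an FCS 3.1 file.

    ``features`` is a sequence of :class:`~pulsegerm.features.FeatureVector`
    (or a DataFrame with the feature columns), one per record in ``batch``.
    Written parameters are the eight scalar features; event count equals
    the record count.  Write-only: the package does not read FCS.
    """
    from . import features as _features
    from .fcs import write_fcs

    table = _features.as_frame(features)
    if len(table) != len(batch.records):
        raise ValueError(
            f"feature/record count mismatch: {len(table)} features "
            f"for {len(batch.records)} records"
        )
    params = [c for c in _features.SCALAR_FEATURES]
    data = table[params].to_numpy(dtype=np.float32)
    write_fcs(path, params, data)
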