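"""Reading, validation and calibration of raw pressure-transducer recordings.

The weight-drop TBI rig records the analog output of an automotive fuel-line
pressure transducer through a 10-bit Arduino ADC.  A recording is one weight
drop: integer counts in [0, 1023] sampled against a millisecond clock,
triggered by a photoresistor when the weight enters the guide tube.

Counts are converted to kilopascals through a fixed three-step chain:

    voltage = 5 * output / 1023          (ADC full scale 5 V)
    PSI     = (voltage - 0.5) * 37.5     (transducer: 0.5 V offset, 37.5 PSI/V)
    kPa     = PSI * 6.895

The composition is affine in the raw count.  Counts whose implied voltage is
below the 0.5 V sensor offset map to negative pressure; those samples are
retained (they carry baseline information) but flagged so rail artifacts stay
auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np

__all__ = [
    "ADC_MAX",
    "ADC_ZERO_OFFSET",
    "KPA_PER_COUNT",
    "DeviceConfig",
    "RawTrace",
    "PressureTrace",
    "adc_to_kpa",
    "kpa_to_adc",
    "convert_trace",
    "read_raw_trace",
    "write_raw_trace",
    "write_pressure_trace",
]

#: 10-bit ADC rail.
ADC_MAX = 1023
#: full-scale ADC reference voltage [V]
_ADC_VOLTS = 5.0
#: transducer zero-pressure output [V]
_VOLT_OFFSET = 0.5
#: transducer gain [PSI per V]
_PSI_PER_VOLT = 37.5
#: unit conversion
_KPA_PER_PSI = 6.895
#: ADC count at which the transducer reads exactly zero pressure (0.5 V).
ADC_ZERO_OFFSET = _VOLT_OFFSET * ADC_MAX / _ADC_VOLTS  # 102.3
#: pressure resolution of one ADC step [kPa]
KPA_PER_COUNT = _KPA_PER_PSI * _PSI_PER_VOLT * _ADC_VOLTS / ADC_MAX

_HOLDERS = ("clamp", "foam_block")


@dataclass(frozen=True)
class DeviceConfig:
    """Physical configuration of one weight-drop setup.

    Parameters
    ----------
    syringe_volume_ml
        Syringe barrel size; the rig uses 10 ml or 20 ml syringes.
    holder
        ``"clamp"`` (three-prong clamp on a stand) or ``"foam_block"``
        (rigid drilled foam block); the holder changes transmitted pressure.
    drop_mass_g
        Mass of the calibration weight dropped down the guide tube [g].
    drop_height_cm
        Guide-tube drop height [cm].
    barrel_diameter_mm
        Inner barrel diameter [mm]; needed for the static Pascal's-law
        calibration, not printed on the syringe.
    media_volume_ml
        Volume of E3 media in the barrel [ml].
    guide_tube_height_cm
        Height of the paper guide tube, if different from drop height [cm].
    """

    syringe_volume_ml: float
    holder: str
    drop_mass_g: float
    drop_height_cm: float
    barrel_diameter_mm: float
    media_volume_ml: float = 1.0
    guide_tube_height_cm: float | None = None

    def __post_init__(self) -> None:
        if self.syringe_volume_ml not in (10, 20):
            raise ValueError(
                f"syringe_volume_ml must be 10 or 20, got {self.syringe_volume_ml}"
            )
        if self.holder not in _HOLDERS:
            raise ValueError(f"holder must be one of {_HOLDERS}, got {self.holder!r}")
        if self.drop_mass_g <= 0:
            raise ValueError(f"drop_mass_g must be > 0, got {self.drop_mass_g}")
        if self.drop_height_cm <= 0:
            raise ValueError(f"drop_height_cm must be > 0, got {self.drop_height_cm}")
        if self.barrel_diameter_mm <= 0:
            raise ValueError(
                f"barrel_diameter_mm must be > 0, got {self.barrel_diameter_mm}"
            )

    def to_dict(self) -> dict:
        d = {
            "syringe_volume_ml": self.syringe_volume_ml,
            "holder": self.holder,
            "drop_mass_g": self.drop_mass_g,
            "drop_height_cm": self.drop_height_cm,
            "barrel_diameter_mm": self.barrel_diameter_mm,
            "media_volume_ml": self.media_volume_ml,
        }
        if self.guide_tube_height_cm is not None:
            d["guide_tube_height_cm"] = self.guide_tube_height_cm
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DeviceConfig":
        known = {
            "syringe_volume_ml": float,
            "holder": str,
            "drop_mass_g": float,
            "drop_height_cm": float,
            "barrel_diameter_mm": float,
            "media_volume_ml": float,
            "guide_tube_height_cm": float,
        }
        kwargs = {}
        for key, conv in known.items():
            if key in d:
                kwargs[key] = conv(d[key])
        return cls(**kwargs)


def _validate_samples(times_ms: np.ndarray, values: np.ndarray, what: str) -> None:
    if times_ms.ndim != 1 or values.ndim != 1 or len(times_ms) != len(values):
        raise ValueError(f"{what}: times and values must be 1-D and equal length")
    if len(times_ms) < 2:
        raise ValueError(f"{what}: need at least 2 samples, got {len(times_ms)}")
    if not np.all(np.diff(times_ms) > 0):
        bad = int(np.flatnonzero(np.diff(times_ms) <= 0)[0]) + 1
        raise ValueError(f"{what}: times not strictly increasing at sample {bad}")


@dataclass(frozen=True)
class RawTrace:
    """One weight-drop recording in raw ADC counts.

    ``times_ms`` is referenced to the photoresistor trigger (t = 0); the
    nominal recording spans 1000 ms but longer captures are accepted.
    Counts may be float (e.g. an un-quantized simulation) but must lie on
    the rail interval [0, 1023].
    """

    times_ms: np.ndarray
    adc: np.ndarray
    device: DeviceConfig
    drop_index: int = 1
    trigger_time_ms: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_ms", np.asarray(self.times_ms, dtype=float))
        object.__setattr__(self, "adc", np.asarray(self.adc, dtype=float))
        _validate_samples(self.times_ms, self.adc, "RawTrace")
        if np.any((self.adc < 0) | (self.adc > ADC_MAX)):
            bad = self.adc[(self.adc < 0) | (self.adc > ADC_MAX)][0]
            raise ValueError(f"ADC output {bad} outside [0, {ADC_MAX}]")
        if self.drop_index < 1:
            raise ValueError(f"drop_index must be >= 1, got {self.drop_index}")

    def __len__(self) -> int:
        return len(self.times_ms)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RawTrace):
            return NotImplemented
        return (
            np.array_equal(self.times_ms, other.times_ms)
            and np.array_equal(self.adc, other.adc)
            and self.device == other.device
            and self.drop_index == other.drop_index
            and self.trigger_time_ms == other.trigger_time_ms
        )


@dataclass(frozen=True)
class PressureTrace:
    """A calibrated recording in kPa, with conversion provenance.

    ``below_zero`` flags samples whose implied transducer voltage was below
    the 0.5 V offset (negative kPa); they are kept, never clipped.
    """

    times_ms: np.ndarray
    pressure_kpa: np.ndarray
    device: DeviceConfig
    below_zero: np.ndarray = field(default=None)  # type: ignore[assignment]
    drop_index: int = 1
    conversion_record: dict = field(
        default_factory=lambda: {
            "adc_volts": _ADC_VOLTS,
            "volt_offset": _VOLT_OFFSET,
            "psi_per_volt": _PSI_PER_VOLT,
            "kpa_per_psi": _KPA_PER_PSI,
        }
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_ms", np.asarray(self.times_ms, dtype=float))
        object.__setattr__(
            self, "pressure_kpa", np.asarray(self.pressure_kpa, dtype=float)
        )
        _validate_samples(self.times_ms, self.pressure_kpa, "PressureTrace")
        if not np.all(np.isfinite(self.pressure_kpa)):
            raise ValueError("pressure values must be finite")
        if self.below_zero is None:
            object.__setattr__(self, "below_zero", self.pressure_kpa < 0.0)
        else:
            object.__setattr__(
                self, "below_zero", np.asarray(self.below_zero, dtype=bool)
            )

    def __len__(self) -> int:
        return len(self.times_ms)

    @property
    def duration_ms(self) -> float:
        return float(self.times_ms[-1] - self.times_ms[0])


def adc_to_kpa(output: Union[float, Iterable[float]]):
    """Convert raw transducer ADC counts to pressure in kPa.

    Applies ``kPa = 6.895 * 37.5 * (5*output/1023 - 0.5)`` exactly, with no
    rounding or clipping.  Accepts a scalar or array; counts below the
    102.3-count sensor offset yield negative kPa.

    Raises
    ------
    ValueError
        If any count lies outside [0, 1023].
    """
    arr = np.asarray(output, dtype=float)
    if np.any((arr < 0) | (arr > ADC_MAX)):
        bad = arr[(arr < 0) | (arr > ADC_MAX)].flat[0]
        raise ValueError(f"ADC output {bad} outside [0, {ADC_MAX}]")
    kpa = _KPA_PER_PSI * _PSI_PER_VOLT * (_ADC_VOLTS * arr / ADC_MAX - _VOLT_OFFSET)
    return float(kpa) if np.isscalar(output) else kpa


def kpa_to_adc(pressure_kpa: Union[float, Iterable[float]]):
    """Inverse of :func:`adc_to_kpa`; returns unclipped float counts."""
    arr = np.asarray(pressure_kpa, dtype=float)
    counts = (arr / (_KPA_PER_PSI * _PSI_PER_VOLT) + _VOLT_OFFSET) * ADC_MAX / _ADC_VOLTS
    return float(counts) if np.isscalar(pressure_kpa) else counts


def convert_trace(raw: RawTrace) -> PressureTrace:
    """Calibrate a :class:`RawTrace` to kPa, element-wise and loss-free.

    Times are preserved exactly; below-offset samples are flagged, not
    clipped, so baseline estimation downstream can see the true signal.
    """
    pressure = adc_to_kpa(raw.adc)
    return PressureTrace(
        times_ms=raw.times_ms.copy(),
        pressure_kpa=pressure,
        device=raw.device,
        below_zero=raw.adc < ADC_ZERO_OFFSET,
        drop_index=raw.drop_index,
    )


def _parse_metadata_comment(line: str, meta: dict) -> None:
    body = line.lstrip("#").strip()
    if "=" in body:
        key, _, value = body.partition("=")
        meta[key.strip()] = value.strip()


def read_raw_trace(
    path: Union[str, Path],
    device: DeviceConfig | None = None,
    drop_index: int | None = None,
) -> RawTrace:
    """Read a raw trace CSV (``time_ms,adc_output``) into a :class:`RawTrace`.

    Dialect: plain UTF-8 CSV, two numeric columns, optional header row, and
    optional ``# key=value`` comment lines carrying device metadata (an
    Arduino serial-capture convention).  If ``device`` is None it is built
    from the embedded metadata.

    Raises
    ------
    ValueError
        For non-numeric rows, non-increasing time or out-of-range ADC
        counts; the message names the offending 1-based data row.
    """
    path = Path(path)
    times: list[float] = []
    counts: list[float] = []
    meta: dict = {}
    row_no = 0
    with path.open("r", encoding="utf-8") as fh:
        for raw_line in fh:
            line = raw_line.strip()
            if not line:
                continue
            if line.startswith("#"):
                _parse_metadata_comment(line, meta)
                continue
            fields = [f.strip() for f in line.split(",")]
            if row_no == 0:
                # optional header
                try:
                    float(fields[0])
                except ValueError:
                    continue
            row_no += 1
            if len(fields) < 2:
                raise ValueError(f"{path.name}: row {row_no}: expected 2 columns")
            try:
                t, v = float(fields[0]), float(fields[1])
            except ValueError:
                raise ValueError(
                    f"{path.name}: row {row_no}: non-numeric value in {fields[:2]}"
                ) from None
            if not 0 <= v <= ADC_MAX:
                raise ValueError(
                    f"{path.name}: row {row_no}: ADC output {v} outside [0, {ADC_MAX}]"
                )
            if times and t <= times[-1]:
                raise ValueError(
                    f"{path.name}: row {row_no}: time {t} not after {times[-1]}"
                )
            times.append(t)
            counts.append(v)
    if device is None:
        device = DeviceConfig.from_dict(meta)
    if drop_index is None:
        drop_index = int(meta.get("drop_index", 1))
    return RawTrace(
        times_ms=np.array(times),
        adc=np.array(counts),
        device=device,
        drop_index=drop_index,
        trigger_time_ms=float(meta.get("trigger_time_ms", 0.0)),
    )


def write_raw_trace(raw: RawTrace, path: Union[str, Path]) -> None:
    """Write a :class:`RawTrace` as CSV with device metadata comments.

    Uses ``repr`` floats so that read -> write -> read round-trips
    bit-identically.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for key, value in raw.device.to_dict().items():
            fh.write(f"# {key}={value}\n")
        fh.write(f"# drop_index={raw.drop_index}\n")
        fh.write(f"# trigger_time_ms={raw.trigger_time_ms!r}\n")
        fh.write("time_ms,adc_output\n")
        for t, v in zip(raw.times_ms, raw.adc):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def write_pressure_trace(trace: PressureTrace, path: Union[str, Path]) -> None:
    """Write a converted trace as CSV ``time_ms,pressure_kpa,flag``."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for key, value in trace.device.to_dict().items():
            fh.write(f"# {key}={value}\n")
        fh.write("time_ms,pressure_kpa,flag\n")
        for t, p, f in zip(trace.times_ms, trace.pressure_kpa, trace.below_zero):
            fh.write(f"{float(t)!r},{float(p)!r},{'below_zero' if f else ''}\n")


def flag_count(trace: PressureTrace) -> int:
    """Number of samples below the transducer's 0.5 V zero offset."""
    return int(np.count_nonzero(trace.below_zero))
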