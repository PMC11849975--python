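"""Pressure-wave segmentation and per-drop dose metrics.

A weight dropped onto the syringe plunger generates a primary pressure wave
and, because the weight bounces, a decaying train of secondary waves.  A
wave is the excursion from the first sample above baseline until the first
sample back at baseline.  Per drop we report the maximal pressure (global
trace maximum — the dose metric the phenotype models use), the segmented
waves with per-wave peak and mean, and start-to-start inter-wave intervals.
Across replicate drops of one configuration we report mean +/- SEM of the
maxima and their relative standard deviation (RSD = 100 * SD / mean), the
rig's consistency metric.

The rig is calibrated statically: a known mass resting on the plunger must
read, by Pascal's principle, weight / barrel cross-sectional area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trace_io import DeviceConfig, PressureTrace

__all__ = [
    "STANDARD_GRAVITY",
    "Wave",
    "DropSummary",
    "ReplicateSummary",
    "SegmentationParams",
    "estimate_baseline",
    "segment_waves",
    "summarize_drop",
    "summarize_replicates",
    "expected_static_pressure",
    "calibration_error",
    "potential_energy",
    "pe_ratio",
]

#: standard gravitational acceleration [m/s^2]
STANDARD_GRAVITY = 9.80665


@dataclass(frozen=True)
class Wave:
    """One baseline-to-baseline pressure excursion.

    ``start_ms`` is the time of the first sample above threshold;
    ``end_ms`` the time of the first subsequent sample back at or below it
    (or the last sample if the trace ends while the wave is open).  Peak and
    mean are computed over the above-threshold samples (uniform-sample
    mean).
    """

    start_ms: float
    end_ms: float
    peak_kpa: float
    mean_kpa: float
    index: int

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise ValueError(f"wave start {self.start_ms} must precede end {self.end_ms}")
        if self.peak_kpa < self.mean_kpa:
            raise ValueError("wave peak cannot be below its mean")
        if self.index < 1:
            raise ValueError("wave index starts at 1")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the wave-segmentation rule.

    ``exceedance_kpa`` is how far above baseline a sample must rise to open
    a wave; None selects ``max(3 * noise_sd, 1 kPa)`` from the baseline
    estimate.  ``min_duration_ms`` discards single-sample noise blips; set
    to 0 for the literal baseline-crossing rule.  ``baseline_window_ms``
    and ``baseline_mode`` control where the quiescent window is taken.
    """

    exceedance_kpa: float | None = None
    min_duration_ms: float = 1.0
    baseline_window_ms: float = 100.0
    baseline_mode: str = "trailing"

    def __post_init__(self) -> None:
        if self.exceedance_kpa is not None and self.exceedance_kpa <= 0:
            raise ValueError("exceedance_kpa must be > 0")
        if self.min_duration_ms < 0:
            raise ValueError("min_duration_ms must be >= 0")
        if self.baseline_mode not in ("trailing", "leading"):
            raise ValueError("baseline_mode must be 'trailing' or 'leading'")


@dataclass(frozen=True)
class DropSummary:
    """Dose metrics for one weight drop."""

    maximal_pressure_kpa: float
    waves: tuple[Wave, ...]
    baseline_kpa: float
    noise_sd_kpa: float
    device: DeviceConfig
    drop_index: int = 1

    @property
    def n_waves(self) -> int:
        return len(self.waves)

    @property
    def inter_wave_intervals_ms(self) -> tuple[float, ...]:
        """Start-to-start intervals between consecutive waves [ms]."""
        starts = [w.start_ms for w in self.waves]
        return tuple(np.diff(starts))

    @property
    def inter_wave_intervals_end_to_start_ms(self) -> tuple[float, ...]:
        """End-to-next-start intervals, the alternative timing convention."""
        return tuple(
            nxt.start_ms - cur.end_ms for cur, nxt in zip(self.waves, self.waves[1:])
        )


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean +/- SEM and RSD of maximal pressures over replicate drops."""

    n_drops: int
    mean_max_pressure_kpa: float
    sem_max_pressure_kpa: float
    rsd_percent: float
    max_pressures_kpa: tuple[float, ...] = field(default=())


def estimate_baseline(
    trace: PressureTrace,
    window_ms: float = 100.0,
    mode: str = "trailing",
) -> tuple[float, float]:
    """Estimate baseline pressure and noise SD from a quiescent window.

    By default the trailing ``window_ms`` of the trace is used (bounce
    ringing has decayed by the end of the nominal 1 s capture); ``mode =
    "leading"`` selects the pre-impact window instead for long recordings.

    Returns ``(baseline_kpa, noise_sd_kpa)`` — the sample mean and SD
    (ddof=1) over the window.

    Raises
    ------
    ValueError
        If the window covers fewer than 10 samples.
    """
    t = trace.times_ms
    if mode == "trailing":
        mask = t >= t[-1] - window_ms
    elif mode == "leading":
        mask = t <= t[0] + window_ms
    else:
        raise ValueError("mode must be 'trailing' or 'leading'")
    vals = trace.pressure_kpa[mask]
    if len(vals) < 10:
        raise ValueError(
            f"baseline window of {window_ms} ms covers only {len(vals)} samples; "
            "need at least 10"
        )
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


def segment_waves(
    trace: PressureTrace,
    baseline_kpa: float,
    exceedance_kpa: float,
    min_duration_ms: float = 1.0,
) -> list[Wave]:
    """Segment a trace into pressure waves by the baseline-crossing rule.

    A wave opens at the first sample with pressure strictly above
    ``baseline + exceedance`` and closes at the first subsequent sample at
    or below that threshold; peak and mean are taken over the open (above-
    threshold) samples.  Waves shorter than ``min_duration_ms`` are
    discarded as noise blips.  A flat trace yields no waves; a wave still
    open at the end of the trace is closed at the last sample.
    """
    if exceedance_kpa <= 0:
        raise ValueError("exceedance_kpa must be > 0")
    thr = baseline_kpa + exceedance_kpa
    t = trace.times_ms
    p = trace.pressure_kpa
    waves: list[Wave] = []
    open_start: int | None = None
    for i in range(len(p)):
        if open_start is None:
            if p[i] > thr:
                open_start = i
        elif p[i] <= thr:
            _close_wave(waves, t, p, open_start, i, min_duration_ms)
            open_start = None
    if open_start is not None:
        _close_wave(waves, t, p, open_start, len(p) - 1, min_duration_ms, truncated=True)
    return waves


def _close_wave(waves, t, p, start_idx, end_idx, min_duration_ms, truncated=False) -> None:
    # open interval excludes the closing (back-at-baseline) sample, but a
    # wave truncated by the end of the trace keeps its last sample
    stop = end_idx + 1 if truncated else end_idx
    above = p[start_idx:stop]
    if len(above) == 0:
        return
    start, end = float(t[start_idx]), float(t[end_idx])
    if end - start < min_duration_ms or end <= start:
        return
    waves.append(
        Wave(
            start_ms=start,
            end_ms=end,
            peak_kpa=float(np.max(above)),
            mean_kpa=float(np.mean(above)),
            index=len(waves) + 1,
        )
    )


def summarize_drop(
    trace: PressureTrace,
    params: SegmentationParams | None = None,
) -> DropSummary:
    """Compute per-drop dose metrics: global maximum, waves, intervals.

    The maximal pressure is the raw trace maximum and therefore does not
    depend on the segmentation parameters.
    """
    params = params or SegmentationParams()
    baseline, noise_sd = estimate_baseline(
        trace, window_ms=params.baseline_window_ms, mode=params.baseline_mode
    )
    exceedance = (
        params.exceedance_kpa
        if params.exceedance_kpa is not None
        else max(3.0 * noise_sd, 1.0)
    )
    waves = segment_waves(trace, baseline, exceedance, params.min_duration_ms)
    return DropSummary(
        maximal_pressure_kpa=float(np.max(trace.pressure_kpa)),
        waves=tuple(waves),
        baseline_kpa=baseline,
        noise_sd_kpa=noise_sd,
        device=trace.device,
        drop_index=trace.drop_index,
    )


def summarize_replicates(drops: list[DropSummary]) -> ReplicateSummary:
    """Mean, SEM and RSD of maximal pressures across replicate drops.

    SD uses the n-1 denominator; SEM = SD / sqrt(n); RSD = 100 * SD / mean.
    Requires at least two drops.
    """
    if len(drops) < 2:
        raise ValueError(f"need >= 2 drops for replicate statistics, got {len(drops)}")
    maxima = np.array([d.maximal_pressure_kpa for d in drops], dtype=float)
    mean = float(np.mean(maxima))
    sd = float(np.std(maxima, ddof=1))
    return ReplicateSummary(
        n_drops=len(drops),
        mean_max_pressure_kpa=mean,
        sem_max_pressure_kpa=sd / np.sqrt(len(drops)),
        rsd_percent=100.0 * sd / mean,
        max_pressures_kpa=tuple(maxima),
    )


def expected_static_pressure(mass_g: float, barrel_diameter_mm: float) -> float:
    """Pascal's-law pressure of a mass resting on the plunger [kPa].

    ``weight / cross-sectional area`` with g = 9.80665 m/s^2: the expected
    transducer reading during static calibration.
    """
    if mass_g < 0:
        raise ValueError("mass_g must be >= 0")
    if barrel_diameter_mm <= 0:
        raise ValueError("barrel_diameter_mm must be > 0")
    force_n = (mass_g / 1000.0) * STANDARD_GRAVITY
    area_m2 = np.pi * (barrel_diameter_mm / 2000.0) ** 2
    return force_n / area_m2 / 1000.0


def calibration_error(measured_kpa: float, expected_kpa: float) -> float:
    """Signed percent deviation of a measured reading from expectation."""
    if expected_kpa == 0:
        raise ValueError("expected_kpa must be nonzero")
    return 100.0 * (measured_kpa - expected_kpa) / expected_kpa


def potential_energy(mass_g: float, height_cm: float) -> float:
    """Gravitational potential energy of a weight before release [J]."""
    if mass_g < 0 or height_cm < 0:
        raise ValueError("mass and height must be >= 0")
    return (mass_g / 1000.0) * STANDARD_GRAVITY * (height_cm / 100.0)


def pe_ratio(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Potential energy of drop ``a`` as a percentage of drop ``b``.

    Each drop is ``(mass_g, height_cm)``.  Two configurations can deliver
    similar peak pressures at very different input energies — e.g. 200 g
    from 27 cm carries half the energy of 100 g from 108 cm — so this
    ratio separates dose settings that pressure alone conflates.
    """
    e_a = potential_energy(*a)
    e_b = potential_energy(*b)
    if e_b == 0:
        raise ValueError("reference drop has zero potential energy")
    return 100.0 * e_a / e_b
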