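"""Synthetic inputs with the structure the analysis pipeline assumes.

Three generators, all bit-reproducible given (config, seed):

* :func:`simulate_drop_trace` — a bouncing-weight pressure recording.  The
  weight hits the plunger at v0 = sqrt(2 g h); each bounce rebounds at a
  fixed restitution coefficient e, so impact k arrives at speed v0 * e^k
  and the flight between impacts k and k+1 lasts 2 * v0 * e^(k+1) / g.
  Pulse amplitude is proportional to impact speed — a modelling choice,
  not a constitutive law; it reproduces the qualitative monotone trends
  (heavier/higher -> larger pressure) without claiming absolute kPa for
  any physical device.  The kPa signal is pushed back through the
  transducer calibration to integer ADC counts, with Gaussian noise and
  optional quantization, so the result exercises the same ingestion path
  as real captures.

* :func:`simulate_activity` — per-larva binned activity with the biphasic
  dose structure of the assay: seizure-like high-activity bouts appear
  preferentially in a moderate-pressure band (roughly 90-300 kPa), while
  higher pressures suppress locomotion and produce minute-scale
  inactivity runs with probability logistic in dose.

* :func:`simulate_phenotypes` — Bernoulli outcomes from a stated logistic
  model in maximal pressure and drop count, the generative inverse of the
  fitted dose-response models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .behavior import ActivityTrace
from .dose_response import PhenotypeRecord
from .dosimetry import STANDARD_GRAVITY
from .trace_io import ADC_MAX, DeviceConfig, RawTrace, kpa_to_adc

__all__ = [
    "ImpactSimConfig",
    "BehaviorSimConfig",
    "PhenotypeSimConfig",
    "default_device",
    "simulate_drop_trace",
    "simulate_activity",
    "simulate_phenotypes",
    "bounce_amplitudes",
    "bounce_impact_times",
]


def default_device(**overrides) -> DeviceConfig:
    """The reference rig: 20 ml syringe in a clamp, 100 g from 108 cm."""
    params = dict(
        syringe_volume_ml=20,
        holder="clamp",
        drop_mass_g=100.0,
        drop_height_cm=108.0,
        barrel_diameter_mm=19.1,
        media_volume_ml=1.0,
    )
    params.update(overrides)
    return DeviceConfig(**params)


@dataclass(frozen=True)
class ImpactSimConfig:
    """Bouncing-weight pressure-trace simulator settings.

    ``pressure_per_velocity`` [kPa per m/s] sets the first-pulse amplitude
    from the impact speed; holder rigidity and syringe size act through
    this single multiplier.  The bounce train is truncated once a pulse
    falls below ``min_pulse_fraction`` of the first.  ``sample_dt_ms``
    defaults to 0.2 ms (5 kHz) and ``pulse_width_ms`` to 5 ms, which
    places simulated inter-wave intervals in the tens-of-milliseconds
    regime observed on the rig.
    """

    device: DeviceConfig = field(default_factory=default_device)
    restitution: float = 0.5
    pulse_shape: str = "half_sine"
    pulse_width_ms: float = 5.0
    pressure_per_velocity: float = 60.0
    min_pulse_fraction: float = 0.1
    noise_sd_kpa: float = 0.0
    adc_quantize: bool = True
    sample_dt_ms: float = 0.2
    duration_ms: float = 1000.0
    first_impact_ms: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.restitution < 1:
            raise ValueError("restitution must be in [0, 1)")
        if self.pulse_shape not in ("half_sine", "exp_decay"):
            raise ValueError("pulse_shape must be 'half_sine' or 'exp_decay'")
        if self.pulse_width_ms <= 0 or self.sample_dt_ms <= 0:
            raise ValueError("pulse_width_ms and sample_dt_ms must be > 0")
        if not 0 < self.min_pulse_fraction <= 1:
            raise ValueError("min_pulse_fraction must be in (0, 1]")


@dataclass(frozen=True)
class BehaviorSimConfig:
    """Dose-structured activity-trace simulator settings.

    Baseline per-bin activity is Normal(mean, sd) truncated at zero.
    Seizure bouts multiply baseline by ``seizure_gain`` and occur with a
    probability peaking inside ``seizure_band_kpa``; inactivity runs of at
    least 60 s occur per larva with probability logistic in dose,
    ``logistic(inactivity_b0 + inactivity_b1 * kPa)``.
    """

    n_per_group: int = 24
    baseline_mean: float = 2.0
    baseline_sd: float = 0.5
    seizure_gain: float = 5.0
    seizure_band_kpa: tuple[float, float] = (90.0, 300.0)
    seizure_peak_prob: float = 0.7
    inactivity_b0: float = -4.0
    inactivity_b1: float = 0.006
    recording_s: float = 1800.0
    bin_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        n_bins = self.recording_s / self.bin_s
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("recording_s must be a multiple of bin_s")


@dataclass(frozen=True)
class PhenotypeSimConfig:
    """Logistic phenotype-table simulator settings.

    ``doses`` lists (max_pressure_kpa, n_drops) conditions; each receives
    ``n_per_dose`` larvae with outcome probability
    ``logistic(b0 + b1_per_kpa * pressure + b2_per_drop * drops)``.
    """

    b0: float = -2.0
    b1_per_kpa: float = np.log(1.005)
    b2_per_drop: float = 0.0
    doses: tuple[tuple[float, int], ...] = (
        (33.0, 1),
        (150.0, 1),
        (300.0, 1),
        (600.0, 1),
        (1105.0, 1),
    )
    n_per_dose: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_dose < 1:
            raise ValueError("n_per_dose must be >= 1")


# ---------------------------------------------------------------------------
# bouncing-weight pressure traces

def _impact_velocity(height_cm: float) -> float:
    return float(np.sqrt(2.0 * STANDARD_GRAVITY * height_cm / 100.0))


def bounce_amplitudes(cfg: ImpactSimConfig) -> np.ndarray:
    """Pulse amplitudes [kPa] of the bounce train, geometric in restitution."""
    v0 = _impact_velocity(cfg.device.drop_height_cm)
    a0 = cfg.pressure_per_velocity * v0
    amps = [a0]
    if cfg.restitution > 0:
        frac = cfg.restitution
        while frac >= cfg.min_pulse_fraction:
            amps.append(a0 * frac)
            frac *= cfg.restitution
    return np.array(amps)


def bounce_impact_times(cfg: ImpactSimConfig) -> np.ndarray:
    """Impact times [ms]; flight after impact k lasts 2 v0 e^(k+1) / g."""
    v0 = _impact_velocity(cfg.device.drop_height_cm)
    n = len(bounce_amplitudes(cfg))
    times = [cfg.first_impact_ms]
    for k in range(1, n):
        flight_s = 2.0 * v0 * cfg.restitution**k / STANDARD_GRAVITY
        times.append(times[-1] + 1000.0 * flight_s)
    return np.array(times)


def simulate_drop_trace(cfg: ImpactSimConfig) -> RawTrace:
    """Simulate one weight-drop recording as a raw ADC trace.

    Pulse peaks are snapped to the sample grid so the peak sample carries
    the exact pulse amplitude; with quantization on and noise off, a
    round trip through calibration and segmentation recovers pulse count
    exactly and peaks to within one ADC step.  Amplitudes beyond the ADC
    rail saturate (clip) when quantizing, with a warning either way.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.sample_dt_ms
    amps = bounce_amplitudes(cfg)
    impacts = bounce_impact_times(cfg)
    # a slow bounce train can outlast the nominal capture; keep recording
    # until it has decayed, plus a quiescent tail for baseline estimation
    duration = max(cfg.duration_ms, impacts[-1] + cfg.pulse_width_ms + 200.0)
    t = np.arange(0.0, duration + dt / 2, dt)
    pressure = np.zeros_like(t)
    w = cfg.pulse_width_ms
    for amp, t_imp in zip(amps, impacts):
        # snap the pulse peak to the sample grid for loss-free peak readout
        t_peak = round((t_imp + w / 2.0) / dt) * dt
        if cfg.pulse_shape == "half_sine":
            lo, hi = t_peak - w / 2.0, t_peak + w / 2.0
            m = (t >= lo) & (t <= hi)
            pressure[m] += amp * np.sin(np.pi * (t[m] - lo) / w)
        else:  # exp_decay
            m = (t >= t_peak) & (t <= t_peak + 5.0 * w)
            pressure[m] += amp * np.exp(-(t[m] - t_peak) / w)

    if cfg.noise_sd_kpa > 0:
        pressure = pressure + rng.normal(0.0, cfg.noise_sd_kpa, size=len(t))

    counts = kpa_to_adc(pressure)
    n_sat = int(np.count_nonzero((counts < 0) | (counts > ADC_MAX)))
    if n_sat:
        warnings.warn(
            f"{n_sat} sample(s) exceed the ADC rail and saturate", stacklevel=2
        )
    counts = np.clip(counts, 0.0, float(ADC_MAX))
    if cfg.adc_quantize:
        counts = np.round(counts)
    return RawTrace(times_ms=t, adc=counts, device=cfg.device, drop_index=1)


# ---------------------------------------------------------------------------
# dose-structured behavior

def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def seizure_probability(cfg: BehaviorSimConfig, dose_kpa: float) -> float:
    """Probability a larva shows seizure bouts, peaking mid-band.

    A Gaussian bump centred on the middle of ``seizure_band_kpa`` with SD
    one quarter of the band width: near zero outside the band, maximal
    (``seizure_peak_prob``) at its centre — the biphasic detectability
    window of behavioural seizures.
    """
    lo, hi = cfg.seizure_band_kpa
    centre, sd = (lo + hi) / 2.0, (hi - lo) / 4.0
    return cfg.seizure_peak_prob * float(np.exp(-(((dose_kpa - centre) / sd) ** 2) / 2))


def suppression_factor(cfg: BehaviorSimConfig, dose_kpa: float) -> float:
    """Multiplier on baseline activity; exactly 1 at dose 0, falls toward 0
    at severe doses (normalized reversed logistic centred past the band)."""
    _, hi = cfg.seizure_band_kpa
    raw = 1.0 - _logistic((dose_kpa - 2.0 * hi) / (0.5 * hi))
    at_zero = 1.0 - _logistic(-2.0 * hi / (0.5 * hi))
    return raw / at_zero


def simulate_activity(
    cfg: BehaviorSimConfig,
    dose_kpa: float,
    group: str | None = None,
    id_prefix: str = "larva",
) -> list[ActivityTrace]:
    """Simulate one group of per-larva activity traces at a given dose."""
    rng = np.random.default_rng(cfg.seed)
    n_bins = int(round(cfg.recording_s / cfg.bin_s))
    edges = np.arange(n_bins + 1) * cfg.bin_s
    group = group if group is not None else f"{dose_kpa:g}kPa"
    p_seiz = seizure_probability(cfg, dose_kpa)
    p_inact = _logistic(cfg.inactivity_b0 + cfg.inactivity_b1 * dose_kpa)
    supp = suppression_factor(cfg, dose_kpa)

    traces = []
    for i in range(cfg.n_per_group):
        activity = np.maximum(
            rng.normal(cfg.baseline_mean * supp, cfg.baseline_sd, size=n_bins), 0.0
        )
        if rng.random() < p_seiz:
            for _ in range(rng.integers(1, 4)):
                start = int(rng.integers(0, max(n_bins - 10, 1)))
                length = int(rng.integers(3, 11))
                activity[start : start + length] *= cfg.seizure_gain
        if rng.random() < p_inact:
            min_bins = int(np.ceil(60.0 / cfg.bin_s))
            length = int(rng.integers(min_bins, min(3 * min_bins, n_bins) + 1))
            start = int(rng.integers(0, n_bins - length + 1))
            activity[start : start + length] = 0.0
        traces.append(
            ActivityTrace(
                larva_id=f"{id_prefix}_{group}_{i:03d}",
                group=group,
                well=f"W{i + 1:02d}",
                t_start_s=edges[:-1],
                t_end_s=edges[1:],
                activity=activity,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# logistic phenotype tables

def simulate_phenotypes(cfg: PhenotypeSimConfig) -> list[PhenotypeRecord]:
    """Draw Bernoulli outcomes from the stated logistic dose model."""
    rng = np.random.default_rng(cfg.seed)
    records = []
    for dose_idx, (pressure, n_drops) in enumerate(cfg.doses):
        p = _logistic(cfg.b0 + cfg.b1_per_kpa * pressure + cfg.b2_per_drop * n_drops)
        for i in range(cfg.n_per_dose):
            records.append(
                PhenotypeRecord(
                    larva_id=f"pheno_{dose_idx}_{i:03d}",
                    group=f"{pressure:g}kPa_{n_drops}drops",
                    outcome=int(rng.random() < p),
                    max_pressure_kpa=pressure,
                    n_drops=n_drops,
                )
            )
    return records
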