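import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from blastdose.trace_io import DeviceConfig, PressureTrace

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def device() -> DeviceConfig:
    return DeviceConfig(
        syringe_volume_ml=20,
        holder="clamp",
        drop_mass_g=100.0,
        drop_height_cm=108.0,
        barrel_diameter_mm=19.1,
    )


@pytest.fixture
def make_pressure_trace(device):
    """Build a PressureTrace from (times_ms, pressures_kpa)."""

    def _make(times_ms, pressures_kpa):
        return PressureTrace(
            times_ms=np.asarray(times_ms, dtype=float),
            pressure_kpa=np.asarray(pressures_kpa, dtype=float),
            device=device,
        )

    return _make


@pytest.fixture
def rectangular_pulse_trace(make_pressure_trace):
    """A trace of disjoint rectangular pulses on a flat baseline.

    pulses: list of (start_ms, width_ms, height_kpa); 1 ms sampling.
    """

    def _make(pulses, duration_ms=1000.0, baseline=0.0, dt=1.0):
        t = np.arange(0.0, duration_ms, dt)
        p = np.full_like(t, baseline)
        for start, width, height in pulses:
            p[(t >= start) & (t < start + width)] = baseline + height
        return make_pressure_trace(t, p)

    return _make


def brute_force_segment(times, pressures, threshold):
    """Literal open/close scan: open strictly above threshold, close at the
    first subsequent sample at or below it.  Returns (start_idx, end_idx,
    peak, mean) tuples; end_idx is the closing sample (or the last sample
    when the trace ends open, which is then included in the wave)."""
    out = []
    i, n = 0, len(pressures)
    while i < n:
        if pressures[i] > threshold:
            j = i
            while j < n and pressures[j] > threshold:
                j += 1
            if j < n:
                above = pressures[i:j]
                end = j
            else:
                above = pressures[i:n]
                end = n - 1
            out.append((i, end, max(above), sum(above) / len(above)))
            i = j + 1
        else:
            i += 1
    return out


def brute_force_runs(flags):
    """Maximal runs of truthy values as (first, last) index pairs."""
    runs, start = [], None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        if not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs
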