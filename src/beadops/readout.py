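"""Optical sensing path: LED -> chamber droplet -> lux sensor.

The colorimetric readout is a transmittance measurement through the
detection-chamber droplet.  Ambient light variation and component warm-up
produce a slowly varying multiplicative baseline drift, compensated by a
three-intensity protocol:

1. at instrument initialisation, a 10 s stabilisation window samples the
   open optical path 100 times at 10 Hz, digitally filtered and averaged to
   the reference baseline ``I_ref``;
2. immediately before the read, the same protocol recaptures the
   instantaneous background ``I_bg``;
3. the sample intensity ``I_raw`` is then sampled and filtered over 10 s,
   and the drift-compensated readout is

       I_readout = I_raw * I_ref / I_bg

   — the unique arrangement of the three intensities that exactly cancels
   a common multiplicative ambient factor.

Transmittance through the droplet follows a Beer-Lambert-style law
``I = I0 * 10**(-signal)`` in absorbance-equivalent units, so the readout
decreases monotonically with the assay signal.  The digital filter is a
moving median (window 5 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.ndimage import median_filter

from .errors import CalibrationError, ConfigError, MeasurementError

DEFAULT_DURATION_S = 10.0
DEFAULT_RATE_HZ = 10.0
DEFAULT_FILTER_WINDOW = 5


@dataclass(frozen=True)
class OpticalTrace:
    """One acquisition burst of raw sensor samples."""

    timestamps: np.ndarray
    intensities: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ConfigError("sampling rate must be > 0")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ConfigError("timestamps must be strictly increasing")


@dataclass(frozen=True)
class CalibrationContext:
    """Reference and instantaneous baselines for drift compensation."""

    i_ref: float
    i_bg: float
    filter_window: int = DEFAULT_FILTER_WINDOW

    def __post_init__(self) -> None:
        if self.i_ref <= 0:
            raise ConfigError("I_ref must be > 0")
        if self.i_bg < 0:
            raise ConfigError("I_bg must be >= 0")


@dataclass(frozen=True)
class ReadoutResult:
    """Filtered raw intensity and its drift-compensated value."""

    i_raw: float
    i_readout: float
    i_ref: float = float("nan")
    i_bg: float = float("nan")


@dataclass(frozen=True)
class DriftModel:
    """Multiplicative ambient drift plus additive sensor noise.

    The ambient factor ``g(t) = 1 + amplitude * sin(2*pi*t/period + phase)``
    multiplies the LED/ambient intensity ``i0`` (sensor units); Gaussian
    noise of SD ``noise_sd`` adds per sample.
    """

    i0: float = 1000.0
    amplitude: float = 0.05
    period_s: float = 300.0
    phase: float = 0.0
    noise_sd: float = 2.0

    def ambient(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.i0 * (1.0 + self.amplitude * np.sin(2 * np.pi * np.asarray(t) / self.period_s + self.phase))


def acquire(
    sensor: Callable[[np.ndarray], np.ndarray],
    duration_s: float = DEFAULT_DURATION_S,
    rate_hz: float = DEFAULT_RATE_HZ,
    filter_window: int = DEFAULT_FILTER_WINDOW,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
    t0: float = 0.0,
) -> tuple[OpticalTrace, float]:
    """Sample the optical path and return (trace, filtered mean intensity).

    ``sensor`` maps timestamps to noiseless intensity; ``round(duration *
    rate)`` samples are drawn (the default 10 s at 10 Hz gives 100), a
    moving median attenuates high-frequency components, and the arithmetic
    mean of the filtered samples is returned.
    """
    if duration_s <= 0 or rate_hz <= 0:
        raise ConfigError("duration and rate must be > 0")
    if filter_window < 1:
        raise ConfigError("filter window must be >= 1")
    n = round(duration_s * rate_hz)
    if n < 1:
        raise ConfigError("acquisition window shorter than one sample period")
    t = t0 + np.arange(n) / rate_hz
    raw = np.asarray(sensor(t), dtype=float)
    if rng is not None and noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd, size=n)
    filtered = median_filter(raw, size=filter_window, mode="nearest")
    return OpticalTrace(timestamps=t, intensities=raw, rate_hz=rate_hz), float(filtered.mean())


def calibrate(i_raw: float, context: CalibrationContext) -> float:
    """Drift-compensated readout ``I_readout = I_raw * I_ref / I_bg``.

    Multiplying both the raw and background intensities by a common
    ambient factor leaves the result unchanged; with ``I_bg = I_ref``
    (no drift) the calibration is the identity.
    """
    if context.i_bg <= 0:
        raise CalibrationError("background intensity I_bg must be > 0")
    return i_raw * context.i_ref / context.i_bg


def measure_chamber(
    chamber_droplet,
    assay_signal: float,
    drift: DriftModel | None = None,
    rng: np.random.Generator | None = None,
    t_init: float = 0.0,
    t_read: float = 600.0,
    duration_s: float = DEFAULT_DURATION_S,
    rate_hz: float = DEFAULT_RATE_HZ,
    filter_window: int = DEFAULT_FILTER_WINDOW,
) -> ReadoutResult:
    """Run the full init -> background -> read protocol on the chamber.

    ``chamber_droplet`` may be None (bare optical path) or a droplet
    object; magnetic beads scatter light, so a droplet still flagged
    ``beads_present`` raises a measurement error.  ``assay_signal`` is the
    absorbance-equivalent signal of the droplet; transmitted intensity is
    ``ambient(t) * 10**(-signal)``.  ``t_init`` and ``t_read`` locate the
    reference and read windows on the drift timeline.
    """
    if chamber_droplet is not None and getattr(chamber_droplet, "beads_present", False):
        raise MeasurementError(
            "beads are still in the detection chamber; extract them before reading "
            "(bead light-scattering corrupts the absorbance measurement)"
        )
    if assay_signal < 0:
        raise ConfigError("assay signal must be >= 0")
    drift = drift or DriftModel()
    noise = drift.noise_sd

    _, i_ref = acquire(
        drift.ambient, duration_s, rate_hz, filter_window, rng=rng, noise_sd=noise, t0=t_init
    )
    _, i_bg = acquire(
        drift.ambient, duration_s, rate_hz, filter_window, rng=rng, noise_sd=noise, t0=t_read
    )
    # The sample window reuses the background window's timeline: droplet
    # insertion is instantaneous in the model, so background and sample see
    # the same ambient factor and the compensation cancels it exactly.
    transmittance = 10.0 ** (-assay_signal)
    _, i_raw = acquire(
        lambda t: drift.ambient(t) * transmittance,
        duration_s,
        rate_hz,
        filter_window,
        rng=rng,
        noise_sd=noise,
        t0=t_read,
    )
    ctx = CalibrationContext(i_ref=i_ref, i_bg=i_bg, filter_window=filter_window)
    return ReadoutResult(i_raw=i_raw, i_readout=calibrate(i_raw, ctx), i_ref=i_ref, i_bg=i_bg)
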