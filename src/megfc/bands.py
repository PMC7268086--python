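"""Canonical oscillatory bands and band-pass filter design.

alpha 8-13 Hz, beta 14-30 Hz, gamma 31-80 Hz.  Filters are Butterworth
band-passes applied zero-phase (forward-backward), so the effective
attenuation one octave beyond a band edge is twice the single-pass ~30 dB.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import signal

from .errors import ConfigurationError


@dataclass(frozen=True)
class BandSpec:
    name: str
    low: float
    high: float

    def __post_init__(self):
        if not (0 < self.low < self.high):
            raise ConfigurationError(f"invalid band edges ({self.low}, {self.high})")


BANDS = {
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta": BandSpec("beta", 14.0, 30.0),
    "gamma": BandSpec("gamma", 31.0, 80.0),
}

BAND_ORDER = ("alpha", "beta", "gamma")

#: Filter order per edge; 5 poles give >= 30 dB one octave out, single pass.
FILTER_ORDER = 5


def get_band(band) -> BandSpec:
    if isinstance(band, BandSpec):
        return band
    try:
        return BANDS[band]
    except KeyError:
        raise ConfigurationError(
            f"unknown band {band!r}; expected one of {sorted(BANDS)}"
        ) from None


def bandpass_sos(band, fs: float):
    """Second-order-section Butterworth band-pass for ``band`` at rate ``fs``."""
    b = get_band(band)
    if b.high >= fs / 2:
        raise ConfigurationError(
            f"band {b.name} upper edge {b.high} Hz is at/above Nyquist ({fs / 2} Hz)"
        )
    return signal.butter(FILTER_ORDER, [b.low, b.high], btype="bandpass",
                         fs=fs, output="sos")
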