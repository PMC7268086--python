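"""In-memory carriers for raw sensor data and its geometry."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError


@dataclass(frozen=True)
class SensorArraySpec:
    """Idealized whole-head magnetometer array.

    Radial magnetometers on a hemisphere of radius ``sensor_radius`` above a
    spherical conductor of radius ``head_radius`` (both meters, model frame).
    """

    positions: np.ndarray        # (n_channels, 3), meters
    orientations: np.ndarray     # (n_channels, 3), unit vectors
    sensor_radius: float
    head_radius: float

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        ori = np.asarray(self.orientations, dtype=float)
        if not (self.sensor_radius > self.head_radius > 0):
            raise ConfigurationError(
                "require sensor_radius > head_radius > 0, got "
                f"{self.sensor_radius}, {self.head_radius}"
            )
        if np.max(np.abs(np.linalg.norm(pos, axis=1) - self.sensor_radius)) > 1e-9:
            raise ConfigurationError("sensor positions must lie on the sensor sphere")
        if np.max(np.abs(np.linalg.norm(ori, axis=1) - 1.0)) > 1e-12:
            raise ConfigurationError("sensor orientations must be unit vectors")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]


@dataclass
class SensorRecording:
    """Multichannel sensor time series with geometry and metadata."""

    data: np.ndarray             # (n_channels, n_samples)
    sampling_rate: float
    array: SensorArraySpec
    subject_id: str = "s0"
    group: str = "unknown"
    moved_over_limit: bool = False   # head moved > 5 mm; loader refuses these

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InputError("data must be 2-D (channels x samples)")
        if self.sampling_rate <= 0:
            raise InputError("sampling_rate must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise InputError("recording contains NaN/Inf")
        if self.data.shape[0] != self.array.n_channels:
            raise InputError(
                f"data has {self.data.shape[0]} rows but the array has "
                f"{self.array.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate
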