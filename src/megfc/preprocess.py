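"""Preprocessing: notch filtering, 500-ms epoching, spike rejection, selection.

The pipeline order is: zero-phase 50-Hz notch on the continuous recording,
segmentation into consecutive non-overlapping 500-ms epochs, robust-z
flagging of epochs containing sharp transients, and random selection of a
fixed number of clean epochs (40 at the full 20-s/1-kHz scale).

Spike rejection is a deterministic surrogate for visual inspection: an
epoch is flagged when any channel sample deviates from that channel's
median (computed across all epochs) by more than ``z_threshold`` robust
standard deviations (1.4826 x MAD).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import ConfigurationError, DataSufficiencyError, InputError
from .recording import SensorArraySpec, SensorRecording

FLAG_OK = "ok"
FLAG_SPIKE = "spike"
FLAG_UNSELECTED = "unselected"

#: -3 dB width of the notch is line_freq / NOTCH_Q
NOTCH_Q = 30.0

MAD_TO_SD = 1.4826


@dataclass
class EpochSet:
    """Non-overlapping, time-ordered fixed-length epochs with rejection flags."""

    epochs: np.ndarray            # (n_epochs, n_channels, samples_per_epoch)
    sampling_rate: float
    epoch_length: float
    flags: np.ndarray             # per-epoch str code: ok / spike / unselected
    array: SensorArraySpec | None = None
    subject_id: str = "s0"
    group: str = "unknown"

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def samples_per_epoch(self) -> int:
        return self.epochs.shape[2]

    @property
    def ok_mask(self) -> np.ndarray:
        return self.flags == FLAG_OK

    def retained(self) -> np.ndarray:
        """Data of the epochs still flagged ok, time order preserved."""
        return self.epochs[self.ok_mask]


def notch_filter(rec: SensorRecording, line_freq: float = 50.0) -> SensorRecording:
    """Zero-phase IIR notch removing power-line interference."""
    if line_freq >= rec.sampling_rate / 2:
        raise ConfigurationError(
            f"line_freq {line_freq} Hz is at/above Nyquist "
            f"({rec.sampling_rate / 2} Hz)"
        )
    b, a = signal.iirnotch(line_freq, NOTCH_Q, fs=rec.sampling_rate)
    filtered = signal.filtfilt(b, a, rec.data, axis=-1)
    return replace(rec, data=filtered)


def segment_epochs(rec: SensorRecording, epoch_length: float = 0.5) -> EpochSet:
    """Fragment a recording into consecutive fixed-length epochs.

    A trailing remainder shorter than one epoch is discarded.
    """
    spe = int(round(epoch_length * rec.sampling_rate))
    if rec.n_samples < spe:
        raise InputError(
            f"recording ({rec.duration:.3f} s) shorter than one epoch "
            f"({epoch_length} s)"
        )
    n_ep = rec.n_samples // spe
    data = rec.data[:, : n_ep * spe]
    epochs = np.ascontiguousarray(
        data.reshape(rec.n_channels, n_ep, spe).transpose(1, 0, 2)
    )
    return EpochSet(
        epochs=epochs,
        sampling_rate=rec.sampling_rate,
        epoch_length=epoch_length,
        flags=np.full(n_ep, FLAG_OK, dtype=object),
        array=rec.array,
        subject_id=rec.subject_id,
        group=rec.group,
    )


def flag_spike_epochs(eps: EpochSet, z_threshold: float = 6.0) -> EpochSet:
    """Flag epochs containing sharp high-amplitude transients.

    Baseline statistics (channel median and MAD-based SD) are computed
    across all epochs jointly, so flagging is order-independent.  A zero
    MAD (constant channel) is floored at machine-epsilon scale of the
    channel range so constant data is never flagged.
    """
    if eps.n_epochs < 4:
        raise InputError(
            f"need >= 4 epochs for a robust baseline, got {eps.n_epochs}"
        )
    x = eps.epochs.transpose(1, 0, 2).reshape(eps.n_channels, -1)
    med = np.median(x, axis=1)
    mad = np.median(np.abs(x - med[:, None]), axis=1)
    scale = MAD_TO_SD * mad
    rng_floor = np.finfo(float).eps * np.maximum(
        np.ptp(x, axis=1), np.max(np.abs(x), axis=1)
    )
    scale = np.maximum(scale, np.maximum(rng_floor, np.finfo(float).tiny))
    dev = np.abs(eps.epochs - med[None, :, None])        # (ep, ch, s)
    spike = np.any(dev > z_threshold * scale[None, :, None], axis=(1, 2))
    flags = eps.flags.copy()
    flags[spike] = FLAG_SPIKE
    return replace(eps, flags=flags)


def select_clean_epochs(eps: EpochSet, k: int = 40, seed=0) -> EpochSet:
    """Uniformly sample ``k`` of the clean epochs without replacement.

    The retained epochs keep their original time order; the remaining clean
    epochs are flagged ``unselected``.  When exactly ``k`` clean epochs are
    available they are all retained and no randomness is consumed.
    """
    ok_idx = np.nonzero(eps.ok_mask)[0]
    if ok_idx.size < k:
        raise DataSufficiencyError(
            f"only {ok_idx.size} clean epochs available, need {k} "
            f"(deficit {k - ok_idx.size})"
        )
    flags = eps.flags.copy()
    if ok_idx.size > k:
        rng = np.random.default_rng(seed)
        keep = rng.choice(ok_idx, size=k, replace=False)
        drop = np.setdiff1d(ok_idx, keep)
        flags[drop] = FLAG_UNSELECTED
    return replace(eps, flags=flags)


def preprocess_recording(
    rec: SensorRecording,
    line_freq: float = 50.0,
    epoch_length: float = 0.5,
    n_epochs: int = 40,
    z_threshold: float = 6.0,
    seed=0,
) -> EpochSet:
    """Full preprocessing chain: notch -> epoch -> reject -> select."""
    eps = segment_epochs(notch_filter(rec, line_freq), epoch_length)
    eps = flag_spike_epochs(eps, z_threshold)
    return select_clean_epochs(eps, n_epochs, seed)
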