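"""Readers and writers: HDF5 recording/epoch containers and TSV tables.

Container layout (HDF5): ``/data`` channels x samples float64, ``/fs``
scalar, ``/positions`` and ``/orientations`` channels x 3, ``/meta`` a JSON
string with subject/group/geometry/flags.  Recordings whose head moved
beyond the 5-mm acquisition limit carry a flag; the reader refuses them.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, InputError
from .preprocess import EpochSet
from .recording import SensorArraySpec, SensorRecording

MOVEMENT_LIMIT_MM = 5.0


def write_recording(rec: SensorRecording, path) -> None:
    meta = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "sensor_radius": rec.array.sensor_radius,
        "head_radius": rec.array.head_radius,
        "moved_over_limit": bool(rec.moved_over_limit),
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, dtype="float64")
        f.create_dataset("fs", data=float(rec.sampling_rate))
        f.create_dataset("positions", data=rec.array.positions)
        f.create_dataset("orientations", data=rec.array.orientations)
        f.create_dataset("meta", data=json.dumps(meta))


def read_recording(path) -> SensorRecording:
    """Load and validate a recording container.

    Raises :class:`FormatError` for malformed/truncated files and
    :class:`InputError` for recordings flagged as having moved beyond the
    5-mm head-movement limit.
    """
    try:
        with h5py.File(path, "r") as f:
            missing = [k for k in ("data", "fs", "positions", "orientations", "meta")
                       if k not in f]
            if missing:
                raise FormatError(f"{path}: missing dataset(s) {missing}")
            data = np.asarray(f["data"], dtype=float)
            fs = float(f["fs"][()])
            pos = np.asarray(f["positions"])
            ori = np.asarray(f["orientations"])
            meta = json.loads(f["meta"][()])
    except (OSError, KeyError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: not a valid recording container ({exc})") from exc
    if meta.get("moved_over_limit", False):
        raise InputError(
            f"{path}: recording rejected — head movement exceeded the "
            f"{MOVEMENT_LIMIT_MM:.0f}-mm acquisition limit"
        )
    if pos.shape != ori.shape or pos.shape[0] != data.shape[0]:
        raise FormatError(f"{path}: channel/position mismatch")
    array = SensorArraySpec(
        positions=pos, orientations=ori,
        sensor_radius=float(meta["sensor_radius"]),
        head_radius=float(meta["head_radius"]),
    )
    return SensorRecording(
        data=data, sampling_rate=fs, array=array,
        subject_id=str(meta.get("subject_id", "s0")),
        group=str(meta.get("group", "unknown")),
    )


def write_epochs(eps: EpochSet, path) -> None:
    meta = {
        "subject_id": eps.subject_id,
        "group": eps.group,
        "epoch_length": eps.epoch_length,
    }
    if eps.array is not None:
        meta["sensor_radius"] = eps.array.sensor_radius
        meta["head_radius"] = eps.array.head_radius
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=eps.epochs, dtype="float64")
        f.create_dataset("fs", data=float(eps.sampling_rate))
        f.create_dataset("flags", data=np.array([s.encode() for s in eps.flags]))
        if eps.array is not None:
            f.create_dataset("positions", data=eps.array.positions)
            f.create_dataset("orientations", data=eps.array.orientations)
        f.create_dataset("meta", data=json.dumps(meta))


def read_epochs(path) -> EpochSet:
    try:
        with h5py.File(path, "r") as f:
            epochs = np.asarray(f["epochs"], dtype=float)
            fs = float(f["fs"][()])
            flags = np.array([s.decode() for s in f["flags"][()]], dtype=object)
            meta = json.loads(f["meta"][()])
            array = None
            if "positions" in f:
                array = SensorArraySpec(
                    positions=np.asarray(f["positions"]),
                    orientations=np.asarray(f["orientations"]),
                    sensor_radius=float(meta["sensor_radius"]),
                    head_radius=float(meta["head_radius"]),
                )
    except (OSError, KeyError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: not a valid epoch container ({exc})") from exc
    return EpochSet(epochs=epochs, sampling_rate=fs,
                    epoch_length=float(meta["epoch_length"]), flags=flags,
                    array=array, subject_id=str(meta.get("subject_id", "s0")),
                    group=str(meta.get("group", "unknown")))


def fc_long_format(fcs) -> pd.DataFrame:
    """Long-format table (subject_id, group, band, roi_a, roi_b, r)."""
    rows = []
    for fc in fcs:
        names = fc.roi_names or tuple(str(i) for i in range(fc.R.shape[0]))
        iu = np.triu_indices(fc.R.shape[0], k=1)
        for a, b in zip(*iu):
            rows.append({
                "subject_id": fc.subject_id, "group": fc.group,
                "band": fc.band.name, "roi_a": names[a], "roi_b": names[b],
                "r": fc.R[a, b],
            })
    return pd.DataFrame(rows)


def degree_long_format(degs) -> pd.DataFrame:
    """Long-format table (subject_id, group, band, roi, degree)."""
    rows = []
    for d in degs:
        names = d.roi_names or tuple(str(i) for i in range(d.degrees.size))
        for i, s in enumerate(d.degrees):
            rows.append({
                "subject_id": d.subject_id, "group": d.group,
                "band": d.band.name, "roi": names[i], "degree": s,
            })
    return pd.DataFrame(rows)
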