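"""Synthetic two-group MEG cohorts with known ground-truth coupling.

The generator states a simple world that carries the statistical structure
the analysis pipeline assumes:

* one tangential current dipole per DMN ROI, orientation fixed per ROI
  (drawn deterministically from the ROI name, shared across subjects so that
  correlation signs are comparable cohort-wide);
* each ROI source is a sum of alpha/beta/gamma band-limited Gaussian
  components; within each band, pairwise coupling coefficients define a
  target correlation matrix realized by Cholesky mixing of independent
  noises (for a single coupled pair this reduces to the shared-component
  construction x_a = sqrt(c) z + sqrt(1-c) e_a);
* sensors see the lead-field projection of the dipoles plus white noise at
  a stated SNR, a common-phase 50-Hz line interference, and Poisson-timed
  80-ms raised-cosine spike bursts at 10x the channel background RMS.

Groups differ only through their band-wise coupling presets; the default
patient/control presets elevate 2, 26 and 42 of the 66 ROI pairs in the
alpha, beta and gamma bands respectively, with the LAG-LPCC pair carrying
the largest elevation in every band.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .bands import BAND_ORDER, BANDS, bandpass_sos, get_band
from .errors import ConfigurationError, GeometryError, ValidityError
from .headmodel import compute_lead_field, mni_to_model
from .recording import SensorArraySpec, SensorRecording
from .rois import ROITable, load_roi_table

#: dipole moment scale, A*m (typical cortical patch ~10 nA*m)
DIPOLE_MOMENT = 1e-8

SPIKE_WIDTH_S = 0.080
SPIKE_GAIN = 10.0          # multiple of channel background RMS


# ---------------------------------------------------------------------------
# sensor array

def make_sensor_array(
    n_channels: int = 102,
    sensor_radius: float = 0.12,
    head_radius: float = 0.09,
) -> SensorArraySpec:
    """Quasi-uniform radial magnetometers on the upper hemisphere.

    Deterministic Fibonacci-spiral layout; channel i sits at height
    z = (i + 0.5)/n on the unit upper hemisphere.
    """
    if n_channels < 16:
        raise ConfigurationError(
            f"need at least 16 channels for a usable array, got {n_channels}"
        )
    i = np.arange(n_channels)
    z = (i + 0.5) / n_channels
    rho = np.sqrt(1.0 - z ** 2)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = i * golden
    unit = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return SensorArraySpec(
        positions=unit * sensor_radius,
        orientations=unit,
        sensor_radius=sensor_radius,
        head_radius=head_radius,
    )


# ---------------------------------------------------------------------------
# configuration

def _norm_pair(a: str, b: str) -> tuple:
    return tuple(sorted((a, b)))


@dataclass(frozen=True)
class CouplingSpec:
    """Band-specific pairwise coupling coefficients for one group."""

    band: str
    pair_couplings: dict
    group: str = ""

    def __post_init__(self):
        get_band(self.band)
        norm = {}
        for (a, b), c in self.pair_couplings.items():
            if not (0.0 <= c < 0.95):
                raise ValidityError(
                    f"coupling for pair ({a}, {b}) must be in [0, 0.95), got {c}"
                )
            norm[_norm_pair(a, b)] = float(c)
        object.__setattr__(self, "pair_couplings", norm)

    def coupling(self, a: str, b: str) -> float:
        return self.pair_couplings.get(_norm_pair(a, b), 0.0)


@dataclass(frozen=True)
class CohortConfig:
    """Stated world for one simulated cohort."""

    n_per_group: int = 15
    duration: float = 20.0           # seconds -> 40 epochs of 500 ms
    sampling_rate: float = 1000.0    # Hz
    snr_db: float = 20.0             # source-to-sensor-noise, dB
    line_noise_amplitude: float = 0.5  # fraction of signal RMS
    spike_rate: float = 2.0          # events / minute
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if self.sampling_rate < 2 * max(b.high for b in BANDS.values()):
            raise ConfigurationError(
                f"sampling_rate {self.sampling_rate} Hz cannot represent the "
                f"gamma band (need >= {2 * BANDS['gamma'].high} Hz)"
            )
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("duration x sampling_rate must be an integer")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


# ---------------------------------------------------------------------------
# ROI source signals

def _coupling_matrix(roi: ROITable, spec: CouplingSpec) -> np.ndarray:
    names = roi.names
    for a, b in spec.pair_couplings:
        if a not in names or b not in names:
            raise ValidityError(f"coupling pair ({a}, {b}) names unknown ROI(s)")
    n = len(names)
    C = np.eye(n)
    for (a, b), c in spec.pair_couplings.items():
        i, j = names.index(a), names.index(b)
        C[i, j] = C[j, i] = c
    return C


def _mixing_cholesky(C: np.ndarray) -> np.ndarray:
    w = np.linalg.eigvalsh(C)
    if w[0] < -1e-9:
        raise ValidityError(
            "coupling coefficients define a non-positive-semidefinite "
            f"correlation matrix (min eigenvalue {w[0]:.3g})"
        )
    jitter = max(0.0, -w[0]) + 1e-12
    return np.linalg.cholesky(C + jitter * np.eye(C.shape[0]))


@dataclass
class SourceSet:
    """Per-ROI source signals and their band components."""

    roi_names: tuple
    band_components: dict          # band name -> (n_roi, n_samples)
    sampling_rate: float

    @property
    def total(self) -> np.ndarray:
        return sum(self.band_components.values())


def simulate_roi_sources(
    roi_table: ROITable, couplings, config: CohortConfig, seed=None
) -> SourceSet:
    """Generate band-limited, coupled Gaussian sources at the ROI centres.

    Each band component is unit-RMS per ROI; the full source is the sum of
    the band components.  ``couplings`` is a list of :class:`CouplingSpec`
    (at most one per band); bands without a spec get independent sources.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    spec_by_band = {}
    for spec in couplings:
        if spec.band in spec_by_band:
            raise ValidityError(f"duplicate CouplingSpec for band {spec.band}")
        spec_by_band[spec.band] = spec

    n_roi = len(roi_table)
    n = config.n_samples
    comps = {}
    for band in BAND_ORDER:
        white = rng.standard_normal((n_roi, n))
        spec = spec_by_band.get(band)
        if spec is not None:
            L = _mixing_cholesky(_coupling_matrix(roi_table, spec))
            white = L @ white
        sos = bandpass_sos(band, config.sampling_rate)
        comp = signal.sosfiltfilt(sos, white, axis=-1)
        rms = np.sqrt(np.mean(comp ** 2, axis=-1, keepdims=True))
        comps[band] = np.ascontiguousarray(comp / np.maximum(rms, 1e-300))
    return SourceSet(roi_names=tuple(roi_table.names), band_components=comps,
                     sampling_rate=config.sampling_rate)


# ---------------------------------------------------------------------------
# forward projection

def roi_orientation(name: str, center_model: np.ndarray) -> np.ndarray:
    """Deterministic tangential dipole orientation for a named ROI.

    The tangent-plane angle is derived from a CRC of the name, so it is
    stable across subjects, cohorts and sessions.  Radial dipoles are
    magnetically silent in a sphere, hence the tangential constraint.
    """
    r = np.asarray(center_model, dtype=float)
    rn = np.linalg.norm(r)
    if rn < 1e-12:
        raise GeometryError(f"ROI {name} maps to the sphere centre")
    rhat = r / rn
    helper = np.array([0.0, 0.0, 1.0])
    if abs(rhat @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(helper, rhat)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(rhat, t1)
    theta = 2.0 * np.pi * (zlib.crc32(name.encode()) / 2 ** 32)
    return np.cos(theta) * t1 + np.sin(theta) * t2


def project_to_sensors(
    sources,
    roi_table: ROITable,
    array: SensorArraySpec,
    config: CohortConfig,
    seed=None,
    subject_id: str = "s0",
    group: str = "unknown",
) -> SensorRecording:
    """Project ROI dipole sources to the sensors and add noise terms.

    sensor = leadfield x (tangential dipoles) + white noise at ``snr_db``
    + 50-Hz common-phase sinusoid + Poisson spike bursts.
    """
    src = sources.total if isinstance(sources, SourceSet) else np.asarray(sources, float)
    n_roi, n = src.shape
    if n_roi != len(roi_table):
        raise ValidityError("source row count does not match the ROI table")

    centers = mni_to_model(roi_table.coords_mni)
    rad = np.linalg.norm(centers, axis=1)
    outside = rad > array.head_radius
    if np.any(outside):
        bad = [roi_table.names[i] for i in np.nonzero(outside)[0]]
        raise GeometryError(f"ROI(s) map outside the head sphere: {bad}")

    lf = compute_lead_field(centers, array, head_radius=array.head_radius)
    ori = np.stack([roi_orientation(nm, c) for nm, c in zip(roi_table.names, centers)])
    # per-ROI sensor topography: (n_channels, n_roi)
    topo = np.einsum("vck,vk->cv", lf.gain, ori) * DIPOLE_MOMENT
    clean = topo @ src

    rng = np.random.default_rng(config.seed if seed is None else seed)
    data = clean.copy()
    signal_rms = float(np.sqrt(np.mean(clean ** 2)))

    if np.isfinite(config.snr_db):
        sigma = signal_rms * 10.0 ** (-config.snr_db / 20.0)
        if sigma > 0:
            data += rng.normal(0.0, sigma, size=data.shape)

    if config.line_noise_amplitude > 0:
        t = np.arange(n) / config.sampling_rate
        phase = rng.uniform(0.0, 2.0 * np.pi)
        data += (config.line_noise_amplitude * signal_rms
                 * np.sin(2.0 * np.pi * 50.0 * t + phase))

    if config.spike_rate > 0:
        duration_min = n / config.sampling_rate / 60.0
        n_events = rng.poisson(config.spike_rate * duration_min)
        width = max(2, int(round(SPIKE_WIDTH_S * config.sampling_rate)))
        burst = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(width) / (width - 1)))
        ch_rms = np.sqrt(np.mean(data ** 2, axis=1))
        for _ in range(n_events):
            start = rng.integers(0, max(1, n - width))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            data[:, start:start + width] += (
                sign * SPIKE_GAIN * ch_rms[:, None] * burst[None, :]
            )

    return SensorRecording(data=data, sampling_rate=config.sampling_rate,
                           array=array, subject_id=subject_id, group=group)


# ---------------------------------------------------------------------------
# coupling presets

_HOMOLOGOUS = [
    ("LAG", "RAG"), ("LPCC", "RPCC"), ("LvMPFC", "RvMPFC"),
    ("LdMPFC", "RdMPFC"), ("LITG", "RITG"), ("LACC", "RACC"),
]
_ALPHA_ELEVATED = [("LAG", "LPCC"), ("RAG", "RPCC")]
_BETA_EXTRA = [
    ("LAG", "LACC"), ("RAG", "RACC"),
    ("LPCC", "LACC"), ("RPCC", "RACC"),
    ("LAG", "LITG"), ("RAG", "RITG"),
    ("LPCC", "LITG"), ("RPCC", "RITG"),
    ("LAG", "LvMPFC"), ("RAG", "RvMPFC"),
    ("LPCC", "LvMPFC"), ("RPCC", "RvMPFC"),
    ("LAG", "LdMPFC"), ("RAG", "RdMPFC"),
    ("LPCC", "LdMPFC"), ("RPCC", "RdMPFC"),
    ("LACC", "LITG"), ("RACC", "RITG"),
]
_GAMMA_EXTRA = [
    ("LvMPFC", "LdMPFC"), ("RvMPFC", "RdMPFC"),
    ("LvMPFC", "LACC"), ("RvMPFC", "RACC"),
    ("LdMPFC", "LACC"), ("RdMPFC", "RACC"),
    ("LvMPFC", "LITG"), ("RvMPFC", "RITG"),
    ("LdMPFC", "LITG"), ("RdMPFC", "RITG"),
    ("LAG", "RPCC"), ("RAG", "LPCC"),
    ("LAG", "RACC"), ("RAG", "LACC"),
    ("LPCC", "RITG"), ("RPCC", "LITG"),
]

#: elevated pair sets per band (2 / 26 / 42 of the 66 pairs)
ELEVATED_PAIRS = {
    "alpha": list(_ALPHA_ELEVATED),
    "beta": _ALPHA_ELEVATED + _HOMOLOGOUS + _BETA_EXTRA,
    "gamma": _ALPHA_ELEVATED + _HOMOLOGOUS + _BETA_EXTRA + _GAMMA_EXTRA,
}

BASELINE_COUPLING = 0.15
_ELEVATED_LEVEL = {"alpha": 0.45, "beta": 0.40, "gamma": 0.45}
_KEY_PAIR_LEVEL = {"alpha": 0.50, "beta": 0.50, "gamma": 0.55}
KEY_PAIR = ("LAG", "LPCC")


def _baseline_map(roi: ROITable) -> dict:
    return {pair: BASELINE_COUPLING for pair in roi.pairs}


def control_coupling_presets(roi_table: ROITable | None = None):
    """Healthy-control world: uniform weak coupling in every band."""
    roi = roi_table if roi_table is not None else load_roi_table()
    return [CouplingSpec(band=b, pair_couplings=_baseline_map(roi), group="control")
            for b in BAND_ORDER]


def patient_coupling_presets(roi_table: ROITable | None = None):
    """Patient world: band-specific elevations over the control baseline.

    Mirrors the qualitative group pattern the analysis should recover:
    few elevated pairs in alpha, more in beta, most in gamma, with
    LAG-LPCC the most elevated pair in every band.
    """
    roi = roi_table if roi_table is not None else load_roi_table()
    specs = []
    for band in BAND_ORDER:
        cmap = _baseline_map(roi)
        for pair in ELEVATED_PAIRS[band]:
            cmap[_norm_pair(*pair)] = _ELEVATED_LEVEL[band]
        cmap[_norm_pair(*KEY_PAIR)] = _KEY_PAIR_LEVEL[band]
        specs.append(CouplingSpec(band=band, pair_couplings=cmap, group="patient"))
    return specs


def null_coupling_presets():
    """Zero coupling in every band (type-I-error calibration world)."""
    return [CouplingSpec(band=b, pair_couplings={}, group="null") for b in BAND_ORDER]


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class Cohort:
    recordings: list                 # of SensorRecording
    covariates: pd.DataFrame
    config: CohortConfig


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_subject(
    config: CohortConfig,
    effects,
    roi_table: ROITable,
    array: SensorArraySpec,
    seed,
    subject_id: str,
    group: str,
) -> SensorRecording:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_src, s_sens = ss.spawn(2)
    sources = simulate_roi_sources(roi_table, effects, config, seed=s_src)
    return project_to_sensors(sources, roi_table, array, config, seed=s_sens,
                              subject_id=subject_id, group=group)


def simulate_cohort(
    config: CohortConfig,
    patient_effects=None,
    control_effects=None,
    roi_table: ROITable | None = None,
    array: SensorArraySpec | None = None,
) -> Cohort:
    """Simulate ``2 x n_per_group`` recordings plus a clinical covariate table.

    Per-subject seeds are spawned deterministically from ``config.seed``;
    the same config reproduces the cohort bit-identically.
    """
    roi = roi_table if roi_table is not None else load_roi_table()
    if patient_effects is None:
        patient_effects = patient_coupling_presets(roi)
    if control_effects is None:
        control_effects = control_coupling_presets(roi)
    if array is None:
        array = make_sensor_array()

    master = np.random.SeedSequence(config.seed)
    n = config.n_per_group
    subject_seeds = master.spawn(2 * n)
    cov_rng = np.random.default_rng(master.spawn(1)[0])

    recordings = []
    rows = []
    for g, (glabel, effects) in enumerate(
        [("patient", patient_effects), ("control", control_effects)]
    ):
        age_mean, age_rng = (21.0, (10.0, 35.0)) if glabel == "patient" else (24.0, (10.0, 40.0))
        p_male = 11 / 15 if glabel == "patient" else 9 / 15
        ages = _truncnorm(cov_rng, age_mean, 5.0, *age_rng, size=n)
        sexes = np.where(cov_rng.random(n) < p_male, "M", "F")
        durations = (_truncnorm(cov_rng, 12.0, 5.0, 0.0, np.inf, size=n)
                     if glabel == "patient" else np.full(n, np.nan))
        for i in range(n):
            sid = f"{glabel[:3]}{i + 1:02d}"
            rec = simulate_subject(config, effects, roi, array,
                                   seed=subject_seeds[g * n + i],
                                   subject_id=sid, group=glabel)
            recordings.append(rec)
            rows.append({
                "subject_id": sid, "group": glabel, "sex": sexes[i],
                "age_years": round(float(ages[i]), 1),
                "duration_years": (round(float(durations[i]), 1)
                                   if np.isfinite(durations[i]) else np.nan),
            })
    return Cohort(recordings=recordings,
                  covariates=pd.DataFrame(rows), config=config)
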