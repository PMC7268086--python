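"""Single-sphere conductor model: source grid, lead fields, peak merging.

The head is modelled as a homogeneous conducting sphere centred at the
origin of the model-head frame (coordinates in meters).  Lead fields use the
closed-form magnetic-dipole-in-sphere solution (Sarvas), which has two exact
properties this package relies on:

* a radial dipole produces no external magnetic field (spherical silence);
* a dipole at the sphere centre is silent for every orientation.

Region coordinates given in MNI millimeters are brought into the model frame
by a fixed isotropic scaling (:func:`mni_to_model`); no individual
coregistration is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, GeometryError

#: Fixed affine taking MNI mm into model-frame meters.  0.7e-3 places every
#: packaged DMN ROI centre (max MNI radius ~94 mm) inside 0.9 x head_radius
#: for the default 0.09 m head sphere.
MNI_SCALE = 0.7e-3

_MU0_4PI = 1e-7  # vacuum permeability / 4 pi, SI


def mni_to_model(coords_mm: np.ndarray) -> np.ndarray:
    """Map MNI coordinates (mm) to model-head-frame meters."""
    return np.asarray(coords_mm, dtype=float) * MNI_SCALE


def model_to_mni(coords_m: np.ndarray) -> np.ndarray:
    return np.asarray(coords_m, dtype=float) / MNI_SCALE


@dataclass(frozen=True)
class SourceGrid:
    """Regular cubic lattice clipped to a spherical mask.

    Parameters
    ----------
    coords : (n_voxels, 3) float array, meters, model-head frame.
    spacing : lattice spacing in meters.
    head_radius : conductor sphere radius in meters.
    mask_fraction : voxels are kept iff ||v|| <= mask_fraction * head_radius.
    """

    coords: np.ndarray
    spacing: float
    head_radius: float
    mask_fraction: float = 0.9

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    @property
    def mask_radius(self) -> float:
        return self.mask_fraction * self.head_radius


def build_source_grid(
    head_radius: float, spacing_mm: float = 6.0, mask_fraction: float = 0.9
) -> SourceGrid:
    """Build the volumetric scanning grid.

    The lattice is centred on the origin with deterministic ordering:
    x varies fastest, then y, then z.
    """
    if spacing_mm <= 0:
        raise ConfigurationError(f"grid spacing must be > 0, got {spacing_mm}")
    if head_radius <= 0:
        raise ConfigurationError(f"head_radius must be > 0, got {head_radius}")
    spacing = spacing_mm * 1e-3
    rmask = mask_fraction * head_radius
    n_steps = int(np.floor(rmask / spacing))
    axis = np.arange(-n_steps, n_steps + 1) * spacing
    # meshgrid with 'ij' then transpose so x is the fastest-varying index
    zz, yy, xx = np.meshgrid(axis, axis, axis, indexing="ij")
    coords = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    inside = np.linalg.norm(coords, axis=1) <= rmask + 1e-12
    coords = coords[inside]
    if coords.shape[0] == 0:  # degenerate lattice still contains the centre
        coords = np.zeros((1, 3))
    return SourceGrid(coords=coords, spacing=spacing, head_radius=head_radius,
                      mask_fraction=mask_fraction)


@dataclass(frozen=True)
class LeadField:
    """Per-voxel forward gain matrices.

    ``gain[v]`` is the (n_channels, 3) matrix mapping a dipole moment at
    voxel ``v`` (model frame, A*m) to the sensor measurements.
    """

    gain: np.ndarray          # (n_voxels, n_channels, 3)
    coords: np.ndarray        # (n_voxels, 3), meters
    head_radius: float = field(default=0.09)


def compute_lead_field(coords, array, head_radius: float | None = None) -> LeadField:
    """Closed-form sphere-model lead field at arbitrary source coordinates.

    Parameters
    ----------
    coords : (n_voxels, 3) source positions in model-frame meters, or a
        :class:`SourceGrid`.
    array : :class:`megfc.simulate.SensorArraySpec`
        Sensor positions/orientations (radial magnetometers).
    """
    if isinstance(coords, SourceGrid):
        if head_radius is None:
            head_radius = coords.head_radius
        coords = coords.coords
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if head_radius is None:
        head_radius = array.head_radius
    rad = np.linalg.norm(coords, axis=1)
    if np.any(rad > head_radius + 1e-12):
        bad = np.nonzero(rad > head_radius + 1e-12)[0]
        raise GeometryError(
            f"source(s) {bad.tolist()} lie outside the conductor sphere "
            f"(radius {head_radius} m)"
        )

    r = np.asarray(array.positions, dtype=float)       # (C, 3)
    n = np.asarray(array.orientations, dtype=float)    # (C, 3)
    r0 = coords                                        # (V, 3)

    a_vec = r[None, :, :] - r0[:, None, :]             # (V, C, 3)
    a = np.linalg.norm(a_vec, axis=2)                  # (V, C)
    rn = np.linalg.norm(r, axis=1)                     # (C,)
    adotr = np.einsum("vck,ck->vc", a_vec, r)          # (V, C)
    r0dotr = r0 @ r.T                                  # (V, C)

    F = a * (rn[None, :] * a + rn[None, :] ** 2 - r0dotr)
    # grad F = c1 * r - c2 * r0
    c1 = a ** 2 / rn[None, :] + adotr / a + 2.0 * a + 2.0 * rn[None, :]
    c2 = a + 2.0 * rn[None, :] + adotr / a
    gradF = c1[..., None] * r[None, :, :] - c2[..., None] * r0[:, None, :]

    gain = np.empty((r0.shape[0], r.shape[0], 3))
    eye = np.eye(3)
    for k in range(3):
        qxr0 = np.cross(eye[k], r0)                    # (V, 3)
        qxr0_dot_r = qxr0 @ r.T                        # (V, C)
        B = _MU0_4PI / F[..., None] ** 2 * (
            F[..., None] * qxr0[:, None, :] - qxr0_dot_r[..., None] * gradF
        )
        gain[:, :, k] = np.einsum("vck,ck->vc", B, n)
    return LeadField(gain=gain, coords=r0, head_radius=head_radius)


def merge_close_peaks(
    peaks: np.ndarray, strengths: np.ndarray, min_separation_mm: float = 10.0
):
    """Greedy strongest-first merging of nearby peaks.

    Peaks closer than ``min_separation_mm`` (model frame) to an already kept,
    stronger peak are absorbed into it.  Returns ``(coords, strengths)``
    sorted by descending strength.
    """
    peaks = np.atleast_2d(np.asarray(peaks, dtype=float))
    strengths = np.asarray(strengths, dtype=float)
    if peaks.size == 0 or strengths.size == 0:
        return np.empty((0, 3)), np.empty(0)
    order = np.argsort(-strengths, kind="stable")
    sep = min_separation_mm * 1e-3
    kept: list[int] = []
    for i in order:
        if all(np.linalg.norm(peaks[i] - peaks[j]) >= sep for j in kept):
            kept.append(i)
    kept_arr = np.asarray(kept)
    return peaks[kept_arr], strengths[kept_arr]
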