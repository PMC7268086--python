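"""Two-step scalar beamformer and accumulated source imaging.

For each voxel the inverse solution proceeds as:

1. lead field L (channels x 3) from the sphere model;
2. voxel-based partial sensor selection (channels whose lead-field row norm
   is at least 10% of the maximum, expanded to a floor of 30 channels);
3. minimum-variance unit-gain vector beamformer on the partial-sensor
   covariance, W = (L' C^-1 L)^-1 L' C^-1.  The sphere model has no radial
   sensitivity, so voxel lead fields are rank 2; the weights are computed
   in the tangential 2-space (reduced SVD basis) and flagged as such;
4. source orientation = dominant eigenvector of the 3x3 source covariance
   W C W';
5. scalar source time series Q(r, t) = eta' W b(t) over the retained epochs.

The accumulated source image is the per-voxel summation of |Q(r, t)| over
all time points (the signed sum would cancel oscillatory activity; a signed
variant is available behind a flag).  Peaks closer than 10 mm are merged,
strongest first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg, signal
from scipy.spatial import cKDTree

from .bands import BandSpec, bandpass_sos, get_band
from .errors import DegenerateVoxelError, InputError
from .headmodel import LeadField, SourceGrid, merge_close_peaks
from .preprocess import EpochSet

DEFAULT_REGULARIZATION = 0.05
DEFAULT_MIN_FRACTION = 0.10
DEFAULT_MIN_COUNT = 30
_RANK_TOL = 1e-8


def bandpass_epochs(eps: EpochSet, band) -> EpochSet:
    """Zero-phase band-pass, applied per epoch (no cross-epoch leakage)."""
    b = get_band(band)
    sos = bandpass_sos(b, eps.sampling_rate)
    return replace(eps, epochs=signal.sosfiltfilt(sos, eps.epochs, axis=-1))


def sensor_covariance(eps: EpochSet, regularization: float = DEFAULT_REGULARIZATION):
    """Pooled epoch covariance with diagonal loading.

    The per-epoch, per-channel mean is removed before pooling; the loading
    adds ``regularization x mean(diag)`` to the diagonal, guaranteeing a
    symmetric positive-definite estimate.
    """
    x = eps.retained()
    n_ep = x.shape[0]
    if n_ep < 2:
        raise InputError(f"need >= 2 retained epochs for a covariance, got {n_ep}")
    n_ch, spe = x.shape[1], x.shape[2]
    if n_ep * spe <= n_ch:
        warnings.warn(
            f"covariance from {n_ep * spe} samples for {n_ch} channels is "
            "poorly conditioned; relying on diagonal loading",
            stacklevel=2,
        )
    xc = x - x.mean(axis=2, keepdims=True)
    flat = xc.transpose(1, 0, 2).reshape(n_ch, -1)
    C = flat @ flat.T / (n_ep * max(spe - 1, 1))
    C += regularization * np.mean(np.diag(C)) * np.eye(n_ch)
    return 0.5 * (C + C.T)


def select_partial_sensors(
    lead_field_voxel: np.ndarray,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    min_count: int = DEFAULT_MIN_COUNT,
) -> np.ndarray:
    """Channels relevant to a voxel, by lead-field row norm.

    Returns the sorted indices of channels whose row norm is at least
    ``min_fraction`` of the maximum, expanded to at least ``min_count``
    channels by descending norm (ties broken by channel index).
    """
    L = np.asarray(lead_field_voxel, dtype=float)
    norms = np.linalg.norm(L, axis=1)
    top = norms.max(initial=0.0)
    if not np.isfinite(top) or top <= 0.0:
        raise DegenerateVoxelError("all-zero lead field (magnetically silent voxel)")
    n_ch = norms.size
    min_count = min(min_count, n_ch)
    sel = norms >= min_fraction * top
    if sel.sum() < min_count:
        order = np.lexsort((np.arange(n_ch), -norms))
        sel = np.zeros(n_ch, dtype=bool)
        sel[order[:min_count]] = True
    return np.nonzero(sel)[0]


@dataclass
class BeamformerWeights:
    """Unit-gain spatial filter for one voxel.

    ``W`` maps the partial-sensor measurements to a 3-vector dipole moment
    estimate.  When the lead field is effectively rank 2 (sphere model),
    ``W`` lives in the tangential plane spanned by ``basis`` and
    ``rank_deficient`` is set; unit gain then holds in that reduced basis.
    """

    W: np.ndarray            # (3, n_subset)
    subset: np.ndarray       # channel indices into the full array
    basis: np.ndarray        # (3, rank) orthonormal moment-space basis
    rank: int

    @property
    def rank_deficient(self) -> bool:
        return self.rank < 3

    def unit_gain_error(self, lead_field_voxel: np.ndarray) -> float:
        """Max-abs deviation of W L from identity in the effective basis."""
        L = np.asarray(lead_field_voxel)[self.subset]
        G = (self.basis.T @ self.W) @ (L @ self.basis)
        return float(np.max(np.abs(G - np.eye(self.rank))))


def vector_beamformer(
    cov: np.ndarray,
    lead_field_voxel: np.ndarray,
    subset: np.ndarray | None = None,
    cho_full=None,
) -> BeamformerWeights:
    """Minimum-variance unit-gain weights W = (L' C^-1 L)^-1 L' C^-1.

    ``cov`` is the full-channel covariance; if ``subset`` is given both the
    covariance and the lead field are restricted to it.  ``cho_full`` may
    carry a precomputed Cholesky factorization of the full covariance to
    reuse when the subset covers all channels.
    """
    L_full = np.asarray(lead_field_voxel, dtype=float)
    if subset is None:
        subset = np.arange(L_full.shape[0])
    L = L_full[subset]
    U, S, Vt = np.linalg.svd(L, full_matrices=False)
    if S[0] <= 0.0:
        raise DegenerateVoxelError("all-zero lead field")
    rank = int(np.sum(S > _RANK_TOL * S[0]))
    if rank < 2:
        raise DegenerateVoxelError(
            f"lead field effective rank {rank} < 2; voxel skipped"
        )
    B = Vt[:rank].T                      # (3, rank)
    Lr = L @ B                           # (n_subset, rank)
    if cho_full is not None and subset.size == cov.shape[0]:
        cf = cho_full
    else:
        cf = linalg.cho_factor(cov[np.ix_(subset, subset)], check_finite=False)
    CinvL = linalg.cho_solve(cf, Lr, check_finite=False)
    G = Lr.T @ CinvL
    Wr = np.linalg.solve(G, CinvL.T)     # (rank, n_subset)
    return BeamformerWeights(W=B @ Wr, subset=np.asarray(subset), basis=B, rank=rank)


@dataclass
class OrientationEstimate:
    vector: np.ndarray       # unit 3-vector
    tied: bool = False       # leading eigenvalues tied; deterministic tie-break


def estimate_orientation(weights: BeamformerWeights, cov: np.ndarray) -> OrientationEstimate:
    """Dominant eigenvector of the 3x3 source covariance W C W'.

    The sign is fixed so the largest-magnitude component is positive.  A
    tie between the two leading eigenvalues (within 1e-12 relative) is
    resolved deterministically by eigenvector order and flagged.
    """
    ix = weights.subset
    S3 = weights.W @ cov[np.ix_(ix, ix)] @ weights.W.T
    vals, vecs = np.linalg.eigh(0.5 * (S3 + S3.T))
    tied = (vals[-1] - vals[-2]) <= 1e-12 * max(abs(vals[-1]), np.finfo(float).tiny)
    v = vecs[:, -1]
    k = int(np.argmax(np.abs(v)))
    if v[k] < 0:
        v = -v
    return OrientationEstimate(vector=v, tied=bool(tied))


def fix_orientation_sign(orientation: np.ndarray, lead_field_voxel: np.ndarray) -> np.ndarray:
    """Resolve the scalar beamformer's inherent +/- ambiguity geometrically.

    The estimated orientation is flipped, if needed, so that it has positive
    dot product with the voxel's dominant lead-field direction (first right
    singular vector, itself sign-fixed by the largest-component rule).  This
    makes the sign of Q depend only on the geometry, not on the data, so
    source correlations are comparable across subjects and groups.
    """
    ori = np.asarray(orientation, dtype=float)
    _, _, Vt = np.linalg.svd(np.asarray(lead_field_voxel, float), full_matrices=False)
    d = Vt[0]
    k = int(np.argmax(np.abs(d)))
    if d[k] < 0:
        d = -d
    dot = ori @ d
    if abs(dot) > 1e-9:
        return ori if dot > 0 else -ori
    return ori


@dataclass
class SourceActivity:
    """Scalar source time series Q(r, t) at one location."""

    Q_epochs: np.ndarray         # (n_epochs, samples_per_epoch)
    orientation: np.ndarray
    band: BandSpec | None = None
    coord: np.ndarray | None = None

    @property
    def Q(self) -> np.ndarray:
        """Q(r, t) concatenated over retained epochs in time order."""
        return self.Q_epochs.reshape(-1)


def scalar_source_timeseries(
    eps: EpochSet, orientation: np.ndarray, weights: BeamformerWeights,
    band=None, coord=None,
) -> SourceActivity:
    """Project the retained epochs through the scalar beamformer."""
    w = np.asarray(orientation, dtype=float) @ weights.W       # (n_subset,)
    data = eps.retained()[:, weights.subset, :]                # (ep, sub, s)
    Q = np.einsum("c,ecs->es", w, data)
    return SourceActivity(Q_epochs=Q, orientation=np.asarray(orientation),
                          band=get_band(band) if band is not None else None,
                          coord=coord)


@dataclass
class AccumulatedSourceImage:
    """Per-voxel accumulated source strength Asi(r) = sum_t |Q(r, t)|.

    ``slice_indices`` records the (1-based) epoch slice bookkeeping; only
    indexing metadata, no computation depends on it.
    """

    asi: np.ndarray              # (n_voxels,)
    coords: np.ndarray           # (n_voxels, 3)
    n_timepoints: int
    band: BandSpec | None = None
    slice_indices: np.ndarray | None = None
    orientations: np.ndarray | None = None


def accumulate_source_image(
    Q, coords=None, band=None, signed: bool = False
) -> AccumulatedSourceImage:
    """Volumetric summation of source activity over time.

    ``Q`` may be a :class:`SourceActivity`, a 1-D series, or an
    (n_voxels, n_timepoints) array.  By default the magnitude |Q| is
    summed; ``signed=True`` gives the literal signed sum.
    """
    if isinstance(Q, SourceActivity):
        if coords is None and Q.coord is not None:
            coords = np.atleast_2d(Q.coord)
        band = band if band is not None else Q.band
        Q = Q.Q
    Q = np.asarray(Q, dtype=float)
    if Q.ndim == 1:
        Q = Q[None, :]
    n_vox, n = Q.shape
    if n == 0:
        raise InputError("empty time axis: nothing to accumulate")
    vals = Q.sum(axis=1) if signed else np.abs(Q).sum(axis=1)
    if coords is None:
        coords = np.full((n_vox, 3), np.nan)
    return AccumulatedSourceImage(
        asi=vals, coords=np.atleast_2d(coords), n_timepoints=n,
        band=get_band(band) if band is not None else None,
        slice_indices=np.arange(1, max(1, n // 2) + 1),
    )


def prepare_scan(
    lead: LeadField,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    min_count: int = DEFAULT_MIN_COUNT,
) -> list:
    """Precompute per-voxel partial-sensor subsets and reduced lead bases.

    These depend only on the geometry, so replicate scans over one array /
    grid can share them.  Silent voxels are marked with ``None``.
    """
    out = []
    for v in range(lead.gain.shape[0]):
        L = lead.gain[v]
        try:
            subset = select_partial_sensors(L, min_fraction, min_count)
        except DegenerateVoxelError:
            out.append(None)
            continue
        Ls = L[subset]
        _, S, Vt = np.linalg.svd(Ls, full_matrices=False)
        rank = int(np.sum(S > _RANK_TOL * S[0])) if S[0] > 0 else 0
        if rank < 2:
            out.append(None)
            continue
        B = Vt[:rank].T
        out.append((subset, B, Ls @ B))
    return out


def beamformer_scan(
    eps: EpochSet,
    lead: LeadField,
    cov: np.ndarray | None = None,
    regularization: float = DEFAULT_REGULARIZATION,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    min_count: int = DEFAULT_MIN_COUNT,
    band=None,
    scan_context: list | None = None,
) -> AccumulatedSourceImage:
    """Accumulated source image over all voxels of a lead field.

    Magnetically silent voxels (rank < 2, e.g. the sphere centre) get
    Asi = 0.  The full-channel covariance factorization is reused whenever
    a voxel's partial-sensor subset covers every channel; pass the output
    of :func:`prepare_scan` to amortize the geometry work over replicates.
    """
    if cov is None:
        cov = sensor_covariance(eps, regularization)
    if scan_context is None:
        scan_context = prepare_scan(lead, min_fraction, min_count)
    cho_full = linalg.cho_factor(cov, check_finite=False)
    data = eps.retained()
    n_ch = cov.shape[0]
    n_vox = lead.gain.shape[0]
    asi = np.zeros(n_vox)
    oris = np.zeros((n_vox, 3))
    for v in range(n_vox):
        ctx = scan_context[v]
        if ctx is None:
            continue
        subset, B, Lr = ctx
        if subset.size == n_ch:
            cf = cho_full
        else:
            cf = linalg.cho_factor(cov[np.ix_(subset, subset)], check_finite=False)
        CinvL = linalg.cho_solve(cf, Lr, check_finite=False)
        Wr = np.linalg.solve(Lr.T @ CinvL, CinvL.T)       # (rank, n_sub)
        Sr = Wr @ cov[np.ix_(subset, subset)] @ Wr.T
        vals, vecs = np.linalg.eigh(0.5 * (Sr + Sr.T))
        u = vecs[:, -1]
        ori = B @ u
        k = int(np.argmax(np.abs(ori)))
        if ori[k] < 0:
            ori, u = -ori, -u
        q = np.einsum("c,ecs->es", u @ Wr, data[:, subset, :])
        asi[v] = np.abs(q).sum()
        oris[v] = ori
    n_t = data.shape[0] * data.shape[2]
    return AccumulatedSourceImage(
        asi=asi, coords=lead.coords, n_timepoints=n_t,
        band=get_band(band) if band is not None else None,
        slice_indices=np.arange(1, max(1, n_t // 2) + 1),
        orientations=oris,
    )


@dataclass
class PeakList:
    coords: np.ndarray           # (n_peaks, 3), sorted by descending strength
    strengths: np.ndarray
    flat: bool = False           # image was flat; arbitrary deterministic peak


def localize_peak(
    asi: AccumulatedSourceImage,
    grid: SourceGrid | None = None,
    min_separation_mm: float = 10.0,
) -> PeakList:
    """Local maxima of the accumulated image, merged by the 10-mm rule."""
    vals = np.asarray(asi.asi, dtype=float)
    coords = np.asarray(asi.coords, dtype=float)
    if vals.size == 0:
        raise InputError("empty source image")
    spread = np.ptp(vals)
    if spread <= 1e-15 * max(np.max(np.abs(vals)), np.finfo(float).tiny):
        return PeakList(coords=coords[:1], strengths=vals[:1], flat=True)
    spacing = grid.spacing if grid is not None else _min_spacing(coords)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=1.5 * spacing, output_type="ndarray")
    is_max = np.ones(vals.size, dtype=bool)
    if pairs.size:
        i, j = pairs[:, 0], pairs[:, 1]
        np.minimum.at(is_max, i[vals[i] < vals[j]], False)
        np.minimum.at(is_max, j[vals[j] < vals[i]], False)
    cand = np.nonzero(is_max)[0]
    merged_coords, merged_strengths = merge_close_peaks(
        coords[cand], vals[cand], min_separation_mm
    )
    return PeakList(coords=merged_coords, strengths=merged_strengths)


def _min_spacing(coords: np.ndarray) -> float:
    if coords.shape[0] < 2:
        return 1.0
    tree = cKDTree(coords)
    d, _ = tree.query(coords, k=2)
    return float(np.min(d[:, 1]))
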