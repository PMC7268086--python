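"""Band filtering, covariance, vector/scalar beamformer, accumulated imaging."""

import numpy as np
import pytest
from scipy import signal as sg

from megfc.bands import bandpass_sos
from megfc.beamform import (
    accumulate_source_image,
    bandpass_epochs,
    beamformer_scan,
    estimate_orientation,
    localize_peak,
    prepare_scan,
    scalar_source_timeseries,
    select_partial_sensors,
    sensor_covariance,
    vector_beamformer,
)
from megfc.errors import ConfigurationError, DegenerateVoxelError, InputError
from megfc.headmodel import compute_lead_field
from megfc.preprocess import segment_epochs
from megfc.recording import SensorRecording
from megfc.simulate import make_sensor_array


@pytest.fixture(scope="module")
def arr16():
    return make_sensor_array(16, 0.12, 0.09)


def epochs_from(data, fs, arr):
    return segment_epochs(SensorRecording(data=data, sampling_rate=fs, array=arr), 0.5)


def sine_epochs(freq, fs, dur, arr):
    t = np.arange(int(dur * fs)) / fs
    return epochs_from(np.tile(np.sin(2 * np.pi * freq * t), (arr.n_channels, 1)), fs, arr)


class TestBandpass:
    def test_in_band_tone_preserved(self, arr16):
        # filter property measured on a long epoch (edge transients on
        # 500-sample epochs would otherwise dominate the RMS)
        t = np.arange(4000) / 1000.0
        data = np.tile(np.sin(2 * np.pi * 10.0 * t), (16, 1))
        eps = segment_epochs(SensorRecording(data=data, sampling_rate=1000.0,
                                             array=arr16), 4.0)
        out = bandpass_epochs(eps, "alpha")
        db = 20 * np.log10(out.epochs.std() / eps.epochs.std())
        assert abs(db) < 1.0

    def test_out_of_band_tone_suppressed(self, arr16):
        t = np.arange(4000) / 1000.0
        data = np.tile(np.sin(2 * np.pi * 50.0 * t), (16, 1))
        eps = segment_epochs(SensorRecording(data=data, sampling_rate=1000.0,
                                             array=arr16), 4.0)
        out = bandpass_epochs(eps, "alpha")
        db = 20 * np.log10(out.epochs.std() / eps.epochs.std())
        assert db <= -30.0

    def test_zero_in_zero_out(self, arr16):
        eps = epochs_from(np.zeros((16, 2000)), 1000.0, arr16)
        assert np.all(bandpass_epochs(eps, "gamma").epochs == 0.0)

    def test_band_above_nyquist_rejected(self, arr16):
        eps = epochs_from(np.zeros((16, 200)), 120.0, arr16)
        with pytest.raises(ConfigurationError):
            bandpass_epochs(eps, "gamma")

    def test_no_cross_epoch_leakage(self, arr16, rng):
        # filtering an epoch alone equals filtering it inside the set
        data = rng.standard_normal((16, 2000))
        eps = epochs_from(data, 1000.0, arr16)
        out = bandpass_epochs(eps, "beta")
        sos = bandpass_sos("beta", 1000.0)
        solo = sg.sosfiltfilt(sos, eps.epochs[1], axis=-1)
        np.testing.assert_allclose(out.epochs[1], solo, atol=1e-12)


class TestCovariance:
    def test_white_noise_recovers_identity(self, arr16):
        rng = np.random.default_rng(3)
        eps = epochs_from(rng.standard_normal((16, 60000)), 1000.0, arr16)
        C = sensor_covariance(eps, regularization=0.0)
        assert np.linalg.norm(C - np.eye(16)) / np.linalg.norm(np.eye(16)) < 0.1

    def test_diagonal_loading_exact(self, arr16, rng):
        eps = epochs_from(rng.standard_normal((16, 2000)), 1000.0, arr16)
        C0 = sensor_covariance(eps, regularization=0.0)
        C1 = sensor_covariance(eps, regularization=0.05)
        np.testing.assert_allclose(np.diag(C1) - np.diag(C0),
                                   0.05 * np.mean(np.diag(C0)), rtol=1e-10)

    def test_rank_deficient_data_still_positive_definite(self, arr16, rng):
        data = rng.standard_normal((16, 2000))
        data[1] = data[0]                      # duplicate channel
        C = sensor_covariance(epochs_from(data, 1000.0, arr16))
        assert np.linalg.eigvalsh(C)[0] > 0

    def test_single_epoch_rejected(self, arr16):
        eps = epochs_from(np.zeros((16, 500)), 1000.0, arr16)
        with pytest.raises(InputError):
            sensor_covariance(eps)


class TestPartialSensors:
    def test_uniform_norms_select_all(self):
        L = np.tile(np.eye(3)[None, 0], (40, 1))
        assert select_partial_sensors(L, min_count=10).size == 40

    def test_dominant_channel_floor_kicks_in(self, rng):
        norms = np.full(60, 0.001)
        norms[7] = 1.0
        L = norms[:, None] * np.array([1.0, 0, 0])[None, :]
        sel = select_partial_sensors(L, min_fraction=0.10, min_count=30)
        assert sel.size == 30
        order = np.lexsort((np.arange(60), -norms))
        np.testing.assert_array_equal(np.sort(order[:30]), sel)

    def test_silent_voxel_raises(self):
        with pytest.raises(DegenerateVoxelError):
            select_partial_sensors(np.zeros((20, 3)))


def random_spd(n, rng):
    A = rng.standard_normal((n, n))
    return A @ A.T + n * np.eye(n)


class TestVectorBeamformer:
    def test_identity_cov_orthonormal_lead(self):
        L, _ = np.linalg.qr(np.arange(30.0).reshape(10, 3) + np.eye(10, 3))
        w = vector_beamformer(np.eye(10), L)
        np.testing.assert_allclose(w.W @ L, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(np.abs(w.W), np.abs(L.T), atol=1e-10)

    def test_unit_gain_random_inputs(self, rng):
        for _ in range(10):
            C = random_spd(24, rng)
            L = rng.standard_normal((24, 3))
            w = vector_beamformer(C, L)
            assert w.unit_gain_error(L) < 1e-8

    def test_minimum_variance_among_unit_gain_candidates(self, rng):
        C = random_spd(12, rng)
        L = rng.standard_normal((12, 3))
        w = vector_beamformer(C, L)
        var_opt = np.trace(w.W @ C @ w.W.T)
        Cinv = np.linalg.inv(C)
        W0 = np.linalg.solve(L.T @ Cinv @ L, L.T @ Cinv)
        for _ in range(100):
            # random unit-gain perturbation: W0 + N with N L = 0
            N = rng.standard_normal((3, 12))
            N -= (N @ L) @ np.linalg.pinv(L)
            alt = W0 + 0.3 * N
            np.testing.assert_allclose(alt @ L, np.eye(3), atol=1e-8)
            assert np.trace(alt @ C @ alt.T) >= var_opt - 1e-10

    def test_rank_two_lead_field_flagged(self, rng):
        C = random_spd(20, rng)
        basis = rng.standard_normal((3, 2))
        L = rng.standard_normal((20, 2)) @ basis.T       # rank 2
        w = vector_beamformer(C, L)
        assert w.rank == 2 and w.rank_deficient
        assert w.unit_gain_error(L) < 1e-8

    def test_rank_one_rejected(self, rng):
        C = random_spd(20, rng)
        L = np.outer(rng.standard_normal(20), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateVoxelError):
            vector_beamformer(C, L)


class TestOrientation:
    def test_dominant_axis_recovered(self, rng):
        # construct weights whose source covariance is diag(4, 1, 0.1)
        n = 15
        C = np.eye(n)
        W = np.zeros((3, n))
        W[0, 0] = 2.0
        W[1, 1] = 1.0
        W[2, 2] = np.sqrt(0.1)
        from megfc.beamform import BeamformerWeights
        w = BeamformerWeights(W=W, subset=np.arange(n), basis=np.eye(3), rank=3)
        est = estimate_orientation(w, C)
        np.testing.assert_allclose(est.vector, [1.0, 0.0, 0.0], atol=1e-12)
        assert not est.tied

    def test_isotropic_source_tie_flagged(self):
        from megfc.beamform import BeamformerWeights
        n = 6
        W = np.zeros((3, n))
        W[:, :3] = np.eye(3)
        w = BeamformerWeights(W=W, subset=np.arange(n), basis=np.eye(3), rank=3)
        est = estimate_orientation(w, np.eye(n))
        assert est.tied

    def test_simulated_dipole_orientation_within_10_degrees(self, array, rng):
        r0 = np.array([0.03, 0.01, 0.05])
        lf = compute_lead_field(r0[None], array)
        rhat = r0 / np.linalg.norm(r0)
        t1 = np.cross([0, 0, 1.0], rhat)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(rhat, t1)
        q = np.cos(0.7) * t1 + np.sin(0.7) * t2
        topo = lf.gain[0] @ q
        s = rng.standard_normal(2000)
        clean = topo[:, None] * s[None, :]
        noise = rng.normal(0, np.sqrt(np.mean(clean ** 2)) * 10 ** (-20 / 20),
                           clean.shape)
        eps = epochs_from(clean + noise, 1000.0, array)
        C = sensor_covariance(eps)
        subset = select_partial_sensors(lf.gain[0])
        w = vector_beamformer(C, lf.gain[0], subset)
        est = estimate_orientation(w, C)
        angle = np.degrees(np.arccos(min(1.0, abs(est.vector @ q))))
        assert angle < 10.0


class TestScalarAndAsi:
    def test_zero_data_zero_q(self, arr16):
        from megfc.beamform import BeamformerWeights
        eps = epochs_from(np.zeros((16, 2000)), 1000.0, arr16)
        w = BeamformerWeights(W=np.ones((3, 16)), subset=np.arange(16),
                              basis=np.eye(3), rank=3)
        sa = scalar_source_timeseries(eps, np.array([1.0, 0, 0]), w)
        assert np.all(sa.Q == 0.0)

    def test_q_linear_in_sensor_data(self, arr16, rng):
        from megfc.beamform import BeamformerWeights
        data = rng.standard_normal((16, 2000))
        w = BeamformerWeights(W=rng.standard_normal((3, 16)),
                              subset=np.arange(16), basis=np.eye(3), rank=3)
        ori = np.array([0.0, 1.0, 0.0])
        q1 = scalar_source_timeseries(epochs_from(data, 1000.0, arr16), ori, w).Q
        q2 = scalar_source_timeseries(epochs_from(3 * data, 1000.0, arr16), ori, w).Q
        np.testing.assert_allclose(q2, 3 * q1, rtol=1e-9)

    def test_asi_trivial_values(self):
        out = accumulate_source_image(np.ones(10))
        assert out.asi[0] == 10.0
        assert accumulate_source_image(np.zeros((2, 5))).asi.tolist() == [0.0, 0.0]

    def test_asi_matches_naive_loop(self, rng):
        Q = rng.standard_normal((7, 40))
        out = accumulate_source_image(Q)
        naive = np.array([sum(abs(Q[v, t]) for t in range(40)) for v in range(7)])
        np.testing.assert_allclose(out.asi, naive, atol=1e-12)

    def test_signed_variant(self, rng):
        Q = rng.standard_normal((3, 20))
        np.testing.assert_allclose(accumulate_source_image(Q, signed=True).asi,
                                   Q.sum(axis=1), atol=1e-12)

    def test_empty_time_axis_rejected(self):
        with pytest.raises(InputError):
            accumulate_source_image(np.empty((3, 0)))


class TestLocalization:
    def test_flat_image_deterministic_flagged_peak(self, grid):
        from megfc.beamform import AccumulatedSourceImage
        asi = AccumulatedSourceImage(asi=np.ones(grid.n_voxels),
                                     coords=grid.coords, n_timepoints=10)
        peaks = localize_peak(asi, grid)
        assert peaks.flat
        np.testing.assert_array_equal(peaks.coords[0], grid.coords[0])

    def test_two_distant_dipoles_resolved(self, array, grid, full_lead, rng):
        locs = np.array([[0.0, 0.04, 0.03], [0.0, 0.0, 0.07]])   # 41 mm apart
        data = np.zeros((array.n_channels, 1000))
        for loc in locs:
            lf = compute_lead_field(loc[None], array)
            rhat = loc / np.linalg.norm(loc)
            t1 = np.cross([1.0, 0, 0], rhat)
            t1 /= np.linalg.norm(t1)
            topo = lf.gain[0] @ t1
            sos = bandpass_sos("beta", 1000.0)
            s = sg.sosfiltfilt(sos, rng.standard_normal(1000))
            data += topo[:, None] * (s / s.std())[None, :]
        data += rng.normal(0, np.sqrt(np.mean(data ** 2)) * 0.1, data.shape)
        eps = bandpass_epochs(epochs_from(data, 1000.0, array), "beta")
        asi = beamformer_scan(eps, full_lead)
        peaks = localize_peak(asi, grid)
        assert peaks.coords.shape[0] >= 2
        for loc in locs:
            err = np.min(np.linalg.norm(peaks.coords[:4] - loc, axis=1))
            assert err <= 0.006

    def test_band_separation_in_source_images(self, array, grid, full_lead, rng):
        # a pure 40-Hz source shows up in the gamma image, not the alpha one
        loc = np.array([0.0, 0.045, 0.04])
        lf = compute_lead_field(loc[None], array)
        rhat = loc / np.linalg.norm(loc)
        t1 = np.cross([1.0, 0, 0], rhat)
        t1 /= np.linalg.norm(t1)
        t = np.arange(1000) / 1000.0
        topo = lf.gain[0] @ t1
        data = topo[:, None] * np.sin(2 * np.pi * 40.0 * t)[None, :]
        data += rng.normal(0, np.sqrt(np.mean(data ** 2)) * 0.1, data.shape)
        eps = epochs_from(data, 1000.0, array)
        vox = int(np.argmin(np.linalg.norm(grid.coords - loc, axis=1)))
        ctx = prepare_scan(full_lead)
        asi_g = beamformer_scan(bandpass_epochs(eps, "gamma"), full_lead,
                                scan_context=ctx)
        asi_a = beamformer_scan(bandpass_epochs(eps, "alpha"), full_lead,
                                scan_context=ctx)
        assert asi_g.asi[vox] >= 10.0 * asi_a.asi[vox]
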