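import numpy as np
import pytest

from conftest import inscribed_mask, rmse
from optij.alignment import GeometryModel
from optij.errors import GeometryError
from optij.opt_sim import (ArtifactSpec, Phantom, forward_project,
                           inject_jitter, make_phantom)
from optij.reconstruct import (FilterSpec, Sinogram, create_sinograms,
                               design_filter, fbp_slice, filter_sinogram,
                               reconstruct_volume)
from optij.stack_io import AcquisitionGeometry


class TestCreateSinograms:
    def test_identity_model_is_passthrough(self, clean_bead_stack):
        sinos = create_sinograms(clean_bead_stack, rows=[10, 16])
        np.testing.assert_array_equal(sinos[0].data,
                                      clean_bead_stack.data[:, 10, :])
        np.testing.assert_array_equal(sinos[1].data,
                                      clean_bead_stack.data[:, 16, :])
        assert sinos[0].center_col == 31.5
        assert sinos[0].slice_row == 10

    def test_integer_offset_is_exact_shift(self, rng):
        from optij.stack_io import ProjectionStack
        data = rng.random((4, 6, 16)).astype(np.float64)
        stack = ProjectionStack(data, AcquisitionGeometry(n_projections=4,
                                                          modality="eOPT"))
        sinos = create_sinograms(stack, GeometryModel(axis_offset_px=3.0),
                                 rows=[2])
        expected = np.zeros_like(data[:, 2, :])
        expected[:, :-3] = data[:, 2, 3:]
        np.testing.assert_allclose(sinos[0].data, expected, atol=1e-12)

    def test_row_out_of_range(self, clean_bead_stack):
        with pytest.raises(IndexError):
            create_sinograms(clean_bead_stack, rows=[99])

    def test_corrections_length_checked(self, clean_bead_stack):
        with pytest.raises(GeometryError):
            create_sinograms(clean_bead_stack,
                             jitter_corrections=np.zeros(5), rows=[0])

    def test_offset_plus_jitter_yield_smooth_sinogram(self, clean_bead_stack):
        """After correction the bead trace matches its fitted sinusoid."""
        from conftest import BEAD_RADIUS_PX, BEAD_ROW
        from optij.alignment import (dynamic_offset, estimate_geometry,
                                     fit_sinusoid, track_fiducial)

        spec = ArtifactSpec(axis_offset_px=4.0, jitter_sigma_px=2.0,
                            jitter_seed=11)
        # rebuild the same bead phantom with artifacts
        ph = make_phantom("bead", (32, 64, 64),
                          {"center": (BEAD_ROW, 31.5, 31.5 + BEAD_RADIUS_PX),
                           "radius": 1.5, "value": 10.0})
        stack = forward_project(ph, clean_bead_stack.geometry, spec)
        roi = (31.5 + BEAD_RADIUS_PX + 4.0 - 14, BEAD_ROW - 14, 28, 28)
        track = track_fiducial(stack, roi, window_px=28)
        model = estimate_geometry(track, stack.center_col)
        corr = dynamic_offset(track)
        sino = create_sinograms(stack, model, corr, rows=[BEAD_ROW])[0]

        cols = np.arange(sino.data.shape[1])
        centroid = (sino.data * cols).sum(1) / sino.data.sum(1)
        fit = fit_sinusoid(sino.angles_deg, centroid)
        assert fit.rmse_px < 0.5
        # corrected trace is centered on the detector again
        assert abs(fit.mean_px - sino.center_col) < 0.3


class TestDesignFilter:
    def test_ramp_at_nyquist(self):
        response = design_filter("ramp", 256, spacing=1.0)
        assert response[128] == pytest.approx(0.5)

    def test_shepp_logan_at_nyquist(self):
        response = design_filter("shepp_logan", 256, spacing=1.0)
        assert response[128] == pytest.approx(0.5 * 2.0 / np.pi, abs=1e-12)

    def test_hamming_at_nyquist(self):
        response = design_filter("hamming", 256, spacing=1.0)
        assert response[128] == pytest.approx(0.5 * (0.54 - 0.46), abs=1e-12)

    def test_spacing_scales_nyquist(self):
        response = design_filter("ramp", 128, spacing=0.5)
        assert response[64] == pytest.approx(1.0)  # f_N = 1/(2*0.5)

    def test_dc_is_discrete_ramlak_value_not_zero(self):
        response = design_filter("ramp", 256)
        assert response[0] > 0.0
        assert response[0] < np.abs(np.fft.fftfreq(256))[1]

    def test_none_filter_all_pass(self):
        np.testing.assert_array_equal(design_filter("none", 64), 1.0)

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError):
            design_filter("ramp", 255)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            design_filter("butterworth", 256)

    def test_frequency_filtering_equals_spatial_convolution(self, rng):
        """Convolution-theorem oracle: the FFT path must equal direct
        circular convolution with the inverse-transformed kernel."""
        n = 128
        signal = rng.normal(size=n)
        response = design_filter("ramp", n)
        via_fft = np.real(np.fft.ifft(np.fft.fft(signal) * response))
        kernel = np.real(np.fft.ifft(response))
        direct = np.array([
            sum(signal[(i - k) % n] * kernel[k] for k in range(n))
            for i in range(n)])
        assert np.max(np.abs(via_fft - direct)) < 1e-10


def _disk_sinogram(n_angles=256, radius=10.0, size=64):
    ph = make_phantom("disks", (8, size, size),
                      {"disks": [((size - 1) / 2, (size - 1) / 2, radius, 1.0)],
                       "z_band": (4, 5)})
    g = AcquisitionGeometry(n_projections=n_angles, modality="eOPT")
    stack = forward_project(ph, g)
    return create_sinograms(stack, rows=[4])[0], ph.voxels[4]


class TestFbpSlice:
    def test_uniform_disk_plateau_and_background(self):
        sino, truth = _disk_sinogram()
        rec = fbp_slice(sino, FilterSpec("ramp"))
        c = 31.5
        yy, xx = np.mgrid[0:64, 0:64]
        rr = np.hypot(yy - c, xx - c)
        assert 0.9 <= rec[rr <= 7].mean() <= 1.1
        assert -0.05 <= rec[rr >= 20].mean() <= 0.05

    def test_zero_sinogram_zero_slice(self):
        sino = Sinogram(np.zeros((16, 32)), np.arange(16) * 22.5, 15.5)
        np.testing.assert_array_equal(fbp_slice(sino), 0.0)

    def test_linearity(self, rng):
        angles = np.arange(32) * 360.0 / 32.0
        s1 = rng.random((32, 40))
        s2 = rng.random((32, 40))
        a, b = 2.0, -0.7
        combo = fbp_slice(Sinogram(a * s1 + b * s2, angles, 19.5))
        parts = (a * fbp_slice(Sinogram(s1, angles, 19.5))
                 + b * fbp_slice(Sinogram(s2, angles, 19.5)))
        np.testing.assert_allclose(combo, parts, atol=1e-10)

    def test_center_shift_matches_content_shift(self):
        """Translation equivariance linking center_col and column shifts:
        shifting the sinogram content by +2 columns and the declared center
        by +2 reconstructs the same slice (feature moves back by -2 relative
        to the new center)."""
        sino, _ = _disk_sinogram(n_angles=64)
        shifted = np.zeros_like(sino.data)
        shifted[:, 2:] = sino.data[:, :-2]
        rec_ref = fbp_slice(sino, FilterSpec("ramp"))
        rec_shift = fbp_slice(
            Sinogram(shifted, sino.angles_deg, sino.center_col + 2.0),
            FilterSpec("ramp"))
        assert rmse(rec_ref, rec_shift) < 5e-3

    def test_single_angle_center_shift_moves_feature(self):
        """At one angle, +2 on center_col moves the back-smeared feature by
        -2 px along the detector direction."""
        data = np.zeros((1, 64))
        data[0, 40] = 1.0
        rec0 = fbp_slice(Sinogram(data, np.array([0.0]), 31.5),
                         FilterSpec("none"), circle=False)
        rec2 = fbp_slice(Sinogram(data, np.array([0.0]), 33.5),
                         FilterSpec("none"), circle=False)
        # angle 0: detector coordinate is x; column of the bright stripe
        col0 = int(np.argmax(rec0[32]))
        col2 = int(np.argmax(rec2[32]))
        assert col2 - col0 == -2

    def test_empty_sinogram(self):
        with pytest.raises(ValueError):
            fbp_slice(Sinogram(np.zeros((0, 8)), np.zeros(0), 3.5))

    def test_output_size_capped_at_detector_width(self):
        sino, _ = _disk_sinogram(n_angles=16)
        with pytest.raises(ValueError):
            fbp_slice(sino, output_size=100)

    def test_outside_inscribed_circle_zeroed(self):
        sino, _ = _disk_sinogram(n_angles=32)
        rec = fbp_slice(sino)
        assert rec[0, 0] == 0.0 and rec[-1, -1] == 0.0

    @pytest.mark.parametrize("kind", ["ramp", "hamming", "shepp_logan"])
    def test_all_filters_reconstruct_disk(self, kind):
        sino, truth = _disk_sinogram(n_angles=128)
        rec = fbp_slice(sino, FilterSpec(kind))
        mask = inscribed_mask(64)
        assert np.corrcoef(rec[mask], truth[mask])[0, 1] > 0.9


class TestSheppLoganOracle:
    def test_fbp_recovers_phantom(self):
        from skimage.data import shepp_logan_phantom
        from skimage.transform import resize

        plane = resize(shepp_logan_phantom(), (128, 128), order=1,
                       anti_aliasing=True, preserve_range=True)
        plane /= plane.max()
        vox = np.zeros((8, 128, 128))
        vox[4] = plane
        g = AcquisitionGeometry(n_projections=256, modality="eOPT")
        stack = forward_project(Phantom(vox), g)
        rec = fbp_slice(create_sinograms(stack, rows=[4])[0],
                        FilterSpec("ramp"))
        mask = inscribed_mask(128)
        r = np.corrcoef(rec[mask], plane[mask])[0, 1]
        assert r >= 0.98
        assert rmse(rec, plane, mask) <= 0.08


class TestReconstructVolume:
    def test_worker_count_does_not_change_voxels(self, rng):
        from optij.stack_io import ProjectionStack
        data = rng.random((24, 32, 48))
        stack = ProjectionStack(data, AcquisitionGeometry(
            n_projections=24, modality="eOPT"))
        v1 = reconstruct_volume(stack, workers=1)
        v4 = reconstruct_volume(stack, workers=4)
        assert np.max(np.abs(v1.voxels - v4.voxels)) < 1e-10

    def test_bead_centroid_recovered_in_3d(self):
        center = (8, 27.0, 38.0)
        ph = make_phantom("bead", (16, 64, 64),
                          {"center": center, "radius": 2.0, "value": 1.0})
        g = AcquisitionGeometry(n_projections=128, modality="eOPT")
        stack = forward_project(ph, g)
        vol = reconstruct_volume(stack, rows=range(16))
        vox = np.clip(vol.voxels, 0, None)
        zz, yy, xx = np.mgrid[0:16, 0:64, 0:64]
        m = vox.sum()
        cz = (vox * zz).sum() / m
        cy = (vox * yy).sum() / m
        cx = (vox * xx).sum() / m
        assert abs(cz - center[0]) < 0.5
        assert abs(cy - center[1]) < 0.5
        assert abs(cx - center[2]) < 0.5

    def test_more_angles_less_streaking(self, disks_phantom):
        truth = disks_phantom.voxels[3]
        mask = inscribed_mask(64)
        errs = []
        for n in (64, 512):
            g = AcquisitionGeometry(n_projections=n, modality="eOPT")
            stack = forward_project(disks_phantom, g)
            vol = reconstruct_volume(stack, rows=[3])
            errs.append(rmse(vol.voxels[0], truth, mask))
        assert errs[1] < errs[0]

    def test_offset_correction_removes_shadow_artifact(self):
        """Uncorrected 5 px axis offset degrades the slice; applying the
        estimated model restores it."""
        from optij.alignment import estimate_geometry, track_fiducial

        disks = make_phantom("disks", (16, 64, 64), {"z_band": (3, 5)})
        bead = make_phantom("bead", (16, 64, 64),
                            {"center": (12, 31.5, 31.5 + 18.0), "radius": 1.5,
                             "value": 10.0})
        ph = Phantom(disks.voxels + bead.voxels)
        g = AcquisitionGeometry(n_projections=128, modality="eOPT")
        stack = forward_project(ph, g, ArtifactSpec(axis_offset_px=5.0))

        truth = disks.voxels[3]
        mask = inscribed_mask(64)
        uncorrected = reconstruct_volume(stack, rows=[3]).voxels[0]

        track = track_fiducial(stack, (31.5 + 18 + 5 - 8, 12 - 5, 16, 10),
                               window_px=12)
        model = estimate_geometry(track, stack.center_col)
        corrected = reconstruct_volume(stack, model, rows=[3]).voxels[0]
        assert rmse(corrected, truth, mask) < rmse(uncorrected, truth, mask)


class TestFilterSinogram:
    def test_padding_suppresses_wraparound(self, rng):
        # a bright edge feature: padded filtering must not wrap energy around
        data = np.zeros((1, 64))
        data[0, :8] = 50.0
        f2 = filter_sinogram(data, FilterSpec("ramp", padding=2))
        f8 = filter_sinogram(data, FilterSpec("ramp", padding=8))
        # far-side response difference shrinks with padding: compare tails
        assert np.max(np.abs(f2[0, 48:] - f8[0, 48:])) < 0.1
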