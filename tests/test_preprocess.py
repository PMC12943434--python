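import numpy as np
import pytest

from xrdtissue.geometry import q_phi_map
from xrdtissue.preprocess import (
    apply_region_mask,
    beam_anisotropy_correction,
    extract_ring_profile,
)
from xrdtissue.simulate import RingSpec, TissueClassModel, cancer_model, generate_frame


@pytest.fixture
def water_frame(centered_geometry):
    """Noiseless frame with lipid (q=14) and water (q=20) rings."""
    model = TissueClassModel(
        label="cancer",
        rings=(
            RingSpec(14.0, 1.2, 40.0, phase_mode="fixed"),
            RingSpec(20.0, 2.2, 240.0, 80.0, 16.0, "fixed", (0.3, 1.1)),
        ),
        background_amplitude=100.0,
        patient_effect_sd=0.0,
    )
    return generate_frame(model, centered_geometry, noise="none")


class TestRegionMask:
    def test_keep_everything_is_identity(self, water_frame, centered_geometry):
        masked, region = apply_region_mask(
            water_frame, centered_geometry, q_ranges=[(0.0, np.inf)]
        )
        assert np.array_equal(masked.data, water_frame.data)
        assert not region.mask.any()

    def test_water_cutoff_zeroes_lipid_keeps_water(self, water_frame, centered_geometry):
        masked, region = apply_region_mask(
            water_frame, centered_geometry, q_ranges=[(16.0, np.inf)]
        )
        q = q_phi_map(centered_geometry).q
        lipid = np.abs(q - 14.0) < 1.0
        water = np.abs(q - 20.0) < 1.0
        assert np.all(masked.data[lipid] == 0)
        assert np.array_equal(masked.data[water], water_frame.data[water])
        assert np.array_equal(region.mask, q < 16.0)

    def test_annulus_pixel_census_matches_brute_force(self, water_frame, centered_geometry):
        masked, region = apply_region_mask(
            water_frame, centered_geometry, q_ranges=[(10.0, 15.0)]
        )
        q = q_phi_map(centered_geometry).q
        brute = sum(
            1
            for r in range(q.shape[0])
            for c in range(q.shape[1])
            if 10.0 <= q[r, c] < 15.0
        )
        assert int((~region.mask).sum()) == brute

    def test_rectangle_keep_is_boundary_inclusive(self, water_frame, centered_geometry):
        masked, region = apply_region_mask(water_frame, centered_geometry, rect=(10, 20, 30, 40))
        kept = ~region.mask
        assert kept[10, 30] and kept[20, 40]
        assert kept.sum() == 11 * 11

    def test_empty_keep_region_raises(self, water_frame, centered_geometry):
        with pytest.raises(ValueError, match="keeps no pixels"):
            apply_region_mask(water_frame, centered_geometry, q_ranges=[(500.0, 600.0)])

    def test_masking_is_idempotent(self, water_frame, centered_geometry):
        once, m1 = apply_region_mask(water_frame, centered_geometry, q_ranges=[(16.0, np.inf)])
        twice, m2 = apply_region_mask(once, centered_geometry, q_ranges=[(16.0, np.inf)])
        assert np.array_equal(once.data, twice.data)
        assert np.array_equal(m1.mask, m2.mask)


class TestBeamCorrection:
    def test_radially_affine_field_maps_to_zero(self, centered_geometry):
        rr, cc = np.meshgrid(
            np.arange(129, dtype=float), np.arange(129, dtype=float), indexing="ij"
        )
        r = np.hypot(rr - 64.0, cc - 64.0)
        a, b = 50.0, 2.0
        field = a + b * r
        corrected, valid = beam_anisotropy_correction(field, centered_geometry, shift=5)
        # nearest-pixel sampling perturbs each sampled radius by < ~0.71 px
        assert np.nanmax(np.abs(corrected[valid])) <= b * 0.25
        # away from the center (where the radius function is nearly flat
        # across a pixel) the annihilation is much tighter
        far = valid & (r >= 15)
        assert np.nanmax(np.abs(corrected[far])) <= 0.05 * b
        corrected_b, valid_b = beam_anisotropy_correction(
            field, centered_geometry, shift=5, sampling="bilinear"
        )
        assert np.nanmax(np.abs(corrected_b[valid_b & (r >= 15)])) <= 0.02 * b

    def test_separable_field_preserves_azimuthal_shape(self, ring_geometry):
        """For I = g(r) h(phi) with Gaussian g, the corrected ring equals
        h(phi) times a positive radial factor."""
        rr, cc = np.meshgrid(
            np.arange(256, dtype=float), np.arange(256, dtype=float), indexing="ij"
        )
        r = np.hypot(rr - 127.5, cc - 127.5)
        phi = np.mod(np.arctan2(rr - 127.5, cc - 127.5), 2 * np.pi)
        r0, sigma, shift = 83.0, 6.0, 5
        g = np.exp(-((r - r0) ** 2) / (2 * sigma**2))
        h = 10.0 + 3.0 * np.sin(2 * phi + 0.4)
        corrected, valid = beam_anisotropy_correction(
            g * h, ring_geometry, shift=shift, sampling="bilinear"
        )
        on_ring = (np.abs(r - r0) < 0.3) & valid
        expected_radial = 1.0 - np.exp(-(shift**2) / (2 * sigma**2))
        ratio = corrected[on_ring] / h[on_ring]
        assert ratio.min() > 0
        assert np.allclose(ratio, expected_radial, rtol=0.08)

    def test_correction_is_linear(self, centered_geometry):
        rng = np.random.default_rng(2)
        I = rng.uniform(0, 100, centered_geometry.shape)
        J = rng.uniform(0, 100, centered_geometry.shape)
        ca, va = beam_anisotropy_correction(I, centered_geometry)
        cb, vb = beam_anisotropy_correction(J, centered_geometry)
        cc_, vc = beam_anisotropy_correction(2.0 * I + 3.0 * J, centered_geometry)
        v = va & vb & vc
        assert np.allclose(cc_[v], 2.0 * ca[v] + 3.0 * cb[v], atol=1e-9)

    def test_smeared_isotropic_ring_spurious_harmonic_reduced(self, ring_geometry):
        from xrdtissue.anisotropy import fit_sinusoids

        for seed in range(3):
            rng = np.random.default_rng(seed)
            model = TissueClassModel(
                label="iso",
                rings=(RingSpec(0.3, 0.02, rng.uniform(80, 160), phase_mode="fixed"),),
                background_amplitude=rng.uniform(10, 40),
                patient_effect_sd=0.0,
            )
            frame = generate_frame(
                model, ring_geometry, noise="none",
                beam_smear=(rng.uniform(0.3, 1.0), rng.uniform(2.0, 3.5)),
            )
            fit_u = fit_sinusoids(extract_ring_profile(frame, ring_geometry, 0.3))
            corr, valid = beam_anisotropy_correction(frame.data, ring_geometry, shift=5)
            fit_c = fit_sinusoids(
                extract_ring_profile(corr, ring_geometry, 0.3, valid=valid)
            )
            assert fit_c.A1 < fit_u.A1

    def test_invalid_shift_rejected(self, centered_geometry):
        with pytest.raises(ValueError, match="shift"):
            beam_anisotropy_correction(
                np.ones(centered_geometry.shape), centered_geometry, shift=0
            )


class TestRingProfile:
    def test_uniform_frame_gives_constant_profile(self, ring_geometry):
        prof = extract_ring_profile(
            np.full(ring_geometry.shape, 4.0), ring_geometry, q_center=0.3
        )
        assert np.allclose(prof.intensity[~prof.empty], 4.0)

    def test_profile_matches_generating_law_within_poisson_error(self, ring_geometry):
        from xrdtissue.anisotropy import fit_sinusoids

        model = TissueClassModel(
            label="x",
            rings=(RingSpec(0.3, 0.02, 480.0, 180.0, 48.0, "fixed", (0.5, 1.0)),),
            background_amplitude=0.0,
            patient_effect_sd=0.0,
        )
        frame = generate_frame(model, ring_geometry, rng=np.random.default_rng(9))
        prof = extract_ring_profile(frame, ring_geometry, q_center=0.3, n_phi_bins=72)
        fit = fit_sinusoids(prof)
        # annulus averaging scales all ring amplitudes by one radial factor,
        # so amplitude ratios and phases are preserved
        assert fit.A1 / fit.A0 == pytest.approx(180.0 / 480.0, rel=0.1)
        assert fit.A2 / fit.A0 == pytest.approx(48.0 / 480.0, rel=0.2)
        assert np.cos(fit.phi1 - 0.5) == pytest.approx(1.0, abs=0.01)
        assert np.cos(fit.phi2 - 1.0) == pytest.approx(1.0, abs=0.01)

    def test_rotated_frame_gives_circularly_shifted_profile(self, ring_geometry):
        model = cancer_model(patient_effect_sd=0.0)
        frame = generate_frame(
            model, ring_geometry, noise="none", phases={0: (0.9, 2.2)}
        )
        prof = extract_ring_profile(frame, ring_geometry, 0.3, n_phi_bins=72)
        # beam center (127.5, 127.5): rot90 is an exact quarter turn
        prof_rot = extract_ring_profile(
            np.rot90(frame.data), ring_geometry, 0.3, n_phi_bins=72
        )
        assert np.allclose(
            np.roll(prof.intensity, 18), prof_rot.intensity, rtol=1e-9, atol=1e-9
        )

    def test_fully_masked_annulus_raises(self, ring_geometry):
        data = np.ones(ring_geometry.shape)
        valid = np.zeros(ring_geometry.shape, dtype=bool)
        with pytest.raises(ValueError, match="no usable pixels"):
            extract_ring_profile(data, ring_geometry, 0.3, valid=valid)

    def test_too_few_bins_rejected(self, ring_geometry):
        with pytest.raises(ValueError, match="n_phi_bins"):
            extract_ring_profile(np.ones(ring_geometry.shape), ring_geometry, 0.3, n_phi_bins=4)
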