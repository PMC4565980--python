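import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import NOISE_OFF
from telolamina import (
    LaminaSurface,
    MultiChannelVolume,
    NucleusMask,
    RadialProfile,
    Section,
    TelomereSpot,
    ValidationError,
    aggregate_profiles,
    analyze_volume,
    categorize_telomeres,
    distance_to_lamina,
    extract_lamina_surface,
    generate_nucleus_volume,
    normalize_profiles,
    nucleus_coverage,
    project_mask,
    project_section,
    radial_profile,
    telomere_coverage,
)


def make_volume(data, voxel=(125.0, 40.0, 40.0), name="lap2a"):
    return MultiChannelVolume(np.asarray(data, dtype=float)[None], [name],
                              voxel)


def make_spot(z, y, x, voxels=None, spot_id=0):
    if voxels is None:
        voxels = np.array([[0, 0, 0]])
    return TelomereSpot(
        centroid_nm=np.array([z, y, x], dtype=float),
        voxels=np.asarray(voxels),
        equivalent_radius_nm=100.0,
        peak_intensity=1.0,
        spot_id=spot_id,
    )


def flat_section(img, pixel=(40.0, 40.0), name="lap2a"):
    return Section(np.asarray(img, dtype=float)[None], [name], pixel,
                   np.array([0]), 0.0, 125.0)


class TestProjectSection:
    def test_544nm_window_at_dz_125_covers_five_planes(self):
        """A 544 nm window centred on plane 10 spans planes 8..12."""
        data = np.tile(np.arange(20, dtype=float)[:, None, None], (1, 4, 4))
        vol = make_volume(data)
        section = project_section(vol, z_center_nm=10 * 125.0,
                                  thickness_nm=544.0)
        assert list(section.z_planes) == [8, 9, 10, 11, 12]
        assert np.allclose(section.data, 10.0)

    def test_1nm_window_returns_nearest_plane_unchanged(self):
        data = np.tile(np.arange(20, dtype=float)[:, None, None], (1, 4, 4))
        section = project_section(make_volume(data), z_center_nm=1250.0,
                                  thickness_nm=1.0)
        assert list(section.z_planes) == [10]
        assert np.allclose(section.data, 10.0)

    def test_constant_volume_projects_to_constant(self):
        section = project_section(make_volume(np.full((6, 4, 4), 3.5)),
                                  z_center_nm=300.0)
        assert np.allclose(section.data, 3.5)

    def test_window_outside_volume_rejected(self):
        with pytest.raises(ValidationError, match="no z-plane"):
            project_section(make_volume(np.zeros((4, 4, 4))),
                            z_center_nm=1e6, thickness_nm=100.0)


class TestRadialProfile:
    def test_constant_channel_gives_constant_profile(self):
        section = flat_section(np.full((64, 64), 7.0))
        mask = np.ones((64, 64), dtype=bool)
        prof = radial_profile(section, make_spot(0, 1280, 1280), "lap2a", mask)
        assert np.allclose(prof.raw_intensity, 7.0)
        assert prof.distances_nm[0] == 0.0
        assert prof.distances_nm[-1] == 400.0

    def test_disc_oracle_step_profile(self):
        """A 200 nm disc around the spot: full value inside, ~0 past 250 nm."""
        img = np.zeros((64, 64))
        yy, xx = np.mgrid[:64, :64]
        img[((yy - 32) * 40.0) ** 2 + ((xx - 32) * 40.0) ** 2 <= 200.0**2] = 5.0
        section = flat_section(img)
        mask = np.ones((64, 64), dtype=bool)
        prof = radial_profile(section, make_spot(0, 32 * 40.0, 32 * 40.0),
                              "lap2a", mask)
        d = prof.distances_nm
        assert np.allclose(prof.raw_intensity[d < 200 - 40], 5.0)
        assert np.all(prof.raw_intensity[d > 250] < 0.25)

    def test_quarter_turn_symmetry(self, rng):
        """8 rays at 45 degrees are invariant under a 90-degree rotation."""
        img = rng.random((65, 65))
        mask = np.ones((65, 65), dtype=bool)
        c = 32 * 40.0
        p1 = radial_profile(flat_section(img), make_spot(0, c, c), "lap2a",
                            mask)
        p2 = radial_profile(flat_section(np.rot90(img)), make_spot(0, c, c),
                            "lap2a", mask)
        np.testing.assert_allclose(p1.raw_intensity, p2.raw_intensity,
                                   atol=1e-9)

    def test_rays_truncated_at_nucleus_border(self):
        """Samples beyond the mask edge are excluded, not zero-filled."""
        img = np.full((64, 64), 9.0)
        mask = np.zeros((64, 64), dtype=bool)
        mask[:, :33] = True  # spot near the right border of the mask
        prof = radial_profile(flat_section(img), make_spot(0, 1280, 1240),
                              "lap2a", mask)
        # truncated rays never pull the mean below the true constant value
        assert np.allclose(prof.raw_intensity[np.isfinite(prof.raw_intensity)],
                           9.0)

    def test_centroid_outside_nucleus_rejected(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[:10, :10] = True
        with pytest.raises(ValidationError, match="outside"):
            radial_profile(flat_section(np.ones((64, 64))),
                           make_spot(0, 2000, 2000), "lap2a", mask)


class TestNormalization:
    def test_extremes_map_to_zero_and_one(self):
        prof = RadialProfile(0, np.arange(3.0), np.array([4.0, 4.0, 4.0]))
        normalize_profiles([prof], channel_min=4.0, channel_max=8.0)
        assert np.allclose(prof.normalized_intensity, 0.0)
        normalize_profiles([prof], channel_min=0.0, channel_max=4.0)
        assert np.allclose(prof.normalized_intensity, 1.0)

    @given(a=st.floats(0.1, 50.0), b=st.floats(-10.0, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        """Rescaling the channel (a*I + b) leaves normalized profiles fixed."""
        raw = np.array([1.0, 3.0, 2.0, 0.5])
        p1 = RadialProfile(0, np.arange(4.0), raw)
        p2 = RadialProfile(0, np.arange(4.0), a * raw + b)
        normalize_profiles([p1], 0.5, 3.0)
        normalize_profiles([p2], a * 0.5 + b, a * 3.0 + b)
        np.testing.assert_allclose(p1.normalized_intensity,
                                   p2.normalized_intensity, atol=1e-12)

    def test_degenerate_range_rejected(self):
        prof = RadialProfile(0, np.arange(3.0), np.zeros(3))
        with pytest.raises(ValidationError, match="degenerate"):
            normalize_profiles([prof], 2.0, 2.0)


class TestCoverage:
    def _nucleus(self):
        m = np.zeros((5, 20, 20), dtype=bool)
        m[1:4, 4:16, 4:16] = True
        return NucleusMask(m, (125.0, 40.0, 40.0))

    def test_half_covered_nucleus_gives_50_percent(self):
        nuc = self._nucleus()
        lap2 = np.zeros_like(nuc.mask)
        lap2[:, 4:16, 4:10] = True
        lap2 &= nuc.mask
        assert nucleus_coverage(lap2, nuc, z_center_nm=250.0) == \
            pytest.approx(50.0)

    def test_empty_lap2_mask_gives_zero(self):
        nuc = self._nucleus()
        assert nucleus_coverage(np.zeros_like(nuc.mask), nuc, 250.0) == 0.0

    def test_spot_fully_inside_mask_is_100(self):
        nuc = self._nucleus()
        lap2 = nuc.mask.copy()
        spot = make_spot(250, 320, 320,
                         voxels=np.array([[2, 8, 8], [2, 8, 9]]))
        assert telomere_coverage(spot, lap2, (125, 40, 40), 250.0) == 100.0

    def test_spot_fully_outside_mask_is_0(self):
        """A telomere with no LAP2alpha overlap scores 0% coverage."""
        nuc = self._nucleus()
        spot = make_spot(250, 320, 320,
                         voxels=np.array([[2, 8, 8], [2, 9, 8]]))
        assert telomere_coverage(spot, np.zeros_like(nuc.mask),
                                 (125, 40, 40), 250.0) == 0.0

    def test_out_of_section_spot_skipped_with_warning(self):
        nuc = self._nucleus()
        spot = make_spot(0, 320, 320, voxels=np.array([[0, 8, 8]]))
        with pytest.warns(UserWarning, match="skipped"):
            out = telomere_coverage(spot, nuc.mask.copy(), (125, 40, 40),
                                    500.0, thickness_nm=125.0)
        assert out is None

    def test_matches_brute_force_intersection_ratio(self, rng):
        for _ in range(20):
            lap2 = rng.random((4, 12, 12)) < 0.4
            vox = np.unique(
                rng.integers(0, [4, 12, 12], size=(6, 3)), axis=0
            )
            spot = make_spot(0, 0, 0, voxels=vox)
            got = telomere_coverage(spot, lap2, (100, 100, 100),
                                    z_center_nm=150.0, thickness_nm=400.0)
            planes = [0, 1, 2, 3]
            proj = lap2[planes].any(axis=0)
            pix = {(y, x) for _, y, x in vox}
            expected = 100.0 * sum(proj[p] for p in pix) / len(pix)
            assert got == pytest.approx(expected)


class TestCategories:
    def test_printed_worked_example(self):
        """Coverages 12.5/85/36/0 % with a nucleus mean of 15.3%:
        36% is high and 0% is low for any admissible sigma."""
        records, hist = categorize_telomeres(
            [12.5, 85.0, 36.0, 0.0], lap2c_percent=15.3, sigma_percent=10.0
        )
        assert [r.category for r in records] == \
            ["average", "high", "high", "low"]
        assert hist == {"low": 1, "average": 1, "high": 2}

    def test_boundary_is_inclusive_into_average(self):
        records, _ = categorize_telomeres([5.0, 25.0], 15.0, 10.0)
        assert [r.category for r in records] == ["average", "average"]

    def test_matches_brute_force_thresholding(self, rng):
        cov = rng.uniform(0, 100, size=1000)
        lap2c, sigma = 15.3, 12.0
        records, hist = categorize_telomeres(cov, lap2c, sigma)
        lo, hi = lap2c - sigma, lap2c + sigma
        expected = np.where(cov < lo, "low",
                            np.where(cov > hi, "high", "average"))
        assert [r.category for r in records] == list(expected)
        assert sum(hist.values()) == 1000

    def test_thresholds_clamped_to_valid_range(self):
        # lower threshold clamps to 0, so a 0% telomere is still "average"
        records, _ = categorize_telomeres([0.0, 100.0], 5.0, 50.0)
        assert [r.category for r in records] == ["average", "high"]
        # upper threshold clamps to 100, so a 100% telomere is "average"
        records, _ = categorize_telomeres([100.0], 60.0, 50.0)
        assert records[0].category == "average"


class TestDistanceToLamina:
    def test_centroid_on_surface_voxel_is_self_proximal(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[1:4, 1:4, 1:4] = True
        surface = extract_lamina_surface(NucleusMask(m, (125.0, 40.0, 40.0)))
        spot = make_spot(1 * 125.0, 1 * 40.0, 1 * 40.0)
        rec = distance_to_lamina([spot], surface)[0]
        assert rec.distance_nm <= np.linalg.norm([125, 40, 40]) / 2

    def test_sphere_center_distance_is_radius(self):
        vol_radius = 1000.0
        voxel = np.array([125.0, 50.0, 50.0])
        half = np.ceil(vol_radius / voxel).astype(int) + 2
        shape = tuple(2 * half + 1)
        zz, yy, xx = [
            ((np.arange(n) - h) * v)
            for n, h, v in zip(shape, half, voxel)
        ]
        m = (
            zz[:, None, None] ** 2 + yy[None, :, None] ** 2
            + xx[None, None, :] ** 2
        ) <= vol_radius**2
        surface = extract_lamina_surface(NucleusMask(m, tuple(voxel)))
        center_nm = half * voxel
        rec = distance_to_lamina([make_spot(*center_nm)], surface)[0]
        assert rec.distance_nm == pytest.approx(
            vol_radius, abs=np.linalg.norm(voxel)
        )

    def test_within_threshold_flag_consistent(self, rng):
        m = rng.random((10, 10, 10)) < 0.5
        m[5, 5, 5] = True
        surface = extract_lamina_surface(NucleusMask(m, (100.0, 60.0, 60.0)))
        spots = [make_spot(*c, spot_id=i)
                 for i, c in enumerate(rng.uniform(0, 500, size=(20, 3)))]
        for rec in distance_to_lamina(spots, surface, threshold_nm=250.0):
            assert rec.within_threshold == (rec.distance_nm <= 250.0)

    def test_matches_brute_force_on_random_masks(self, rng):
        voxel = np.array([110.0, 45.0, 45.0])
        for _ in range(10):
            m = rng.random((12, 12, 12)) < 0.3
            m[6, 6, 6] = True
            surface = extract_lamina_surface(NucleusMask(m, tuple(voxel)))
            coords = surface.voxels * voxel
            spots = [make_spot(*c, spot_id=i) for i, c in
                     enumerate(rng.uniform(0, 11, size=(5, 3)) * voxel)]
            recs = distance_to_lamina(spots, surface)
            for spot, rec in zip(spots, recs):
                brute = np.min(
                    np.linalg.norm(coords - spot.centroid_nm, axis=1)
                )
                assert rec.distance_nm == pytest.approx(brute, abs=1e-6)


class TestAggregateProfiles:
    def _profiles(self, curves):
        out = []
        for i, c in enumerate(curves):
            p = RadialProfile(i, np.arange(len(c), dtype=float) * 40.0,
                              np.asarray(c, dtype=float))
            p.normalized_intensity = np.asarray(c, dtype=float)
            out.append(p)
        return out

    def test_identical_profiles_have_zero_sem(self):
        profiles = self._profiles([[0.2, 0.8, 0.4]] * 5)
        agg = aggregate_profiles({"wt": profiles})["wt"]
        assert np.allclose(agg.sem, 0.0)
        assert np.allclose(agg.mean, [0.2, 0.8, 0.4])
        assert agg.peak_nm == 40.0

    def test_mismatched_grids_rejected(self):
        p1 = self._profiles([[0.1, 0.2]])[0]
        p2 = self._profiles([[0.1, 0.2, 0.3]])[0]
        with pytest.raises(ValidationError, match="grid"):
            aggregate_profiles({"c": [p1, p2]})

    def test_single_profile_rejected(self):
        with pytest.raises(ValidationError, match=">= 2"):
            aggregate_profiles({"c": self._profiles([[0.1, 0.2]])})


class TestPipelineConservation:
    def test_category_counts_and_lamina_fractions_conserve(self, small_params):
        vol, _ = generate_nucleus_volume(small_params)
        res = analyze_volume(vol)
        assert sum(res.category_histogram.values()) == \
            len(res.coverage_records)
        frac_in = np.mean([r.within_threshold for r in res.distance_records])
        frac_out = np.mean(
            [not r.within_threshold for r in res.distance_records]
        )
        assert frac_in + frac_out == pytest.approx(1.0)
        for prof in res.profiles:
            finite = prof.normalized_intensity[
                np.isfinite(prof.normalized_intensity)
            ]
            assert np.all((finite >= 0) & (finite <= 1))
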