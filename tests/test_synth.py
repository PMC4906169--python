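"""Generator correctness: determinism, geometry, event statistics, presets."""

import numpy as np
import pandas as pd
import pytest

from golgiring import synth
from golgiring.synth import (
    FrapSpec,
    GolgiPopulationSpec,
    ImagingParams,
    TrackSpec,
    field_area_um2,
    generate_coloc_pair,
    generate_frap_movie,
    generate_golgi_image,
    generate_gold_particles,
    generate_profile_population,
    generate_track_set,
    preset,
)


class TestProfilePopulation:
    def test_solid_profiles_have_single_maximum(self, imaging_clean):
        spec = GolgiPopulationSpec(n_objects=20, solid_fraction=1.0, seed=3)
        profs, truth = generate_profile_population(spec, imaging_clean)
        assert (truth.table["class"] == "solid").all()
        for p in profs:
            interior = p.intensities[1:-1]
            is_max = (interior > p.intensities[:-2]) & (interior > p.intensities[2:])
            above = interior > imaging_clean.background + 1e-9
            assert (is_max & above).sum() == 1

    def test_seeded_runs_are_bit_identical(self, imaging):
        spec = GolgiPopulationSpec(n_objects=10, solid_fraction=0.5, seed=7)
        p1, t1 = generate_profile_population(spec, imaging)
        p2, t2 = generate_profile_population(spec, imaging)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.intensities, b.intensities)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_ring_argmax_separation_matches_diameter(self, imaging_clean):
        # D=600 nm ring, noise off: distance between the two profile argmaxima
        # equals 600 nm to within one sampling step (brute-force argmax oracle)
        spec = GolgiPopulationSpec(
            n_objects=30, solid_fraction=0.0,
            ring_diameter_mean=600.0, ring_diameter_sd=0.0, seed=5)
        profs, truth = generate_profile_population(spec, imaging_clean)
        step = profs[0].step
        for p in profs:
            y = p.intensities
            i1 = int(np.argmax(y))
            half = len(y) // 2
            # second argmax on the other side of the centre
            other = y.copy()
            if p.positions[i1] > 0:
                other[half:] = -np.inf
            else:
                other[:half + 1] = -np.inf
            i2 = int(np.argmax(other))
            sep = abs(p.positions[i1] - p.positions[i2])
            assert abs(sep - 600.0) <= step + 1e-9

    def test_noise_changes_no_truth_record(self, imaging, imaging_clean):
        spec = GolgiPopulationSpec(n_objects=25, solid_fraction=0.4, seed=11)
        _, t_noisy = generate_profile_population(spec, imaging)
        _, t_clean = generate_profile_population(spec, imaging_clean)
        pd.testing.assert_frame_equal(t_noisy.table, t_clean.table)

    def test_truth_roundtrips_through_csv(self, tmp_path, imaging):
        spec = GolgiPopulationSpec(n_objects=8, solid_fraction=0.5, seed=2)
        _, truth = generate_profile_population(spec, imaging)
        path = tmp_path / "truth.csv"
        truth.to_csv(path)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, truth.table, check_dtype=False)

    def test_invalid_spec_names_offending_field(self):
        with pytest.raises(ValueError, match="solid_fraction"):
            GolgiPopulationSpec(n_objects=5, solid_fraction=1.5)
        with pytest.raises(ValueError, match="pixel_size"):
            ImagingParams(pixel_size=-1.0)
        with pytest.raises(ValueError, match="psf_fwhm"):
            ImagingParams(pixel_size=200.0, psf_fwhm=100.0)


class TestGolgiImage:
    def test_zero_objects_is_background_only(self, imaging_clean):
        spec = GolgiPopulationSpec(n_objects=0, solid_fraction=0.0, seed=1)
        img, truth = generate_golgi_image(spec, imaging_clean)
        assert truth.table.empty
        np.testing.assert_allclose(img, imaging_clean.background)

    def test_solid_maximum_at_recorded_centre(self, imaging_clean):
        spec = GolgiPopulationSpec(n_objects=1, solid_fraction=1.0, seed=4)
        img, truth = generate_golgi_image(spec, imaging_clean)
        iy, ix = np.unravel_index(np.argmax(img), img.shape)
        assert abs(ix - truth.table.x_px[0]) <= 0.5
        assert abs(iy - truth.table.y_px[0]) <= 0.5

    def test_ring_line_scan_shows_two_maxima_a_diameter_apart(self, imaging_clean):
        spec = GolgiPopulationSpec(
            n_objects=1, solid_fraction=0.0,
            ring_diameter_mean=800.0, ring_diameter_sd=0.0, seed=9)
        img, truth = generate_golgi_image(spec, imaging_clean)
        cy = truth.table.y_px[0]
        row = img[int(round(cy))]
        cx = truth.table.x_px[0]
        left = row.copy(); left[int(cx):] = -np.inf
        right = row.copy(); right[:int(cx) + 1] = -np.inf
        sep_px = np.argmax(right) - np.argmax(left)
        sep_nm = sep_px * imaging_clean.pixel_size
        # peaks pull inward by ~sigma^2/R for a PSF-convolved thin rim
        assert abs(sep_nm - 800.0) <= 1.5 * imaging_clean.pixel_size

    def test_flux_independent_of_diameter(self, imaging_clean):
        # integrated intensity above background conserved to 1% across D
        totals = []
        for d in (532.0, 800.0, 1100.0):
            spec = GolgiPopulationSpec(
                n_objects=1, solid_fraction=0.0,
                ring_diameter_mean=d, ring_diameter_sd=0.0, seed=1)
            img, _ = generate_golgi_image(spec, imaging_clean)
            totals.append((img - imaging_clean.background).sum())
        totals = np.array(totals)
        assert np.ptp(totals) / totals.mean() < 0.01

    def test_overcrowded_field_raises_placement_error(self):
        tiny = ImagingParams(field_size=(3.0, 3.0), photon_scale=0.0, read_noise_sd=0.0)
        spec = GolgiPopulationSpec(n_objects=50, solid_fraction=0.0, seed=1)
        with pytest.raises(ValueError, match="place"):
            generate_golgi_image(spec, tiny)


class TestFrapMovie:
    def test_zero_rate_zero_decoys_empty_truth(self, imaging_clean):
        spec = FrapSpec(true_rate=0.0, decoy_density=0.0, duration=60.0, seed=1)
        movie, truth = generate_frap_movie(spec, imaging_clean)
        assert truth.table.empty
        np.testing.assert_allclose(movie, imaging_clean.background)

    def test_same_seed_identical_event_times(self, imaging):
        spec = FrapSpec(true_rate=3.0, duration=120.0, seed=42)
        _, t1 = generate_frap_movie(spec, imaging)
        _, t2 = generate_frap_movie(spec, imaging)
        np.testing.assert_array_equal(t1.table.time_s, t2.table.time_s)

    def test_poisson_event_count_matches_closed_form(self):
        # mean count over many seeds vs rate x area x duration
        imaging = ImagingParams(field_size=(10.0, 10.0),
                                photon_scale=0.0, read_noise_sd=0.0)
        spec = FrapSpec(true_rate=4.8, duration=600.0, decoy_density=0.0)
        area = field_area_um2(imaging)
        expected = 4.8 * area * (600.0 / 3600.0)
        counts = []
        rng_seeds = range(200)
        for s in rng_seeds:
            rng = np.random.default_rng(s)
            counts.append(rng.poisson(spec.true_rate * area * spec.duration / 3600.0))
        # full-movie generation for a subset confirms the generator agrees
        gen_counts = [len(generate_frap_movie(spec, imaging, seed=s)[1].table)
                      for s in range(40)]
        counts = np.asarray(counts, dtype=float)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - expected) <= 3.0 * se
        gen_counts = np.asarray(gen_counts, dtype=float)
        se_gen = gen_counts.std(ddof=1) / np.sqrt(gen_counts.size)
        assert abs(gen_counts.mean() - expected) <= 3.0 * se_gen


class TestTrackSet:
    def test_noise_free_steps_are_exact(self):
        # 600 nm/min at 5-s frames = 50 nm per step, exactly
        spec = TrackSpec(n_tracks=3, speed_mean=600.0, speed_sd=0.0,
                         n_frames=10, frame_interval=5.0, loc_noise_sd=0.0, seed=1)
        det, truth = generate_track_set(spec)
        for k, g in det.groupby("truth_track"):
            steps = np.hypot(np.diff(g.x_nm), np.diff(g.y_nm))
            np.testing.assert_allclose(steps, 50.0, rtol=1e-9)

    def test_truth_speed_moments_match_spec(self):
        spec = TrackSpec(n_tracks=500, speed_mean=255.0, speed_sd=128.0, seed=8)
        _, truth = generate_track_set(spec)
        speeds = truth.table.true_speed_nm_min.to_numpy()
        se = speeds.std(ddof=1) / np.sqrt(speeds.size)
        assert abs(speeds.mean() - 255.0) <= 3.0 * se
        assert (speeds > 0).all()

    def test_seed_reproducibility(self):
        spec = TrackSpec(n_tracks=5, speed_mean=200.0, speed_sd=50.0, seed=13)
        d1, t1 = generate_track_set(spec)
        d2, t2 = generate_track_set(spec)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(t1.table, t2.table)


class TestGoldParticles:
    def test_uniform_mean_relative_distance_is_quarter(self):
        tbl = generate_gold_particles(10_000, golgi_length=1000.0,
                                      mode="uniform", seed=1)
        assert abs(tbl.relative_distance.mean() - 0.25) < 0.01

    def test_central_mode_is_more_central_than_uniform(self):
        uni = generate_gold_particles(5000, 1000.0, "uniform", seed=2)
        cen = generate_gold_particles(5000, 1000.0, "central",
                                      concentration=4.0, seed=2)
        assert cen.relative_distance.median() < uni.relative_distance.median()

    def test_peripheral_mode_is_more_peripheral_than_uniform(self):
        uni = generate_gold_particles(5000, 1000.0, "uniform", seed=3)
        per = generate_gold_particles(5000, 1000.0, "peripheral",
                                      concentration=4.0, seed=3)
        assert per.relative_distance.median() > uni.relative_distance.median()

    def test_single_particle_single_row(self):
        for mode in ("uniform", "peripheral", "central"):
            assert len(generate_gold_particles(1, 500.0, mode, seed=1)) == 1

    def test_unknown_mode_lists_valid_modes(self):
        with pytest.raises(ValueError, match="uniform"):
            generate_gold_particles(10, 500.0, mode="bogus")


class TestColocPair:
    def test_full_overlap_with_identical_placement(self, imaging_clean):
        a, b, truth = generate_coloc_pair(10, 1.0, imaging_clean, seed=1)
        np.testing.assert_array_equal(a, b)
        assert (truth.table.channel == "both").all()

    def test_zero_overlap_disjoint_memberships(self, imaging_clean):
        a, b, truth = generate_coloc_pair(8, 0.0, imaging_clean, seed=2)
        assert set(truth.table.channel) == {"a", "b"}

    def test_invalid_overlap_fraction(self, imaging_clean):
        with pytest.raises(ValueError, match="overlap_fraction"):
            generate_coloc_pair(5, 1.5, imaging_clean, seed=1)


class TestPresets:
    @pytest.mark.parametrize("name,attr,value", [
        ("wt_golgi", "solid_fraction", 0.08),
        ("wt_golgi", "n_objects", 870),
        ("stl_golgi", "solid_fraction", 0.54),
        ("stl_golgi", "n_objects", 820),
        ("wt_frap", "true_rate", 4.8),
        ("stl_frap", "true_rate", 2.2),
        ("wt_speed", "speed_mean", 255.0),
        ("wt_speed", "speed_sd", 128.0),
        ("stl_speed", "speed_mean", 191.0),
        ("stl_speed", "speed_sd", 92.0),
    ])
    def test_preset_parameters(self, name, attr, value):
        assert getattr(preset(name), attr) == value

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError, match="wt_golgi"):
            preset("bogus")
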