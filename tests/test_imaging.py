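"""Measurement chain: background subtraction, detection, ROI read-outs,
colocalization gating."""

import numpy as np
import pytest

from cvtquant import simulate as sim
from cvtquant.imaging import (
    ImageStack,
    SpotMeasurement,
    colocalization_gate,
    detect_spots,
    integrate_through_stack,
    measure_brightest_frame,
    median_background_subtract,
    quantify_stack_pair,
)


def _stack(voxels, **kw):
    return ImageStack(np.asarray(voxels, dtype=float), pixel_size=129.0, **kw)


class TestBackgroundSubtraction:
    def test_constant_image_goes_to_zero(self):
        stack = _stack(np.full((3, 64, 64), 37.0))
        sub = median_background_subtract(stack, 21)
        assert np.allclose(sub.voxels[:, 12:-12, 12:-12], 0.0)

    def test_single_bright_pixel_survives(self):
        vox = np.zeros((3, 64, 64))
        vox[1, 30, 30] = 500.0
        sub = median_background_subtract(_stack(vox), 21)
        assert sub.voxels[1, 30, 30] == pytest.approx(500.0)

    def test_even_kernel_normalized_to_odd(self, caplog):
        stack = _stack(np.full((3, 64, 64), 10.0))
        with caplog.at_level("WARNING"):
            even = median_background_subtract(stack, 20)
        odd = median_background_subtract(stack, 21)
        assert np.array_equal(even.voxels, odd.voxels)
        assert "21" in caplog.text

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            median_background_subtract(_stack(np.zeros((3, 16, 16))), 21)

    def test_idempotent_on_flat_images(self):
        stack = _stack(np.full((3, 48, 48), 55.0))
        once = median_background_subtract(stack, 11)
        twice = median_background_subtract(once, 11)
        assert np.allclose(once.voxels, twice.voxels, atol=1e-12)

    def test_unclipped_keeps_negative_residuals(self, rng):
        stack = _stack(rng.normal(100, 5, (3, 64, 64)))
        sub = median_background_subtract(stack, 21, clip=False)
        assert (sub.voxels < 0).any()
        clipped = median_background_subtract(stack, 21, clip=True)
        assert clipped.voxels.min() >= 0


class TestDetection:
    def test_blank_stack_gives_empty_list(self):
        assert detect_spots(_stack(np.zeros((5, 64, 64)))) == []

    def test_two_separated_spots_found_at_planted_centers(self, noise_free_scene):
        spots = [
            sim.PlantedSpot(0, 0, 2000.0, 40.0, 40.0, 4.0),
            sim.PlantedSpot(1, 0, 2000.0, 90.0, 85.0, 4.0),
        ]
        green, _, _ = sim.generate_stack_pair(noise_free_scene, spots)
        sub = median_background_subtract(green, 21, clip=False)
        found = detect_spots(sub, min_intensity=200.0)
        assert len(found) == 2
        centers = sorted((s.x, s.y) for s in found)
        for (fx, fy), (px, py) in zip(centers, [(40.0, 40.0), (90.0, 85.0)]):
            assert abs(fx - px) <= 1.0 and abs(fy - py) <= 1.0

    def test_spot_peaking_in_first_frame_flagged(self, noise_free_scene):
        spots = [sim.PlantedSpot(0, 0, 2000.0, 60.0, 60.0, 0.0)]
        green, _, _ = sim.generate_stack_pair(noise_free_scene, spots)
        sub = median_background_subtract(green, 21, clip=False)
        found = detect_spots(sub, min_intensity=200.0)
        assert len(found) == 1
        assert found[0].flag_edge_of_stack
        assert integrate_through_stack(sub, found[0]) is None


class TestIntensityMeasurement:
    def test_single_frame_spot_measured_exactly(self):
        vox = np.zeros((5, 64, 64))
        vox[2, 28:33, 28:33] = 40.0  # total 1000 in one frame
        stack = _stack(vox)
        spot = SpotMeasurement(0, "green", 30, 30, 2, (24, 37, 24, 37))
        assert measure_brightest_frame(stack, spot) == pytest.approx(1000.0, rel=0.005)

    def test_roi_over_blank_region_is_zero(self):
        stack = _stack(np.zeros((5, 64, 64)))
        spot = SpotMeasurement(0, "green", 30, 30, 2, (24, 37, 24, 37))
        assert measure_brightest_frame(stack, spot) == 0.0

    def test_brightest_frame_matches_planted_z(self, noise_free_scene):
        green, _, _ = sim.generate_stack_pair(
            noise_free_scene, [sim.PlantedSpot(0, 0, 2000.0, 60.0, 60.0, 5.0)])
        sub = median_background_subtract(green, 21, clip=False)
        found = detect_spots(sub, min_intensity=200.0)
        assert abs(found[0].brightest_frame - 5) <= 1

    def test_integrated_at_least_brightest(self, small_scene, rng):
        planted = sim.plant_spot_population(small_scene, 8, 1000.0, rng=rng)
        green, _, _ = sim.generate_stack_pair(small_scene, planted)
        sub = median_background_subtract(green, 21, clip=False)
        interior = [s for s in detect_spots(sub) if not s.flag_edge_of_stack]
        assert interior
        for s in interior:
            assert integrate_through_stack(sub, s) >= measure_brightest_frame(sub, s) - 1e-9

    def test_noise_free_integration_recovers_planted_photons(self, flat_noise_free_scene, rng):
        planted = sim.plant_spot_population(flat_noise_free_scene, 8, 1000.0,
                                            sigma_log=0.3, rng=rng)
        green, _, _ = sim.generate_stack_pair(flat_noise_free_scene, planted)
        sub = median_background_subtract(green, 21, clip=False)
        found = detect_spots(sub, min_intensity=100.0)
        assert len(found) == len(planted)
        pxy = np.array([[s.x, s.y] for s in planted])
        for f in found:
            nearest = int(np.argmin(np.hypot(pxy[:, 0] - f.x, pxy[:, 1] - f.y)))
            t = planted[nearest].true_molecules * flat_noise_free_scene.photons_per_molecule
            integ = integrate_through_stack(sub, f)
            assert integ is not None
            assert integ == pytest.approx(t, rel=0.01)

    def test_cell_background_bias_stays_within_5_percent(self, noise_free_scene):
        """Median filtering a curved cell background leaves a small bias
        under the spot; for a punctum at the cell center it stays below 5%
        of the planted intensity (noise-free)."""
        cy, cx = sim.cell_centers(noise_free_scene)[0]
        spot = [sim.PlantedSpot(0, 0, 1000.0, float(cx), float(cy), 10.0)]
        green, _, _ = sim.generate_stack_pair(noise_free_scene, spot)
        sub = median_background_subtract(green, 21, clip=False)
        found = detect_spots(sub, min_intensity=100.0)
        planted = 1000.0 * noise_free_scene.photons_per_molecule
        assert integrate_through_stack(sub, found[0]) == pytest.approx(planted, rel=0.05)


def _spot(spot_id, x, y):
    return SpotMeasurement(spot_id, "green", x, y, 2, (0, 4, 0, 4))


class TestColocalizationGate:
    def test_identical_coordinates_all_colocalized(self):
        greens = [_spot(i, 10.0 * i, 5.0) for i in range(4)]
        reds = [_spot(i, 10.0 * i, 5.0) for i in range(4)]
        colocalization_gate(greens, reds, max_distance=300.0, pixel_size=129.0)
        assert all(g.flag_colocalized for g in greens)

    def test_empty_red_list_gates_everything_out(self):
        greens = [_spot(0, 5.0, 5.0)]
        colocalization_gate(greens, [], max_distance=300.0, pixel_size=129.0)
        assert not greens[0].flag_colocalized

    def test_boundary_distance_is_inclusive(self):
        greens = [_spot(0, 0.0, 0.0)]
        reds = [_spot(0, 3.0, 0.0)]  # exactly 300 nm at 100 nm/px
        colocalization_gate(greens, reds, max_distance=300.0, pixel_size=100.0)
        assert greens[0].flag_colocalized
        colocalization_gate(greens, reds, max_distance=299.0, pixel_size=100.0)
        assert not greens[0].flag_colocalized

    def test_one_to_one_matching(self):
        greens = [_spot(0, 0.0, 0.0), _spot(1, 1.0, 0.0)]
        reds = [_spot(0, 0.5, 0.0)]
        colocalization_gate(greens, reds, max_distance=300.0, pixel_size=100.0)
        assert sum(g.flag_colocalized for g in greens) == 1
        assert greens[0].flag_colocalized  # closer green wins

    def test_gate_monotone_in_distance(self, rng):
        greens = [_spot(i, *rng.uniform(0, 50, 2)) for i in range(15)]
        reds = [_spot(i, *rng.uniform(0, 50, 2)) for i in range(10)]
        previous = -1
        for dist in [50, 150, 400, 1000, 5000]:
            colocalization_gate(greens, reds, max_distance=dist, pixel_size=100.0)
            n = sum(g.flag_colocalized for g in greens)
            assert n >= previous
            previous = n


def test_quantify_stack_pair_schema_and_gating(small_scene, rng):
    planted = sim.plant_spot_population(small_scene, 6, 2000.0, rng=rng,
                                        partner_offset=0.0)
    green, red, _ = sim.generate_stack_pair(small_scene, planted)
    table = quantify_stack_pair(green, red)
    assert list(table.columns) == [
        "spot_id", "channel", "x", "y", "brightest_frame",
        "intensity_brightest", "intensity_integrated", "edge_flag", "coloc_flag"]
    assert table["coloc_flag"].sum() >= 5  # planted partners gate spots in


def test_tiff_round_trip(tmp_path, small_scene, rng):
    planted = sim.plant_spot_population(small_scene, 3, 1000.0, rng=rng)
    green, _, _ = sim.generate_stack_pair(small_scene, planted)
    path = tmp_path / "green.tif"
    green.to_tiff(path)
    loaded = ImageStack.from_tiff(path)
    assert loaded.pixel_size == green.pixel_size
    assert loaded.z_spacing == green.z_spacing
    assert loaded.channel == "green"
    assert np.allclose(loaded.voxels, np.round(green.voxels), atol=0.5)
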