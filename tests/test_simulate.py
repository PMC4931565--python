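"""Generator contracts: photon conservation, determinism, planted truth."""

import numpy as np
import pandas as pd
import pytest

from cvtquant import simulate as sim


def _one_spot(molecules=100.0, x=60.0, y=60.0, z=10.0):
    return [sim.PlantedSpot(spot_id=0, cell_id=0, true_molecules=molecules,
                            x=x, y=y, z=z)]


class TestStackPair:
    def test_photon_conservation_noise_free(self, noise_free_scene):
        green, _, _ = sim.generate_stack_pair(noise_free_scene, _one_spot())
        planted = 100.0 * noise_free_scene.photons_per_molecule
        recovered = (green.voxels - sim.background_field(noise_free_scene)).sum()
        assert recovered == pytest.approx(planted, rel=0.005)

    def test_multi_spot_conservation(self, noise_free_scene, rng):
        spots = [
            sim.PlantedSpot(i, 0, float(m), x, y, z)
            for i, (m, x, y, z) in enumerate(
                zip([50, 200, 1000], [40.5, 64.0, 90.2], [40.0, 80.7, 60.0],
                    [8.0, 10.5, 12.0])
            )
        ]
        green, _, _ = sim.generate_stack_pair(noise_free_scene, spots)
        planted = 1250.0 * noise_free_scene.photons_per_molecule
        recovered = (green.voxels - sim.background_field(noise_free_scene)).sum()
        assert recovered == pytest.approx(planted, rel=0.005)

    def test_same_seed_bit_identical(self, small_scene):
        a_g, a_r, _ = sim.generate_stack_pair(small_scene, _one_spot(z=4.0))
        b_g, b_r, _ = sim.generate_stack_pair(small_scene, _one_spot(z=4.0))
        assert np.array_equal(a_g.voxels, b_g.voxels)
        assert np.array_equal(a_r.voxels, b_r.voxels)

    def test_different_seed_differs(self, small_scene):
        other = sim.SceneConfig(**{**small_scene.__dict__, "seed": 99})
        a_g, _, _ = sim.generate_stack_pair(small_scene, _one_spot(z=4.0))
        b_g, _, _ = sim.generate_stack_pair(other, _one_spot(z=4.0))
        assert not np.array_equal(a_g.voxels, b_g.voxels)

    def test_out_of_bounds_spot_rejected_with_name(self, small_scene):
        bad = [sim.PlantedSpot(spot_id=17, cell_id=0, true_molecules=5.0,
                               x=500.0, y=10.0, z=4.0)]
        with pytest.raises(ValueError, match="spot 17"):
            sim.generate_stack_pair(small_scene, bad)

    def test_truth_table_echoes_planted(self, small_scene):
        spots = _one_spot(molecules=123.0, x=30.5, y=44.25, z=5.5)
        _, _, truth = sim.generate_stack_pair(small_scene, spots)
        row = truth.iloc[0]
        assert row["true_molecules"] == 123.0
        assert (row["x"], row["y"], row["z"]) == (30.5, 44.25, 5.5)

    def test_red_partner_rendered_at_offset(self, noise_free_scene):
        offset_nm = 2 * noise_free_scene.pixel_size
        spot = [sim.PlantedSpot(0, 0, 100.0, 60.0, 60.0, 4.0,
                                partner_offset=offset_nm)]
        _, red, _ = sim.generate_stack_pair(noise_free_scene, spot)
        resid = red.voxels - sim.background_field(noise_free_scene)
        zc, yc, xc = np.unravel_index(np.argmax(resid), resid.shape)
        assert (yc, xc) == (60, 62)


class TestPlantedStatistics:
    def test_lognormal_median_converges(self, rng):
        draws = sim.sample_molecule_counts(3585.0, 0.4, 10_000, rng)
        assert np.median(draws) == pytest.approx(3585.0, rel=0.02)

    def test_population_respects_min_separation(self, small_scene, rng):
        planted = sim.plant_spot_population(small_scene, 12, 500.0, rng=rng,
                                            min_separation=14.0)
        xy = np.array([[s.x, s.y] for s in planted])
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 14.0

    def test_overcrowded_scene_raises(self, small_scene, rng):
        with pytest.raises(ValueError, match="could not place"):
            sim.plant_spot_population(small_scene, 500, 500.0, rng=rng)


class TestTwoStrainExperiment:
    def test_invalid_parameters(self, small_scene):
        with pytest.raises(ValueError):
            sim.generate_two_strain_experiment(small_scene, fold_change=0.0)
        with pytest.raises(ValueError):
            sim.generate_two_strain_experiment(small_scene, 2.0, n_spots=(0, 5))

    def test_planted_medians_scale_with_fold_change(self, small_scene):
        out = sim.generate_two_strain_experiment(
            small_scene, fold_change=4.0, n_spots=(12, 12), seed=3,
            sigma_log=0.0)
        med_a = out["A"][2]["true_molecules"].median()
        med_b = out["B"][2]["true_molecules"].median()
        assert med_b / med_a == pytest.approx(4.0, rel=1e-9)


class TestChainField:
    def test_pure_singletons(self):
        cfg = sim.ChainFieldConfig(seed=1, n_particles=60,
                                   chain_length_pmf={1: 1.0}, n_micrographs=4,
                                   field_size=(2000.0, 2000.0))
        field = sim.generate_chain_field(cfg)
        assert (field["assembly_size"] == 1).all()
        assert len(field) == 60

    def test_pure_doublets_give_exact_pairs(self):
        cfg = sim.ChainFieldConfig(seed=2, n_particles=100,
                                   chain_length_pmf={2: 1.0}, n_micrographs=5,
                                   field_size=(3000.0, 3000.0))
        field = sim.generate_chain_field(cfg)
        sizes = field.groupby("assembly_id").size()
        assert len(sizes) == 50
        assert (sizes == 2).all()

    def test_within_and_between_assembly_distances(self):
        cfg = sim.ChainFieldConfig(seed=3, n_particles=120, n_micrographs=4,
                                   field_size=(3000.0, 3000.0))
        field = sim.generate_chain_field(cfg)
        d = cfg.particle_diameter
        for _, mic in field.groupby("micrograph_id"):
            pts = mic[["x_nm", "y_nm"]].to_numpy()
            labels = mic["assembly_id"].to_numpy()
            dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            same = labels[:, None] == labels[None, :]
            np.fill_diagonal(dist, np.nan)
            across = dist[~same]
            if across.size:
                assert np.nanmin(across) > 2 * d
            within = dist[same & ~np.isnan(dist)]
            if within.size:
                # chain neighbours sit ~one diameter apart (plus jitter)
                assert np.nanmin(within) > d - 6 * cfg.jitter_sd

    def test_field_too_small_raises(self):
        cfg = sim.ChainFieldConfig(seed=4, n_particles=500, n_micrographs=1,
                                   field_size=(200.0, 200.0))
        with pytest.raises(ValueError, match="too small"):
            sim.generate_chain_field(cfg)

    def test_invalid_pmf_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            sim.ChainFieldConfig(chain_length_pmf={1: 0.5, 2: 0.2}).validate()
        with pytest.raises(ValueError, match="keys"):
            sim.ChainFieldConfig(chain_length_pmf={5: 1.0}).validate()

    def test_deterministic(self):
        cfg = sim.ChainFieldConfig(seed=5, n_particles=80, n_micrographs=4,
                                   field_size=(2500.0, 2500.0))
        a = sim.generate_chain_field(cfg)
        b = sim.generate_chain_field(cfg)
        pd.testing.assert_frame_equal(a, b)
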