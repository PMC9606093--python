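"""Phantom generator: rasterisation oracle, determinism, conservation."""

import numpy as np
import pytest

import ichdquant as iq
from ichdquant.synthetic import PopulationSpec, PhantomConfig
from ichdquant.volume import PlacementError


def brute_force_sphere(center, diameter, shape, voxel):
    """Independent voxel-centre-in-sphere enumeration (python loops)."""
    r2 = (diameter / 2.0) ** 2
    mask = np.zeros(shape, dtype=bool)
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                pz, py, px = ((i + 0.5) * voxel for i in (z, y, x))
                d2 = (pz - center[0]) ** 2 + (py - center[1]) ** 2 + (px - center[2]) ** 2
                mask[z, y, x] = d2 <= r2
    return mask


class TestRasterizeSphere:
    def test_matches_enumeration_oracle(self):
        mask = iq.rasterize_sphere((4.8, 5.1, 4.5), 6.0, (32, 32, 32), 0.3)
        oracle = brute_force_sphere((4.8, 5.1, 4.5), 6.0, (32, 32, 32), 0.3)
        assert np.array_equal(mask, oracle)

    def test_subvoxel_sphere_on_voxel_center_is_one_voxel(self):
        # voxel centre of index 5 at 0.5 um voxels is 2.75 um
        mask = iq.rasterize_sphere((2.75, 2.75, 2.75), 0.2, (16, 16, 16), 0.5)
        assert mask.sum() == 1
        assert mask[5, 5, 5]

    def test_volume_within_2pct_of_analytic(self):
        vox = 0.3
        mask = iq.rasterize_sphere((12.0, 12.0, 12.0), 8.0, (80, 80, 80), vox)
        analytic = np.pi / 6 * 8.0**3 / vox**3
        assert abs(mask.sum() - analytic) / analytic < 0.02

    def test_corner_sphere_is_about_one_eighth(self):
        vox = 0.25
        interior = iq.rasterize_sphere((8.0, 8.0, 8.0), 6.0, (64, 64, 64), vox).sum()
        corner = iq.rasterize_sphere((0.0, 0.0, 0.0), 6.0, (64, 64, 64), vox).sum()
        assert abs(corner - interior / 8) / (interior / 8) < 0.05

    def test_off_grid_sphere_empty_not_error(self):
        mask = iq.rasterize_sphere((-50.0, -50.0, -50.0), 4.0, (16, 16, 16), 0.5)
        assert mask.sum() == 0

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            iq.rasterize_sphere((1, 1, 1), 0.0, (8, 8, 8), 0.5)


class TestGeneratePhantom:
    def test_empty_config_gives_background_only(self):
        cfg = PhantomConfig(shape=(16, 16, 16), voxel_size_um=0.5,
                            populations=(), noise_sd=0.0, background_sd=0.0,
                            blur_sigma_um=0.0)
        volume, truth = iq.generate_phantom(cfg)
        assert np.allclose(volume.values, cfg.background_mean)
        assert truth.true_load_percent["total"] == 0.0
        assert truth.count() == 0

    def test_determinism_bitwise(self):
        cfg = iq.default_phantom_config(seed=3, shape=(48, 48, 48))
        v1, t1 = iq.generate_phantom(cfg)
        v2, t2 = iq.generate_phantom(cfg)
        assert np.array_equal(v1.values, v2.values)
        assert t1.to_dataframe().equals(t2.to_dataframe())

    def test_single_sphere_matches_oracle_exactly(self):
        pop = PopulationSpec("ichd", 1, 8.0, 0.0, 150.0, 0.0)
        cfg = PhantomConfig(shape=(48, 48, 48), voxel_size_um=0.3,
                            populations=(pop,), noise_sd=0.0, background_sd=0.0,
                            blur_sigma_um=0.0, exact_counts=True, seed=11)
        volume, truth = iq.generate_phantom(cfg)
        [p] = truth.particles
        fg = volume.values > cfg.background_mean
        oracle = brute_force_sphere(p.center_um, p.diameter_um,
                                    cfg.shape, cfg.voxel_size_um)
        assert np.array_equal(fg, oracle)
        assert p.voxel_count == oracle.sum()

    def test_prenoise_particles_above_background(self):
        cfg = iq.default_phantom_config(seed=5, shape=(64, 64, 64),
                                        noise_sd=0.0, background_sd=0.0,
                                        blur_sigma_um=0.0)
        volume, truth = iq.generate_phantom(cfg)
        assert truth.count() > 0
        assert volume.values.max() > cfg.background_mean

    def test_true_load_recomputable_from_voxel_counts(self, small_phantom):
        cfg, _, truth = small_phantom
        total_vox = float(np.prod(cfg.shape))
        recomputed = 100.0 * sum(p.voxel_count for p in truth.particles) / total_vox
        assert abs(recomputed - truth.true_load_percent["total"]) <= 1e-9 * max(
            1.0, recomputed
        )

    def test_packing_bound_respected(self, small_phantom):
        cfg, _, truth = small_phantom
        frac = sum(p.voxel_count for p in truth.particles) / float(np.prod(cfg.shape))
        assert frac < cfg.vessel_fraction + cfg.particle_volume_fraction() + 0.05

    def test_placement_failure_raises(self):
        # passes the volume-fraction invariant but cannot be packed with gaps
        pop = PopulationSpec("ichd", 30, 2.8, 0.0, 150.0, 1.0)
        cfg = PhantomConfig(shape=(16, 16, 16), voxel_size_um=0.5,
                            populations=(pop,), exact_counts=True, seed=0)
        with pytest.raises(PlacementError):
            iq.generate_phantom(cfg)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(shape=(4, 16, 16))
        with pytest.raises(ValueError):
            PhantomConfig(voxel_size_um=0.0)
        with pytest.raises(ValueError):
            # hyperdense population below background intensity
            PhantomConfig(populations=(
                PopulationSpec("glia", 5, 4.0, 0.5, 50.0, 1.0),))


class TestResampleVolume:
    def test_identity_at_ratio_one(self, small_phantom):
        _, volume, _ = small_phantom
        out = iq.resample_volume(volume, volume.voxel_size)
        assert np.array_equal(out.values, volume.values)

    def test_constant_stays_constant(self):
        v = iq.VoxelVolume(np.full((24, 24, 24), 7.5), 0.5)
        out = iq.resample_volume(v, 1.5)
        assert out.voxel_size == pytest.approx(1.5)
        assert np.allclose(out.values, 7.5)

    def test_integrated_density_conserved(self, small_phantom, rng):
        _, volume, _ = small_phantom
        out = iq.resample_volume(volume, 3.0)
        m = out.meta["resample_block"]
        nz, ny, nx = out.shape
        cropped = volume.values[: nz * m, : ny * m, : nx * m]
        total_fine = cropped.sum(dtype=np.float64) * volume.voxel_volume_um3
        total_coarse = out.values.sum(dtype=np.float64) * out.voxel_volume_um3
        assert abs(total_fine - total_coarse) / abs(total_fine) < 1e-6

    def test_upsampling_rejected(self):
        v = iq.VoxelVolume(np.zeros((16, 16, 16)), 1.0)
        with pytest.raises(ValueError):
            iq.resample_volume(v, 0.5)

    def test_small_particles_vanish_at_coarse_scale(self):
        """Particles < 2 coarse voxels lose contrast after block-averaging."""
        pop = PopulationSpec("nucleoli", 12, 2.0, 0.2, 150.0, 1.0)
        cfg = PhantomConfig(shape=(120, 120, 120), voxel_size_um=0.3,
                            populations=(pop,), noise_sd=0.0, background_sd=0.0,
                            blur_sigma_um=0.1, seed=2)
        volume, truth = iq.generate_phantom(cfg)
        coarse = iq.resample_volume(volume, 3.0)
        # at most ~1 partial-volume voxel per particle retains >=half contrast
        strong = (coarse.values > cfg.background_mean + 25).sum()
        assert strong <= truth.count()


class TestXfmPhantom:
    def test_default_mask_has_33_cells(self):
        maps, mask, truth = iq.generate_xfm_maps(iq.default_xfm_config(seed=1))
        assert len(mask.label_ids) == 33
        classes = list(mask.classes.values())
        assert classes.count("normal") == 22 and classes.count("ichd") == 11

    def test_zero_noise_cell_is_exactly_planted_mean(self):
        cfg = iq.ElementalPhantomConfig(
            map_shape=(64, 64), pixel_size_um=0.5, elements=("Fe",),
            n_normal_cells=1, n_ichd_cells=1,
            class_density_means={"Fe": {"normal": 5.0, "ichd": 15.0}},
            density_sd=0.0, background_density=0.0, seed=4,
        )
        maps, mask, truth = iq.generate_xfm_maps(cfg)
        img = maps["Fe"].values
        for lab in mask.label_ids:
            planted = truth.loc[truth.cell_id == lab, "planted_mean"].iloc[0]
            assert np.all(img[mask.labels == lab] == planted)

    def test_determinism(self):
        cfg = iq.default_xfm_config(seed=9)
        m1, k1, t1 = iq.generate_xfm_maps(cfg)
        m2, k2, t2 = iq.generate_xfm_maps(cfg)
        assert np.array_equal(m1["Fe"].values, m2["Fe"].values)
        assert np.array_equal(k1.labels, k2.labels)
        assert t1.equals(t2)


class TestGroupStudy:
    def test_base_design_is_60_rows(self):
        table, arts = iq.generate_group_study(iq.StudyConfig(seed=0))
        assert len(table) == 60
        assert len(arts) == 60
        counts = table.groupby("group")["animal_id"].nunique()
        assert dict(counts) == {"WT-saline": 4, "WT-LY": 4,
                                "TG-saline": 3, "TG-LY": 4}

    def test_extra_dorsal_vois_give_66_rows(self):
        table, _ = iq.generate_group_study(iq.StudyConfig(n_extra_dorsal=6, seed=0))
        assert len(table) == 66
        extra = table.iloc[60:]
        assert set(extra["region"]) <= {"dCTX", "dHIP"}

    def test_planted_elevation_visible_in_truth(self):
        table, _ = iq.generate_group_study(iq.default_study_config(seed=1))
        v = table[table.region == "vCTX"].groupby("group")["true_load_percent"].mean()
        assert v["TG-saline"] > v["TG-LY"]
        assert v["TG-saline"] > v["WT-saline"]

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            iq.StudyConfig(group_sizes={"mystery-group": 3})
        with pytest.raises(ValueError):
            iq.StudyConfig(effects={("TG-saline", "cerebellum"): 2.0})

    def test_rendered_study_links_truth(self):
        cfg = iq.StudyConfig(
            group_sizes={"WT-saline": 2, "TG-saline": 2},
            regions=("vCTX",), seed=3,
        )
        template = iq.default_phantom_config(shape=(32, 32, 32),
                                             voxel_size_um=0.7)
        table, arts = iq.generate_group_study(cfg, render=True,
                                              phantom_template=template)
        assert len(table) == 4
        for voi_id, load in zip(table.voi_id, table.true_load_percent):
            _, truth = arts[voi_id]
            assert load == truth.true_load_percent["total"]
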