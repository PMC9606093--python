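"""3-D object counting against a flood-fill oracle; measurement closed forms."""

from collections import deque

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ichdquant as iq
from ichdquant.particles import filter_small


def flood_fill_label(mask, connectivity):
    """Independent BFS labeling oracle."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for idx in np.argwhere(mask):
        if labels[tuple(idx)]:
            continue
        nxt += 1
        q = deque([tuple(idx)])
        labels[tuple(idx)] = nxt
        while q:
            z, y, x = q.popleft()
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if any(c < 0 or c >= s for c, s in zip(p, mask.shape)):
                    continue
                if mask[p] and not labels[p]:
                    labels[p] = nxt
                    q.append(p)
    return labels, nxt


def same_partition(a, b):
    """Two labelings agree up to label permutation."""
    fa, fb = a.ravel(), b.ravel()
    pairs = set(zip(fa.tolist(), fb.tolist()))
    return (len({p[0] for p in pairs}) == len(pairs)
            and len({p[1] for p in pairs}) == len(pairs))


class TestLabelComponents:
    def test_empty_mask(self):
        _, n = iq.label_components(np.zeros((5, 5, 5), bool))
        assert n == 0

    def test_corner_touching_voxels(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        assert iq.label_components(mask, 26)[1] == 1
        assert iq.label_components(mask, 6)[1] == 2

    def test_edge_touching_voxels(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = mask[0, 1, 1] = True  # share an edge
        assert iq.label_components(mask, 18)[1] == 1
        assert iq.label_components(mask, 6)[1] == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(41)
        for _ in range(15):
            mask = rng.random(rng.integers(4, 16, size=3)) < 0.3
            labeled, n = iq.label_components(mask, connectivity)
            oracle, n_oracle = flood_fill_label(mask, connectivity)
            assert n == n_oracle
            assert same_partition(labeled, oracle)

    def test_canonical_label_order(self, rng):
        mask = rng.random((12, 12, 12)) < 0.15
        labeled, n = iq.label_components(mask, 6)
        flat = labeled.ravel()
        firsts = [np.flatnonzero(flat == k)[0] for k in range(1, n + 1)]
        assert firsts == sorted(firsts)

    def test_bad_connectivity(self):
        with pytest.raises(ValueError):
            iq.label_components(np.ones((3, 3, 3), bool), 10)


class TestMeasureParticles:
    def test_single_voxel_closed_form(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2, 3, 4] = True
        labeled, n = iq.label_components(mask)
        cat = iq.measure_particles(labeled, 0.3, n)
        [rec] = cat.records
        assert rec.volume_um3 == pytest.approx(0.027)
        assert rec.eq_diameter_um == pytest.approx(
            2 * (3 * 0.027 / (4 * np.pi)) ** (1 / 3))
        assert rec.centroid_um == pytest.approx((0.75, 1.05, 1.35))

    def test_full_volume_centroid_is_center(self):
        labeled = np.ones((10, 10, 10), dtype=int)
        cat = iq.measure_particles(labeled, 1.0, 1)
        assert cat.records[0].centroid_um == pytest.approx((5.0, 5.0, 5.0))

    def test_voxel_count_conservation(self, rng):
        mask = rng.random((20, 20, 20)) < 0.2
        labeled, n = iq.label_components(mask)
        cat = iq.measure_particles(labeled, 0.5, n)
        assert sum(r.voxel_count for r in cat.records) == mask.sum()
        assert [r.id for r in cat.records] == list(range(1, n + 1))

    def test_planted_spheres_counts_match_oracle(self):
        vox, shape = 0.3, (64, 64, 64)
        centers = [(5.0, 5.0, 5.0), (14.0, 12.0, 9.0), (9.0, 16.5, 15.5)]
        dias = [4.0, 6.0, 3.0]
        mask = np.zeros(shape, bool)
        expected = []
        for c, d in zip(centers, dias):
            s = iq.rasterize_sphere(c, d, shape, vox)
            expected.append(int(s.sum()))
            mask |= s
        labeled, n = iq.label_components(mask)
        cat = iq.measure_particles(labeled, vox, n)
        assert n == 3
        assert sorted(r.voxel_count for r in cat.records) == sorted(expected)


class TestEquivalentSphereDiameter:
    def test_unit_closed_form(self):
        assert iq.equivalent_sphere_diameter(np.pi / 6) == pytest.approx(1.0)

    def test_inverse_of_sphere_volume(self):
        v = np.pi / 6 * 8.0**3
        assert iq.equivalent_sphere_diameter(v) == pytest.approx(8.0)

    @given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6))
    def test_monotone(self, v1, v2):
        d1 = iq.equivalent_sphere_diameter(v1)
        d2 = iq.equivalent_sphere_diameter(v2)
        assert (v1 < v2) == (d1 < d2) or v1 == v2

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            iq.equivalent_sphere_diameter(0.0)


class TestFilterPlaques:
    def test_no_particle_above_cutoff(self, small_voi_result):
        kept, excluded = iq.filter_plaques(small_voi_result.catalog, 20.0)
        assert excluded == []
        assert len(kept) == len(small_voi_result.catalog)

    def test_planted_plaque_excluded_exactly(self):
        from ichdquant.synthetic import PopulationSpec, PhantomConfig
        pops = (
            PopulationSpec("plaque", 1, 60.0, 0.0, 160.0, 0.0),
            PopulationSpec("ichd", 6, 8.0, 0.5, 150.0, 2.0),
            PopulationSpec("glia", 10, 4.0, 0.4, 150.0, 2.0),
        )
        cfg = PhantomConfig(shape=(128, 128, 128), voxel_size_um=1.0,
                            populations=pops, noise_sd=0.0, background_sd=0.0,
                            blur_sigma_um=0.0, exact_counts=True, seed=21)
        volume, truth = iq.generate_phantom(cfg)
        res = iq.process_voi(volume, "plaque-voi", gmm_candidates=(2,))
        assert len(res.excluded_plaques) == truth.count("plaque") == 1
        assert res.excluded_plaques[0].eq_diameter_um > 20.0
        assert len(res.catalog.retained) == truth.count() - 1

    def test_sparse_plaques_stay_below_reported_bound(self):
        """Plaque-like clusters are rare (<10 per sample) and all excluded."""
        from ichdquant.synthetic import PopulationSpec, PhantomConfig
        pops = (PopulationSpec("plaque", 4, 40.0, 5.0, 160.0, 2.0),)
        cfg = PhantomConfig(shape=(160, 160, 160), voxel_size_um=2.0,
                            populations=pops, noise_sd=0.0, background_sd=0.0,
                            blur_sigma_um=0.0, seed=8)
        _, truth = iq.generate_phantom(cfg)
        assert truth.count("plaque") < 10


class TestComputeLoad:
    def test_empty_catalog_zero(self):
        cat = iq.measure_particles(np.zeros((5, 5, 5), int), 1.0, 0)
        assert iq.compute_load(cat) == 0.0

    def test_full_mask_hundred(self):
        cat = iq.measure_particles(np.ones((5, 5, 5), int), 1.0, 1)
        assert iq.compute_load(cat) == pytest.approx(100.0)

    def test_additive_over_disjoint_vois(self, rng):
        m1 = rng.random((10, 10, 10)) < 0.1
        m2 = rng.random((14, 10, 10)) < 0.25
        def load(m):
            lab, n = iq.label_components(m)
            return iq.compute_load(iq.measure_particles(lab, 1.0, n))
        union = np.concatenate([m1, m2], axis=0)
        w = np.array([m1.size, m2.size], float)
        expected = (load(m1) * w[0] + load(m2) * w[1]) / w.sum()
        assert load(union) == pytest.approx(expected, rel=1e-12)

    def test_recovery_against_planted_truth(self, small_phantom, small_voi_result):
        _, _, truth = small_phantom
        est = small_voi_result.result.load_percent
        true = truth.true_load_percent["total"]
        assert abs(est - true) / true < 0.10


def test_filter_small_reports_count(small_voi_result):
    cat = small_voi_result.catalog
    filtered, n_removed = filter_small(cat, 10)
    assert n_removed == len(cat) - len(filtered)
    assert all(r.voxel_count >= 10 for r in filtered.records)
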