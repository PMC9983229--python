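"""Resorption index, deformation index, TRAP area, adhesion ratio."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from osteoquant import (
    adhesion_ratio,
    binarize_and_label,
    bone_resorption_index,
    cell_deformation_index,
    deformation_indices,
    osteoclast_movie_config,
    otsu_threshold,
    render_stack,
    simulate_trajectories,
    trap_area,
    unmix,
)
from osteoquant.preprocess import GAMMA_PHOCAS, GAMMA_TDTOMATO, gamma_correct


def _disk_mask(shape, center, radius):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestBri:
    def test_uniform_field_gives_one(self):
        img = np.full((32, 32), 5.0)
        mask = _disk_mask((32, 32), (16, 16), 6)
        assert bone_resorption_index(img, mask).bri == 1.0

    def test_constructed_means(self):
        mask = np.zeros((20, 20), bool)
        mask[:10] = True
        img = np.where(mask, 200.0, 50.0)
        res = bone_resorption_index(img, mask)
        assert (res.signal, res.noise, res.bri) == (200.0, 50.0, 4.0)

    def test_scale_invariance(self, rng):
        img = rng.uniform(1, 10, (24, 24))
        mask = _disk_mask((24, 24), (12, 12), 5)
        base = bone_resorption_index(img, mask).bri
        scaled = bone_resorption_index(3.7 * img, mask).bri
        assert scaled == pytest.approx(base, rel=1e-12)

    @pytest.mark.parametrize(
        "mask", [np.zeros((8, 8), bool), np.ones((8, 8), bool)],
        ids=["empty", "full"],
    )
    def test_degenerate_masks_rejected(self, mask):
        with pytest.raises(ValueError):
            bone_resorption_index(np.ones((8, 8)), mask)

    def test_zero_noise_rejected(self):
        mask = np.zeros((8, 8), bool)
        mask[:4] = True
        img = np.where(mask, 1.0, 0.0)
        with pytest.raises(ValueError, match="noise"):
            bone_resorption_index(img, mask)

    def test_r_type_scene_scores_higher_than_n_type(self, library):
        """Acidification foci sit only under R-type cells, so an all-R
        scene must out-score an all-N scene at the same photon budget."""
        bris = {}
        for frac in (1.0, 0.0):
            cfg = osteoclast_movie_config(
                field_size_px=(96, 96), n_osteoclasts=4,
                r_type_fraction=frac, seed=21, photon_scale=200.0,
            )
            stack = render_stack(simulate_trajectories(cfg))
            un = unmix(stack, library)
            td = gamma_correct(un.channel("tdTomato"), GAMMA_TDTOMATO)[0].max(axis=0)
            ph = gamma_correct(un.channel("pHocas3"), GAMMA_PHOCAS)[0].max(axis=0)
            mask = td > otsu_threshold(td)
            bris[frac] = bone_resorption_index(ph, mask).bri
        assert bris[1.0] > bris[0.0]


class TestCdi:
    def test_identical_masks(self):
        mask = _disk_mask((30, 30), (15, 15), 7)
        res = cell_deformation_index(mask, mask)
        assert res.cdi == 1.0
        assert res.area_t0_um2 == res.overlap_um2 == res.area_t1_um2

    def test_disjoint_equal_areas(self):
        a = np.zeros((10, 30), bool)
        c = np.zeros((10, 30), bool)
        a[:, :10] = True
        c[:, 20:] = True
        assert cell_deformation_index(a, c).cdi == 2.0

    def test_constructed_areas_100_60_80(self):
        a = np.zeros((12, 10), bool)
        a[:10] = True  # A = 100
        c = np.zeros((12, 10), bool)
        c[:6] = True  # 60 px inside A
        c[10:12] = True  # 20 px outside => C = 80, B = 60
        res = cell_deformation_index(a, c)
        assert (res.area_t0_um2, res.overlap_um2, res.area_t1_um2) == (100, 60, 80)
        assert res.cdi == 1.125

    def test_empty_footprint_rejected(self):
        with pytest.raises(ValueError):
            cell_deformation_index(np.zeros((4, 4), bool), np.ones((4, 4), bool))

    @given(seed=st.integers(0, 10_000))
    def test_cdi_at_least_one(self, seed):
        r = np.random.default_rng(seed)
        a = _disk_mask((24, 24), r.integers(6, 18, 2), r.integers(2, 7))
        c = _disk_mask((24, 24), r.integers(6, 18, 2), r.integers(2, 7))
        res = cell_deformation_index(a, c)
        assert res.cdi >= 1.0
        assert res.overlap_um2 <= min(res.area_t0_um2, res.area_t1_um2)

    def test_matched_cells_across_frames(self):
        """Centroid matching pairs each object with its displaced self."""
        f0 = np.zeros((40, 60))
        f1 = np.zeros((40, 60))
        f0[_disk_mask((40, 60), (10, 12), 5)] = 1
        f0[_disk_mask((40, 60), (28, 45), 6)] = 1
        f1[_disk_mask((40, 60), (12, 14), 5)] = 1  # small shift
        f1[_disk_mask((40, 60), (28, 45), 6)] = 1  # stationary
        l0 = binarize_and_label(f0, 0.5, 1.0)
        l1 = binarize_and_label(f1, 0.5, 1.0)
        results = deformation_indices(l0, l1, max_match_um=20.0)
        assert len(results) == 2
        cdis = sorted(r.cdi for r in results)
        assert cdis[0] == 1.0  # stationary cell
        assert cdis[1] > 1.0  # shifted cell

    def test_n_type_cells_more_deformed_than_r_type(self, library):
        cdis = {}
        for frac in (1.0, 0.0):
            cfg = osteoclast_movie_config(
                field_size_px=(96, 96), n_osteoclasts=4,
                r_type_fraction=frac, seed=22, photon_scale=None,
            )
            scene = simulate_trajectories(cfg)
            shape = cfg.field_size_px
            vals = [
                cell_deformation_index(
                    c.footprint_mask(0, shape), c.footprint_mask(2, shape),
                    cfg.pixel_size_um,
                ).cdi
                for c in scene.cells_of("osteoclast")
            ]
            cdis[frac] = np.mean(vals)
        assert cdis[0.0] > cdis[1.0]


class TestTrapArea:
    def _labels(self, n_px):
        img = np.zeros((10, 10 * len(n_px)))
        for i, n in enumerate(n_px):
            img[0, 10 * i : 10 * i + 1] = 0
            ys, xs = np.unravel_index(np.arange(n), (10, 8))
            img[ys, xs + 10 * i] = 1
        return binarize_and_label(img, 0.5, pixel_size_um=2.0)

    def test_self_reference_is_one(self):
        labels = self._labels([20, 30])
        assert trap_area(labels, labels.total_measure()) == 1.0

    def test_linearity_in_object_area(self):
        small = self._labels([10, 15])
        double = self._labels([20, 30])
        ref = 100.0
        assert trap_area(double, ref) == pytest.approx(2 * trap_area(small, ref))

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            trap_area(self._labels([10]), 0.0)

    def test_cell_count_scales_ground_truth_area(self):
        totals = {}
        for n in (10, 20):
            cfg = osteoclast_movie_config(
                field_size_px=(256, 256), n_osteoclasts=n, r_type_fraction=0.5,
                seed=23, photon_scale=None,
            )
            scene = simulate_trajectories(cfg)
            totals[n] = sum(
                c.footprints[0][2].sum() for c in scene.cells_of("osteoclast")
            )
        assert totals[20] / totals[10] == pytest.approx(2.0, rel=0.35)


class TestAdhesionRatio:
    def _labels_3d(self, mask):
        return binarize_and_label(
            mask.astype(float), 0.5, pixel_size_um=1.0, z_step_um=1.0
        )

    def test_constructed_ratio(self):
        cells = np.ones((3, 10, 10), bool)
        cells[:, :, 9] = False  # 270 voxels, 1 µm³ each
        adhesion = np.zeros((3, 10, 10), bool)
        adhesion[0] = cells[0]  # 90 voxels
        res = adhesion_ratio(self._labels_3d(cells), adhesion)
        assert res.printed_ratio == 3.0
        assert res.adhesion_fraction == pytest.approx(1 / 3)
        assert res.printed_ratio * res.adhesion_fraction == pytest.approx(1.0)

    def test_full_contact_bound(self):
        cells = np.zeros((2, 6, 6), bool)
        cells[:, 2:4, 2:4] = True
        res = adhesion_ratio(self._labels_3d(cells), cells)
        assert res.adhesion_fraction == 1.0 and res.printed_ratio == 1.0

    def test_zero_adhesion_flagged(self):
        cells = np.zeros((2, 6, 6), bool)
        cells[0, :2, :2] = True
        res = adhesion_ratio(self._labels_3d(cells), np.zeros_like(cells))
        assert res.flagged and res.adhesion_fraction == 0.0
        assert np.isnan(res.printed_ratio)

    def test_adhesion_outside_cells_rejected(self):
        cells = np.zeros((2, 6, 6), bool)
        cells[0, :2, :2] = True
        stray = np.zeros_like(cells)
        stray[1, 4, 4] = True
        with pytest.raises(ValueError):
            adhesion_ratio(self._labels_3d(cells), stray)

    def test_contact_propensity_orders_ground_truth_fractions(self):
        """Cohorts generated at high vs low bone-contact propensity order
        their mean contact fractions accordingly."""
        from osteoquant import precursor_movie_config

        fractions = {}
        for p in (0.8, 0.2):
            vals = []
            for seed in range(5):
                cfg = precursor_movie_config(
                    field_size_px=(128, 128), n_precursors=20,
                    adhesion_probability=p, seed=40 + seed, photon_scale=None,
                )
                scene = simulate_trajectories(cfg)
                flags = [c.bone_contact[0] for c in scene.cells_of("precursor")]
                vals.append(np.mean(flags))
            fractions[p] = np.mean(vals)
        assert fractions[0.8] > fractions[0.2]
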