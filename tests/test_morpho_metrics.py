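import numpy as np
import pytest

from choromvq.morpho import (
    bifurcation_angle,
    compute_biomarkers,
    fractal_dimension,
    murray_deviation,
    skeletonize_and_segment,
    tortuosity,
    vessel_density,
)
from choromvq.morpho.binarize import BinaryVesselMask
from choromvq.morpho.skeleton import BranchPoint, Skeleton
from choromvq.synth import generate_vessel_tree, rasterize
from conftest import synthetic_junction_skeleton


class TestVesselDensity:
    def test_full_and_empty(self):
        roi = np.ones((16, 16), dtype=bool)
        assert vessel_density(BinaryVesselMask(roi.copy(), roi, 50.0)) == 1.0
        assert vessel_density(BinaryVesselMask(np.zeros_like(roi), roi, 50.0)) == 0.0

    def test_band_fraction(self):
        roi = np.ones((64, 64), dtype=bool)
        mask = np.zeros_like(roi)
        mask[10:18, :] = True  # 8 of 64 rows
        assert vessel_density(BinaryVesselMask(mask, roi, 50.0)) == pytest.approx(0.125)


class TestTortuosity:
    def test_straight_segment_unity(self, band_mask):
        sk = skeletonize_and_segment(band_mask, prune_px=4.0, pixel_pitch_um=50.0)
        taus, tmean, tmax = tortuosity(sk)
        assert tmean == pytest.approx(1.0, abs=1e-9)

    def test_half_circle_approaches_pi_over_2(self, half_annulus_mask):
        sk = skeletonize_and_segment(half_annulus_mask, prune_px=6.0, pixel_pitch_um=1.0)
        _, _, tmax = tortuosity(sk)
        assert tmax == pytest.approx(np.pi / 2, rel=0.02)

    def test_max_at_least_mean(self):
        tree = generate_vessel_tree(3, 4, tortuosity_amplitude=0.25)
        raster = rasterize(tree, 50.0, (256, 256))
        sk = skeletonize_and_segment(raster.occupancy, prune_px=4.0, pixel_pitch_um=50.0)
        _, tmean, tmax = tortuosity(sk)
        assert tmax >= tmean >= 1.0

    def test_empty_skeleton_rejected(self):
        sk = skeletonize_and_segment(np.zeros((16, 16), dtype=bool), prune_px=4.0)
        with pytest.raises(ValueError):
            tortuosity(sk)


class TestMurrayDeviation:
    def test_murray_compliant_junction_zero(self):
        sk = synthetic_junction_skeleton(2.0 ** (1.0 / 3.0), 1.0, 1.0)
        mds, md_mean, md_max, ok = murray_deviation(sk)
        assert ok
        assert md_mean == pytest.approx(0.0, abs=1e-12)

    def test_equal_diameters_give_unity(self):
        sk = synthetic_junction_skeleton(1.0, 1.0, 1.0)
        _, md_mean, _, ok = murray_deviation(sk)
        assert md_mean == pytest.approx(1.0, abs=1e-12)

    def test_unmeasurable_without_branch_points(self, band_mask):
        sk = skeletonize_and_segment(band_mask, prune_px=4.0, pixel_pitch_um=50.0)
        _, md_mean, md_max, ok = murray_deviation(sk)
        assert not ok
        assert np.isnan(md_mean) and np.isnan(md_max)

    def test_zero_on_rasterized_murray_tree(self):
        """gamma=3 trees rasterized noise-free: MD small (limited only by
        pixel-quantized diameter estimates)."""
        tree = generate_vessel_tree(2, 2, tortuosity_amplitude=0.05, root_diameter_um=700.0)
        raster = rasterize(tree, 50.0, (256, 256))
        sk = skeletonize_and_segment(raster.occupancy, prune_px=4.0, pixel_pitch_um=50.0)
        _, md_mean, _, ok = murray_deviation(sk)
        assert ok
        assert md_mean < 0.6


class TestFractalDimension:
    def test_straight_line_dimension_one(self):
        m = np.zeros((512, 512), dtype=bool)
        m[256, :] = True
        assert fractal_dimension(m) == pytest.approx(1.0, abs=0.05)

    def test_filled_block_dimension_two(self):
        m = np.ones((512, 512), dtype=bool)
        assert fractal_dimension(m) == pytest.approx(2.0, abs=0.05)

    def test_sierpinski_prefractal(self):
        """Bitwise-AND Sierpinski raster has box-counting slope log2(3)."""
        n = 256
        i, j = np.mgrid[0:n, 0:n]
        m = (i & j) == 0
        assert fractal_dimension(m) == pytest.approx(np.log2(3.0), abs=0.1)

    def test_empty_flagged_nan(self):
        assert np.isnan(fractal_dimension(np.zeros((64, 64), dtype=bool)))

    def test_too_few_box_sizes_rejected(self):
        m = np.ones((64, 64), dtype=bool)
        with pytest.raises(ValueError):
            fractal_dimension(m, box_sizes=[2, 4])


class TestBifurcationAngle:
    def test_y_at_45_degrees(self, y_mask):
        sk = skeletonize_and_segment(y_mask, prune_px=4.0, pixel_pitch_um=50.0)
        _, ba_mean, ba_max, ok = bifurcation_angle(sk)
        assert ok
        assert ba_mean == pytest.approx(90.0, abs=5.0)

    def test_synthetic_junction_90_degrees(self):
        sk = synthetic_junction_skeleton(2.0, 1.0, 1.0)
        _, ba_mean, _, ok = bifurcation_angle(sk)
        assert ok
        assert ba_mean == pytest.approx(90.0, abs=2.0)

    def test_collinear_daughters_approach_180(self):
        """T-junction: daughters leave in opposite directions."""
        j = (50, 50)
        trunk = np.array([(50 - k, 50) for k in range(12, 0, -1)] + [j])
        left = np.array([j] + [(50, 50 - k) for k in range(1, 13)])
        right = np.array([j] + [(50, 50 + k) for k in range(1, 13)])
        paths = [trunk, left, right]
        mask = np.zeros((100, 100), dtype=bool)
        for p in paths:
            mask[p[:, 0], p[:, 1]] = True
        sk = Skeleton(
            segments=paths,
            segment_diameters_um=[np.full(len(p), d) for p, d in zip(paths, (2.0, 1.0, 1.0))],
            branch_points=[BranchPoint((50.0, 50.0), [j], [0, 1, 2])],
            pixel_pitch_um=1.0,
            skeleton_mask=mask,
            mask=mask,
        )
        _, ba_mean, _, ok = bifurcation_angle(sk)
        assert ok
        assert ba_mean == pytest.approx(180.0, abs=2.0)

    def test_unmeasurable_without_branch_points(self, band_mask):
        sk = skeletonize_and_segment(band_mask, prune_px=4.0, pixel_pitch_um=50.0)
        _, _, _, ok = bifurcation_angle(sk)
        assert not ok


class TestComputeBiomarkers:
    def test_empty_mask_record(self):
        img = np.zeros((64, 64))
        rec = compute_biomarkers(img, np.ones((64, 64), dtype=bool), pixel_pitch_um=50.0)
        assert rec.VD == 0.0
        assert rec.NV == 0 and rec.NB == 0
        assert not rec.measurable_MD_BA
        assert np.isnan(rec.MDmean) and np.isnan(rec.BAmax_deg)

    def test_melanoma_like_exceeds_nevus_like(self):
        """Dense tortuous phantom beats sparse straight phantom on all six
        discriminative biomarkers (VD, NV, NB, Dmax, tau_max, mvFD)."""
        mel_tree = generate_vessel_tree(
            10, 8, tortuosity_amplitude=0.3, root_diameter_um=800.0
        )
        nev_tree = generate_vessel_tree(
            11, 1, tortuosity_amplitude=0.03, root_diameter_um=500.0
        )
        roi = np.ones((256, 256), dtype=bool)
        recs = {}
        for name, tree in (("mel", mel_tree), ("nev", nev_tree)):
            raster = rasterize(tree, 50.0, (256, 256))
            recs[name] = compute_biomarkers(
                raster.occupancy.astype(float), roi, pixel_pitch_um=50.0
            )
        m, n = recs["mel"], recs["nev"]
        assert m.VD > n.VD
        assert m.NV > n.NV
        assert m.NB > n.NB
        assert m.Dmax_um > n.Dmax_um
        assert m.tau_max > n.tau_max
        assert m.mvFD > n.mvFD

    def test_record_invariants_on_random_phantoms(self):
        """tau_max >= tau_mean >= 1, Dmax >= Dmean, and the missingness
        coupling, over a sweep of random phantoms."""
        rng = np.random.default_rng(0)
        roi = np.ones((192, 192), dtype=bool)
        for trial in range(25):
            tree = generate_vessel_tree(
                int(rng.integers(0, 2**31 - 1)),
                int(rng.integers(0, 6)),
                tortuosity_amplitude=float(rng.uniform(0, 0.3)),
                root_diameter_um=float(rng.uniform(300, 800)),
                extent_mm=(9.6, 9.6),
                segment_length_mm=1.8,
            )
            raster = rasterize(tree, 50.0, (192, 192))
            rec = compute_biomarkers(raster.occupancy.astype(float), roi, pixel_pitch_um=50.0)
            if rec.NV == 0:
                continue
            assert rec.tau_max >= rec.tau_mean >= 1.0
            assert rec.Dmax_um >= rec.Dmean_um
            assert rec.measurable_MD_BA == (rec.NB > 0)
            assert 0.0 <= rec.VD <= 1.0

    def test_pixel_pitch_equivariance(self):
        """Halving the pitch (doubling the grid) leaves physical measures
        within 5%."""
        tree = generate_vessel_tree(6, 2, tortuosity_amplitude=0.15, root_diameter_um=600.0)
        coarse = rasterize(tree, 50.0, (256, 256))
        fine = rasterize(tree, 25.0, (512, 512))
        rec_c = compute_biomarkers(
            coarse.occupancy.astype(float), np.ones((256, 256), bool), pixel_pitch_um=50.0
        )
        rec_f = compute_biomarkers(
            fine.occupancy.astype(float),
            np.ones((512, 512), bool),
            {"prune_px": 8.0},
            pixel_pitch_um=25.0,
        )
        assert rec_f.Dmean_um == pytest.approx(rec_c.Dmean_um, rel=0.05)
        assert rec_f.VD == pytest.approx(rec_c.VD, rel=0.05)
        assert rec_f.tau_mean == pytest.approx(rec_c.tau_mean, rel=0.05)

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValueError, match="config"):
            compute_biomarkers(
                np.ones((16, 16)), np.ones((16, 16), bool), {"bogus": 1}, pixel_pitch_um=50.0
            )
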