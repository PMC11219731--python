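import numpy as np
import pytest

from ifhdr import quant, synth
from ifhdr.imgio import TumorAnnotation
from ifhdr.quant import (
    StainBasis,
    area_proportion,
    case_summary,
    deconvolve,
    macenko_stains,
    od_transform,
    tps_category,
)


@pytest.fixture(scope="module")
def ihc_truth():
    return synth.make_phantom(rows=256, cols=256, n_nuclei=25, seed=11)


@pytest.fixture(scope="module")
def ihc_clean(ihc_truth):
    return synth.render_ihc(ihc_truth, noise_sd=0.0, seed=11)


class TestODTransform:
    def test_near_white_is_zero(self):
        od = od_transform(np.full((2, 2, 3), 254, dtype=np.uint8))
        np.testing.assert_allclose(od, 0.0)

    def test_log10_definition(self):
        # (pixel+1)/I0 = 0.1  ->  OD = 1
        pixel = np.full((1, 1, 3), 24.5)
        np.testing.assert_allclose(od_transform(pixel, i0=255.0), 1.0)

    def test_matches_generator_od_within_quantization(self, ihc_truth, ihc_clean):
        od = od_transform(ihc_clean)
        c_h, c_d = synth.true_concentrations(ihc_truth)
        expected = (
            c_h[..., None] * ihc_truth.stain_basis_true[:, 0]
            + c_d[..., None] * ihc_truth.stain_basis_true[:, 1]
        )
        assert np.abs(od - expected).max() < 0.02


class TestMacenkoStains:
    def test_recovers_generator_vectors(self, ihc_truth, ihc_clean):
        basis = macenko_stains(od_transform(ihc_clean))
        for rec, true in zip(basis.matrix.T, ihc_truth.stain_basis_true.T):
            angle = np.degrees(np.arccos(np.clip(rec @ true, -1, 1)))
            assert angle < 2.0

    def test_hematoxylin_column_is_less_blue_absorbing(self, ihc_clean):
        basis = macenko_stains(od_transform(ihc_clean))
        assert basis.hematoxylin[2] < basis.dab[2]

    def test_pixel_permutation_invariance(self, ihc_clean):
        od = od_transform(ihc_clean).reshape(-1, 3)
        perm = np.random.default_rng(0).permutation(len(od))
        a = macenko_stains(od.reshape(-1, 1, 3))
        b = macenko_stains(od[perm].reshape(-1, 1, 3))
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-9)

    def test_single_stain_is_degenerate(self):
        rng = np.random.default_rng(0)
        s = np.array([0.27, 0.57, 0.78])
        s /= np.linalg.norm(s)
        od = rng.uniform(0.3, 1.5, 5000)[:, None] * s
        with pytest.raises(ValueError, match="degenerate"):
            macenko_stains(od.reshape(-1, 1, 3))

    def test_too_few_stained_pixels(self):
        od = np.zeros((50, 50, 3))
        with pytest.raises(ValueError, match="insufficient"):
            macenko_stains(od)


class TestDeconvolve:
    @pytest.fixture()
    def basis(self):
        h = np.array([0.65, 0.70, 0.29])
        d = np.array([0.27, 0.57, 0.78])
        return StainBasis(
            matrix=np.stack([h / np.linalg.norm(h), d / np.linalg.norm(d)], axis=1)
        )

    def test_pure_dab_unit(self, basis):
        od = basis.dab.reshape(1, 1, 3)
        maps = deconvolve(od, basis)
        assert maps.hematoxylin[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert maps.dab[0, 0] == pytest.approx(1.0)

    def test_zero_od_gives_zero(self, basis):
        maps = deconvolve(np.zeros((2, 2, 3)), basis)
        np.testing.assert_allclose(maps.hematoxylin, 0.0)
        np.testing.assert_allclose(maps.dab, 0.0)

    def test_round_trip_random_concentrations(self, basis):
        rng = np.random.default_rng(1)
        c = rng.uniform(0, 2, (64, 64, 2))
        od = c @ basis.matrix.T
        maps = deconvolve(od, basis)
        np.testing.assert_allclose(maps.hematoxylin, c[..., 0], atol=1e-6)
        np.testing.assert_allclose(maps.dab, c[..., 1], atol=1e-6)

    def test_generator_concentrations_recovered(self, ihc_truth, ihc_clean):
        od = od_transform(ihc_clean)
        maps = deconvolve(od, macenko_stains(od))
        c_h, c_d = synth.true_concentrations(ihc_truth)
        rmse = np.sqrt(np.mean((maps.dab - c_d) ** 2 + (maps.hematoxylin - c_h) ** 2))
        assert rmse < 0.05


class TestAreaProportion:
    def test_all_positive(self):
        ann = TumorAnnotation(mask=np.ones((8, 8), bool), mpp=1.0)
        res = area_proportion(np.full((8, 8), 10.0), ann, threshold_rule=5.0)
        assert res.proportion == 1.0
        assert res.positive_pixels == res.total_pixels == 64

    def test_checkerboard_half(self):
        vals = np.indices((8, 8)).sum(axis=0) % 2 * 4095
        ann = TumorAnnotation(mask=np.ones((8, 8), bool), mpp=1.0)
        assert area_proportion(vals, ann, threshold_rule=2000.0).proportion == 0.5

    def test_boundary_pixels_are_negative(self):
        ann = TumorAnnotation(mask=np.ones((4, 4), bool), mpp=1.0)
        assert area_proportion(np.full((4, 4), 7.0), ann, threshold_rule=7.0).proportion == 0.0

    def test_phantom_detection_threshold_matches_membrane_fraction(
        self, phantom, stack
    ):
        med = stack.pdl1_images(virtual=False)[1]
        ann = TumorAnnotation(mask=np.ones(phantom.shape, bool), mpp=quant.MPP_IF)
        res = area_proportion(
            med.pixels, ann, threshold_rule=synth.detection_threshold(phantom)
        )
        assert res.proportion == pytest.approx(phantom.membrane_mask.mean(), abs=0.01)

    def test_mpp_affects_area_not_proportion(self):
        vals = np.arange(64).reshape(8, 8).astype(float)
        for mpp in (0.334, 0.465, 2.0):
            res = area_proportion(
                vals, TumorAnnotation(mask=np.ones((8, 8), bool), mpp=mpp), 31.0
            )
            assert res.proportion == 32 / 64
            assert res.area_um2 == pytest.approx(32 * mpp**2)

    def test_mask_fixing_permutation_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.random((16, 16))
        mask = rng.random((16, 16)) > 0.5
        ann = TumorAnnotation(mask=mask, mpp=1.0)
        base = area_proportion(vals, ann, threshold_rule="otsu")
        inside = vals[mask]
        perm = rng.permutation(inside.size)
        vals2 = vals.copy()
        vals2[mask] = inside[perm]
        res = area_proportion(vals2, ann, threshold_rule="otsu")
        assert res.proportion == base.proportion
        assert res.threshold_used == base.threshold_used

    def test_empty_mask_rejected(self):
        ann = TumorAnnotation(mask=np.zeros((4, 4), bool), mpp=1.0)
        with pytest.raises(ValueError, match="empty annotation"):
            area_proportion(np.zeros((4, 4)), ann)


class TestTPSCategories:
    @pytest.mark.parametrize(
        "percent,expected",
        [(0.0, "<1%"), (0.5, "<1%"), (1.0, "1-49%"), (25.0, "1-49%"),
         (49.9, "1-49%"), (50.0, ">=50%"), (100.0, ">=50%")],
    )
    def test_boundaries(self, percent, expected):
        assert tps_category(percent) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tps_category(101.0)

    @pytest.mark.parametrize(
        "count,percent,expected",
        [(99, 70.0, "excluded"), (0, 10.0, "excluded"), (100, 70.0, ">=50%")],
    )
    def test_case_summary_exclusion_rule(self, count, percent, expected):
        assert case_summary(percent, count) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            case_summary(10.0, -1)
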