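"""Engulfment scoring: colocalization, the triple criterion, the
pixel-shift null, depth correlation, and layer density."""

import numpy as np
import pytest
from scipy import stats

from neuroquant.engulfment import (
    MicrogliaCell,
    cd68_reactivity,
    colocalization_fraction,
    depth_correlation,
    microglia_density,
    score_roi,
    shifted_null,
    triple_engulfment,
)
from neuroquant.imaging import PixelGeometry, binarize
from neuroquant.synth import EngulfmentSceneParams, generate_engulfment_stack


def _cell(shape=(60, 60), box=(10, 40, 10, 40), depth=50.0):
    m = np.zeros(shape, bool)
    m[box[0] : box[1], box[2] : box[3]] = True
    return MicrogliaCell(cell_mask=m, cortical_depth_um=depth)


def _mask(shape, box):
    m = np.zeros(shape, bool)
    m[box[0] : box[1], box[2] : box[3]] = True
    return m


class TestColocalization:
    def test_signal_equals_cell_gives_100_pct(self):
        c = _cell()
        pct, pos = colocalization_fraction(c, c.cell_mask.copy())
        assert pct == 100.0 and pos

    def test_disjoint_masks_give_zero_and_negative(self):
        c = _cell()
        pct, pos = colocalization_fraction(c, _mask((60, 60), (45, 55, 45, 55)))
        assert pct == 0.0 and not pos

    def test_planted_overlap_matches_pixel_count(self):
        c = _cell()
        pct, pos = colocalization_fraction(c, _mask((60, 60), (20, 25, 20, 28)))
        assert pct == pytest.approx(100.0 * 5 * 8 / c.area_px)
        assert pos

    def test_empty_cell_mask_rejected(self):
        with pytest.raises(ValueError):
            MicrogliaCell(cell_mask=np.zeros((5, 5), bool))

    def test_regions_below_min_pixels_discarded(self):
        c = _cell()
        sig = np.zeros((60, 60), bool)
        sig[20, 20] = sig[20, 21] = True  # 2-px region
        pct, pos = colocalization_fraction(c, sig, min_pixels=3)
        assert pct == 0.0 and not pos


class TestTripleEngulfment:
    def test_punctum_inside_lysosome_inside_cell_is_positive(self):
        c = _cell()
        psd = _mask((60, 60), (20, 23, 20, 23))
        cd68 = _mask((60, 60), (18, 26, 18, 26))
        pct, pos = triple_engulfment(c, psd, cd68)
        assert pos and pct == pytest.approx(100.0 * 9 / c.area_px)

    def test_punctum_outside_lysosome_is_negative(self):
        c = _cell()
        psd = _mask((60, 60), (20, 23, 20, 23))
        cd68 = _mask((60, 60), (30, 38, 30, 38))  # elsewhere in the cell
        pct, pos = triple_engulfment(c, psd, cd68)
        assert not pos and pct == 0.0

    def test_two_pixel_triple_overlap_below_size_filter(self):
        c = _cell()
        psd = _mask((60, 60), (20, 21, 20, 22))  # 1x2
        cd68 = _mask((60, 60), (18, 26, 18, 26))
        _pct, pos = triple_engulfment(c, psd, cd68, min_pixels=3)
        assert not pos

    def test_raising_min_pixels_never_increases_positivity(self):
        params = EngulfmentSceneParams(roi_size_um=(100, 120), n_microglia=8, seed=5)
        stack, truth = generate_engulfment_stack(params)
        z = stack.shape_zyx[0] // 2
        psd = binarize(stack.channel("PSD95")[z], "fixed", 50).mask
        cd68 = binarize(stack.channel("CD68")[z], "fixed", 50).mask
        cells = [MicrogliaCell(cell_mask=m.cell_mask) for m in truth.microglia]
        positives = []
        for mp in (1, 3, 9, 27):
            summary = score_roi(cells, psd, cd68, min_pixels=mp)
            positives.append(summary.pct_positive)
        assert all(a >= b for a, b in zip(positives, positives[1:]))

    def test_triple_area_bounded_by_pairwise_overlaps(self):
        c = _cell()
        rng = np.random.default_rng(8)
        psd = rng.uniform(size=(60, 60)) < 0.3
        cd68 = rng.uniform(size=(60, 60)) < 0.3
        tri, _p = triple_engulfment(c, psd, cd68, min_pixels=1)
        pair_psd, _ = colocalization_fraction(c, psd, min_pixels=1)
        pair_cd, _ = colocalization_fraction(c, cd68, min_pixels=1)
        assert tri <= pair_psd and tri <= pair_cd

    def test_pipeline_recovers_generator_truth(self, small_scene):
        params, stack, truth = small_scene
        z = stack.shape_zyx[0] // 2
        psd = binarize(stack.channel("PSD95")[z], "fixed", params.amplitude / 2).mask
        cd68 = binarize(stack.channel("CD68")[z], "fixed", params.amplitude / 2).mask
        cells = [MicrogliaCell(cell_mask=m.cell_mask) for m in truth.microglia]
        summary = score_roi(cells, psd, cd68)
        expected = 100.0 * truth.n_engulfment_positive / len(truth.microglia)
        assert summary.pct_positive == pytest.approx(expected)


class TestShiftedNull:
    def test_zero_distance_reproduces_observed_metrics(self, small_scene):
        params, stack, truth = small_scene
        z = stack.shape_zyx[0] // 2
        psd = binarize(stack.channel("PSD95")[z], "fixed", 50).mask
        cd68 = binarize(stack.channel("CD68")[z], "fixed", 50).mask
        cells = [MicrogliaCell(cell_mask=m.cell_mask) for m in truth.microglia]
        observed = score_roi(cells, psd, cd68)
        null = shifted_null(psd, cd68, cells, stack.geometry, distance_um=0.0, n_rounds=2, seed=0)
        assert (null["pct_positive"] == observed.pct_positive).all()

    def test_shift_collapses_true_engulfment(self):
        params = EngulfmentSceneParams(
            roi_size_um=(140, 160), n_microglia=10, engulfment_rate=0.6,
            lysosomes_per_microglia=4.0, seed=9,
        )
        stack, truth = generate_engulfment_stack(params)
        z = stack.shape_zyx[0] // 2
        psd = binarize(stack.channel("PSD95")[z], "fixed", 50).mask
        cd68 = binarize(stack.channel("CD68")[z], "fixed", 50).mask
        cells = [MicrogliaCell(cell_mask=m.cell_mask) for m in truth.microglia]
        observed = score_roi(cells, psd, cd68)
        null = shifted_null(psd, cd68, cells, stack.geometry, n_rounds=8, seed=1)
        assert observed.pct_positive >= 40.0
        assert null["pct_positive"].mean() < observed.pct_positive / 4

    def test_invalid_rounds_rejected(self, small_scene):
        params, stack, truth = small_scene
        cells = [MicrogliaCell(cell_mask=truth.microglia[0].cell_mask)]
        with pytest.raises(ValueError):
            shifted_null(
                truth.microglia[0].cell_mask,
                truth.microglia[0].cell_mask,
                cells,
                stack.geometry,
                n_rounds=0,
            )


class TestDepthCorrelation:
    def _cohort(self, slope=-0.05, intercept=20.0, noise=1.0, n=30, seed=0):
        rng = np.random.default_rng(seed)
        cells = []
        for _ in range(n):
            d = rng.uniform(10, 290)
            c = _cell(depth=d)
            c.metrics["engulf_positive"] = True
            c.metrics["engulf_area_pct"] = max(
                intercept + slope * d + rng.normal(0, noise), 0.01
            )
            cells.append(c)
        return cells

    def test_negative_depth_trend_recovered_with_ci(self):
        res = depth_correlation(self._cohort(slope=-0.05, seed=1))
        assert res["r"] < 0
        lo, hi = res["slope_ci95"]
        assert lo <= -0.05 <= hi

    def test_cells_beyond_depth_limit_excluded(self):
        cells = self._cohort(n=10, seed=2)
        deep = _cell(depth=350.0)
        deep.metrics["engulf_positive"] = True
        deep.metrics["engulf_area_pct"] = 99.0
        res_without = depth_correlation(cells)
        res_with = depth_correlation(cells + [deep])
        assert res_with["n"] == res_without["n"]

    def test_engulfment_negative_cells_excluded(self):
        cells = self._cohort(n=10, seed=3)
        neg = _cell(depth=100.0)
        neg.metrics["engulf_positive"] = False
        neg.metrics["engulf_area_pct"] = 0.0
        assert depth_correlation(cells + [neg])["n"] == 10

    def test_constant_engulfment_flagged_degenerate(self):
        cells = []
        for d in (50, 100, 150, 200):
            c = _cell(depth=float(d))
            c.metrics["engulf_positive"] = True
            c.metrics["engulf_area_pct"] = 5.0
            cells.append(c)
        res = depth_correlation(cells)
        assert res["degenerate"] and np.isnan(res["r"])

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            depth_correlation(self._cohort(n=2, seed=4))


class TestMicrogliaDensity:
    def test_density_is_count_over_volume(self):
        cells = [_cell(depth=50.0) for _ in range(10)]
        df = microglia_density(cells, {"L1": 1e5, "L2/3": 1e5}).set_index("layer")
        assert df.loc["L1", "density_per_um3"] == pytest.approx(1e-4)
        assert df.loc["L2/3", "n_cells"] == 0

    def test_boundary_cell_at_120_um_is_L1(self):
        df = microglia_density([_cell(depth=120.0)], {"L1": 1.0, "L2/3": 1.0})
        assert df.set_index("layer").loc["L1", "n_cells"] == 1

    def test_cells_deeper_than_bins_excluded_and_logged(self):
        df = microglia_density([_cell(depth=400.0)], {"L1": 1.0, "L2/3": 1.0})
        assert df["n_cells"].sum() == 0 and df.attrs["n_excluded"] == 1

    def test_uniform_placement_matches_volume_ratio(self):
        rng = np.random.default_rng(12)
        cells = [_cell(depth=rng.uniform(0, 300)) for _ in range(600)]
        df = microglia_density(cells, {"L1": 120.0, "L2/3": 180.0}).set_index("layer")
        n1, n23 = df.loc["L1", "n_cells"], df.loc["L2/3", "n_cells"]
        # counts follow the 120:180 volume split
        lo, hi = stats.binom.interval(0.999, 600, 120 / 300)
        assert lo <= n1 <= hi
        assert df.loc["L1", "density_per_um3"] == pytest.approx(n1 / 120.0)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            microglia_density([], {"L1": 0.0})


class TestCd68Reactivity:
    def test_full_coverage_and_no_coverage(self):
        c = _cell()
        assert cd68_reactivity(c, c.cell_mask.copy()) == 100.0
        assert cd68_reactivity(c, np.zeros((60, 60), bool)) == 0.0

    def test_planted_lysosome_area_ratio(self):
        c = _cell()
        assert cd68_reactivity(c, _mask((60, 60), (20, 30, 20, 30))) == pytest.approx(
            100.0 * 100 / c.area_px
        )


class TestRateRatioRecovery:
    def test_arm_ratio_recovered_within_bootstrap_ci(self):
        # two synthetic arms at engulfment rates 0.2 / 0.46 (ratio 2.3); the
        # scored positivity ratio must cover the truth in its bootstrap CI
        def arm(rate, seed0):
            vals = []
            for s in range(26):
                params = EngulfmentSceneParams(
                    roi_size_um=(120, 140), n_microglia=8, engulfment_rate=rate,
                    lysosomes_per_microglia=4.0, seed=seed0 + s,
                )
                stack, truth = generate_engulfment_stack(params)
                z = stack.shape_zyx[0] // 2
                psd = binarize(stack.channel("PSD95")[z], "fixed", 50).mask
                cd68 = binarize(stack.channel("CD68")[z], "fixed", 50).mask
                cells = [MicrogliaCell(cell_mask=m.cell_mask) for m in truth.microglia]
                vals.append(score_roi(cells, psd, cd68).pct_positive)
            return np.array(vals)

        a = arm(0.2, 1000)
        b = arm(0.46, 2000)
        rng = np.random.default_rng(0)
        boots = []
        for _ in range(2000):
            ra = rng.choice(a, len(a)).mean()
            rb = rng.choice(b, len(b)).mean()
            if ra > 0:
                boots.append(rb / ra)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        assert lo <= 2.3 <= hi
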