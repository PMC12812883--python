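import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage import draw

from hydrolipid.lipids import (
    CellMeasurement,
    DropletMeasurement,
    SegmentationError,
    SegmentationParams,
    droplet_geometry,
    feret_diameters,
    lipid_index,
    lipid_production_rate,
    measure_cell,
    measure_image_set,
    population_summary,
    segment_image,
)
from hydrolipid.pipeline import paired_ttest
from hydrolipid.synthetic import (
    SyntheticCellSpec,
    cell_spec_for_total_volume,
    generate_cell_image_set,
)

from conftest import feret_oracle


def _rect_mask(h, w, pad=6):
    mask = np.zeros((h + 2 * pad, w + 2 * pad), dtype=bool)
    mask[pad:pad + h, pad:pad + w] = True
    return mask


class TestFeretDiameters:
    def test_digital_disk(self):
        mask = np.zeros((60, 60), dtype=bool)
        rr, cc = draw.disk((30, 30), 20)
        mask[rr, cc] = True
        fmax, fmin = feret_diameters(mask)
        assert fmax == pytest.approx(40, abs=1.2)
        assert fmin == pytest.approx(40, abs=1.2)
        assert fmax >= fmin

    def test_axis_aligned_rectangle(self):
        """10x4 px rectangle: diagonal sqrt(116) and width 4 on the
        pixel-outline polygon."""
        fmax, fmin = feret_diameters(_rect_mask(4, 10))
        assert fmax == pytest.approx(math.sqrt(116), rel=1e-6)
        assert fmin == pytest.approx(4.0, rel=1e-6)

    def test_rotation_invariance(self):
        """A 60x24 px rectangle digitized at 37 deg keeps its Feret pair
        (within discretization) and matches the fine-sweep oracle."""
        h, w, theta = 24, 60, math.radians(37.0)
        yy, xx = np.mgrid[-50:51, -50:51].astype(float)
        u = xx * math.cos(theta) + yy * math.sin(theta)
        v = -xx * math.sin(theta) + yy * math.cos(theta)
        rotated = (np.abs(u) <= w / 2) & (np.abs(v) <= h / 2)
        fmax, fmin = feret_diameters(rotated)
        assert fmax == pytest.approx(math.hypot(h, w), rel=0.02)
        # outline-polygon width exceeds the continuous width by up to
        # (|sin|+|cos|) px for a rotated edge
        pad = abs(math.sin(theta)) + abs(math.cos(theta))
        assert h - 0.1 <= fmin <= h + pad + 0.1
        omax, omin = feret_oracle(rotated)
        assert fmax == pytest.approx(omax, rel=1e-9)
        assert fmin == pytest.approx(omin, rel=0.01)

    def test_single_pixel_convention(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert feret_diameters(mask) == (1.0, 1.0)

    def test_pixel_size_scaling(self):
        mask = _rect_mask(4, 10)
        fmax_um, fmin_um = feret_diameters(mask, pixel_size_um=0.1)
        fmax_px, fmin_px = feret_diameters(mask)
        assert fmax_um == pytest.approx(0.1 * fmax_px)
        assert fmin_um == pytest.approx(0.1 * fmin_px)

    def test_agrees_with_brute_force_oracle_on_random_masks(self):
        """Implementation (hull + 1 deg sweep) vs oracle (all boundary corner
        pairs + 0.1 deg sweep) on random blob masks."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 100:
            mask = np.zeros((36, 36), dtype=bool)
            n_disks = rng.integers(1, 4)
            for _ in range(n_disks):
                rr, cc = draw.ellipse(
                    rng.uniform(12, 24), rng.uniform(12, 24),
                    rng.uniform(2, 9), rng.uniform(2, 9),
                    shape=mask.shape, rotation=rng.uniform(0, math.pi),
                )
                mask[rr, cc] = True
            from skimage import measure as skmeasure

            labels = skmeasure.label(mask)
            mask = labels == 1  # keep one connected blob
            if mask.sum() < 2:
                continue
            fmax, fmin = feret_diameters(mask)
            omax, omin = feret_oracle(mask)
            assert fmax == pytest.approx(omax, rel=1e-9)
            # the 1 deg production sweep can only overestimate the 0.1 deg
            # oracle minimum, by at most the coarse-grid projection error
            assert omin * (1 - 1e-12) <= fmin <= omin * 1.01
            assert fmax >= fmin
            checked += 1


class TestDropletGeometry:
    def test_sphere_case(self):
        V, A = droplet_geometry(2.0, 2.0)
        assert V == pytest.approx(4.18879, abs=1e-4)
        assert A == pytest.approx(math.pi, rel=1e-12)

    def test_prolate_volume_closed_form(self):
        V, _ = droplet_geometry(4.0, 2.0)
        assert V == pytest.approx(8 * math.pi / 3, rel=1e-12)

    def test_equivalent_sphere_area(self):
        _, A = droplet_geometry(4.0, 2.0)  # r_eq = 2^(1/3)
        assert A == pytest.approx(math.pi * 2 ** (2 / 3), rel=1e-12)
        assert A == pytest.approx(4.987, abs=1e-3)

    def test_swapped_inputs_warn_and_reorder(self):
        with pytest.warns(UserWarning, match="swapped"):
            assert droplet_geometry(2.0, 4.0) == droplet_geometry(4.0, 2.0)

    @given(
        a=st.floats(0.5, 20.0), b=st.floats(0.5, 20.0),
        da=st.floats(0.01, 5.0), db=st.floats(0.01, 5.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_volume_monotone_in_both_diameters(self, a, b, da, db):
        hi, lo = max(a, b), min(a, b)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v0, a0 = droplet_geometry(hi, lo)
            v1, _ = droplet_geometry(hi + da, lo)
            v2, _ = droplet_geometry(hi, lo + db)
        assert v1 > v0 and v2 > v0

    @given(d=st.floats(0.1, 50.0))
    @settings(max_examples=100, deadline=None)
    def test_sphere_consistency(self, d):
        """Equal diameters reduce the standardized area to pi d^2/4."""
        _, A = droplet_geometry(d, d)
        assert A == pytest.approx(math.pi * d**2 / 4, rel=1e-9)


class TestSegmentation:
    def test_blank_image_has_no_cell(self, seg_params):
        with pytest.raises(SegmentationError, match="no cell|blank"):
            segment_image(np.full((64, 64), 500, dtype=np.uint16), seg_params)

    def test_finds_exactly_the_rendered_droplets(self, seg_params):
        spec = SyntheticCellSpec(n_cells=1, droplet_count_law=("fixed", 2),
                                 droplet_volume_law=("lognormal", 20.0, 5.0), seed=3)
        images, truth = generate_cell_image_set(spec)
        seg = segment_image(images[0], seg_params)
        assert len(seg.droplet_masks) == 2

    def test_subminimum_droplet_is_filtered(self):
        spec = SyntheticCellSpec(n_cells=1, droplet_count_law=("fixed", 1),
                                 droplet_volume_law=("fixed", 0.05),  # ~0.45 um circle
                                 droplet_aspect_law=(1.0, 1.0), seed=4)
        images, _ = generate_cell_image_set(spec)
        params = SegmentationParams(pixel_size_um=0.1, min_droplet_area_px=40)
        seg = segment_image(images[0], params)
        assert len(seg.droplet_masks) == 0

    def test_droplet_free_cell_yields_no_droplets(self, seg_params):
        spec = SyntheticCellSpec(n_cells=1, droplet_count_law=("fixed", 0), seed=5)
        images, _ = generate_cell_image_set(spec)
        seg = segment_image(images[0], seg_params)
        assert len(seg.droplet_masks) == 0
        # cell area recovered within 2% of the rendered disk
        spec_area_px = math.pi * (spec.cell_diameter_um / 2 / spec.pixel_size_um) ** 2
        assert seg.cell_mask.sum() == pytest.approx(spec_area_px, rel=0.02)


class TestMeasureCell:
    def test_no_droplets_means_zero_lipid(self, seg_params):
        spec = SyntheticCellSpec(n_cells=1, droplet_count_law=("fixed", 0), seed=6)
        images, _ = generate_cell_image_set(spec)
        cell = measure_cell(images[0], seg_params)
        assert cell.n_droplets == 0
        assert cell.total_volume_um3 == 0.0
        assert cell.normalized_lipid_area == 0.0

    def test_normalized_area_arithmetic(self):
        droplet = DropletMeasurement(2.0, 2.0, 4.19, math.pi, (0, 0))
        cell = CellMeasurement(cell_area_um2=62.83, droplets=(droplet, droplet))
        assert cell.normalized_lipid_area == pytest.approx(0.1, rel=1e-3)

    def test_recovers_true_total_volume(self, seg_params):
        spec = cell_spec_for_total_volume(170.3, 58.6, n_cells=8, seed=8)
        images, truth = generate_cell_image_set(spec)
        for img, (_, row) in zip(images, truth.cells.iterrows()):
            cell = measure_cell(img, seg_params)
            assert cell.n_droplets == row.n_droplets
            assert cell.total_volume_um3 == pytest.approx(row.total_volume_um3, rel=0.10)

    def test_population_mean_volume_is_unbiased(self, seg_params):
        """Median relative error of the mean recovered volume over seeds."""
        errors = []
        for seed in range(12):
            spec = cell_spec_for_total_volume(60.0, 25.0, n_cells=10, seed=seed)
            images, truth = generate_cell_image_set(spec)
            cells = measure_image_set(images, seg_params)
            est = np.mean([c.total_volume_um3 for c in cells])
            errors.append(abs(est - truth.cells.total_volume_um3.mean())
                          / truth.cells.total_volume_um3.mean())
        assert np.median(errors) < 0.10


class TestPopulationSummary:
    def _identical_cells(self, n):
        droplet = DropletMeasurement(2.0, 2.0, 4.19, math.pi, (0, 0))
        return [CellMeasurement(cell_area_um2=100.0, droplets=(droplet,))] * n

    def test_identical_cells_have_zero_spread(self):
        s = population_summary(self._identical_cells(60), n_subsample=20, seed=0)
        assert s.n_cells == 20
        assert s.sd_normalized_area == pytest.approx(0.0, abs=1e-12)
        assert s.mean_normalized_area == pytest.approx(math.pi / 100)

    def test_seeded_subsample_is_reproducible(self):
        spec = cell_spec_for_total_volume(40.0, 15.0, n_cells=6, seed=9)
        images, _ = generate_cell_image_set(spec)
        cells = measure_image_set(images, SegmentationParams(pixel_size_um=0.1))
        s1 = population_summary(cells, n_subsample=4, seed=123)
        s2 = population_summary(cells, n_subsample=4, seed=123)
        assert s1.measurements == s2.measurements

    def test_small_population_uses_all_with_flag(self):
        s = population_summary(self._identical_cells(5), n_subsample=20)
        assert s.used_all and s.n_cells == 5

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            population_summary([])


class TestLipidIndex:
    def test_identical_summaries(self):
        cells = [CellMeasurement(100.0, (DropletMeasurement(2, 2, 4.19, math.pi, (0, 0)),))] * 5
        s = population_summary(cells, n_subsample=5)
        assert lipid_index(s, s) == 1.0

    def test_fourfold_ratio(self):
        d = DropletMeasurement(2, 2, 4.19, math.pi, (0, 0))
        s1 = population_summary([CellMeasurement(100.0, (d,))] * 5, n_subsample=5)
        s4 = population_summary([CellMeasurement(25.0, (d,))] * 5, n_subsample=5)
        assert lipid_index(s4, s1) == pytest.approx(4.0)

    def test_end_to_end_matches_generator_truth(self, seg_params):
        """IL computed from rendered images tracks the true normalized-area
        ratio of the immediate-onset lipid distributions."""
        summaries, truths = {}, {}
        for cond, (mean, sd), seed in (("static", (22.0, 18.1), 21),
                                       ("perturbed", (170.3, 58.6), 22)):
            spec = cell_spec_for_total_volume(mean, sd, n_cells=25, seed=seed)
            images, truth = generate_cell_image_set(spec)
            cells = measure_image_set(images, seg_params)
            summaries[cond] = population_summary(cells, n_subsample=25)
            truths[cond] = truth.cells.normalized_lipid_area_true.mean()
        il = lipid_index(summaries["perturbed"], summaries["static"])
        assert il == pytest.approx(truths["perturbed"] / truths["static"], rel=0.15)

    def test_paired_test_of_identical_cell_sets_is_null(self):
        values = [0.1, 0.12, 0.15, 0.11]
        t, p = paired_ttest(values, values)
        assert p == 1.0


class TestLipidProductionRate:
    def test_stationary_accumulation_rate(self):
        assert lipid_production_rate(180.0, 350.0) == pytest.approx(0.514, abs=1e-3)

    def test_rejects_nonpositive_interval(self):
        with pytest.raises(ValueError):
            lipid_production_rate(180.0, 0.0)
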