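"""Segmentation, medial-axis morphometry, constrictions, classification."""

import numpy as np
import pytest

from icmkaryo import densitometry, morphometry, sizing, synthetic
from icmkaryo.errors import (
    AxisError,
    NoConstrictionError,
    SegmentationError,
    ValidationError,
)
from icmkaryo.synthetic import ChromosomePairSpec, ImageParams, KaryotypeSpec


class TestSegmentation:
    def test_finds_all_20_chromosomes_with_high_overlap(self, measured_plate):
        assert len(measured_plate.masks) == 20
        shape = measured_plate.image.pixels.shape
        for mask in measured_plate.masks:
            best = 0.0
            for t in measured_plate.truth.chromosomes:
                g = t.full_mask(shape)
                inter = np.logical_and(mask, g).sum()
                if inter:
                    best = max(best, inter / mask.sum())
            assert best >= 0.98

    def test_blank_image_raises(self):
        with pytest.raises(SegmentationError, match="no objects"):
            morphometry.segment_chromosomes(np.zeros((64, 64)))

    def test_touching_chromosomes_split_by_watershed(self):
        params = ImageParams(seed=3, canvas_shape=(300, 700))
        image, truth = synthetic.render_touching_fixture(params)
        i0 = densitometry.estimate_background(image.pixels)
        od = densitometry.to_od(image.pixels, i0, params.pixel_size_um)
        masks = morphometry.segment_chromosomes(od)
        assert len(masks) == 4  # merged pair split in two + two singles
        areas = sorted(int(m.sum()) for m in masks)
        assert areas[2] / areas[3] > 0.9  # split halves are near-equal

    def test_expected_count_mismatch_warns(self, plate):
        with pytest.warns(UserWarning, match="expected 19"):
            morphometry.segment_chromosomes(plate.od, expected_count=19)


class TestMedialAxis:
    def test_rectangle_length_and_width(self):
        um = 0.08
        mask = np.zeros((60, 200), bool)
        mask[20 : 20 + round(1 / um), 10 : 10 + round(10 / um)] = True
        ax = morphometry.medial_axis_profile(mask, um)
        assert ax.total_length_um == pytest.approx(10.0, abs=0.2)
        mid = slice(len(ax) // 4, 3 * len(ax) // 4)
        assert float(np.median(ax.width_um[mid])) == pytest.approx(1.0, abs=0.1)

    def test_curved_chromosome_lengths_within_3_percent(self, measured_plate):
        for m in measured_plate.measurements:
            true = measured_plate.spec.pair(m.pair_id).total_um
            assert m.total_length_um == pytest.approx(true, rel=0.03)

    def test_disconnected_mask_raises(self):
        mask = np.zeros((50, 50), bool)
        mask[5:15, 5:45] = True
        mask[30:40, 5:45] = True
        with pytest.raises(AxisError, match="connected"):
            morphometry.medial_axis_profile(mask, 0.08)


class TestCentromere:
    def test_symmetric_dip_at_midpoint_gives_ci_50(self):
        n = 101
        w = 1.0 - 0.4 * np.exp(-0.5 * ((np.arange(n) - 50) / 8.0) ** 2)
        assert morphometry.locate_centromere(w) == 50

    def test_submetacentric_ci_recovered_within_2_points(self):
        """A rendered arm-ratio-2 chromosome yields CI within +-2 of 33.3."""
        pair = ChromosomePairSpec(
            1, short_arm_um=2.5, long_arm_um=5.0, dna_pair_2C_pg=0.6,
            arm_dna_fractions={"S": 1 / 3, "L": 2 / 3},
        )
        spec = KaryotypeSpec((pair,), 0.6)
        params = ImageParams(seed=9, noise_sd=0.0, canvas_shape=(256, 256))
        image, truth = synthetic.render_metaphase(spec, params, straight=True)
        od = densitometry.to_od(image.pixels, params.background, params.pixel_size_um)
        masks = morphometry.segment_chromosomes(od)
        assert len(masks) == 2  # two homologs of the single pair
        for mask in masks:
            m = morphometry.measure_chromosome(od, mask)
            assert m.ci == pytest.approx(33.3, abs=2.0)

    def test_monotone_wedge_has_no_constriction(self):
        w = np.linspace(0.5, 1.0, 80)
        with pytest.raises(NoConstrictionError):
            morphometry.locate_centromere(w)

    def test_flat_profile_has_no_constriction(self):
        with pytest.raises(NoConstrictionError):
            morphometry.locate_centromere(np.full(60, 1.0))


class TestSecondaryConstriction:
    def test_satellited_pair_boundary_close_to_truth(self, measured_plate):
        sats = [
            m for m in measured_plate.by_pair[6] if m.sat_index is not None
        ]
        assert len(sats) >= 1
        true_sat = measured_plate.spec.pair(6).satellite_um
        for m in sats:
            measured = m.lengths_um["SAT"]
            # boundary within 3 axis samples (~0.25 um) of the true split
            assert measured == pytest.approx(true_sat, abs=0.25)

    def test_plain_chromosomes_have_no_satellite(self, measured_plate):
        for pid, ms in measured_plate.by_pair.items():
            if pid == 6:
                continue
            assert all(m.sat_index is None for m in ms), pid

    def test_detection_can_be_disabled(self, measured_plate):
        m6 = measured_plate.by_pair[6][0]
        remeasured = morphometry.measure_chromosome(
            measured_plate.od, m6.mask, detect_satellite=False
        )
        assert remeasured.sat_index is None


class TestPartition:
    def test_partition_is_disjoint_and_exhaustive(self, measured_plate):
        for m in measured_plate.measurements:
            union = np.zeros(m.mask.shape, bool)
            total = 0
            for sub in m.arm_masks.values():
                assert not (union & sub).any()
                union |= sub
                total += sub.sum()
            assert np.array_equal(union, m.mask)
            assert total == m.mask.sum()

    def test_arm_iods_sum_to_chromosome_iod(self, measured_plate):
        for m in measured_plate.measurements:
            assert m.iod == pytest.approx(
                sum(s.iod for s in m.arm_stats.values()), rel=1e-12
            )

    def test_per_arm_areas_within_5_percent_of_truth(self, measured_plate):
        shape = measured_plate.image.pixels.shape
        errs = []
        for m in measured_plate.measurements:
            t = max(
                (t for t in measured_plate.truth.chromosomes),
                key=lambda t: np.logical_and(t.full_mask(shape), m.mask).sum(),
            )
            region_full = np.full(shape, 255, np.uint8)
            r0, r1, c0, c1 = t.bbox
            region_full[r0:r1, c0:c1] = t.region_local
            code = {"SAT": 0, "S": 1, "L": 2}
            for arm, sub in m.arm_masks.items():
                true_area = (region_full == code[arm]).sum()
                if true_area:
                    errs.append(abs(sub.sum() - true_area) / true_area)
        assert np.median(errs) < 0.05

    def test_centromere_on_boundary_rejected(self, measured_plate):
        m = measured_plate.measurements[0]
        with pytest.raises(ValidationError):
            morphometry.partition_arms(m.mask, m.axis, 0)

    def test_ci_and_long_share_sum_to_100(self, measured_plate):
        for m in measured_plate.measurements:
            long_share = 100.0 * m.long_um / (m.short_um + m.long_um)
            assert m.ci + long_share == pytest.approx(100.0, abs=1e-9)


class TestClassification:
    @pytest.mark.parametrize(
        "r,label",
        [
            (1.0, "M"),
            (1.2, "m"),
            (1.49999, "m"),
            (1.5, "sm"),
            (2.0, "sm"),
            (2.9999, "sm"),
            (3.0, "st"),
            (6.5, "st"),
            (7.0, "t"),
            (40.0, "t"),
        ],
    )
    def test_guerra_threshold_table(self, r, label):
        assert morphometry.classify_class(r) == label

    def test_ratio_below_one_rejected(self):
        with pytest.raises(ValidationError, match="mislabel"):
            morphometry.classify_class(0.8)

    def test_maize_defaults_classify_2m_8sm(self, measured_plate):
        labels = {}
        for pid, ms in measured_plate.by_pair.items():
            labels[pid] = morphometry.classify_class(
                float(np.mean([m.arm_ratio for m in ms]))
            )
        assert [labels[p] for p in (1, 5)] == ["m", "m"]
        assert all(labels[p] == "sm" for p in (2, 3, 4, 6, 7, 8, 9, 10))


class TestKnobBands:
    def test_uniform_chromosome_has_no_bands(self, measured_plate):
        for pid in (1, 5, 10):
            for m in measured_plate.by_pair[pid]:
                assert morphometry.knob_band_profile(
                    measured_plate.od, m.mask, m.axis
                ) == []

    def test_knobbed_long_arms_show_a_band_overlapping_truth(self, measured_plate):
        spec = measured_plate.spec
        found = 0
        for pid in (2, 3, 4, 7, 8, 9):
            pair = spec.pair(pid)
            knob = pair.knobs[0]
            centre = pair.satellite_um + pair.short_arm_um + knob.rel_pos * pair.long_arm_um
            for m in measured_plate.by_pair[pid]:
                bands = morphometry.knob_band_profile(measured_plate.od, m.mask, m.axis)
                # the knob may sit at either end of the measured axis
                hits = [
                    b for b in bands
                    if b.start_um - 0.6 <= centre <= b.stop_um + 0.6
                    or b.start_um - 0.6 <= m.total_length_um - centre <= b.stop_um + 0.6
                ]
                found += bool(hits)
        assert found >= 10  # of 12 knobbed chromosomes on the plate

    def test_band_count_rises_across_detection_threshold(self):
        """The same chromosome gains a knob band once the density multiplier
        crosses the 1.3x linear-density rule."""
        counts = {}
        for mult in (1.05, 2.2):
            pair = ChromosomePairSpec(
                1, 2.5, 5.0, 0.6, arm_dna_fractions={"S": 1 / 3, "L": 2 / 3},
                knobs=(synthetic.KnobBlock("L", 0.5, 1.0, mult),),
            )
            spec = KaryotypeSpec((pair,), 0.6)
            params = ImageParams(seed=5, noise_sd=0.0, canvas_shape=(256, 256))
            image, truth = synthetic.render_metaphase(spec, params, straight=True)
            od = densitometry.to_od(
                image.pixels, params.background, params.pixel_size_um
            )
            mask = morphometry.segment_chromosomes(od)[0]
            m = morphometry.measure_chromosome(od, mask)
            counts[mult] = len(
                morphometry.knob_band_profile(od, mask, m.axis)
            )
        assert counts[1.05] == 0
        assert counts[2.2] >= 1
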