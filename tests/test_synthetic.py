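"""Synthetic generator: default karyotype, rendering physics, determinism."""

import numpy as np
import pytest

from icmkaryo import synthetic
from icmkaryo.errors import ValidationError
from icmkaryo.synthetic import (
    ChromosomePairSpec,
    ImageParams,
    KaryotypeSpec,
    KnobBlock,
    default_maize_spec,
    render_calibration_targets,
    render_metaphase,
    simulate_fcm_histogram,
)


class TestDefaultSpec:
    def test_complement_totals_match_published_values(self):
        spec = default_maize_spec(0)
        assert len(spec.pairs) == 10
        assert spec.nuclear_2C_pg == pytest.approx(6.10, abs=0.005)
        assert spec.pair(6).arm_dna_pg("SAT") == pytest.approx(0.053, abs=1e-9)
        assert spec.pair(9).dna_pair_2C_pg == pytest.approx(0.561, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 3, 17])
    def test_exactly_one_satellited_pair(self, seed):
        spec = default_maize_spec(seed)
        satellited = [p for p in spec.pairs if p.satellite_um > 0]
        assert [p.pair_id for p in satellited] == [6]

    def test_arm_ratios_fall_in_class_bands(self):
        spec = default_maize_spec(0)
        for p in spec.pairs:
            # satellite counts with the short arm for the class-defining ratio
            r = p.long_arm_um / (p.short_arm_um + p.satellite_um)
            if p.pair_id in (1, 5):
                assert r < 1.5
            else:
                assert 1.5 <= r < 3.0

    def test_knobs_sit_on_long_arms_of_pairs_2_to_9(self):
        spec = default_maize_spec(0)
        knobbed = {p.pair_id for p in spec.pairs if p.knobs}
        assert knobbed == {2, 3, 4, 6, 7, 8, 9}
        assert all(k.arm == "L" for p in spec.pairs for k in p.knobs)

    def test_dna_must_sum_to_nuclear_value(self):
        pair = ChromosomePairSpec(1, 2.0, 3.0, 1.0)
        with pytest.raises(ValidationError):
            KaryotypeSpec((pair,), nuclear_2C_pg=2.0)


def _single_pair_spec(**overrides):
    kw = dict(
        pair_id=1, short_arm_um=3.0, long_arm_um=4.0, dna_pair_2C_pg=0.8,
        arm_dna_fractions={"S": 0.45, "L": 0.55},
    )
    kw.update(overrides)
    pair = ChromosomePairSpec(**kw)
    return KaryotypeSpec((pair,), pair.dna_pair_2C_pg)


class TestRenderMetaphase:
    def test_seeded_render_is_bit_identical(self, maize_spec):
        params = ImageParams(seed=11)
        img1, _ = render_metaphase(maize_spec, params)
        img2, _ = render_metaphase(maize_spec, params)
        assert np.array_equal(img1.pixels, img2.pixels)

    def test_noiseless_pixel_sum_recovers_true_integrated_od(self):
        spec = _single_pair_spec()
        params = ImageParams(seed=0, noise_sd=0.0, canvas_shape=(256, 256))
        image, truth = render_metaphase(spec, params, straight=True)
        t = truth.chromosomes[0]
        mask = t.full_mask(image.pixels.shape)
        od = np.log10(params.background / np.clip(image.pixels.astype(float), 0.5, None))
        recovered = od[mask].sum() * params.pixel_area_um2
        assert recovered == pytest.approx(t.iod, rel=0.01)

    def test_homologs_carry_equal_true_iod(self, plate):
        by_pair = {}
        for t in plate.truth.chromosomes:
            by_pair.setdefault(t.pair_id, []).append(t.iod)
        for pair_id, iods in by_pair.items():
            assert iods[0] == pytest.approx(iods[1], rel=1e-9), pair_id

    def test_conservation_single_global_od_constant(self, noiseless_plate):
        """Total integrated OD of every chromosome is proportional to its DNA
        with one slide-wide constant."""
        truth = noiseless_plate.truth
        spec = noiseless_plate.spec
        ratios = [
            t.iod / (spec.pair(t.pair_id).dna_pair_2C_pg / 2.0)
            for t in truth.chromosomes
        ]
        assert np.ptp(ratios) / np.mean(ratios) < 1e-3

    def test_knob_multiplier_raises_local_density_not_arm_total(self):
        """A stronger knob concentrates the arm's DNA without changing arm
        totals (conservation) or touching the other arm."""
        base = _single_pair_spec(knobs=(KnobBlock("L", 0.5, 1.0, 1.5),))
        strong = _single_pair_spec(knobs=(KnobBlock("L", 0.5, 1.0, 2.5),))
        params = ImageParams(seed=4, noise_sd=0.0, canvas_shape=(256, 256))
        peak = {}
        for name, spec in (("base", base), ("strong", strong)):
            _, truth = render_metaphase(spec, params, straight=True)
            t = truth.chromosomes[0]
            assert t.arm_iod["L"] == pytest.approx(
                0.8 * 0.55 / 2.0 * params.iod_per_pg, rel=1e-9
            )
            assert t.arm_iod["S"] == pytest.approx(
                0.8 * 0.45 / 2.0 * params.iod_per_pg, rel=1e-9
            )
            peak[name] = truth.od_true.max()
        assert peak["strong"] > peak["base"]

    def test_placement_failure_names_the_conflict(self):
        params = ImageParams(seed=0, canvas_shape=(80, 80))
        with pytest.raises(synthetic.PlacementError, match="canvas"):
            render_metaphase(default_maize_spec(0), params, max_attempts=5)


class TestCalibrationTargets:
    def test_noise_free_bands_are_exact(self):
        params = ImageParams(seed=0, noise_sd=0.0)
        targets = render_calibration_targets(params)
        for odk, mask in zip(targets.step_ods, targets.band_masks):
            expected = params.background * 10.0 ** (-odk)
            assert targets.stepped_image[mask].mean() == pytest.approx(expected, abs=1e-9)
        assert np.all(targets.blank_image == params.background)

    def test_step_ods_must_increase(self):
        with pytest.raises(ValidationError):
            render_calibration_targets(ImageParams(seed=0), step_ods=[0.3, 0.2, 0.4])


class TestFCMSimulation:
    def test_sample_peak_lands_at_channel_219(self):
        h = simulate_fcm_histogram(5.57, 6.10, 3.2, 3.8, n_nuclei=200_000, seed=5)
        assert h.metadata["sample_channel"] == pytest.approx(219.0, abs=0.1)
        # empirical mode of the upper component
        upper = h.counts[210:230]
        assert abs((210 + np.argmax(upper)) - 219) <= 2

    def test_degenerate_cv_collapses_to_two_channels(self):
        h = simulate_fcm_histogram(5.0, 10.0, 1e-6, 1e-6, n_nuclei=5000, seed=1)
        assert (h.counts > 0).sum() == 2

    def test_overlapping_peaks_flagged(self):
        near = simulate_fcm_histogram(5.57, 5.70, 3.8, 3.8, n_nuclei=1000, seed=1)
        far = simulate_fcm_histogram(5.57, 9.0, 3.8, 3.8, n_nuclei=1000, seed=1)
        assert near.metadata["overlap_warning"]
        assert not far.metadata["overlap_warning"]
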