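"""Shared fixtures: one rendered, measured synthetic metaphase plate.

Session-scoped so the (sub-second, but repeated) rendering and measurement
work is shared across test modules.
"""

from types import SimpleNamespace

import pytest

from icmkaryo import densitometry, morphometry, synthetic
from icmkaryo.pipeline import match_measurements_to_truth


@pytest.fixture(scope="session")
def maize_spec():
    return synthetic.default_maize_spec(0)


@pytest.fixture(scope="session")
def plate(maize_spec):
    """One default-noise rendered plate with its OD map and ground truth."""
    params = synthetic.ImageParams(seed=1)
    image, truth = synthetic.render_metaphase(maize_spec, params)
    i0 = densitometry.estimate_background(image.pixels)
    od = densitometry.to_od(image.pixels, i0, params.pixel_size_um)
    return SimpleNamespace(
        spec=maize_spec, params=params, image=image, truth=truth, od=od, i0=i0
    )


@pytest.fixture(scope="session")
def measured_plate(plate):
    """The same plate segmented and measured, with ground-truth pair ids."""
    masks = morphometry.segment_chromosomes(plate.od, expected_count=20)
    measurements = [morphometry.measure_chromosome(plate.od, m) for m in masks]
    match_measurements_to_truth(measurements, plate.truth, plate.image.pixels.shape)
    by_pair: dict[int, list] = {}
    for m in measurements:
        by_pair.setdefault(m.pair_id, []).append(m)
    return SimpleNamespace(
        **vars(plate), masks=masks, measurements=measurements, by_pair=by_pair
    )


@pytest.fixture(scope="session")
def noiseless_plate(maize_spec):
    """A noise-free, gradient-free rendering for exact-recovery checks."""
    params = synthetic.ImageParams(seed=2, noise_sd=0.0)
    image, truth = synthetic.render_metaphase(maize_spec, params)
    od = densitometry.to_od(image.pixels, params.background, params.pixel_size_um)
    return SimpleNamespace(spec=maize_spec, params=params, image=image, truth=truth, od=od)
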