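"""Shared fixtures: fixture cohort, synthetic slides, preprocessed matrices."""

import numpy as np
import pytest

from ploidyims import clinstats, discover, imsproc, synthgen


@pytest.fixture(scope="session")
def tma_records():
    return clinstats.load_tma_cohort()


@pytest.fixture(scope="session")
def tumor_records(tma_records):
    return clinstats.select(tma_records, "tumor")


@pytest.fixture(scope="session")
def noisy_slide():
    """Default-condition two-class slide: noise, jitter, and null pixels."""
    spec = synthgen.two_region_slide_spec(
        seed=11, noise_sd=0.5, ppm_jitter_sd=100.0, null_pixel_fraction=0.02
    )
    return synthgen.generate_ims_slide(spec)


@pytest.fixture(scope="session")
def zero_noise_slide():
    spec = synthgen.two_region_slide_spec(
        seed=7,
        planted_peaks=synthgen.default_two_class_peaks(cv=0.0),
    )
    return synthgen.generate_ims_slide(spec)


@pytest.fixture(scope="session")
def processed_noisy(noisy_slide):
    ds, masks = noisy_slide
    proc, log = imsproc.preprocess(ds)
    return proc, masks, log


@pytest.fixture(scope="session")
def discovery_matrix(processed_noisy):
    """Windows picked on the grand average plus the ROI-labeled peak matrix."""
    proc, masks, _ = processed_noisy
    avg = imsproc.class_average(list(proc.pixels.values()))
    windows = imsproc.pick_peaks(avg)
    rois = [
        discover.ROI(lab, {(int(x), int(y)) for x, y in zip(*np.nonzero(masks[lab]))})
        for lab in sorted(masks)
    ]
    matrix = discover.extract_roi_matrix(proc, rois, windows)
    return windows, matrix
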